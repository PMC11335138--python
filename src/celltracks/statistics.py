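"""Effect sizes and replicate-aware hypothesis tests for condition contrasts.

Two complementary tests are provided for each pair of groups:

* a label-randomization (permutation) test on the absolute Cohen's *d*,
  with exhaustive enumeration whenever the number of group assignments is
  small enough and a seeded Monte-Carlo approximation otherwise; the
  Monte-Carlo estimate uses the add-one convention
  ``p = (1 + #extreme) / (1 + n_iter)`` so p is never exactly 0;
* a SuperPlots-style bootstrap t-test that treats the biological repeat as
  the experimental unit: tracks are resampled with replacement within each
  repeat, repeat means are averaged into a group mean, and the two bootstrap
  distributions of group means are compared with Welch's t-test.

Bonferroni correction multiplies each p by the number of comparisons and
caps at 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data_model_io import Dataset
from .errors import DegenerateVarianceError

logger = logging.getLogger(__name__)

EXHAUSTIVE_LIMIT = 20_000  # max number of enumerable group assignments


@dataclass
class ComparisonResult:
    """One pairwise group comparison with its provenance."""

    group_a: str
    group_b: str
    n_a: int
    n_b: int
    cohens_d: float
    p_randomization: float
    p_bootstrap_t: float | None
    p_adjusted: float | None
    n_iterations: int
    seed: int | None


def cohens_d(a, b) -> float:
    """Standardized mean difference (mean(a) - mean(b)) / pooled sample SD.

    NaN when both groups are constant and equal; an error when the pooled SD
    is zero but the means differ (the effect size is then unbounded).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError(f"cohens_d needs >= 2 values per group, got {len(a)} and {len(b)}")
    na, nb = len(a), len(b)
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    diff = a.mean() - b.mean()
    if pooled_var == 0:
        if diff == 0:
            return float("nan")
        raise DegenerateVarianceError("zero pooled SD with unequal means: d is unbounded")
    return float(diff / np.sqrt(pooled_var))


def _abs_d_from_assignments(pool: np.ndarray, a_idx: np.ndarray) -> np.ndarray:
    """|Cohen's d| for many group-A index sets at once (rows of a_idx)."""
    n = len(pool)
    na = a_idx.shape[1]
    nb = n - na
    total_sum = pool.sum()
    total_sq = (pool ** 2).sum()
    a_vals = pool[a_idx]
    sum_a = a_vals.sum(axis=1)
    sq_a = (a_vals ** 2).sum(axis=1)
    sum_b = total_sum - sum_a
    sq_b = total_sq - sq_a
    mean_a = sum_a / na
    mean_b = sum_b / nb
    var_a = (sq_a - na * mean_a ** 2) / (na - 1)
    var_b = (sq_b - nb * mean_b ** 2) / (nb - 1)
    pooled = ((na - 1) * var_a + (nb - 1) * var_b) / (na + nb - 2)
    pooled = np.clip(pooled, 0.0, None)  # numerical noise can drive it < 0
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.abs(mean_a - mean_b) / np.sqrt(pooled)
    return np.where(pooled == 0, 0.0, d)


def randomization_test(a, b, n_iter: int = 1000, seed: int | None = None) -> float:
    """Permutation p-value for the absolute Cohen's d between two samples.

    All ``C(n_a+n_b, n_a)`` assignments are enumerated exactly when their
    number is at most ``EXHAUSTIVE_LIMIT`` (exact p = fraction at least as
    extreme); otherwise ``n_iter`` seeded random assignments are drawn and
    the add-one estimate is returned.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    d_obs = cohens_d(a, b)
    if np.isnan(d_obs):
        return 1.0
    # |d| is invariant under swapping the groups (complement assignment), so
    # working on the sorted pool with the smaller group size makes the null
    # distribution — and hence the Monte-Carlo p — exactly swap-invariant
    pool = np.sort(np.concatenate([a, b]))
    k = min(len(a), len(b))
    n = len(pool)
    n_comb = comb(n, k)
    if n_comb <= EXHAUSTIVE_LIMIT:
        a_idx = np.array(list(combinations(range(n), k)), dtype=np.intp)
        d_null = _abs_d_from_assignments(pool, a_idx)
        return float((d_null >= abs(d_obs) - 1e-12).sum() / n_comb)
    rng = np.random.default_rng(seed)
    # vectorized permutations: argsort of uniform draws gives random orders
    perm = np.argsort(rng.random((n_iter, n)), axis=1)[:, :k]
    d_null = _abs_d_from_assignments(pool, perm)
    n_extreme = int((d_null >= abs(d_obs) - 1e-12).sum())
    return float((1 + n_extreme) / (1 + n_iter))


def bootstrap_superplot_test(
    values_by_repeat_a: dict[str, np.ndarray],
    values_by_repeat_b: dict[str, np.ndarray],
    n_boot: int = 1000,
    seed: int | None = None,
) -> float:
    """Bootstrap t-test on group means with the repeat as experimental unit.

    Per iteration, tracks are resampled with replacement within each repeat;
    repeat means are averaged into one group mean.  The two bootstrap
    distributions of group means are compared with a two-sample
    unequal-variance (Welch) t-test.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2: a single bootstrap draw has no distribution")
    for label, group in (("a", values_by_repeat_a), ("b", values_by_repeat_b)):
        if len(group) < 2:
            raise ValueError(f"group {label} needs >= 2 repeats, got {len(group)}")
        for rep, vals in group.items():
            if len(np.asarray(vals)) < 2:
                raise ValueError(f"repeat {rep!r} of group {label} has < 2 tracks")
    rng = np.random.default_rng(seed)

    def boot_means(group: dict[str, np.ndarray]) -> np.ndarray:
        rep_means = np.empty((n_boot, len(group)))
        for j, vals in enumerate(group.values()):
            vals = np.asarray(vals, dtype=float)
            idx = rng.integers(0, len(vals), size=(n_boot, len(vals)))
            rep_means[:, j] = vals[idx].mean(axis=1)
        return rep_means.mean(axis=1)

    means_a = boot_means(values_by_repeat_a)
    means_b = boot_means(values_by_repeat_b)
    if means_a.std() == 0 and means_b.std() == 0 and means_a.mean() == means_b.mean():
        return 1.0
    p = sps.ttest_ind(means_a, means_b, equal_var=False).pvalue
    return float(max(p, np.finfo(float).tiny))


def adjust_bonferroni(p_values, m: int | None = None) -> list[float]:
    """Bonferroni adjustment: each p becomes min(1, p * m), order preserved."""
    p_values = list(p_values)
    for p in p_values:
        if not 0 <= p <= 1:
            raise ValueError(f"p-value outside [0, 1]: {p}")
    if m is None:
        m = len(p_values)
    return [min(1.0, p * m) for p in p_values]


def tukey_boxplot_stats(ds: Dataset, metric: str, by_repeat: bool = True) -> pd.DataFrame:
    """Tukey boxplot summary per condition (and repeat): quartiles, whiskers
    at the last datum within 1.5 x IQR, and 10 x IQR axis-limit metadata."""
    if metric not in ds.tracks.columns:
        raise KeyError(f"metric column {metric!r} not in track table")
    keys = ["condition", "repeat"] if by_repeat else ["condition"]
    rows = []
    for key, grp in ds.tracks.groupby(keys, sort=True):
        vals = grp[metric].dropna().to_numpy(float)
        if len(vals) == 0:
            continue
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        in_lo = vals[vals >= lo_fence]
        in_hi = vals[vals <= hi_fence]
        row = dict(zip(keys, key if isinstance(key, tuple) else (key,)))
        row.update(metric=metric, n=len(vals), q1=q1, median=med, q3=q3,
                   whisker_low=in_lo.min() if len(in_lo) else q1,
                   whisker_high=in_hi.max() if len(in_hi) else q3,
                   axis_low=med - 10 * iqr, axis_high=med + 10 * iqr)
        rows.append(row)
    return pd.DataFrame(rows)


def pairwise_comparison_matrix(
    ds: Dataset,
    metric: str,
    test: str = "randomization",
    adjust: bool = True,
    n_iter: int = 1000,
    seed: int | None = None,
) -> tuple[list[ComparisonResult], pd.DataFrame]:
    """All pairwise condition comparisons for one track metric.

    Returns the list of :class:`ComparisonResult` and a mirrored condition
    matrix with Cohen's d above the diagonal and the (adjusted) p-value
    below.  ``test`` selects which p fills the matrix: ``"randomization"``
    or ``"bootstrap"``.  Non-finite metric values are dropped per pair with
    a logged count.
    """
    if metric not in ds.tracks.columns:
        raise KeyError(f"metric column {metric!r} not in track table")
    if test not in ("randomization", "bootstrap"):
        raise ValueError(f"unknown test {test!r}")
    conditions = sorted(ds.tracks["condition"].unique())
    if len(conditions) < 2:
        raise ValueError("need >= 2 conditions for pairwise comparison")
    pairs = list(combinations(conditions, 2))
    m = len(pairs)

    results: list[ComparisonResult] = []
    for k, (ca, cb) in enumerate(pairs):
        sub_a = ds.tracks[ds.tracks["condition"] == ca]
        sub_b = ds.tracks[ds.tracks["condition"] == cb]
        va = sub_a[metric].to_numpy(float)
        vb = sub_b[metric].to_numpy(float)
        dropped = int((~np.isfinite(va)).sum() + (~np.isfinite(vb)).sum())
        if dropped:
            logger.info("pair (%s, %s): dropped %d non-finite %s values", ca, cb, dropped, metric)
        va = va[np.isfinite(va)]
        vb = vb[np.isfinite(vb)]
        pair_seed = None if seed is None else seed + k
        d = cohens_d(va, vb)
        p_rand = randomization_test(va, vb, n_iter=n_iter, seed=pair_seed)
        p_boot: float | None = None
        if test == "bootstrap":
            by_rep_a = {r: g.loc[np.isfinite(g[metric]), metric].to_numpy(float)
                        for r, g in sub_a.groupby("repeat")}
            by_rep_b = {r: g.loc[np.isfinite(g[metric]), metric].to_numpy(float)
                        for r, g in sub_b.groupby("repeat")}
            p_boot = bootstrap_superplot_test(by_rep_a, by_rep_b, n_boot=n_iter, seed=pair_seed)
        results.append(ComparisonResult(
            group_a=ca, group_b=cb, n_a=len(va), n_b=len(vb), cohens_d=d,
            p_randomization=p_rand, p_bootstrap_t=p_boot, p_adjusted=None,
            n_iterations=n_iter, seed=pair_seed,
        ))

    raw = [r.p_bootstrap_t if test == "bootstrap" else r.p_randomization for r in results]
    adjusted = adjust_bonferroni(raw, m) if adjust else list(raw)
    for r, p_adj in zip(results, adjusted):
        r.p_adjusted = p_adj

    matrix = pd.DataFrame(np.nan, index=conditions, columns=conditions)
    for r in results:
        matrix.loc[r.group_a, r.group_b] = r.cohens_d  # upper triangle: d
        matrix.loc[r.group_b, r.group_a] = r.p_adjusted  # lower triangle: p
    return results, matrix


def comparison_results_frame(results: list[ComparisonResult]) -> pd.DataFrame:
    """Tidy one-row-per-pair export of comparison results."""
    return pd.DataFrame([vars(r) for r in results])
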