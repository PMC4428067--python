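"""Group comparison machinery with permutation-based multiplicity control.

Between-group differences in network metrics are assessed with the
Kruskal–Wallis rank test and corrected for multiple comparisons with a
max-statistic permutation scheme: group labels are permuted across
subjects, the whole family of tests is recomputed for every relabeling, and
each observed statistic is referred to the permutation distribution of the
family-wise maximum.  This controls the family-wise error rate without
distributional assumptions.

Two family definitions are used: for time-course comparisons the family is
every window of one metric; for span-averaged comparisons it is the five
network metrics within one span.
"""
from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sstats

from .network_metrics import NETWORK_METRICS, MetricSeries, average_windows

logger = logging.getLogger("netfluct")

ALPHA = 0.05


def kruskal_wallis(values_by_group: Sequence[np.ndarray]) -> tuple[float, float]:
    """Kruskal–Wallis H with tie correction and its chi-squared p-value.

    Degenerate input where every observation is identical gives H = 0,
    p = 1 (no evidence of a location difference).
    """
    samples = [np.asarray(s, dtype=float) for s in values_by_group]
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    if any(s.size < 2 for s in samples):
        raise ValueError("each group needs at least 2 observations")
    pooled = np.concatenate(samples)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = sstats.kruskal(*samples)
    return float(h), float(p)


def _kw_h_table(ranks: np.ndarray, tie_factor: np.ndarray,
                group_masks: np.ndarray) -> np.ndarray:
    """Vectorized tie-corrected H for a table of tests.

    ranks : (n, T) mid-ranks per test; tie_factor : (T,) tie-correction
    denominators; group_masks : (G, n) 0/1 group membership.  Returns (T,).
    """
    n = ranks.shape[0]
    sums = group_masks @ ranks  # (G, T)
    sizes = group_masks.sum(axis=1)  # (G,)
    h = 12.0 / (n * (n + 1)) * (sums**2 / sizes[:, None]).sum(axis=0) \
        - 3.0 * (n + 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        h = np.where(tie_factor > 0, h / tie_factor, 0.0)
    return np.maximum(h, 0.0)


def _rank_table(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mid-ranks and tie-correction factors per column of a (n, T) table."""
    ranks = sstats.rankdata(values, axis=0)
    n = values.shape[0]
    tie_factor = np.empty(values.shape[1])
    for t in range(values.shape[1]):
        _, counts = np.unique(values[:, t], return_counts=True)
        tie_factor[t] = 1.0 - ((counts**3 - counts).sum()) / (n**3 - n)
    return ranks, tie_factor


def _distinct_relabelings(labels: np.ndarray) -> int:
    vals, counts = np.unique(labels, return_counts=True)
    total = math.factorial(len(labels))
    for c in counts:
        total //= math.factorial(int(c))
    return total


@dataclass
class GroupComparison:
    """Raw and permutation-corrected p-values for one family of tests."""

    table: "object"  # pandas DataFrame: test, statistic, p_raw, p_corrected, significant
    family: str
    n_permutations: int
    seed: int
    exhaustive: bool
    group_sizes: dict
    alpha: float = ALPHA

    def significant_tests(self) -> list:
        return list(self.table.loc[self.table["significant"], "test"])

    def to_tsv(self, path, **extra) -> None:
        df = self.table.copy()
        for k, v in extra.items():
            df[k] = v
        df["family"] = self.family
        df["n_permutations"] = self.n_permutations
        df["seed"] = self.seed
        df.to_csv(path, sep="\t", index=False)


def permutation_correct(values: np.ndarray, groups: Sequence,
                        test_names: Sequence | None = None,
                        n_perm: int = 10_000, seed: int = 0,
                        family: str = "family",
                        alpha: float = ALPHA) -> GroupComparison:
    """Max-statistic permutation correction over a family of tests.

    Parameters
    ----------
    values : ndarray, shape (n_subjects, n_tests)
        One column per test in the family (e.g. one column per window).
    groups : sequence of labels, length n_subjects
        Group membership, permuted across subjects under the null.
    n_perm : int
        Number of random relabelings (the add-one estimator keeps every
        corrected p strictly positive).  When the number of distinct
        relabelings does not exceed ``n_perm`` the full enumeration is used
        instead and p-values are exact.

    The corrected p of a test compares its observed H with the permutation
    distribution of ``max_t H_t``; corrected p-values are additionally
    floored at the raw (chi-squared) p so that correction never *gains*
    significance.
    """
    import pandas as pd

    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[1] == 0:
        raise ValueError("values must be (n_subjects, n_tests), non-empty")
    labels = np.asarray(groups)
    if labels.shape[0] != values.shape[0]:
        raise ValueError("one group label per subject required")
    uniq, codes = np.unique(labels, return_inverse=True)
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    sizes = np.bincount(codes)
    if sizes.min() < 2:
        raise ValueError("each group needs at least 2 subjects")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    n, n_tests = values.shape
    if test_names is None:
        test_names = list(range(n_tests))

    ranks, tie_factor = _rank_table(values)
    obs_masks = np.stack([(codes == g).astype(float) for g in range(len(uniq))])
    h_obs = _kw_h_table(ranks, tie_factor, obs_masks)
    df_chi2 = len(uniq) - 1
    p_raw = np.where(tie_factor > 0, sstats.chi2.sf(h_obs, df_chi2), 1.0)

    n_distinct = _distinct_relabelings(labels)
    exhaustive = n_distinct <= n_perm and len(uniq) == 2
    if exhaustive:
        n1 = int(sizes[0])
        max_stats = np.empty(n_distinct)
        for k, combo in enumerate(itertools.combinations(range(n), n1)):
            mask0 = np.zeros(n)
            mask0[list(combo)] = 1.0
            masks = np.stack([mask0, 1.0 - mask0])
            max_stats[k] = _kw_h_table(ranks, tie_factor, masks).max()
        p_corr = (max_stats[None, :] >= h_obs[:, None] - 1e-12).mean(axis=1)
        n_used = n_distinct
        logger.info("%s: exhaustive enumeration over %d relabelings",
                    family, n_distinct)
    else:
        rng = np.random.default_rng(seed)
        perm_codes = rng.permuted(
            np.tile(codes, (n_perm, 1)), axis=1)  # (n_perm, n)
        max_stats = np.empty(n_perm)
        # group-sum via one matmul per group
        for g in range(len(uniq)):
            gm = (perm_codes == g).astype(float)  # (n_perm, n)
            part = (gm @ ranks) ** 2 / sizes[g]  # (n_perm, T)
            if g == 0:
                acc = part
            else:
                acc += part
        h_perm = 12.0 / (n * (n + 1)) * acc - 3.0 * (n + 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            h_perm = np.where(tie_factor[None, :] > 0,
                              h_perm / tie_factor[None, :], 0.0)
        max_stats = h_perm.max(axis=1)
        p_corr = ((1 + (max_stats[None, :] >= h_obs[:, None] - 1e-12).sum(axis=1))
                  / (1 + n_perm))
        n_used = n_perm

    p_corr = np.minimum(np.maximum(p_corr, p_raw), 1.0)
    table = pd.DataFrame({
        "test": list(test_names),
        "statistic": h_obs,
        "p_raw": p_raw,
        "p_corrected": p_corr,
        "significant": p_corr < alpha,
    })
    return GroupComparison(
        table=table,
        family=family,
        n_permutations=n_used,
        seed=seed,
        exhaustive=exhaustive,
        group_sizes={str(u): int(s) for u, s in zip(uniq, sizes)},
        alpha=alpha,
    )


def _metric_table(cohort: Sequence[MetricSeries], metric: str) -> np.ndarray:
    return np.stack([m.network[metric] for m in cohort])  # (subjects, W)


def compare_timecourses(cohort_a: Sequence[MetricSeries],
                        cohort_b: Sequence[MetricSeries],
                        metric: str = "S", n_perm: int = 10_000,
                        seed: int = 0) -> GroupComparison:
    """Per-window group comparison of one metric, corrected over all windows."""
    ref = cohort_a[0]
    for m in list(cohort_a) + list(cohort_b):
        if not np.array_equal(m.window_starts_ms, ref.window_starts_ms):
            raise ValueError("cohorts must share the window grid")
    values = np.vstack([_metric_table(cohort_a, metric),
                        _metric_table(cohort_b, metric)])
    groups = ([m.group or "A" for m in cohort_a]
              + [m.group or "B" for m in cohort_b])
    return permutation_correct(
        values, groups,
        test_names=[f"window_{w}" for w in range(values.shape[1])],
        n_perm=n_perm, seed=seed, family=f"timecourse:{metric}")


def compare_averaged(cohort_a: Sequence[MetricSeries],
                     cohort_b: Sequence[MetricSeries],
                     span: str, n_perm: int = 10_000,
                     seed: int = 0) -> GroupComparison:
    """Group comparison of span-averaged metrics; family = the five metrics."""
    def tab(cohort):
        return np.array([[average_windows(m, span)[metric]
                          for metric in NETWORK_METRICS] for m in cohort])

    values = np.vstack([tab(cohort_a), tab(cohort_b)])
    groups = ([m.group or "A" for m in cohort_a]
              + [m.group or "B" for m in cohort_b])
    return permutation_correct(values, groups, test_names=list(NETWORK_METRICS),
                               n_perm=n_perm, seed=seed, family=f"span:{span}")


def behavior_correlation(metric_values: np.ndarray,
                         behavior: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation between a metric and task performance.

    ``behavior`` is typically the per-subject percentage of correct
    answers.  Returns (rho, p); a constant input vector makes the
    correlation undefined and yields (nan, nan) with a warning.
    """
    x = np.asarray(metric_values, dtype=float)
    y = np.asarray(behavior, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("metric_values and behavior must be equal-length 1D")
    if x.size < 4:
        raise ValueError("need at least 4 subjects")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("constant input: correlation undefined")
        return float("nan"), float("nan")
    rho, p = sstats.spearmanr(x, y)
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# pipeline orchestration
# ---------------------------------------------------------------------------
def subject_metric_series(epochs, layout, *, band: str = "alpha",
                          window_ms: float = 50.0, pad_ms: float = 200.0,
                          normalize: bool = True) -> MetricSeries:
    """Epochs → phases → windowed PLV → (baseline normalization) → metrics.

    Runs the narrow bands whose centers fall in the requested broad band,
    merges them, and computes the five network measures per window.
    """
    from .spectral_sync import (BROAD_BANDS, extract_phase, make_bands,
                                merge_bands, normalize_to_baseline,
                                windowed_plv)
    from .network_metrics import metric_series

    low, high = BROAD_BANDS[band]
    narrow = [b for b in make_bands(8.0, 48.0, 4.0) if low <= b.center < high]
    series = []
    for b in narrow:
        phases = extract_phase(epochs, b, pad_ms=pad_ms)
        s = windowed_plv(phases, window_ms=window_ms)
        if normalize:
            base = extract_phase(epochs, b, pad_ms=pad_ms, which="baseline")
            s = normalize_to_baseline(s, base)
        series.append(s)
    merged = merge_bands(series, band)
    return metric_series(merged, layout)


def analyze_cohorts(cohort_a, cohort_b, layout, *, band: str = "alpha",
                    window_ms: float = 50.0, metric: str = "S",
                    n_perm: int = 10_000, seed: int = 0,
                    normalize: bool = True) -> dict:
    """Full two-cohort analysis: metrics, time-course and span comparisons,
    and strength-fluctuation summaries.

    ``cohort_a``/``cohort_b`` are lists of (preprocessed) EpochSet objects.
    Returns a dict with per-subject MetricSeries, GroupComparison objects
    per window family and per span, the pooled fluctuation series, and
    per-group-per-regime survival curves.
    """
    from .fluctuations import (FluctuationSeries, strength_increments,
                               survival_distribution)

    metrics_a = [subject_metric_series(e, layout, band=band,
                                       window_ms=window_ms, normalize=normalize)
                 for e in cohort_a]
    metrics_b = [subject_metric_series(e, layout, band=band,
                                       window_ms=window_ms, normalize=normalize)
                 for e in cohort_b]
    results: dict = {"metrics_a": metrics_a, "metrics_b": metrics_b}
    results["timecourse"] = compare_timecourses(
        metrics_a, metrics_b, metric=metric, n_perm=n_perm, seed=seed)
    results["spans"] = {
        span: compare_averaged(metrics_a, metrics_b, span,
                               n_perm=n_perm, seed=seed)
        for span in ("MM", "I", "MM+I")
    }
    flucts = FluctuationSeries.pool(
        [strength_increments(m, "network") for m in metrics_a + metrics_b]
        + [strength_increments(m, "node") for m in metrics_a + metrics_b])
    results["fluctuations"] = flucts
    curves = {}
    groups = sorted({m.group for m in metrics_a + metrics_b if m.group},
                    key=str)
    for g in groups:
        for regime in ("MM", "I"):
            try:
                curves[(g, regime)] = survival_distribution(flucts, g, regime)
            except ValueError:
                continue
    results["survival"] = curves
    return results
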