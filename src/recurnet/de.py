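"""Differential expression of count data between recurrence groups.

Counts are normalized between samples with TMM (trimmed mean of M-values)
scaling factors, expressed as CPM / log2(CPM+1), tested per feature with the
Mann-Whitney U test on log2CPM, and adjusted with Benjamini-Hochberg. DE calls
from two cohorts are intersected direction-consistently, then filtered for
high, stable expression before downstream modelling.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import CountMatrix

log = logging.getLogger(__name__)

GROUP_CASE = "BCR"  # biochemical recurrence (unfavorable prognosis)
GROUP_CONTROL = "BRF"  # recurrence-free

__all__ = [
    "NormFactors",
    "tmm_factors",
    "cpm_matrix",
    "mw_test",
    "bh_adjust",
    "call_de",
    "cross_cohort_de",
    "expression_stability_filter",
]


@dataclass
class NormFactors:
    """Per-sample library sizes and TMM scaling factors.

    Factors are dimensionless, positive, and rescaled so their geometric mean
    is 1 (the edgeR convention); the effective library size of sample k is
    ``library_sizes[k] * factors[k]``.
    """

    sample_ids: list[str]
    library_sizes: np.ndarray
    factors: np.ndarray

    def __post_init__(self) -> None:
        self.library_sizes = np.asarray(self.library_sizes, dtype=float)
        self.factors = np.asarray(self.factors, dtype=float)
        if (self.factors <= 0).any():
            raise ValueError("TMM factors must be positive")


def _tmm_pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> float:
    """TMM factor of one sample against the reference column.

    M-values (log-fold-changes) and A-values (mean abundances) are computed
    over features nonzero in both samples; both tails of M (30%) and A (5%)
    are trimmed by rank, and the factor is 2 to the precision-weighted mean of
    the surviving M-values, with weights from the delta-method binomial
    variance of each M.
    """
    both = (obs > 0) & (ref > 0)
    if both.sum() < 2:
        warnings.warn("fewer than 2 shared nonzero features; TMM factor set to 1")
        return 1.0
    o = obs[both].astype(float)
    r = ref[both].astype(float)
    m = np.log2((o / lib_obs) / (r / lib_ref))
    a = 0.5 * np.log2((o / lib_obs) * (r / lib_ref))
    # inverse of the asymptotic variance of M
    w = 1.0 / ((lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r))
    if np.abs(m).max() < 1e-6:  # edgeR shortcut: identical profiles
        return 1.0
    n = m.size
    m_rank = stats.rankdata(m)
    a_rank = stats.rankdata(a)
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    keep = (m_rank >= lo_m) & (m_rank <= hi_m) & (a_rank >= lo_a) & (a_rank <= hi_a)
    if keep.sum() == 0:
        return 1.0
    f = np.sum(w[keep] * m[keep]) / np.sum(w[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def tmm_factors(counts: CountMatrix) -> NormFactors:
    """Trimmed-mean-of-M-values scaling factors (Robinson-Oshlack procedure).

    The reference sample is the one whose upper-quartile of library-size-scaled
    counts is closest to the mean upper-quartile across samples.
    """
    x = counts.values
    if x.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = x.sum(axis=0).astype(float)
    if (lib <= 0).any():
        bad = [counts.sample_ids[i] for i in np.where(lib <= 0)[0]]
        raise ValueError(f"samples with zero library size: {bad}")
    uq = np.quantile(x / lib, 0.75, axis=0)
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    ref = x[:, ref_idx]
    factors = np.array(
        [
            _tmm_pair_factor(x[:, k], ref, lib[k], lib[ref_idx])
            for k in range(x.shape[1])
        ]
    )
    factors = factors / np.exp(np.mean(np.log(factors)))
    return NormFactors(list(counts.sample_ids), lib, factors)


def cpm_matrix(counts: CountMatrix, factors: NormFactors, log: bool = False) -> pd.DataFrame:
    """Counts per million on TMM-effective library sizes; optionally log2(CPM+1)."""
    if list(counts.sample_ids) != list(factors.sample_ids):
        raise ValueError("normalization factors computed on different samples")
    eff_lib = factors.library_sizes * factors.factors
    cpm = counts.values / eff_lib * 1e6
    if log:
        cpm = np.log2(cpm + 1.0)
    return pd.DataFrame(cpm, index=counts.feature_ids, columns=counts.sample_ids)


def mw_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test of two independent samples.

    Returns (U of x, two-sided p). The exact permutation distribution is used
    when n1+n2 <= 20 and the data are tie-free; otherwise the normal
    approximation with midranks, tie-corrected variance and continuity
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    tie_free = np.unique(pooled).size == pooled.size
    if np.ptp(pooled) == 0:
        # all values identical: no evidence either way
        return float(x.size * y.size / 2.0), 1.0
    if x.size + y.size <= 20 and tie_free:
        method = "exact"
    else:
        if x.size + y.size <= 20 and not tie_free:
            log.debug("ties at small n: falling back to normal approximation")
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment, order-preserving, capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _split_groups(meta: pd.DataFrame, sample_ids: list[str]) -> tuple[np.ndarray, np.ndarray]:
    groups = meta.loc[sample_ids, "group"].to_numpy()
    unknown = set(groups) - {GROUP_CASE, GROUP_CONTROL}
    if unknown:
        raise ValueError(f"unknown group labels: {sorted(unknown)}")
    return groups == GROUP_CASE, groups == GROUP_CONTROL


def call_de(
    counts: CountMatrix,
    meta: pd.DataFrame,
    alpha: float = 0.05,
    min_abundance: float = 0.0,
) -> pd.DataFrame:
    """Per-feature differential expression between BCR and BRF samples.

    Fold change is the ratio of group CPM means (direction-annotated), the
    test is Mann-Whitney on log2CPM values, and FDR is Benjamini-Hochberg.
    A feature is called DE when its raw MW p-value is <= ``alpha``. Features
    with mean log2CPM below ``min_abundance`` are dropped before testing.
    """
    case, ctrl = _split_groups(meta, counts.sample_ids)
    if case.sum() < 2 or ctrl.sum() < 2:
        raise ValueError("each group needs at least 2 samples")
    factors = tmm_factors(counts)
    cpm = cpm_matrix(counts, factors).to_numpy()
    logcpm = np.log2(cpm + 1.0)
    mean_logcpm = logcpm.mean(axis=1)
    keep = mean_logcpm >= min_abundance
    rows = []
    for i in np.where(keep)[0]:
        mean_case = cpm[i, case].mean()
        mean_ctrl = cpm[i, ctrl].mean()
        if mean_ctrl == 0 and mean_case == 0:
            fc, direction = 1.0, "↑"
        elif mean_ctrl == 0:
            fc, direction = np.inf, "↑"
        else:
            ratio = mean_case / mean_ctrl
            if ratio >= 1:
                fc, direction = ratio, "↑"
            else:
                fc, direction = 1.0 / ratio, "↓"
        _, p = mw_test(logcpm[i, case], logcpm[i, ctrl])
        rows.append(
            {
                "feature": counts.feature_ids[i],
                "FC": fc,
                "direction": direction,
                "log2CPM": mean_logcpm[i],
                "p_MW": p,
            }
        )
    res = pd.DataFrame(rows)
    if len(res):
        res["FDR"] = bh_adjust(res["p_MW"].to_numpy())
        res["is_DE"] = res["p_MW"] <= alpha
    else:
        res = pd.DataFrame(columns=["feature", "FC", "direction", "log2CPM", "p_MW", "FDR", "is_DE"])
    return res


def cross_cohort_de(res_a: pd.DataFrame, res_b: pd.DataFrame) -> dict:
    """Direction-consistent intersection of two cohorts' DE calls.

    Returns the shared feature set plus the per-cohort up/down partitions
    (the Venn bookkeeping used to nominate cross-cohort markers).
    """
    def parts(res: pd.DataFrame) -> tuple[set, set]:
        de = res[res["is_DE"]]
        return (
            set(de.loc[de["direction"] == "↑", "feature"]),
            set(de.loc[de["direction"] == "↓", "feature"]),
        )

    up_a, down_a = parts(res_a)
    up_b, down_b = parts(res_b)
    shared = (up_a & up_b) | (down_a & down_b)
    return {
        "shared": shared,
        "up_a": up_a,
        "down_a": down_a,
        "up_b": up_b,
        "down_b": down_b,
    }


def expression_stability_filter(
    features: set[str] | list[str],
    cohorts: dict[str, tuple[CountMatrix, pd.DataFrame]],
    median_log2cpm: float = 1.0,
    detection_rate: float = 0.8,
) -> set[str]:
    """Keep features with high, stable expression in every group of every cohort.

    A feature passes when, in each group of each cohort, its median log2CPM is
    >= ``median_log2cpm`` and it is detected (raw count > 0) in at least
    ``detection_rate`` of the group's samples. This operationalizes "high level
    and stable distribution of expression"; both thresholds are configurable.
    """
    kept = set(features)
    for counts, meta in cohorts.values():
        factors = tmm_factors(counts)
        logcpm = cpm_matrix(counts, factors, log=True)
        detected = counts.to_frame() > 0
        case, ctrl = _split_groups(meta, counts.sample_ids)
        for mask in (case, ctrl):
            cols = np.asarray(counts.sample_ids)[mask]
            med = logcpm[cols].median(axis=1)
            det = detected[cols].mean(axis=1)
            for f in list(kept):
                if f not in logcpm.index:
                    kept.discard(f)
                    continue
                if med[f] < median_log2cpm or det[f] < detection_rate:
                    kept.discard(f)
    return kept
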