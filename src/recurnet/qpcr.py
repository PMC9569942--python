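"""qPCR relative quantification (delta-CT) and group-comparison statistics.

Technical replicates are averaged to a mean CT per (sample, assay); delta-CT
is taken against the matched reference assay (a control gene for mRNA targets,
a control miRNA for miRNA targets) and relative expression is 2^(-dCT).
Group contrasts report a median-ratio fold change, the Mann-Whitney p-value,
and the Spearman correlation of relative expression with the binary
recurrence indicator.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .de import GROUP_CASE, GROUP_CONTROL, mw_test

log = logging.getLogger(__name__)

__all__ = ["relative_expression", "qpcr_group_stats"]


def relative_expression(
    ct: pd.DataFrame, reference_map: dict[str, str]
) -> pd.DataFrame:
    """Per (sample, assay): mean CT, delta-CT vs reference, 2^(-dCT).

    ``reference_map`` assigns each assay its reference assay id (a reference
    maps to itself, giving delta-CT = 0 and relative expression 1). Samples
    missing a required reference measurement are skipped with a log entry.
    """
    if (ct["ct"] <= 0).any() or not np.isfinite(ct["ct"]).all():
        raise ValueError("CT values must be finite and positive")
    missing_ref = set(reference_map.values()) - set(ct["assay"])
    if missing_ref:
        raise ValueError(f"reference assays never measured: {sorted(missing_ref)}")
    mean_ct = ct.groupby(["sample", "assay"], sort=False)["ct"].mean()
    rows = []
    for (sample, assay), m in mean_ct.items():
        ref = reference_map.get(assay)
        if ref is None:
            raise ValueError(f"assay {assay!r} has no reference assigned")
        if (sample, ref) not in mean_ct.index:
            log.warning("sample %s lacks reference %s; skipping %s", sample, ref, assay)
            continue
        dct = m - mean_ct[(sample, ref)]
        rows.append(
            {
                "sample": sample,
                "assay": assay,
                "mean_ct": m,
                "delta_ct": dct,
                "rel_expr": 2.0 ** (-dct),
            }
        )
    return pd.DataFrame(rows)


def qpcr_group_stats(
    records: pd.DataFrame,
    meta: pd.DataFrame,
    alpha: float = 0.05,
    fc_stat: str = "median",
    exclude_assays: set[str] | None = None,
) -> pd.DataFrame:
    """Per-assay BCR-vs-BRF contrast on relative expression.

    FC is the direction-annotated ratio of group medians (means with
    ``fc_stat='mean'``); p_MW from the Mann-Whitney test; r_s is the Spearman
    correlation between relative expression and the binary group indicator
    (rank-biserial association) with its p-value. Assays whose MW p exceeds
    ``alpha`` are flagged ``excluded`` from downstream modelling.
    """
    if fc_stat not in {"median", "mean"}:
        raise ValueError("fc_stat must be 'median' or 'mean'")
    exclude_assays = exclude_assays or set()
    agg = np.median if fc_stat == "median" else np.mean
    rows = []
    for assay, sub in records.groupby("assay", sort=False):
        if assay in exclude_assays:
            continue
        groups = meta.loc[sub["sample"], "group"].to_numpy()
        vals = sub["rel_expr"].to_numpy(dtype=float)
        case = vals[groups == GROUP_CASE]
        ctrl = vals[groups == GROUP_CONTROL]
        if case.size == 0 or ctrl.size == 0:
            log.warning("assay %s present in only one group; skipped", assay)
            continue
        ratio = agg(case) / agg(ctrl)
        if ratio >= 1:
            fc, direction = ratio, "↑"
        else:
            fc, direction = 1.0 / ratio, "↓"
        _, p_mw = mw_test(case, ctrl)
        indicator = (groups == GROUP_CASE).astype(float)
        if np.ptp(vals) == 0:
            r_s, p_rs = 0.0, 1.0
        else:
            sp = stats.spearmanr(vals, indicator)
            r_s, p_rs = float(sp.statistic), float(sp.pvalue)
        rows.append(
            {
                "assay": assay,
                "FC": fc,
                "direction": direction,
                "p_MW": p_mw,
                "r_s": r_s,
                "p_rs": p_rs,
                "excluded": p_mw > alpha,
            }
        )
    return pd.DataFrame(rows)
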