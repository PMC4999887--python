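"""Relative transcript quantification by the Livak 2^-ddCt method.

Input is a tidy Ct table (one row per well): gene, sample group, replicate
index, Ct.  For each gene and group, dCt = mean Ct(target) - mean
Ct(reference gene); ddCt = dCt(group) - dCt(calibrator group); relative
quantity RQ = 2^-ddCt, assuming perfect doubling per cycle.  Replicates
are averaged at the dCt level (the standard Livak convention), so the
calibrator's RQ is exactly 1; per-replicate dCt values are retained for
group comparison by Welch's t-test.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

CT_COLUMNS = ("gene", "group", "replicate", "ct")


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a Ct TSV with columns gene, group, replicate, ct."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "group": str})
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"Ct table {path}: missing column(s) {missing}")
    df["ct"] = pd.to_numeric(df["ct"], errors="raise")
    if (df["ct"] <= 0).any():
        raise ValueError(f"Ct table {path}: Ct values must be positive")
    return df.loc[:, list(CT_COLUMNS)]


def delta_delta_ct(
    ct: pd.DataFrame, reference_gene: str, calibrator_group: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compute dCt, ddCt and RQ = 2^-ddCt per gene and group.

    Returns
    -------
    summary : DataFrame
        One row per (gene, group): ``n_reps``, ``delta_ct`` (mean),
        ``sd_delta_ct``, ``delta_delta_ct``, ``rq``.  The reference gene
        itself is excluded from the summary.
    replicates : DataFrame
        Per-replicate dCt (Ct of the replicate minus the group's mean
        reference Ct) and per-replicate RQ, for dispersion and testing.

    Raises
    ------
    ValueError
        If the reference gene is absent from any group (the message names
        the group) or the calibrator group is missing for a gene.
    """
    groups = sorted(ct["group"].unique())
    if calibrator_group not in groups:
        raise ValueError(f"calibrator group {calibrator_group!r} not present in Ct table")
    ref_mean: dict[str, float] = {}
    for g in groups:
        ref = ct.loc[(ct["gene"] == reference_gene) & (ct["group"] == g), "ct"]
        if ref.empty:
            raise ValueError(f"reference gene {reference_gene!r} missing in group {g!r}")
        ref_mean[g] = float(ref.mean())

    targets = ct.loc[ct["gene"] != reference_gene].copy()
    targets["delta_ct"] = targets["ct"] - targets["group"].map(ref_mean)

    summary_rows = []
    for (gene, group), grp in targets.groupby(["gene", "group"], sort=True):
        cal = targets.loc[(targets["gene"] == gene) & (targets["group"] == calibrator_group)]
        if cal.empty:
            raise ValueError(f"gene {gene!r} has no measurements in calibrator group {calibrator_group!r}")
        dct = float(grp["delta_ct"].mean())
        ddct = dct - float(cal["delta_ct"].mean())
        summary_rows.append(
            {
                "gene": gene,
                "group": group,
                "n_reps": int(len(grp)),
                "delta_ct": dct,
                "sd_delta_ct": float(grp["delta_ct"].std(ddof=1)) if len(grp) > 1 else float("nan"),
                "delta_delta_ct": ddct,
                "rq": float(2.0 ** (-ddct)),
            }
        )
    summary = pd.DataFrame(summary_rows)

    cal_mean = (
        targets.loc[targets["group"] == calibrator_group]
        .groupby("gene")["delta_ct"]
        .mean()
    )
    replicates = targets.loc[:, ["gene", "group", "replicate", "ct", "delta_ct"]].copy()
    replicates["rq"] = 2.0 ** -(replicates["delta_ct"] - replicates["gene"].map(cal_mean))
    return summary, replicates


def compare_groups(
    replicates: pd.DataFrame, gene: str, group_a: str, group_b: str, alpha: float = 0.05
) -> dict:
    """Welch two-sample t-test on per-replicate dCt values of one gene.

    Testing on the dCt (cycle) scale keeps the statistic close to normal;
    a two-sided p below ``alpha`` flags a significant expression change.
    """
    a = replicates.loc[
        (replicates["gene"] == gene) & (replicates["group"] == group_a), "delta_ct"
    ].to_numpy(float)
    b = replicates.loc[
        (replicates["gene"] == gene) & (replicates["group"] == group_b), "delta_ct"
    ].to_numpy(float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError(f"compare_groups needs >= 2 replicates per group (got {len(a)}, {len(b)})")
    res = sps.ttest_ind(a, b, equal_var=False)
    stat, p = float(res.statistic), float(res.pvalue)
    if np.isnan(stat):  # both groups constant: compare the means directly
        stat, p = (0.0, 1.0) if np.isclose(a.mean(), b.mean()) else (float("inf"), 0.0)
    return {
        "gene": gene,
        "group_a": group_a,
        "group_b": group_b,
        "statistic": stat,
        "p_value": p,
        "significant": bool(p < alpha),
    }
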