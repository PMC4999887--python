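"""Differential-expression calls, profile clustering and set overlaps.

A protein is called differentially expressed in a comparison when its
ratio clears the fold-change cutoff (>= 2 or <= 0.5 by default), its
Significance B p-value is below alpha (0.05), and it is supported by at
least ``min_unique`` unique peptides (2 by default).  Both fold-change
boundaries are inclusive.  The union of DE proteins across comparisons is
clustered on its log2-ratio profiles with Ward-linkage agglomerative
clustering into k expression groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import AgglomerativeClustering


def call_differential(
    proteins: pd.DataFrame,
    significance: pd.DataFrame,
    comparison: str,
    fc_up: float = 2.0,
    fc_down: float = 0.5,
    alpha: float = 0.05,
    min_unique: int = 2,
) -> pd.DataFrame:
    """Assign up / down / ns / not_tested status per protein for one comparison.

    ``proteins`` must carry ``ratio_<comparison>`` and ``n_unique_peptides``;
    ``significance`` supplies the per-protein p-value (joined on
    ``protein_group``).  Proteins lacking a ratio or a p-value are
    ``not_tested``.
    """
    if fc_up <= fc_down:
        raise ValueError(f"fc_up ({fc_up}) must exceed fc_down ({fc_down})")
    rcol = f"ratio_{comparison}"
    if rcol not in proteins.columns:
        raise KeyError(f"proteins table has no column {rcol!r}")

    out = proteins.loc[:, ["protein_group", "n_unique_peptides", rcol]].copy()
    out = out.rename(columns={rcol: "ratio"})
    out["comparison"] = comparison
    out = out.merge(
        significance.loc[:, ["protein_group", "p"]].rename(columns={"p": "p_value"}),
        on="protein_group",
        how="left",
    )

    ratio = out["ratio"].to_numpy(float)
    p = out["p_value"].to_numpy(float)
    n_uniq = out["n_unique_peptides"].to_numpy()
    tested = ~(np.isnan(ratio) | np.isnan(p))
    passes = tested & (p < alpha) & (n_uniq >= min_unique)

    status = np.where(~tested, "not_tested", "ns")
    status = np.where(passes & (ratio >= fc_up), "up", status)
    status = np.where(passes & (ratio <= fc_down), "down", status)
    out["status"] = status
    return out.loc[:, ["protein_group", "comparison", "ratio", "p_value", "n_unique_peptides", "status"]]


def summarize_de(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-comparison up / down / total counts (total = up + down)."""
    rows = []
    for cid, grp in calls.groupby("comparison", sort=True):
        n_up = int((grp["status"] == "up").sum())
        n_down = int((grp["status"] == "down").sum())
        rows.append(
            {"comparison": cid, "n_up": n_up, "n_down": n_down, "n_total": n_up + n_down}
        )
    return pd.DataFrame(rows)


def de_union_profiles(proteins: pd.DataFrame, calls: pd.DataFrame) -> pd.DataFrame:
    """Log2-ratio profile rows for proteins DE in at least one comparison."""
    de_ids = sorted(set(calls.loc[calls["status"].isin(["up", "down"]), "protein_group"]))
    cols = ["protein_group"] + [c for c in proteins.columns if c.startswith("log2_")]
    return (
        proteins.loc[proteins["protein_group"].isin(de_ids), cols]
        .sort_values("protein_group")
        .reset_index(drop=True)
    )


def cluster_profiles(
    profiles: pd.DataFrame,
    k: int = 5,
    linkage: str = "ward",
    metric: str = "euclidean",
) -> pd.DataFrame:
    """Cut a hierarchical tree on log2-ratio profiles into exactly k clusters.

    Profiles are the ``log2_*`` columns; a missing entry (protein DE in one
    comparison but unquantified in the other) is imputed as 0 and flagged.
    Cluster labels are renumbered 1..k by decreasing cluster size, ties
    broken by the smallest member id, so labels do not depend on input row
    order.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    prof_cols = [c for c in profiles.columns if c.startswith("log2_")]
    if not prof_cols:
        raise ValueError("profiles table has no log2_* columns")
    d = profiles.sort_values("protein_group", kind="stable").reset_index(drop=True)
    if len(d) < k:
        raise ValueError(
            f"only {len(d)} proteins but k={k}; choose a smaller number of clusters"
        )

    x = d[prof_cols].to_numpy(float)
    imputed = np.isnan(x).any(axis=1)
    x = np.nan_to_num(x, nan=0.0)

    if k == 1:
        raw = np.zeros(len(d), dtype=int)
    else:
        model = AgglomerativeClustering(n_clusters=k, linkage=linkage, metric=metric)
        raw = model.fit_predict(x)

    # renumber 1..k: largest cluster first, ties by smallest member id
    order = sorted(
        range(k),
        key=lambda lab: (-int((raw == lab).sum()), d.loc[raw == lab, "protein_group"].min()),
    )
    relabel = {old: new + 1 for new, old in enumerate(order)}

    out = d.loc[:, ["protein_group"] + prof_cols].copy()
    out["cluster"] = [relabel[v] for v in raw]
    out["imputed"] = imputed
    return out


@dataclass(frozen=True)
class OverlapSummary:
    """Sizes and Jaccard-style percent overlap of two protein sets."""

    n_a: int
    n_b: int
    n_intersection: int
    n_union: int

    @property
    def percent_common(self) -> int:
        """|A n B| / |A u B| * 100, rounded half away from zero."""
        if self.n_union == 0:
            return 0
        return int(math.floor(100.0 * self.n_intersection / self.n_union + 0.5))

    def to_dict(self) -> dict:
        return {
            "n_a": self.n_a,
            "n_b": self.n_b,
            "n_intersection": self.n_intersection,
            "n_union": self.n_union,
            "percent_common": self.percent_common,
        }


def overlap_summary(set_a, set_b) -> OverlapSummary:
    """Overlap of two collections of protein ids (symmetric in A and B)."""
    a, b = set(set_a), set(set_b)
    inter = len(a & b)
    return OverlapSummary(n_a=len(a), n_b=len(b), n_intersection=inter, n_union=len(a | b))
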