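"""PSM-level quantification: I/O, filtering, impurity correction, roll-up.

A PSM (peptide-spectrum match) table is a pandas DataFrame with one row per
identified spectrum and columns::

    spectrum_id  peptide  protein_group  is_unique  confidence  I114 I115 I116 I117

``confidence`` is an identification error probability (FDR/PEP scale, lower
is better).  ``is_unique`` marks peptides assigned to exactly one protein
group; only unique peptides contribute to protein ratios.  Shared peptides
carry a composite ``protein_group`` id joining their parents with ``;``.

The roll-up convention is the one standard for isobaric labelling:
peptide intensity = arithmetic mean of its PSM intensities per channel,
peptide ratio = geometric mean of numerator channels over geometric mean of
denominator channels, protein ratio = geometric mean of its unique-peptide
ratios.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Reporter channels of the 4-plex reagent, in fixed matrix order.
CHANNELS: tuple[str, ...] = ("114", "115", "116", "117")

INTENSITY_COLS: tuple[str, ...] = tuple(f"I{c}" for c in CHANNELS)

PSM_COLUMNS: tuple[str, ...] = (
    "spectrum_id",
    "peptide",
    "protein_group",
    "is_unique",
    "confidence",
) + INTENSITY_COLS


class SchemaError(ValueError):
    """Input table does not match the required schema."""


@dataclass(frozen=True)
class Comparison:
    """A ratio contrast between two disjoint sets of reporter channels.

    Channels on the same side are aggregated by geometric mean before the
    ratio is formed, so a two-channel denominator (e.g. duplicate labelling
    of one biological sample with tags 114 and 115) averages on the log
    scale, consistent with the rest of the pipeline.
    """

    id: str
    numerator: tuple[str, ...]
    denominator: tuple[str, ...]

    def __post_init__(self) -> None:
        num = tuple(str(c) for c in self.numerator)
        den = tuple(str(c) for c in self.denominator)
        object.__setattr__(self, "numerator", num)
        object.__setattr__(self, "denominator", den)
        if not num or not den:
            raise ValueError(f"comparison {self.id!r}: empty channel list")
        unknown = (set(num) | set(den)) - set(CHANNELS)
        if unknown:
            raise ValueError(f"comparison {self.id!r}: unknown channels {sorted(unknown)}")
        if set(num) & set(den):
            raise ValueError(f"comparison {self.id!r}: numerator and denominator overlap")


@dataclass(frozen=True)
class CorrectionMatrix:
    """4x4 isotope-impurity mixing matrix in channel order 114,115,116,117.

    Entry ``(i, j)`` is the fraction of tag *j*'s true reporter signal that
    is observed in channel *i*, as tabulated on the manufacturer's
    certificate of analysis.  Correction solves the linear system
    ``M x = observed`` for the true signal ``x``.
    """

    values: np.ndarray

    MAX_CONDITION: float = field(default=1e8, repr=False)

    def __post_init__(self) -> None:
        m = np.asarray(self.values, dtype=float)
        if m.shape != (4, 4):
            raise ValueError(f"correction matrix must be 4x4, got {m.shape}")
        if (m < 0).any():
            raise ValueError("correction matrix entries must be non-negative")
        colsums = m.sum(axis=0)
        if (colsums > 1 + 1e-9).any():
            raise ValueError(f"correction matrix column sums exceed 1: {colsums}")
        if np.linalg.cond(m) > self.MAX_CONDITION:
            raise np.linalg.LinAlgError(
                f"correction matrix is ill-conditioned (cond > {self.MAX_CONDITION:g})"
            )
        object.__setattr__(self, "values", m)

    @classmethod
    def identity(cls) -> "CorrectionMatrix":
        return cls(np.eye(4))

    @classmethod
    def typical_itraq4(cls) -> "CorrectionMatrix":
        """A representative 4-plex certificate: ~1% -2 Da, ~6% -1 Da, ~6% +1 Da
        and ~0.1% +2 Da isotope satellites per tag."""
        m = np.array(
            [
                [0.929, 0.020, 0.000, 0.000],
                [0.063, 0.923, 0.030, 0.001],
                [0.002, 0.056, 0.924, 0.040],
                [0.000, 0.001, 0.045, 0.938],
            ]
        )
        return cls(m)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CorrectionMatrix":
        """Read a 4x4 matrix of fractions with channel row/column labels."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.map(str)
        df.columns = df.columns.map(str)
        try:
            df = df.loc[list(CHANNELS), list(CHANNELS)]
        except KeyError as exc:
            raise SchemaError(f"correction matrix file {path}: missing channel {exc}") from exc
        return cls(df.to_numpy(dtype=float))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=CHANNELS, columns=CHANNELS).to_csv(
            path, sep="\t", index_label="channel"
        )


def read_psm_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a PSM TSV; row order is preserved.

    Raises
    ------
    SchemaError
        If a required column is missing.
    ValueError
        If an intensity is negative or a confidence is outside [0, 1];
        the message names the offending row.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"spectrum_id": str, "peptide": str, "protein_group": str},
    )
    missing = [c for c in PSM_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"PSM table {path}: missing column(s) {missing}")
    df = df.loc[:, list(PSM_COLUMNS)]
    df["is_unique"] = df["is_unique"].astype(bool)
    for col in ("confidence",) + INTENSITY_COLS:
        df[col] = pd.to_numeric(df[col], errors="raise")
    for col in INTENSITY_COLS:
        bad = np.flatnonzero(df[col].to_numpy() < 0)
        if bad.size:
            raise ValueError(f"PSM table {path}: negative {col} at row {bad[0]}")
    bad = np.flatnonzero((df["confidence"] < 0) | (df["confidence"] > 1))
    if bad.size:
        raise ValueError(f"PSM table {path}: confidence outside [0,1] at row {bad[0]}")
    return df


def write_psm_table(df: pd.DataFrame, path: str | Path) -> None:
    df.loc[:, list(PSM_COLUMNS)].to_csv(path, sep="\t", index=False)


def filter_psms(
    records: pd.DataFrame,
    min_confidence: float = 0.01,
    require_complete: bool = True,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply identification-confidence and complete-reporter filters.

    A PSM passes when its identification error ``confidence`` is at most
    ``min_confidence`` (1% FDR by default) and, with ``require_complete``,
    when all four reporter intensities are strictly positive — spectra with
    a missing reporter ion are discarded rather than imputed.

    Returns the retained rows and a per-reason removal count
    (``low_confidence`` counts rows that failed confidence regardless of
    completeness; ``incomplete`` counts confident rows missing a reporter).
    """
    conf_ok = records["confidence"].to_numpy() <= min_confidence
    complete = (records[list(INTENSITY_COLS)].to_numpy() > 0).all(axis=1)
    keep = conf_ok & (complete | (not require_complete))
    report = {
        "input": int(len(records)),
        "low_confidence": int((~conf_ok).sum()),
        "incomplete": int((conf_ok & ~complete).sum()) if require_complete else 0,
        "retained": int(keep.sum()),
    }
    logger.info("filter_psms: %s", report)
    return records.loc[keep].reset_index(drop=True), report


def correct_isotope_impurities(
    records: pd.DataFrame, matrix: CorrectionMatrix
) -> pd.DataFrame:
    """Deconvolve reporter cross-talk by solving ``M x = observed`` per PSM.

    Negative solution components (possible when noise exceeds the satellite
    signal) are clamped to zero; the clamp count is logged.  An identity
    matrix is a no-op.
    """
    out = records.copy()
    observed = out[list(INTENSITY_COLS)].to_numpy(dtype=float)
    if np.allclose(matrix.values, np.eye(4)):
        return out
    corrected = np.linalg.solve(matrix.values, observed.T).T
    n_clamped = int((corrected < 0).sum())
    if n_clamped:
        logger.warning(
            "correct_isotope_impurities: clamped %d negative components to 0", n_clamped
        )
        corrected = np.clip(corrected, 0.0, None)
    out[list(INTENSITY_COLS)] = corrected
    return out


def rollup_peptides(records: pd.DataFrame) -> pd.DataFrame:
    """Average PSM reporter intensities to one row per (peptide, protein_group).

    Per-channel peptide intensity is the arithmetic mean over all of that
    peptide's PSMs; ``n_psms`` records the number averaged.
    """
    if records.empty:
        return pd.DataFrame(
            columns=["peptide", "protein_group", "is_unique", "n_psms", *INTENSITY_COLS]
        )
    grouped = records.groupby(["peptide", "protein_group"], sort=True)
    agg = grouped.agg(
        is_unique=("is_unique", "first"),
        n_psms=("spectrum_id", "size"),
        **{c: (c, "mean") for c in INTENSITY_COLS},
    ).reset_index()
    return agg


def _geomean_rows(values: np.ndarray) -> np.ndarray:
    """Row-wise geometric mean; rows containing a zero yield 0."""
    with np.errstate(divide="ignore"):
        logs = np.log(values)
    out = np.exp(logs.mean(axis=1))
    out[(values <= 0).any(axis=1)] = 0.0
    return out


def compute_protein_ratios(
    peptides: pd.DataFrame,
    comparisons: list[Comparison],
    min_unique_for_quant: int = 1,
) -> pd.DataFrame:
    """Roll peptides up to proteins and form per-comparison ratios.

    For each comparison, a unique peptide's ratio is
    geomean(numerator-channel intensities) / geomean(denominator channels);
    the protein ratio is the geometric mean of those unique-peptide ratios.
    Peptides with a zero intensity in any involved channel are excluded from
    that comparison (a complete reporter set is required upstream, so zeros
    are treated as missing, not as measurements).  Proteins with fewer than
    ``min_unique_for_quant`` usable unique peptides get no ratio (NaN) for
    that comparison.

    Returns one row per protein group with columns ``protein_group``,
    ``n_peptides`` (all peptides mapped to the group, shared included),
    ``n_unique_peptides``, ``summed_intensity`` (total reporter signal over
    channels and unique peptides; the binning variable for Significance B),
    per-channel summed intensities ``I114..I117``, and ``ratio_<id>`` /
    ``log2_<id>`` per comparison.
    """
    if peptides.empty:
        cols = ["protein_group", "n_peptides", "n_unique_peptides", "summed_intensity"]
        cols += list(INTENSITY_COLS)
        for comp in comparisons:
            cols += [f"ratio_{comp.id}", f"log2_{comp.id}"]
        return pd.DataFrame(columns=cols)

    unique_peps = peptides.loc[peptides["is_unique"]].copy()

    # shared peptides carry composite ';'-joined group ids: count membership only
    membership = peptides.assign(
        protein_group=peptides["protein_group"].str.split(";")
    ).explode("protein_group")
    n_peptides = membership.groupby("protein_group").size()

    base = (
        unique_peps.groupby("protein_group")
        .agg(
            n_unique_peptides=("peptide", "size"),
            **{c: (c, "sum") for c in INTENSITY_COLS},
        )
        .reset_index()
    )
    base["summed_intensity"] = base[list(INTENSITY_COLS)].sum(axis=1)
    base["n_peptides"] = base["protein_group"].map(n_peptides).fillna(0).astype(int)

    for comp in comparisons:
        num = _geomean_rows(unique_peps[[f"I{c}" for c in comp.numerator]].to_numpy(float))
        den = _geomean_rows(unique_peps[[f"I{c}" for c in comp.denominator]].to_numpy(float))
        usable = (num > 0) & (den > 0)
        n_dropped = int((~usable).sum())
        if n_dropped:
            logger.info(
                "compute_protein_ratios[%s]: %d unique peptides excluded (zero intensity)",
                comp.id,
                n_dropped,
            )
        with np.errstate(divide="ignore", invalid="ignore"):
            log2r = np.where(usable, np.log2(num) - np.log2(den), np.nan)
        tmp = unique_peps.assign(_log2r=log2r).dropna(subset=["_log2r"])
        prot = tmp.groupby("protein_group")["_log2r"].agg(["mean", "size"])
        ok = prot["size"] >= min_unique_for_quant
        log2_ratio = prot.loc[ok, "mean"]
        base[f"log2_{comp.id}"] = base["protein_group"].map(log2_ratio)
        base[f"ratio_{comp.id}"] = np.exp2(base[f"log2_{comp.id}"])

    order = ["protein_group", "n_peptides", "n_unique_peptides", "summed_intensity"]
    order += list(INTENSITY_COLS)
    for comp in comparisons:
        order += [f"ratio_{comp.id}", f"log2_{comp.id}"]
    return base.loc[:, order].sort_values("protein_group").reset_index(drop=True)
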