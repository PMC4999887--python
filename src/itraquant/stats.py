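"""Outlier statistics and replicate-concordance QC for protein ratios.

Significance B is the intensity-binned robust outlier p-value of Cox &
Mann: proteins are sorted by total reporter intensity and split into
consecutive bins; within each bin the log2-ratio distribution is
summarised by its median ``m`` and the asymmetric robust half-widths
``r_plus = P84.13 - m`` and ``r_minus = m - P15.87`` (the one-sigma
percentiles of a Gaussian), a protein's z-score is its distance from the
bin median in units of the half-width on its side, and the p-value is the
Gaussian upper tail.  Binning lets the null width shrink with intensity,
as reporter-ion noise does.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats as sps

from .quant import Comparison

logger = logging.getLogger(__name__)


class DegenerateDistributionError(ValueError):
    """All ratios identical: no outlier scale can be estimated."""


def _bin_edges(n: int, bin_size: int) -> list[int]:
    """Consecutive bins of bin_size; a remainder smaller than bin_size/2 is
    merged into the last full bin; fewer than 2*bin_size rows form one bin."""
    if n < 2 * bin_size:
        return [0, n]
    nbins = n // bin_size
    rem = n - nbins * bin_size
    edges = list(range(0, nbins * bin_size + 1, bin_size))
    if rem >= bin_size / 2:
        edges.append(n)
    else:
        edges[-1] = n
    return edges


def significance_b(
    proteins: pd.DataFrame,
    comparison: str | Comparison,
    bin_size: int = 300,
    two_sided: bool = False,
) -> pd.DataFrame:
    """Intensity-binned robust outlier p-values for one comparison's ratios.

    Parameters
    ----------
    proteins
        Protein table with ``log2_<comparison>`` and ``summed_intensity``.
    comparison
        Comparison id (or a :class:`Comparison`, whose id is used).
    bin_size
        Target proteins per intensity bin.  Bins whose half-width collapses
        to zero are merged with a neighbour.
    two_sided
        Double and cap the Gaussian tail p at 1.

    Returns
    -------
    DataFrame with ``protein_group``, ``bin``, ``bin_median``, ``r_plus``,
    ``r_minus``, ``z`` and ``p`` for every protein with a defined ratio.
    """
    cid = comparison.id if isinstance(comparison, Comparison) else comparison
    col = f"log2_{cid}"
    if col not in proteins.columns:
        raise KeyError(f"proteins table has no column {col!r}")
    d = proteins.loc[:, ["protein_group", "summed_intensity", col]].dropna()
    if len(d) < 10:
        raise ValueError(f"significance_b needs >= 10 quantified proteins, got {len(d)}")
    d = d.sort_values(["summed_intensity", "protein_group"], kind="stable").reset_index(drop=True)

    x = d[col].to_numpy(float)
    edges = _bin_edges(len(d), bin_size)
    bins = [np.arange(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]

    def _stats(idx: np.ndarray) -> tuple[float, float, float]:
        lo, m, hi = np.percentile(x[idx], [15.87, 50.0, 84.13])
        return m, hi - m, m - lo

    # merge bins whose robust width collapsed (all ratios identical on a side)
    i = 0
    while i < len(bins):
        m, rp, rm = _stats(bins[i])
        if rp > 0 and rm > 0:
            i += 1
            continue
        if len(bins) == 1:
            raise DegenerateDistributionError(
                "all log2 ratios identical: robust width is zero in the only bin"
            )
        j = i + 1 if i + 1 < len(bins) else i - 1
        lo, hi = min(i, j), max(i, j)
        bins[lo] = np.concatenate([bins[lo], bins[hi]])
        del bins[hi]
        i = min(i, len(bins) - 1)
        logger.info("significance_b: merged degenerate bin (now %d bins)", len(bins))

    bin_of = np.empty(len(d), dtype=int)
    med = np.empty(len(d))
    rplus = np.empty(len(d))
    rminus = np.empty(len(d))
    for b, idx in enumerate(bins):
        m, rp, rm = _stats(idx)
        bin_of[idx] = b
        med[idx] = m
        rplus[idx] = rp
        rminus[idx] = rm

    z = np.where(x >= med, (x - med) / rplus, (med - x) / rminus)
    p = 0.5 * special.erfc(z / np.sqrt(2.0))
    if two_sided:
        p = np.minimum(1.0, 2.0 * p)

    return pd.DataFrame(
        {
            "protein_group": d["protein_group"].to_numpy(),
            "bin": bin_of,
            "bin_median": med,
            "r_plus": rplus,
            "r_minus": rminus,
            "z": z,
            "p": p,
        }
    )


@dataclass
class QCReport:
    """Concordance of two reporter channels measuring the same sample.

    ``sigma_log2`` is the sample sd of log2(A/B) across proteins — the
    quantification noise floor.  ``pearson_r2`` and ``regression_slope``
    summarise the intensity scatter (OLS of B on A).  ``variation`` holds
    each protein's percent variation |I_A - I_B| / mean(I_A, I_B) * 100;
    its empirical CDF is the cumulative %-variation curve used to pick a
    fold-change cutoff.
    """

    channel_a: str
    channel_b: str
    n: int
    sigma_log2: float
    pearson_r2: float
    regression_slope: float
    regression_intercept: float
    variation: np.ndarray = field(repr=False)

    def variation_curve(self) -> tuple[np.ndarray, np.ndarray]:
        """Sorted %-variations and the cumulative fraction at each."""
        v = np.sort(self.variation)
        return v, np.arange(1, len(v) + 1) / len(v)

    def frac_within(self, percent: float) -> float:
        """Fraction of proteins with %-variation <= ``percent``."""
        return float(np.mean(self.variation <= percent))

    def to_dict(self) -> dict:
        v, cum = self.variation_curve()
        return {
            "channel_a": self.channel_a,
            "channel_b": self.channel_b,
            "n": self.n,
            "sigma_log2": self.sigma_log2,
            "pearson_r2": self.pearson_r2,
            "regression_slope": self.regression_slope,
            "regression_intercept": self.regression_intercept,
            "frac_within_30pct": self.frac_within(30.0),
            "variation_curve": {"percent_variation": v.tolist(), "cumulative_fraction": cum.tolist()},
        }


def replicate_qc(proteins: pd.DataFrame, channel_a: str, channel_b: str) -> QCReport:
    """Concordance statistics between two replicate channels.

    Uses every protein with positive intensity in both channels; requires
    at least three.  A zero-variance channel leaves the correlation and
    slope undefined (NaN) with a warning.
    """
    a = proteins[f"I{channel_a}"].to_numpy(float)
    b = proteins[f"I{channel_b}"].to_numpy(float)
    ok = (a > 0) & (b > 0)
    a, b = a[ok], b[ok]
    if len(a) < 3:
        raise ValueError(f"replicate_qc needs >= 3 proteins quantified in both channels, got {len(a)}")

    log_ratio = np.log2(a / b)
    sigma = float(np.std(log_ratio, ddof=1))
    variation = np.abs(a - b) / ((a + b) / 2.0) * 100.0

    if np.ptp(a) == 0 or np.ptp(b) == 0:
        logger.warning("replicate_qc: zero-variance channel, correlation undefined")
        r2 = slope = intercept = float("nan")
    else:
        r = sps.pearsonr(a, b).statistic
        r2 = float(r * r)
        slope, intercept = np.polyfit(a, b, 1)

    return QCReport(
        channel_a=str(channel_a),
        channel_b=str(channel_b),
        n=int(len(a)),
        sigma_log2=sigma,
        pearson_r2=r2,
        regression_slope=float(slope),
        regression_intercept=float(intercept),
        variation=variation,
    )


def mixing_check(
    proteins: pd.DataFrame, reference_channel: str = "114", tolerance: float = 0.5
) -> pd.DataFrame:
    """Equal-mixing check: per-channel log2 ratio quartiles vs a reference.

    Samples pooled in equal amounts should centre every channel's log2
    ratio to the reference near zero; a channel whose |median| exceeds
    ``tolerance`` is flagged as a loading/mixing deviation.
    """
    ref = proteins[f"I{reference_channel}"].to_numpy(float)
    rows = []
    for ch in ("114", "115", "116", "117"):
        if ch == str(reference_channel):
            continue
        cur = proteins[f"I{ch}"].to_numpy(float)
        ok = (ref > 0) & (cur > 0)
        lr = np.log2(cur[ok] / ref[ok])
        q1, med, q3 = np.percentile(lr, [25, 50, 75]) if ok.any() else (np.nan,) * 3
        rows.append(
            {
                "channel": ch,
                "reference": str(reference_channel),
                "n": int(ok.sum()),
                "median_log2": med,
                "q1_log2": q1,
                "q3_log2": q3,
                "flagged": bool(abs(med) > tolerance),
            }
        )
    return pd.DataFrame(rows)


def median_normalize(proteins: pd.DataFrame, comparison: str | Comparison) -> pd.DataFrame:
    """Shift one comparison's log2 ratios so their median is exactly zero.

    Off by default in the pipeline: with verified equal mixing the raw
    ratios are left untouched; this is an opt-in adjustment.
    """
    cid = comparison.id if isinstance(comparison, Comparison) else comparison
    out = proteins.copy()
    col = f"log2_{cid}"
    shift = np.nanmedian(out[col].to_numpy(float))
    out[col] = out[col] - shift
    out[f"ratio_{cid}"] = np.exp2(out[col])
    return out
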