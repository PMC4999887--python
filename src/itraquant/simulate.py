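"""Synthetic 4-plex PSM tables with known ground truth.

The generator emulates the study design the pipeline targets: four iTRAQ
reporter channels where tags 114 and 115 carry the same biological sample
(immature GV oocytes, labelled in duplicate), tag 116 carries competent
matured (MII G) oocytes and tag 117 incompetent matured (MII B) oocytes.
Protein abundance is lognormal, a chosen fraction of proteins carry a true
fold change applied to the MII G sample, per-PSM technical noise is
multiplicative lognormal (additive Gaussian on the log2 scale, matching the
normally distributed log ratios such experiments show), and reporter
cross-talk can be applied forward with any impurity matrix so that the
downstream correction step has something real to undo.

All randomness flows through a single ``numpy.random.Generator`` keyed by
``SimConfig.seed``; draws are consumed in a fixed documented order
(protein intensities, DE assignment, peptide counts, shared-peptide
assignment, peptide efficiencies, PSM counts, PSM noise), so a config+seed
pair pins the fixture byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .quant import CHANNELS, INTENSITY_COLS, CorrectionMatrix, read_psm_table, write_psm_table

#: Peptides-per-protein distribution over {1,2,3,4,5,6+} matching the
#: identification-depth shape typical of a deep 4-plex oocyte run.
DEFAULT_PEPTIDE_DIST: tuple[float, ...] = (0.17, 0.11, 0.07, 0.06, 0.05, 0.54)

DEFAULT_CHANNEL_DESIGN: dict[str, str] = {
    "114": "GVO",
    "115": "GVO",
    "116": "MII_G",
    "117": "MII_B",
}


def _check_dist(name: str, dist: tuple[float, ...]) -> None:
    arr = np.asarray(dist, dtype=float)
    if (arr < 0).any():
        raise ValueError(f"{name}: probabilities must be non-negative")
    if abs(arr.sum() - 1.0) > 1e-9:
        raise ValueError(f"{name}: probabilities must sum to 1 (got {arr.sum()!r})")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic 4-plex experiment.

    Parameters
    ----------
    n_proteins
        Number of simulated protein groups.
    peptides_per_protein_dist
        Probabilities over peptide counts {1, 2, 3, 4, 5, 6+}; the ``6+``
        category draws 6 plus a geometric tail (p = 0.3).
    psms_per_peptide_dist
        Probabilities over PSM counts {1, 2, 3, ...} per peptide.
    base_log_intensity_mean, base_log_intensity_sd
        Mean and sd of per-protein base reporter intensity on the log2
        scale (arbitrary units; defaults put typical intensities near 2^16
        with ~1.5 log2 units of spread, as in Orbitrap reporter data).
    frac_de
        Fraction of proteins carrying a true fold change; exactly
        ``round(frac_de * n_proteins)`` proteins are altered.
    log2fc_magnitudes, log2fc_weights
        Distribution of |true log2 fold change| for altered proteins
        (default point mass at 2, i.e. 4-fold).
    tech_noise_sd
        Sd of per-PSM, per-channel technical noise on the log2 scale.
    frac_shared_peptides
        Fraction of peptides additionally assigned to a second protein
        group; their intensity is the sum of both parents' contributions
        and they are flagged non-unique.
    impurity_matrix
        Mixing matrix applied forward to every PSM's true intensities.
    channel_design
        Mapping channel label -> biological sample label; channels sharing
        a label always share true abundance multipliers.
    technical_replicate_renoise
        When True, ``simulate_psm_table(..., replicate=r)`` redraws only
        the PSM-level noise for each technical replicate, sharing all
        labelling-level truth; models repeated LC-MS/MS injection of one
        labelled pool.
    """

    n_proteins: int = 1000
    peptides_per_protein_dist: tuple[float, ...] = DEFAULT_PEPTIDE_DIST
    psms_per_peptide_dist: tuple[float, ...] = (0.6, 0.25, 0.15)
    base_log_intensity_mean: float = 16.0
    base_log_intensity_sd: float = 1.5
    frac_de: float = 0.1
    log2fc_magnitudes: tuple[float, ...] = (2.0,)
    log2fc_weights: tuple[float, ...] = (1.0,)
    tech_noise_sd: float = 0.2
    frac_shared_peptides: float = 0.0
    impurity_matrix: CorrectionMatrix = field(default_factory=CorrectionMatrix.identity)
    channel_design: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_CHANNEL_DESIGN)
    )
    technical_replicate_renoise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if self.tech_noise_sd < 0:
            raise ValueError("tech_noise_sd must be >= 0")
        for frac in (self.frac_de, self.frac_shared_peptides):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        _check_dist("peptides_per_protein_dist", self.peptides_per_protein_dist)
        _check_dist("psms_per_peptide_dist", self.psms_per_peptide_dist)
        _check_dist("log2fc_weights", self.log2fc_weights)
        if len(self.log2fc_magnitudes) != len(self.log2fc_weights):
            raise ValueError("log2fc_magnitudes and log2fc_weights must align")
        if set(self.channel_design) != set(CHANNELS):
            raise ValueError(f"channel_design must map exactly channels {CHANNELS}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["impurity_matrix"] = self.impurity_matrix.values.tolist()
        return d


@dataclass(frozen=True)
class GroundTruth:
    """True protein abundances, channel multipliers and peptide map.

    ``proteins`` has one row per protein group: ``protein_group``,
    ``base_intensity``, per-channel multiplier ``mult_<channel>`` and
    ``is_de``.  Channels mapped to the same sample always share a
    multiplier; non-DE proteins have all multipliers equal to 1.
    ``peptides`` has one row per generated peptide: ``peptide``,
    ``protein_group`` (``;``-joined when shared), ``is_unique``.
    """

    proteins: pd.DataFrame
    peptides: pd.DataFrame

    def true_log2_ratio(self, numerator: tuple[str, ...], denominator: tuple[str, ...]) -> pd.Series:
        """True log2 ratio per protein for a channel contrast (geomean sides)."""
        num = np.mean(
            [np.log2(self.proteins[f"mult_{c}"].to_numpy(float)) for c in numerator], axis=0
        )
        den = np.mean(
            [np.log2(self.proteins[f"mult_{c}"].to_numpy(float)) for c in denominator], axis=0
        )
        return pd.Series(num - den, index=self.proteins["protein_group"].to_numpy())


def generate_ground_truth(config: SimConfig) -> GroundTruth:
    """Draw per-protein truth and the peptide map; deterministic given seed.

    Exactly ``round(frac_de * n_proteins)`` proteins are altered: their
    MII G (here: the sample of channel 116) multiplier is set to
    ``2**(+-magnitude)`` with a 50/50 up/down split, all other samples stay
    at 1, so an altered protein is truly changed in every contrast against
    channel 116.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_proteins
    width = max(4, len(str(n)))
    ids = np.array([f"P{i:0{width}d}" for i in range(n)])

    base = np.exp2(
        rng.normal(config.base_log_intensity_mean, config.base_log_intensity_sd, size=n)
    )

    n_de = int(round(config.frac_de * n))
    de_idx = rng.choice(n, size=n_de, replace=False)
    mags = np.asarray(config.log2fc_magnitudes, float)[
        rng.choice(len(config.log2fc_magnitudes), size=n_de, p=np.asarray(config.log2fc_weights))
    ]
    signs = np.where(rng.random(n_de) < 0.5, 1.0, -1.0)

    samples = sorted(set(config.channel_design.values()))
    sample_mult = {s: np.ones(n) for s in samples}
    de_sample = config.channel_design["116"]
    sample_mult[de_sample][de_idx] = np.exp2(signs * mags)

    proteins = pd.DataFrame({"protein_group": ids, "base_intensity": base})
    for ch in CHANNELS:
        proteins[f"mult_{ch}"] = sample_mult[config.channel_design[ch]]
    is_de = np.zeros(n, dtype=bool)
    is_de[de_idx] = True
    proteins["is_de"] = is_de

    # peptide counts: categories 1..5 literal, 6+ gets a geometric tail
    cat = rng.choice(len(config.peptides_per_protein_dist), size=n,
                     p=np.asarray(config.peptides_per_protein_dist))
    n_pep = np.where(cat < 5, cat + 1, 6 + rng.geometric(0.3, size=n) - 1)

    pep_protein = np.repeat(ids, n_pep)
    pep_names = np.array(
        [f"PEP{j:07d}" for j in range(int(n_pep.sum()))]
    )
    peptides = pd.DataFrame({"peptide": pep_names, "protein_group": pep_protein})
    peptides["is_unique"] = True

    if config.frac_shared_peptides > 0 and n > 1:
        share = rng.random(len(peptides)) < config.frac_shared_peptides
        partners = ids[rng.integers(0, n, size=len(peptides))]
        # avoid self-sharing; leave those peptides unique
        share &= partners != peptides["protein_group"].to_numpy()
        joined = [
            ";".join(sorted([g, p]))
            for g, p in zip(peptides["protein_group"], partners)
        ]
        peptides.loc[share, "protein_group"] = np.asarray(joined, dtype=object)[share]
        peptides.loc[share, "is_unique"] = False

    return GroundTruth(proteins=proteins, peptides=peptides)


def simulate_psm_table(
    truth: GroundTruth, config: SimConfig, replicate: int = 0
) -> pd.DataFrame:
    """Forward-simulate the PSM table for one LC-MS/MS run.

    Each PSM's observed intensity vector is
    ``impurity_matrix @ (true channel intensities * lognormal noise)`` where
    the true vector for a unique peptide is
    ``base_intensity * efficiency * mult_channel`` and for a shared peptide
    the sum of its parents' contributions.  ``replicate`` indexes a
    technical re-injection: with ``technical_replicate_renoise`` only the
    PSM noise stream differs between replicates.
    """
    rng = np.random.default_rng(config.seed + 1)

    prot = truth.proteins.set_index("protein_group")
    mult = prot[[f"mult_{c}" for c in CHANNELS]].to_numpy(float)
    base = prot["base_intensity"].to_numpy(float)
    row_of = {g: i for i, g in enumerate(prot.index)}

    n_pep = len(truth.peptides)
    efficiency = np.exp2(rng.normal(0.0, 0.5, size=n_pep))

    # true per-channel intensity of each peptide (sum over parent proteins)
    pep_true = np.zeros((n_pep, 4))
    for i, (group, eff) in enumerate(zip(truth.peptides["protein_group"], efficiency)):
        for g in group.split(";"):
            j = row_of[g]
            pep_true[i] += base[j] * mult[j]
        pep_true[i] *= eff

    n_psms = 1 + rng.choice(
        len(config.psms_per_peptide_dist),
        size=n_pep,
        p=np.asarray(config.psms_per_peptide_dist),
    )

    if config.technical_replicate_renoise:
        noise_rng = np.random.default_rng(config.seed + 1000 + replicate)
    else:
        noise_rng = rng

    total = int(n_psms.sum())
    noise = np.exp2(noise_rng.normal(0.0, config.tech_noise_sd, size=(total, 4)))
    pep_idx = np.repeat(np.arange(n_pep), n_psms)
    observed = (pep_true[pep_idx] * noise) @ config.impurity_matrix.values.T

    table = pd.DataFrame(
        {
            "spectrum_id": [f"R{replicate}.S{i:08d}" for i in range(total)],
            "peptide": truth.peptides["peptide"].to_numpy()[pep_idx],
            "protein_group": truth.peptides["protein_group"].to_numpy()[pep_idx],
            "is_unique": truth.peptides["is_unique"].to_numpy()[pep_idx],
            "confidence": np.round(noise_rng.uniform(0.0, 0.01, size=total), 6),
        }
    )
    for k, col in enumerate(INTENSITY_COLS):
        table[col] = observed[:, k]
    return table


def write_fixture(
    truth: GroundTruth, psm_table: pd.DataFrame, directory: str | Path, config: SimConfig | None = None
) -> dict[str, Path]:
    """Write ``psms.tsv``, ``truth_proteins.tsv``, ``truth_peptides.tsv`` and a
    config echo to ``directory``; returns the paths.  The PSM table
    round-trips bit-identically through :func:`read_psm_table`."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "psms": directory / "psms.tsv",
        "truth_proteins": directory / "truth_proteins.tsv",
        "truth_peptides": directory / "truth_peptides.tsv",
    }
    write_psm_table(psm_table, paths["psms"])
    truth.proteins.to_csv(paths["truth_proteins"], sep="\t", index=False)
    truth.peptides.to_csv(paths["truth_peptides"], sep="\t", index=False)
    if config is not None:
        paths["config"] = directory / "sim_config.json"
        paths["config"].write_text(json.dumps(config.to_dict(), indent=2) + "\n")
    return paths


def read_fixture_psms(directory: str | Path) -> pd.DataFrame:
    return read_psm_table(Path(directory) / "psms.tsv")
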