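import numpy as np
import pandas as pd
import pytest

from itraquant import Comparison, SimConfig, generate_ground_truth, simulate_psm_table


@pytest.fixture(scope="session")
def comparisons():
    return [
        Comparison("MIIG_vs_GVO", ("116",), ("114", "115")),
        Comparison("MIIG_vs_MIIB", ("116",), ("117",)),
    ]


@pytest.fixture(scope="session")
def noise_free_sim():
    """Small noise-free simulation: 3 peptides and 1 PSM per protein."""
    cfg = SimConfig(
        n_proteins=200,
        tech_noise_sd=0.0,
        frac_de=0.1,
        seed=11,
        peptides_per_protein_dist=(0.0, 0.0, 1.0, 0.0, 0.0, 0.0),
        psms_per_peptide_dist=(1.0,),
    )
    truth = generate_ground_truth(cfg)
    table = simulate_psm_table(truth, cfg)
    return cfg, truth, table


def make_psms(rows):
    """Build a PSM table from (spectrum, peptide, protein, unique, conf, i114..i117)."""
    cols = ["spectrum_id", "peptide", "protein_group", "is_unique", "confidence",
            "I114", "I115", "I116", "I117"]
    return pd.DataFrame(rows, columns=cols)


def make_proteins(log2_ratios, intensities=None, comparison="c", n_unique=3, rng=None):
    """Protein table with one comparison's log2 ratios and summed intensities."""
    n = len(log2_ratios)
    if intensities is None:
        rng = rng or np.random.default_rng(0)
        intensities = rng.lognormal(10, 1, n)
    log2_ratios = np.asarray(log2_ratios, float)
    return pd.DataFrame(
        {
            "protein_group": [f"P{i:05d}" for i in range(n)],
            "n_peptides": n_unique,
            "n_unique_peptides": n_unique,
            "summed_intensity": intensities,
            f"ratio_{comparison}": np.exp2(log2_ratios),
            f"log2_{comparison}": log2_ratios,
        }
    )
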