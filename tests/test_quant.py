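import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from itraquant import (
    Comparison,
    CorrectionMatrix,
    compute_protein_ratios,
    correct_isotope_impurities,
    filter_psms,
    read_psm_table,
    rollup_peptides,
)
from itraquant.quant import SchemaError, write_psm_table

from conftest import make_psms


def psm(spectrum, peptide, protein, i114, i115, i116, i117, unique=True, conf=0.001):
    return (spectrum, peptide, protein, unique, conf, i114, i115, i116, i117)


class TestReadPSMTable:
    def test_missing_column_is_schema_error(self, tmp_path):
        df = make_psms([psm("s1", "PEP1", "P1", 1, 1, 1, 1)]).drop(columns=["I117"])
        path = tmp_path / "psms.tsv"
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(SchemaError, match="I117"):
            read_psm_table(path)

    def test_negative_intensity_names_row(self, tmp_path):
        df = make_psms([psm("s1", "PEP1", "P1", 1, 1, 1, 1), psm("s2", "PEP1", "P1", 1, -5, 1, 1)])
        path = tmp_path / "psms.tsv"
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="row 1"):
            read_psm_table(path)

    def test_empty_file_with_header_ok(self, tmp_path):
        path = tmp_path / "psms.tsv"
        write_psm_table(make_psms([]), path)
        assert read_psm_table(path).empty

    def test_row_order_preserved(self, tmp_path):
        rows = [psm(f"s{i}", f"PEP{i}", "P1", i + 1, 1, 1, 1) for i in range(5)][::-1]
        path = tmp_path / "psms.tsv"
        write_psm_table(make_psms(rows), path)
        assert list(read_psm_table(path)["spectrum_id"]) == [r[0] for r in rows]


class TestFilterPSMs:
    def test_incomplete_reporter_removed(self):
        df = make_psms([psm("s1", "PEP1", "P1", 10, 0, 10, 10)])
        kept, report = filter_psms(df, require_complete=True)
        assert kept.empty and report["incomplete"] == 1

    def test_all_confident_retained(self):
        df = make_psms([psm(f"s{i}", "PEP1", "P1", 1, 1, 1, 1, conf=0.001) for i in range(4)])
        kept, _ = filter_psms(df, min_confidence=0.01)
        assert len(kept) == 4

    def test_counts_by_reason(self):
        rows = [psm(f"ok{i}", "PEP1", "P1", 1, 1, 1, 1) for i in range(5)]
        rows += [psm(f"inc{i}", "PEP1", "P1", 0, 1, 1, 1) for i in range(3)]
        rows += [psm(f"lc{i}", "PEP1", "P1", 1, 1, 1, 1, conf=0.5) for i in range(2)]
        kept, report = filter_psms(make_psms(rows))
        assert len(kept) == 5
        assert report["incomplete"] == 3 and report["low_confidence"] == 2

    def test_incomplete_kept_when_not_required(self):
        df = make_psms([psm("s1", "PEP1", "P1", 10, 0, 10, 10)])
        kept, _ = filter_psms(df, require_complete=False)
        assert len(kept) == 1


class TestCorrectionMatrix:
    def test_identity_is_noop(self):
        df = make_psms([psm("s1", "PEP1", "P1", 10, 20, 30, 40)])
        out = correct_isotope_impurities(df, CorrectionMatrix.identity())
        pd.testing.assert_frame_equal(out, df)

    def test_single_column_crosstalk_solved(self):
        # 5% of tag 114's signal appears in channel 115: (95, 5, 0, 0) was a pure 100 in 114
        m = np.eye(4)
        m[:, 0] = [0.95, 0.05, 0.0, 0.0]
        df = make_psms([psm("s1", "PEP1", "P1", 95, 5, 0, 0)])
        out = correct_isotope_impurities(df, CorrectionMatrix(m))
        np.testing.assert_allclose(
            out[["I114", "I115", "I116", "I117"]].to_numpy()[0], [100, 0, 0, 0], atol=1e-9
        )

    def test_forward_mix_then_correct_is_identity(self):
        rng = np.random.default_rng(42)
        m = CorrectionMatrix.typical_itraq4()
        true = rng.uniform(0, 1e6, size=(200, 4))
        mixed = true @ m.values.T
        df = make_psms([psm(f"s{i}", "PEP1", "P1", *mixed[i]) for i in range(len(mixed))])
        out = correct_isotope_impurities(df, m)
        np.testing.assert_allclose(
            out[["I114", "I115", "I116", "I117"]].to_numpy(), true, rtol=1e-9, atol=1e-6
        )

    def test_singular_matrix_rejected(self):
        m = np.eye(4)
        m[:, 1] = m[:, 0]
        with pytest.raises(np.linalg.LinAlgError):
            CorrectionMatrix(0.5 * m)

    def test_column_sum_above_one_rejected(self):
        m = np.eye(4) * 1.2
        with pytest.raises(ValueError, match="column sums"):
            CorrectionMatrix(m)

    def test_tsv_roundtrip(self, tmp_path):
        m = CorrectionMatrix.typical_itraq4()
        m.to_tsv(tmp_path / "m.tsv")
        back = CorrectionMatrix.from_tsv(tmp_path / "m.tsv")
        np.testing.assert_allclose(back.values, m.values)


class TestRollup:
    def test_mean_of_psm_intensities(self):
        df = make_psms([
            psm("s1", "PEP1", "P1", 100, 10, 10, 10),
            psm("s2", "PEP1", "P1", 200, 20, 10, 10),
        ])
        pep = rollup_peptides(df)
        assert len(pep) == 1
        assert pep.loc[0, "I114"] == 150 and pep.loc[0, "n_psms"] == 2

    def test_single_psm_is_identity(self):
        df = make_psms([psm("s1", "PEP1", "P1", 7, 8, 9, 10)])
        pep = rollup_peptides(df)
        assert pep.loc[0, ["I114", "I115", "I116", "I117"]].tolist() == [7, 8, 9, 10]

    def test_one_row_per_peptide(self):
        rows = [psm(f"s{p}_{j}", f"PEP{p}", f"P{p % 10}", 1, 1, 1, 1)
                for p in range(50) for j in range(3)]
        pep = rollup_peptides(make_psms(rows))
        assert len(pep) == 50 and (pep["n_psms"] == 3).all()


class TestProteinRatios:
    C = [Comparison("c", ("116",), ("114",))]

    def _proteins(self, peptide_rows):
        return compute_protein_ratios(rollup_peptides(make_psms(peptide_rows)), self.C)

    def test_geomean_of_unique_peptide_ratios(self):
        # peptide ratios 2 and 8 -> protein ratio 4
        prot = self._proteins([
            psm("s1", "PEP1", "P1", 100, 1, 200, 1),
            psm("s2", "PEP2", "P1", 100, 1, 800, 1),
        ])
        assert prot.loc[0, "ratio_c"] == pytest.approx(4.0, abs=1e-12)

    def test_reciprocal_ratios_cancel(self):
        prot = self._proteins([
            psm("s1", "PEP1", "P1", 100, 1, 50, 1),
            psm("s2", "PEP2", "P1", 100, 1, 200, 1),
        ])
        assert prot.loc[0, "ratio_c"] == pytest.approx(1.0, abs=1e-12)

    def test_ratio_inversion_between_orientations(self):
        comps = [Comparison("ab", ("116",), ("114",)), Comparison("ba", ("114",), ("116",))]
        rows = [psm("s1", "PEP1", "P1", 123, 1, 456, 1), psm("s2", "PEP2", "P1", 77, 1, 11, 1)]
        prot = compute_protein_ratios(rollup_peptides(make_psms(rows)), comps)
        assert prot.loc[0, "ratio_ab"] * prot.loc[0, "ratio_ba"] == pytest.approx(1.0, abs=1e-12)

    def test_shared_peptides_never_affect_ratio(self):
        base = [psm("s1", "PEP1", "P1", 100, 1, 200, 1)]
        with_shared = base + [psm("s2", "PEP2", "P1;P2", 100, 1, 900000, 1, unique=False)]
        r1 = self._proteins(base)
        r2 = self._proteins(with_shared)
        assert r2.set_index("protein_group").loc["P1", "ratio_c"] == \
               r1.set_index("protein_group").loc["P1", "ratio_c"]
        assert r2.set_index("protein_group").loc["P1", "n_peptides"] == 2

    def test_zero_intensity_peptide_excluded_from_comparison(self):
        prot = self._proteins([
            psm("s1", "PEP1", "P1", 100, 1, 200, 1),
            psm("s2", "PEP2", "P1", 0, 1, 900, 1),
        ])
        assert prot.loc[0, "ratio_c"] == pytest.approx(2.0, abs=1e-12)

    def test_min_unique_for_quant_gates_ratio(self):
        pep = rollup_peptides(make_psms([psm("s1", "PEP1", "P1", 100, 1, 200, 1)]))
        prot = compute_protein_ratios(pep, self.C, min_unique_for_quant=2)
        assert np.isnan(prot.loc[0, "ratio_c"])

    def test_unknown_channel_in_comparison_rejected(self):
        with pytest.raises(ValueError, match="unknown channels"):
            Comparison("bad", ("118",), ("114",))

    def test_multichannel_denominator_uses_geomean(self):
        comp = [Comparison("c", ("116",), ("114", "115"))]
        rows = [psm("s1", "PEP1", "P1", 100, 400, 600, 1)]
        prot = compute_protein_ratios(rollup_peptides(make_psms(rows)), comp)
        assert prot.loc[0, "ratio_c"] == pytest.approx(600 / 200, abs=1e-12)  # geomean(100,400)=200

    @given(c=st.floats(min_value=0.01, max_value=100))
    @settings(max_examples=25, deadline=None)
    def test_scale_equivariance(self, c):
        rows = [psm("s1", "PEP1", "P1", 100, 1, 200, 1), psm("s2", "PEP2", "P1", 50, 1, 400, 1)]
        scaled = [psm("s1", "PEP1", "P1", 100, 1, 200 * c, 1),
                  psm("s2", "PEP2", "P1", 50, 1, 400 * c, 1)]
        r = self._proteins(rows).loc[0, "ratio_c"]
        rc = self._proteins(scaled).loc[0, "ratio_c"]
        assert rc == pytest.approx(c * r, rel=1e-9)

    def test_permutation_invariance(self):
        rows = [psm(f"s{i}", f"PEP{i % 5}", f"P{i % 3}", 10 + i, 5, 20 + i, 7) for i in range(15)]
        a = self._proteins(rows)
        b = self._proteins(rows[::-1])
        pd.testing.assert_frame_equal(a, b)


def test_noise_free_pipeline_recovers_truth(noise_free_sim, comparisons):
    """End-to-end oracle: with no noise and identity mixing, computed protein
    ratios equal the ground-truth channel-multiplier ratios to 1e-9."""
    cfg, truth, table = noise_free_sim
    kept, _ = filter_psms(table)
    prot = compute_protein_ratios(rollup_peptides(kept), comparisons)
    for comp in comparisons:
        expect = truth.true_log2_ratio(comp.numerator, comp.denominator)
        got = prot.set_index("protein_group")[f"log2_{comp.id}"]
        assert np.abs(got - expect.loc[got.index]).max() < 1e-9
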