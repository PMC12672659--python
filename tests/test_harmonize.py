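import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from patientnets.harmonize import (
    OmicsMatrix,
    filter_missing_analytes,
    flag_modulated,
    harmonize_phosphosites,
    impute_missing,
    sequence_window,
    zscore_matrix,
)


def make_matrix(values, kind="transcriptomics", stage="raw"):
    arr = np.asarray(values, dtype=float)
    df = pd.DataFrame(arr, index=[f"g{i}" for i in range(arr.shape[0])],
                      columns=[f"s{i}" for i in range(arr.shape[1])])
    return OmicsMatrix(df, kind, stage)


class TestFilterMissing:
    def test_strictly_above_threshold_removed_boundary_retained(self):
        vals = np.ones((2, 10))
        vals[0, :9] = np.nan  # 9/10 missing -> removed
        vals[1, :8] = np.nan  # exactly 8/10 -> retained (strict inequality)
        m = make_matrix(vals, kind="proteomics")
        out = filter_missing_analytes(m, 0.8)
        assert out.analyte_keys == ["g1"]
        assert out.stage == "filtered"

    def test_transcriptomics_residual_missing_set_to_zero(self):
        vals = np.ones((1, 10))
        vals[0, :2] = np.nan
        out = filter_missing_analytes(make_matrix(vals), 0.8)
        assert (out.data.iloc[0, :2] == 0).all()
        assert not out.data.isna().any().any()

    def test_proteomics_missing_left_for_imputation(self):
        vals = np.ones((1, 10))
        vals[0, 0] = np.nan
        out = filter_missing_analytes(make_matrix(vals, kind="proteomics"), 0.8)
        assert out.data.isna().sum().sum() == 1

    def test_errors(self):
        vals = np.full((1, 4), np.nan)
        with pytest.raises(ValueError, match="no analytes"):
            filter_missing_analytes(make_matrix(vals), 0.5)
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            filter_missing_analytes(make_matrix(np.ones((1, 2))), 1.5)


class TestImpute:
    @pytest.mark.parametrize("method", ["normal_regression", "pmm_like", "mean"])
    def test_complete_matrix_unchanged_and_observed_untouched(self, method, proteomics_matrix):
        filtered = filter_missing_analytes(proteomics_matrix, 0.8)
        out = impute_missing(filtered, method, seed=3)
        obs = ~filtered.data.isna()
        assert out.data.where(obs).equals(filtered.data.where(obs))
        assert not out.data.isna().any().any()
        complete = make_matrix(np.arange(12.0).reshape(3, 4), kind="proteomics", stage="filtered")
        same = impute_missing(complete, method, seed=0)
        pd.testing.assert_frame_equal(same.data, complete.data)

    @pytest.mark.parametrize("method", ["normal_regression", "pmm_like", "mean"])
    def test_seed_determinism(self, method, proteomics_matrix):
        filtered = filter_missing_analytes(proteomics_matrix, 0.8)
        a = impute_missing(filtered, method, seed=11)
        b = impute_missing(filtered, method, seed=11)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_mean_method_matches_row_mean(self):
        vals = np.array([[1.0, 2.0, np.nan, 3.0]])
        m = make_matrix(vals, kind="proteomics", stage="filtered")
        out = impute_missing(m, "mean", seed=0)
        assert out.data.iloc[0, 2] == pytest.approx(2.0)

    def test_fully_missing_row_errors(self):
        vals = np.full((1, 3), np.nan)
        m = make_matrix(vals, kind="proteomics", stage="filtered")
        with pytest.raises(ValueError, match="entirely missing"):
            impute_missing(m, "mean", seed=0)

    def test_unknown_method(self, proteomics_matrix):
        filtered = filter_missing_analytes(proteomics_matrix, 0.8)
        with pytest.raises(ValueError, match="unknown imputation"):
            impute_missing(filtered, "magic", seed=0)


class TestZscore:
    def test_simple_column(self):
        m = make_matrix([[1.0], [2.0], [3.0]], stage="imputed")
        out = zscore_matrix(m, by="sample", center="median")
        assert list(out.data.iloc[:, 0]) == [-1.0, 0.0, 1.0]
        assert out.stage == "zscored"

    def test_median_zero_and_unit_sd(self):
        rng = np.random.default_rng(5)
        m = make_matrix(rng.normal(3, 4, size=(31, 6)), stage="imputed")
        out = zscore_matrix(m, by="sample", center="median")
        assert (out.data.median(axis=0) == 0).all()
        assert np.allclose(out.data.std(axis=0, ddof=1), 1.0, atol=1e-12)

    def test_rezscore_is_idempotent_up_to_tolerance(self):
        rng = np.random.default_rng(6)
        m = make_matrix(rng.normal(size=(25, 5)), stage="imputed")
        z1 = zscore_matrix(m, by="sample", center="median")
        z2 = zscore_matrix(OmicsMatrix(z1.data, z1.omic_kind, "imputed"), by="sample", center="median")
        assert np.allclose(z1.data.to_numpy(), z2.data.to_numpy(), atol=1e-12)

    def test_analyte_axis_and_mean_center(self):
        m = make_matrix([[1.0, 2.0, 3.0]], stage="imputed")
        out = zscore_matrix(m, by="analyte", center="mean")
        assert np.allclose(out.data.to_numpy(), [[-1.0, 0.0, 1.0]])

    def test_constant_vector_errors(self):
        m = make_matrix([[5.0], [5.0], [5.0]], stage="imputed")
        with pytest.raises(ValueError, match="zero standard deviation"):
            zscore_matrix(m, by="sample")


class TestFlagModulated:
    def test_threshold_is_strict(self):
        m = make_matrix([[2.5], [1.96], [-3.1], [-1.96]], stage="zscored")
        calls = flag_modulated(m)
        by_analyte = calls.set_index("analyte")["modulated"]
        assert by_analyte["g0"] == "up"
        assert by_analyte["g1"] == "none"
        assert by_analyte["g2"] == "down"
        assert by_analyte["g3"] == "none"

    def test_counts_match_brute_force(self):
        rng = np.random.default_rng(8)
        z = rng.normal(size=(50, 12)) * 1.5
        m = make_matrix(z, stage="zscored")
        calls = flag_modulated(m)
        assert (calls["modulated"] == "up").sum() == (z > 1.96).sum()
        assert (calls["modulated"] == "down").sum() == (z < -1.96).sum()
        assert len(calls) == z.size

    def test_nonpositive_threshold_errors(self):
        m = make_matrix([[0.0]], stage="zscored")
        with pytest.raises(ValueError, match="positive"):
            flag_modulated(m, threshold=0.0)


SEQ = "ABCDEFSHIJKLMNOPQR"


class TestPhosphosites:
    def test_window_left_padded_at_terminus(self):
        assert sequence_window(SEQ, 7, flank=7) == "_ABCDEFSHIJKLMN"

    @given(pos=st.integers(1, len(SEQ)), flank=st.integers(1, 10))
    @settings(max_examples=50, deadline=None)
    def test_window_length_and_center(self, pos, flank):
        w = sequence_window(SEQ, pos, flank)
        assert len(w) == 2 * flank + 1
        assert w[flank] == SEQ[pos - 1]

    def test_dedup_longest_peptide_then_lowest_multiplicity(self):
        table = pd.DataFrame([
            {"gene": "G", "accession": "A1", "residue": "S", "position": 7,
             "peptide": "SHORTPEP1", "multiplicity": 1},
            {"gene": "G", "accession": "A1", "residue": "S", "position": 7,
             "peptide": "LONGERPEPTIDE", "multiplicity": 2},
        ])
        keys, report = harmonize_phosphosites(table, {"A1": SEQ})
        assert len(keys) == 1
        assert keys[0].peptide == "LONGERPEPTIDE"
        assert report["deduplicated"] == 1

    def test_ambiguous_residue_removed(self):
        table = pd.DataFrame([
            {"gene": "G", "accession": "A1", "residue": "S/T", "position": 7,
             "peptide": None, "multiplicity": 1},
        ])
        keys, report = harmonize_phosphosites(table, {"A1": SEQ})
        assert keys == []
        assert report["ambiguous_residue"] == 1

    def test_reanchor_to_nearest_matching_residue(self):
        # stated position 9 holds 'I'; the nearest S is at 7
        table = pd.DataFrame([
            {"gene": "G", "accession": "A1", "residue": "S", "position": 9,
             "peptide": None, "multiplicity": 1},
        ])
        keys, _ = harmonize_phosphosites(table, {"A1": SEQ})
        assert keys[0].position == 7

    def test_unanchorable_and_missing_sequences_reported(self):
        table = pd.DataFrame([
            {"gene": "G", "accession": "A1", "residue": "Y", "position": 2,
             "peptide": None, "multiplicity": 1},   # no Y within +/-5
            {"gene": "H", "accession": "MISSING", "residue": "S", "position": 1,
             "peptide": None, "multiplicity": 1},
        ])
        keys, report = harmonize_phosphosites(table, {"A1": SEQ})
        assert keys == []
        assert report["unanchorable"] == 1
        assert report["missing_sequence"] == 1

    def test_no_duplicate_site_keys(self):
        seq = "MSTYASDTKYLSSTRY"
        rng = np.random.default_rng(0)
        rows = []
        for _ in range(40):
            pos = int(rng.integers(1, len(seq) + 1))
            rows.append({"gene": "G", "accession": "A1", "residue": seq[pos - 1],
                         "peptide": "PEP" * int(rng.integers(1, 4)), "position": pos,
                         "multiplicity": int(rng.integers(1, 4))})
        table = pd.DataFrame(rows)
        keys, _ = harmonize_phosphosites(table, {"A1": seq})
        assert len(keys) > 3
        ids = [(k.accession, k.residue, k.position) for k in keys]
        assert len(ids) == len(set(ids))
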