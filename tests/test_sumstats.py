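"""Reading, validation, harmonization and LD computation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import drugtarget_mr as dm
from drugtarget_mr.sumstats import is_palindromic

from conftest import make_gwas


def _write_table(tmp_path, rows, name="sumstats.tsv"):
    path = tmp_path / name
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


BASE_ROW = {
    "rsid": "rs1",
    "chr": "16",
    "bp": 31_480_000,
    "ea": "A",
    "oa": "G",
    "freq": 0.3,
    "b": 0.1,
    "stderr": 0.01,
    "p": 1e-8,
    "samples": 10_000,
}
CMAP = {
    "variant_id": "rsid",
    "chrom": "chr",
    "pos": "bp",
    "effect_allele": "ea",
    "other_allele": "oa",
    "eaf": "freq",
    "beta": "b",
    "se": "stderr",
    "pval": "p",
    "n": "samples",
}


class TestReadSumstats:
    def test_well_formed_table_roundtrips(self, tmp_path):
        rows = [dict(BASE_ROW, rsid=f"rs{i}", bp=BASE_ROW["bp"] + i) for i in range(3)]
        table = dm.read_sumstats(_write_table(tmp_path, rows), CMAP, "hba1c")
        assert len(table) == 3
        assert table.trait_label == "hba1c"
        assert list(table.df["variant_id"]) == ["rs0", "rs1", "rs2"]

    def test_invalid_rows_dropped_and_logged(self, tmp_path):
        rows = [
            dict(BASE_ROW, rsid="rs1"),
            dict(BASE_ROW, rsid="rs2", stderr=0.0),
            dict(BASE_ROW, rsid="rs3", p=0.0),
            dict(BASE_ROW, rsid="rs4", ea="A", oa="A"),
        ]
        table = dm.read_sumstats(_write_table(tmp_path, rows), CMAP, "t")
        assert len(table) == 1
        reasons = sorted(r.reason for r in table.log)
        assert reasons == ["bad_alleles", "pval_out_of_range", "se_nonpositive"]

    def test_duplicate_keeps_lowest_p(self, tmp_path):
        rows = [
            dict(BASE_ROW, rsid="rs1", p=1e-4, b=0.1),
            dict(BASE_ROW, rsid="rs1", p=1e-9, b=0.2),
        ]
        table = dm.read_sumstats(_write_table(tmp_path, rows), CMAP, "t")
        assert len(table) == 1
        assert table.df["beta"].iloc[0] == 0.2
        assert sum(r.reason == "duplicate_variant_id" for r in table.log) == 1

    def test_missing_mandatory_column_is_config_error(self, tmp_path):
        path = _write_table(tmp_path, [BASE_ROW])
        bad_map = dict(CMAP, beta="nonexistent")
        with pytest.raises(dm.ConfigError):
            dm.read_sumstats(path, bad_map, "t")

    def test_empty_after_validation_is_data_error(self, tmp_path):
        path = _write_table(tmp_path, [dict(BASE_ROW, stderr=-1.0)])
        with pytest.raises(dm.DataError):
            dm.read_sumstats(path, CMAP, "t")


class TestHarmonize:
    def _pair(self, exp_alleles, out_alleles, out_eaf=0.3, exp_eaf=0.3, beta_y=0.2):
        exposure = make_gwas(
            [{"effect_allele": exp_alleles[0], "other_allele": exp_alleles[1], "eaf": exp_eaf}],
            label="X",
        )
        outcome = make_gwas(
            [{"effect_allele": out_alleles[0], "other_allele": out_alleles[1], "eaf": out_eaf, "beta": beta_y}],
            label="Y",
        )
        return exposure, outcome

    # rule table over allele configurations: (exposure, outcome, expected sign or None)
    @pytest.mark.parametrize(
        "exp_al,out_al,expected_sign",
        [
            (("A", "G"), ("A", "G"), +1),     # identical
            (("A", "G"), ("G", "A"), -1),     # swapped
            (("A", "G"), ("T", "C"), +1),     # strand flip
            (("A", "G"), ("C", "T"), -1),     # strand flip + swap
            (("A", "G"), ("A", "C"), None),   # mismatch
        ],
    )
    def test_allele_alignment_rules(self, exp_al, out_al, expected_sign):
        exposure, outcome = self._pair(exp_al, out_al)
        if expected_sign is None:
            with pytest.raises(dm.DataError):
                dm.harmonize_pair(exposure, outcome, ["rs1"])
        else:
            h = dm.harmonize_pair(exposure, outcome, ["rs1"])
            assert h.beta_y[0] == pytest.approx(expected_sign * 0.2)

    @pytest.mark.parametrize("eaf", [0.5, 0.45, 0.55])
    def test_palindromic_near_half_excluded(self, eaf):
        exposure, outcome = self._pair(("A", "T"), ("A", "T"), out_eaf=eaf, exp_eaf=eaf)
        with pytest.raises(dm.DataError):
            dm.harmonize_pair(exposure, outcome, ["rs1"])

    def test_palindromic_inferred_by_frequency(self):
        # frequencies on the same side of 0.5: alleles agree, beta kept
        exposure, outcome = self._pair(("A", "T"), ("A", "T"), exp_eaf=0.2, out_eaf=0.25)
        h = dm.harmonize_pair(exposure, outcome, ["rs1"])
        assert h.beta_y[0] == pytest.approx(0.2)
        # opposite sides: the stated effect alleles are opposite, beta negated
        exposure, outcome = self._pair(("A", "T"), ("A", "T"), exp_eaf=0.2, out_eaf=0.8)
        h = dm.harmonize_pair(exposure, outcome, ["rs1"])
        assert h.beta_y[0] == pytest.approx(-0.2)

    def test_palindromic_missing_eaf_excluded(self):
        exposure, outcome = self._pair(("C", "G"), ("C", "G"), out_eaf=np.nan, exp_eaf=0.2)
        with pytest.raises(dm.DataError):
            dm.harmonize_pair(exposure, outcome, ["rs1"])

    def test_variant_missing_from_outcome_logged(self):
        exposure = make_gwas([{}, {}], label="X")
        outcome = make_gwas([{}], label="Y")
        h = dm.harmonize_pair(exposure, outcome, ["rs1", "rs2"])
        assert h.k == 1
        assert any(r.reason == "missing_in_outcome" for r in h.log)

    def test_idempotent_on_aligned_pair(self):
        exposure = make_gwas([{"beta": 0.1}, {"beta": -0.2}], label="X")
        outcome = make_gwas([{"beta": 0.3}, {"beta": 0.4}], label="Y")
        h1 = dm.harmonize_pair(exposure, outcome, ["rs1", "rs2"])
        again = make_gwas(
            [{"beta": b} for b in h1.beta_y], label="Y"
        )
        h2 = dm.harmonize_pair(exposure, again, ["rs1", "rs2"])
        np.testing.assert_array_equal(h1.beta_y, h2.beta_y)

    @given(
        beta=st.floats(-2, 2, allow_nan=False),
        eaf=st.floats(0.01, 0.99),
    )
    def test_double_swap_restores_exactly(self, beta, eaf):
        """Swapping alleles twice is the identity on (beta, eaf)."""
        b1, e1 = -beta, 1 - eaf
        b2, e2 = -b1, 1 - e1
        assert b2 == beta
        assert e2 == pytest.approx(eaf, abs=1e-15)

    def test_is_palindromic(self):
        assert is_palindromic("A", "T") and is_palindromic("G", "C")
        assert not is_palindromic("A", "G")


class TestLdMatrix:
    def test_self_correlation_is_one(self):
        g = dm.simulate_genotypes(200, 3, ld_rho=0.5, seed=1)
        r = dm.ld_matrix(g, ["a", "b", "c"])
        np.testing.assert_allclose(np.diag(r), 1.0)
        assert r.loc["a", "b"] == pytest.approx(r.loc["b", "a"])

    def test_independent_columns_near_zero(self):
        g = dm.simulate_genotypes(10_000, 2, ld_rho=0.0, seed=42)
        r = dm.ld_matrix(g)
        assert abs(r.iloc[0, 1]) < 0.05

    def test_perfect_anticorrelation(self):
        col = np.array([0.0, 1, 2, 1, 0, 2])
        g = np.column_stack([col, 2 - col])
        r = dm.ld_matrix(g)
        assert r.iloc[0, 1] == pytest.approx(-1.0)

    def test_constant_column_is_data_error(self):
        g = np.column_stack([np.ones(10), np.arange(10.0)])
        with pytest.raises(dm.DataError, match="v0"):
            dm.ld_matrix(g)

    def test_output_positive_semidefinite(self):
        g = dm.simulate_genotypes(500, 8, ld_rho=0.7, seed=3)
        r = dm.ld_matrix(g)
        eigs = np.linalg.eigvalsh(r.to_numpy())
        assert eigs.min() > -1e-8
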