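"""Reading, validation, allele harmonisation and LD computation."""

import numpy as np
import pandas as pd
import pytest
from conftest import make_summary

from cismr import summary_io as sio
from cismr.simulate import ScenarioSpec, simulate_panel


def write_tsv(df, path):
    df.to_csv(path, sep="\t", index=False)
    return path


class TestReadSummary:
    def test_well_formed_table_read_intact(self, tmp_path):
        df = make_summary([100, 200, 300], beta=[0.1, -0.2, 0.0], se=0.05)
        path = write_tsv(df, tmp_path / "s.tsv")
        got = sio.read_summary(path)
        assert len(got) == 3
        assert len(got.attrs["rejects"]) == 0
        np.testing.assert_allclose(got["beta"], df["beta"])

    def test_invalid_rows_rejected_with_reasons(self, tmp_path):
        df = make_summary([100, 200, 300], beta=0.1, se=0.05)
        df.loc[1, "eaf"] = 1.2
        path = write_tsv(df, tmp_path / "s.tsv")
        got = sio.read_summary(path)
        assert len(got) == 2
        rejects = got.attrs["rejects"]
        assert list(rejects["reason"]) == ["invalid_range"]
        assert list(rejects["row"]) == [1]

    @pytest.mark.parametrize(
        "col,val,reason",
        [
            ("ea", "AT", "invalid_alleles"),  # indel-like rejected
            ("oa", "A", "invalid_alleles"),  # ea == oa
            ("se", 0.0, "invalid_range"),
            ("pvalue", 0.0, "invalid_range"),
            ("beta", "x", "non_numeric"),
        ],
    )
    def test_invariant_violations(self, tmp_path, col, val, reason):
        df = make_summary([100, 200], beta=0.1, se=0.05).astype({col: object})
        df.loc[0, col] = val
        got = sio.read_summary(write_tsv(df, tmp_path / "s.tsv"))
        assert len(got) == 1
        assert got.attrs["rejects"]["reason"].iloc[0] == reason

    def test_missing_column_fatal(self, tmp_path):
        df = make_summary([100], beta=0.1, se=0.05).drop(columns="eaf")
        with pytest.raises(ValueError, match="eaf"):
            sio.read_summary(write_tsv(df, tmp_path / "s.tsv"))

    def test_rereading_is_deterministic(self, tmp_path):
        df = make_summary([100, 200, 300], beta=[0.1, 0.2, 0.3], se=0.05)
        path = write_tsv(df, tmp_path / "s.tsv")
        a = sio.read_summary(path)
        b = sio.read_summary(path)
        pd.testing.assert_frame_equal(a, b)

    def test_comma_dialect_and_column_map(self, tmp_path):
        df = make_summary([100], beta=0.1, se=0.05).rename(
            columns={"chrom": "CHR", "pos": "BP"}
        )
        path = tmp_path / "s.csv"
        df.to_csv(path, index=False)
        got = sio.read_summary(path, dialect={"chrom": "CHR", "pos": "BP"})
        assert got["pos"].iloc[0] == 100


@pytest.mark.parametrize(
    "ea,oa,expected",
    [("A", "T", True), ("T", "A", True), ("C", "G", True), ("G", "C", True),
     ("A", "G", False), ("A", "C", False), ("T", "G", False)],
)
def test_strand_ambiguity_predicate(ea, oa, expected):
    assert sio.is_strand_ambiguous(ea, oa) is expected


class TestHarmonise:
    def test_swapped_alleles_flip_outcome_beta(self):
        exp = make_summary([100], beta=0.5, se=0.1)
        out = make_summary([100], beta=0.3, se=0.1, ea="G", oa="A", eaf=0.7)
        h = sio.harmonise(exp, out)
        assert h["beta_out"].iloc[0] == pytest.approx(-0.3)
        assert h["eaf_out"].iloc[0] == pytest.approx(0.3)

    def test_strand_flip_reconciled_without_sign_change(self):
        exp = make_summary([100], beta=0.5, se=0.1, ea="A", oa="G")
        out = make_summary([100], beta=0.3, se=0.1, ea="T", oa="C")
        h = sio.harmonise(exp, out)
        assert h["beta_out"].iloc[0] == pytest.approx(0.3)

    def test_common_palindromic_variant_dropped(self):
        # A/T SNP with MAF 0.45 > 0.40 cannot be frequency-aligned
        exp = make_summary([100, 200], beta=0.5, se=0.1,
                           ea=["A", "A"], oa=["T", "G"], eaf=0.45)
        out = make_summary([100, 200], beta=0.3, se=0.1,
                           ea=["A", "A"], oa=["T", "G"], eaf=0.45)
        h = sio.harmonise(exp, out)
        assert len(h) == 1
        assert h.attrs["counts"]["palindromic"] == 1

    def test_rare_palindromic_variant_frequency_aligned(self):
        exp = make_summary([100], beta=0.5, se=0.1, ea="A", oa="T", eaf=0.1)
        out = make_summary([100], beta=0.3, se=0.1, ea="A", oa="T", eaf=0.9)
        h = sio.harmonise(exp, out)  # frequencies on opposite sides: flip
        assert h["beta_out"].iloc[0] == pytest.approx(-0.3)
        assert h["eaf_out"].iloc[0] == pytest.approx(0.1)

    def test_irreconcilable_alleles_dropped_and_counted(self):
        exp = make_summary([100], beta=0.5, se=0.1, ea="A", oa="G")
        out = make_summary([100], beta=0.3, se=0.1, ea="A", oa="C")
        h = sio.harmonise(exp, out)
        assert len(h) == 0
        assert h.attrs["counts"]["irreconcilable"] == 1

    def test_self_harmonisation_is_identity(self):
        exp = make_summary([100, 200, 300], beta=[0.5, -0.2, 0.1], se=0.1,
                           eaf=[0.2, 0.3, 0.4])
        h = sio.harmonise(exp, exp)
        np.testing.assert_allclose(h["beta_out"], h["beta_exp"])
        np.testing.assert_allclose(h["beta_exp"], exp["beta"])

    def test_idempotent_on_own_output(self):
        exp = make_summary([100, 200], beta=0.5, se=0.1)
        out = make_summary([100, 200], beta=[0.3, -0.4], se=0.1,
                           ea="G", oa="A", eaf=0.7)
        h1 = sio.harmonise(exp, out)
        out2 = h1[["chrom", "pos", "rsid", "ea", "oa"]].copy()
        out2[["eaf", "beta", "se", "pvalue", "n"]] = h1[
            ["eaf_out", "beta_out", "se_out", "pvalue_out", "n_out"]
        ].to_numpy()
        h2 = sio.harmonise(exp, out2)
        np.testing.assert_allclose(h2["beta_out"], h1["beta_out"])
        np.testing.assert_allclose(h2["eaf_out"], h1["eaf_out"])

    def test_record_count_conservation(self):
        exp = make_summary([100, 200, 300, 400], beta=0.5, se=0.1,
                           ea=["A", "A", "A", "A"], oa=["G", "T", "G", "G"],
                           eaf=[0.3, 0.5, 0.3, 0.3])
        out = make_summary([100, 200, 300, 500], beta=0.3, se=0.1,
                           ea=["A", "A", "A", "A"], oa=["G", "T", "C", "G"],
                           eaf=[0.3, 0.5, 0.3, 0.3])
        h = sio.harmonise(exp, out)
        c = h.attrs["counts"]
        n_intersect = 3
        assert c["matched"] + c["palindromic"] + c["irreconcilable"] == n_intersect
        assert c["unmatched"] == 2


class TestComputeLD:
    def test_duplicated_column_perfect_correlation(self):
        hap = np.array([[0, 0], [1, 1], [0, 0], [1, 1], [1, 1], [0, 0]])
        panel = sio.ReferencePanel(
            hap,
            pd.DataFrame({"chrom": "1", "pos": [1, 2], "rsid": ["a", "b"],
                          "ea": "A", "oa": "G"}),
        )
        sub = make_summary([1, 2], beta=0.1, se=0.05)
        ld = sio.compute_ld(panel, sub)
        assert ld.r[0, 1] == pytest.approx(1.0)

    def test_allele_flip_negates_correlation(self):
        rng = np.random.default_rng(0)
        hap = rng.integers(0, 2, size=(200, 2))
        hap[:, 1] = hap[:, 0] ^ (rng.random(200) < 0.1)
        panel = sio.ReferencePanel(
            hap,
            pd.DataFrame({"chrom": "1", "pos": [1, 2], "rsid": ["a", "b"],
                          "ea": "A", "oa": "G"}),
        )
        sub = make_summary([1, 2], beta=0.1, se=0.05)
        r_plus = sio.compute_ld(panel, sub).r[0, 1]
        sub_flip = make_summary([1, 2], beta=0.1, se=0.05,
                                ea=["A", "G"], oa=["G", "A"])
        r_minus = sio.compute_ld(panel, sub_flip).r[0, 1]
        assert r_minus == pytest.approx(-r_plus)

    def test_independent_columns_near_zero_r(self):
        rng = np.random.default_rng(1)
        hap = rng.integers(0, 2, size=(10_000, 2))
        panel = sio.ReferencePanel(
            hap,
            pd.DataFrame({"chrom": "1", "pos": [1, 2], "rsid": ["a", "b"],
                          "ea": "A", "oa": "G"}),
        )
        sub = make_summary([1, 2], beta=0.1, se=0.05)
        assert abs(sio.compute_ld(panel, sub).r[0, 1]) < 0.05

    def test_missing_variant_fatal(self, small_panel):
        panel, _ = small_panel
        sub = make_summary([999_999_999], beta=0.1, se=0.05)
        with pytest.raises(KeyError):
            sio.compute_ld(panel, sub)

    def test_ld_invariants_on_simulated_panel(self, small_panel):
        panel, _ = small_panel
        sub = panel.variants.copy()
        sub["eaf"] = 0.3
        ld = sio.compute_ld(panel, sub)
        assert np.allclose(np.diag(ld.r), 1.0)
        assert np.allclose(ld.r, ld.r.T, atol=1e-12)
        assert np.abs(ld.r).max() <= 1 + 1e-12
        assert np.linalg.eigvalsh(ld.r).min() >= -1e-8

    def test_ld_round_trip(self, small_panel, tmp_path):
        panel, _ = small_panel
        sub = panel.variants.iloc[:5].copy()
        ld = sio.compute_ld(panel, sub)
        sio.write_ld(ld, tmp_path / "m.tsv", tmp_path / "v.tsv")
        got = sio.read_ld(tmp_path / "m.tsv", tmp_path / "v.tsv")
        np.testing.assert_allclose(got.r, ld.r, atol=1e-9)
        assert got.variants == ld.variants


def test_panel_round_trip(tmp_path):
    spec = ScenarioSpec(n_variants=10, n_haplotypes=50, seed=7)
    panel = simulate_panel(spec)
    sio.write_panel(panel, tmp_path / "h.tsv", tmp_path / "v.tsv")
    got = sio.read_panel(tmp_path / "h.tsv", tmp_path / "v.tsv")
    np.testing.assert_array_equal(got.haplotypes, panel.haplotypes)


def test_monomorphic_panel_rejected():
    hap = np.array([[0, 1], [0, 0], [0, 1]])
    with pytest.raises(ValueError, match="monomorphic"):
        sio.ReferencePanel(
            hap,
            pd.DataFrame({"chrom": "1", "pos": [1, 2], "rsid": ["a", "b"],
                          "ea": "A", "oa": "G"}),
        )
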