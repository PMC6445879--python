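"""Reader, harmonization, LD pruning and confounder-screen behaviour."""

import io
import logging

import numpy as np
import pytest
from hypothesis import given, strategies as st

from selmr import datasets as ds
from selmr.summary_data import (
    ConfigurationError,
    DuplicateVariantError,
    HarmonizationError,
    LdMatrix,
    RowParseError,
    SummaryDataError,
    VariantAssociation,
    harmonize,
    ld_prune,
    read_ld_matrix,
    read_summary_table,
    screen_confounders,
)

EXPOSURE_HEADER = "rsid\tchrom\tpos\tea\toa\teaf\tz\tp\tn\n"


def make_variant(rsid="rs1", ea="T", oa="C", **kw):
    defaults = dict(eaf=0.3, beta=0.1, se=0.05, pval=0.01, n=1000)
    defaults.update(kw)
    return VariantAssociation(rsid=rsid, effect_allele=ea, other_allele=oa, **defaults)


class TestReadSummaryTable:
    def test_published_exposure_table_parses(self):
        records = read_summary_table(ds.exposure_path())
        assert len(records) == 4
        by_rsid = {r.rsid: r for r in records}
        assert by_rsid["rs921943"].zscore == pytest.approx(13.14)
        assert by_rsid["rs921943"].eaf == pytest.approx(0.29)
        assert [r.rsid for r in records] == [
            "rs1789953", "rs6586282", "rs6859667", "rs921943"]  # file order kept

    def test_empty_file_with_header_gives_empty_list(self):
        assert read_summary_table(io.StringIO(EXPOSURE_HEADER)) == []

    def test_invalid_eaf_row_rejected_with_diagnostic(self, caplog):
        body = (EXPOSURE_HEADER
                + "rs1\tchr1\t100\tT\tC\t0.2\t5.0\t1e-7\t9000\n"
                + "rs2\tchr1\t200\tT\tC\t1.2\t4.0\t1e-5\t9000\n"
                + "rs3\tchr1\t300\tA\tG\t0.4\t6.0\t1e-9\t9000\n"
                + "rs4\tchr1\t400\tA\tC\t0.5\t3.0\t1e-3\t9000\n")
        with caplog.at_level(logging.WARNING, logger="selmr.summary_data"):
            records = read_summary_table(io.StringIO(body))
        assert [r.rsid for r in records] == ["rs1", "rs3", "rs4"]
        assert any("line 3" in m for m in caplog.messages)

    def test_duplicate_rsid_raises_naming_it(self):
        body = (EXPOSURE_HEADER
                + "rs1\tchr1\t100\tT\tC\t0.2\t5.0\t1e-7\t9000\n"
                + "rs1\tchr1\t100\tT\tC\t0.2\t5.0\t1e-7\t9000\n")
        with pytest.raises(DuplicateVariantError, match="rs1"):
            read_summary_table(io.StringIO(body))

    def test_unparseable_numeric_reports_line_number(self):
        body = EXPOSURE_HEADER + "rs1\tchr1\t100\tT\tC\t0.2\tfive\t1e-7\t9000\n"
        with pytest.raises(RowParseError, match="line 2"):
            read_summary_table(io.StringIO(body))

    def test_explicit_map_with_missing_column_is_config_error(self):
        with pytest.raises(ConfigurationError):
            read_summary_table(io.StringIO(EXPOSURE_HEADER),
                               column_map={"rsid": "rsid", "effect_allele": "ea",
                                           "other_allele": "oa", "beta": "nope", "se": "se"})

    def test_inconsistent_beta_se_z_rejected(self):
        with pytest.raises(SummaryDataError, match="inconsistent"):
            make_variant(beta=0.16, se=0.03, zscore=9.9)


class TestHarmonize:
    def test_matching_alleles_pass_through(self):
        exp = make_variant(beta=0.16, se=0.03, eaf=0.14)
        out = make_variant(beta=-0.04, se=0.02, eaf=0.13, pval=0.12)
        inst = harmonize(exp, out)
        assert inst.beta_out == pytest.approx(-0.04)
        assert not inst.flipped and not inst.palindromic

    def test_swapped_alleles_flip_sign_and_frequency(self):
        exp = make_variant(ea="T", oa="C", beta=0.16, se=0.03, eaf=0.14)
        out = make_variant(ea="C", oa="T", beta=0.04, se=0.02, eaf=0.87)
        inst = harmonize(exp, out)
        assert inst.flipped
        assert inst.beta_out == pytest.approx(-0.04)
        assert inst.eaf_out == pytest.approx(0.13)

    def test_strand_flip_resolved_by_complement(self):
        exp = make_variant(ea="G", oa="T", beta=0.2, se=0.05, eaf=0.3)
        out = make_variant(ea="C", oa="A", beta=0.1, se=0.05, eaf=0.31)
        inst = harmonize(exp, out)
        assert not inst.flipped and inst.beta_out == pytest.approx(0.1)
        out_swapped = make_variant(ea="A", oa="C", beta=0.1, se=0.05, eaf=0.69)
        inst2 = harmonize(exp, out_swapped)
        assert inst2.flipped and inst2.beta_out == pytest.approx(-0.1)

    def test_uninformative_palindromic_pair_is_dropped(self):
        exp = make_variant(ea="A", oa="T", eaf=0.50)
        out = make_variant(ea="A", oa="T", eaf=0.50)
        assert harmonize(exp, out, "keep_if_eaf_informative") is None
        assert harmonize(exp, out, "drop") is None
        kept = harmonize(exp, out, "keep")
        assert kept is not None and kept.palindromic

    def test_informative_palindromic_pair_aligned_by_frequency(self):
        exp = make_variant(ea="C", oa="G", eaf=0.10, beta=0.2, se=0.05)
        # outcome reported on the other strand: eaf near 1 - 0.10
        out = make_variant(ea="C", oa="G", eaf=0.88, beta=0.1, se=0.05)
        inst = harmonize(exp, out, "keep_if_eaf_informative")
        assert inst.flipped and inst.beta_out == pytest.approx(-0.1)

    def test_incompatible_alleles_raise(self):
        exp = make_variant(ea="T", oa="C")
        out = make_variant(ea="A", oa="G")  # complement of A/G is T/C -> compatible
        assert harmonize(exp, out) is not None
        bad = make_variant(ea="A", oa="C")
        with pytest.raises(HarmonizationError, match="rs1"):
            harmonize(exp, bad)

    @given(beta=st.floats(-1, 1, allow_nan=False).filter(lambda b: abs(b) > 1e-6),
           eaf=st.floats(0.05, 0.95))
    def test_involution_under_allele_swap(self, beta, eaf):
        """Re-representing the outcome on the swapped allele changes nothing."""
        exp = make_variant(ea="T", oa="C", beta=0.2, se=0.05, eaf=0.3)
        out = make_variant(ea="T", oa="C", beta=beta, se=0.05, eaf=eaf)
        swapped = make_variant(ea="C", oa="T", beta=-beta, se=0.05, eaf=1 - eaf)
        a, b = harmonize(exp, out), harmonize(exp, swapped)
        assert a.beta_out == pytest.approx(b.beta_out)
        assert a.eaf_out == pytest.approx(b.eaf_out)
        assert a.flipped != b.flipped


def two_locus_panel():
    """Eleven variants at two loci collapsing to two representatives each."""
    rsids, variants = [], []
    pvals = [1e-12, 1e-10, 1e-9, 1e-8, 5e-8, 2e-8,
             1e-11, 3e-9, 4e-8, 2.5e-8, 1.5e-8]
    for j, p in enumerate(pvals):
        rsid = f"rsA{j}" if j < 6 else f"rsB{j}"
        rsids.append(rsid)
        variants.append(make_variant(rsid=rsid, pval=p, beta=0.1, se=0.02))
    r2 = np.zeros((11, 11))
    for locus in (range(0, 6), range(6, 11)):
        for i in locus:
            for j in locus:
                if i != j:
                    r2[i, j] = 0.9
    # one nearly independent pair inside each locus
    lead_a = int(np.argmin(pvals[:6]))
    lead_b = 6 + int(np.argmin(pvals[6:]))
    r2[lead_a, 1], r2[1, lead_a] = 0.01, 0.01
    r2[lead_b, 9], r2[9, lead_b] = 0.02, 0.02
    np.fill_diagonal(r2, 1.0)
    return variants, LdMatrix(rsids=tuple(rsids), r2=r2)


class TestLdPrune:
    def test_two_loci_collapse_to_four_representatives(self):
        variants, ld = two_locus_panel()
        kept = ld_prune(variants, ld, 0.05)
        assert len(kept) == 4
        assert {v.rsid for v in kept} == {"rsA0", "rsA1", "rsB6", "rsB9"}

    def test_independent_pair_both_retained(self):
        variants = [make_variant(rsid="rs1", pval=1e-8), make_variant(rsid="rs2", pval=1e-7)]
        ld = LdMatrix(rsids=("rs1", "rs2"), r2=np.eye(2))
        assert len(ld_prune(variants, ld, 0.05)) == 2

    def test_single_cluster_keeps_smallest_p(self):
        variants = [make_variant(rsid=f"rs{i}", pval=p)
                    for i, p in enumerate([1e-8, 1e-12, 1e-9])]
        r2 = np.full((3, 3), 0.9)
        np.fill_diagonal(r2, 1.0)
        ld = LdMatrix(rsids=("rs0", "rs1", "rs2"), r2=r2)
        kept = ld_prune(variants, ld, 0.05)
        assert [v.rsid for v in kept] == ["rs1"]

    def test_result_independent_of_input_order(self):
        variants, ld = two_locus_panel()
        baseline = [v.rsid for v in ld_prune(variants, ld, 0.05)]
        rng = np.random.default_rng(7)
        for _ in range(5):
            shuffled = list(variants)
            rng.shuffle(shuffled)
            assert [v.rsid for v in ld_prune(shuffled, ld, 0.05)] == baseline

    def test_every_retained_pair_below_threshold(self):
        variants, ld = two_locus_panel()
        kept = ld_prune(variants, ld, 0.05)
        for a in kept:
            for b in kept:
                if a.rsid != b.rsid:
                    assert ld.lookup(a.rsid, b.rsid) < 0.05

    def test_variant_missing_from_matrix_raises(self):
        ld = LdMatrix(rsids=("rs1",), r2=np.eye(1))
        with pytest.raises(SummaryDataError, match="rs2"):
            ld_prune([make_variant(rsid="rs2")], ld, 0.05)

    def test_packaged_fixture_matrix_reads_and_validates(self):
        ld = read_ld_matrix(ds.ld_path())
        assert ld.lookup("rs1789953", "rs6586282") == pytest.approx(0.04)
        assert ld.lookup("rs6859667", "rs921943") == pytest.approx(0.03)


class TestConfounderScreen:
    def test_empty_table_passes_all(self):
        variants = [make_variant(rsid=f"rs{i}") for i in range(4)]
        results = screen_confounders(variants, [], risk_factor_count=7)
        assert all(r.passed for r in results.values())

    def test_association_below_threshold_fails_and_names_trait(self):
        v = make_variant(rsid="rs921943")
        results = screen_confounders([v], [("rs921943", "BMI", 1e-4)], 7)
        assert not results["rs921943"].passed
        assert results["rs921943"].offending == (("BMI", 1e-4),)

    def test_association_above_threshold_passes(self):
        v = make_variant(rsid="rs921943")
        results = screen_confounders([v], [("rs921943", "BMI", 0.01)], 7)
        assert results["rs921943"].passed  # 0.01 > 0.05/7

    def test_nonpositive_count_is_config_error(self):
        with pytest.raises(ConfigurationError):
            screen_confounders([make_variant()], [], risk_factor_count=0)
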