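import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from targetmr.sumstats import (COMPLEMENT, HarmonisedInstrument, LDMatrix,
                               LDPanelError, Rejection, SchemaError,
                               ValidationError, find_proxy, harmonise,
                               harmonise_pairs, ld_prune, read_sumstats,
                               two_sided_p, write_sumstats)

from conftest import make_assoc

HEADER = "SNP\tCHR\tPOS\tEA\tOA\tEAF\tBETA\tSE\tP\tN\tPHENO\n"


def _row(snp="rs1", chrom="1", pos=100, ea="A", oa="G", eaf=0.3,
         beta=0.1, se=0.02, p=None, n=1000, pheno="x"):
    if p is None:
        p = two_sided_p(beta / se)
    return f"{snp}\t{chrom}\t{pos}\t{ea}\t{oa}\t{eaf}\t{beta}\t{se}\t{p}\t{n}\t{pheno}\n"


class TestReadSumstats:
    def test_well_formed_three_rows(self, tmp_path):
        f = tmp_path / "s.tsv"
        f.write_text(HEADER + _row("rs1") + _row("rs2", pos=200) + _row("rs3", pos=300))
        records, report = read_sumstats(f)
        assert len(records) == 3
        assert report.n_dropped == 0

    def test_zero_se_dropped_and_reported(self, tmp_path):
        f = tmp_path / "s.tsv"
        f.write_text(HEADER + _row("rs1") + _row("rs2", se=0.0, p=0.5))
        records, report = read_sumstats(f)
        assert [r.variant_id for r in records] == ["rs1"]
        assert report.dropped == [("rs2", "se not positive")]

    def test_identical_alleles_dropped(self, tmp_path):
        f = tmp_path / "s.tsv"
        f.write_text(HEADER + _row("rs1", ea="A", oa="A"))
        records, report = read_sumstats(f)
        assert records == []
        assert report.dropped[0][1] == "effect and other allele identical"

    def test_missing_mandatory_column(self, tmp_path):
        f = tmp_path / "s.tsv"
        f.write_text("SNP\tCHR\tPOS\n" + "rs1\t1\t100\n")
        with pytest.raises(SchemaError, match="missing mandatory"):
            read_sumstats(f)

    def test_empty_file(self, tmp_path):
        f = tmp_path / "s.tsv"
        f.write_text(HEADER)
        with pytest.raises(SchemaError, match="no data rows"):
            read_sumstats(f)

    def test_comment_lines_and_column_map(self, tmp_path):
        f = tmp_path / "s.tsv"
        f.write_text("# a comment\n" +
                     HEADER.replace("SNP", "rsid") + _row("rs1"))
        records, _ = read_sumstats(f, column_map={"rsid": "SNP"})
        assert records[0].variant_id == "rs1"

    def test_missing_p_recomputed(self, tmp_path):
        f = tmp_path / "s.tsv"
        f.write_text("SNP\tCHR\tPOS\tEA\tOA\tBETA\tSE\n" +
                     "rs1\t1\t100\tA\tG\t0.1\t0.02\n")
        records, _ = read_sumstats(f)
        assert records[0].pval == pytest.approx(two_sided_p(5.0), rel=1e-12)

    def test_inconsistent_p_dropped(self, tmp_path):
        f = tmp_path / "s.tsv"
        f.write_text(HEADER + _row("rs1", beta=0.1, se=0.02, p=0.9))
        records, report = read_sumstats(f)
        assert records == []
        assert report.dropped[0][1] == "p inconsistent with beta/se"

    def test_round_trip(self, tmp_path):
        recs = [make_assoc("rs1"), make_assoc("rs2", pos=200, eaf=None)]
        f = tmp_path / "out.tsv"
        write_sumstats(recs, f)
        back, report = read_sumstats(f)
        assert report.n_dropped == 0
        assert back[0].beta == recs[0].beta
        assert back[1].eaf is None


class TestHarmonise:
    def test_sign_flip_identity(self):
        exp = make_assoc(ea="A", oa="G", beta=0.10)
        out = make_assoc(ea="G", oa="A", beta=-0.05)
        h = harmonise(exp, out)
        assert isinstance(h, HarmonisedInstrument)
        assert h.effect_allele == "A"
        assert h.beta_outcome == pytest.approx(0.05)

    def test_ambiguous_palindrome_rejected(self):
        exp = make_assoc(ea="A", oa="T", eaf=0.50)
        out = make_assoc(ea="A", oa="T", eaf=0.50)
        res = harmonise(exp, out)
        assert isinstance(res, Rejection)
        assert "ambiguous" in res.reason

    def test_palindrome_without_eaf_rejected(self):
        exp = make_assoc(ea="C", oa="G", eaf=None)
        out = make_assoc(ea="C", oa="G", eaf=0.2)
        assert isinstance(harmonise(exp, out), Rejection)

    def test_strand_flip_then_align(self):
        exp = make_assoc(ea="A", oa="G", beta=0.10)
        out = make_assoc(ea="T", oa="C", beta=-0.05)
        h = harmonise(exp, out)
        # T/C complements to A/G: same orientation as exposure, no sign flip
        assert isinstance(h, HarmonisedInstrument)
        assert h.beta_outcome == pytest.approx(-0.05)

    def test_all_nonpalindromic_configurations(self):
        # enumerate the 4 resolvable allele/strand configurations plus
        # an incompatible pair, exposure fixed at A/G
        exp = make_assoc(ea="A", oa="G", beta=0.10)
        cases = {
            ("A", "G"): +1,   # identical
            ("G", "A"): -1,   # swapped
            ("T", "C"): +1,   # complemented
            ("C", "T"): -1,   # complemented + swapped
        }
        for (ea, oa), sign in cases.items():
            out = make_assoc(ea=ea, oa=oa, beta=-0.05)
            h = harmonise(exp, out)
            assert isinstance(h, HarmonisedInstrument), (ea, oa)
            assert h.beta_outcome == pytest.approx(sign * -0.05), (ea, oa)
        bad = make_assoc(ea="A", oa="C", beta=-0.05)
        res = harmonise(exp, bad)
        assert isinstance(res, Rejection) and res.reason == "incompatible alleles"

    def test_palindromic_resolutions(self):
        # same-strand palindrome, clear frequencies: letters decide
        exp = make_assoc(ea="A", oa="T", eaf=0.10, beta=0.10)
        same = make_assoc(ea="A", oa="T", eaf=0.12, beta=0.05)
        h = harmonise(exp, same)
        assert h.beta_outcome == pytest.approx(0.05)
        swapped = make_assoc(ea="T", oa="A", eaf=0.88, beta=0.05)
        h2 = harmonise(exp, swapped)
        assert h2.beta_outcome == pytest.approx(-0.05)
        # opposite strand: outcome reports A at 0.9 -> its A is our T
        flipped_strand = make_assoc(ea="A", oa="T", eaf=0.90, beta=0.05)
        h3 = harmonise(exp, flipped_strand)
        assert h3.beta_outcome == pytest.approx(-0.05)

    def test_already_aligned_is_noop(self):
        exp = make_assoc(ea="A", oa="G", beta=0.10)
        out = make_assoc(ea="A", oa="G", beta=-0.05)
        h = harmonise(exp, out)
        assert (h.beta_outcome, h.se_outcome) == (out.beta, out.se)

    @given(beta=st.floats(-1, 1, allow_nan=False),
           eaf=st.floats(0.05, 0.95))
    @settings(max_examples=50, deadline=None)
    def test_involution_property(self, beta, eaf):
        exp = make_assoc(ea="A", oa="G", eaf=eaf, beta=0.1)
        out = make_assoc(ea="A", oa="G", eaf=eaf, beta=beta)
        h = harmonise(exp, out)
        assert h.beta_outcome == beta  # aligned pair untouched

    def test_harmonise_pairs_missing_outcome(self):
        exp = [make_assoc("rs1"), make_assoc("rs2", pos=200)]
        out = [make_assoc("rs1", beta=0.05)]
        kept, rejected = harmonise_pairs(exp, out)
        assert len(kept) == 1
        assert rejected[0].reason == "absent from outcome"


def _panel(r):
    ids = tuple(f"v{i}" for i in range(len(r)))
    return LDMatrix(ids, np.array(r))


class TestLDMatrix:
    def test_validation(self):
        with pytest.raises(ValidationError):
            LDMatrix(("a", "b"), np.array([[1.0, 0.5], [0.4, 1.0]]))  # asymmetric
        with pytest.raises(ValidationError):
            LDMatrix(("a", "b"), np.array([[1.0, 0.5], [0.5, 0.9]]))  # diag != 1
        with pytest.raises(ValidationError):
            LDMatrix(("a",), np.eye(2))  # dimension mismatch

    def test_file_round_trip(self, tmp_path):
        ld = _panel([[1.0, 0.6], [0.6, 1.0]])
        ld.to_files(tmp_path / "m.ld", tmp_path / "m.ids")
        back = LDMatrix.from_files(tmp_path / "m.ld", tmp_path / "m.ids")
        assert back.variant_ids == ld.variant_ids
        np.testing.assert_allclose(back.r, ld.r)


class TestFindProxy:
    def test_high_r2_candidate(self):
        ld = _panel([[1.0, np.sqrt(0.95)], [np.sqrt(0.95), 1.0]])
        assert find_proxy("v0", ["v1"], ld) == "v1"

    def test_below_threshold_none(self):
        ld = _panel([[1.0, np.sqrt(0.5)], [np.sqrt(0.5), 1.0]])
        assert find_proxy("v0", ["v1"], ld) is None

    def test_argmax_rule(self):
        r12, r13 = np.sqrt(0.92), np.sqrt(0.85)
        ld = _panel([[1.0, r12, r13], [r12, 1.0, 0.5], [r13, 0.5, 1.0]])
        assert find_proxy("v0", ["v1", "v2"], ld) == "v1"

    def test_target_absent_is_error(self):
        ld = _panel([[1.0]])
        with pytest.raises(LDPanelError):
            find_proxy("missing", ["v0"], ld)

    def test_self_proxy(self):
        ld = _panel([[1.0, 0.1], [0.1, 1.0]])
        assert find_proxy("v0", ["v0", "v1"], ld) == "v0"


class TestLDPrune:
    def _two(self, r2, p1, p2):
        r = np.sqrt(r2)
        ld = LDMatrix(("rs1", "rs2"), np.array([[1.0, r], [r, 1.0]]))
        a = make_assoc("rs1", pos=100, pval=p1, beta=1e-9, se=1.0)
        b = make_assoc("rs2", pos=200, pval=p2, beta=1e-9, se=1.0)
        return [a, b], ld

    def test_correlated_keeps_lowest_p(self):
        recs, ld = self._two(0.5, 1e-10, 1e-8)
        kept = ld_prune(recs, ld)
        assert [r.variant_id for r in kept] == ["rs1"]

    def test_independent_keeps_both(self):
        recs, ld = self._two(0.0005, 1e-10, 1e-8)
        assert len(ld_prune(recs, ld)) == 2

    def test_tie_breaks_by_position(self):
        recs, ld = self._two(0.5, 1e-8, 1e-8)
        kept = ld_prune(recs[::-1], ld)
        assert [r.variant_id for r in kept] == ["rs1"]  # lower pos wins

    def test_missing_variant_named(self):
        recs, ld = self._two(0.5, 1e-10, 1e-8)
        recs.append(make_assoc("rs999", pos=300, beta=1e-9, se=1.0, pval=0.5))
        with pytest.raises(LDPanelError, match="rs999"):
            ld_prune(recs, ld)

    def test_order_independence_and_r2_bound(self):
        rng = np.random.default_rng(7)
        m = 8
        a = rng.normal(size=(m, m + 3))
        r = np.corrcoef(a)
        ids = tuple(f"rs{i}" for i in range(m))
        ld = LDMatrix(ids, r)
        recs = [make_assoc(f"rs{i}", pos=100 + i, beta=1e-9, se=1.0,
                           pval=float(rng.uniform(1e-10, 1e-3)))
                for i in range(m)]
        kept1 = ld_prune(recs, ld, r2_max=0.2)
        kept2 = ld_prune(recs[::-1], ld, r2_max=0.2)
        assert [r.variant_id for r in kept1] == [r.variant_id for r in kept2]
        for i, x in enumerate(kept1):
            for y in kept1[i + 1:]:
                assert ld.r2(x.variant_id, y.variant_id) < 0.2
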