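"""Exclusion filters, alignment-based indel discovery, window presence
testing, annotation, and N50."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from telmap import (
    GeneModel,
    GenomicInterval,
    PanelLine,
    RegionSequence,
    Variant,
    VariantSet,
    annotate_candidates,
    apply_variant,
    contig_n50,
    discover_large_indels,
    exclude_by_panel,
    indel_presence_in_window,
    restrict_to_interval,
    subtract_control,
)
from telmap.exclusion import SURVIVED, AlignmentQualityError


def make_ref(n=2000, seed=0, chrom="3R", origin=1000):
    rng = np.random.default_rng(seed)
    return RegionSequence(chrom, origin, "".join(rng.choice(list("ACGT"), size=n)))


def vset(name, *variants, normalized=True):
    return VariantSet(name, variants, normalized=normalized)


class TestSubtractControl:
    A = Variant("3R", 1100, "A", "G")
    B = Variant("3R", 1200, "C", "T")
    C = Variant("3R", 1300, "G", "A")

    def test_shared_variant_removed(self):
        out, prov = subtract_control(vset("m", self.A, self.B, self.C),
                                     vset("c", self.B))
        assert {v.key for v in out} == {self.A.key, self.C.key}
        assert prov[self.B.key] == "in_control"

    def test_disjoint_sets_unchanged(self):
        out, _ = subtract_control(vset("m", self.A), vset("c", self.C))
        assert {v.key for v in out} == {self.A.key}

    def test_unnormalized_input_rejected(self):
        with pytest.raises(ValueError, match="not normalized"):
            subtract_control(vset("m", self.A, normalized=False), vset("c"))


class TestRestrictToInterval:
    iv = GenomicInterval("3R", 1100, 1200)

    def test_boundary_positions_retained(self):
        s = vset("m", Variant("3R", 1100, "A", "G"), Variant("3R", 1200, "C", "T"))
        out, _ = restrict_to_interval(s, self.iv)
        assert len(out) == 2

    def test_one_bp_outside_dropped(self):
        s = vset("m", Variant("3R", 1099, "A", "G"), Variant("3R", 1201, "C", "T"))
        out, prov = restrict_to_interval(s, self.iv)
        assert len(out) == 0
        assert set(prov.values()) == {"outside_interval"}

    def test_straddling_deletion_kept(self):
        # anchor at 1095 (outside) but deleted bases run to 1102 (inside)
        d = Variant("3R", 1095, "ACGTACGT", "A")
        out, _ = restrict_to_interval(vset("m", d), self.iv)
        assert len(out) == 1

    def test_deletion_ending_just_before_interval_dropped(self):
        d = Variant("3R", 1090, "ACGTACGTA", "A")  # span 1090-1098
        out, _ = restrict_to_interval(vset("m", d), self.iv)
        assert len(out) == 0

    def test_other_chromosome_dropped_with_provenance(self):
        s = vset("m", Variant("2L", 1150, "A", "G"))
        out, prov = restrict_to_interval(s, self.iv)
        assert len(out) == 0
        assert list(prov.values()) == ["other_chromosome"]


class TestExcludeByPanel:
    A = Variant("3R", 1100, "A", "G")
    D = Variant("3R", 1200, "CTG", "C")

    def panel(self, *line_variants, phenotype="normal"):
        return [
            PanelLine(line_id=f"l{i}", phenotype=phenotype, variants=vset(f"l{i}", *vs))
            for i, vs in enumerate(line_variants)
        ]

    def test_variant_in_one_line_excluded(self):
        rep = exclude_by_panel(vset("m", self.A, self.D), self.panel((self.A,)))
        assert {v.key for v in rep.survivors} == {self.D.key}
        assert rep.provenance[self.A.key] == "in_panel:l0"

    def test_absent_variant_survives(self):
        rep = exclude_by_panel(vset("m", self.D), self.panel((self.A,)))
        assert rep.provenance[self.D.key] == SURVIVED

    def test_outlier_lines_do_not_exclude(self):
        rep = exclude_by_panel(vset("m", self.A),
                               self.panel((self.A,), phenotype="outlier"))
        assert len(rep.survivors) == 1

    def test_empty_panel_is_identity(self):
        rep = exclude_by_panel(vset("m", self.A, self.D), [])
        assert len(rep.survivors) == 2

    def test_class_restriction(self):
        # an indel-carrying line must not exclude when only SNPs are in scope
        rep = exclude_by_panel(vset("m", self.A, self.D),
                               self.panel((self.A, self.D)), classes="SNP")
        assert {v.key for v in rep.survivors} == {self.D.key}

    def test_filters_compose_to_exact_provenance_partition(self):
        ref = make_ref()
        mut = vset("m", self.A, self.D, Variant("3R", 1300, "G", "A"),
                   Variant("2L", 1150, "T", "C"))
        ctl = vset("c", Variant("3R", 1300, "G", "A"))
        prov = {}
        s1, p1 = subtract_control(mut, ctl)
        s2, p2 = restrict_to_interval(s1, GenomicInterval("3R", 1000, 1150))
        rep = exclude_by_panel(s2, self.panel((self.A,)))
        for p in (p1, p2, rep.provenance):
            prov.update({k: v for k, v in p.items() if v != SURVIVED})
        for v in rep.survivors:
            prov[v.key] = SURVIVED
        assert set(prov) == mut.keys()  # every input in exactly one bin
        assert sorted(prov.values()) == sorted(
            ["in_control", "in_panel:l0", "other_chromosome", "outside_interval"])
        assert len(rep.survivors) == 0


class TestDiscoverLargeIndels:
    def test_planted_deletion_recovered_exactly(self):
        ref = make_ref(1200, seed=1)
        # excise 8 bp at genomic 1500 (offset 500)
        contig = ref.seq[:500] + ref.seq[508:]
        found = discover_large_indels(contig, ref, min_len=5)
        assert len(found) == 1
        v = found[0]
        assert v.variant_class == "deletion" and v.indel_length == 8
        # haplotype oracle: applying the call to the reference gives the contig
        assert apply_variant(ref.seq, ref.origin, v) == contig

    def test_identical_sequences_no_calls(self):
        ref = make_ref(800, seed=2)
        assert discover_large_indels(ref.seq, ref) == []

    def test_min_len_filters_small_events(self):
        ref = make_ref(1500, seed=3)
        rng = np.random.default_rng(9)
        ins = "".join(rng.choice(list("ACGT"), size=12))
        # 12 bp insertion at offset 300, 3 bp deletion at offset 900
        contig = ref.seq[:300] + ins + ref.seq[300:900] + ref.seq[903:]
        found = discover_large_indels(contig, ref, min_len=5)
        assert len(found) == 1
        assert found[0].variant_class == "insertion"
        assert found[0].indel_length == 12
        both = discover_large_indels(contig, ref, min_len=1)
        assert sorted(v.variant_class for v in both) == ["deletion", "insertion"]

    def test_normalized_keys_match_planted_truth(self):
        ref = make_ref(1000, seed=4)
        planted = Variant("3R", 1400, ref.fetch(1400, 1409), ref.base(1400))
        contig = apply_variant(ref.seq, ref.origin, planted)
        found = discover_large_indels(contig, ref, min_len=5)
        from telmap import normalize_variant
        assert [v.key for v in found] == [normalize_variant(planted, ref).key]

    def test_unrelated_sequence_rejected(self):
        ref = RegionSequence("3R", 1, "A" * 400)
        with pytest.raises(AlignmentQualityError):
            discover_large_indels("C" * 400, ref)


@pytest.fixture(scope="module")
def setup():
    ref = make_ref(3000, seed=5)
    v = Variant("3R", 2200, ref.fetch(2200, 2203), ref.base(2200))  # 3 bp del
    alt_window = apply_variant(ref.fetch(1900, 2500), 1900, v)
    ref_window = ref.fetch(1900, 2500)
    return ref, v, ref_window, alt_window


class TestIndelPresenceInWindow:

    def test_alternate_window_present(self, setup):
        ref, v, _, alt_window = setup
        assert indel_presence_in_window(v, alt_window, ref) == "present"

    def test_reference_window_absent(self, setup):
        ref, v, ref_window, _ = setup
        assert indel_presence_in_window(v, ref_window, ref) == "absent"

    def test_unrelated_snp_in_core_undetermined(self, setup):
        ref, v, ref_window, _ = setup
        # corrupt one base 5 bp from the deletion site inside both cores
        i = (2205 - 1900)
        base = ref_window[i]
        other = {"A": "C", "C": "G", "G": "T", "T": "A"}[base]
        noisy = ref_window[:i] + other + ref_window[i + 1:]
        assert indel_presence_in_window(v, noisy, ref) == "undetermined"


class TestAnnotateCandidates:
    gene = GeneModel(
        gene_id="geneA", chrom="3R",
        exons=tuple((1000 + k * 100, 1000 + k * 100 + 19) for k in range(10)),
    )  # introns of 80 bp between 20 bp exons; intron 8 spans 1720-1799

    def test_intron_8_variant(self):
        v = Variant("3R", 1749, "ATGT", "A")  # first deleted base 1750
        rep = annotate_candidates(vset("m", v), [self.gene])
        ann = rep.annotations[v.key]
        assert (ann.kind, ann.gene, ann.intron_index) == ("intronic", "geneA", 8)

    def test_exonic_variant(self):
        v = Variant("3R", 1205, "A", "G")
        ann = annotate_candidates(vset("m", v), [self.gene]).annotations[v.key]
        assert (ann.kind, ann.exon_index) == ("exonic", 3)

    def test_intergenic_distances(self):
        left = GeneModel(gene_id="L", chrom="3R", exons=((100, 200),))
        right = GeneModel(gene_id="R", chrom="3R", exons=((900, 950),))
        v = Variant("3R", 400, "A", "G")
        ann = annotate_candidates(vset("m", v), [left, right]).annotations[v.key]
        assert ann.kind == "intergenic"
        assert (ann.left_gene, ann.left_distance) == ("L", 200)
        assert (ann.right_gene, ann.right_distance) == ("R", 500)

    def test_no_annotation_infinite_distances(self):
        v = Variant("3R", 400, "A", "G")
        ann = annotate_candidates(vset("m", v), []).annotations[v.key]
        assert ann.kind == "intergenic"
        assert ann.left_distance == float("inf")


class TestContigN50:
    @pytest.mark.parametrize(
        "lengths,expected",
        [([2, 2, 2, 3, 3, 4], 3), ([7], 7), ([5, 5, 5, 5], 5), ([1, 1, 10], 10)],
    )
    def test_known_values(self, lengths, expected):
        assert contig_n50(lengths) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            contig_n50([])

    @settings(max_examples=100, derandomize=True)
    @given(lengths=st.lists(st.integers(1, 500), min_size=1, max_size=40))
    def test_matches_bruteforce_definition(self, lengths):
        total = sum(lengths)
        candidates = [
            L for L in sorted(set(lengths), reverse=True)
            if sum(x for x in lengths if x >= L) * 2 >= total
        ]
        assert contig_n50(lengths) == max(candidates)
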