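"""Repair-template construction and the Cas9 counter-selection escape."""

import pytest

from crmage.genome_io import (
    CdsFeature,
    EditSpec,
    GenomeSequence,
    Interval,
    reverse_complement,
)
from crmage.offtarget import GuideCandidate, brute_force_offtargets, count_offtargets
from crmage.pam_scan import N20, PamSite, extract_n20, find_pam_sites
from crmage.template import (
    EscapeError,
    TemplateError,
    apply_template,
    build_template,
    ensure_cas9_escape,
    locus_is_cleavable,
)

GUIDE = "ACGTTGCAGGATCCTTAACG"


def genome_with_site(pad_left=100, pad_right=100, pam="TGG", strand="+"):
    """Linear genome holding one perfect protospacer+PAM locus."""
    if strand == "+":
        core = GUIDE + pam
    else:
        core = reverse_complement(GUIDE + pam)
    seq = "ATCG" * (pad_left // 4) + core + "CTAG" * (pad_right // 4)
    genome = GenomeSequence("c1", seq)
    if strand == "+":
        site = PamSite("c1", pad_left + 20, "+", pam, Interval(pad_left, pad_left + 20))
    else:
        site = PamSite("c1", pad_left, "-", pam,
                       Interval(pad_left + 3, pad_left + 23))
    n20 = N20(GUIDE, site)
    return genome, GuideCandidate(n20=n20, site=site, offtarget_count=0)


class TestBuildTemplate:
    def test_default_length_single_difference(self):
        genome, _ = genome_with_site()
        edit = EditSpec("c1", 110, genome.fetch(110, 111), "T"
                        if genome.fetch(110, 111) != "T" else "A", "e")
        t = build_template(genome, edit)
        assert len(t.seq) == 80
        window = genome.fetch(t.interval.start, t.interval.end)
        diffs = [i for i, (a, b) in enumerate(zip(window, t.seq)) if a != b]
        assert diffs == [edit.pos - t.interval.start]
        assert [e.reason for e in t.edits_applied] == ["desired"]

    def test_tiny_hand_checkable(self):
        genome = GenomeSequence("c1", "AAGAA")
        t = build_template(genome, EditSpec("c1", 2, "G", "A", "e"), length=5)
        assert t.seq == "AAAAA"
        assert t.interval == Interval(0, 5)

    def test_multibase_edit_two_entries(self):
        genome = GenomeSequence("c1", "A" * 40 + "GT" + "A" * 40)
        t = build_template(genome, EditSpec("c1", 40, "GT", "AC", "e"))
        reasons = [(e.pos, e.ref, e.alt, e.reason) for e in t.edits_applied]
        assert reasons == [(40, "G", "A", "desired"), (41, "T", "C", "desired")]

    def test_partially_matching_alt_lists_only_differences(self):
        genome = GenomeSequence("c1", "A" * 40 + "GT" + "A" * 40)
        t = build_template(genome, EditSpec("c1", 40, "GT", "GA", "e"))
        assert [(e.pos, e.ref, e.alt) for e in t.edits_applied] == [(41, "T", "A")]

    def test_off_contig_error_names_padding(self):
        genome = GenomeSequence("c1", "A" * 60 + "G" + "A" * 100)
        with pytest.raises(TemplateError, match="padding"):
            build_template(genome, EditSpec("c1", 10, "A", "G", "e"))

    def test_circular_wraps(self):
        genome = GenomeSequence("c1", "G" + "A" * 99, circular=True)
        t = build_template(genome, EditSpec("c1", 0, "G", "T", "e"))
        assert len(t.seq) == 80
        post = apply_template(genome, t)
        assert post.fetch(0, 1) == "T"


class TestApplyTemplate:
    def test_definition_round_trip(self):
        genome, _ = genome_with_site()
        edit = EditSpec("c1", 112, genome.fetch(112, 113),
                        "G" if genome.fetch(112, 113) != "G" else "C", "e")
        t = build_template(genome, edit)
        post = apply_template(genome, t)
        assert post.fetch(t.interval.start, t.interval.end) == t.seq
        # the inverse edit now validates against the recombined genome
        inverse = EditSpec("c1", edit.pos, edit.alt, edit.ref, "inv")
        inverse.validate_against(post)

    def test_lengths_and_untouched_flanks(self):
        genome, _ = genome_with_site()
        edit = EditSpec("c1", 112, genome.fetch(112, 113),
                        "G" if genome.fetch(112, 113) != "G" else "C", "e")
        t = build_template(genome, edit)
        post = apply_template(genome, t)
        assert len(post) == len(genome)
        assert post.fetch(0, t.interval.start) == genome.fetch(0, t.interval.start)


class TestEnsureCas9Escape:
    def _edit_outside_protospacer(self, genome, candidate):
        pos = candidate.site.protospacer.start - 10
        ref = genome.fetch(pos, pos + 1)
        alt = "A" if ref != "A" else "T"
        return EditSpec("c1", pos, ref, alt, "e")

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_edit_outside_locus_gains_pam_escape(self, strand):
        genome, cand = genome_with_site(strand=strand)
        edit = self._edit_outside_protospacer(genome, cand)
        t = build_template(genome, edit)
        escaped = ensure_cas9_escape(genome, t, cand)
        reasons = [e.reason for e in escaped.edits_applied]
        assert reasons.count("pam_escape") == 1
        post = apply_template(genome, escaped)
        assert not locus_is_cleavable(post, cand)
        # the recombined genome carries no perfect protospacer+PAM anywhere
        assert brute_force_offtargets(post, cand.n20, threshold=1, require_pam=True) == []

    def test_default_escape_mutates_second_pam_g_to_a(self):
        genome, cand = genome_with_site(strand="+")
        edit = self._edit_outside_protospacer(genome, cand)
        escaped = ensure_cas9_escape(genome, build_template(genome, edit), cand)
        (esc,) = [e for e in escaped.edits_applied if e.reason == "pam_escape"]
        assert esc.pos == cand.site.pam_start + 2
        assert (esc.ref, esc.alt) == ("G", "A")

    def test_edit_in_pam_needs_no_extra_mutation(self):
        genome, cand = genome_with_site(strand="+")
        pos = cand.site.pam_start + 2  # second G of NGG
        edit = EditSpec("c1", pos, "G", "T", "e")
        t = build_template(genome, edit)
        escaped = ensure_cas9_escape(genome, t, cand)
        assert escaped == t
        assert all(e.reason == "desired" for e in escaped.edits_applied)

    def test_edit_in_protospacer_escapes_under_strict_rule(self):
        genome, cand = genome_with_site(strand="+")
        pos = cand.site.protospacer.start + 10
        ref = genome.fetch(pos, pos + 1)
        edit = EditSpec("c1", pos, ref, "A" if ref != "A" else "T", "e")
        t = build_template(genome, edit)
        escaped = ensure_cas9_escape(genome, t, cand)
        assert escaped == t  # one mismatch already defeats a perfect-match Cas9
        post = apply_template(genome, escaped)
        assert count_offtargets(post, cand.n20, threshold=1, require_pam=True
                                ).offtarget_count == 0

    def test_permissive_rule_forces_pam_mutation(self):
        genome, cand = genome_with_site(strand="+")
        pos = cand.site.protospacer.start + 10
        ref = genome.fetch(pos, pos + 1)
        edit = EditSpec("c1", pos, ref, "A" if ref != "A" else "T", "e")
        t = build_template(genome, edit)
        escaped = ensure_cas9_escape(genome, t, cand, escape_min_mismatches=3)
        assert any(e.reason == "pam_escape" for e in escaped.edits_applied)

    def test_pam_outside_template_is_error(self):
        genome, cand = genome_with_site(pad_left=200, pad_right=200)
        # an edit far from the locus: its 80-base template cannot reach the PAM
        edit = EditSpec("c1", 320, genome.fetch(320, 321),
                        "A" if genome.fetch(320, 321) != "A" else "T", "e")
        t = build_template(genome, edit)
        with pytest.raises(EscapeError, match="longer template"):
            ensure_cas9_escape(genome, t, cand)

    def _coding_locus(self, right_pad_start):
        """Genome with GUIDE at [100, 120) and PAM 'CGG' at [120, 123).

        GUIDE ends in G, so genome[119:123] == 'GCGG'; the bases after the
        PAM are taken from ``right_pad_start``.
        """
        left = "ATCG" * 25
        seq = left + GUIDE + "CGG" + right_pad_start + "CTAG" * 25
        genome = GenomeSequence("c1", seq)
        site = PamSite("c1", 120, "+", "CGG", Interval(100, 120))
        cand = GuideCandidate(n20=N20(GUIDE, site), site=site, offtarget_count=0)
        pos = 90
        ref = genome.fetch(pos, pos + 1)
        edit = EditSpec("c1", pos, ref, "A" if ref != "A" else "T", "e")
        return genome, cand, build_template(genome, edit)

    def test_synonymous_escape_preferred_when_available(self):
        # Frame starting at 119 puts the second PAM G (122) at a first codon
        # position of GGA (Gly): G->A/C/T all change the amino acid.  The
        # first PAM G (121) is the third position of GCG (Ala): G->A gives
        # GCA, still Ala.  The CDS-aware escape must therefore pick 121.
        genome, cand, t = self._coding_locus(right_pad_start="GA")
        assert genome.fetch(119, 125) == "GCGGGA"
        cds = [CdsFeature("c1", 119, 125, "+", 0)]
        escaped = ensure_cas9_escape(genome, t, cand, cds=cds)
        (esc,) = [e for e in escaped.edits_applied if e.reason == "pam_escape"]
        assert (esc.pos, esc.ref, esc.alt) == (121, "G", "A")
        post = apply_template(genome, escaped)
        assert not locus_is_cleavable(post, cand)

    def test_no_synonymous_option_falls_back_to_default(self):
        # Frame starting at 121 makes the codon GGG (Gly): mutating either
        # PAM G (first or second codon position) is never synonymous, so the
        # default second-G -> A substitution is kept.
        genome, cand, t = self._coding_locus(right_pad_start="G")
        assert genome.fetch(121, 124) == "GGG"
        cds = [CdsFeature("c1", 121, 124, "+", 0)]
        escaped = ensure_cas9_escape(genome, t, cand, cds=cds)
        (esc,) = [e for e in escaped.edits_applied if e.reason == "pam_escape"]
        assert (esc.pos, esc.ref, esc.alt) == (122, "G", "A")
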