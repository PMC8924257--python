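"""80-base repair-template construction and Cas9 counter-selection escape.

CRMAGE selects for recombinants by letting Cas9 cleave the unedited locus:
the single-stranded repair oligo must therefore both carry the desired
change and leave the recombined genome invisible to the guide.  A locus is
considered cleavable when the protospacer still matches the guide with
fewer than ``escape_min_mismatches`` mismatches (default 1, i.e. only a
perfect match cleaves) *and* an NGG PAM is intact on the guide's strand.
When the desired edit alone does not already break this condition, one
extra mutation is written into the template at one of the PAM's two G
positions (the classic two-mutation oligo design: one change does the
biology, the other buys escape from Cas9).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

from Bio.Seq import Seq

from .genome_io import (
    CdsFeature,
    EditSpec,
    GenomeSequence,
    Interval,
    reverse_complement,
)
from .offtarget import GuideCandidate
from .pam_scan import PAM_LENGTH, PROTOSPACER_LENGTH

log = logging.getLogger(__name__)

DEFAULT_TEMPLATE_LENGTH = 80

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


class TemplateError(ValueError):
    pass


class EscapeError(TemplateError):
    """The template cannot be made to escape Cas9 counter-selection."""


@dataclass(frozen=True)
class AppliedEdit:
    """One base change carried by a template, with its purpose."""

    pos: int  # genomic, 0-based
    ref: str
    alt: str
    reason: str  # "desired" or "pam_escape"


@dataclass(frozen=True)
class RepairTemplate:
    """Single-stranded homology repair oligo spanning ``interval``.

    ``seq`` is written on the forward strand by default; it differs from the
    genomic subsequence of ``interval`` exactly at ``edits_applied``.
    """

    seq: str
    contig: str
    interval: Interval
    edits_applied: tuple[AppliedEdit, ...]
    strand: str = "+"

    def __post_init__(self) -> None:
        if len(self.seq) != self.interval.length:
            raise TemplateError("template sequence length must match its interval")
        if not any(e.reason == "desired" for e in self.edits_applied):
            raise TemplateError("template must carry at least one desired edit")

    @property
    def oligo(self) -> str:
        """The oligo sequence on the requested synthesis strand."""
        return self.seq if self.strand == "+" else reverse_complement(self.seq)


def build_template(
    genome: GenomeSequence,
    edit: EditSpec,
    length: int = DEFAULT_TEMPLATE_LENGTH,
    strand: str = "+",
) -> RepairTemplate:
    """Repair template of ``length`` bases centered on the edit.

    Centering mirrors the PAM-scan neighborhood (center = pos + len(ref)//2)
    so that with the default window the two intervals coincide.  On a linear
    contig the full window must fit (an error names the padding required);
    on a circular contig it wraps.
    """
    if length < len(edit.ref):
        raise TemplateError(
            f"template length {length} shorter than edit {edit.label!r} ref"
        )
    L = len(genome)
    center = edit.pos + len(edit.ref) // 2
    start = center - length // 2
    end = start + length
    if genome.circular:
        if length > L:
            raise TemplateError("template longer than circular contig")
        start %= L
        end = start + length
    elif start < 0 or end > L:
        pad = max(0 - start, end - L)
        raise TemplateError(
            f"template window [{start}, {end}) runs off linear contig "
            f"{genome.name!r} (length {L}); needs {pad} base(s) of padding"
        )
    window = genome.fetch(start, end)
    off = (edit.pos - start) % L if genome.circular else edit.pos - start
    if off < 0 or off + len(edit.ref) > length:
        raise TemplateError(f"edit {edit.label!r} does not fit inside the template")
    if window[off : off + len(edit.ref)] != edit.ref:
        raise TemplateError(f"edit {edit.label!r} ref mismatch inside template window")
    seq = window[:off] + edit.alt + window[off + len(edit.ref) :]
    applied = tuple(
        AppliedEdit(pos=(edit.pos + i) % L, ref=r, alt=a, reason="desired")
        for i, (r, a) in enumerate(zip(edit.ref, edit.alt))
        if r != a
    )
    return RepairTemplate(
        seq=seq, contig=genome.name, interval=Interval(start, end),
        edits_applied=applied, strand=strand,
    )


def apply_template(genome: GenomeSequence, template: RepairTemplate) -> GenomeSequence:
    """In-silico recombineering: replace the template interval in the genome.

    Models perfect homologous replacement; used to verify escape and for
    round-trip consistency checks.
    """
    if template.contig != genome.name:
        raise TemplateError(
            f"template contig {template.contig!r} != genome {genome.name!r}"
        )
    start, end = template.interval
    L = len(genome)
    if not genome.circular and (start < 0 or end > L):
        raise TemplateError("template interval outside linear contig")
    s = start % L
    seq = list(genome.seq)
    for i, base in enumerate(template.seq):
        seq[(s + i) % L] = base
    return GenomeSequence(name=genome.name, seq="".join(seq), circular=genome.circular)


def locus_is_cleavable(
    genome: GenomeSequence,
    guide: GuideCandidate,
    escape_min_mismatches: int = 1,
) -> bool:
    """Can Cas9 still cut the guide's on-target locus in this genome?

    True iff the protospacer read from the genome has Hamming distance
    < ``escape_min_mismatches`` to the spacer and the PAM reads NGG on the
    guide's strand.
    """
    site = guide.site
    proto = genome.fetch(site.protospacer.start, site.protospacer.end)
    if site.strand == "-":
        proto = reverse_complement(proto)
    mm = sum(a != b for a, b in zip(proto, guide.n20.seq))
    if mm >= escape_min_mismatches:
        return False
    pam = genome.fetch(site.pam_start, site.pam_start + PAM_LENGTH)
    if site.strand == "-":
        pam = reverse_complement(pam)
    return pam[1:3] == "GG"


def _pam_g_positions(site) -> list[int]:
    """Forward-coordinate genomic positions of the PAM's two G's.

    Ordered by preference: the second G of NGG first (the default escape
    target), then the first.  On the minus strand the NGG G's sit at lower
    forward coordinates (as C's on the forward strand).
    """
    if site.strand == "+":
        return [site.pam_start + 2, site.pam_start + 1]
    return [site.pam_start, site.pam_start + 1]


def _synonymous(
    recombined: GenomeSequence,
    pos: int,
    new_base: str,
    cds: Sequence[CdsFeature],
) -> bool | None:
    """Is the substitution synonymous under the standard code?  None if non-coding."""
    for feat in cds:
        if feat.contig != recombined.name:
            continue
        off = feat.contig_pos_in_frame(pos)
        if off is None:
            continue
        if feat.strand == "+":
            codon_start = pos - off % 3
            codon_iv = (codon_start, codon_start + 3)
        else:
            codon_end = pos + off % 3 + 1
            codon_iv = (codon_end - 3, codon_end)
        if codon_iv[0] < 0 or codon_iv[1] > len(recombined):
            continue
        before = list(recombined.fetch(*codon_iv))
        after = before.copy()
        after[pos - codon_iv[0]] = new_base
        if feat.strand == "-":
            before = list(reverse_complement("".join(before)))
            after = list(reverse_complement("".join(after)))
        return str(Seq("".join(before)).translate()) == str(Seq("".join(after)).translate())
    return None


def ensure_cas9_escape(
    genome: GenomeSequence,
    template: RepairTemplate,
    guide: GuideCandidate,
    cds: Sequence[CdsFeature] | None = None,
    escape_min_mismatches: int = 1,
) -> RepairTemplate:
    """Guarantee the recombined genome escapes cleavage by ``guide``.

    If applying the template already breaks the cleavage condition (the
    desired edit hit the PAM or, under a permissive ``escape_min_mismatches``,
    the protospacer), the template is returned unchanged.  Otherwise one
    G -> non-G mutation is added inside the template at a PAM G position
    (second G of NGG to A by default; when CDS annotation is supplied, a
    synonymous choice is preferred).  Raises :class:`EscapeError` when no
    PAM G position lies inside the template interval.
    """
    recombined = apply_template(genome, template)
    if not locus_is_cleavable(recombined, guide, escape_min_mismatches):
        return template
    L = len(genome)
    in_template = [
        pos for pos in _pam_g_positions(guide.site)
        if template.interval.contains(pos, L if genome.circular else None)
    ]
    if not in_template:
        raise EscapeError(
            f"PAM at {guide.site.contig}:{guide.site.pam_start} not covered by the "
            f"template interval [{template.interval.start}, {template.interval.end}); "
            f"use a longer template or a different guide"
        )
    # Candidate substitutions in deterministic preference order; bases are
    # expressed on the PAM's strand and complemented onto the forward strand.
    candidates: list[tuple[int, str]] = []
    for pos in in_template:
        for pam_strand_base in "ACT":
            fwd = pam_strand_base if guide.site.strand == "+" else _COMP[pam_strand_base]
            candidates.append((pos, fwd))
    chosen = candidates[0]
    if cds:
        for pos, fwd in candidates:
            if _synonymous(recombined, pos, fwd, cds):
                chosen = (pos, fwd)
                break
    pos, fwd = chosen
    start = template.interval.start
    off = (pos - start) % L if genome.circular else pos - start
    old = template.seq[off]
    escaped = replace(
        template,
        seq=template.seq[:off] + fwd + template.seq[off + 1 :],
        edits_applied=template.edits_applied
        + (AppliedEdit(pos=pos, ref=old, alt=fwd, reason="pam_escape"),),
    )
    if locus_is_cleavable(apply_template(genome, escaped), guide, escape_min_mismatches):
        raise EscapeError("escape mutation failed to disable the PAM")  # unreachable
    return escaped
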