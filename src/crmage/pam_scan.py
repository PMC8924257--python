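"""NGG PAM discovery near an edit and N20 protospacer extraction.

SpCas9 requires an NGG protospacer-adjacent motif (PAM) immediately 3' of
the 20-base protospacer.  Both strands are scanned: a forward-strand PAM at
position ``p`` reads ``seq[p:p+3] == NGG``; a reverse-strand PAM occupying
forward coordinates ``[p, p+3)`` reads NGG on its own strand exactly when
the forward sequence there starts ``CC`` (revcomp(CCx) == xGG... precisely,
revcomp("CC"+b) == comp(b)+"GG").

Strand convention for the spacer: the N20 is written 5'->3' on the
protospacer (non-target) strand, i.e. it equals the spacer sequence cloned
into the gRNA.  On the minus strand the protospacer interval lies at
*higher* forward coordinates than the PAM triplet.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .genome_io import EditSpec, GenomeSequence, GenomeIOError, Interval, reverse_complement

log = logging.getLogger(__name__)

PROTOSPACER_LENGTH = 20
PAM_LENGTH = 3
DEFAULT_WINDOW = 80


class PamScanError(ValueError):
    pass


@dataclass(frozen=True)
class PamSite:
    """One candidate NGG PAM and its protospacer placement.

    ``pam_start`` is the 0-based forward-coordinate start of the 3-base PAM
    triplet regardless of strand; ``protospacer`` is the 0-based half-open
    forward-coordinate interval of the 20 protospacer bases (its ``end`` may
    exceed the contig length on a circular contig, meaning wrap-around).
    """

    contig: str
    pam_start: int
    strand: str
    pam_seq: str
    protospacer: Interval

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise PamScanError(f"bad strand {self.strand!r}")
        if self.pam_seq[1:3] != "GG":
            raise PamScanError(f"PAM {self.pam_seq!r} does not read NGG on its strand")
        if self.protospacer.length != PROTOSPACER_LENGTH:
            raise PamScanError("protospacer interval must have length 20")


@dataclass(frozen=True)
class N20:
    """The 20-base spacer sequence, 5'->3' on the protospacer strand."""

    seq: str
    site: PamSite

    def __post_init__(self) -> None:
        if len(self.seq) != PROTOSPACER_LENGTH:
            raise PamScanError("N20 must be exactly 20 bases")
        if "N" in self.seq:
            raise PamScanError("N20 may not contain N")

    @property
    def contig(self) -> str:
        return self.site.contig


def neighborhood(
    edit: EditSpec,
    genome: GenomeSequence,
    window: int = DEFAULT_WINDOW,
    offset: int = 0,
) -> Interval:
    """Interval of ``window`` bases around an edit, clipped to the contig.

    The window is centered on the edit (center = pos + len(ref)//2, shifted
    by ``offset`` bases to allow off-center placement), matching the repair
    template placement so that every PAM in the window lies inside the
    default-length template.  On a linear contig the interval is clipped to
    the contig bounds (logged, not an error); on a circular contig it wraps.
    """
    if window < 1:
        raise PamScanError("window must be >= 1")
    center = edit.pos + len(edit.ref) // 2 + offset
    start = center - window // 2
    end = start + window
    L = len(genome)
    if genome.circular:
        if window > L:
            start, end = 0, L
        return Interval(start % L, start % L + (end - start))
    clipped = Interval(max(0, start), min(L, end))
    if clipped != (start, end):
        log.warning(
            "window for edit %r clipped from [%d, %d) to [%d, %d) at contig bounds",
            edit.label, start, end, clipped.start, clipped.end,
        )
    return clipped


def find_pam_sites(genome: GenomeSequence, region: Interval) -> list[PamSite]:
    """All NGG PAM triplets fully inside ``region``, on both strands.

    Overlapping matches are all reported.  Sites whose 20-base protospacer
    would run off a linear contig, or whose protospacer or PAM contains N,
    are dropped (logged at debug level).
    """
    L = len(genome)
    if not genome.circular:
        region = Interval(max(0, region.start), min(L, region.end))
    sites: list[PamSite] = []
    for p in range(region.start, region.end - PAM_LENGTH + 1):
        triplet = genome.fetch(p, p + PAM_LENGTH)
        pos = p % L
        if triplet[1:3] == "GG":
            site = _make_site(genome, pos, "+", triplet)
            if site is not None:
                sites.append(site)
        if triplet[0:2] == "CC":
            site = _make_site(genome, pos, "-", reverse_complement(triplet))
            if site is not None:
                sites.append(site)
    return sites


def _make_site(
    genome: GenomeSequence, pam_start: int, strand: str, pam_seq: str
) -> PamSite | None:
    L = len(genome)
    if "N" in pam_seq:
        log.debug("dropping %s-strand PAM at %d: N in PAM", strand, pam_start)
        return None
    if strand == "+":
        proto = Interval(pam_start - PROTOSPACER_LENGTH, pam_start)
    else:
        proto = Interval(pam_start + PAM_LENGTH, pam_start + PAM_LENGTH + PROTOSPACER_LENGTH)
    if not genome.circular and (proto.start < 0 or proto.end > L):
        log.debug(
            "dropping %s-strand PAM at %d: protospacer off contig end", strand, pam_start
        )
        return None
    if genome.circular:
        s = proto.start % L
        proto = Interval(s, s + PROTOSPACER_LENGTH)
    if "N" in genome.fetch(proto.start, proto.end):
        log.debug("dropping %s-strand PAM at %d: N in protospacer", strand, pam_start)
        return None
    return PamSite(
        contig=genome.name,
        pam_start=pam_start,
        strand=strand,
        pam_seq=pam_seq,
        protospacer=proto,
    )


def extract_n20(genome: GenomeSequence, site: PamSite) -> N20:
    """Spacer sequence for a PAM site, 5'->3' on the protospacer strand.

    Identical to the protospacer-strand genomic sequence, hence complementary
    to (a 20-base region of homology with) the target strand.
    """
    forward = genome.fetch(site.protospacer.start, site.protospacer.end)
    seq = forward if site.strand == "+" else reverse_complement(forward)
    if "N" in seq:
        raise PamScanError(
            f"protospacer at {site.contig}:{site.protospacer.start} contains N"
        )
    return N20(seq=seq, site=site)
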