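"""Genome-wide fuzzy off-target counting for N20 spacers.

The off-target rule: a 20-mer window anywhere in the genome, on either
strand, is an off-target hit when its Hamming distance to the spacer is
*strictly less than* the exclusion threshold (default 2, so hits carry 0 or
1 mismatches).  The on-target locus itself — same contig, same forward
start, same strand as the spacer's source site — is excluded by coordinate,
not by distance, so perfect duplicates elsewhere in the genome do count.

Distance is substitution-only (no bulges or gaps); an ``N`` in a genomic
window counts as a mismatch at that position.  With ``require_pam`` the
3-mer immediately 3' of the window on its strand must additionally read NGG
(off by default, which reproduces a plain subsequence search; the PAM-aware
mode is the biologically stricter option).

Two independent implementations are provided: :func:`count_offtargets`
(vectorized numpy scan, the production path) and
:func:`brute_force_offtargets` (naive per-window loop, the test oracle).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .genome_io import GenomeSequence, reverse_complement
from .pam_scan import N20, PamSite, PROTOSPACER_LENGTH

DEFAULT_MISMATCH_THRESHOLD = 2

_BRUTE_FORCE_MAX_LENGTH = 1_000_000

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i


class OffTargetError(ValueError):
    pass


@dataclass(frozen=True, order=True)
class OffTargetHit:
    """One approximate match of a spacer: forward-coordinate 20-mer window."""

    contig: str
    start: int
    strand: str
    mismatches: int


@dataclass(frozen=True)
class GuideCandidate:
    """A scored guide: spacer + source PAM site + off-target tally."""

    n20: N20
    site: PamSite
    offtarget_count: int
    hits: tuple[OffTargetHit, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.offtarget_count != len(self.hits):
            raise OffTargetError("offtarget_count must equal the number of hits")


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _as_list(genomes: GenomeSequence | Sequence[GenomeSequence]) -> list[GenomeSequence]:
    if isinstance(genomes, GenomeSequence):
        return [genomes]
    return list(genomes)


def _pam_ok(seq: str, start: int, strand: str, circular: bool) -> bool:
    """Is there an NGG immediately 3' of the window on its strand?"""
    L = len(seq)
    if strand == "+":
        i, j = start + PROTOSPACER_LENGTH + 1, start + PROTOSPACER_LENGTH + 2
        want = "G"
    else:
        i, j = start - 3, start - 2
        want = "C"
    if not circular and (i < 0 or j >= L):
        return False
    return seq[i % L] == want and seq[j % L] == want


def _is_on_target(hit_contig: str, start: int, strand: str, site: PamSite) -> bool:
    return (
        hit_contig == site.contig
        and start == site.protospacer.start
        and strand == site.strand
    )


def count_offtargets(
    genomes: GenomeSequence | Sequence[GenomeSequence],
    n20: N20,
    threshold: int = DEFAULT_MISMATCH_THRESHOLD,
    require_pam: bool = False,
) -> GuideCandidate:
    """Score a spacer by fuzzy homology search against the rest of the genome.

    Scans every 20-mer window on both strands of every contig and collects
    windows with Hamming distance < ``threshold``, excluding the spacer's
    own on-target locus.  Returns the candidate with its hit list sorted by
    (contig, start, strand).
    """
    if threshold < 1:
        raise OffTargetError("threshold must be >= 1")
    hits: list[OffTargetHit] = []
    queries = {"+": _encode(n20.seq), "-": _encode(reverse_complement(n20.seq))}
    for genome in _as_list(genomes):
        L = len(genome)
        if L < PROTOSPACER_LENGTH:
            continue
        code = _encode(genome.seq)
        if genome.circular:
            ext = np.concatenate([code, code[: PROTOSPACER_LENGTH - 1]])
            n_windows = L
        else:
            ext = code
            n_windows = L - PROTOSPACER_LENGTH + 1
        for strand, query in queries.items():
            mm = np.zeros(n_windows, dtype=np.int16)
            for j in range(PROTOSPACER_LENGTH):
                mm += ext[j : j + n_windows] != query[j]
            for s in np.nonzero(mm < threshold)[0]:
                start = int(s)
                if require_pam and not _pam_ok(genome.seq, start, strand, genome.circular):
                    continue
                if _is_on_target(genome.name, start, strand, n20.site):
                    continue
                hits.append(OffTargetHit(genome.name, start, strand, int(mm[s])))
    hits.sort()
    return GuideCandidate(n20=n20, site=n20.site, offtarget_count=len(hits), hits=tuple(hits))


def brute_force_offtargets(
    genomes: GenomeSequence | Sequence[GenomeSequence],
    n20: N20,
    threshold: int = DEFAULT_MISMATCH_THRESHOLD,
    require_pam: bool = False,
) -> list[OffTargetHit]:
    """Naive per-window scan with the identical hit definition (test oracle).

    Guarded to genomes totalling <= 1 Mb; intended as ground truth for the
    vectorized scanner on small inputs, never as the production path.
    """
    genome_list = _as_list(genomes)
    total = sum(len(g) for g in genome_list)
    if total > _BRUTE_FORCE_MAX_LENGTH:
        raise OffTargetError(
            f"brute-force oracle guard: genome totals {total} bases (> 1 Mb)"
        )
    k = PROTOSPACER_LENGTH
    hits: list[OffTargetHit] = []
    for genome in genome_list:
        L = len(genome)
        if L < k:
            continue
        ext = genome.seq + (genome.seq[: k - 1] if genome.circular else "")
        n_windows = L if genome.circular else L - k + 1
        for strand in "+-":
            query = n20.seq if strand == "+" else reverse_complement(n20.seq)
            for start in range(n_windows):
                mm = 0
                for a, b in zip(query, ext[start : start + k]):
                    if a != b:
                        mm += 1
                        if mm >= threshold:
                            break
                if mm >= threshold:
                    continue
                if require_pam and not _pam_ok(genome.seq, start, strand, genome.circular):
                    continue
                if _is_on_target(genome.name, start, strand, n20.site):
                    continue
                hits.append(OffTargetHit(genome.name, start, strand, mm))
    hits.sort()
    return hits


def write_hits_tsv(
    candidate: GuideCandidate,
    genomes: GenomeSequence | Sequence[GenomeSequence],
    path: str | Path,
) -> None:
    """Hit report: contig, 0-based start, strand, mismatches, matched sequence."""
    index = {g.name: g for g in _as_list(genomes)}
    with open(path, "w") as fh:
        fh.write("contig\tstart\tstrand\tmismatches\tsequence\n")
        for hit in candidate.hits:
            genome = index[hit.contig]
            window = genome.fetch(hit.start, hit.start + PROTOSPACER_LENGTH)
            if hit.strand == "-":
                window = reverse_complement(window)
            fh.write(
                f"{hit.contig}\t{hit.start}\t{hit.strand}\t{hit.mismatches}\t{window}\n"
            )
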