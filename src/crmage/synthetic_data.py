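"""Seeded synthetic genomes with planted guides and machine-readable truth.

Real design runs target a complete strain genome; the tests instead use
genomes built here: i.i.d. background at a chosen GC content with guide
copies planted at exact Hamming distances, so every off-target count is
known by construction.  The background is rejection-checked — any window
that lands within Hamming distance < 2 of a planted guide by chance is
re-rolled — because the test suite asserts *exact* hit sets, not
approximate ones.

All randomness flows from one integer seed through a single
``numpy.random.Generator`` (PCG64); draws happen in a fixed order (guides,
then placements left to right, then mutations, then re-rolls), so fixtures
are byte-identical across runs and releases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genome_io import EditSpec, GenomeSequence, reverse_complement
from .offtarget import _encode  # shared base encoding
from .pam_scan import PROTOSPACER_LENGTH

log = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_MAX_REROLL_ROUNDS = 50
_MAX_PLACEMENT_TRIES = 1000


class FixtureError(ValueError):
    pass


@dataclass(frozen=True)
class Plant:
    """A request to plant ``count`` copies of a guide at a Hamming distance.

    ``guide`` is a 20-base sequence or ``"random"`` (drawn from the
    background composition).  ``at`` pins the forward protospacer start of
    the first copy (remaining copies are placed randomly); ``with_pam``
    adds an NGG PAM 3' of the protospacer on the requested strand.
    """

    guide: str
    strand: str = "+"
    count: int = 1
    distance: int = 0
    with_pam: bool = True
    at: int | None = None


@dataclass(frozen=True)
class FixtureSpec:
    seed: int
    length: int
    gc: float = 0.5
    plants: tuple[Plant, ...] = ()
    edit: EditSpec | None = None
    contig_name: str = "synth1"
    circular: bool = False


@dataclass(frozen=True)
class PlantedSite:
    """Ground truth for one planted protospacer copy."""

    contig: str
    start: int  # forward-coordinate start of the 20-mer window
    strand: str
    distance: int
    guide: str  # the exact guide this copy derives from
    sequence: str  # planted 20-mer, written on its own strand
    with_pam: bool


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=n, p=p)]


def _mutate(rng: np.random.Generator, guide: str, distance: int) -> str:
    """Copy of ``guide`` with exactly ``distance`` substituted positions."""
    if distance > len(guide):
        raise FixtureError("distance exceeds guide length")
    seq = list(guide)
    positions = rng.choice(len(guide), size=distance, replace=False)
    for pos in sorted(int(p) for p in positions):
        alternatives = [b for b in "ACGT" if b != seq[pos]]
        seq[pos] = alternatives[int(rng.integers(3))]
    return "".join(seq)


def _footprint(plant: Plant, proto_start: int) -> tuple[int, int]:
    """Forward-coordinate interval occupied by protospacer (+ optional PAM)."""
    if not plant.with_pam:
        return proto_start, proto_start + PROTOSPACER_LENGTH
    if plant.strand == "+":
        return proto_start, proto_start + PROTOSPACER_LENGTH + 3
    return proto_start - 3, proto_start + PROTOSPACER_LENGTH


def generate_fixture(spec: FixtureSpec) -> tuple[GenomeSequence, list[PlantedSite]]:
    """Build the genome and its ground-truth table.

    Fails loudly when plants cannot be placed (too dense, or degenerate
    composition that defeats rejection-checking, e.g. an all-G guide on a
    GC-1.0 background).
    """
    rng = np.random.default_rng(spec.seed)
    if not 0.0 <= spec.gc <= 1.0:
        raise FixtureError("gc must be in [0, 1]")

    # resolve guides in declaration order so the stream is stable
    resolved: list[Plant] = []
    for plant in spec.plants:
        guide = plant.guide.upper()
        if guide == "RANDOM":
            guide = _random_bases(rng, PROTOSPACER_LENGTH, spec.gc).tobytes().decode()
        if len(guide) != PROTOSPACER_LENGTH or set(guide) - set("ACGT"):
            raise FixtureError(f"bad guide {guide!r}")
        if plant.strand not in "+-":
            raise FixtureError(f"bad strand {plant.strand!r}")
        resolved.append(
            Plant(guide, plant.strand, plant.count, plant.distance,
                  plant.with_pam, plant.at)
        )

    total_planted = sum((23 if p.with_pam else 20) * p.count for p in resolved)
    if total_planted > 0.5 * spec.length:
        raise FixtureError(
            f"infeasible: {total_planted} planted bases > half of genome "
            f"length {spec.length}"
        )

    genome = _random_bases(rng, spec.length, spec.gc)
    occupied: list[tuple[int, int]] = []  # fixed (non-rerollable) intervals
    if spec.edit is not None:
        ref = spec.edit.ref
        if spec.edit.end > spec.length:
            raise FixtureError("planted edit outside genome")
        genome[spec.edit.pos : spec.edit.end] = _encode_bytes(ref)
        occupied.append((spec.edit.pos, spec.edit.end))

    truth: list[PlantedSite] = []
    for plant in resolved:
        for copy_idx in range(plant.count):
            mutated = _mutate(rng, plant.guide, plant.distance)
            at = plant.at if copy_idx == 0 else None
            proto_start = _place(
                rng, plant, at, spec.length, occupied, spec.contig_name
            )
            lo, hi = _footprint(plant, proto_start)
            occupied.append((lo, hi))
            _write_plant(rng, genome, plant, proto_start, mutated)
            truth.append(
                PlantedSite(
                    contig=spec.contig_name,
                    start=proto_start,
                    strand=plant.strand,
                    distance=plant.distance,
                    guide=plant.guide,
                    sequence=mutated,
                    with_pam=plant.with_pam,
                )
            )
    if spec.edit is not None:
        observed = genome[spec.edit.pos : spec.edit.end].tobytes().decode()
        if observed != spec.edit.ref:
            raise FixtureError("a plant overwrote the planted edit")

    _reject_accidental_matches(rng, genome, resolved, truth, occupied, spec)

    seq = genome.tobytes().decode()
    return (
        GenomeSequence(name=spec.contig_name, seq=seq, circular=spec.circular),
        truth,
    )


def _encode_bytes(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _place(
    rng: np.random.Generator,
    plant: Plant,
    at: int | None,
    length: int,
    occupied: list[tuple[int, int]],
    contig: str,
) -> int:
    size = 23 if plant.with_pam else 20
    for attempt in range(_MAX_PLACEMENT_TRIES):
        if at is not None:
            proto_start = at
        else:
            lo_min = 3 if (plant.with_pam and plant.strand == "-") else 0
            proto_start = int(rng.integers(lo_min, length - size - 3 + 1))
        lo, hi = _footprint(plant, proto_start)
        if lo < 0 or hi > length:
            if at is not None:
                raise FixtureError(f"pinned plant at {at} runs off contig {contig!r}")
            continue
        if all(hi <= s or lo >= e for s, e in occupied):
            return proto_start
        if at is not None:
            raise FixtureError(f"pinned plant at {at} overlaps another plant")
    raise FixtureError("could not place a plant without overlap (genome too dense)")


def _write_plant(
    rng: np.random.Generator,
    genome: np.ndarray,
    plant: Plant,
    proto_start: int,
    mutated: str,
) -> None:
    pam = "" if not plant.with_pam else "ACGT"[int(rng.integers(4))] + "GG"
    if plant.strand == "+":
        fwd = mutated + pam
        lo = proto_start
    else:
        fwd = reverse_complement(mutated + pam)  # == revcomp(pam) + revcomp(mutated)
        lo = proto_start - len(pam)
    genome[lo : lo + len(fwd)] = _encode_bytes(fwd)


def _reject_accidental_matches(
    rng: np.random.Generator,
    genome: np.ndarray,
    plants: list[Plant],
    truth: list[PlantedSite],
    occupied: list[tuple[int, int]],
    spec: FixtureSpec,
) -> None:
    """Re-roll background windows that stray within Hamming distance < 2
    of any planted guide, so ground truth is exactly the planted table."""
    guides = sorted({p.guide for p in plants})
    if not guides:
        return
    expected = {
        (t.start, t.strand, t.guide) for t in truth if t.distance < 2
    }
    for round_idx in range(_MAX_REROLL_ROUNDS):
        offending = _find_offending(genome, guides, expected, spec.circular)
        if not offending:
            return
        rerolled = False
        for start, _strand, _guide in offending:
            for i in range(start, start + PROTOSPACER_LENGTH):
                pos = i % len(genome) if spec.circular else i
                if all(not (s <= pos < e) for s, e in occupied):
                    genome[pos] = _random_bases(rng, 1, spec.gc)[0]
                    rerolled = True
        if not rerolled:
            raise FixtureError(
                "accidental near-match overlaps only planted bases; "
                "choose different guides or a longer genome"
            )
    raise FixtureError(
        "rejection-checking did not converge (degenerate composition, "
        "e.g. low-complexity guide on matching background)"
    )


def _find_offending(
    genome: np.ndarray,
    guides: list[str],
    expected: set[tuple[int, str, str]],
    circular: bool,
) -> list[tuple[int, str, str]]:
    code = _encode(genome.tobytes().decode())
    L = len(code)
    if L < PROTOSPACER_LENGTH:
        return []
    if circular:
        ext = np.concatenate([code, code[: PROTOSPACER_LENGTH - 1]])
        n_windows = L
    else:
        ext = code
        n_windows = L - PROTOSPACER_LENGTH + 1
    offending = []
    for guide in guides:
        for strand in "+-":
            q = _encode(guide if strand == "+" else reverse_complement(guide))
            mm = np.zeros(n_windows, dtype=np.int16)
            for j in range(PROTOSPACER_LENGTH):
                mm += ext[j : j + n_windows] != q[j]
            for s in np.nonzero(mm < 2)[0]:
                key = (int(s), strand, guide)
                if key not in expected:
                    offending.append(key)
    return offending


@dataclass(frozen=True)
class DesignCase:
    """A complete synthetic design scenario with known ground truth."""

    genome: GenomeSequence
    edit: EditSpec
    truth: tuple[PlantedSite, ...]
    planted_counts: dict[str, int]  # guide -> number of planted off-targets


def generate_design_case(
    seed: int,
    length: int = 12_000,
    gc: float = 0.5,
    max_offtargets: int = 3,
) -> DesignCase:
    """A genome with one edit and three planted candidate PAMs near it.

    Two plus-strand and one minus-strand candidate protospacers (with NGG
    PAMs) are pinned inside the 80-base window around the edit position;
    each candidate guide additionally gets a known number (0..max_offtargets)
    of distance-1 copies planted elsewhere, plus one distance-2 decoy that
    must never be counted.  The edit's reference allele is read back from
    the generated genome so it is valid by construction.
    """
    rng = np.random.default_rng(seed)
    center = length // 2
    guides = []
    while len(guides) < 3:
        g = _random_bases(rng, PROTOSPACER_LENGTH, gc).tobytes().decode()
        if g not in guides:
            guides.append(g)
    counts = {g: int(rng.integers(0, max_offtargets + 1)) for g in guides}
    plants = [
        Plant(guides[0], "+", 1, 0, True, center - 60),
        Plant(guides[1], "+", 1, 0, True, center - 32),
        Plant(guides[2], "-", 1, 0, True, center + 10),
    ]
    for g in guides:
        if counts[g]:
            plants.append(Plant(g, "+", counts[g], 1, False))
        plants.append(Plant(g, "+", 1, 2, False))  # decoy beyond the threshold
    spec = FixtureSpec(
        seed=int(rng.integers(2**31)), length=length, gc=gc, plants=tuple(plants)
    )
    genome, truth = generate_fixture(spec)
    ref = genome.fetch(center, center + 1)
    alt = "ACGT"[("ACGT".index(ref) + 1) % 4]
    edit = EditSpec(genome.name, center, ref, alt, f"case{seed}")
    return DesignCase(genome, edit, tuple(truth), counts)


def write_fixture(
    genome: GenomeSequence,
    truth: list[PlantedSite],
    prefix: str | Path,
) -> tuple[Path, Path]:
    """Write FASTA + ground-truth TSV next to each other; returns both paths."""
    prefix = Path(prefix)
    fasta = prefix.with_suffix(".fasta")
    tsv = prefix.with_suffix(".truth.tsv")
    from .genome_io import write_fasta

    write_fasta([(genome.name, genome.seq)], fasta)
    with open(tsv, "w") as fh:
        fh.write("contig\tstart\tstrand\tdistance\tguide\tsequence\twith_pam\n")
        for t in truth:
            fh.write(
                f"{t.contig}\t{t.start}\t{t.strand}\t{t.distance}\t{t.guide}"
                f"\t{t.sequence}\t{int(t.with_pam)}\n"
            )
    return fasta, tsv
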