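# Methods

## The design procedure

For a desired substitution (contig, position, ref → alt) the pipeline
executes, per edit:

1. **Neighborhood.** An 80-base window centered on the edit
   (center = pos + ⌊len(ref)/2⌋). The window equals the repair-template
   size by design, so every PAM inside the window is guaranteed to lie
   inside the default-length template and a PAM-escape mutation is always
   possible. Centering maximizes the homology arms on both sides of the
   edit; an `offset` parameter allows off-center placement. At contig
   ends the window is clipped (with a warning) in linear mode and wraps
   in circular mode.
2. **PAM scan.** Every position where a 3-mer reads N-G-G on either
   strand, with the triplet fully inside the window. The membership rule
   is PAM-in-window (the protospacer may extend beyond), because cleavage
   position is governed by the PAM. A forward triplet `CCx` is a
   minus-strand PAM; minus-strand protospacers lie at higher forward
   coordinates than their PAM. Overlapping PAMs (e.g. `AGGG`) are all
   reported. Sites whose protospacer runs off a linear contig or contains
   N are dropped and logged.
3. **Spacer extraction.** The N20 is the 20 bases immediately 5′ of the
   PAM, written 5′→3′ on the protospacer (non-target) strand — the
   sequence cloned into the gRNA, complementary to the target strand.
4. **Off-target scoring.** Every 20-mer window on both strands of every
   contig is compared to the spacer; a window is a hit iff its Hamming
   distance is strictly below the threshold (default 2). Distance-0
   duplicates elsewhere in the genome are off-targets; only the exact
   on-target window (same contig, forward start, strand) is excluded —
   the scan runs "against the rest of the genome", not against
   dissimilar sequence. The model is substitution-only: no bulges or
   gaps, and an N in a genomic window counts as a mismatch (conservative).
   An optional `require_pam` mode additionally demands an NGG 3′ of the
   hit on its strand; it is off by default, making the default a plain
   fuzzy subsequence search, with the PAM-aware mode as the biologically
   stricter option. Both strands are always searched — a protospacer on
   either strand is cleavable, so a single-strand search would
   undercount.
5. **Ranking and selection.** Candidates are sorted by off-target count
   ascending, then by the gap in bases between the PAM triplet and the
   edit interval (cleavage-to-edit proximity drives recombineering
   efficiency), then by `pam_start`, then `+` before `-`. The first `k`
   (default 6) are kept. The full ladder makes selection a total order,
   hence byte-deterministic outputs.
6. **Template construction.** An 80-base single-stranded oligo spanning
   the same centered interval, with alt substituted for ref. Emitted on
   the forward strand by default; a flag selects the reverse strand for
   users who track lagging-strand preference (the preference is real in
   MAGE but is not automated here — no replication-origin annotation is
   assumed).
7. **Cas9-escape guarantee.** The template is applied in silico
   (`apply_template`, modeling perfect homologous replacement) and the
   locus re-read: it is *cleavable* iff the protospacer matches the guide
   with fewer than `escape_min_mismatches` mismatches (default 1, i.e.
   only a perfect match cleaves) and the NGG PAM is intact. If still
   cleavable, one G → non-G mutation is added inside the template at a
   PAM G position. Strict perfect-match is the minimal defensible
   cleavage rule given that Cas9 mismatch tolerance is context-dependent;
   `escape_min_mismatches` is the knob for users who want seed-region
   margin (any value works, because a destroyed PAM blocks cleavage at
   every mismatch level).

### Escape-mutation choice

Candidate substitutions are enumerated in a fixed preference order:
second G of NGG, then first G; target base A, then C, then T (expressed
on the PAM's strand and complemented onto the forward strand for
minus-strand sites). Without annotation the first candidate — second
G → A — is applied. When CDS features are supplied (GFF3), the first
candidate in that order that is synonymous under the standard genetic
code is preferred; if none is synonymous the default is kept. Codons are
read from the *recombined* sequence so that a desired edit in the same
codon is taken into account. Candidates whose PAM lies outside the
template interval cannot be rescued; such guides are dropped from
selection with a warning and the next-ranked guide fills in (this only
arises when the window and template sizes differ or the window was
clipped).

## Parameters

| parameter | default | meaning |
|---|---|---|
| `window` | 80 bases | PAM search neighborhood; equals template size |
| `template_length` | 80 bases | repair oligo length |
| `mismatch_threshold` | 2 | off-target = Hamming distance < this |
| `select` (`-k`) | 6 | guides kept per edit |
| `require_pam_offtargets` | off | count only NGG-adjacent off-targets |
| `escape_min_mismatches` | 1 | cleavable when protospacer mismatches < this |
| `circular` | off | wrap windows and scans around the origin |

## Coordinate and strand conventions

Internal coordinates are 0-based half-open everywhere; TSV edit tables
and VCF are 1-based on input; BED output is 0-based half-open. On a
circular contig an interval may be stored with `end > len(contig)`,
meaning it wraps. `PamSite.pam_start` is always the forward-coordinate
start of the PAM triplet, on both strands; hit starts are forward
coordinates of the 20-mer window. N20 and planted-site sequences are
written on their own strand.

## The synthetic-genome generator

Fixtures are i.i.d. background DNA at a chosen GC content with guide
copies planted at exact Hamming distances (mutations never re-create the
original base), optionally with an NGG PAM, non-overlapping, at random or
pinned positions. After planting, the background is rejection-checked:
any window within Hamming distance < 2 of a planted guide that is not
itself a planted site is re-rolled (up to 50 rounds), so the ground-truth
table is *exactly* the off-target hit set — the tests assert exact
equality, not approximate counts. Degenerate compositions that defeat
rejection-checking (an all-G guide on a GC=1 background) fail loudly.
All randomness flows from one integer seed through a single PCG64
generator with a fixed draw order (guide resolution, then placement, then
mutation, then re-rolls), so fixtures are byte-stable across runs.

`generate_design_case` composes a complete scenario: three candidate
protospacers (two plus-strand, one minus-strand) pinned with PAMs inside
the 80-base window around a central edit, each with 0–3 planted
distance-1 copies elsewhere plus a distance-2 decoy that must never be
counted. The edit's reference base is read back from the generated
genome, so it is valid by construction.

What the generator does **not** emulate: real genomic base composition
(operons, GC skew, repeats), so passing tests demonstrate correctness of
the scanning/scoring/selection machinery, not off-target statistics of
any real genome. On real bacterial genomes the same code paths run
unchanged; only the expected counts differ.

## Screen statistics

Killing rate: white/(white+red) per biological replicate; replicates with
zero colonies are excluded with a warning. Indigoidine index: A615/A800
per sample; A800 ≤ 0 is flagged and excluded. Both report the replicate
mean and the *sample* standard deviation (n−1 denominator; undefined and
reported as NA for a single replicate). No blank subtraction is applied
before the absorbance ratio — the index is defined as the plain ratio,
which already cancels multiplicative volume/turbidity effects.

## Numerical and performance notes

The production off-target scanner encodes bases as small integers and
accumulates mismatch counts across the 20 offsets with vectorized
comparisons, O(20·L) per strand per contig — ample for bacterial-scale
genomes without a persisted index. Its independent check is a naive
per-window loop with early termination (`brute_force_offtargets`),
guarded to ≤ 1 Mb totals; the two share only the hit definition. Test
problem sizes: 200 seeded genomes of 2–40 kb for scanner/oracle
equivalence, 100 twelve-kilobase end-to-end cases for selection-recovery,
chosen so the whole suite runs in seconds while still exercising every
code path (both strands, all planted distances, clipping, wrap-around).

## Known limitations

- Substitution edits only; no indels.
- NGG PAMs only (no NAG or non-SpCas9 nucleases); no on-target
  efficiency scoring (Doench/Azimuth) and no weighted off-target scores
  (MIT/CFD) — counts under the strict distance rule only.
- Off-target distance is Hamming (no bulges); a gapped aligner would
  find additional RNA-bulge off-targets.
- Lagging-strand oligo choice is manual (a strand flag), not inferred
  from replichore position.
- Multi-edit pooling/cycle planning and verification-primer design are
  out of scope.
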