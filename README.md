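# crmage

Guide-RNA and repair-template design for CRISPR-assisted MAGE (CRMAGE)
recombineering in bacteria.

CRMAGE combines λ Red ssDNA recombineering with Cas9 counter-selection:
cells receive an oligo that writes a point mutation into the genome, and
Cas9 — directed by a guide RNA to the *unedited* locus — kills every cell
that failed to recombine. Designing such an experiment for a desired point
edit means answering four questions, and this package automates all of
them:

1. **Which guides are available?** Every NGG protospacer-adjacent motif
   (PAM) on either strand within an 80-base neighborhood of the edit is a
   candidate; the 20-base protospacer 5′ of the PAM (written on the
   protospacer strand) is the guide's N20 spacer.
2. **Which guides are safe?** Each N20 is scored by a fuzzy homology
   search over the whole genome: a 20-mer window on either strand counts
   as an off-target when its Hamming distance to the spacer is **< 2**
   (0 or 1 mismatches); the on-target locus itself is excluded by
   coordinate. Guides are ranked by fewest off-targets (ties: PAM closest
   to the edit, then coordinate, then strand).
3. **What oligo do I order?** An 80-base single-stranded repair template
   centered on the edit, carrying the desired substitution.
4. **Will the edited cell survive Cas9?** The template must leave the
   recombined genome uncleavable. If the desired edit does not itself
   destroy the guide's perfect protospacer+NGG match, the designer adds
   one extra mutation at a PAM G (G→A at the second G by default; with a
   GFF of CDS features it prefers a synonymous substitution) — the
   classic two-mutation oligo: one change does the biology, the other
   buys escape from counter-selection.

Companion utilities quantify the two screening readouts of such an
experiment: the colorimetric **killing rate** (white colonies as a
proportion of all colonies per replicate, mean ± sample SD) and the
**indigoidine production index** (A615/A800 per sample, which cancels
background turbidity and pipetting-volume variation).

## Worked example

Generate a seeded 20 kb synthetic genome with a planted protospacer+PAM
at position 9990 and two distance-1 near-copies elsewhere, then design
guides for an A→C edit at 1-based position 10001:

```bash
crmage make-fixture --seed 42 --length 20000 \
    --plant ACGTTGCAGGATCCTTAACG:+:1:0:1:9990 \
    --plant ACGTTGCAGGATCCTTAACG:+:2:1 \
    --out demo
printf 'contig\tpos\tref\talt\tlabel\nsynth1\t10001\tA\tC\tdemo-edit\n' > edits.tsv
crmage design --genome demo.fasta --edits edits.tsv --out demo_out
```

```
INFO crmage.selection: designing guides for edit 'demo-edit'
INFO crmage: 1 edit(s), 6 guide(s) selected; outputs in demo_out
```

`demo_out/summary.tsv` lists the six selected guides, best first:

```
label      contig  pam_start  strand  n20                   offtarget_count  oligo_name
demo-edit  synth1  9997       +       TAACATGGTTTCCACGTTGC  0                demo-edit_g1
demo-edit  synth1  10002      -       TAGGTCGACTATCCACGTTA  0                demo-edit_g2
...
```

Every selected guide has off-target count 0 — the planted guide, which
carries two genome-wide near-matches by construction, is out-ranked by
clean background candidates, exactly the "fewest off-target matches"
rule. The oligo FASTA records the 80-base template and both mutations it
carries:

```
>demo-edit_g1|synth1|9960-10040|+|10001A>C:desired,10000G>A:pam_escape
CCATAACGAGGATCGAGTAACATGGTTTCCACGTTGCAGACTCCTTAACGTGGATAGTCG
ACCTAATATGGTGATTTGGG
```

Here the desired edit (1-based 10001, A→C) sits outside guide g1's PAM,
so the designer added the `10000G>A` PAM-escape mutation; after in-silico
recombineering (`crmage.apply_template`) the locus no longer contains a
perfect protospacer+NGG site for that guide. `demo_out/report.json`
carries the full per-candidate detail and `demo_out/sites.bed` the
protospacer coordinates (BED6, score = off-target count).

The same pipeline is available as a library:

```python
from crmage import read_fasta, read_edits, design, DesignConfig

genomes = read_fasta("demo.fasta")
edits = read_edits("edits.tsv", genomes)
reports = design(genomes, edits, DesignConfig(select=6))
```

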