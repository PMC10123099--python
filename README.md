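# splicesuite

Downstream analysis of differential alternative-splicing (AS) results.
Tools such as rMATS turn RNA-seq into lists of hundreds to thousands of
statistically significant splicing changes — skipped exons (SE), retained
introns (RI), alternative 5′/3′ splice sites (A5SS/A3SS), mutually
exclusive exons (MXE) — and then leave the investigator to work out what
the list means. `splicesuite` consumes rMATS JCEC output together with a
transcript annotation (BED12 with CDS), a genome FASTA and a gene-level
TPM table, and answers the questions that typically follow:

* **Footprint** — what fraction of expressed genes (mean control TPM ≥ t)
  carries a significant SE or RI change?
* **Novelty** — what fraction of significant skip junctions is absent
  from the annotation (a signature of splicing *disruption* rather than
  regulation)?
* **Multi-exon skipping** — how many annotated exons does each skip
  junction jump over?
* **Architecture** — flanking exon/intron and skipped-exon sizes versus
  an annotated-transcriptome baseline.
* **Splice-site strength** — maximum-entropy donor (9-mer, 3 exonic + 6
  intronic bases) and acceptor (23-mer, 20 intronic + 3 exonic bases)
  scores in bits, `log2 P_model(s) / P_bg(s)`, for the four sites around
  each skipped exon and the two sites of each retained intron.
* **Functional impact** — reconstruct the skipped isoform on an annotated
  host transcript, translate it, classify the frame effect
  (frameshift ⇔ removed coding length mod 3 ≠ 0), apply the 50-nt
  nonsense-mediated-decay (NMD) rule — a termination codon ending
  strictly more than 50 nt upstream of the last exon–exon junction marks
  an NMD candidate — and emit protein isoforms, frameshift neopeptides
  and in-frame excised peptides as FASTA.
* **Similarity** — pairwise overlap of significant event sets across
  experiments, scored with an exact upper-tail hypergeometric probability
  P(X ≥ k) over the union of tested events, with clustered −log10(p)
  matrices.

Events are filtered at FDR < 0.0005 by default (strict `<`). The sign
convention assumes rMATS sample 1 is the test condition: negative
inclusion-level difference on SE means increased skipping, positive on RI
means increased retention (`--flip-sign` reverses it).

## Worked example

The package ships a deterministic synthetic-data generator (toy genome,
BED12 annotation, JCEC files, TPM table) with a planted-truth manifest,
so the whole pipeline can be exercised without any downloads:

```sh
splicesuite make-fixtures --seed 42 --outdir demo/fixtures
splicesuite se-medley \
    --se-file    demo/fixtures/fixture_SE.MATS.JCEC.txt \
    --annotation demo/fixtures/annotation.bed \
    --genome     demo/fixtures/genome.fa \
    --expression demo/fixtures/expression.tsv \
    --outdir     demo/results
```

prints (abridged):

```
SE negative min_tpm=3: 12/27 = 0.4444
neg: 2/15 unannotated (13.33%)
neg: 0:0 1:12 2:2 3:1 >=4:0
neg: n=15 means=150.4 284.0 98.1 372.0 360.0
neg: 6/11 NMD (54.55%), 8 neopeptides >12 aa
se-medley: ran 6 tools: fraction_expressed, unannotated, number_skipped,
           intron_exon_sizes, splice_site_scoring, translate_nmd
```

Reading the lines in order: 12 of 27 genes expressed at ≥3 mean control
TPM carry at least one significant increased-skipping event (44 %); 2 of
the 15 increased-skipping junctions are novel; 12 events skip a single
annotated exon, two skip two and one skips three; the mean upstream-exon
/ upstream-intron / skipped-exon / downstream-intron / downstream-exon
sizes are 150.4 / 284.0 / 98.1 / 372.0 / 360.0 nt; and 6 of the 11
translatable skipped isoforms are NMD candidates, with 8 frameshift
neopeptides longer than 12 aa. Per-event tables, FASTA files, BED
listings and an annotated baseline land under `demo/results/`.

Other entry points: `ri-medley` (the three RI tools), `splice-compare`
(overlap matrices + clustered heatmap over a directory of
`<name>_<TYPE>.MATS.JCEC.txt` files), `batch`, and one subcommand per
individual tool (`splicesuite --help`).

Note on splice-site scores: the bundled maximum-entropy model is
*synthetic* — built from first-order splice-site base frequencies — so
its bit scores rank sites correctly but are not numerically comparable
to scores from models trained on real aligned splice sites. Trained
tables in the documented dialect can be supplied with `--model-dir`
(see `docs/methods.md`).

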