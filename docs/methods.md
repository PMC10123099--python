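# Methods

## Scope and data model

`splicesuite` post-processes rMATS JCEC differential-splicing files. It
does not compute inclusion levels or FDRs; every statistic is conditional
on the rMATS output it is given. An event is identified by AS type,
chromosome, strand and its full coordinate tuple — gene symbol, FDR and
inclusion difference are deliberately excluded from the identity so the
same physical event from two experiments compares equal. All
coordinates, everywhere, are 0-based half-open on the genomic axis (the
BED native convention, matching rMATS's `*_0base` columns).

Column contract (1-based): SE/RI/A5SS/A3SS files carry the gene symbol
in column 3, chromosome in 4, strand in 5, six coordinates in 6–11, FDR
in 20 and inclusion difference in 23; MXE files carry eight coordinates
in 6–13 with FDR in 22 and inclusion difference in 25. Line 1 must be a
header; all other columns are ignored, so files assembled from other
callers are accepted (with `--lenient` padding missing trailing
columns). Duplicate coordinate tuples are collapsed keeping the smallest
FDR, with a logged warning.

Significance is `FDR < threshold` (strict; default 0.0005) plus a sign
requirement on the inclusion difference; events with difference exactly
zero belong to neither sign class. rMATS sample 1 is assumed to be the
test condition, making negative SE differences "increased skipping" and
positive RI differences "increased retention"; `--flip-sign` negates the
column for pipelines with the opposite sample order. The rMATS
"upstream"/"downstream" flank labels are accepted as emitted and
re-normalized internally onto the genomic axis, so downstream modules
are strand-safe regardless of which convention the producer used.

## Footprint

A gene is *expressed* at threshold t when the mean of its control TPM
columns is ≥ t (the `--all-replicates` flag switches to requiring every
control column ≥ t; the mean was chosen as the default because it is
robust to a single dropped-out replicate). The footprint at (t, sign) is
the fraction of expressed genes with at least one significant event of
that sign, matched by exact, case-sensitive gene-symbol equality. A gene
with several events counts once. Event genes absent from the expression
table are written to a diagnostics file and excluded from the fraction
rather than silently dropped. Default threshold grid: 1, 2, 3, 5 TPM.

## Structural statistics

*Annotation status.* A skip junction (upstream-exon end, downstream-exon
start) is annotated iff exactly that intron occurs between consecutive
exons of some transcript on the same chromosome and strand. Matching is
exact at both ends by default; `--fuzz N` tolerates ±N nt at each end
for annotation dialects with off-by-one boundaries.

*Intervening exons.* The number of exons a junction skips is counted as
the number of overlap-clusters of annotated exon intervals fully
contained in the open skip interval: identical intervals across isoforms
count once, and mutually overlapping variants of one exon (isoform end
variation) merge into one locus. This makes the count invariant to
transcript duplication in the annotation. The histogram is reported over
bins 0 / 1 / 2 / 3 / ≥4; bin 0 (no annotated exon inside the junction at
all, i.e. an entirely novel exon) is kept separate so the histogram
always sums to the event count.

*Sizes.* For each SE event the upstream exon, upstream intron, skipped
exon, downstream intron and downstream exon lengths are reported in
transcript orientation (on the minus strand the genomic-left flank is
the downstream one); for RI events the flanking exons and the retained
intron. For multi-exon skips the "intron" lengths are the full gaps
between the reported flanks. Baselines are the same means over every
potential skipping configuration (each internal exon of each multi-exon
transcript, deduplicated) or every unique annotated intron.

## Splice-site scoring

Scores are log2 likelihood ratios (bits) between a splice-site model and
a background model. The engine implements the standard maximum-entropy
decomposition: donors are 9-mers (3 exonic + 6 intronic bases) with the
near-invariant GT at intron +1/+2 scored by consensus frequency ratios
and the remaining 7 positions by a joint table of 4^7 ratios; acceptors
are 23-mers (20 intronic + 3 exonic) with AG at intron −2/−1 scored by
consensus ratios and the remaining 21 bases by five overlapping 7-mer
sub-tables divided by four lower-order sub-tables covering the window
overlaps, so every position contributes exactly once.

Model tables are plain text, one ratio per line in lexicographic k-mer
order (A<C<G<T), plus a small consensus-ratio TSV; `save_models` /
`load_models` round-trip the dialect and trained tables converted to it
drop straight in. The bundled default model is **synthetic**: the
maximum-entropy distribution subject to first-order per-position base
frequencies (which is the independence model), built from representative
mammalian splice-site frequencies embedded in the source. It orders
sites sensibly — the canonical CAG|GTAAGT donor is the exhaustive-
enumeration maximum — but its absolute values are not comparable to
scores from tables trained on aligned sites, and the CLI says so when it
is used. Sites containing non-ACGT bases or running off a contig are
flagged, excluded from means, and counted in a diagnostics column.
Scores are reported to 2 decimals in TSV output.

Per SE event four sites are scored (upstream-exon donor, skipped-exon
acceptor, skipped-exon donor, downstream-exon acceptor), per RI event
the retained intron's donor and acceptor, all in transcript orientation.
Reference means are computed over the annotated configurations
enumerated for the size baselines, and an increased/decreased mean-score
ratio table is emitted per site role.

## Translation and NMD

A transcript *hosts* an SE event when its intron chain contains both
flanking introns of the inclusion isoform; among multiple hosts the one
with the longest CDS is representative (ties broken lexicographically by
transcript ID), with all matches recorded. The skipped isoform is the
host minus the skipped exon, which must match an annotated exon interval
exactly. Multi-exon skip junctions have no host by construction and are
reported as unhosted diagnostics.

Translation starts at the first CDS base (mapped from the BED12
thickStart/thickEnd through the isoform's exon chain — if the original
start codon was removed, the first remaining CDS base is used with a
warning) and runs to the first stop codon. Frame classification follows
the removed coding length: the overlap of the skipped exon with the CDS
span, mod 3. Frameshift neopeptides are the isoform residues after the
longest common prefix with the host protein; in-frame excised peptides
are the host residues whose codons cover the removed interval (suitable
for conserved-domain queries). Skips entirely in the 5′ or 3′ UTR leave
the protein unchanged; hosts without a CDS yield a non-coding outcome
that is excluded from the NMD denominator.

NMD uses the classic 50-nt rule against the *last* exon–exon junction of
the skipped isoform: a stop codon whose final base lies strictly more
than 50 nt upstream of that junction marks an NMD candidate. The rule is
applied to whatever first stop the translation finds, so junction stops
created by in-frame splicing and natural stops stranded upstream of a
remaining junction by 3′-UTR skips are tested by the same criterion; a
stop in the final exon can never satisfy it. The reported NMD fraction
uses hosted, translatable events as the denominator (both this count and
the raw event count are emitted, since the choice of denominator
changes the number).

## Cross-experiment comparison

Experiments are discovered by the `<name>_<TYPE>.MATS.JCEC.txt` suffix
convention. For each pair, the overlap k of significant key sets (sizes
K and n) is scored with the exact upper tail
P(X ≥ k) = Σᵢ C(K,i)·C(N−K,n−i)/C(N,n), computed in log space
(lgamma + log-sum-exp) for stability at genome-scale set sizes; the
population N is the union of all tested event keys across the two files
(the intersection variant is available behind a flag for sensitivity
analysis). Self-comparisons record the minimal achievable tail for the
set and are masked out of clustering. p-values are floored at 1e−300
before −log10. No multiple-testing correction is applied by default —
the matrices are emitted raw so users can apply their preferred
adjustment; Benjamini–Hochberg is available behind a flag. Clustering of
the −log10(p) rows is average-linkage on Euclidean distance (recorded in
an output metadata file); the heatmap reorders rows and columns by the
dendrogram leaf order.

## Synthetic data generator

The generator emulates exactly the input surface the suite consumes: a
two-contig toy genome (~100 kb), BED12 transcripts with GT…AG introns
and planted donor/acceptor motifs, JCEC files obeying the column
contract, and a TPM table. Exon bodies are drawn from {A, C, G} only;
since every stop codon begins with T, stops exist exactly where planted,
which lets the generator place premature termination codons at exact
distances (10/50/51/200/… nt) upstream of the skipped isoform's last
junction and guarantee frame outcomes. Planted conditions per run:
eight frameshift events spanning the NMD boundary, two in-frame events,
one 5′-UTR and one non-coding event, three multi-exon skips (2/2/3
intervening exons), two novel junctions among fifteen significant
increased-skipping events, three decreased-skipping and three
non-significant events, six retained introns (four significant), six
background genes, and an expression table with ~⅓ of genes below the
3-TPM threshold plus one event gene deliberately absent. Strong sites
use consensus motifs (CAG|GTAAGT donors, pyrimidine-tract acceptors),
weak sites low-frequency variants with the GT/AG cores intact. The
generator re-translates every planted isoform before writing and raises
if any planting is violated; the same-seed output tree is byte-identical
across runs.

What the fixtures do **not** emulate: realistic human exon/intron length
and base-composition statistics, overlapping genes, alternative
first/last exons, sequencing noise in TPMs, or correlated FDRs.
Passing tests therefore demonstrate coordinate, frame, rule and
statistical correctness — not calibration against biological data.

The cross-experiment fixture plants two clusters of three experiments
over a shared 400-event universe (100-event significant cores, 5 random
substitutions per experiment), giving exactly computable overlap
parameters and a known clustering.

## Numerical and edge-case choices

* Hypergeometric tails are summed in log space; exactness is verified
  against rational-arithmetic enumeration for all parameter combinations
  with N ≤ 20 (max |Δ| ~1e−14) and against an independent survival
  function on random larger instances.
* Probability-ratio tables must be strictly positive; zero or negative
  entries fail loading.
* Empty event sets produce NA fractions and empty per-event files, never
  exceptions; degenerate skip intervals and out-of-bounds genome windows
  raise or flag per the operation's contract.
* Problem sizes in tests and the acceptance script (tens of events,
  ~50 transcripts, 400-event comparison universe, 1000-sequence scoring
  panels) were chosen so the full battery completes in well under a
  minute while still covering every planted condition; they are study
  conditions, not tuning knobs.

## Known limitations

* GTF/GFF annotations are not parsed; the BED12-with-CDS contract is the
  interface, and conversion is the user's step.
* Only SE events are translated (matching the tool family's scope); RI
  translation and branch-point scoring are out of scope.
* The bundled splice-site model is synthetic (above); quantitative
  comparisons with published bit scores require supplying trained
  tables.
* Single-process execution throughout; comparison of many experiments is
  O(pairs) and the optional per-pair common-event lists multiply output
  files accordingly.
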