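"""BED12 transcript models, junction/exon indexing and genome access.

The annotation contract is BED12 with the name field holding
``<EnsemblTranscriptID>_<HUGOSymbol>`` and thickStart/thickEnd delimiting
the CDS (thickStart == thickEnd marks a non-coding transcript).  All
coordinates everywhere in this package are 0-based half-open on the
genomic axis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from intervaltree import IntervalTree
from pyfaidx import Fasta

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVNacgtryswkmbdhvn",
    "TGCAYRSWMKVHDBNtgcayrswmkvhdbn",
)


def revcomp(seq: str) -> str:
    """Reverse complement, preserving IUPAC ambiguity codes and case."""
    return seq.translate(_COMPLEMENT)[::-1]


class BedFormatError(ValueError):
    pass


class GenomeLookupError(KeyError):
    pass


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript as an ordered exon chain with an optional CDS span."""

    transcript_id: str
    gene_symbol: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]  # ascending genomic order
    cds_span: tuple[int, int] | None = None  # [thickStart, thickEnd)

    def __post_init__(self) -> None:
        if not self.exons:
            raise BedFormatError(f"{self.transcript_id}: transcript with no exons")
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if not (s1 < e1 <= s2 < e2):
                raise BedFormatError(
                    f"{self.transcript_id}: exon blocks unsorted or overlapping"
                )
        if self.exons[-1][0] >= self.exons[-1][1]:
            raise BedFormatError(f"{self.transcript_id}: empty exon block")
        if self.cds_span is not None:
            cs, ce = self.cds_span
            if not (self.exons[0][0] <= cs <= ce <= self.exons[-1][1]):
                raise BedFormatError(
                    f"{self.transcript_id}: CDS span outside transcript extent"
                )

    @property
    def is_coding(self) -> bool:
        return self.cds_span is not None

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple((a[1], b[0]) for a, b in zip(self.exons, self.exons[1:]))

    @property
    def tx_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def cds_length(self) -> int:
        if self.cds_span is None:
            return 0
        cs, ce = self.cds_span
        return sum(max(0, min(e, ce) - max(s, cs)) for s, e in self.exons)

    def exons_transcript_order(self) -> tuple[tuple[int, int], ...]:
        """Exons ordered 5'→3' along the transcript."""
        return self.exons if self.strand == "+" else self.exons[::-1]

    def genomic_to_tx(self, gpos: int) -> int:
        """Map a genomic position (0-based, on an exon) to a transcript offset.

        For minus-strand transcripts the position indexes the base whose
        genomic coordinate interval is [gpos, gpos+1); raises ValueError
        if the position is intronic or outside the transcript.
        """
        off = 0
        for s, e in self.exons_transcript_order():
            if s <= gpos < e:
                if self.strand == "+":
                    return off + (gpos - s)
                return off + (e - 1 - gpos)
            off += e - s
        raise ValueError(f"{self.transcript_id}: genomic position {gpos} not exonic")

    def to_bed12_line(self, score: int = 0) -> str:
        cs, ce = self.cds_span if self.cds_span is not None else (self.exons[0][0],) * 2
        start = self.exons[0][0]
        sizes = ",".join(str(e - s) for s, e in self.exons) + ","
        starts = ",".join(str(s - start) for s, e in self.exons) + ","
        name = f"{self.transcript_id}_{self.gene_symbol}"
        return "\t".join(
            [
                self.chrom,
                str(start),
                str(self.exons[-1][1]),
                name,
                str(score),
                self.strand,
                str(cs),
                str(ce),
                "0",
                str(len(self.exons)),
                sizes,
                starts,
            ]
        )


def _split_name(name: str) -> tuple[str, str]:
    # Ensembl transcript IDs contain no underscore, so the LAST underscore
    # separates transcript ID from gene symbol.
    if "_" not in name:
        logger.warning("BED name %r has no underscore; using it as both IDs", name)
        return name, name
    tid, sym = name.rsplit("_", 1)
    return tid, sym


def read_bed12(path: str | Path) -> list[TranscriptModel]:
    """Parse a BED12 annotation into transcript models."""
    out: list[TranscriptModel] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise BedFormatError(
                    f"{path}, line {line_no}: {len(fields)} columns, BED12 requires 12"
                )
            chrom, start, _end, name, _score, strand = fields[:6]
            thick_start, thick_end = int(fields[6]), int(fields[7])
            block_count = int(fields[9])
            sizes = [int(x) for x in fields[10].rstrip(",").split(",") if x]
            starts = [int(x) for x in fields[11].rstrip(",").split(",") if x]
            if len(sizes) != block_count or len(starts) != block_count:
                raise BedFormatError(
                    f"{path}, line {line_no}: blockCount={block_count} but "
                    f"{len(sizes)} sizes / {len(starts)} starts"
                )
            chrom_start = int(start)
            exons = tuple(
                (chrom_start + off, chrom_start + off + size)
                for off, size in zip(starts, sizes)
            )
            tid, sym = _split_name(name)
            cds = None if thick_start == thick_end else (thick_start, thick_end)
            try:
                out.append(
                    TranscriptModel(
                        transcript_id=tid,
                        gene_symbol=sym,
                        chrom=chrom,
                        strand=strand,
                        exons=exons,
                        cds_span=cds,
                    )
                )
            except BedFormatError as exc:
                raise BedFormatError(f"{path}, line {line_no}: {exc}") from None
    return out


def write_bed12(path: str | Path, transcripts: Iterable[TranscriptModel]) -> None:
    with open(path, "w") as fh:
        for tx in transcripts:
            fh.write(tx.to_bed12_line() + "\n")


class JunctionIndex:
    """Annotated introns and interval-searchable exons, keyed by (chrom, strand)."""

    def __init__(self, transcripts: Sequence[TranscriptModel]):
        self.intron_set: set[tuple[str, str, int, int]] = set()
        self._exon_trees: dict[tuple[str, str], IntervalTree] = {}
        for tx in transcripts:
            key = (tx.chrom, tx.strand)
            tree = self._exon_trees.setdefault(key, IntervalTree())
            for s, e in tx.exons:
                tree[s:e] = None
            for a, b in tx.introns:
                self.intron_set.add((tx.chrom, tx.strand, a, b))
        self._intron_starts: dict[tuple[str, str], list[tuple[int, int]]] = {}
        for chrom, strand, a, b in self.intron_set:
            self._intron_starts.setdefault((chrom, strand), []).append((a, b))
        for lst in self._intron_starts.values():
            lst.sort()

    def has_intron(
        self, chrom: str, strand: str, start: int, end: int, fuzz: int = 0
    ) -> bool:
        """Exact intron membership, or within ±fuzz nt at both ends.

        ``fuzz`` accommodates off-by-one annotation dialects; the default
        is exact matching.
        """
        if fuzz == 0:
            return (chrom, strand, start, end) in self.intron_set
        import bisect

        starts = self._intron_starts.get((chrom, strand))
        if not starts:
            return False
        lo = bisect.bisect_left(starts, (start - fuzz, -1))
        hi = bisect.bisect_right(starts, (start + fuzz, 10**15))
        return any(abs(e - end) <= fuzz for _s, e in starts[lo:hi])

    def exons_within(
        self, chrom: str, strand: str, start: int, end: int
    ) -> list[tuple[int, int]]:
        """Unique annotated exon intervals fully contained in [start, end)."""
        tree = self._exon_trees.get((chrom, strand))
        if tree is None:
            return []
        hits = {
            (iv.begin, iv.end)
            for iv in tree.overlap(start, end)
            if start <= iv.begin and iv.end <= end
        }
        return sorted(hits)


def build_junction_index(transcripts: Sequence[TranscriptModel]) -> JunctionIndex:
    return JunctionIndex(transcripts)


class GenomeSequence:
    """Indexed FASTA access with chromosome-name dialect normalization.

    Queries may use either the "chr1" or the bare "1" dialect regardless of
    which the FASTA uses; the chrM/MT synonym pair is mapped both ways.
    """

    def __init__(self, fasta_path: str | Path):
        self._fasta = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)
        self._names: dict[str, str] = {}
        for name in self._fasta.keys():
            self._names[name] = name
            if name.startswith("chr"):
                alias = name[3:]
                self._names.setdefault("MT" if alias == "M" else alias, name)
            else:
                alias = "chrM" if name == "MT" else "chr" + name
                self._names.setdefault(alias, name)

    def resolve(self, chrom: str) -> str:
        try:
            return self._names[chrom]
        except KeyError:
            alt = chrom[3:] if chrom.startswith("chr") else "chr" + chrom
            raise GenomeLookupError(
                f"chromosome {chrom!r} not in FASTA (also tried {alt!r})"
            ) from None

    def chrom_length(self, chrom: str) -> int:
        return len(self._fasta[self.resolve(chrom)])

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        """Sequence of [start, end) on the given strand, uppercase.

        Minus strand returns the reverse complement of the plus-strand
        slice, i.e. the sequence read 5'→3' along a minus-strand transcript.
        """
        name = self.resolve(chrom)
        if not (0 <= start < end <= len(self._fasta[name])):
            raise ValueError(
                f"range [{start}, {end}) out of bounds for {name} "
                f"(length {len(self._fasta[name])})"
            )
        seq = str(self._fasta[name][start:end])
        return revcomp(seq) if strand == "-" else seq


def fetch_sequence(
    genome: GenomeSequence, chrom: str, start: int, end: int, strand: str = "+"
) -> str:
    return genome.fetch(chrom, start, end, strand)


def enumerate_annotated_se_triples(
    transcripts: Sequence[TranscriptModel],
) -> list[tuple[str, str, tuple[int, int], tuple[int, int], tuple[int, int]]]:
    """All potential exon-skipping configurations in an annotation.

    For every internal exon of every multi-exon transcript, yields
    ``(chrom, strand, upstream_exon, skipped_exon, downstream_exon)`` in
    transcript orientation; identical triples across isoforms are
    collapsed.
    """
    seen = set()
    out = []
    for tx in transcripts:
        exons = tx.exons_transcript_order()
        for i in range(1, len(exons) - 1):
            triple = (tx.chrom, tx.strand, exons[i - 1], exons[i], exons[i + 1])
            if triple not in seen:
                seen.add(triple)
                out.append(triple)
    return out


def enumerate_annotated_introns(
    transcripts: Sequence[TranscriptModel],
) -> list[tuple[str, str, tuple[int, int], tuple[int, int], tuple[int, int]]]:
    """All annotated intron-retention configurations.

    Yields ``(chrom, strand, upstream_exon, intron, downstream_exon)`` in
    transcript orientation, one record per unique configuration.
    """
    seen = set()
    out = []
    for tx in transcripts:
        exons = tx.exons_transcript_order()
        for a, b in zip(exons, exons[1:]):
            if tx.strand == "+":
                intron = (a[1], b[0])
            else:
                intron = (b[1], a[0])
            rec = (tx.chrom, tx.strand, a, intron, b)
            if rec not in seen:
                seen.add(rec)
                out.append(rec)
    return out
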