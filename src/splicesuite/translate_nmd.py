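"""Skipped-isoform construction, translation, NMD and neopeptide prediction.

For each significant skipped-exon event this module finds annotated
transcripts that express the inclusion isoform (both flanking introns
present in the transcript's intron chain), deletes the skipped exon from
a representative host, translates the resulting isoform, and classifies
the outcome:

* frame effect — a skipped exon removing a coding length not divisible by
  3 shifts the downstream reading frame;
* NMD — a termination codon ending more than 50 nt upstream of the
  skipped isoform's last exon-exon junction marks the transcript as a
  nonsense-mediated-decay candidate (the classic 50-nt rule);
* neopeptide — the novel C-terminal peptide read in the shifted frame,
  a candidate source of neo-epitopes;
* excised peptide — for in-frame events, the stretch of the host protein
  encoded by the removed exon, suitable for conserved-domain searches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from Bio.Seq import Seq

from .annotation import GenomeSequence, TranscriptModel
from .rmats_io import ASType, SEEventView, Sign, SpliceEvent, event_key

logger = logging.getLogger(__name__)

NMD_DISTANCE_NT = 50  # PTC must end strictly more than this upstream of the last junction
NEOPEPTIDE_MIN_AA = 12  # "long" neopeptides are strictly longer than this


class Region(str, Enum):
    CDS_OVERLAP = "cds_overlap"
    UTR5_ONLY = "utr5_only"
    UTR3_ONLY = "utr3_only"
    NONCODING = "noncoding"


class FrameClass(str, Enum):
    IN_FRAME = "in_frame"
    FRAMESHIFT = "frameshift"
    NOT_APPLICABLE = "not_applicable"


@dataclass(frozen=True)
class HostMatch:
    event_key: str
    transcript: TranscriptModel


@dataclass
class IsoformOutcome:
    event_key: str
    gene_symbol: str
    transcript_id: str
    region: Region
    frame_class: FrameClass
    protein: str
    ptc_tx_pos: int | None  # tx offset just past the stop codon's last base
    last_junction_tx_pos: int  # tx offset of the skipped isoform's last junction
    nmd: bool
    neopeptide: str
    excised_peptide: str
    removed_coding_len: int
    valid: bool = True
    note: str = ""


def find_hosts(
    view: SEEventView, transcripts: Sequence[TranscriptModel]
) -> list[HostMatch]:
    """Transcripts whose intron chain contains both flanking introns.

    Such a transcript expresses the inclusion isoform around the skipped
    exon and can host the exon deletion.
    """
    ev = view.event
    up_intron = (view.left_ee, view.exon_start)
    dn_intron = (view.exon_end, view.right_es)
    key = event_key(ev)
    matches = []
    for tx in transcripts:
        if tx.chrom != ev.chrom or tx.strand != ev.strand:
            continue
        introns = set(tx.introns)
        if up_intron in introns and dn_intron in introns:
            matches.append(HostMatch(event_key=key, transcript=tx))
    return matches


def representative_host(matches: Sequence[HostMatch]) -> HostMatch:
    """Longest CDS wins; ties broken lexicographically by transcript ID."""
    return min(
        matches, key=lambda m: (-m.transcript.cds_length(), m.transcript.transcript_id)
    )


class HostMismatchError(ValueError):
    pass


def build_skipped_isoform(host: TranscriptModel, view: SEEventView) -> TranscriptModel:
    """Delete the skipped exon (exact interval match required) from the host."""
    target = (view.exon_start, view.exon_end)
    if target not in host.exons:
        raise HostMismatchError(
            f"{host.transcript_id}: exon {target} is not an exact exon of the host"
        )
    new_exons = tuple(e for e in host.exons if e != target)
    return replace(host, exons=new_exons)


def _tx_sequence(tx: TranscriptModel, genome: GenomeSequence) -> str:
    return "".join(
        genome.fetch(tx.chrom, s, e, tx.strand) for s, e in tx.exons_transcript_order()
    )


def _cds_tx_start(tx: TranscriptModel) -> int | None:
    """Transcript offset of the first CDS base present in this exon chain."""
    if tx.cds_span is None:
        return None
    cs, ce = tx.cds_span
    off = 0
    for s, e in tx.exons_transcript_order():
        lo, hi = max(s, cs), min(e, ce)
        if lo < hi:
            if tx.strand == "+":
                return off + (lo - s)
            return off + (e - hi)
        off += e - s
    return None


def _translate_from(seq: str, start: int) -> tuple[str, int | None]:
    """Translate from ``start`` to the first stop.

    Returns (protein, tx offset just past the stop codon) — the offset is
    None when no stop codon occurs before the end of the sequence.
    """
    coding = seq[start:]
    coding = coding[: len(coding) - len(coding) % 3]
    aa = str(Seq(coding).translate())
    stop_idx = aa.find("*")
    if stop_idx == -1:
        return aa, None
    return aa[:stop_idx], start + 3 * (stop_idx + 1)


def _last_junction_offset(tx: TranscriptModel) -> int:
    exons = tx.exons_transcript_order()
    return sum(e - s for s, e in exons[:-1])


def classify_nmd(outcome: IsoformOutcome) -> bool:
    """The 50-nt rule: stop ends >50 nt upstream of the last junction."""
    if outcome.ptc_tx_pos is None:
        return False
    return (outcome.last_junction_tx_pos - outcome.ptc_tx_pos) > NMD_DISTANCE_NT


def _common_prefix_len(a: str, b: str) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n


def translate_outcome(
    isoform: TranscriptModel,
    host: TranscriptModel,
    view: SEEventView,
    genome: GenomeSequence,
) -> IsoformOutcome:
    """Translate the skipped isoform and classify its fate."""
    ev = view.event
    key = event_key(ev)
    last_junction = _last_junction_offset(isoform)
    base = dict(
        event_key=key,
        gene_symbol=ev.gene_symbol,
        transcript_id=host.transcript_id,
        last_junction_tx_pos=last_junction,
        ptc_tx_pos=None,
        nmd=False,
        neopeptide="",
        excised_peptide="",
        removed_coding_len=0,
    )
    if host.cds_span is None:
        return IsoformOutcome(
            region=Region.NONCODING,
            frame_class=FrameClass.NOT_APPLICABLE,
            protein="",
            **base,
        )

    cs, ce = host.cds_span
    removed = max(0, min(view.exon_end, ce) - max(view.exon_start, cs))
    base["removed_coding_len"] = removed
    if removed == 0:
        if (view.exon_end <= cs) if host.strand == "+" else (view.exon_start >= ce):
            region = Region.UTR5_ONLY
        else:
            region = Region.UTR3_ONLY
        frame = FrameClass.NOT_APPLICABLE
    else:
        region = Region.CDS_OVERLAP
        frame = FrameClass.IN_FRAME if removed % 3 == 0 else FrameClass.FRAMESHIFT

    iso_seq = _tx_sequence(isoform, genome)
    cds_start = _cds_tx_start(isoform)
    if cds_start is None or cds_start + 3 > len(iso_seq):
        return IsoformOutcome(
            region=region,
            frame_class=frame,
            protein="",
            valid=False,
            note="CDS start unmappable on skipped isoform",
            **base,
        )
    if iso_seq[cds_start : cds_start + 3] != "ATG":
        logger.warning(
            "%s/%s: spliced CDS does not begin with ATG; translating anyway",
            key,
            host.transcript_id,
        )
    protein, stop_end = _translate_from(iso_seq, cds_start)
    base["ptc_tx_pos"] = stop_end

    host_seq = _tx_sequence(host, genome)
    host_cds_start = _cds_tx_start(host)
    host_protein, _ = _translate_from(host_seq, host_cds_start)

    neopeptide = ""
    excised = ""
    if frame is FrameClass.FRAMESHIFT:
        lcp = _common_prefix_len(protein, host_protein)
        neopeptide = protein[lcp:]
    elif frame is FrameClass.IN_FRAME:
        # host-protein residues covering the removed coding interval
        if host.strand == "+":
            first_removed = max(view.exon_start, cs)
        else:
            first_removed = min(view.exon_end, ce) - 1
        cds_off = host.genomic_to_tx(first_removed) - host_cds_start
        aa_start = cds_off // 3
        aa_end = -(-(cds_off + removed) // 3)  # ceil
        excised = host_protein[aa_start:aa_end]
        # if splicing created a stop across the new junction, the translated
        # protein is truncated and ptc_tx_pos already marks it for the NMD rule
    outcome = IsoformOutcome(
        region=region,
        frame_class=frame,
        protein=protein,
        neopeptide=neopeptide,
        excised_peptide=excised,
        **{k: v for k, v in base.items() if k not in ("neopeptide", "excised_peptide")},
    )
    outcome.nmd = classify_nmd(outcome)
    return outcome


@dataclass
class TranslateNMDSummary:
    sign: Sign
    n_events: int
    n_hosted: int
    n_translatable: int
    n_nmd: int
    n_frameshift: int
    n_in_frame: int
    n_long_neopeptides: int  # neopeptides strictly longer than NEOPEPTIDE_MIN_AA
    outcomes: list[IsoformOutcome]
    unhosted_keys: list[str]

    @property
    def fraction_nmd(self) -> float | None:
        return (self.n_nmd / self.n_translatable) if self.n_translatable else None


def run_translate_nmd(
    events: Iterable[SpliceEvent],
    transcripts: Sequence[TranscriptModel],
    genome: GenomeSequence,
    sign: Sign,
) -> TranslateNMDSummary:
    """Translate every hosted event of the requested sign and tally fates."""
    outcomes: list[IsoformOutcome] = []
    unhosted: list[str] = []
    n_events = 0
    for ev in events:
        if ev.as_type is not ASType.SE:
            raise ValueError("translation applies to SE events only")
        if sign is Sign.NEGATIVE and not ev.inc_diff < 0:
            continue
        if sign is Sign.POSITIVE and not ev.inc_diff > 0:
            continue
        n_events += 1
        view = SEEventView(ev)
        matches = find_hosts(view, transcripts)
        if not matches:
            unhosted.append(event_key(ev))
            continue
        host = representative_host(matches).transcript
        try:
            isoform = build_skipped_isoform(host, view)
        except HostMismatchError as exc:
            logger.warning("%s: %s", event_key(ev), exc)
            unhosted.append(event_key(ev))
            continue
        outcomes.append(translate_outcome(isoform, host, view, genome))
    translatable = [o for o in outcomes if o.valid and o.region is not Region.NONCODING]
    return TranslateNMDSummary(
        sign=sign,
        n_events=n_events,
        n_hosted=len(outcomes),
        n_translatable=len(translatable),
        n_nmd=sum(o.nmd for o in translatable),
        n_frameshift=sum(o.frame_class is FrameClass.FRAMESHIFT for o in outcomes),
        n_in_frame=sum(o.frame_class is FrameClass.IN_FRAME for o in outcomes),
        n_long_neopeptides=sum(
            len(o.neopeptide) > NEOPEPTIDE_MIN_AA for o in outcomes
        ),
        outcomes=outcomes,
        unhosted_keys=unhosted,
    )


# ---------------------------------------------------------------- output


def _fasta_header(o: IsoformOutcome, kind: str, length: int) -> str:
    return (
        f">{o.gene_symbol}|{o.transcript_id}|{o.event_key}|{kind}|"
        f"{o.frame_class.value}|len={length}"
    )


def write_translate_nmd(
    outdir: str | Path,
    label: str,
    summary: TranslateNMDSummary,
    events_by_key: dict[str, SpliceEvent] | None = None,
) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    with open(outdir / f"protein_isoforms_{label}.fa", "w") as fh:
        for o in summary.outcomes:
            if o.protein:
                fh.write(_fasta_header(o, "protein", len(o.protein)) + "\n")
                fh.write(o.protein + "\n")
    with open(outdir / f"neopeptides_{label}.fa", "w") as fh:
        for o in summary.outcomes:
            if o.frame_class is FrameClass.FRAMESHIFT:
                fh.write(_fasta_header(o, "neopeptide", len(o.neopeptide)) + "\n")
                fh.write(o.neopeptide + "\n")
    with open(outdir / f"excised_peptides_{label}.fa", "w") as fh:
        for o in summary.outcomes:
            if o.excised_peptide:
                fh.write(_fasta_header(o, "excised", len(o.excised_peptide)) + "\n")
                fh.write(o.excised_peptide + "\n")

    with open(outdir / f"nmd_events_{label}.bed", "w") as fh:
        for o in summary.outcomes:
            if not o.nmd or events_by_key is None:
                continue
            ev = events_by_key.get(o.event_key)
            if ev is None:
                continue
            view = SEEventView(ev)
            start, end = view.left_es, view.right_ee
            sizes = f"{view.left_ee - view.left_es},{view.exon_end - view.exon_start},{view.right_ee - view.right_es},"
            starts = f"0,{view.exon_start - start},{view.right_es - start},"
            fh.write(
                "\t".join(
                    [
                        ev.chrom,
                        str(start),
                        str(end),
                        f"{o.gene_symbol}|{o.event_key}",
                        "0",
                        ev.strand,
                        str(start),
                        str(start),
                        "0",
                        "3",
                        sizes,
                        starts,
                    ]
                )
                + "\n"
            )
    with open(outdir / f"nmd_genes_{label}.txt", "w") as fh:
        for gene in sorted({o.gene_symbol for o in summary.outcomes if o.nmd}):
            fh.write(gene + "\n")
    frac = summary.fraction_nmd
    with open(outdir / f"translate_nmd_summary_{label}.tsv", "w") as fh:
        fh.write(
            "sign\tevents\thosted\ttranslatable\tnmd\tfraction_nmd\t"
            "frameshift\tin_frame\tneopeptides_gt12aa\tunhosted\n"
        )
        fh.write(
            f"{summary.sign.value}\t{summary.n_events}\t{summary.n_hosted}\t"
            f"{summary.n_translatable}\t{summary.n_nmd}\t"
            f"{'NA' if frac is None else f'{frac:.4f}'}\t{summary.n_frameshift}\t"
            f"{summary.n_in_frame}\t{summary.n_long_neopeptides}\t"
            f"{len(summary.unhosted_keys)}\n"
        )
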