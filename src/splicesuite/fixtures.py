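"""Deterministic synthetic test data with a machine-readable truth manifest.

The generator builds a toy genome, a BED12 annotation, rMATS-layout JCEC
files and a TPM expression table in which every analytically relevant
quantity is planted by construction:

* skip junctions that are / are not present in the annotation,
* events skipping 1, 2 or 3 annotated exons,
* skipped exons whose coding length mod 3 is 0, 1 or 2,
* premature termination codons at exact distances (10/50/51/200... nt)
  upstream of the skipped isoform's last exon-exon junction,
* strong versus weak splice-site motifs,
* expression levels above/below the TPM thresholds, plus event genes
  deliberately missing from the expression table.

Every exon body is drawn from {A, C, G} only; because all three stop
codons start with T, stop codons exist exactly where the generator writes
them, which makes frame and NMD outcomes exact.  Introns are uncon-
strained apart from their GT...AG ends and splice-site motifs.  The
truth manifest (JSON) records the expected per-event outcomes and the
aggregate statistics, computed from the design itself before any file is
written; the generator re-translates each designed isoform and refuses
to write output that contradicts its own plantings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio.Seq import Seq

from .annotation import TranscriptModel
from .rmats_io import ASType, SpliceEvent, event_key, write_rmats

DONOR_EXON = {"strong": "CAG", "weak": "GGC"}
DONOR_INTRON = {"strong": "GTAAGT", "weak": "GTCCCC"}
ACCEPTOR_INTRON = {  # last 20 intronic bases, ending in the invariant AG
    "strong": "TCTTTCTTTTCTTTCTC" + "CAG",
    "weak": "AAAAGAAAAGAAAAGAA" + "GAG",
}
ACCEPTOR_EXON = {"strong": "GAC", "weak": "CCA"}

SIG_FDR = 1e-8
NONSIG_FDR = 0.5
NEG_INC = -0.35
POS_INC = 0.28


class GenerationError(RuntimeError):
    """A planted constraint could not be satisfied."""


@dataclass
class FixtureSpec:
    """Planting plan for one fixture set.

    The defaults define the standard study conditions used throughout the
    test suite: ten hosted single-skip coding events carrying the NMD
    boundary battery, three multi-exon-skip events, two novel (unannotated)
    junctions, strong/weak splice-site groups, and an expression table in
    which roughly a third of genes fall below the TPM threshold.
    """

    seed: int = 42
    # (distance of PTC upstream of last junction, expected NMD verdict)
    frameshift_offsets: tuple[int, ...] = (51, 200, 60, 100, 150, 300, 10, 50)
    n_in_frame: int = 2
    novel_junction_events: tuple[int, ...] = (8, 9)  # indices into the SE gene list
    multiskip_counts: tuple[int, ...] = (2, 2, 3)  # intervening exons per extra event
    n_positive: int = 3
    n_nonsig: int = 3
    n_ri: int = 4
    n_ri_nonsig: int = 2
    n_background: int = 6
    include_utr5_event: bool = True
    include_noncoding_event: bool = True
    expressed_tpm: float = 5.0
    low_tpm: float = 0.5
    min_tpms: tuple[float, ...] = (1.0, 2.0, 3.0, 5.0)


# --------------------------------------------------------------- builder


@dataclass
class _Gene:
    symbol: str
    tid: str
    chrom: str
    strand: str
    strength: str
    exon_lens: list[int]
    intron_lens: list[int]
    seq: bytearray = field(default_factory=bytearray)  # pre-mRNA, tx orientation
    cds_tx: tuple[int, int] | None = None  # [start, end) tx offsets incl. stop
    g0: int = -1  # genomic offset of the locus (set at placement)

    # ---- coordinate helpers (transcript space / local pre-mRNA space)
    def tx_offsets(self) -> list[int]:
        out, acc = [], 0
        for L in self.exon_lens:
            out.append(acc)
            acc += L
        return out

    def local_exon_start(self, i: int) -> int:
        return sum(self.exon_lens[:i]) + sum(self.intron_lens[:i])

    @property
    def locus_len(self) -> int:
        return sum(self.exon_lens) + sum(self.intron_lens)

    def tx_to_local(self, tx: int) -> int:
        for i, off in enumerate(self.tx_offsets()):
            if off <= tx < off + self.exon_lens[i]:
                return self.local_exon_start(i) + (tx - off)
        raise GenerationError(f"{self.symbol}: tx offset {tx} not exonic")

    def local_to_genomic(self, a: int, b: int) -> tuple[int, int]:
        """Map a local [a, b) interval to genomic coordinates."""
        if self.strand == "+":
            return (self.g0 + a, self.g0 + b)
        return (self.g0 + self.locus_len - b, self.g0 + self.locus_len - a)

    def exon_genomic(self, i: int) -> tuple[int, int]:
        a = self.local_exon_start(i)
        return self.local_to_genomic(a, a + self.exon_lens[i])

    def genomic_seq(self) -> str:
        s = self.seq.decode()
        return s if self.strand == "+" else str(Seq(s).reverse_complement())

    def tx_seq(self, skip: Sequence[int] = ()) -> str:
        parts = []
        for i in range(len(self.exon_lens)):
            if i in skip:
                continue
            a = self.local_exon_start(i)
            parts.append(self.seq[a : a + self.exon_lens[i]].decode())
        return "".join(parts)

    def transcript_model(
        self, tid: str | None = None, skip: Sequence[int] = (), coding: bool = True
    ) -> TranscriptModel:
        exons = sorted(
            self.exon_genomic(i) for i in range(len(self.exon_lens)) if i not in skip
        )
        cds = None
        if coding and self.cds_tx is not None:
            s, e = self.cds_tx
            ga = self.local_to_genomic(self.tx_to_local(s), self.tx_to_local(s) + 1)
            gb = self.local_to_genomic(self.tx_to_local(e - 1), self.tx_to_local(e - 1) + 1)
            cds = (min(ga[0], gb[0]), max(ga[1], gb[1]))
        return TranscriptModel(
            transcript_id=tid or self.tid,
            gene_symbol=self.symbol,
            chrom=self.chrom,
            strand=self.strand,
            exons=tuple(exons),
            cds_span=cds,
        )

    # ---- sequence planting
    def write_exon(self, i: int, offset: int, text: str) -> None:
        """Write ``text`` at position ``offset`` inside exon i's body."""
        if offset < 0 or offset + len(text) > self.exon_lens[i]:
            raise GenerationError(
                f"{self.symbol}: plant outside exon {i} ({offset}+{len(text)})"
            )
        a = self.local_exon_start(i) + offset
        self.seq[a : a + len(text)] = text.encode()


def _rand_exon_body(rng: np.random.Generator, n: int) -> str:
    # T-free: stop codons can only occur where explicitly planted
    return "".join(rng.choice(["A", "C", "G"], size=n).tolist())


def _rand_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(["A", "C", "G", "T"], size=n).tolist())


def _build_gene(
    rng: np.random.Generator,
    symbol: str,
    tid: str,
    chrom: str,
    strand: str,
    exon_lens: Sequence[int],
    intron_lens: Sequence[int],
    strength: str = "strong",
) -> _Gene:
    if len(intron_lens) != len(exon_lens) - 1:
        raise GenerationError("need one intron fewer than exons")
    if any(L < 30 for L in intron_lens) or any(L < 12 for L in exon_lens):
        raise GenerationError("exon/intron lengths too small for splice motifs")
    g = _Gene(symbol, tid, chrom, strand, strength, list(exon_lens), list(intron_lens))
    parts = []
    for i, L in enumerate(exon_lens):
        body = _rand_exon_body(rng, L)
        if i > 0:  # acceptor exonic trinucleotide
            body = ACCEPTOR_EXON[strength] + body[3:]
        if i < len(exon_lens) - 1:  # donor exonic trinucleotide
            body = body[:-3] + DONOR_EXON[strength]
        parts.append(body)
        if i < len(intron_lens):
            core = _rand_dna(rng, intron_lens[i] - 26)
            parts.append(DONOR_INTRON[strength] + core + ACCEPTOR_INTRON[strength])
    g.seq = bytearray("".join(parts).encode())
    return g


def _plant_cds(g: _Gene, cds_start_tx: int, stop_exon: int, end_margin: int = 30) -> None:
    """ATG at ``cds_start_tx`` and an in-frame TAA near the end of ``stop_exon``."""
    offs = g.tx_offsets()
    target = offs[stop_exon] + g.exon_lens[stop_exon] - end_margin
    s_nat = cds_start_tx + 3 * ((target - cds_start_tx) // 3)
    exon_i = next(
        i for i, o in enumerate(offs) if o <= s_nat < o + g.exon_lens[i]
    )
    if exon_i != stop_exon:
        raise GenerationError(f"{g.symbol}: natural stop landed outside exon {stop_exon}")
    start_exon = next(i for i, o in enumerate(offs) if o <= cds_start_tx < o + g.exon_lens[i])
    g.write_exon(start_exon, cds_start_tx - offs[start_exon], "ATGC")
    g.write_exon(stop_exon, s_nat - offs[stop_exon] - 2, "CCTAACC")
    g.cds_tx = (cds_start_tx, s_nat + 3)


def _plant_ptc_for_skip(g: _Gene, skipped: int, downstream: int, distance: int) -> None:
    """TAA in the shifted frame ending ``distance`` nt before the skipped
    isoform's last junction (requires the congruence set up by the caller)."""
    iso_exons = [i for i in range(len(g.exon_lens)) if i != skipped]
    iso_last_junction = sum(g.exon_lens[i] for i in iso_exons[:-1])
    stop_start_iso = iso_last_junction - distance - 3
    if (stop_start_iso - g.cds_tx[0]) % 3 != 0:
        raise GenerationError(f"{g.symbol}: PTC not on shifted codon boundary")
    # map isoform tx offset back to exon-local position
    acc = 0
    for i in iso_exons:
        if acc <= stop_start_iso < acc + g.exon_lens[i]:
            if i != downstream:
                raise GenerationError(
                    f"{g.symbol}: PTC for distance {distance} fell in exon {i}, "
                    f"expected {downstream}"
                )
            off = stop_start_iso - acc
            g.write_exon(i, off - 2, "CCTAACC")
            return
        acc += g.exon_lens[i]
    raise GenerationError(f"{g.symbol}: PTC beyond isoform end (distance {distance})")


def _translate(seq: str, start: int) -> tuple[str, int | None]:
    coding = seq[start:]
    coding = coding[: len(coding) - len(coding) % 3]
    aa = str(Seq(coding).translate())
    i = aa.find("*")
    if i == -1:
        return aa, None
    return aa[:i], start + 3 * (i + 1)


def _lcp(a: str, b: str) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n


# --------------------------------------------------------------- events


@dataclass
class _PlantedSE:
    gene: _Gene
    upstream: int  # exon indices in transcript order
    skipped: int
    downstream: int
    fdr: float
    inc_diff: float
    annotated: bool  # emit a skip isoform into the annotation
    n_intervening: int
    coding_kind: str  # frameshift | in_frame | utr5 | noncoding
    nmd_distance: int | None = None  # planted PTC distance, frameshift only

    def splice_event(self) -> SpliceEvent:
        g = self.gene
        se = g.exon_genomic(self.skipped)
        up = g.exon_genomic(self.upstream)
        dn = g.exon_genomic(self.downstream)
        return SpliceEvent(
            as_type=ASType.SE,
            gene_symbol=g.symbol,
            chrom=g.chrom,
            strand=g.strand,
            coords=(se[0], se[1], up[0], up[1], dn[0], dn[1]),
            fdr=self.fdr,
            inc_diff=self.inc_diff,
        )

    def sizes(self) -> dict[str, int]:
        g = self.gene
        se = g.exon_genomic(self.skipped)
        up = g.exon_genomic(self.upstream)
        dn = g.exon_genomic(self.downstream)
        left, right = (up, dn) if up[0] <= dn[0] else (dn, up)
        left_gap = se[0] - left[1]
        right_gap = right[0] - se[1]
        if g.strand == "+":
            up_i, dn_i = left_gap, right_gap
        else:
            up_i, dn_i = right_gap, left_gap
        return {
            "upstream_exon_len": up[1] - up[0],
            "upstream_intron_len": up_i,
            "skipped_exon_len": se[1] - se[0],
            "downstream_intron_len": dn_i,
            "downstream_exon_len": dn[1] - dn[0],
        }


@dataclass
class _PlantedRI:
    gene: _Gene
    fdr: float
    inc_diff: float

    def splice_event(self) -> SpliceEvent:
        g = self.gene
        e0 = g.exon_genomic(0)
        e1 = g.exon_genomic(1)
        left, right = (e0, e1) if e0[0] <= e1[0] else (e1, e0)
        up, dn = (left, right) if g.strand == "+" else (right, left)
        return SpliceEvent(
            as_type=ASType.RI,
            gene_symbol=g.symbol,
            chrom=g.chrom,
            strand=g.strand,
            coords=(left[0], right[1], up[0], up[1], dn[0], dn[1]),
            fdr=self.fdr,
            inc_diff=self.inc_diff,
        )

    def sizes(self) -> dict[str, int]:
        g = self.gene
        up = g.exon_genomic(0)
        dn = g.exon_genomic(1)
        return {
            "upstream_exon_len": up[1] - up[0],
            "retained_intron_len": g.intron_lens[0],
            "downstream_exon_len": dn[1] - dn[0],
        }


# ------------------------------------------------------------- generate


def _congruent_len(base: int, distance: int) -> int:
    """Upstream-flank exon length making the planted PTC codon-aligned."""
    return base + ((distance - base) % 3)


def generate(spec: FixtureSpec, outdir: str | Path) -> dict:
    """Write the full fixture set and return the truth manifest (also saved
    as ``truth.json``)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    genes: list[_Gene] = []
    transcripts: list[TranscriptModel] = []
    se_plants: list[_PlantedSE] = []
    ri_plants: list[_PlantedRI] = []
    counter = [0]

    def next_ids() -> tuple[str, str]:
        counter[0] += 1
        return f"GENE{counter[0]:03d}", f"TX{counter[0]:05d}"

    def strand_for(i: int) -> str:
        return "-" if i % 3 == 1 else "+"

    # --- hosted single-skip coding genes: frameshift battery + in-frame
    single_skip: list[_PlantedSE] = []
    kinds: list[tuple[str, int | None]] = [
        ("frameshift", d) for d in spec.frameshift_offsets
    ] + [("in_frame", None)] * spec.n_in_frame
    for idx, (kind, dist) in enumerate(kinds):
        sym, tid = next_ids()
        strength = "strong" if idx % 2 == 0 else "weak"
        if kind == "frameshift":
            e1 = _congruent_len(150, dist)
            e2 = 100 if idx % 2 == 0 else 101
        else:
            e1, e2 = 150, 99
        g = _build_gene(
            rng,
            sym,
            tid,
            "chr1",
            strand_for(idx),
            exon_lens=[120, e1, e2, 360, 180],
            intron_lens=[300, 280, 260, 320],
            strength=strength,
        )
        _plant_cds(g, cds_start_tx=30, stop_exon=4)
        if kind == "frameshift":
            _plant_ptc_for_skip(g, skipped=2, downstream=3, distance=dist)
        plant = _PlantedSE(
            gene=g,
            upstream=1,
            skipped=2,
            downstream=3,
            fdr=SIG_FDR,
            inc_diff=NEG_INC,
            annotated=idx not in spec.novel_junction_events,
            n_intervening=1,
            coding_kind=kind,
            nmd_distance=dist,
        )
        genes.append(g)
        single_skip.append(plant)
        se_plants.append(plant)

    # --- UTR5-only and non-coding hosted events
    extra_idx = len(kinds)
    if spec.include_utr5_event:
        sym, tid = next_ids()
        g = _build_gene(
            rng, sym, tid, "chr1", strand_for(extra_idx),
            exon_lens=[120, 150, 100, 360, 180],
            intron_lens=[300, 280, 260, 320],
        )
        offs = g.tx_offsets()
        _plant_cds(g, cds_start_tx=offs[3] + 30, stop_exon=4)
        genes.append(g)
        se_plants.append(
            _PlantedSE(g, 1, 2, 3, SIG_FDR, NEG_INC, True, 1, "utr5")
        )
        extra_idx += 1
    if spec.include_noncoding_event:
        sym, tid = next_ids()
        g = _build_gene(
            rng, sym, tid, "chr1", strand_for(extra_idx),
            exon_lens=[120, 150, 100, 360, 180],
            intron_lens=[300, 280, 260, 320],
        )
        genes.append(g)
        se_plants.append(
            _PlantedSE(g, 1, 2, 3, SIG_FDR, NEG_INC, True, 1, "noncoding")
        )
        extra_idx += 1

    # --- multi-exon skip events (unhosted by construction: the skip
    #     junction spans several annotated introns)
    for j, k in enumerate(spec.multiskip_counts):
        sym, tid = next_ids()
        exon_lens = [120, 150] + [90] * k + [360, 180]
        intron_lens = [300] * (len(exon_lens) - 1)
        g = _build_gene(rng, sym, tid, "chr2", strand_for(j), exon_lens, intron_lens)
        genes.append(g)
        se_plants.append(
            _PlantedSE(
                g, upstream=1, skipped=2, downstream=k + 2,
                fdr=SIG_FDR, inc_diff=NEG_INC, annotated=True,
                n_intervening=k, coding_kind="noncoding",
            )
        )

    # --- positive-sign (decreased skipping) events, in-frame coding
    for j in range(spec.n_positive):
        sym, tid = next_ids()
        g = _build_gene(
            rng, sym, tid, "chr2", strand_for(j),
            exon_lens=[120, 150, 99, 360, 180],
            intron_lens=[300, 280, 260, 320],
        )
        _plant_cds(g, cds_start_tx=30, stop_exon=4)
        genes.append(g)
        se_plants.append(_PlantedSE(g, 1, 2, 3, SIG_FDR, POS_INC, True, 1, "in_frame"))

    # --- non-significant events
    for j in range(spec.n_nonsig):
        sym, tid = next_ids()
        g = _build_gene(
            rng, sym, tid, "chr2", strand_for(j + 1),
            exon_lens=[120, 150, 99, 360, 180],
            intron_lens=[300, 280, 260, 320],
        )
        _plant_cds(g, cds_start_tx=30, stop_exon=4)
        genes.append(g)
        se_plants.append(_PlantedSE(g, 1, 2, 3, NONSIG_FDR, NEG_INC, True, 1, "in_frame"))

    # --- retained-intron events
    for j in range(spec.n_ri + spec.n_ri_nonsig):
        sym, tid = next_ids()
        g = _build_gene(
            rng, sym, tid, "chr2", strand_for(j),
            exon_lens=[200, 200], intron_lens=[150],
        )
        genes.append(g)
        fdr = SIG_FDR if j < spec.n_ri else NONSIG_FDR
        ri_plants.append(_PlantedRI(g, fdr, POS_INC))

    # --- background genes without events
    for j in range(spec.n_background):
        sym, tid = next_ids()
        g = _build_gene(
            rng, sym, tid, "chr1", strand_for(j),
            exon_lens=[150, 120, 130, 160],
            intron_lens=[250, 350, 300],
        )
        _plant_cds(g, cds_start_tx=30, stop_exon=3)
        genes.append(g)

    # --- place loci on contigs and assemble genome
    contigs: dict[str, list[str]] = {"chr1": [], "chr2": []}
    cursors = {"chr1": 0, "chr2": 0}
    for g in genes:
        gap = _rand_dna(rng, 600)
        contigs[g.chrom].append(gap)
        cursors[g.chrom] += len(gap)
        g.g0 = cursors[g.chrom]
        contigs[g.chrom].append(g.genomic_seq())
        cursors[g.chrom] += g.locus_len
    for name in contigs:
        contigs[name].append(_rand_dna(rng, 600))

    # --- annotation: host transcripts + skip isoforms for annotated events
    for g in genes:
        transcripts.append(g.transcript_model(coding=g.cds_tx is not None))
    for p in se_plants:
        if p.annotated:
            skip = list(range(p.skipped, p.skipped + p.n_intervening))
            transcripts.append(
                p.gene.transcript_model(
                    tid=p.gene.tid + "S", skip=skip, coding=False
                )
            )

    # --- planted-truth translation (generator self-check)
    truth_se: dict[str, dict] = {}
    for p in se_plants:
        g = p.gene
        ev = p.splice_event()
        key = event_key(ev)
        entry: dict = {
            "gene": g.symbol,
            "significant": p.fdr < 0.0005,
            "sign": "neg" if p.inc_diff < 0 else "pos",
            "annotated": p.annotated,
            "n_intervening": p.n_intervening,
            "sizes": p.sizes(),
            "site_strength": g.strength,
            "hosted": p.n_intervening == 1,
            "coding_kind": p.coding_kind,
        }
        if p.n_intervening == 1 and p.coding_kind in ("frameshift", "in_frame", "utr5"):
            host_seq = g.tx_seq()
            iso_seq = g.tx_seq(skip=[p.skipped])
            cds_start = g.cds_tx[0]
            iso_cds_start = cds_start
            offs = g.tx_offsets()
            if cds_start >= offs[p.skipped] + g.exon_lens[p.skipped]:
                iso_cds_start = cds_start - g.exon_lens[p.skipped]
            host_prot, _ = _translate(host_seq, cds_start)
            iso_prot, stop_end = _translate(iso_seq, iso_cds_start)
            iso_last_junction = sum(
                g.exon_lens[i]
                for i in range(len(g.exon_lens) - 1)
                if i != p.skipped
            )
            nmd = stop_end is not None and (iso_last_junction - stop_end) > 50
            neopeptide = ""
            excised = ""
            if p.coding_kind == "frameshift":
                neopeptide = iso_prot[_lcp(iso_prot, host_prot):]
                want = p.nmd_distance is not None and p.nmd_distance > 50
                if stop_end is None or (iso_last_junction - stop_end) != p.nmd_distance:
                    raise GenerationError(
                        f"{g.symbol}: re-translation places PTC at distance "
                        f"{None if stop_end is None else iso_last_junction - stop_end}, "
                        f"planted {p.nmd_distance}"
                    )
                if nmd is not want:
                    raise GenerationError(f"{g.symbol}: NMD verdict mismatch")
                if not neopeptide:
                    raise GenerationError(f"{g.symbol}: empty frameshift neopeptide")
            elif p.coding_kind == "in_frame":
                removed = g.exon_lens[p.skipped]
                if removed % 3 != 0:
                    raise GenerationError(f"{g.symbol}: in-frame exon length % 3 != 0")
                cds_off = offs[p.skipped] - cds_start
                excised = host_prot[cds_off // 3 : -(-(cds_off + removed) // 3)]
                if len(iso_prot) != len(host_prot) - removed // 3:
                    raise GenerationError(f"{g.symbol}: in-frame protein length mismatch")
            else:  # utr5: protein unchanged
                if iso_prot != host_prot:
                    raise GenerationError(f"{g.symbol}: UTR5 skip altered the protein")
            entry["translation"] = {
                "region": {
                    "frameshift": "cds_overlap",
                    "in_frame": "cds_overlap",
                    "utr5": "utr5_only",
                }[p.coding_kind],
                "frame_class": {
                    "frameshift": "frameshift",
                    "in_frame": "in_frame",
                    "utr5": "not_applicable",
                }[p.coding_kind],
                "nmd": bool(nmd),
                "nmd_distance": p.nmd_distance,
                "neopeptide": neopeptide,
                "excised_peptide": excised,
                "protein_len": len(iso_prot),
            }
        elif p.n_intervening == 1 and p.coding_kind == "noncoding":
            entry["translation"] = {
                "region": "noncoding",
                "frame_class": "not_applicable",
                "nmd": False,
                "nmd_distance": None,
                "neopeptide": "",
                "excised_peptide": "",
                "protein_len": 0,
            }
        else:
            entry["translation"] = None  # unhosted multi-skip event
        truth_se[key] = entry

    truth_ri = {
        event_key(p.splice_event()): {
            "gene": p.gene.symbol,
            "significant": p.fdr < 0.0005,
            "sign": "pos" if p.inc_diff > 0 else "neg",
            "sizes": p.sizes(),
        }
        for p in ri_plants
    }

    # --- expression table: event genes mostly expressed; some low; one absent
    event_gene_order = [p.gene.symbol for p in se_plants] + [
        p.gene.symbol for p in ri_plants
    ]
    background_syms = [g.symbol for g in genes if g.symbol not in set(event_gene_order)]
    low_genes = set(
        [p.gene.symbol for p in se_plants if not p.annotated]  # the novel-junction genes
        + background_syms[len(background_syms) // 2 :]
    )
    multiskip_syms = [p.gene.symbol for p in se_plants if p.n_intervening > 1]
    missing_genes = set(multiskip_syms[:1])  # one event gene absent from the table
    expression_rows = []
    for sym in event_gene_order + background_syms:
        if sym in missing_genes:
            continue
        level = spec.low_tpm if sym in low_genes else spec.expressed_tpm
        expression_rows.append((sym, level, level, level * 0.8, level * 1.2))

    # --- aggregates (computed from the design)
    sig_neg = [p for p in se_plants if p.fdr < 0.0005 and p.inc_diff < 0]
    sig_pos = [p for p in se_plants if p.fdr < 0.0005 and p.inc_diff > 0]
    hist = {"0": 0, "1": 0, "2": 0, "3": 0, ">=4": 0}
    for p in sig_neg:
        n = p.n_intervening
        hist[">=4" if n >= 4 else str(n)] += 1
    translatable = [
        truth_se[event_key(p.splice_event())]["translation"]
        for p in sig_neg
        if truth_se[event_key(p.splice_event())]["translation"] is not None
        and truth_se[event_key(p.splice_event())]["translation"]["region"] != "noncoding"
    ]
    n_nmd = sum(t["nmd"] for t in translatable)
    frameshift_t = [t for t in translatable if t["frame_class"] == "frameshift"]

    expressed = {r[0] for r in expression_rows if (r[1] + r[2]) / 2 >= 3.0}
    sig_neg_genes = {p.gene.symbol for p in sig_neg}
    footprint = []
    for t in spec.min_tpms:
        expr_t = {r[0] for r in expression_rows if (r[1] + r[2]) / 2 >= t}
        n_as = len(expr_t & sig_neg_genes)
        footprint.append(
            {
                "min_tpm": t,
                "expressed_genes": len(expr_t),
                "as_genes": n_as,
                "fraction": (n_as / len(expr_t)) if expr_t else None,
            }
        )

    def _mean(vals: list[int]) -> float | None:
        return (sum(vals) / len(vals)) if vals else None

    size_fields = [
        "upstream_exon_len",
        "upstream_intron_len",
        "skipped_exon_len",
        "downstream_intron_len",
        "downstream_exon_len",
    ]
    se_means_neg = {
        f: _mean([p.sizes()[f] for p in sig_neg]) for f in size_fields
    }
    # annotated baselines over unique SE triples / introns (independent loop)
    triples = set()
    introns = set()
    for tx in transcripts:
        exons = tx.exons if tx.strand == "+" else tx.exons[::-1]
        for i in range(1, len(exons) - 1):
            triples.add((tx.chrom, tx.strand, exons[i - 1], exons[i], exons[i + 1]))
        for a, b in zip(exons, exons[1:]):
            introns.add((tx.chrom, tx.strand, a, b))
    base_rows = []
    for chrom, strand, up, mid, dn in triples:
        left, right = (up, dn) if up[0] < dn[0] else (dn, up)
        lg, rg = mid[0] - left[1], right[0] - mid[1]
        up_i, dn_i = (lg, rg) if strand == "+" else (rg, lg)
        base_rows.append(
            (up[1] - up[0], up_i, mid[1] - mid[0], dn_i, dn[1] - dn[0])
        )
    se_baseline = {
        f: _mean([r[i] for r in base_rows]) for i, f in enumerate(size_fields)
    }
    ri_fields = ["upstream_exon_len", "retained_intron_len", "downstream_exon_len"]
    ri_sig = [p for p in ri_plants if p.fdr < 0.0005]
    ri_means = {f: _mean([p.sizes()[f] for p in ri_sig]) for f in ri_fields}
    ri_base_rows = []
    for chrom, strand, a, b in introns:
        left, right = (a, b) if a[0] < b[0] else (b, a)
        ri_base_rows.append((a[1] - a[0], right[0] - left[1], b[1] - b[0]))
    ri_baseline = {f: _mean([r[i] for r in ri_base_rows]) for i, f in enumerate(ri_fields)}

    manifest = {
        "seed": spec.seed,
        "se_events": truth_se,
        "ri_events": truth_ri,
        "maxent_groups": {
            "strong": [k for k, v in truth_se.items() if v["site_strength"] == "strong"],
            "weak": [k for k, v in truth_se.items() if v["site_strength"] == "weak"],
        },
        "aggregates": {
            "n_sig_neg": len(sig_neg),
            "n_sig_pos": len(sig_pos),
            "fraction_unannotated_neg": (
                sum(not p.annotated for p in sig_neg) / len(sig_neg) if sig_neg else None
            ),
            "number_skipped_hist_neg": hist,
            "n_translatable_neg": len(translatable),
            "n_nmd_neg": n_nmd,
            "fraction_nmd_neg": (n_nmd / len(translatable)) if translatable else None,
            "n_neopeptides_neg": len(frameshift_t),
            "n_long_neopeptides_neg": sum(
                len(t["neopeptide"]) > 12 for t in frameshift_t
            ),
            "se_size_means_neg": se_means_neg,
            "se_size_baseline": se_baseline,
            "ri_size_means_sig": ri_means,
            "ri_size_baseline": ri_baseline,
            "footprint_neg": footprint,
            "unmatched_event_genes": sorted(
                {p.gene.symbol for p in sig_neg} & missing_genes
            ),
        },
    }

    # --- write everything
    _write_fasta(outdir / "genome.fa", {n: "".join(p) for n, p in contigs.items()})
    with open(outdir / "annotation.bed", "w") as fh:
        for tx in transcripts:
            fh.write(tx.to_bed12_line() + "\n")
    write_rmats(
        outdir / "fixture_SE.MATS.JCEC.txt", [p.splice_event() for p in se_plants]
    )
    write_rmats(
        outdir / "fixture_RI.MATS.JCEC.txt", [p.splice_event() for p in ri_plants]
    )
    with open(outdir / "expression.tsv", "w") as fh:
        fh.write("gene_id\tctrl_1\tctrl_2\ttest_1\ttest_2\n")
        for sym, c1, c2, t1, t2 in expression_rows:
            fh.write(f"{sym}\t{c1:g}\t{c2:g}\t{t1:g}\t{t2:g}\n")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest


def _write_fasta(path: Path, contigs: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


# ----------------------------------------------- cross-experiment fixture


def generate_compare_dir(
    outdir: str | Path,
    seed: int = 42,
    n_universe: int = 400,
    cluster_sizes: tuple[int, int] = (3, 3),
    sig_per_cluster: int = 100,
    jitter: int = 5,
) -> dict:
    """Experiment directory with two planted similarity clusters.

    Every experiment tests the same universe of synthetic SE events; the
    experiments of one cluster share a core significant set (up to
    ``jitter`` substitutions each), and the two clusters' cores are
    disjoint.  Returns a manifest with the planted cluster labels and the
    expected exact overlap parameters for within-cluster pairs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    universe = []
    pos = 1000
    for i in range(n_universe):
        a = pos
        universe.append(
            SpliceEvent(
                as_type=ASType.SE,
                gene_symbol=f"G{i:04d}",
                chrom="chr9",
                strand="+",
                coords=(a, a + 100, a - 400, a - 300, a + 500, a + 600),
                fdr=NONSIG_FDR,
                inc_diff=-0.05,
            )
        )
        pos += 2000
    idx = np.arange(n_universe)
    core_a = idx[:sig_per_cluster]
    core_b = idx[sig_per_cluster : 2 * sig_per_cluster]
    spare = idx[2 * sig_per_cluster :]

    manifest: dict = {"clusters": {}, "pairs": {}, "n_universe": n_universe}
    sig_sets: dict[str, set[int]] = {}
    names: list[str] = []
    for c, (label, core) in enumerate(zip("AB", (core_a, core_b))):
        for j in range(cluster_sizes[c]):
            name = f"exp{label}{j + 1}"
            names.append(name)
            drop = rng.choice(core, size=jitter, replace=False)
            add = rng.choice(spare, size=jitter, replace=False)
            sig = (set(core.tolist()) - set(drop.tolist())) | set(add.tolist())
            sig_sets[name] = sig
            manifest["clusters"][name] = label
            events = []
            for i, ev in enumerate(universe):
                if i in sig:
                    # alternate signs within the significant core
                    inc = NEG_INC if i % 2 == 0 else POS_INC
                    events.append(
                        SpliceEvent(
                            as_type=ev.as_type, gene_symbol=ev.gene_symbol,
                            chrom=ev.chrom, strand=ev.strand, coords=ev.coords,
                            fdr=SIG_FDR, inc_diff=inc,
                        )
                    )
                else:
                    events.append(ev)
            write_rmats(outdir / f"{name}_SE.MATS.JCEC.txt", events)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            k = len(sig_sets[a] & sig_sets[b])
            manifest["pairs"][f"{a}|{b}"] = {
                "k_total": k,
                "K": len(sig_sets[a]),
                "n": len(sig_sets[b]),
                "N": n_universe,
            }
    with open(outdir / "compare_truth.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest
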