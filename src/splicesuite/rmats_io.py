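"""Reading, validating and filtering rMATS JCEC differential-splicing files.

rMATS emits one tab-separated file per alternative-splicing type (SE, RI,
A5SS, A3SS, MXE).  The columns this suite consumes are fixed by position
(1-based, as conventionally described):

* SE/RI/A5SS/A3SS — gene symbol (col 3), chromosome (col 4), strand (col 5),
  six 0-based genomic coordinates (cols 6-11), FDR (col 20), inclusion-level
  difference (col 23).
* MXE — as above but eight coordinates (cols 6-13), FDR (col 22),
  inclusion-level difference (col 25).

Line 1 must be a header.  All other columns are ignored, so output from
other callers can be shimmed into the layout by filling only the columns
above (enable ``lenient`` to accept files with missing trailing columns).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)


class ASType(str, Enum):
    """The five alternative-splicing event types reported by rMATS."""

    SE = "SE"
    RI = "RI"
    A5SS = "A5SS"
    A3SS = "A3SS"
    MXE = "MXE"

    @property
    def n_coords(self) -> int:
        return 8 if self is ASType.MXE else 6

    @property
    def fdr_col(self) -> int:
        """1-based column of the FDR field."""
        return 22 if self is ASType.MXE else 20

    @property
    def inc_diff_col(self) -> int:
        """1-based column of the inclusion-level difference field."""
        return 25 if self is ASType.MXE else 23

    @property
    def min_columns(self) -> int:
        return self.inc_diff_col


class Sign(str, Enum):
    """Requested sign of the inclusion-level difference.

    For SE events a negative difference means increased skipping under the
    test condition; for RI a positive difference means increased retention
    (sample 1 of the rMATS run is taken to be the test condition).
    """

    NEGATIVE = "negative"
    POSITIVE = "positive"
    BOTH = "both"


class RmatsFormatError(ValueError):
    """Structural problem in a JCEC file (missing header, short line...)."""


class RmatsValidationError(ValueError):
    """A parsed field violates its contract (FDR outside [0,1]...)."""


@dataclass(frozen=True)
class SpliceEvent:
    """One rMATS record, reduced to the fields the suite consumes.

    ``coords`` keeps the 0-based half-open genomic coordinates in file
    order: 6 values for SE/RI/A5SS/A3SS, 8 for MXE.
    """

    as_type: ASType
    gene_symbol: str
    chrom: str
    strand: str
    coords: tuple[int, ...]
    fdr: float
    inc_diff: float
    source_line: int = 0

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise RmatsValidationError(
                f"line {self.source_line}: strand must be '+' or '-', got {self.strand!r}"
            )
        if len(self.coords) != self.as_type.n_coords:
            raise RmatsValidationError(
                f"line {self.source_line}: {self.as_type.value} events need "
                f"{self.as_type.n_coords} coordinates, got {len(self.coords)}"
            )
        if any(c < 0 for c in self.coords):
            raise RmatsValidationError(f"line {self.source_line}: negative coordinate")
        for s, e in zip(self.coords[::2], self.coords[1::2]):
            if not s < e:
                raise RmatsValidationError(
                    f"line {self.source_line}: exon interval [{s}, {e}) is empty or inverted"
                )
        if not 0.0 <= self.fdr <= 1.0:
            raise RmatsValidationError(f"line {self.source_line}: FDR {self.fdr} outside [0, 1]")
        if not -1.0 <= self.inc_diff <= 1.0:
            raise RmatsValidationError(
                f"line {self.source_line}: IncLevelDifference {self.inc_diff} outside [-1, 1]"
            )


@dataclass(frozen=True)
class SEEventView:
    """Strand-normalized accessors over a skipped-exon event.

    rMATS labels the flanking exons "upstream"/"downstream"; this view
    exposes both the raw file-order fields and transcript-oriented
    accessors so downstream modules are strand-safe regardless of which
    convention the producing pipeline used.  Genomic-axis attributes
    (``left_*`` / ``right_*``) always satisfy
    ``left_ee <= exon_start < exon_end <= right_es``.
    """

    event: SpliceEvent

    def __post_init__(self) -> None:
        if self.event.as_type is not ASType.SE:
            raise ValueError(f"SEEventView requires an SE event, got {self.event.as_type}")

    @property
    def exon_start(self) -> int:
        return self.event.coords[0]

    @property
    def exon_end(self) -> int:
        return self.event.coords[1]

    # flanking exons sorted onto the genomic axis
    def _flanks(self) -> tuple[tuple[int, int], tuple[int, int]]:
        a = (self.event.coords[2], self.event.coords[3])
        b = (self.event.coords[4], self.event.coords[5])
        return (a, b) if a[0] <= b[0] else (b, a)

    @property
    def left_es(self) -> int:
        return self._flanks()[0][0]

    @property
    def left_ee(self) -> int:
        return self._flanks()[0][1]

    @property
    def right_es(self) -> int:
        return self._flanks()[1][0]

    @property
    def right_ee(self) -> int:
        return self._flanks()[1][1]

    # transcript-oriented flanks: on '-' the genomic-right exon is upstream
    @property
    def upstream_exon(self) -> tuple[int, int]:
        left, right = self._flanks()
        return left if self.event.strand == "+" else right

    @property
    def downstream_exon(self) -> tuple[int, int]:
        left, right = self._flanks()
        return right if self.event.strand == "+" else left

    @property
    def skip_junction(self) -> tuple[str, str, int, int]:
        """The (chrom, strand, intron_start, intron_end) joined by skipping."""
        return (self.event.chrom, self.event.strand, self.left_ee, self.right_es)

    def validate(self) -> None:
        if not (self.left_ee <= self.exon_start < self.exon_end <= self.right_es):
            raise RmatsValidationError(
                f"line {self.event.source_line}: skipped exon "
                f"[{self.exon_start}, {self.exon_end}) not between flanking exons"
            )


@dataclass(frozen=True)
class RIEventView:
    """Accessors over a retained-intron event (genomic axis + orientation)."""

    event: SpliceEvent

    def __post_init__(self) -> None:
        if self.event.as_type is not ASType.RI:
            raise ValueError(f"RIEventView requires an RI event, got {self.event.as_type}")

    def _flanks(self) -> tuple[tuple[int, int], tuple[int, int]]:
        a = (self.event.coords[2], self.event.coords[3])
        b = (self.event.coords[4], self.event.coords[5])
        return (a, b) if a[0] <= b[0] else (b, a)

    @property
    def left_exon(self) -> tuple[int, int]:
        return self._flanks()[0]

    @property
    def right_exon(self) -> tuple[int, int]:
        return self._flanks()[1]

    @property
    def intron(self) -> tuple[int, int]:
        return (self.left_exon[1], self.right_exon[0])

    @property
    def upstream_exon(self) -> tuple[int, int]:
        return self.left_exon if self.event.strand == "+" else self.right_exon

    @property
    def downstream_exon(self) -> tuple[int, int]:
        return self.right_exon if self.event.strand == "+" else self.left_exon


@dataclass(frozen=True)
class SignificanceFilter:
    """FDR threshold (strict ``<``) plus a sign requirement on IncDiff."""

    fdr_threshold: float = 0.0005
    sign: Sign = Sign.BOTH

    def __post_init__(self) -> None:
        if not 0.0 < self.fdr_threshold <= 1.0:
            raise ValueError(f"fdr_threshold must be in (0, 1], got {self.fdr_threshold}")

    def accepts(self, event: SpliceEvent) -> bool:
        if not event.fdr < self.fdr_threshold:
            return False
        if self.sign is Sign.NEGATIVE:
            return event.inc_diff < 0
        if self.sign is Sign.POSITIVE:
            return event.inc_diff > 0
        return True


def _parse_line(
    fields: Sequence[str], as_type: ASType, line_no: int
) -> SpliceEvent:
    try:
        coords = tuple(
            int(fields[i]) for i in range(5, 5 + as_type.n_coords)
        )
        fdr = float(fields[as_type.fdr_col - 1])
        inc_diff = float(fields[as_type.inc_diff_col - 1])
    except ValueError as exc:
        raise RmatsFormatError(
            f"line {line_no}: could not parse required numeric field ({exc})"
        ) from None
    return SpliceEvent(
        as_type=as_type,
        gene_symbol=fields[2].strip('"'),
        chrom=fields[3],
        strand=fields[4],
        coords=coords,
        fdr=fdr,
        inc_diff=inc_diff,
        source_line=line_no,
    )


def read_rmats(
    path: str | Path,
    as_type: ASType | str,
    *,
    lenient: bool = False,
    flip_sign: bool = False,
) -> list[SpliceEvent]:
    """Parse a JCEC file into :class:`SpliceEvent` records in file order.

    Parameters
    ----------
    path
        Tab-separated JCEC file; line 1 must be a header.
    as_type
        Which of the five AS types the file holds (fixes column positions).
    lenient
        Pad missing trailing columns with blanks — accepts files shimmed
        together by other callers, as long as the required columns exist.
    flip_sign
        Negate every inclusion-level difference, for runs where rMATS
        sample 1 was the control rather than the test condition.
    """
    as_type = ASType(as_type)
    path = Path(path)
    events: list[SpliceEvent] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise RmatsFormatError(f"{path}: missing header line")
        for line_no, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < as_type.min_columns:
                if lenient and len(fields) >= 5 + as_type.n_coords:
                    fields = fields + [""] * (as_type.min_columns - len(fields))
                else:
                    raise RmatsFormatError(
                        f"{path}, line {line_no}: {len(fields)} columns, "
                        f"{as_type.value} requires at least {as_type.min_columns}"
                    )
            ev = _parse_line(fields, as_type, line_no)
            if flip_sign:
                ev = replace(ev, inc_diff=-ev.inc_diff)
            events.append(ev)
    return dedupe_events(events)


def dedupe_events(events: Iterable[SpliceEvent]) -> list[SpliceEvent]:
    """Collapse records with identical identity keys, keeping the smallest FDR."""
    best: dict[str, SpliceEvent] = {}
    order: list[str] = []
    n_dup = 0
    for ev in events:
        key = event_key(ev)
        if key not in best:
            best[key] = ev
            order.append(key)
        else:
            n_dup += 1
            if ev.fdr < best[key].fdr:
                best[key] = ev
    if n_dup:
        logger.warning("deduplicated %d event line(s) with identical coordinates", n_dup)
    return [best[k] for k in order]


def filter_significant(
    events: Iterable[SpliceEvent], sig_filter: SignificanceFilter
) -> list[SpliceEvent]:
    """Keep events with FDR strictly below the threshold and matching sign.

    Events with inclusion-difference exactly zero belong to neither sign
    class.  Order-preserving and idempotent.
    """
    return [ev for ev in events if sig_filter.accepts(ev)]


def event_key(event: SpliceEvent) -> str:
    """Canonical identity of an event: type, chrom, strand and coordinates.

    Deliberately excludes gene symbol and statistics so that the same
    physical event parsed from two experiments compares equal.
    """
    coords = ":".join(str(c) for c in event.coords)
    return f"{event.as_type.value}:{event.chrom}:{event.strand}:{coords}"


def write_rmats(path: str | Path, events: Sequence[SpliceEvent]) -> None:
    """Write events back out in the JCEC column layout (round-trip safe).

    Columns not consumed by the suite are left blank; numbers are printed
    with :func:`repr` so a write/read cycle is value-stable.
    """
    if not events:
        as_type = ASType.SE
    else:
        as_type = events[0].as_type
        if any(ev.as_type is not as_type for ev in events):
            raise ValueError("write_rmats requires a single AS type per file")
    n_cols = as_type.min_columns
    with open(path, "w") as fh:
        fh.write("\t".join(f"col{i}" for i in range(1, n_cols + 1)) + "\n")
        for ev in events:
            fields = [""] * n_cols
            fields[2] = ev.gene_symbol
            fields[3] = ev.chrom
            fields[4] = ev.strand
            for i, c in enumerate(ev.coords):
                fields[5 + i] = str(c)
            fields[as_type.fdr_col - 1] = repr(ev.fdr)
            fields[as_type.inc_diff_col - 1] = repr(ev.inc_diff)
            fh.write("\t".join(fields) + "\n")
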