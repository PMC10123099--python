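"""rMATS JCEC parsing, significance filtering and event identity."""

import pytest
from hypothesis import given, settings, strategies as st

from splicesuite.rmats_io import (
    ASType,
    RmatsFormatError,
    RmatsValidationError,
    SEEventView,
    SignificanceFilter,
    Sign,
    SpliceEvent,
    dedupe_events,
    event_key,
    filter_significant,
    read_rmats,
    write_rmats,
)


def _se_line(fdr="1e-6", inc="-0.31", coords=None, n_cols=23):
    coords = coords or ["48052363", "48052463", "48051000", "48051100", "48053000", "48053100"]
    fields = [""] * n_cols
    fields[0], fields[1], fields[2] = "1", "ENSG0001", "NFE2L1"
    fields[3], fields[4] = "chr17", "-"
    fields[5:11] = coords
    fields[19] = fdr
    fields[22] = inc
    return "\t".join(fields)


def _write_se(tmp_path, lines, name="x_SE.MATS.JCEC.txt", header=True):
    path = tmp_path / name
    content = ("\t".join(f"c{i}" for i in range(23)) + "\n") if header else ""
    path.write_text(content + "\n".join(lines) + ("\n" if lines else ""))
    return path


class TestReadRmats:
    def test_se_fields_land_in_the_documented_columns(self, tmp_path):
        events = read_rmats(_write_se(tmp_path, [_se_line()]), ASType.SE)
        assert len(events) == 1
        ev = events[0]
        assert ev.gene_symbol == "NFE2L1"
        assert ev.chrom == "chr17"
        assert ev.strand == "-"
        assert ev.coords == (48052363, 48052463, 48051000, 48051100, 48053000, 48053100)
        assert ev.fdr == pytest.approx(1e-6)
        assert ev.inc_diff == pytest.approx(-0.31)
        assert ev.source_line == 2

    def test_header_only_file_yields_empty_list(self, tmp_path):
        assert read_rmats(_write_se(tmp_path, []), ASType.SE) == []

    def test_mxe_uses_eight_coords_and_shifted_stat_columns(self, tmp_path):
        fields = [""] * 25
        fields[2], fields[3], fields[4] = "GENE", "chr2", "+"
        fields[5:13] = [str(v) for v in (100, 200, 300, 400, 50, 90, 500, 600)]
        fields[21], fields[24] = "1e-9", "0.5"
        path = tmp_path / "m_MXE.MATS.JCEC.txt"
        path.write_text("\t".join(["h"] * 25) + "\n" + "\t".join(fields) + "\n")
        (ev,) = read_rmats(path, ASType.MXE)
        assert len(ev.coords) == 8
        assert ev.fdr == pytest.approx(1e-9)
        assert ev.inc_diff == pytest.approx(0.5)

    def test_empty_file_is_a_format_error(self, tmp_path):
        path = tmp_path / "e_SE.MATS.JCEC.txt"
        path.write_text("")
        with pytest.raises(RmatsFormatError, match="header"):
            read_rmats(path, ASType.SE)

    def test_short_line_rejected_with_line_number(self, tmp_path):
        path = _write_se(tmp_path, [_se_line(), "\t".join(["x"] * 12)])
        with pytest.raises(RmatsFormatError, match="line 3"):
            read_rmats(path, ASType.SE)

    def test_lenient_mode_pads_missing_trailing_columns(self, tmp_path):
        # only 11 columns: coords present, stats missing -> still rejected
        # because FDR/IncDiff cannot be parsed from blanks
        line = _se_line(n_cols=23).split("\t")[:21]
        path = _write_se(tmp_path, ["\t".join(line)])
        with pytest.raises(RmatsFormatError):
            read_rmats(path, ASType.SE, lenient=True)
        # 21 columns with FDR at 20 parse only under lenient
        with pytest.raises(RmatsFormatError):
            read_rmats(path, ASType.SE)

    def test_out_of_range_fdr_is_a_validation_error(self, tmp_path):
        path = _write_se(tmp_path, [_se_line(fdr="1.5")])
        with pytest.raises(RmatsValidationError, match="FDR"):
            read_rmats(path, ASType.SE)

    def test_flip_sign_negates_inclusion_difference(self, tmp_path):
        (ev,) = read_rmats(_write_se(tmp_path, [_se_line(inc="-0.31")]),
                           ASType.SE, flip_sign=True)
        assert ev.inc_diff == pytest.approx(0.31)

    def test_duplicate_lines_keep_smallest_fdr(self, tmp_path):
        path = _write_se(tmp_path, [_se_line(fdr="0.01"), _se_line(fdr="1e-9")])
        (ev,) = read_rmats(path, ASType.SE)
        assert ev.fdr == pytest.approx(1e-9)


class TestFilterSignificant:
    def _events(self, pairs):
        return [
            SpliceEvent(ASType.SE, "G", "chr1", "+",
                        (100, 200, 10, 50, 300, 400), fdr, inc)
            for fdr, inc in pairs
        ]

    def test_threshold_is_strict_less_than(self):
        events = self._events([(1e-6, -0.2), (0.0005, -0.2), (0.2, -0.2)])
        kept = filter_significant(events, SignificanceFilter(0.0005, Sign.BOTH))
        assert [e.fdr for e in kept] == [1e-6]

    def test_sign_classes_exclude_zero_inc_diff(self):
        events = self._events([(0.0, d) for d in (-0.4, -0.1, 0.0, 0.1, 0.4)])
        neg = filter_significant(events, SignificanceFilter(0.0005, Sign.NEGATIVE))
        pos = filter_significant(events, SignificanceFilter(0.0005, Sign.POSITIVE))
        assert [e.inc_diff for e in neg] == [-0.4, -0.1]
        assert [e.inc_diff for e in pos] == [0.1, 0.4]

    def test_idempotent_and_order_preserving(self):
        events = self._events([(1e-9, -0.5), (1e-7, 0.3), (0.9, -0.1)])
        f = SignificanceFilter(0.0005, Sign.BOTH)
        once = filter_significant(events, f)
        assert filter_significant(once, f) == once
        assert once == events[:2]

    def test_empty_input_gives_empty_output(self):
        assert filter_significant([], SignificanceFilter()) == []


class TestEventKey:
    def _ev(self, **kw):
        base = dict(as_type=ASType.SE, gene_symbol="G", chrom="chr1", strand="+",
                    coords=(100, 200, 10, 50, 300, 400), fdr=0.1, inc_diff=0.2)
        base.update(kw)
        return SpliceEvent(**base)

    def test_key_ignores_statistics_and_gene_symbol(self):
        a = self._ev(fdr=0.001, inc_diff=-0.9, gene_symbol="A")
        b = self._ev(fdr=0.9, inc_diff=0.1, gene_symbol="B")
        assert event_key(a) == event_key(b)

    def test_strand_and_type_distinguish_keys(self):
        assert event_key(self._ev()) != event_key(self._ev(strand="-"))
        mxe = self._ev(as_type=ASType.MXE,
                       coords=(100, 200, 10, 50, 300, 400, 500, 600))
        assert event_key(mxe) != event_key(self._ev())


class TestSEEventView:
    def test_orientation_normalization_on_minus_strand(self):
        # flanks supplied in transcript order: upstream is genomic-right
        ev = SpliceEvent(ASType.SE, "G", "chr1", "-",
                         (500, 650, 900, 1000, 100, 200), 1e-9, -0.3)
        view = SEEventView(ev)
        view.validate()
        assert view.upstream_exon == (900, 1000)
        assert view.downstream_exon == (100, 200)
        assert view.skip_junction == ("chr1", "-", 200, 900)

    def test_invalid_nesting_raises(self):
        ev = SpliceEvent(ASType.SE, "G", "chr1", "+",
                         (100, 200, 150, 250, 300, 400), 1e-9, -0.3)
        with pytest.raises(RmatsValidationError):
            SEEventView(ev).validate()


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    st.lists(
        st.tuples(
            st.integers(0, 10_000),
            st.floats(0, 1, allow_nan=False),
            st.floats(-1, 1, allow_nan=False),
        ),
        max_size=30,
    )
)
def test_write_read_round_trip_preserves_all_fields(tmp_path_factory, rows):
    """Writing parsed events in JCEC layout and re-parsing is lossless."""
    events = dedupe_events(
        SpliceEvent(
            ASType.SE, f"G{i}", "chr1", "+",
            (s, s + 10, s + 20, s + 30, s + 40, s + 50), fdr, inc,
        )
        for i, (s, fdr, inc) in enumerate(rows)
    )
    path = tmp_path_factory.mktemp("rt") / "rt_SE.MATS.JCEC.txt"
    write_rmats(path, events)
    back = read_rmats(path, ASType.SE)
    assert [
        (e.gene_symbol, e.chrom, e.strand, e.coords, e.fdr, e.inc_diff) for e in back
    ] == [
        (e.gene_symbol, e.chrom, e.strand, e.coords, e.fdr, e.inc_diff) for e in events
    ]
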