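"""Annotation status, multi-exon skipping counts and size statistics."""

import pytest

from splicesuite.annotation import TranscriptModel, build_junction_index
from splicesuite.rmats_io import ASType, SEEventView, SpliceEvent, event_key
from splicesuite.structure_stats import (
    RI_SIZE_FIELDS,
    SE_SIZE_FIELDS,
    classify_annotation,
    count_intervening_exons,
    number_skipped_summary,
    ri_intron_exon_sizes,
    se_intron_exon_sizes,
    se_size_record,
)


def _se(coords, strand="+"):
    return SpliceEvent(ASType.SE, "G", "chr1", strand, coords, 1e-9, -0.3)


def _view(coords, strand="+"):
    return SEEventView(_se(coords, strand))


def _tx(exons, tid="T1"):
    return TranscriptModel(tid, "G", "chr1", "+", tuple(exons))


class TestClassifyAnnotation:
    def test_matches_planted_annotation_flags(self, sig_neg, junction_index, truth):
        summary = classify_annotation(sig_neg, junction_index)
        assert summary.fraction_unannotated == pytest.approx(
            truth["aggregates"]["fraction_unannotated_neg"]
        )
        for status in summary.statuses:
            assert status.annotated == truth["se_events"][status.event_key]["annotated"]

    def test_empty_annotation_makes_everything_unannotated(self, sig_neg):
        summary = classify_annotation(sig_neg, build_junction_index([]))
        assert summary.fraction_unannotated == 1.0

    def test_fuzz_tolerates_shifted_boundaries(self):
        idx = build_junction_index([_tx([(0, 100), (500, 600)])])
        shifted = _se((200, 300, 0, 101, 500, 600))  # junction (101, 500)
        exact = classify_annotation([shifted], idx)
        fuzzy = classify_annotation([shifted], idx, fuzz=1)
        assert not exact.statuses[0].annotated
        assert fuzzy.statuses[0].annotated

    def test_empty_event_set_gives_na_fraction(self, junction_index):
        summary = classify_annotation([], junction_index)
        assert summary.total == 0
        assert summary.fraction_unannotated is None


class TestCountIntervening:
    def test_disjoint_contained_exons_count_separately(self):
        idx = build_junction_index(
            [_tx([(500, 1000), (2000, 2100), (5000, 5100)]),
             _tx([(500, 1000), (3000, 3090), (5000, 5100)], tid="T2")]
        )
        view = _view((2000, 2100, 500, 1000, 5000, 5100))
        assert count_intervening_exons(view, idx) == 2

    def test_overlapping_exon_variants_form_one_cluster(self):
        idx = build_junction_index(
            [_tx([(500, 1000), (2000, 2100), (5000, 5100)]),
             _tx([(500, 1000), (2050, 2150), (5000, 5100)], tid="T2")]
        )
        view = _view((2000, 2100, 500, 1000, 5000, 5100))
        assert count_intervening_exons(view, idx) == 1

    def test_transcript_duplication_does_not_change_count(self):
        base = [_tx([(500, 1000), (2000, 2100), (5000, 5100)])]
        dup = base + [_tx([(500, 1000), (2000, 2100), (5000, 5100)], tid="T9")]
        view = _view((2000, 2100, 500, 1000, 5000, 5100))
        assert count_intervening_exons(view, build_junction_index(base)) == \
            count_intervening_exons(view, build_junction_index(dup))

    def test_histogram_matches_planted_multiskip_counts(
        self, sig_neg, junction_index, truth
    ):
        hist, records = number_skipped_summary(sig_neg, junction_index)
        assert hist == truth["aggregates"]["number_skipped_hist_neg"]
        assert sum(hist.values()) == len(records) == len(sig_neg)
        for rec in records:
            assert rec.n_intervening == truth["se_events"][rec.event_key]["n_intervening"]


class TestSizes:
    def test_plus_strand_coordinate_arithmetic(self):
        rec = se_size_record(_view((500, 650, 100, 200, 900, 1000)))
        assert rec.as_tuple() == (100, 300, 150, 250, 100)

    def test_minus_strand_swaps_flank_labels(self):
        rec = se_size_record(_view((500, 650, 900, 1000, 100, 200), strand="-"))
        assert rec.as_tuple() == (100, 250, 150, 300, 100)

    def test_event_and_baseline_means_match_manifest(
        self, sig_neg, transcripts, truth
    ):
        from splicesuite.annotation import enumerate_annotated_se_triples

        _, means, baseline = se_intron_exon_sizes(
            sig_neg, enumerate_annotated_se_triples(transcripts)
        )
        for value, field in zip(means, SE_SIZE_FIELDS):
            assert value == pytest.approx(
                truth["aggregates"]["se_size_means_neg"][field]
            )
        for value, field in zip(baseline, SE_SIZE_FIELDS):
            assert value == pytest.approx(
                truth["aggregates"]["se_size_baseline"][field]
            )

    def test_union_mean_is_weighted_mean_of_parts(self, sig_neg):
        _, all_means, _ = se_intron_exon_sizes(sig_neg)
        recs_a, means_a, _ = se_intron_exon_sizes(sig_neg[:4])
        recs_b, means_b, _ = se_intron_exon_sizes(sig_neg[4:])
        na, nb = len(recs_a), len(recs_b)
        for i in range(5):
            weighted = (means_a[i] * na + means_b[i] * nb) / (na + nb)
            assert all_means[i] == pytest.approx(weighted)

    def test_ri_sizes_match_manifest(self, ri_events, transcripts, truth):
        from splicesuite.annotation import enumerate_annotated_introns
        from splicesuite.rmats_io import SignificanceFilter, Sign, filter_significant

        sig = filter_significant(ri_events, SignificanceFilter(0.0005, Sign.POSITIVE))
        records, means, baseline = ri_intron_exon_sizes(
            sig, enumerate_annotated_introns(transcripts)
        )
        for rec in records:
            expect = truth["ri_events"][rec.event_key]["sizes"]
            assert rec.as_tuple() == tuple(expect[f] for f in RI_SIZE_FIELDS)
        for value, field in zip(baseline, RI_SIZE_FIELDS):
            assert value == pytest.approx(
                truth["aggregates"]["ri_size_baseline"][field]
            )

    def test_simple_ri_arithmetic(self):
        ev = SpliceEvent(ASType.RI, "G", "chr1", "+",
                         (100, 600, 100, 200, 500, 600), 1e-9, 0.4)
        from splicesuite.rmats_io import RIEventView
        from splicesuite.structure_stats import ri_size_record

        assert ri_size_record(RIEventView(ev)).as_tuple() == (100, 300, 100)
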