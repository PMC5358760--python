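"""Nested-unit discovery, cross-confirmation, roadblock statistics and
NELF/DSIF classification."""
import numpy as np
import pytest

from pol3roadblock import scenarios, synthio
from pol3roadblock.core import GeneModel, Interval
from pol3roadblock.nesting import (FunnelConfig, classify_accumulation,
                                   cross_confirm, detect_roadblock,
                                   find_nested, run_funnel)
from pol3roadblock.tagweight import CoverageTrack, assign_weights, build_coverage
from conftest import SEED

GENE = GeneModel("g1", "chr1", 500, 5000, "+", body_level=10)


def track_from(arr, bin_size=10, read_length=36.0):
    arr = np.asarray(arr, dtype=float)
    return CoverageTrack({"chr1": arr}, bin_size,
                         total_weight=float(arr.sum()) * bin_size / read_length,
                         read_length=read_length)


class TestFindNested:
    def test_contained_antisense_peak_yields_one_event(self):
        events = find_nested([Interval("chr1", 1000, 1100, "-", "pk")], [GENE])
        assert len(events) == 1
        assert events[0].orientation == "antisense"
        assert events[0].host_gene.gene_id == "g1"
        assert events[0].distance_to_host_tss == 500

    def test_peak_straddling_tes_excluded(self):
        assert find_nested([Interval("chr1", 4950, 5050, "+")], [GENE]) == []

    def test_peak_in_promoter_exclusion_zone_excluded(self):
        # within 250 bp of the TSS: TSS pausing must not count as nested
        assert find_nested([Interval("chr1", 600, 700, "+")], [GENE]) == []
        minus = GeneModel("g2", "chr1", 500, 5000, "-")
        assert find_nested([Interval("chr1", 4800, 4900, "+")], [minus]) == []

    def test_unstranded_peak_uses_hint_or_errors(self):
        peak = Interval("chr1", 1000, 1100, ".", "pk")
        events = find_nested([peak], [GENE], strand_hints={"pk": "-"})
        assert events[0].orientation == "antisense"
        with pytest.raises(ValueError, match="no strand"):
            find_nested([peak], [GENE])

    def test_polr3e_like_configuration(self):
        """An antisense MIR in the first intron is the single nesting event;
        the tRNA gene upstream of the host TSS yields none."""
        genome = synthio.generate_genome(scenarios.polr3e_like_spec(seed=SEED))
        peaks = [Interval(u.contig, u.start, u.end, u.strand, n)
                 for u, n in zip(genome.pol3_units, ("MIR", "tRNA-Leu"))]
        events = find_nested(peaks, genome.genes)
        assert len(events) == 1
        assert events[0].pol3_unit.name == "MIR"
        assert events[0].orientation == "antisense"


class TestCrossConfirm:
    def _events(self, n=10):
        peaks = [Interval("chr1", 1000 + i * 300, 1100 + i * 300, "+", f"p{i}")
                 for i in range(n)]
        gene = GeneModel("g", "chr1", 0, 10_000, "+")
        return find_nested(peaks, gene and [gene])

    def test_identical_peaksets_all_confirmed(self):
        events = self._events()
        second = [ev.pol3_unit for ev in events]
        cross_confirm(events, second)
        assert all(ev.cross_confirmed for ev in events)

    def test_empty_second_set_confirms_none(self):
        events = self._events()
        cross_confirm(events, [])
        assert not any(ev.cross_confirmed for ev in events)

    def test_partial_overlap_confirms_exactly_the_shared_peaks(self):
        events = self._events(10)
        second = [ev.pol3_unit for ev in events[:7]]
        cross_confirm(events, second)
        assert sum(bool(ev.cross_confirmed) for ev in events) == 7

    def test_summit_distance_threshold_is_respected(self):
        events = self._events(1)
        summit = events[0].summit()
        near = [Interval("chr1", summit + 150, summit + 250, "+")]   # d = 200
        far = [Interval("chr1", summit + 151, summit + 251, "+")]    # d = 201
        cross_confirm(events, near, max_summit_distance=200)
        assert events[0].cross_confirmed
        cross_confirm(events, far, max_summit_distance=200)
        assert not events[0].cross_confirmed


class TestDetectRoadblock:
    def _event(self, unit_start=3000, strand="+"):
        return find_nested(
            [Interval("chr1", unit_start, unit_start + 260, strand)], [GENE])[0]

    def test_uniform_coverage_gives_fold_one_nonsignificant(self):
        pol2 = track_from(np.full(500, 12.0))
        call = detect_roadblock(pol2, self._event())
        assert call.fold == pytest.approx(1.0, abs=0.01)
        assert call.p_value > 0.2

    def test_fivefold_window_over_background(self):
        arr = np.full(500, 10.0)
        arr[280:300] = 50.0  # the 200 bp window [2800, 3000) before the unit
        call = detect_roadblock(track_from(arr), self._event())
        assert call.fold == pytest.approx(5.0)
        assert call.window.start == 2800 and call.window.end == 3000
        assert call.p_value < 1e-6

    def test_window_faces_tss_on_minus_strand_host(self):
        minus = GeneModel("gm", "chr1", 500, 5000, "-", body_level=10)
        ev = find_nested([Interval("chr1", 3000, 3260, "+")], [minus])[0]
        call = detect_roadblock(track_from(np.full(500, 10.0)), ev)
        assert (call.window.start, call.window.end) == (3260, 3460)

    def test_zero_background_flagged_unclassified(self):
        arr = np.zeros(500)
        arr[280:300] = 5.0
        call = detect_roadblock(track_from(arr), self._event())
        assert call.flag == "zero_background"
        call = classify_accumulation(call, self._event(), nelf=track_from(np.ones(500)))
        assert call.classification == "unclassified"

    def test_null_type_one_error_is_calibrated(self):
        """On ~100 genes with nested units but no pileups, the fraction of
        events at p < 0.05 stays near the nominal level."""
        genome = synthio.generate_genome(
            scenarios.calibration_spec(n_genes=100, seed=SEED))
        tags = synthio.simulate_chip_tags(genome, "pol2", depth=100_000,
                                          seed=SEED + 31)
        pol2 = build_coverage(assign_weights(tags), scenarios.BIN_SIZE,
                              genome.contig_lengths())
        peaks = [Interval(u.contig, u.start, u.end, u.strand)
                 for u in genome.pol3_units]
        events = find_nested(peaks, genome.genes)
        assert len(events) == 100
        frac = np.mean([detect_roadblock(pol2, ev).p_value < 0.05
                        for ev in events])
        assert frac <= 0.09  # nominal 0.05 with binomial slack at n=100


class TestClassifyAccumulation:
    def _call_and_event(self):
        ev = find_nested([Interval("chr1", 3000, 3260, "+")], [GENE])[0]
        arr = np.full(500, 10.0)
        arr[280:300] = 40.0
        call = detect_roadblock(track_from(arr), ev)
        return call, ev

    def test_flat_nelf_with_dsif_is_roadblock(self):
        call, ev = self._call_and_event()
        nelf = track_from(np.full(500, 4.0))
        dsif = np.full(500, 4.0)
        dsif[280:300] = 16.0
        out = classify_accumulation(call, ev, nelf, track_from(dsif))
        assert out.classification == "roadblock"
        assert out.dsif_enrichment > 2.0

    def test_nelf_enriched_window_is_putative_internal_tss(self):
        call, ev = self._call_and_event()
        nelf = np.full(500, 4.0)
        nelf[280:300] = 20.0
        out = classify_accumulation(call, ev, track_from(nelf), None)
        assert out.classification == "putative_internal_TSS"

    def test_missing_nelf_track_leaves_unclassified(self):
        call, ev = self._call_and_event()
        out = classify_accumulation(call, ev, None, None)
        assert out.classification == "unclassified"


class TestRunFunnel:
    def test_planted_events_recovered_with_orientations(self, funnel_genome,
                                                        funnel_tracks):
        manifest = funnel_genome.manifest()
        peaks = [Interval(u.contig, u.start, u.end, u.strand, f"peak_{i}")
                 for i, u in enumerate(funnel_genome.pol3_units)]
        report = run_funnel(peaks, funnel_genome.genes,
                            funnel_tracks["pol3_ip"], funnel_tracks["input"],
                            pol2=funnel_tracks["pol2"], second_peakset=peaks,
                            nelf=funnel_tracks["nelf"], dsif=funnel_tracks["dsif"])
        c = report.counts
        assert c["input_peaks"] == c["confirmed"] == c["nested"] == 10
        assert c["cross_confirmed"] == 10
        assert c["host_genes"] == 10
        # all hosts run at 10x intergenic background, so all are occupied
        assert c["pol2_occupied_host_genes"] == 10

        truth = {(u["start"], u["end"]): u["orientation"]
                 for u in manifest["pol3_units"]}
        for ev in report.events:
            assert ev.orientation == truth[(ev.pol3_unit.start, ev.pol3_unit.end)]

        # both orientations are detected as significant accumulations
        sig = {ev.orientation for ev in report.events
               if ev.roadblock.q_value < 0.05}
        assert sig == {"sense", "antisense"}

        # NELF logic agrees with the manifest decoy flags everywhere
        decoy = {(rb["unit_start"], rb["unit_end"]): rb["is_decoy_tss"]
                 for rb in manifest["roadblocks"]}
        for ev in report.events:
            expected = ("putative_internal_TSS"
                        if decoy[(ev.pol3_unit.start, ev.pol3_unit.end)]
                        else "roadblock")
            assert ev.roadblock.classification == expected

    def test_stage_counts_non_increasing(self, funnel_genome, funnel_tracks):
        peaks = [Interval(u.contig, u.start, u.end, u.strand, f"peak_{i}")
                 for i, u in enumerate(funnel_genome.pol3_units)]
        report = run_funnel(peaks, funnel_genome.genes,
                            funnel_tracks["pol3_ip"], funnel_tracks["input"],
                            pol2=funnel_tracks["pol2"],
                            second_peakset=peaks[:6], nelf=funnel_tracks["nelf"])
        c = report.counts
        chain = [c["input_peaks"], c["confirmed"], c["nested"]]
        assert chain == sorted(chain, reverse=True)
        assert c["cross_confirmed"] == 6
        assert c["roadblocks"] <= c["nested"]

    def test_empty_peaks_give_all_zero_counts(self, funnel_genome, funnel_tracks):
        report = run_funnel([], funnel_genome.genes, funnel_tracks["pol3_ip"],
                            funnel_tracks["input"], pol2=funnel_tracks["pol2"],
                            second_peakset=[])
        assert all(v == 0 for v in report.counts.values())

    def test_missing_pol2_track_skips_roadblock_stage(self, funnel_genome,
                                                      funnel_tracks):
        peaks = [Interval(u.contig, u.start, u.end, u.strand)
                 for u in funnel_genome.pol3_units]
        report = run_funnel(peaks, funnel_genome.genes,
                            funnel_tracks["pol3_ip"], funnel_tracks["input"],
                            pol2=None, second_peakset=peaks)
        assert "detect_roadblock" in report.stages_skipped
        assert report.counts["roadblocks"] is None
        assert report.counts["cross_confirmed"] == 10
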