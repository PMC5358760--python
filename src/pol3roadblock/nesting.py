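"""Nested Pol III units inside Pol II genes and roadblock detection.

A Pol III peak fully contained in a Pol II transcription unit (past a
promoter-exclusion zone downstream of the TSS) defines a nesting event, with
sense/antisense orientation from strand comparison. For each event, Pol II
signal in a window abutting the Pol III unit on the side facing the host
gene's TSS — the side an elongating Pol II reaches first — is compared with
the gene-body background by a Poisson upper-tail test on tag counts, with
Benjamini-Hochberg correction across events. NELF/DSIF tracks then separate
a true elongation roadblock (DSIF may pile up, NELF does not) from a
putative internal TSS (NELF piles up, as it does only at promoter-proximal
pause sites).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import GeneModel, Interval
from .occupancy import confirm_peaks
from .tagweight import CoverageTrack

PROMOTER_EXCLUSION = 250     # bp downstream of TSS never counted as nested
MAX_SUMMIT_DISTANCE = 200    # bp for cross-dataset peak coincidence
ROADBLOCK_WINDOW = 200       # bp abutting the Pol III unit, TSS side
BACKGROUND_EXCLUSION = 500   # bp around TSS excluded from background
NELF_ENRICH_THRESHOLD = 2.0
ALPHA = 0.05
POL2_OCCUPIED_FOLD = 2.0     # gene-body level vs genomic background


@dataclass
class RoadblockCall:
    window: Interval
    fold: float
    window_mean: float
    background: float
    p_value: float
    q_value: float = float("nan")
    classification: str = "unclassified"
    nelf_enrichment: float = float("nan")
    dsif_enrichment: float = float("nan")
    flag: str = ""


@dataclass
class NestingEvent:
    pol3_unit: Interval
    host_gene: GeneModel
    orientation: str                  # sense | antisense
    distance_to_host_tss: int
    cross_confirmed: bool | None = None
    roadblock: RoadblockCall | None = None

    def summit(self) -> int:
        return self.pol3_unit.midpoint


def find_nested(
    pol3_peaks: list[Interval],
    genes: list[GeneModel],
    promoter_exclusion: int = PROMOTER_EXCLUSION,
    strand_hints: dict[str, str] | None = None,
) -> list[NestingEvent]:
    """Pol III peaks fully contained in a gene's [TSS + exclusion, TES] span.

    Orientation is sense iff peak and host strands agree. Unstranded peaks
    take their strand from ``strand_hints`` (peak name -> strand, e.g. from
    an internal-promoter scan) and are rejected when no hint exists either.
    """
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.contig, IntervalTree()).addi(g.start, g.end, g)

    events = []
    for pk in pol3_peaks:
        if pk.contig not in trees:
            continue
        for hit in sorted(trees[pk.contig].overlap(pk.start, pk.end)):
            g: GeneModel = hit.data
            if g.strand == "+":
                lo, hi = g.start + promoter_exclusion, g.end
            else:
                lo, hi = g.start, g.end - promoter_exclusion
            if not (lo <= pk.start and pk.end <= hi):
                continue
            strand = pk.strand
            if strand not in ("+", "-") and strand_hints:
                strand = strand_hints.get(pk.name, strand)
            if strand not in ("+", "-"):
                raise ValueError(
                    f"peak {pk.name or pk.contig} has no strand; orientation "
                    "cannot be assigned (supply a strand, e.g. from a promoter scan)"
                )
            orientation = "sense" if strand == g.strand else "antisense"
            near_edge = pk.start if g.strand == "+" else pk.end
            dist = abs(near_edge - g.tss)
            events.append(NestingEvent(pk, g, orientation, dist))
    return events


def cross_confirm(
    events: list[NestingEvent],
    second_peakset: list[Interval],
    max_summit_distance: int = MAX_SUMMIT_DISTANCE,
) -> list[NestingEvent]:
    """Flag events whose summit coincides with a summit in a second dataset."""
    summits: dict[str, np.ndarray] = {}
    for pk in second_peakset:
        summits.setdefault(pk.contig, []).append(pk.midpoint)
    summits = {c: np.sort(np.asarray(v)) for c, v in summits.items()}
    for ev in events:
        s = ev.summit()
        arr = summits.get(ev.pol3_unit.contig)
        if arr is None or arr.size == 0:
            ev.cross_confirmed = False
            continue
        i = int(np.searchsorted(arr, s))
        nearest = min(
            (abs(int(arr[j]) - s) for j in (i - 1, i) if 0 <= j < arr.size),
            default=math.inf,
        )
        ev.cross_confirmed = nearest <= max_summit_distance
    return events


def _gene_background(track: CoverageTrack, gene: GeneModel,
                     exclude: list[tuple[int, int]],
                     background_exclusion: int) -> float:
    """Median bin signal over the gene body, excluding the TSS neighbourhood
    and any given windows."""
    bs = track.bin_size
    arr = track.bins[gene.contig]
    b0, b1 = gene.start // bs, -(-gene.end // bs)
    mask = np.ones(b1 - b0, dtype=bool)

    def drop(lo, hi):
        lo_b = max(b0, lo // bs)
        hi_b = min(b1, -(-hi // bs))
        if hi_b > lo_b:
            mask[lo_b - b0:hi_b - b0] = False

    drop(gene.tss - background_exclusion, gene.tss + background_exclusion)
    for lo, hi in exclude:
        drop(lo, hi)
    vals = arr[b0:b1][mask]
    return float(np.median(vals)) if vals.size else 0.0


def detect_roadblock(
    pol2: CoverageTrack,
    event: NestingEvent,
    window: int = ROADBLOCK_WINDOW,
    background_exclusion: int = BACKGROUND_EXCLUSION,
) -> RoadblockCall:
    """Test for Pol II accumulation just upstream (in the host's reading
    direction) of the nested Pol III unit.

    The expected window tag count under no accumulation is the gene-body
    median per-base signal times the window length, converted to tag counts
    through the track's read length; the p-value is the Poisson upper tail.
    """
    g = event.host_gene
    u = event.pol3_unit
    if g.strand == "+":
        w0, w1 = u.start - window, u.start
    else:
        w0, w1 = u.end, u.end + window
    w0 = max(w0, g.start)
    w1 = min(w1, g.end)
    if w1 <= w0:
        return RoadblockCall(Interval(g.contig, u.start, u.start), float("nan"),
                             0.0, 0.0, 1.0, flag="degenerate_window")
    win = Interval(g.contig, w0, w1)
    window_mean = pol2.interval_mean(g.contig, w0, w1)
    background = _gene_background(pol2, g, [(w0, w1), (u.start, u.end)],
                                  background_exclusion)
    if background <= 0:
        return RoadblockCall(win, float("nan"), window_mean, background, 1.0,
                             flag="zero_background")
    fold = window_mean / background
    # per-base mass -> tag counts via read length
    obs = window_mean * (w1 - w0) / pol2.read_length
    lam = background * (w1 - w0) / pol2.read_length
    p = float(stats.poisson.sf(math.ceil(obs) - 1, lam))
    call = RoadblockCall(win, fold, window_mean, background, p)
    event.roadblock = call
    return call


def adjust_q_values(events: list[NestingEvent]) -> None:
    """Benjamini-Hochberg across all events carrying a roadblock call."""
    called = [ev for ev in events if ev.roadblock is not None]
    if not called:
        return
    pvals = [ev.roadblock.p_value for ev in called]
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    for ev, q in zip(called, qvals):
        ev.roadblock.q_value = float(q)


def classify_accumulation(
    call: RoadblockCall,
    event: NestingEvent,
    nelf: CoverageTrack | None,
    dsif: CoverageTrack | None = None,
    enrich_threshold: float = NELF_ENRICH_THRESHOLD,
) -> RoadblockCall:
    """NELF logic: NELF enrichment at the window marks a putative internal
    TSS; its absence marks a roadblock; no NELF track leaves the call
    unclassified."""
    if call.flag == "zero_background":
        call.classification = "unclassified"
        return call
    g = event.host_gene
    w = call.window
    for track, attr in ((nelf, "nelf_enrichment"), (dsif, "dsif_enrichment")):
        if track is None:
            continue
        mean = track.interval_mean(w.contig, w.start, w.end)
        bg = _gene_background(track, g, [(w.start, w.end),
                                         (event.pol3_unit.start, event.pol3_unit.end)],
                              BACKGROUND_EXCLUSION)
        setattr(call, attr, mean / bg if bg > 0 else float("inf"))
    if nelf is None:
        call.classification = "unclassified"
    elif call.nelf_enrichment >= enrich_threshold:
        call.classification = "putative_internal_TSS"
    else:
        call.classification = "roadblock"
    return call


@dataclass
class FunnelConfig:
    confirm_threshold: float = 1.0
    pseudocount: float = 1.0
    promoter_exclusion: int = PROMOTER_EXCLUSION
    max_summit_distance: int = MAX_SUMMIT_DISTANCE
    window: int = ROADBLOCK_WINDOW
    background_exclusion: int = BACKGROUND_EXCLUSION
    nelf_enrich_threshold: float = NELF_ENRICH_THRESHOLD
    alpha: float = ALPHA
    pol2_occupied_fold: float = POL2_OCCUPIED_FOLD


@dataclass
class FunnelReport:
    counts: dict[str, int | None]
    events: list[NestingEvent]
    confirm_report: dict = field(default_factory=dict)
    stages_skipped: list[str] = field(default_factory=list)

    def to_table(self):
        import pandas as pd

        rows = []
        for ev in self.events:
            rb = ev.roadblock
            rows.append({
                "peak": ev.pol3_unit.name or
                        f"{ev.pol3_unit.contig}:{ev.pol3_unit.start}-{ev.pol3_unit.end}",
                "contig": ev.pol3_unit.contig,
                "start": ev.pol3_unit.start,
                "end": ev.pol3_unit.end,
                "peak_strand": ev.pol3_unit.strand,
                "host_gene": ev.host_gene.gene_id,
                "host_strand": ev.host_gene.strand,
                "orientation": ev.orientation,
                "distance_to_host_tss": ev.distance_to_host_tss,
                "cross_confirmed": ev.cross_confirmed,
                "fold": rb.fold if rb else float("nan"),
                "p_value": rb.p_value if rb else float("nan"),
                "q_value": rb.q_value if rb else float("nan"),
                "classification": rb.classification if rb else "not_tested",
            })
        return pd.DataFrame(rows)


def _pol2_occupied_genes(pol2: CoverageTrack, genes: list[GeneModel],
                         fold: float) -> set[str]:
    """Genes whose body signal is >= fold over the intergenic median."""
    bs = pol2.bin_size
    intergenic = []
    for contig in sorted(pol2.bins):
        mask = np.ones(len(pol2.bins[contig]), dtype=bool)
        for g in genes:
            if g.contig == contig:
                mask[g.start // bs:-(-g.end // bs)] = False
        intergenic.append(pol2.bins[contig][mask])
    intergenic = np.concatenate(intergenic) if intergenic else np.array([])
    genome_bg = float(np.median(intergenic)) if intergenic.size else 0.0
    if genome_bg <= 0:
        genome_bg = pol2.total_mass / sum(
            len(a) * bs for a in pol2.bins.values())
    occupied = set()
    for g in genes:
        body = pol2.interval_mean(g.contig, g.start, g.end)
        if genome_bg > 0 and body / genome_bg >= fold:
            occupied.add(g.gene_id)
    return occupied


def run_funnel(
    pol3_peaks: list[Interval],
    genes: list[GeneModel],
    ip: CoverageTrack,
    input_: CoverageTrack,
    pol2: CoverageTrack | None = None,
    second_peakset: list[Interval] | None = None,
    nelf: CoverageTrack | None = None,
    dsif: CoverageTrack | None = None,
    config: FunnelConfig | None = None,
) -> FunnelReport:
    """Run the full detection funnel: confirm peaks on weighted tracks, find
    those nested in genes, cross-confirm against a second dataset, test for
    Pol II accumulation, and classify with NELF/DSIF.

    Stage counts are non-increasing; absent optional inputs skip their stage
    and are recorded as skipped.
    """
    cfg = config or FunnelConfig()
    counts: dict[str, int | None] = {"input_peaks": len(pol3_peaks)}
    skipped: list[str] = []

    confirmed, confirm_report = confirm_peaks(
        pol3_peaks, ip, input_, cfg.confirm_threshold, cfg.pseudocount)
    counts["confirmed"] = len(confirmed)

    events = find_nested(confirmed, genes, cfg.promoter_exclusion)
    counts["nested"] = len(events)

    if second_peakset is not None:
        cross_confirm(events, second_peakset, cfg.max_summit_distance)
        counts["cross_confirmed"] = sum(bool(ev.cross_confirmed) for ev in events)
    else:
        skipped.append("cross_confirm")
        counts["cross_confirmed"] = None

    counts["host_genes"] = len({ev.host_gene.gene_id for ev in events})

    if pol2 is not None:
        for ev in events:
            call = detect_roadblock(pol2, ev, cfg.window, cfg.background_exclusion)
            ev.roadblock = call
        adjust_q_values(events)
        for ev in events:
            classify_accumulation(ev.roadblock, ev, nelf, dsif,
                                  cfg.nelf_enrich_threshold)
        if nelf is None:
            skipped.append("classify_accumulation")
        counts["roadblocks"] = sum(
            ev.roadblock.q_value < cfg.alpha
            and ev.roadblock.classification != "putative_internal_TSS"
            for ev in events if ev.roadblock is not None
        )
        occupied = _pol2_occupied_genes(pol2, [ev.host_gene for ev in events],
                                        cfg.pol2_occupied_fold)
        counts["pol2_occupied_host_genes"] = len(
            {ev.host_gene.gene_id for ev in events} & occupied)
    else:
        skipped.extend(["detect_roadblock", "classify_accumulation"])
        counts["roadblocks"] = None
        counts["pol2_occupied_host_genes"] = None

    return FunnelReport(counts=counts, events=events,
                        confirm_report=confirm_report, stages_skipped=skipped)
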