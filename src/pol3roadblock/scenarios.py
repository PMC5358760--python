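"""Canonical synthetic validation scenarios.

These fix, in one place, the study conditions under which the pipeline is
validated: genome sizes, repeat-family geometry, planted IP enrichment
(8-fold, the strong occupancy typical of a bona fide Pol III unit over
input), Pol II gene models (body level 10x intergenic background, 5-fold
promoter-proximal pausing peak), roadblock pileups (3-fold over body, 200 bp
wide) and sequencing depth (1e5 single-end 36-bp tags per track). Tests and
the reproduction script both consume these so that every measurement refers
to the same planted truth.
"""
from __future__ import annotations

from .core import GeneModel
from .synthio import (GenomeSpec, PlantedPol3Unit, PlantedRoadblock,
                      RepeatFamily)

TAG_LENGTH = 36
DEPTH = 100_000
BIN_SIZE = 10

BODY_LEVEL = 10.0
TSS_PEAK_FOLD = 5.0
IP_FOLD = 8.0
ROADBLOCK_FOLD = 3.0
ROADBLOCK_WIDTH = 200
DECOY_NELF_FOLD = 4.0

UNIT_LENGTH = 260  # a MIR-sized Pol III unit


def repeat_family_spec(seed: int = 0, copy_number: int = 3,
                       divergence: float = 0.0) -> GenomeSpec:
    """A 100 kb contig carrying near-identical copies of a 260 bp element,
    each planted as an 8-fold Pol III-occupied locus (so the IP track is the
    realistic, enriched case in which multi-mapping matters)."""
    length = 100_000
    gap = length // (copy_number + 1)
    positions = [("chr1", gap * (i + 1)) for i in range(copy_number)]
    strands = ["+" if i % 2 == 0 else "-" for i in range(copy_number)]
    consensus = _element_consensus()
    units = [PlantedPol3Unit("chr1", s, s + UNIT_LENGTH, strands[i], IP_FOLD)
             for i, (_, s) in enumerate(positions)]
    fam = RepeatFamily("MIR", consensus, copy_number, divergence,
                       strands=strands, positions=positions)
    return GenomeSpec(contigs=[("chr1", length)], repeat_families=[fam],
                      planted_pol3_units=units, seed=seed)


def occupancy_fold_spec(folds=(1.0, 2.0, 4.0, 8.0), seed: int = 0) -> GenomeSpec:
    """Unrelated loci planted at a ladder of IP folds on a 100 kb contig."""
    length = 100_000
    gap = length // (len(folds) + 1)
    units = [PlantedPol3Unit("chr1", gap * (i + 1), gap * (i + 1) + UNIT_LENGTH,
                             "+", fold)
             for i, fold in enumerate(folds)]
    return GenomeSpec(contigs=[("chr1", length)], planted_pol3_units=units,
                      seed=seed)


def funnel_spec(n_genes: int = 10, with_roadblocks: bool = True,
                decoy_idx: tuple[int, ...] = (), seed: int = 0) -> GenomeSpec:
    """``n_genes`` Pol II genes, each hosting one mid-gene Pol III unit with
    mixed sense/antisense orientation; optional 3-fold Pol II pileups at the
    TSS-facing unit boundary, with NELF co-enrichment at ``decoy_idx`` events
    (turning them into decoy internal TSSs)."""
    gene_len, pitch, margin = 8_000, 12_000, 6_000
    length = margin + n_genes * pitch + margin
    genes, units, roadblocks = [], [], []
    for i in range(n_genes):
        gstart = margin + i * pitch
        gstrand = "+" if i % 2 == 0 else "-"
        genes.append(GeneModel(f"gene_{i:02d}", "chr1", gstart, gstart + gene_len,
                               gstrand, tss_peak_fold=TSS_PEAK_FOLD,
                               body_level=BODY_LEVEL))
        ustart = gstart + gene_len // 2
        ustrand = "+" if i % 4 < 2 else "-"
        units.append(PlantedPol3Unit("chr1", ustart, ustart + UNIT_LENGTH,
                                     ustrand, IP_FOLD))
        if with_roadblocks:
            roadblocks.append(PlantedRoadblock(
                "chr1", ustart, ustart + UNIT_LENGTH,
                pol2_fold=ROADBLOCK_FOLD, width=ROADBLOCK_WIDTH,
                nelf_fold=DECOY_NELF_FOLD if i in decoy_idx else 1.0))
    return GenomeSpec(contigs=[("chr1", length)], genes=genes,
                      planted_pol3_units=units,
                      planted_roadblocks=roadblocks, seed=seed)


def calibration_spec(n_genes: int = 200, seed: int = 0) -> GenomeSpec:
    """Many genes with nested units but no planted pileups — the null for
    the roadblock test's false-positive calibration."""
    gene_len, pitch, margin = 3_000, 4_500, 1_000
    length = margin + n_genes * pitch + margin
    genes, units = [], []
    for i in range(n_genes):
        gstart = margin + i * pitch
        genes.append(GeneModel(f"null_{i:03d}", "chr1", gstart, gstart + gene_len,
                               "+" if i % 2 == 0 else "-",
                               tss_peak_fold=TSS_PEAK_FOLD, body_level=BODY_LEVEL))
        ustart = gstart + gene_len // 2
        units.append(PlantedPol3Unit("chr1", ustart, ustart + UNIT_LENGTH,
                                     "+" if i % 4 < 2 else "-", IP_FOLD))
    return GenomeSpec(contigs=[("chr1", length)], genes=genes,
                      planted_pol3_units=units, seed=seed)


def polr3e_like_spec(seed: int = 0) -> GenomeSpec:
    """The archetypal configuration: a host gene with an antisense MIR in its
    first intron and a tRNA gene just upstream of the TSS (which must never
    be called nested)."""
    gene = GeneModel("host", "chr1", 10_000, 30_000, "+",
                     exons=[(10_000, 10_300), (14_000, 14_500), (29_000, 30_000)],
                     tss_peak_fold=TSS_PEAK_FOLD, body_level=BODY_LEVEL)
    mir = PlantedPol3Unit("chr1", 12_000, 12_000 + UNIT_LENGTH, "-", IP_FOLD)
    trna = PlantedPol3Unit("chr1", 9_400, 9_480, "+", IP_FOLD)
    rb = PlantedRoadblock("chr1", 12_000, 12_000 + UNIT_LENGTH,
                          pol2_fold=ROADBLOCK_FOLD, width=ROADBLOCK_WIDTH)
    return GenomeSpec(contigs=[("chr1", 40_000)], genes=[gene],
                      planted_pol3_units=[mir, trna],
                      planted_roadblocks=[rb], seed=seed)


def _element_consensus(length: int = UNIT_LENGTH) -> str:
    """A fixed, non-degenerate 260 bp element consensus (deterministic,
    independent of any RNG so scenario geometry never shifts)."""
    import numpy as np

    rng = np.random.default_rng(2718281828)
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])
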