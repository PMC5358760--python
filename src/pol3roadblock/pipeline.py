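"""End-to-end orchestration: synthesis (or real inputs) -> weighted coverage
-> occupancy confirmation -> nesting/roadblock funnel, from one YAML config.

Every stage's artifacts are persisted under the output directory, every seed
and parameter is echoed into a machine-readable run report, and a fixed seed
reproduces all stochastic stages bit-exactly.
"""
from __future__ import annotations

import logging
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, model_validator

from . import io as pio
from . import synthio
from .core import GeneModel, Interval
from .nesting import FunnelConfig, run_funnel
from .tagweight import assign_weights, build_coverage

log = logging.getLogger(__name__)

__version__ = "0.1.0"


class SyntheticSpec(BaseModel):
    contigs: list[tuple[str, int]]
    repeat_families: list[dict] = Field(default_factory=list)
    genes: list[dict] = Field(default_factory=list)
    pol3_units: list[dict] = Field(default_factory=list)
    roadblocks: list[dict] = Field(default_factory=list)

    def to_genome_spec(self, seed: int) -> synthio.GenomeSpec:
        return synthio.GenomeSpec(
            contigs=[tuple(c) for c in self.contigs],
            repeat_families=[synthio.RepeatFamily(**d) for d in self.repeat_families],
            genes=[GeneModel(**d) for d in self.genes],
            planted_pol3_units=[synthio.PlantedPol3Unit(**d) for d in self.pol3_units],
            planted_roadblocks=[synthio.PlantedRoadblock(**d) for d in self.roadblocks],
            seed=seed,
        )


class InputPaths(BaseModel):
    pol3_peaks_bed: str
    genes_gff3: str
    ip_bedgraph: str
    input_bedgraph: str
    pol2_bedgraph: str | None = None
    nelf_bedgraph: str | None = None
    dsif_bedgraph: str | None = None
    second_peaks_bed: str | None = None


class RunConfig(BaseModel):
    outdir: str
    seed: int = 0
    depth: int = 100_000
    tag_length: int = 36
    bin_size: int = 10
    scheme: str = "uniform"
    tracks: list[str] = Field(
        default_factory=lambda: ["pol3_ip", "input", "pol2", "nelf", "dsif"])
    synthetic: SyntheticSpec | None = None
    inputs: InputPaths | None = None
    funnel: dict = Field(default_factory=dict)
    use_planted_units_as_second_peakset: bool = True

    @model_validator(mode="after")
    def _one_mode(self):
        if (self.synthetic is None) == (self.inputs is None):
            raise ValueError("config must give exactly one of 'synthetic' or 'inputs'")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


class RunReport(BaseModel):
    version: str
    seed: int
    track_seeds: dict[str, int] = Field(default_factory=dict)
    parameters: dict
    stage_counts: dict[str, int | None]
    stages_skipped: list[str]
    artifacts: dict[str, str]


def _track_seed(seed: int, kind: str) -> int:
    offset = {"pol3_ip": 1, "input": 2, "pol2": 3, "nelf": 4, "dsif": 5}[kind]
    return (seed * 1_000_003 + offset) % (2**31 - 1)


def run(config: RunConfig) -> RunReport:
    """Execute the configured stages in order and write the run report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    track_seeds: dict[str, int] = {}

    if config.inputs is not None:
        missing = [p for p in config.inputs.model_dump().values()
                   if p is not None and not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing input file(s): {missing}")

    if config.synthetic is not None:
        genome = synthio.generate_genome(config.synthetic.to_genome_spec(config.seed))
        pio.write_fasta(genome.sequences, outdir / "genome.fa")
        pio.write_gff3(genome.genes, outdir / "genes.gff3")
        pio.write_bed6(genome.repeats, outdir / "repeats.bed")
        pio.write_json(genome.manifest(), outdir / "manifest.json")
        artifacts.update(genome="genome.fa", genes="genes.gff3",
                         repeats="repeats.bed", manifest="manifest.json")

        tracks = {}
        for kind in config.tracks:
            ts = _track_seed(config.seed, kind)
            track_seeds[kind] = ts
            tags = synthio.simulate_chip_tags(
                genome, kind, config.depth, config.tag_length, seed=ts)
            pio.write_tags(tags, outdir / f"{kind}.tags.tsv")
            placements = assign_weights(tags, config.scheme)
            track = build_coverage(placements, config.bin_size,
                                   genome.contig_lengths())
            pio.write_bedgraph(track, outdir / f"{kind}.bedGraph", name=kind)
            tracks[kind] = track
            artifacts[f"{kind}_tags"] = f"{kind}.tags.tsv"
            artifacts[f"{kind}_track"] = f"{kind}.bedGraph"

        peaks = [Interval(u.contig, u.start, u.end, u.strand, f"peak_{i}")
                 for i, u in enumerate(genome.pol3_units)]
        second = peaks if config.use_planted_units_as_second_peakset else None
        genes = genome.genes
        ip, inp = tracks["pol3_ip"], tracks["input"]
        pol2 = tracks.get("pol2")
        nelf = tracks.get("nelf")
        dsif = tracks.get("dsif")
    else:
        paths = config.inputs
        peaks = pio.read_bed6(paths.pol3_peaks_bed)
        genes = pio.read_gff3_genes(paths.genes_gff3)
        ip = pio.read_bedgraph(paths.ip_bedgraph)
        inp = pio.read_bedgraph(paths.input_bedgraph)
        pol2 = pio.read_bedgraph(paths.pol2_bedgraph) if paths.pol2_bedgraph else None
        nelf = pio.read_bedgraph(paths.nelf_bedgraph) if paths.nelf_bedgraph else None
        dsif = pio.read_bedgraph(paths.dsif_bedgraph) if paths.dsif_bedgraph else None
        second = pio.read_bed6(paths.second_peaks_bed) if paths.second_peaks_bed else None

    fcfg = FunnelConfig(**config.funnel)
    report = run_funnel(peaks, genes, ip, inp, pol2=pol2, second_peakset=second,
                        nelf=nelf, dsif=dsif, config=fcfg)

    table = report.to_table()
    table.to_csv(outdir / "events.tsv", sep="\t", index=False)
    artifacts["events"] = "events.tsv"
    windows = [ev.roadblock.window for ev in report.events
               if ev.roadblock is not None and not ev.roadblock.flag]
    pio.write_bed6(windows, outdir / "roadblock_windows.bed")
    artifacts["roadblock_windows"] = "roadblock_windows.bed"

    run_report = RunReport(
        version=__version__,
        seed=config.seed,
        track_seeds=track_seeds,
        parameters={**config.model_dump(exclude={"synthetic", "inputs"}),
                    "funnel_resolved": vars(fcfg)},
        stage_counts=report.counts,
        stages_skipped=report.stages_skipped,
        artifacts=artifacts,
    )
    pio.write_json(run_report.model_dump(), outdir / "run_report.json")
    return run_report


def report_schema() -> dict:
    """JSON schema of the run report (also shipped as package data)."""
    return RunReport.model_json_schema()
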