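"""Synthetic genomes, annotations and ChIP tag sets with planted ground truth.

The generator emulates the data situation around Pol III-occupied repeats
nested in Pol II genes: a background genome carrying near-identical repeat
copies (so multi-mapping is real), Pol II gene models with promoter-proximal
pausing peaks, planted Pol III-occupied loci with a chosen IP/input fold,
intragenic Pol II pileups placed at the Pol III unit boundary that a
polymerase travelling in the host gene's direction meets first, and NELF /
DSIF tracks that distinguish a true elongation roadblock (DSIF without NELF)
from a cryptic internal TSS (NELF present).

Every planted feature is recorded in a ground-truth manifest so downstream
detection can be scored exactly. Tag "mapping" is exact-string matching by
construction (substitution-only repeat divergence, no indels), so a tag's
match list is the complete set of genomic positions whose sequence equals it.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import GeneModel, Interval, revcomp
from .tagweight import Match, TagAlignment

BASES = np.frombuffer(b"ACGT", dtype="S1")

TSS_PEAK_WIDTH = 200   # bp of promoter-proximal pausing signal
DEFAULT_TAG_LENGTH = 36
TRACK_KINDS = ("pol3_ip", "input", "pol2", "nelf", "dsif")


@dataclass
class RepeatFamily:
    """A family of near-identical copies of one consensus.

    ``divergence`` is the per-base substitution probability applied
    independently to every copy (no indels, so exact-string mapping stays
    well defined). Copies are placed at ``positions`` when given, otherwise
    at random non-overlapping locations.
    """

    name: str
    consensus: str
    copy_number: int
    divergence: float = 0.0
    strands: list[str] | None = None
    positions: list[tuple[str, int]] | None = None  # (contig, start)

    def __post_init__(self):
        if self.copy_number < 1:
            raise ValueError(f"family {self.name}: copy_number must be >= 1")
        if not 0.0 <= self.divergence <= 1.0:
            raise ValueError(f"family {self.name}: divergence must lie in [0, 1]")
        if not self.consensus:
            raise ValueError(f"family {self.name}: empty consensus")


@dataclass
class PlantedPol3Unit:
    """A locus to be enriched in the Pol III IP track at ``ip_fold``."""

    contig: str
    start: int
    end: int
    strand: str
    ip_fold: float = 8.0

    def __post_init__(self):
        if self.ip_fold < 1:
            raise ValueError("ip_fold must be >= 1")

    @property
    def interval(self) -> Interval:
        return Interval(self.contig, self.start, self.end, self.strand)


@dataclass
class PlantedRoadblock:
    """A Pol II pileup tied to a planted Pol III unit nested in a gene.

    The pileup of ``width`` bp is centred on the unit boundary first met by
    a polymerase travelling in the host gene's direction, at ``pol2_fold``
    times the gene-body level. ``nelf_fold`` > 1 additionally plants NELF
    there, turning the site into a decoy internal TSS rather than a
    roadblock.
    """

    contig: str
    unit_start: int
    unit_end: int
    pol2_fold: float = 3.0
    width: int = 200
    nelf_fold: float = 1.0

    def __post_init__(self):
        if self.pol2_fold < 1 or self.nelf_fold < 1:
            raise ValueError("folds must be >= 1")
        if self.width < 1:
            raise ValueError("width must be >= 1")


@dataclass
class GenomeSpec:
    contigs: list[tuple[str, int]]
    repeat_families: list[RepeatFamily] = field(default_factory=list)
    genes: list[GeneModel] = field(default_factory=list)
    planted_pol3_units: list[PlantedPol3Unit] = field(default_factory=list)
    planted_roadblocks: list[PlantedRoadblock] = field(default_factory=list)
    seed: int = 0


@dataclass
class ResolvedRoadblock:
    planted: PlantedRoadblock
    host_gene: GeneModel
    window_start: int
    window_end: int


@dataclass
class Genome:
    """Generated sequences plus the resolved annotation / ground truth."""

    sequences: dict[str, str]
    genes: list[GeneModel]
    repeats: list[Interval]            # name = family, one per copy
    repeat_mutations: list[int]        # substitutions applied per copy
    pol3_units: list[PlantedPol3Unit]
    roadblocks: list[ResolvedRoadblock]
    seed: int
    _kmer_cache: dict = field(default_factory=dict, repr=False)

    def contig_lengths(self) -> dict[str, int]:
        return {name: len(s) for name, s in self.sequences.items()}

    def kmer_index(self, k: int) -> dict[str, list[tuple[str, int]]]:
        """Forward-strand index of every k-mer to all its genomic starts."""
        if k not in self._kmer_cache:
            index: dict[str, list[tuple[str, int]]] = {}
            for contig, seq in self.sequences.items():
                for i in range(len(seq) - k + 1):
                    index.setdefault(seq[i:i + k], []).append((contig, i))
            self._kmer_cache[k] = index
        return self._kmer_cache[k]

    def manifest(self) -> dict:
        return {
            "seed": self.seed,
            "contigs": {c: len(s) for c, s in self.sequences.items()},
            "genes": [
                {"gene_id": g.gene_id, "contig": g.contig, "start": g.start,
                 "end": g.end, "strand": g.strand, "tss": g.tss, "tes": g.tes,
                 "tss_peak_fold": g.tss_peak_fold, "body_level": g.body_level,
                 "exons": [list(e) for e in g.exons]}
                for g in self.genes
            ],
            "repeats": [
                {"family": r.name, "contig": r.contig, "start": r.start,
                 "end": r.end, "strand": r.strand, "n_mutations": n}
                for r, n in zip(self.repeats, self.repeat_mutations)
            ],
            "pol3_units": [
                {"contig": u.contig, "start": u.start, "end": u.end,
                 "strand": u.strand, "ip_fold": u.ip_fold,
                 "host_gene": (h.gene_id if (h := self._host_gene(u)) else None),
                 "orientation": (("sense" if h.strand == u.strand else "antisense")
                                 if h else None)}
                for u in self.pol3_units
            ],
            "roadblocks": [
                {"contig": rb.planted.contig,
                 "unit_start": rb.planted.unit_start,
                 "unit_end": rb.planted.unit_end,
                 "pol2_fold": rb.planted.pol2_fold,
                 "nelf_fold": rb.planted.nelf_fold,
                 "width": rb.planted.width,
                 "host_gene": rb.host_gene.gene_id,
                 "window_start": rb.window_start,
                 "window_end": rb.window_end,
                 "is_decoy_tss": rb.planted.nelf_fold > 1}
                for rb in self.roadblocks
            ],
        }

    def _host_gene(self, unit: PlantedPol3Unit) -> GeneModel | None:
        for g in self.genes:
            if g.interval.contains(unit.interval):
                return g
        return None


def _mutate(rng: np.random.Generator, seq_arr: np.ndarray, divergence: float,
            protected: np.ndarray | None = None) -> tuple[np.ndarray, int]:
    """Substitution-only mutation; each hit base moves to one of the 3 others."""
    out = seq_arr.copy()
    hit = rng.random(len(seq_arr)) < divergence
    if protected is not None:
        hit &= ~protected
    idx = np.flatnonzero(hit)
    if idx.size:
        base_idx = np.searchsorted(BASES, out[idx])
        shift = rng.integers(1, 4, size=idx.size)
        out[idx] = BASES[(base_idx + shift) % 4]
    return out, int(idx.size)


def _seq_to_arr(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode(), dtype="S1").copy()


def _arr_to_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode()


def generate_genome(spec: GenomeSpec) -> Genome:
    """Build contig sequences with repeat copies inserted in place, and the
    resolved annotation of every planted feature.

    Raises ``ValueError`` on planted features that overlap on the same strand
    or fall outside their contig.
    """
    rng = np.random.default_rng(spec.seed)
    lengths = dict(spec.contigs)

    for g in spec.genes:
        if g.contig not in lengths or g.end > lengths[g.contig]:
            raise ValueError(f"gene {g.gene_id} outside contig bounds")
    for u in spec.planted_pol3_units:
        if u.contig not in lengths or u.end > lengths[u.contig]:
            raise ValueError(f"pol3 unit {u.contig}:{u.start}-{u.end} outside contig bounds")

    seqs = {name: rng.choice(BASES, size=length)
            for name, length in spec.contigs}

    repeats: list[Interval] = []
    repeat_mutations: list[int] = []
    for fam in spec.repeat_families:
        cons = _seq_to_arr(fam.consensus)
        L = len(cons)
        placements: list[tuple[str, int, str]] = []
        for i in range(fam.copy_number):
            strand = (fam.strands[i % len(fam.strands)] if fam.strands
                      else ("+" if rng.random() < 0.5 else "-"))
            if fam.positions is not None:
                contig, start = fam.positions[i]
            else:
                contig, start = _random_placement(rng, lengths, L, repeats, placements)
            if start < 0 or start + L > lengths[contig]:
                raise ValueError(f"repeat copy of {fam.name} outside contig {contig}")
            placements.append((contig, start, strand))
        for contig, start, strand in placements:
            mutated, n_mut = _mutate(rng, cons, fam.divergence)
            copy_seq = mutated if strand == "+" else _seq_to_arr(revcomp(_arr_to_seq(mutated)))
            seqs[contig][start:start + L] = copy_seq
            repeats.append(Interval(contig, start, start + L, strand, fam.name))
            repeat_mutations.append(n_mut)

    _check_same_strand_overlaps(
        [(r, "repeat") for r in repeats]
        + [(u.interval, "pol3_unit") for u in spec.planted_pol3_units]
    )

    genome = Genome(
        sequences={c: _arr_to_seq(a) for c, a in seqs.items()},
        genes=list(spec.genes),
        repeats=repeats,
        repeat_mutations=repeat_mutations,
        pol3_units=list(spec.planted_pol3_units),
        roadblocks=[],
        seed=spec.seed,
    )
    genome.roadblocks = [_resolve_roadblock(rb, spec.genes) for rb in spec.planted_roadblocks]
    return genome


def _random_placement(rng, lengths, L, existing, placements):
    taken = [(r.contig, r.start, r.end) for r in existing]
    taken += [(c, s, s + L) for c, s, _ in placements]
    contigs = sorted(lengths)
    for _ in range(1000):
        contig = contigs[int(rng.integers(len(contigs)))]
        if lengths[contig] < L:
            continue
        start = int(rng.integers(0, lengths[contig] - L + 1))
        if all(not (c == contig and start < e and s < start + L) for c, s, e in taken):
            return contig, start
    raise ValueError("could not place repeat copy without overlap after 1000 draws")


def _check_same_strand_overlaps(features: list[tuple[Interval, str]]) -> None:
    for i, (a, ka) in enumerate(features):
        for b, kb in features[i + 1:]:
            if a.strand == b.strand and a.overlaps(b) and (a.start, a.end) != (b.start, b.end):
                raise ValueError(
                    f"planted {ka} {a.contig}:{a.start}-{a.end}({a.strand}) overlaps "
                    f"{kb} {b.contig}:{b.start}-{b.end}({b.strand}) on the same strand"
                )


def _resolve_roadblock(rb: PlantedRoadblock, genes: list[GeneModel]) -> ResolvedRoadblock:
    unit = Interval(rb.contig, rb.unit_start, rb.unit_end)
    host = next((g for g in genes if g.interval.contains(unit)), None)
    if host is None:
        raise ValueError(
            f"planted roadblock at {rb.contig}:{rb.unit_start}-{rb.unit_end} "
            "is not nested in any gene"
        )
    # boundary first met by a polymerase travelling in the host's direction
    boundary = rb.unit_start if host.strand == "+" else rb.unit_end
    w0 = boundary - rb.width // 2
    w1 = w0 + rb.width
    return ResolvedRoadblock(planted=rb, host_gene=host, window_start=w0, window_end=w1)


# ------------------------------------------------------------- tag sampling

def _position_weights(genome: Genome, track_kind: str, tag_length: int) -> dict[str, np.ndarray]:
    """Per-contig sampling weight for each valid tag start position."""
    weights = {}
    for contig, seq in genome.sequences.items():
        n_valid = len(seq) - tag_length + 1
        if n_valid < 1:
            raise ValueError(f"tag_length {tag_length} exceeds contig {contig}")
        weights[contig] = np.ones(n_valid)

    def span(contig, start, end):
        """Start positions whose tag overlaps [start, end)."""
        n = len(weights[contig])
        return slice(max(0, start - tag_length + 1), min(n, max(0, end)))

    if track_kind == "pol3_ip":
        for u in genome.pol3_units:
            weights[u.contig][span(u.contig, u.start, u.end)] *= u.ip_fold
    elif track_kind in ("pol2", "nelf", "dsif"):
        for g in genome.genes:
            if track_kind == "pol2":
                w = weights[g.contig][span(g.contig, g.start, g.end)]
                np.maximum(w, g.body_level, out=w)
            t0, t1 = (g.tss, g.tss + TSS_PEAK_WIDTH) if g.strand == "+" else \
                     (g.tss - TSS_PEAK_WIDTH, g.tss)
            level = g.body_level if track_kind == "pol2" else 1.0
            weights[g.contig][span(g.contig, t0, t1)] += level * (g.tss_peak_fold - 1)
        for rb in genome.roadblocks:
            contig = rb.planted.contig
            sl = span(contig, rb.window_start, rb.window_end)
            if track_kind == "pol2":
                weights[contig][sl] += rb.host_gene.body_level * (rb.planted.pol2_fold - 1)
            elif track_kind == "dsif":
                weights[contig][sl] += rb.planted.pol2_fold - 1
            elif track_kind == "nelf" and rb.planted.nelf_fold > 1:
                weights[contig][sl] += rb.planted.nelf_fold - 1
    elif track_kind != "input":
        raise ValueError(f"unknown track kind {track_kind!r}; expected one of {TRACK_KINDS}")
    return weights


def simulate_chip_tags(
    genome: Genome,
    track_kind: str,
    depth: int,
    tag_length: int = DEFAULT_TAG_LENGTH,
    seed: int = 0,
) -> list[TagAlignment]:
    """Sample ``depth`` single-end tags for one track and map each back to
    every exactly matching genomic position.

    Identical tag sequences are collapsed into one :class:`TagAlignment`
    with multiplicity ``c`` equal to the number of times sampled, so the sum
    of ``c`` over the returned tags equals ``depth``.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    weights = _position_weights(genome, track_kind, tag_length)

    contigs = sorted(weights)
    sizes = np.array([len(weights[c]) for c in contigs])
    flat = np.concatenate([weights[c] for c in contigs])
    p = flat / flat.sum()
    draws = rng.choice(len(flat), size=depth, p=p)
    strands = rng.random(depth) < 0.5  # True -> '-'

    offsets = np.concatenate([[0], np.cumsum(sizes)])
    index = genome.kmer_index(tag_length)

    counts: dict[str, int] = {}
    for d, minus in zip(draws, strands):
        ci = int(np.searchsorted(offsets, d, side="right")) - 1
        contig = contigs[ci]
        start = int(d - offsets[ci])
        fwd = genome.sequences[contig][start:start + tag_length]
        readseq = revcomp(fwd) if minus else fwd
        counts[readseq] = counts.get(readseq, 0) + 1

    tags = []
    for i, (readseq, c) in enumerate(sorted(counts.items())):
        plus = [(ctg, s, "+") for ctg, s in index.get(readseq, [])]
        rc = revcomp(readseq)
        minus = [(ctg, s, "-") for ctg, s in index.get(rc, [])] if rc != readseq else []
        matches = [Match(ctg, s, s + tag_length, strand)
                   for ctg, s, strand in sorted(plus + minus)]
        tags.append(TagAlignment(f"{track_kind}_{i:07d}", c, matches, seq=readseq))
    return tags


def simulate_element_family(
    consensus: str,
    n: int,
    divergence: float,
    plant_boxes: tuple[str, int, str] | None = None,
    seed: int = 0,
    box_offset: int = 10,
) -> dict[str, str]:
    """Generate ``n`` diverged copies of a consensus element.

    ``plant_boxes = (a_box_seq, spacer_bp, b_box_seq)`` writes an internal
    type-2 promoter into the consensus at ``box_offset`` with the exact
    spacer, and shields the box positions from mutation so every copy keeps
    a scannable promoter.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    cons = _seq_to_arr(consensus)
    protected = np.zeros(len(cons), dtype=bool)
    if plant_boxes is not None:
        a_seq, spacer, b_seq = plant_boxes
        a0 = box_offset
        b0 = a0 + len(a_seq) + spacer
        if b0 + len(b_seq) > len(cons):
            raise ValueError("consensus too short for planted boxes at this spacer")
        cons[a0:a0 + len(a_seq)] = _seq_to_arr(a_seq)
        cons[b0:b0 + len(b_seq)] = _seq_to_arr(b_seq)
        protected[a0:a0 + len(a_seq)] = True
        protected[b0:b0 + len(b_seq)] = True
    out = {}
    for i in range(n):
        mutated, _ = _mutate(rng, cons, divergence, protected)
        out[f"copy_{i:03d}"] = _arr_to_seq(mutated)
    return out
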