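"""Multi-mapping-aware tag weighting and weighted coverage tracks.

ChIP-seq of Pol III-transcribed loci is dominated by repetitive elements
(SINEs, tRNA genes), so a large fraction of sequence tags matches several
genomic locations. Discarding those tags erases the signal at exactly the
loci of interest. Instead, every tag carries its sequencing multiplicity
``c`` (how many times the identical sequence was read) and its match list
of length ``m`` (how many genomic positions it fits exactly), and its total
weight ``c`` is divided over the matches:

* ``uniform`` — each match receives ``c / m``;
* ``em`` — weights start at ``c / m`` and are iteratively redistributed in
  proportion to the local weighted coverage (seeded by uniquely mapping
  tags) in a window around each match, until convergence.

Both schemes conserve weight: per tag the assigned weights sum to ``c``.
"""
from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)

EM_WINDOW = 500  # bp each side of a match used for local coverage
EM_TOL = 1e-6
EM_MAX_ITER = 100


@dataclass(frozen=True)
class Match:
    contig: str
    start: int
    end: int
    strand: str = "+"


@dataclass
class TagAlignment:
    """One distinct tag sequence: multiplicity ``c`` and all exact matches."""

    tag_id: str
    c: int
    matches: list[Match]
    seq: str = ""

    def __post_init__(self):
        if self.c < 1:
            raise ValueError(f"tag {self.tag_id}: multiplicity c must be >= 1")
        if not self.matches:
            raise ValueError(f"tag {self.tag_id}: empty match list")
        lengths = {m.end - m.start for m in self.matches}
        if len(lengths) != 1:
            raise ValueError(f"tag {self.tag_id}: matches of unequal length")

    @property
    def m(self) -> int:
        return len(self.matches)


@dataclass
class Placement:
    """A tag match with its assigned fractional weight."""

    contig: str
    start: int
    end: int
    strand: str
    weight: float
    tag_id: str


@dataclass
class CoverageTrack:
    """Binned, strand-collapsed weighted coverage per contig.

    Bin values are mean per-base weighted coverage over the bin, so a
    placement of weight ``w`` and length ``L`` adds ``w * L / bin_size``
    in total across the bins it overlaps. ``total_weight`` is the sum of
    assigned weights (= sum of multiplicities ``c`` for a full tag set);
    ``read_length`` is the placement length, needed to convert per-base
    mass back to tag counts.
    """

    bins: dict[str, np.ndarray]
    bin_size: int
    total_weight: float
    read_length: float = 1.0

    def contig_length(self, contig: str) -> int:
        return len(self.bins[contig]) * self.bin_size

    @property
    def total_mass(self) -> float:
        """Total per-base signal mass (sum over all bases of coverage)."""
        return sum(float(a.sum()) for a in self.bins.values()) * self.bin_size

    def interval_mass(self, contig: str, start: int, end: int) -> float:
        """Per-base signal mass over [start, end), prorating edge bins."""
        if contig not in self.bins:
            raise KeyError(f"contig {contig!r} not in track")
        arr = self.bins[contig]
        if start < 0 or end > len(arr) * self.bin_size:
            raise ValueError(
                f"interval {contig}:{start}-{end} outside track bounds "
                f"(0-{len(arr) * self.bin_size})"
            )
        b0, b1 = start // self.bin_size, (end - 1) // self.bin_size
        total = 0.0
        for b in range(b0, b1 + 1):
            lo = max(start, b * self.bin_size)
            hi = min(end, (b + 1) * self.bin_size)
            total += float(arr[b]) * (hi - lo)
        return total

    def interval_mean(self, contig: str, start: int, end: int) -> float:
        if end <= start:
            raise ValueError("empty interval")
        return self.interval_mass(contig, start, end) / (end - start)


def _unique_multi_split(tags: list[TagAlignment]):
    unique = [t for t in tags if t.m == 1]
    multi = [t for t in tags if t.m > 1]
    return unique, multi


def assign_weights(
    tags: list[TagAlignment],
    scheme: str = "uniform",
    window: int = EM_WINDOW,
    tol: float = EM_TOL,
    max_iter: int = EM_MAX_ITER,
) -> list[Placement]:
    """Distribute each tag's multiplicity ``c`` over its ``m`` matches.

    Returns one :class:`Placement` per match of every tag. Per-tag weights
    always sum to ``c`` (conservation), for either scheme.
    """
    if not tags:
        raise ValueError("empty tag list")
    if scheme not in ("uniform", "em"):
        raise ValueError(f"unknown scheme {scheme!r}")

    if scheme == "em":
        unique, _ = _unique_multi_split(tags)
        if not unique:
            log.warning("em weighting requested but no uniquely mapping tags; "
                        "falling back to uniform c/m weights")
            scheme = "uniform"

    if scheme == "uniform":
        return [
            Placement(m.contig, m.start, m.end, m.strand, t.c / t.m, t.tag_id)
            for t in tags
            for m in t.matches
        ]
    return _assign_weights_em(tags, window, tol, max_iter)


def _assign_weights_em(tags, window, tol, max_iter):
    # Flat arrays over all placements; multi-mapper weights are the only
    # free parameters, updated from window sums of the full current coverage.
    contigs = sorted({m.contig for t in tags for m in t.matches})
    cidx = {c: i for i, c in enumerate(contigs)}

    tag_of, starts, contig_of, weights = [], [], [], []
    spans = []  # (first placement index, n placements, c) per multi tag
    for ti, t in enumerate(tags):
        if t.m > 1:
            spans.append((len(starts), t.m, t.c))
        for m in t.matches:
            tag_of.append(ti)
            starts.append(m.start)
            contig_of.append(cidx[m.contig])
            weights.append(t.c / t.m)
    starts = np.asarray(starts)
    contig_of = np.asarray(contig_of)
    weights = np.asarray(weights, dtype=float)

    order = np.lexsort((starts, contig_of))
    multi_idx = np.concatenate(
        [np.arange(i0, i0 + m) for i0, m, _ in spans]
    ) if spans else np.array([], dtype=int)

    if multi_idx.size:
        # local coverage: weight of placements starting within +/- window
        # (placements are tag-length, << window, so start-anchoring suffices)
        win_lo = starts[multi_idx] - window
        win_hi = starts[multi_idx] + window + 1
        for _ in range(max_iter):
            s_sorted = starts[order]
            c_sorted = contig_of[order]
            w_sorted = weights[order]
            csum = np.concatenate([[0.0], np.cumsum(w_sorted)])
            # searchsorted restricted to each contig's sorted block
            lo = np.empty(multi_idx.size, dtype=int)
            hi = np.empty(multi_idx.size, dtype=int)
            for ci in range(len(contigs)):
                sel = contig_of[multi_idx] == ci
                if not sel.any():
                    continue
                b0 = np.searchsorted(c_sorted, ci, side="left")
                b1 = np.searchsorted(c_sorted, ci, side="right")
                block = s_sorted[b0:b1]
                lo[sel] = b0 + np.searchsorted(block, win_lo[sel], side="left")
                hi[sel] = b0 + np.searchsorted(block, win_hi[sel], side="left")
            local = csum[hi] - csum[lo]

            new_w = weights.copy()
            delta = 0.0
            for k, (i0, m, c) in enumerate(spans):
                pos = slice(
                    np.searchsorted(multi_idx, i0),
                    np.searchsorted(multi_idx, i0) + m,
                )
                loc = local[pos]
                tot = loc.sum()
                if tot <= 0:
                    w = np.full(m, c / m)
                else:
                    w = c * loc / tot
                delta = max(delta, float(np.abs(w - weights[i0:i0 + m]).max()))
                new_w[i0:i0 + m] = w
            weights = new_w
            if delta < tol:
                break

    placements = []
    k = 0
    for t in tags:
        for m in t.matches:
            placements.append(
                Placement(m.contig, m.start, m.end, m.strand, float(weights[k]), t.tag_id)
            )
            k += 1
    return placements


def build_coverage(
    placements: list[Placement],
    bin_size: int = 10,
    contig_lengths: dict[str, int] | None = None,
) -> CoverageTrack:
    """Accumulate weighted placements into a binned coverage track.

    Each placement adds its weight to every base it covers; a bin stores the
    mean per-base coverage over the bin, so partial overlaps are prorated.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    if contig_lengths is None:
        contig_lengths = defaultdict(int)
        for p in placements:
            contig_lengths[p.contig] = max(contig_lengths[p.contig], p.end)
        contig_lengths = dict(contig_lengths)

    per_base = {c: np.zeros(length + 1) for c, length in contig_lengths.items()}
    total_weight = 0.0
    lengths = []
    for p in placements:
        if p.end > contig_lengths[p.contig]:
            raise ValueError(f"placement {p.contig}:{p.start}-{p.end} exceeds contig")
        arr = per_base[p.contig]
        arr[p.start] += p.weight
        arr[p.end] -= p.weight
        total_weight += p.weight
        lengths.append(p.end - p.start)

    bins = {}
    for contig, length in contig_lengths.items():
        cov = np.cumsum(per_base[contig][:-1])
        n_bins = -(-length // bin_size)
        padded = np.zeros(n_bins * bin_size)
        padded[:length] = cov
        bins[contig] = padded.reshape(n_bins, bin_size).sum(axis=1) / bin_size
    read_length = float(np.mean(lengths)) if lengths else 1.0
    return CoverageTrack(bins=bins, bin_size=bin_size,
                         total_weight=total_weight, read_length=read_length)


def unique_only(tags: list[TagAlignment]) -> list[TagAlignment]:
    """Keep only uniquely mapping tags (m = 1); the naive baseline that
    underestimates coverage of repeat families."""
    return [t for t in tags if t.m == 1]
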