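"""Occupancy scoring of loci as log2(IP/input) with percentage normalization.

The score of a locus is ``S = log2((ip + p) / (inp + p))`` where ``ip`` and
``inp`` are library-size-normalized signal masses over the locus (parts per
million of each track's total mass) and ``p`` is a pseudocount that keeps
depleted or empty loci finite. Scores can be re-expressed as percentages of
a reference locus (floored at 0 for depleted loci), and peak lists can be
re-scored and confirmed against a threshold — the step that separates true
Pol III-occupied loci from multi-mapping artifacts once tags are re-weighted.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .core import Interval
from .tagweight import CoverageTrack

DEFAULT_PSEUDOCOUNT = 1.0
OCCUPIED_THRESHOLD = 1.0  # S >= 1, i.e. at least 2-fold IP over input


@dataclass(frozen=True)
class LocusScore:
    locus: Interval
    class_label: str
    ip_mass: float
    input_mass: float
    S: float
    percent: float = float("nan")


def log2_ratio(ip_mass: float, input_mass: float,
               pseudocount: float = DEFAULT_PSEUDOCOUNT) -> float:
    """S = log2((ip + p) / (inp + p)) on already-normalized masses."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    return math.log2((ip_mass + pseudocount) / (input_mass + pseudocount))


def _ppm_mass(track: CoverageTrack, locus: Interval) -> float:
    """Locus signal mass in parts per million of the track total."""
    total = track.total_mass
    if total <= 0:
        raise ValueError("track has zero total mass")
    return track.interval_mass(locus.contig, locus.start, locus.end) * 1e6 / total


def score_locus(
    ip: CoverageTrack,
    input_: CoverageTrack,
    locus: Interval,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    class_label: str = "other",
) -> LocusScore:
    """log2(IP/input) occupancy score of one locus, per-million normalized."""
    if ip.bin_size != input_.bin_size:
        raise ValueError("IP and input tracks have different bin sizes")
    ip_mass = _ppm_mass(ip, locus)
    input_mass = _ppm_mass(input_, locus)
    s = log2_ratio(ip_mass, input_mass, pseudocount)
    return LocusScore(locus=locus, class_label=class_label,
                      ip_mass=ip_mass, input_mass=input_mass, S=s)


def score_loci(ip, input_, loci, pseudocount=DEFAULT_PSEUDOCOUNT, labels=None):
    labels = labels if labels is not None else ["other"] * len(loci)
    return [score_locus(ip, input_, loc, pseudocount, lab)
            for loc, lab in zip(loci, labels)]


def normalize_percent(scores: list[LocusScore], reference: str = "max") -> list[LocusScore]:
    """Express scores as percentages of a reference locus.

    ``reference`` is a locus name or ``"max"`` (the highest-scoring locus).
    Negative scores floor at 0%; the reference itself is 100% exactly.
    """
    if not scores:
        return []
    if reference == "max":
        s_ref = max(sc.S for sc in scores)
    else:
        try:
            s_ref = next(sc.S for sc in scores if sc.locus.name == reference)
        except StopIteration:
            raise KeyError(f"reference locus {reference!r} not in score list") from None
    if s_ref <= 0:
        raise ValueError("reference score must be positive for percentage normalization")
    return [replace(sc, percent=100.0 * max(sc.S, 0.0) / s_ref) for sc in scores]


def class_mean(
    scores: list[LocusScore],
    class_label: str,
    occupied_threshold: float = OCCUPIED_THRESHOLD,
) -> float:
    """Mean S over occupied loci (S >= threshold) of one class."""
    vals = [sc.S for sc in scores
            if sc.class_label == class_label and sc.S >= occupied_threshold]
    if not vals:
        raise ValueError(f"no occupied loci with class {class_label!r}")
    return sum(vals) / len(vals)


def confirm_peaks(
    peaks: list[Interval],
    ip: CoverageTrack,
    input_: CoverageTrack,
    threshold: float = OCCUPIED_THRESHOLD,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> tuple[list[Interval], dict]:
    """Re-score externally supplied peaks on weighted tracks and keep those
    with S >= threshold. Returns (confirmed peaks, summary report)."""
    scores = [score_locus(ip, input_, pk, pseudocount) for pk in peaks]
    confirmed = [pk for pk, sc in zip(peaks, scores) if sc.S >= threshold]
    report = {
        "n_input": len(peaks),
        "n_confirmed": len(confirmed),
        "threshold": threshold,
        "pseudocount": pseudocount,
        "scores": {pk.name or f"{pk.contig}:{pk.start}-{pk.end}": sc.S
                   for pk, sc in zip(peaks, scores)},
    }
    return confirmed, report
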