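"""Type-2 Pol III internal promoter scanning (A box / B box with a spacer).

tRNA genes and tRNA-derived SINEs such as MIRs carry their promoter inside
the transcribed region: an A box and a downstream B box bound by TFIIIC.
The scanner matches both boxes as IUPAC consensi with a mismatch budget (or
as position weight matrices with a score floor) on both strands, requiring
the B box downstream of the A box on the hit strand, with the intervening
spacer inside a configured range. An element is "potentially functional"
when at least one A/B pair passes.

Defaults are the community-standard type-2 consensi (A box TRGCNNARYNNG,
B box GTTCRANNC, <= 2 mismatches each) and a general spacer range of
20-40 bp; the ``strict-mir`` preset narrows the spacer to the 25-26 bp
spacing characteristic of conserved intronic MIRs.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

from .core import revcomp

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class BoxModel:
    """One promoter box: IUPAC consensus with a mismatch budget, or a PWM
    (rows A, C, G, T; one column per position) with a minimum score."""

    consensus: str | None = None
    max_mismatches: int = 2
    pwm: np.ndarray | None = None
    min_score: float = 0.0

    def __post_init__(self):
        if self.consensus is None and self.pwm is None:
            raise ValueError("box needs a consensus or a PWM")
        if self.consensus is not None and not self.consensus:
            raise ValueError("empty box consensus")
        if self.pwm is not None:
            self.pwm = np.asarray(self.pwm, dtype=float)
            if self.pwm.shape[0] != 4:
                raise ValueError("PWM must have 4 rows (A, C, G, T)")

    def __len__(self) -> int:
        return len(self.consensus) if self.consensus is not None else self.pwm.shape[1]

    def score(self, window: str) -> tuple[bool, float]:
        """(passes, score). Consensus score = mismatch count (lower better);
        PWM score = summed column scores (higher better). N never matches."""
        if self.consensus is not None:
            mm = sum(
                1 for c, s in zip(self.consensus, window)
                if s == "N" or s not in IUPAC[c]
            )
            return mm <= self.max_mismatches, float(mm)
        if "N" in window:
            return False, float("-inf")
        sc = float(sum(self.pwm[BASE_INDEX[s], i] for i, s in enumerate(window)))
        return sc >= self.min_score, sc


@dataclass
class PromoterModel:
    a_box: BoxModel
    b_box: BoxModel
    spacer_range: tuple[int, int] = (20, 40)

    def __post_init__(self):
        lo, hi = self.spacer_range
        if lo > hi or lo < 0:
            raise ValueError(f"invalid spacer range {self.spacer_range}")


@dataclass(frozen=True)
class PromoterHit:
    """An A-box/B-box pair. Coordinates are forward-frame positions on the
    scanned sequence (0-based half-open); on the minus strand the A box
    therefore lies to the right of the B box in forward coordinates, while
    remaining upstream of it on the hit strand."""

    a_start: int
    a_end: int
    b_start: int
    b_end: int
    strand: str
    spacer: int
    a_score: float
    b_score: float


def default_model(preset: str = "default") -> PromoterModel:
    """The shipped type-2 promoter model; ``preset='strict-mir'`` narrows the
    spacer to 25-26 bp."""
    text = resources.files("pol3roadblock.data").joinpath("type2_promoter.yaml").read_text()
    return load_model_dict(yaml.safe_load(text), preset)


def load_model(path: str, preset: str = "default") -> PromoterModel:
    with open(path) as fh:
        return load_model_dict(yaml.safe_load(fh), preset)


def load_model_dict(doc: dict, preset: str = "default") -> PromoterModel:
    def box(d):
        return BoxModel(
            consensus=d.get("consensus"),
            max_mismatches=int(d.get("max_mismatches", 2)),
            pwm=d.get("pwm"),
            min_score=float(d.get("min_score", 0.0)),
        )

    spacer = doc.get("spacer_range", [20, 40])
    if preset != "default":
        presets = doc.get("presets", {})
        if preset not in presets:
            raise KeyError(f"unknown preset {preset!r}; available: {sorted(presets)}")
        spacer = presets[preset].get("spacer_range", spacer)
    return PromoterModel(box(doc["a_box"]), box(doc["b_box"]),
                         tuple(int(x) for x in spacer))


def _box_hits(seq: str, box: BoxModel) -> list[tuple[int, float]]:
    k = len(box)
    out = []
    for i in range(len(seq) - k + 1):
        ok, sc = box.score(seq[i:i + k])
        if ok:
            out.append((i, sc))
    return out


def scan(sequence: str, model: PromoterModel | None = None) -> list[PromoterHit]:
    """All A/B box pairs on both strands meeting box thresholds and the
    spacer constraint (B box downstream of the A box on the hit strand).

    The spacer is the gap between the A box end and the B box start,
    0-based half-open; overlapping boxes never pair. A sequence too short to
    host a pair yields an empty list.
    """
    model = model or default_model()
    sequence = sequence.upper()
    bad = set(sequence) - set("ACGTN")
    if bad:
        raise ValueError(f"sequence contains non-ACGTN characters: {sorted(bad)}")
    lo, hi = model.spacer_range
    L = len(sequence)
    hits = []
    for strand in "+-":
        seq = sequence if strand == "+" else revcomp(sequence)
        a_hits = _box_hits(seq, model.a_box)
        b_hits = _box_hits(seq, model.b_box)
        for a0, a_sc in a_hits:
            a1 = a0 + len(model.a_box)
            for b0, b_sc in b_hits:
                spacer = b0 - a1
                if spacer < lo or spacer > hi:
                    continue
                b1 = b0 + len(model.b_box)
                if strand == "+":
                    hits.append(PromoterHit(a0, a1, b0, b1, "+", spacer, a_sc, b_sc))
                else:
                    hits.append(PromoterHit(L - a1, L - a0, L - b1, L - b0,
                                            "-", spacer, a_sc, b_sc))
    return hits


def classify_functional(hits: list[PromoterHit]) -> bool:
    """True iff at least one A/B pair passed both boxes and the spacer."""
    return len(hits) > 0


def scan_elements(elements: dict[str, str],
                  model: PromoterModel | None = None) -> dict[str, dict]:
    """Scan a set of element sequences; per element, hits plus the
    potentially-functional call."""
    model = model or default_model()
    out = {}
    for name, seq in elements.items():
        h = scan(seq, model)
        out[name] = {"hits": h, "functional": classify_functional(h)}
    return out
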