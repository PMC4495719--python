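"""Pairwise pseudo-energy distance constraints and satisfaction statistics.

Each proximity hit becomes a distance constraint between the O2' atom of
the 5' residue (where the radical source would sit) and the C4' atom of
the 3' residue (the cleavage-sensitive sugar position).  The pseudo-energy
potential favors separations of 0-30 A and penalizes larger ones, built
from the smoothstep polynomial S(x) = 3x^2 - 2x^3:

    E(d) = 4 (1 - S(d/15))        0 <= d < 15
         = 4 S(d/15 - 1)          15 <= d < 30
         = 4 + 36 S(d/30 - 1)     30 <= d < 60
         = 40                     d >= 60

in Rosetta-style energy units, continuous at every breakpoint with its
minimum (0) at 15 A.  Weak hits use the same shape at 1/5 amplitude.

A constraint counts as satisfied in a 3D model when the O2'(i)-C4'(j)
distance is strictly below 30 A.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import EvaluationError, MohcaError, ValidationError
from .maps_io import ModelCoordinates

STRENGTH_SCALE = {"strong": 1.0, "weak": 0.2}
SATISFACTION_CUTOFF = 30.0  # Angstrom, strict


@dataclass(frozen=True)
class ConstraintPair:
    """One proximity constraint: O2' of residue i to C4' of residue j (i < j)."""

    i: int
    j: int
    strength: str
    atom_i: str = "O2'"
    atom_j: str = "C4'"

    def __post_init__(self) -> None:
        if self.i >= self.j:
            raise ValidationError(f"constraint requires i < j, got ({self.i}, {self.j})")
        if self.strength not in STRENGTH_SCALE:
            raise ValidationError(f"unknown strength {self.strength!r}")


def smoothstep(x: float | np.ndarray) -> float | np.ndarray:
    """S(x) = 3x^2 - 2x^3, with x clamped to [0, 1]."""
    x = np.clip(x, 0.0, 1.0)
    return 3.0 * x**2 - 2.0 * x**3


def potential_energy(d: float | np.ndarray, strength: str = "strong") -> float | np.ndarray:
    """Pseudo-energy at distance d (A); weak applies the 1/5 amplitude."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValidationError("distance must be non-negative")
    e = np.where(
        d < 15.0, 4.0 * (1.0 - smoothstep(d / 15.0)),
        np.where(
            d < 30.0, 4.0 * smoothstep(d / 15.0 - 1.0),
            np.where(d < 60.0, 4.0 + 36.0 * smoothstep(d / 30.0 - 1.0), 40.0),
        ),
    )
    e = e * STRENGTH_SCALE[strength]
    return float(e) if e.ndim == 0 else e


def hits_to_constraints(hits) -> list[ConstraintPair]:
    """Convert extracted hits into constraint pairs (same i < j orientation)."""
    return [ConstraintPair(i=h.i, j=h.j, strength=h.strength) for h in hits]


def write_constraints(pairs: list[ConstraintPair], path) -> None:
    """Write a constraint table: i, j, atoms, strength, amplitude scale."""
    if not pairs:
        raise ValidationError("refusing to write an empty constraint list")
    ordered = sorted(pairs, key=lambda p: (p.i, p.j, p.strength))
    with open(path, "w") as fh:
        fh.write("# i\tj\tatom_i\tatom_j\tstrength\tscale\n")
        for p in ordered:
            fh.write(f"{p.i}\t{p.j}\t{p.atom_i}\t{p.atom_j}\t"
                     f"{p.strength}\t{STRENGTH_SCALE[p.strength]:g}\n")


def read_constraints(path) -> list[ConstraintPair]:
    pairs = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        toks = line.split("\t")
        if len(toks) < 5:
            raise MohcaError(f"malformed constraint line: {line!r}")
        pairs.append(ConstraintPair(i=int(toks[0]), j=int(toks[1]),
                                    strength=toks[4], atom_i=toks[2], atom_j=toks[3]))
    return pairs


def constraint_distance(pair: ConstraintPair, model: ModelCoordinates) -> float:
    a = model.coord(pair.i, pair.atom_i)
    b = model.coord(pair.j, pair.atom_j)
    if a is None:
        raise EvaluationError(
            f"model {model.model_id}: missing atom {pair.atom_i} on residue {pair.i}")
    if b is None:
        raise EvaluationError(
            f"model {model.model_id}: missing atom {pair.atom_j} on residue {pair.j}")
    return float(np.linalg.norm(a - b))


def is_satisfied(pair: ConstraintPair, model: ModelCoordinates) -> bool:
    """True iff the O2'(i)-C4'(j) distance is strictly less than 30 A."""
    return constraint_distance(pair, model) < SATISFACTION_CUTOFF


def satisfaction_stats(pairs: list[ConstraintPair],
                       models: list[ModelCoordinates]) -> dict:
    """Percent satisfied per strength class, per model and averaged.

    Returns ``{"per_model": {model_id: {strength: pct}}, "mean": {strength: pct}}``
    with percentages on a 0-100 scale; classes with no constraints are
    reported as None.
    """
    if not pairs:
        raise ValidationError("no constraints to evaluate")
    if not models:
        raise ValidationError("at least one model is required")
    by_strength = {s: [p for p in pairs if p.strength == s] for s in STRENGTH_SCALE}
    per_model: dict[str, dict[str, float | None]] = {}
    for model in models:
        row: dict[str, float | None] = {}
        for s, plist in by_strength.items():
            if not plist:
                row[s] = None
                continue
            n_sat = sum(is_satisfied(p, model) for p in plist)
            row[s] = 100.0 * n_sat / len(plist)
        per_model[model.model_id] = row
    mean: dict[str, float | None] = {}
    for s in STRENGTH_SCALE:
        vals = [per_model[m.model_id][s] for m in models
                if per_model[m.model_id][s] is not None]
        mean[s] = float(np.mean(vals)) if vals else None
    return {"per_model": per_model, "mean": mean}
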