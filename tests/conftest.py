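"""Shared fixtures: toy matrices, synthetic model ensembles, PDB builders."""

from __future__ import annotations

import numpy as np
import pytest

from mohcaseq.maps_io import CountMatrix, ModelCoordinates, RnaSequence


@pytest.fixture
def seq4() -> RnaSequence:
    return RnaSequence(name="toy4", residues="GACU")


@pytest.fixture
def toy_counts(seq4) -> CountMatrix:
    F = np.zeros((4, 4))
    F[0, 2] = 10.0   # (i=1, j=3)
    F[1, 3] = 5.0    # (i=2, j=4)
    return CountMatrix(F=F, seq=seq4)


def make_rna_model(model_id: str, n_res: int = 6, score: float | None = None,
                   rng: np.random.Generator | None = None,
                   jitter: float = 0.0,
                   offset: np.ndarray | None = None,
                   twist: float = 0.6) -> ModelCoordinates:
    """A synthetic backbone-like model with O2'/C4'/P atoms per residue.

    Residues are laid out on a gentle helix so the geometry is non-degenerate;
    ``jitter`` adds Gaussian noise, ``offset`` a rigid translation (removed by
    superposition), and a different ``twist`` gives a genuinely different
    fold (not removed by superposition).
    """
    rng = rng or np.random.default_rng(0)
    atoms = []
    for res in range(1, n_res + 1):
        theta = twist * res
        base = np.array([9.0 * np.cos(theta), 9.0 * np.sin(theta), 2.8 * res])
        if offset is not None:
            base = base + offset
        for name, shift in (("P", (0.0, 0.0, 0.0)),
                            ("C4'", (1.2, 0.4, 0.3)),
                            ("O2'", (2.1, -0.8, 0.9))):
            xyz = base + np.array(shift)
            if jitter > 0:
                xyz = xyz + rng.normal(0.0, jitter, 3)
            atoms.append((res, name, *xyz.tolist()))
    return ModelCoordinates(model_id=model_id, atoms=atoms, score=score)


def write_pdb(path, model: ModelCoordinates, star_dialect: bool = False) -> None:
    """Serialize a model as minimal fixed-column PDB ATOM records."""
    lines = []
    serial = 1
    for (res, name) in model.atom_keys():
        x, y, z = model.coord(res, name)
        pdb_name = name.replace("'", "*") if star_dialect else name
        lines.append(
            f"ATOM  {serial:5d} {pdb_name:<4s} {'A':>3s} A{res:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}           C"
        )
        serial += 1
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


@pytest.fixture
def model_factory():
    return make_rna_model


@pytest.fixture
def pdb_writer():
    return write_pdb


@pytest.fixture
def two_population_models():
    """12 models: 9 perturbed copies of one fold, 3 of a different fold."""
    rng = np.random.default_rng(42)
    models = []
    for k in range(9):
        models.append(make_rna_model(f"a{k}", score=float(k), rng=rng, jitter=0.3))
    for k in range(3):
        models.append(make_rna_model(f"b{k}", score=float(10 + k), rng=rng,
                                     jitter=0.3, twist=1.7))
    return models
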