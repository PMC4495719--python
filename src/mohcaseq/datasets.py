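"""Canonical synthetic benchmark datasets.

The reference validation dataset is a 120-nt RNA with flat background
stopping and cleavage at 0.01 per nucleotide, six planted tertiary
contacts whose correlated signal is ten times the local background
(source fraction 0.02 x damage amplitude 0.05 = 10 x r*b), and one
million paired-end fragments.  The last twelve residues act as the
3'-flanking region and carry no contacts, matching the experimental
design where the flank holds the primer-binding site.
"""

from __future__ import annotations

from .cohcoa import CohcoaConfig
from .forward_model import PlantedContact, simulate_planted_dataset

BENCHMARK_LENGTH = 120
BENCHMARK_CONTACTS = [(10, 55), (15, 70), (25, 90), (35, 100), (45, 80), (60, 95)]
BENCHMARK_FLANK = (109, 120)
BENCHMARK_STOP_RATE = 0.01
BENCHMARK_CLEAVAGE_RATE = 0.01
BENCHMARK_DEPTH = 1e6
_SOURCE_FRACTION = 0.02
_AMPLITUDE = 0.05  # source_fraction * amplitude = 10 * r * b


def planted_contact_dataset(seed: int = 0, contacts=None) -> dict:
    """The reference planted-contact dataset (see module docstring).

    Pass ``contacts=[]`` for the matched background-only (null) dataset.
    """
    if contacts is None:
        contacts = BENCHMARK_CONTACTS
    planted = [PlantedContact(i=i, j=j, amplitude=_AMPLITUDE,
                              source_fraction=_SOURCE_FRACTION)
               for i, j in contacts]
    return simulate_planted_dataset(
        BENCHMARK_LENGTH, planted,
        r=BENCHMARK_STOP_RATE, b=BENCHMARK_CLEAVAGE_RATE,
        read_depth=BENCHMARK_DEPTH, seed=seed)


def benchmark_config(**overrides) -> CohcoaConfig:
    """Solver configuration matched to the benchmark's flanking region."""
    kwargs = dict(flank_region=BENCHMARK_FLANK)
    kwargs.update(overrides)
    return CohcoaConfig(**kwargs)
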