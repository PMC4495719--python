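"""Simulate a tethered-source probing experiment and deconvolve it.

Builds a 60-nt RNA with one planted tertiary contact (residues 12 and 40),
simulates 200,000 paired-end fragments over flat backgrounds, then runs the
iterative closure solver.  The printed table shows that the correlated
signal Q concentrates at the planted pair and that its signal-to-noise
ratio towers over the background cells.
"""

import numpy as np

from mohcaseq import CohcoaConfig, PlantedContact, run_cohcoa, simulate_planted_dataset

data = simulate_planted_dataset(
    length=60,
    contacts=[PlantedContact(i=12, j=40, amplitude=0.05, source_fraction=0.02)],
    r=0.01, b=0.01, read_depth=2e5, seed=1)

result = run_cohcoa(data["counts"], CohcoaConfig(flank_region=(55, 60)))

print(f"iterations run: {len(result.trace)} "
      f"(converged at {result.converged_at}, "
      f"final max relative change {100 * result.trace[-1]:.3g}%)")

snr = result.Q.snr()
i, j = np.unravel_index(np.argmax(snr), snr.shape)
print(f"strongest cell: ({i + 1}, {j + 1})  "
      f"Q = {result.Q.Q[i, j]:.1f} +- {result.Q.Q_err[i, j]:.1f} counts "
      f"(SNR {snr[i, j]:.1f})")
print(f"planted contact was (12, 40); ground-truth Q there: "
      f"{data['truth_q'].Q[11, 39]:.1f} counts")
mask = result.Q.mask
frac_null = np.mean(result.Q.Q[mask] <= 3 * result.Q.Q_err[mask])
print(f"background cells consistent with zero at 3 sigma: {100 * frac_null:.1f}%")
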