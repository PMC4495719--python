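"""Strand-scission and reverse-transcription-stop rate quantification.

Projecting the 2D count matrix onto its column axis gives, per cleavage/
ligation site j, the total fragments sharing that ssDNA-adapter ligation
site; normalizing by the full-length (3'-terminus) ligation total yields
the fraction cleaved at each internal position.  Projecting onto the row
axis and normalizing each stop position by all fragments ligated 3' of it
that stopped at or 5' of it corrects for reverse-transcriptase attenuation
and yields the fraction of transcripts stopping at each position.  Summing
a profile over non-masked positions gives the overall modification rate;
the mask excludes positions whose signal is not oxidative (e.g. the
residue carrying the tethered radical source).
"""

from __future__ import annotations

import logging

import numpy as np

from .errors import ValidationError
from .maps_io import CountMatrix, Profile1D

logger = logging.getLogger(__name__)


def scission_profile(F: CountMatrix) -> Profile1D:
    """Fraction cleaved per position: column sums over the full-length column.

    value_j = sum_i F_ij / sum_i F_{i,L} for internal j; the full-length
    position L itself is reported as 1 by construction.
    """
    length = F.length
    col_sums = F.F.sum(axis=0)
    full_length = col_sums[length - 1]
    if full_length <= 0:
        raise ValidationError("no counts in the full-length (3'-terminus) column")
    values = col_sums / full_length
    values[length - 1] = 1.0
    errors = np.sqrt(np.maximum(col_sums, 1.0)) / full_length
    errors[length - 1] = 0.0
    return Profile1D(values=values, role="scission_rate", errors=errors)


def stop_profile(F: CountMatrix) -> Profile1D:
    """Attenuation-corrected stop fraction per position.

    value_i = sum_j F_ij / sum_{i' <= i, j > i} F_{i'j}: fragments stopping
    exactly at i over all fragments ligated 3' of i that stopped at or 5'
    of i.  Positions with a zero denominator are reported missing (NaN).
    """
    length = F.length
    row_sums = F.F.sum(axis=1)
    values = np.full(length, np.nan)
    errors = np.zeros(length)
    for i in range(length):
        denom = F.F[: i + 1, i + 1:].sum()
        if denom > 0:
            values[i] = row_sums[i] / denom
            errors[i] = np.sqrt(max(row_sums[i], 1.0)) / denom
        else:
            logger.debug("stop profile undefined at position %d (zero denominator)", i + 1)
    return Profile1D(values=values, role="stop_rate", errors=errors)


def total_rate(profile: Profile1D, mask: list[int] | None = None) -> float:
    """Sum of the fraction modified over non-masked, non-missing positions.

    ``mask`` lists 1-based positions to exclude; scission profiles exclude
    the full-length (3'-terminus) position automatically, since only
    internal cleavage sites report oxidative scission.
    """
    excluded = set(mask or [])
    if profile.role == "scission_rate":
        excluded.add(len(profile.values))
    total = 0.0
    for pos, value in enumerate(profile.values, start=1):
        if pos in excluded or not np.isfinite(value):
            continue
        total += value
    return total
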