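"""Visualization post-processing and discrete hit extraction.

Raw solver output is turned into a display-ready proximity map in three
strictly ordered stages: (1) remove cells with signal-to-noise ratio < 1,
(2) smooth with a small 2D box mean restricted to defined (i < j) cells,
(3) scale by dividing by 5 times the map mean (negatives floored at 0), so
a typical strong feature lands near 1 on a dimensionless color scale.

Hits — residue pairs proposed as spatially proximal — are local maxima of
the scaled map, graded strong or weak by their signal-to-noise ratio.
Pairs closer than 7 nt in sequence are ignored (short fragments align
ambiguously), as are pairs attributable to secondary structure: cells
within a band around each helix's base-pairing anti-diagonal, which also
collects radical diffusion across the major and minor grooves.

``combine_libraries`` merges a size-selected sequencing library (enriched
for long fragments) back into the primary library by rebalancing its
per-sequence-separation totals and taking an inverse-variance-weighted
cellwise mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, DimensionError, ValidationError
from .maps_io import CountMatrix, ProximityMap

logger = logging.getLogger(__name__)

_STAGE_ORDER = ["raw_cohcoa", "filtered", "smoothed", "scaled"]


def _require_stage(pmap: ProximityMap, expected: str) -> None:
    if pmap.stage != expected:
        raise ValidationError(
            f"operation requires a {expected!r}-stage map, got {pmap.stage!r} "
            f"(stages advance {' -> '.join(_STAGE_ORDER)})"
        )


@dataclass
class HelixElement:
    """A secondary-structure helix: two antiparallel paired ranges (1-based)."""

    name: str
    range5: tuple[int, int]
    range3: tuple[int, int]

    def __post_init__(self) -> None:
        a1, a2 = self.range5
        b1, b2 = self.range3
        if not (a1 <= a2 and b1 <= b2):
            raise ValidationError(f"helix {self.name}: malformed ranges")
        if a2 - a1 != b2 - b1:
            raise ValidationError(f"helix {self.name}: paired ranges differ in length")
        if not (a2 < b1 or b2 < a1):
            raise ValidationError(f"helix {self.name}: paired ranges overlap")

    def base_pairs(self) -> list[tuple[int, int]]:
        """Antiparallel pairing: first of range5 pairs with last of range3."""
        a1, a2 = self.range5
        b1, b2 = self.range3
        pairs = [(a1 + k, b2 - k) for k in range(a2 - a1 + 1)]
        return [(min(p, q), max(p, q)) for p, q in pairs]


@dataclass
class Hit:
    """A proposed proximal residue pair extracted from the scaled map."""

    i: int
    j: int
    strength: str
    peak_value: float
    snr: float


def snr_filter(pmap: ProximityMap) -> ProximityMap:
    """Zero out cells with signal-to-noise ratio < 1 (strictly below)."""
    _require_stage(pmap, "raw_cohcoa")
    snr = pmap.snr()
    keep = snr >= 1.0
    Q = np.where(keep & pmap.mask, pmap.Q, 0.0)
    return ProximityMap(Q=Q, Q_err=pmap.Q_err.copy(), seq=pmap.seq,
                        stage="filtered", meta=dict(pmap.meta))


def smooth2d(pmap: ProximityMap, kernel_width: int = 3) -> ProximityMap:
    """Box-mean smoothing over defined (i < j) neighbors only.

    Each cell becomes the mean of the defined cells in a
    kernel_width x kernel_width window; near the diagonal the mean runs
    over the fewer defined neighbors.  Errors combine as the RMS of the
    contributing errors divided by the neighbor count.
    """
    _require_stage(pmap, "filtered")
    if kernel_width % 2 == 0 or kernel_width < 1:
        raise ConfigurationError("kernel_width must be a positive odd integer")
    half = kernel_width // 2
    length = pmap.length
    mask = pmap.mask
    Q = np.zeros_like(pmap.Q)
    E = np.zeros_like(pmap.Q)
    for i in range(length):
        for j in range(i + 1, length):
            i0, i1 = max(0, i - half), min(length, i + half + 1)
            j0, j1 = max(0, j - half), min(length, j + half + 1)
            sub_mask = mask[i0:i1, j0:j1]
            n = sub_mask.sum()
            if n == 0:
                continue
            Q[i, j] = pmap.Q[i0:i1, j0:j1][sub_mask].sum() / n
            E[i, j] = np.sqrt((pmap.Q_err[i0:i1, j0:j1][sub_mask] ** 2).sum()) / n
    return ProximityMap(Q=Q, Q_err=E, seq=pmap.seq, stage="smoothed",
                        meta=dict(pmap.meta, kernel_width=kernel_width))


def scale_map(pmap: ProximityMap) -> ProximityMap:
    """Divide by 5x the map mean (negatives set to 0 before averaging)."""
    _require_stage(pmap, "smoothed")
    vals = np.maximum(pmap.Q, 0.0)[pmap.mask]
    mu = vals.mean() if vals.size else 0.0
    if mu == 0.0:
        logger.warning("map mean is zero; returning all-zero scaled map")
        Q = np.zeros_like(pmap.Q)
        E = np.zeros_like(pmap.Q)
    else:
        Q = pmap.Q / (5.0 * mu)
        E = pmap.Q_err / (5.0 * mu)
    return ProximityMap(Q=Q, Q_err=E, seq=pmap.seq, stage="scaled",
                        meta=dict(pmap.meta, scale_mean=mu))


def _separation_bins(length: int) -> dict[int, int]:
    """Map each sequence separation to a bin id: 1-wide below 50, 2-wide
    for 50-100, 10-wide above 100."""
    bins: dict[int, int] = {}
    for sep in range(1, length):
        if sep < 50:
            bins[sep] = sep
        elif sep <= 100:
            bins[sep] = 1000 + (sep - 50) // 2
        else:
            bins[sep] = 2000 + (sep - 101) // 10
    return bins


def combine_libraries(primary: CountMatrix, size_selected: CountMatrix) -> CountMatrix:
    """Rebalance a size-selected library and merge it into the primary one.

    Per-separation (diagonal) totals are binned; the size-selected signal
    in each bin is multiplied by max(ratio)/ratio, where ratio is the
    size-selected/primary total — undoing the size-selection profile.  The
    two matrices are then combined cellwise by the mean weighted by the
    inverse error squared.
    """
    if primary.length != size_selected.length or \
            primary.seq.residues != size_selected.seq.residues:
        raise DimensionError("libraries must share sequence and shape")
    length = primary.length
    bins = _separation_bins(length)
    bin_ids = sorted(set(bins.values()))
    sums_p = {b: 0.0 for b in bin_ids}
    sums_s = {b: 0.0 for b in bin_ids}
    for sep in range(1, length):
        b = bins[sep]
        sums_p[b] += np.trace(primary.F, offset=sep)
        sums_s[b] += np.trace(size_selected.F, offset=sep)
    ratio = {}
    for b in bin_ids:
        if sums_p[b] > 0:
            ratio[b] = sums_s[b] / sums_p[b]
    if not ratio:
        raise ValidationError("primary library has no signal in any bin")
    max_ratio = max(ratio.values())
    factor = {}
    for b in bin_ids:
        if b in ratio and ratio[b] > 0:
            factor[b] = max_ratio / ratio[b]
        else:
            factor[b] = 1.0
            logger.warning("no usable signal in separation bin %s; factor = 1", b)
    reb = size_selected.F.copy()
    reb_err = size_selected.F_err.copy()
    for sep in range(1, length):
        f = factor[bins[sep]]
        idx = (np.arange(length - sep), np.arange(sep, length))
        reb[idx] *= f
        reb_err[idx] *= f
    w1 = np.zeros_like(primary.F)
    w2 = np.zeros_like(primary.F)
    mask = primary.mask
    with np.errstate(divide="ignore", invalid="ignore"):
        w1[mask] = 1.0 / np.maximum(primary.F_err[mask], 1e-12) ** 2
        w2[mask] = 1.0 / np.maximum(reb_err[mask], 1e-12) ** 2
        combined = np.where(mask, (w1 * primary.F + w2 * reb) / (w1 + w2), 0.0)
        err = np.where(mask, np.sqrt(1.0 / (w1 + w2)), 0.0)
    combined = np.nan_to_num(combined)
    err = np.nan_to_num(err, posinf=0.0)
    return CountMatrix(F=combined, F_err=err, seq=primary.seq,
                       meta=dict(primary.meta, combined="rebalanced"))


def helix_exclusion_mask(length: int, helices: list[HelixElement],
                         band_halfwidth: int = 2) -> np.ndarray:
    """Cells within ``band_halfwidth`` of any helix base pair (i < j only)."""
    excl = np.zeros((length, length), dtype=bool)
    for helix in helices:
        for p, q in helix.base_pairs():
            i0 = max(0, p - 1 - band_halfwidth)
            i1 = min(length, p - 1 + band_halfwidth + 1)
            j0 = max(0, q - 1 - band_halfwidth)
            j1 = min(length, q - 1 + band_halfwidth + 1)
            excl[i0:i1, j0:j1] = True
    return excl


def extract_hits(pmap: ProximityMap, helices: list[HelixElement] | None = None,
                 min_separation: int = 7, strong_snr: float = 5.0,
                 weak_snr: float = 2.0, band_halfwidth: int = 2) -> list[Hit]:
    """Call discrete hits as SNR-graded local maxima of the scaled map.

    A cell is a peak if it is >= all of its 8 neighbors (outside-triangle
    neighbors ignored), has SNR >= weak_snr, is at least ``min_separation``
    nt from the diagonal, and does not fall in a helix exclusion band.
    Peaks with SNR >= strong_snr are graded strong.  Output is ordered by
    descending peak value, ties broken by (i, j).
    """
    _require_stage(pmap, "scaled")
    helices = helices or []
    length = pmap.length
    mask = pmap.mask
    snr = pmap.snr()
    excl = helix_exclusion_mask(length, helices, band_halfwidth)
    hits: list[Hit] = []
    for i in range(length):
        for j in range(i + 1, length):
            if (j - i) < min_separation or excl[i, j]:
                continue
            v = pmap.Q[i, j]
            if v <= 0 or snr[i, j] < weak_snr:
                continue
            is_peak = True
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    if di == 0 and dj == 0:
                        continue
                    ni, nj = i + di, j + dj
                    if 0 <= ni < length and 0 <= nj < length and mask[ni, nj]:
                        if pmap.Q[ni, nj] > v:
                            is_peak = False
                            break
                if not is_peak:
                    break
            if not is_peak:
                continue
            strength = "strong" if snr[i, j] >= strong_snr else "weak"
            hits.append(Hit(i=i + 1, j=j + 1, strength=strength,
                            peak_value=float(v), snr=float(snr[i, j])))
    hits.sort(key=lambda h: (-h.peak_value, h.i, h.j))
    return hits
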