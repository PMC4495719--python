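"""Iterative closure solver separating proximity signal from plaid background.

A raw paired-end count matrix F_ij mixes three effects: uncorrelated
reverse-transcription stops (1D profile R_i), uncorrelated cleavages (1D
profile B_j), and the correlated two-point signal Q_ij that encodes
spatial proximity.  All of it is modulated by an attenuation factor A_ij —
the probability that reverse transcription launched at cleavage site j
survives back to stop site i.  The closed system solved here is

    F_ij = A_ij (R_i B_j + Q_ij)
    A_ij = prod_{i<m<j} (1 - R_m) (1 - R_i Q_mj / D_ij) (1 - rho Q_im B_j / D_ij)

with D_ij = R_i B_j + Q_ij the unattenuated model frequency; the system is
exact when Q is negligible and guarantees positive solutions.  Each outer
iteration: fit the separable background R_i B_j to the
attenuation-corrected data with the significant part of Q subtracted;
re-derive Q as the positive part of F/A - R B; update the attenuation
product (with relaxation).  Iteration runs a fixed number of cycles
(default 40) or until the maximum relative change of Q falls below a
tolerance (default 1%).

Three practical points shape the implementation.  (1) Units: the closure's
correction factors are dimensionally consistent only when F is a
per-transcript frequency, so counts are normalized by an estimated
transcript number.  (2) Scale of R: the rank-1 background with attenuation
is exactly separable, so only the product R_i B_j is data-identified; the
split is anchored to runoff-corrected stop fractions whose overall scale
comes from the decay of signal with sequence separation (a stationarity
assumption).  (3) Noise hygiene: only cells that clear a significance gate
enter the background subtraction and the attenuation corrections —
subtracting the positivity-clipped map itself would ratchet the background
downward by the clipped noise and bias A.

Errors: Poisson counting errors on F propagate first-order into A through
the Q estimates in the correction factors, and combine in quadrature with
the direct F errors into standard errors on Q.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, MohcaError
from .maps_io import CountMatrix, Profile1D, ProximityMap, upper_mask

logger = logging.getLogger(__name__)

_FACTOR_FLOOR = 1e-6  # keeps every attenuation factor, hence A, in (0, 1]


@dataclass
class CohcoaConfig:
    """Solver configuration.

    rho is the ratio of RT-terminating chemical modification to backbone
    cleavage (robust over 1-5, fixed at 2.5 by default).  flank_region is
    the 1-based inclusive position interval of the 3'-flanking region used
    to seed R and A; it is assumed to make no specific tertiary contacts.
    """

    rho: float = 2.5
    n_iterations: int = 40
    flank_region: tuple[int, int] | None = None
    convergence_tol: float = 0.01
    epsilon_floor: float = 0.5
    fallback_stop_rate: float = 0.01
    transcript_count: float | None = None
    damping: float = 0.5  # relaxation on the attenuation update, in (0, 1]
    inner_iterations: int = 5  # background/Q sub-iterations per attenuation update

    def __post_init__(self) -> None:
        if not (1.0 <= self.rho <= 5.0):
            raise ConfigurationError(f"rho {self.rho} outside the robust range [1, 5]")
        if self.n_iterations < 1:
            raise ConfigurationError("n_iterations must be >= 1")
        if self.epsilon_floor <= 0:
            raise ConfigurationError("epsilon_floor must be positive")


@dataclass
class CohcoaResult:
    """Fitted Q, backgrounds, attenuation, and the per-iteration trace."""

    Q: ProximityMap
    R: Profile1D
    B: Profile1D
    A: np.ndarray
    A_err: np.ndarray
    trace: list[float] = field(default_factory=list)
    converged_at: int | None = None


def _default_flank(length: int) -> tuple[int, int]:
    """Last ~10% of the sequence (at least 5 nt) as the 3'-flanking region."""
    width = max(5, length // 10)
    return (length - width + 1, length)


def _attenuation_from_R(R: np.ndarray) -> np.ndarray:
    """A_ij = prod_{i<m<j} (1 - R_m); empty product (j = i+1) is 1."""
    length = len(R)
    one_minus = np.clip(1.0 - R, _FACTOR_FLOOR, 1.0)
    logs = np.log(one_minus)
    csum = np.concatenate([[0.0], np.cumsum(logs)])  # csum[k] = sum(logs[:k])
    i_idx = np.arange(length)[:, None]
    j_idx = np.arange(length)[None, :]
    # sum of logs over 0-based m in (i, j) exclusive = csum[j] - csum[i+1]
    A = np.exp(csum[j_idx] - csum[np.minimum(i_idx + 1, length)])
    A = np.where(j_idx > i_idx, A, 1.0)
    return np.clip(A, _FACTOR_FLOOR, 1.0)


_STOP_CAP = 0.5  # per-nucleotide stop probabilities beyond this are nonphysical


def stop_fraction_profile(F: np.ndarray, columns: slice | None = None,
                          min_denominator: float = 0.0,
                          seed_rate: float | None = None) -> np.ndarray:
    """Per-position stop probability from a count matrix, runoff-corrected.

    The raw attenuation-exact ratio is
    Rhat_i = sum_{j, j > i} F_ij / sum_{i' <= i, j > i} F_i'j — fragments
    stopping exactly at i over fragments that stopped at i or 5' of it.
    Because cDNAs that run off the 5' end produce no fragment, that
    denominator undercounts the at-risk pool: the observable ratio equals
    p_i / (1 - prod_{m<=i} (1 - p_m)).  The true stop probabilities p are
    recovered by fixed-point inversion; positions where the inversion is
    unidentifiable (little stopping mass 5' of them, or fewer than
    ``min_denominator`` fragments) are set to the median of the
    well-determined positions.  Values are capped at 0.5 so a noisy cell
    cannot annihilate the downstream survival product.
    """
    length = F.shape[0]
    sub = np.zeros_like(F)
    cols = columns if columns is not None else slice(0, length)
    sub[:, cols] = F[:, cols]
    sub = np.where(upper_mask(length), np.maximum(sub, 0.0), 0.0)
    # denom_i = sum over rows 0..i of columns i+1..L-1
    row_cum = np.cumsum(sub, axis=0)                       # rows 0..i
    tail = np.cumsum(row_cum[:, ::-1], axis=1)[:, ::-1]    # columns j..L-1
    denom = np.array([tail[i, i + 1] if i + 1 < length else 0.0
                      for i in range(length)])
    stops = sub.sum(axis=1)
    ratio = np.zeros(length)
    has_data = denom > min_denominator
    ratio[has_data] = np.clip(stops[has_data] / denom[has_data], 0.0, 1.0)
    included = np.zeros((length, length), dtype=bool)
    included[:, cols] = True
    included &= upper_mask(length)
    decay_rate = _mean_stop_rate_from_decay(sub, included)
    from_decay = decay_rate is not None
    mean_rate = decay_rate if from_decay else (
        seed_rate if seed_rate is not None else 1e-3)
    # invert ratio = p / (1 - prod_{m<=i}(1 - p_m)).  The relation admits a
    # one-parameter solution family (the overall 5'-region scale); the decay
    # anchor selects the physical branch by seeding with the mean rate.
    p = np.full(length, mean_rate)
    for _ in range(100):
        cum = np.cumprod(1.0 - p)                          # prod_{m<=i}
        p_new = np.where(has_data,
                         np.clip(ratio * (1.0 - cum), 0.0, _STOP_CAP),
                         mean_rate)
        if np.max(np.abs(p_new - p)) < 1e-12:
            p = p_new
            break
        p = p_new
    if not from_decay and p.sum() > 0:
        # without decay information only the shape is data-determined; pin
        # the total to the seed so repeated estimation cannot drift
        p = p * (mean_rate * length / p.sum())
    return np.clip(p, 0.0, _STOP_CAP)


def _mean_stop_rate_from_decay(sub: np.ndarray, included: np.ndarray,
                               min_total: float = 10.0) -> float | None:
    """Mean per-nucleotide stop rate from the decay of per-separation totals.

    Reverse-transcription attenuation makes the total signal at sequence
    separation d fall off as (1 - Rbar)^d for roughly uniform backgrounds;
    a weighted log-linear fit of the diagonal sums of the count matrix
    therefore estimates the mean stop rate Rbar directly, independent of
    the unobservable runoff fragments.  Returns None when the fit is
    uninformative (too few separations, or a non-negative slope).
    """
    length = sub.shape[0]
    seps, totals, weights = [], [], []
    for d in range(1, length):
        cells = np.trace(sub, offset=d)
        n_cells = np.trace(included.astype(float), offset=d)
        if cells > min_total and n_cells > 0:
            seps.append(d)
            totals.append(np.log(cells / n_cells))
            weights.append(cells)  # ~inverse variance of a log-Poisson total
    if len(seps) < 3:
        return None
    coeffs = np.polyfit(np.asarray(seps), np.asarray(totals), 1,
                        w=np.sqrt(np.asarray(weights)))
    slope = coeffs[0]
    if slope >= 0:
        return None
    rate = 1.0 - np.exp(slope)
    return float(np.clip(rate, 1e-4, 0.2))


def initialize(F: CountMatrix, cfg: CohcoaConfig) -> tuple[Profile1D, np.ndarray]:
    """Seed R and A from cleavages landing in the 3'-flanking region.

    The flank is assumed to carry no specific contacts, so fragments
    cleaved there reflect pure background stopping.  R_i is the
    attenuation-exact stop fraction at i among fragments ligated in the
    flank (counts stopping at i over counts stopping at or 5' of i), and
    the initial attenuation is A_ij = prod_{i<m<j} (1 - R_m).
    """
    length = F.length
    flank = cfg.flank_region or _default_flank(length)
    lo, hi = flank
    if lo > hi or not (1 <= lo and hi <= length):
        raise ConfigurationError(f"flank region {flank} outside positions 1..{length}")
    cols = slice(lo - 1, hi)
    if F.F[:, cols].sum() == 0:
        logger.warning("all-zero counts in flank %s; falling back to uniform R = %g",
                       flank, cfg.fallback_stop_rate)
        R_vals = np.full(length, cfg.fallback_stop_rate)
    else:
        # the flank's few columns may not constrain the decay slope on
        # short molecules; the full matrix then seeds the overall scale
        sub = np.where(upper_mask(length), F.F, 0.0)
        full_rate = _mean_stop_rate_from_decay(sub, upper_mask(length))
        seed = full_rate if full_rate is not None else cfg.fallback_stop_rate
        # require a handful of fragments before trusting a position's ratio
        R_vals = stop_fraction_profile(F.F, columns=cols, min_denominator=5.0,
                                       seed_rate=seed)
    R = Profile1D(values=R_vals, role="rt_stop_background")
    A = _attenuation_from_R(R_vals)
    return R, A


def fit_background(X: np.ndarray, weights: np.ndarray, mask: np.ndarray,
                   max_inner: int = 200, tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """Best rank-1 non-negative factorization R_i B_j of X on the i<j mask.

    Weighted least squares (weights = 1/variance), solved by alternating
    closed-form non-negative updates to a fixed point.  The scale split
    between R and B is not identifiable from the product; it is resolved by
    matching the geometric mean of the nonzero B entries to the geometric
    mean of the nonzero column sums of X, keeping both profiles in
    count-like units.
    """
    length = X.shape[0]
    W = np.where(mask, weights, 0.0)
    Xp = np.where(mask, np.maximum(X, 0.0), 0.0)
    col = Xp.sum(axis=0)
    col_scale = np.exp(np.mean(np.log(col[col > 0]))) if np.any(col > 0) else 1.0
    if Xp.sum() == 0:
        return np.zeros(length), np.zeros(length)
    # init B from weighted column means
    denom = W.sum(axis=0)
    B = np.divide((W * Xp).sum(axis=0), denom, out=np.zeros(length), where=denom > 0)
    R = np.ones(length)
    prev = None
    for _ in range(max_inner):
        num = (W * Xp * B[None, :]).sum(axis=1)
        den = (W * B[None, :] ** 2).sum(axis=1)
        R = np.divide(num, den, out=np.zeros(length), where=den > 0)
        R = np.maximum(R, 0.0)
        num = (W * Xp * R[:, None]).sum(axis=0)
        den = (W * R[:, None] ** 2).sum(axis=0)
        B = np.divide(num, den, out=np.zeros(length), where=den > 0)
        B = np.maximum(B, 0.0)
        prod = np.outer(R, B)
        if prev is not None:
            scale = max(prod.max(), 1e-300)
            if np.max(np.abs(prod - prev)) / scale < tol:
                break
        prev = prod
    nzB = B[B > 0]
    if nzB.size:
        g = np.exp(np.mean(np.log(nzB)))
        factor = col_scale / g if g > 0 else 1.0
        B = B * factor
        R = R / factor
    return R, B


def update_Q(F: CountMatrix, A: np.ndarray, R: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Q_ij = max(0, F_ij / A_ij - R_i B_j); negatives are reset to zero."""
    mask = F.mask
    Q = F.F / np.maximum(A, _FACTOR_FLOOR) - np.outer(R, B)
    Q = np.maximum(Q, 0.0)
    Q[~mask] = 0.0
    return Q


def update_attenuation(F: CountMatrix, R: np.ndarray, B: np.ndarray,
                       Q: np.ndarray, cfg: CohcoaConfig,
                       epsilon_floor: float | None = None,
                       A_prev: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Attenuation and its first-order Poisson error.

    A_ij is the product over intervening positions m of three factors:
    background stopping (1 - R_m), stopping correlated with the observed
    cleavage (1 - R_i Q_mj / D_ij), and stopping correlated with the
    observed stop (1 - rho Q_im B_j / D_ij), where D_ij = R_i B_j + Q_ij
    is the unattenuated model frequency.  (The second-order expansion that
    motivates this closure cancels the denominator against the
    *unattenuated* frequency; dividing by the observed, attenuated counts
    instead makes the factors exceed 1 at long sequence separations and
    destabilizes the iteration.)  Cells where D falls below
    ``epsilon_floor`` are floored; each factor is clamped so A stays in
    (0, 1].  Poisson errors on F enter through the Q estimates
    (sigma_Q ~ F_err / A) appearing in the correction factors.
    """
    length = F.length
    mask = F.mask
    floor = cfg.epsilon_floor if epsilon_floor is None else epsilon_floor
    D = np.maximum(np.outer(R, B) + Q, floor)
    one_minus_R = np.clip(1.0 - R, _FACTOR_FLOOR, 1.0)
    Aref = np.maximum(A_prev if A_prev is not None else np.ones_like(D), _FACTOR_FLOOR)
    sigma_Q = F.F_err / Aref
    # only clearly significant signal enters the correction factors:
    # positivity clipping leaves every noise cell slightly positive, and a
    # systematic attenuation bias can push long-range cells to a few sigma,
    # so sub-threshold Q would otherwise feed a self-sustaining downward
    # bias of A.  Genuine contacts sit at tens of sigma and pass the gate;
    # the soft shrinkage keeps the update continuous at the threshold.
    Qs = np.where(Q > 5.0 * sigma_Q, np.maximum(Q - 2.0 * sigma_Q, 0.0), 0.0)
    A = np.ones((length, length))
    var_logA = np.zeros((length, length))
    for i in range(length):
        for j in range(i + 2, length):
            mrange = slice(i + 1, j)
            d = D[i, j]
            fac_bg = one_minus_R[mrange]
            c1 = R[i] * Qs[mrange, j] / d
            c2 = cfg.rho * Qs[i, mrange] * B[j] / d
            fac1 = np.clip(1.0 - c1, _FACTOR_FLOOR, 1.0)
            fac2 = np.clip(1.0 - c2, _FACTOR_FLOOR, 1.0)
            A[i, j] = np.clip(np.prod(fac_bg) * np.prod(fac1) * np.prod(fac2),
                              _FACTOR_FLOOR, 1.0)
            # d(log A)/dQ_mj = -(R_i / d) / fac1 etc., only where unclamped
            live1 = (1.0 - c1) > _FACTOR_FLOOR
            live2 = (1.0 - c2) > _FACTOR_FLOOR
            s1 = (R[i] * sigma_Q[mrange, j][live1] / d) / fac1[live1]
            s2 = (cfg.rho * B[j] * sigma_Q[i, mrange][live2] / d) / fac2[live2]
            var_logA[i, j] = (s1**2).sum() + (s2**2).sum()
    A[~mask] = 1.0
    A_err = A * np.sqrt(var_logA)
    A_err[~mask] = 0.0
    return A, A_err


def propagate_errors(F: CountMatrix, A: np.ndarray, A_err: np.ndarray) -> np.ndarray:
    """Combine Poisson errors on F with attenuation errors, in quadrature.

    Q_err_ij = sqrt((F_err/A)^2 + (F * A_err / A^2)^2).
    """
    Asafe = np.maximum(A, _FACTOR_FLOOR)
    term_f = F.F_err / Asafe
    term_a = F.F * A_err / Asafe**2
    Q_err = np.sqrt(term_f**2 + term_a**2)
    Q_err[~F.mask] = 0.0
    return Q_err


def _relative_change(Q_new: np.ndarray, Q_old: np.ndarray, mask: np.ndarray) -> float:
    """Max over cells of |dQ| / max(Q, map mean) — mixed relative/absolute."""
    vals = Q_new[mask]
    scale = vals.mean() if vals.size else 0.0
    if scale <= 0:
        return 0.0
    denom = np.maximum(Q_new, scale)
    rel = np.abs(Q_new - Q_old) / denom
    return float(rel[mask].max())


def run(F: CountMatrix, cfg: CohcoaConfig | None = None) -> CohcoaResult:
    """Run the full iterative closure analysis on a raw count matrix.

    The closed system's correction factors mix stop probabilities with the
    cleavage profile and the signal map, so they are dimensionally
    consistent only when F is expressed as a per-transcript frequency.
    Counts are therefore divided by the transcript number before
    iterating; when ``cfg.transcript_count`` is not given it defaults to
    the total fragment count, i.e. roughly one cleavage-ligation event per
    transcript — the single-hit regime the experiment targets.  Reported
    Q, backgrounds and errors are rescaled back to count-like units.
    """
    cfg = cfg or CohcoaConfig()
    mask = F.mask
    R_prof, A = initialize(F, cfg)  # stop-fraction ratios: scale-free
    nhat = cfg.transcript_count or _estimate_transcripts(F, R_prof.values, cfg.rho)
    Fp = CountMatrix(F=F.F / nhat, F_err=F.F_err / nhat, seq=F.seq)
    floor_p = cfg.epsilon_floor / nhat
    R = R_prof.values.copy()
    Q = np.zeros_like(Fp.F)        # clipped signal map, as reported
    Q_sig = np.zeros_like(Fp.F)    # significance-gated signal
    B = np.zeros(Fp.length)
    var = (np.maximum(F.F_err, 1.0) / nhat) ** 2
    trace: list[float] = []
    converged_at: int | None = None
    A_err = np.zeros_like(A)
    # the flank-based initial estimate seeds the R-scale anchor
    R_ref_total = float(R.sum())
    for it in range(1, cfg.n_iterations + 1):
        Asafe = np.maximum(A, _FACTOR_FLOOR)
        weights = Asafe**2 / var  # var(F/A) ~ var(F)/A^2
        sigma = Fp.F_err / Asafe
        # scale anchor for the R/B split: attenuation-exact stop fractions
        # of the counts with the *significant* signal removed.  Subtracting
        # only the gated Q keeps the anchor free of contact contamination
        # (which distorts the separation-decay fit badly on short RNAs)
        # without inheriting the positivity bias a noise-clipped map has.
        # Blending across iterations keeps one noisy estimate from wrecking
        # the split while the signal assignment is still settling.
        anchor_counts = np.maximum(F.F - Asafe * Q_sig * nhat, 0.0)
        new_ref = stop_fraction_profile(
            anchor_counts, min_denominator=5.0,
            seed_rate=R_ref_total / max(F.length, 1)).sum()
        R_ref_total = 0.5 * R_ref_total + 0.5 * float(new_ref)
        # inner sub-iterations settle which cells count as signal at fixed
        # attenuation.  Only the significance-gated part of Q is excluded
        # from the background fit target: subtracting the positivity-clipped
        # map instead would ratchet the plaid downward by the clipped noise.
        for _ in range(max(1, cfg.inner_iterations)):
            Fcorr = Fp.F / Asafe - Q_sig
            R, B = fit_background(Fcorr, weights, mask)
            # Only the product R_i B_j is fixed by the fit; the attenuation
            # factors (1 - R_m) need R on the true stop-probability scale,
            # so the split is re-anchored to the attenuation-exact total.
            if R.sum() > 0 and R_ref_total > 0:
                k = R_ref_total / R.sum()
                R = np.clip(R * k, 0.0, _STOP_CAP)
                B = B / k
            resid = Fp.F / Asafe - np.outer(R, B)
            Q_sig = np.where(resid > 5.0 * sigma,
                             np.maximum(resid - 2.0 * sigma, 0.0), 0.0)
            Q_sig[~mask] = 0.0
        Q_new = update_Q(Fp, A, R, B)
        A_new, A_err = update_attenuation(Fp, R, B, Q_new, cfg,
                                          epsilon_floor=floor_p, A_prev=A)
        # geometric relaxation: damps the own-cell Q <-> A feedback cycle
        g = cfg.damping
        A = np.clip(A ** (1.0 - g) * A_new ** g, _FACTOR_FLOOR, 1.0)
        if not (np.all(np.isfinite(Q_new)) and np.all(np.isfinite(A))):
            raise MohcaError(
                f"non-finite intermediate at iteration {it}: "
                f"max Q {np.nanmax(Q_new)}, min A {np.nanmin(A)}"
            )
        change = _relative_change(Q_new, Q, mask)
        trace.append(change)
        Q = Q_new
        if converged_at is None and change < cfg.convergence_tol:
            converged_at = it
            break
    Q_err = propagate_errors(Fp, A, A_err)
    # back to count-like units for reporting
    Q = Q * nhat
    Q_err = Q_err * nhat
    R_rep, B_rep = _report_scale(R, B, F.F, A, mask, nhat)
    qmap = ProximityMap(Q=Q, Q_err=Q_err, seq=F.seq, stage="raw_cohcoa",
                        meta=dict(F.meta, rho=cfg.rho, iterations=len(trace)))
    return CohcoaResult(
        Q=qmap,
        R=Profile1D(values=R_rep, role="rt_stop_background"),
        B=Profile1D(values=B_rep, role="cleavage_background"),
        A=A,
        A_err=A_err,
        trace=trace,
        converged_at=converged_at,
    )


def _estimate_transcripts(F: CountMatrix, R0: np.ndarray, rho: float) -> float:
    """Estimate the transcript number behind the observed fragment counts.

    The closure's correction factors need the cleavage profile as a
    per-transcript probability, which requires an absolute normalization
    that doubly-cut fragments alone cannot provide.  Two identifiable
    pieces close the gap: the total stop probability (from the attenuation
    decay, via R0) and the identity colsum_j = N * B_j * D_j with
    D_j = 1 - prod_{m<j}(1 - R_m).  Assuming background stops and
    scissions arise from the same oxidative chemistry partitioned by rho
    (sum R ~ rho * sum B) then yields N.  Floored at the total fragment
    count, since each transcript contributes at most one fragment.
    """
    cum = np.cumprod(1.0 - np.clip(R0, 0.0, _STOP_CAP))
    D = 1.0 - np.concatenate([[1.0], cum[:-1]])  # D_1 = 0: no stops 5' of j=1
    colsum = F.F.sum(axis=0)
    usable = D > 1e-3
    total = F.F.sum()
    if not usable.any() or R0.sum() <= 0:
        return max(total, 1.0)
    B_counts = (colsum[usable] / D[usable]).sum()
    nhat = rho * B_counts / R0.sum()
    return float(max(nhat, total, 1.0))


def _report_scale(R: np.ndarray, B: np.ndarray, F_counts: np.ndarray,
                  A: np.ndarray, mask: np.ndarray, nhat: float):
    """Split the count-scale product (nhat R B) by the geometric-mean rule.

    Only the product R_i B_j is identifiable; for reporting, B is scaled so
    the geometric mean of its nonzero entries matches the geometric mean of
    the nonzero column sums of the attenuation-corrected counts, keeping
    both profiles in count-like units.
    """
    col = np.where(mask, F_counts / np.maximum(A, _FACTOR_FLOOR), 0.0).sum(axis=0)
    nz_col = col[col > 0]
    nzB = B[B > 0]
    if not (nz_col.size and nzB.size):
        return R * nhat, B.copy()
    target = np.exp(np.mean(np.log(nz_col)))
    g = np.exp(np.mean(np.log(nzB)))
    k = target / g
    return R * nhat / k, B * k
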