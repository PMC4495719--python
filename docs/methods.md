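# Methods

## The forward model

A transcript carries at most one tethered radical source, at position *s*
with probability ε(s) (s = 0 means none). On activation, radicals cleave
the backbone and oxidize sugars/bases within the diffusion radius
(~0–30 Å). A sequenced fragment arises when reverse transcription, primed
at a cleavage/ligation site *j*, stops at *i < j*; its expected frequency
is

```
F_ij = Σ_s p_i^s · Π_{i<m<j} (1 − p_m^s) · q_j^s · ε(s)
```

with per-nucleotide cleavage `q_j^s = 1 − (1 − b_j)(1 − π_j^s)` and stop
`p_i^s = 1 − (1 − r_i)(1 − ρ_i π_i^s)`. Here `b_j`, `r_i` are
source-independent backgrounds, `π_i^s` the correlated damage from the
source at *s*, and `ρ` the ratio of RT-terminating modification to
backbone scission (scalar 2.5 by default; a per-residue vector is
accepted). Reverse transcriptase always stops at the tethered source
itself (`p_s^s = 1`), so no fragment spans its source. The simulator
(`forward_model`) evaluates this expression exactly (no truncation) and
samples fragments as independent Poisson counts at a requested total
depth, with errors `sqrt(max(count, 1))`.

The ground-truth correlated signal used for validation is the
second-order excess over the separable background:
`Q_ij = ρ_i (⟨π_i π_j⟩ − ⟨π_i⟩⟨π_j⟩) + ε_i (π_j^i − ⟨π_j⟩)` — the
two-point damage cumulant plus the direct source readout (stop at the
source at *i*, correlated cleavage at *j*).

## The closure solver

The solver (`cohcoa`) decomposes observed counts as
`F = A (R_i B_j + Q)` with the attenuation product
`A_ij = Π_{i<m<j} (1 − R_m)(1 − R_i Q_mj / D_ij)(1 − ρ Q_im B_j / D_ij)`,
`D_ij = R_i B_j + Q_ij`. Using the unattenuated model frequency `D` in
the correction denominators follows from the second-order expansion that
motivates the closure (the denominator must cancel an unattenuated
frequency); dividing by the observed, attenuated counts instead makes the
factors exceed 1 at long separations and destabilizes the iteration.

Each outer cycle (default 40, early exit when the maximum relative change
of Q drops below 1%):

1. **Background fit.** The separable plaid `R_i B_j` is fit to
   `F/A − Q_sig` by weighted (1/variance) alternating non-negative
   least squares. Only the *significance-gated* part of the signal,
   `Q_sig = max(resid − 2σ, 0)` where `resid > 5σ`, is subtracted:
   subtracting the positivity-clipped map itself would ratchet the plaid
   downward by the systematically positive clipped noise (measured ~2σ).
   Five inner sub-iterations settle the signal assignment at fixed
   attenuation; without them the slow exchange of mass between the plaid
   and Q dominates the convergence rate.
2. **Signal update.** `Q = max(0, F/A − R_i B_j)`; negatives are reset to
   zero.
3. **Attenuation update.** The triple product above, each factor clamped
   to (0, 1], relaxed geometrically against the previous attenuation
   (damping 0.5) to suppress an own-cell Q↔A oscillation.

Poisson errors on F propagate first-order into A through the gated Q
estimates in the correction factors and combine in quadrature with the
direct `F_err/A` term into `Q_err`.

### Identifiability and the two scale anchors

Two quantities are not identifiable from doubly-cut fragment counts alone
and are fixed by explicit, documented estimators:

- **The split of R versus B.** Background × attenuation is *exactly*
  rank-1 separable (`A_bg,ij = C_{j−1}/C_i` with `C` a cumulative
  survival), so the data determine only the product `R_i B_j`; yet the
  factors `(1 − R_m)` need R in true stop-probability units. The scale is
  anchored to runoff-corrected stop fractions: the observable ratio
  (stops at *i* over stops at or 5′ of *i*) equals
  `p_i / (1 − Π_{m≤i}(1 − p_m))` because runoff cDNAs are unobservable;
  the physical branch of the inversion is selected by the mean stop rate
  estimated from the decay of per-separation totals — a stationarity
  assumption on the background profiles. On short RNAs, where
  composition effects break the decay fit, the anchor holds at its
  seeded value instead of drifting. The reported R and B are re-split by
  a geometric-mean convention to stay in count-like units; only the
  product and Q are quantitative.
- **The transcript normalization.** The correction factors mix the
  cleavage profile as a per-transcript probability with count-scale
  quantities, requiring an absolute transcript number N that fragment
  counts cannot supply. When not given
  (`CohcoaConfig.transcript_count`), N is estimated from the identity
  `colsum_j = N · B_j · D_j` combined with the assumption that
  background stops and scissions share the oxidative partition ratio
  (`ΣR ≈ ρ ΣB`), floored at the total fragment count. Misestimating N
  scales the (second-order) correction strength, not the leading
  decomposition.

Initialization estimates R from fragments ligated in the 3′-flanking
region (assumed contact-free), with the same runoff correction, and sets
`A = Π(1 − R_m)`, `Q = 0`. Zero-count cells use an epsilon floor (0.5
counts) in denominators; every attenuation factor is clamped to
`[1e−6, 1]`.

The convergence metric is the maximum over cells of
`|ΔQ| / max(Q, map mean)` — a mixed relative/absolute criterion that
avoids division by near-zero cells.

## Post-processing and hit calling

Display maps advance through fixed stages: remove cells with SNR < 1
(strictly), 3×3 box-mean smoothing over defined (i < j) cells with errors
combined as RMS/n, then division by 5× the map mean (negatives floored at
zero first). Hits are 8-neighbor local maxima of the scaled map with
SNR ≥ 2 (weak) or ≥ 5 (strong) — thresholds are configurable, since the
strong/weak division has no canonical numeric boundary — excluding pairs
under 7 nt apart (short fragments align ambiguously) and cells within
±2 of any helix base pair (radical diffusion across the grooves produces
secondary-structure signal). Peak picking is automatic here;
expert-curated hit lists can be supplied directly to the constraints
layer.

Size-selected libraries are merged by computing per-separation totals
(bins of 2 for separations 50–100, bins of 10 above 100), multiplying the
size-selected signal by max(ratio)/ratio of the size-selected/primary
totals, and averaging cellwise weighted by inverse variance.

## Constraints and model analytics

Each hit becomes a distance constraint between O2′ of the 5′ residue and
C4′ of the 3′ residue under the smoothstep potential (4 units at contact,
minimum 0 at 15 Å, 4 at 30 Å, plateau 40 beyond 60 Å); weak hits scale
the whole curve, plateau included, by 1/5. A constraint is satisfied in a
model when the distance is strictly below 30 Å.

Model ensembles are reduced to the lowest-energy fraction (1/6 before
refinement; 3% of refined or 0.5% of unrefined models for clustering,
counts rounded up so selection is never empty, ties broken by model id),
then clustered greedily: the model with the most neighbors within the
RMSD threshold (ties: lowest score, then id) seeds a cluster and is
removed with its neighbors. The threshold is the smallest observed
pairwise RMSD at which the top cluster holds ≥ 1/6 of the models — the
achieved fraction is a step function of the threshold, so only observed
values need scanning. The threshold doubles as the intra-cluster RMSD,
and the in situ precision is that value × √2 (triangle estimate through
the cluster's most accurate member). Across independent modeling runs,
the mean pairwise RMSD between top-cluster centers substitutes for the
intra-cluster RMSD. RMSD uses closed-form optimal superposition (SVD),
validated against a rotation-search oracle.

## Rates

The scission profile is each ligation column's total over the full-length
column's total; the stop profile is the attenuation-exact stop fraction
(stops at *i* over fragments at risk at *i*). The stop profile's
expectation is `p / (1 − (1 − p)^i)` — biased upward near the 5′ end
because runoff cDNAs are invisible — so totals should mask 5′-proximal
positions along with the tethered-source residue.

## What the synthetic benchmark does and does not emulate

The reference dataset is a 120-nt RNA, flat stop and cleavage backgrounds
of 0.01/nt, six planted contacts whose correlated signal is 10× the local
background (source fraction 0.02 × damage amplitude 0.05), 10⁶ fragments,
and a contact-free 12-nt 3′ flank. It reproduces the count statistics,
attenuation, and plaid-plus-signal structure of the real assay. It does
not emulate: sequence-dependent background variation, multiple sources
per transcript (folded into backgrounds to first order), ligation-bias
chemistry, alignment ambiguity of short reads, or diffuse many-residue
damage neighborhoods (planted damage spans ±1 residue). Passing tests
therefore demonstrate correctness of the deconvolution under the model's
own assumptions, not robustness to every artifact of real libraries.
Oracle-equivalence checks run at L = 8 with three sources on distinct
rows and columns; on such short RNAs a single row holding several contact
cells makes the rank-1 background absorb the signal — a real
identifiability limit, not an implementation artifact.

## Known limitations

- The absolute correction-factor strength depends on the estimated
  transcript normalization (see above); supply
  `transcript_count` when library metadata provides it.
- The R-scale anchor assumes approximately stationary backgrounds; on
  short RNAs it falls back to a configurable prior rate.
- Hit grading thresholds (strong ≥ 5, weak ≥ 2 SNR) are operational
  defaults, not calibrated probabilities.
- Knot screening of clustered models and sequence-independent structural
  alignment of peripheral regions are out of scope.
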