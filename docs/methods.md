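# Methods

## DEER forward model

A doubly spin-labelled receptor produces a four-pulse DEER signal

V(t) = (1 − λ + λ·F(t)) · B(t),    F(t) = ∫ K(t, r) P(r) dr,

where P(r) is the label–label distance distribution, λ the modulation depth
(fraction of echo amplitude modulated by pumped spin pairs) and B the
intermolecular background. The powder-averaged kernel is

K(t, r) = ∫₀¹ cos[(1 − 3x²) ω(r) t] dx,  ω(r) = 2π · 52.04 MHz·nm³ / r³,

with the community-standard nitroxide dipolar constant 52.04 MHz·nm³. Two
independent evaluations are implemented: Gauss–Legendre quadrature over
x = cosθ (default 500 nodes) and the closed form via Fresnel integrals
C and S,

K = √(π/6ωt) [C(q) cos ωt + S(q) sin ωt],  q = √(6ωt/π),

which agree to < 1e-6 and serve as mutual oracles in the tests.

The background is taken as 3-D homogeneous, B(t) = exp(−k t) with
k = 2.0×10⁻⁴ µs⁻¹ · c(µM) · λ. The proportionality constant is a package
convention: simulator and fitter share it, so recovery tests are
self-consistent whatever the spectrometer-specific physical value. Units
are Å for distances and µs for time throughout the API; the default
simulation axis is 0–3.4 µs in 16 ns steps and the default distance grid
15–100 Å at 0.5 Å.

## Global Gaussian-mixture fit

All conditions are fit **simultaneously**: Gaussian centers (bounded
20–100 Å) and widths (2–20 Å) are global; each condition owns a population
vector on the simplex, a modulation depth in [0.3, 0.7]; each transducer
group owns a spin concentration in [25, 150] µM. Populations are
parameterized by K−1 free logits mapped through a softmax, which enforces
nonnegativity and sum-to-one exactly. The number of free parameters is
2K + n_cond(K−1) + n_cond + n_groups.

The least-squares problem is solved with a trust-region reflective solver
using an **analytic sparse Jacobian** (population logits and λ touch only
their condition's residual block, concentrations their group's); this is
what makes the ~200-parameter, 30-dataset problem tractable in seconds per
fit on one core. Multi-start uses 10 starts — one deterministic spread
plus Latin-hypercube draws over centers/widths with a fixed seed —
screened with a capped iteration budget; the best screened solution is
polished to full tolerance. Ties are broken by the lowest start index and
components are sorted by ascending center after every fit, so results are
deterministic given the seed.

A caveat the fit inherits from the physics: components whose separation is
smaller than their widths (here the 43/45 Å pair) produce a family of
near-degenerate optima that differ mainly in how population is allocated
between the overlapping components, with residual sums agreeing to within
~1e-4 relative. The global structure (centers, widths, the remaining
populations) is stable across these optima; the per-condition allocation
within the overlapping pair carries an intrinsic uncertainty of a few
percentage points that no start strategy can remove, because the data are
genuinely indifferent along that direction at the operating noise level.

Model selection refits at every K in the scan range and compares the
concentrated-Gaussian information criteria

AICc = N ln(RSS/N) + 2k + 2k(k+1)/(N−k−1),  BIC = N ln(RSS/N) + k ln N,

with N the total residual count and k the free-parameter count. AICc is
the primary criterion; the BIC choice is reported alongside and
disagreement is flagged rather than resolved silently. AICc is reported
as undefined when N − k − 1 ≤ 0.

Uncertainty is quantified by residual-resampling bootstrap: per iteration
each dataset's fit residuals are resampled with replacement, added back to
the fitted curves, and the model is refit starting from the point estimate
(default 1,000 iterations; percentile 95% intervals). Label switching
across iterations is resolved by nearest-center assignment against the
point estimate. A population shift between two conditions is called
significant when the two 95% intervals are disjunct.

Correlation analysis computes pairwise Pearson r (two-sided t-test
p-values) between component populations across all fitted conditions.
Components are grouped by the graph of significant (p < 0.05)
correlations; components outside the largest connected block take no part
in the common conformational equilibrium and are listed as exclusion
candidates — in the receptor system these are the long-distance
oligomeric/nonfunctional peaks. Zero-variance populations yield undefined
entries, reported as missing.

The model-free cross-check inverts the form factor by nonnegative
Tikhonov regularization, min ‖K P − F‖² + α²‖L P‖² with L the
second-difference operator, background and λ fixed from a prior mixture
fit. α is picked at the L-curve corner (maximum curvature in log–log
coordinates); an effective-degrees-of-freedom AICc is reported per α as a
cross-check. The mixture fit deliberately allows per-component widths,
which is what lets it separate adjacent peaks of unequal width (39 Å,
σ 3.8 vs 43 Å, σ 2) that a single smoothness parameter tends to merge.

## smFRET corrections, filters and histograms

Corrected efficiency per frame: E = (1 + γ·I_D/(I_A − χ·I_D))⁻¹, with
χ = 0.05 and γ = 1 (Cy3/Cy5) or 0.2 (Cy3/Cy7) applied globally; per-trace
γ estimation from acceptor photobleach steps (γ = ΔI_A/ΔI_D, 10-frame
windows either side of the step) is available but off by default. Frames
where I_A − χ·I_D ≤ 0 are masked invalid.

Trace quality requires all three of: SNR (mean/SD of total intensity
before the donor bleach) ≥ 4 for Cy3/Cy5 and ≥ 3 for Cy3/Cy7; exactly one
donor photobleach step; pre-bleach duration ≥ 2 s (20 frames at the 0.1 s
frame interval). Steps are found by binary-segmentation change-point
detection with a BIC stopping rule; a *bleach* step must be an
irreversible drop (> 20% of the initial level, with no later segment
recovering above the post-step level by more than 25% of that level) —
this distinguishes photobleaching from donor-intensity excursions caused
by FRET state transitions, which reverse. "Near-baseline" means the
post-step mean is below 10% of the pre-step level.

Histograms pool all valid frames, bin width 0.02 over [−0.2, 1.2],
normalized to unit area. Peak fitting is least squares with one or two
signal Gaussians plus an optional broad noise component constrained to
σ ≥ 0.15, all areas nonnegative; peaks are reported sorted by center.

## Two-state kinetics

Each corrected trace (≥ 20 valid frames) is fit by Baum–Welch EM with
Gaussian emissions: means initialized at the 25th/75th percentiles, SDs at
half the interquartile range, convergence at Δlog-likelihood < 1e-6 or 500
sweeps, then Viterbi decoding. Traces whose two emission means collapse
(|Δμ| < 0.02) are flagged degenerate and excluded from kinetics. Dwells
are maximal constant-state runs in seconds; the first and last run of
every trace are censored by default, because boundary runs oversample long
dwells (length bias) in the regime where dwells are short relative to the
trace. Dwell distributions are summarized by unweighted least-squares fits
of the empirical survival curve S(t) = ΣAᵢ exp(−t/τᵢ): mono-exponential
for the high-FRET state, bi-exponential with the amplitude-weighted mean
τ̄ = ΣAᵢτᵢ/ΣAᵢ for the low-FRET state (minimum 30/100 uncensored dwells);
the maximum-likelihood mean is available as a cross-check. The GDP
titration summary reports, per concentration: the low-FRET center from a
Gaussian fit of HMM-assigned low frames (not the three-peak histogram
fit), the low-FRET area from the two-signal-plus-noise histogram fit, and
the dwell time constants; missing quantities are flagged per
concentration.

## Synthetic data

The DEER fixture encodes a six-component ensemble at 26/33/39/43/45/57 Å
observed under 30 conditions (10 ligands × {ligand only, +G protein,
+arrestin}). The 39/43 Å widths are the 3.8/2 Å pair that motivates
per-component widths; the inactive components are broad (σ 5 and 4 Å) and
the 45/57 Å peaks (σ 2.5 and 4 Å) are kept narrow enough to be separable
from the 43 Å peak, matching the demonstrated resolvability of the
long-distance species. Per-condition populations live in an editable CSV
and are synthetic stand-ins shaped by the known narrative: the antagonist
condition is mostly inactive, the reference full agonist carries a summed
active population of 25%, super-efficacy agonists are mostly active, and
G protein boosts the active pair; the 45/57 Å populations vary
independently of the others so the correlation analysis singles them out.
Modulation depths span 0.35–0.65, group concentrations are 60/90/120 µM
and the default noise is iid Gaussian with σ = 0.003 on a normalized
amplitude.

FRET trajectories are generated from named schemes (YAML fixtures): slow
states follow a continuous-time two-state chain sampled at frame
midpoints; fast sub-states, when present, are simulated at 50× the frame
rate and averaged within each frame, which reproduces the time-averaging
law (a 50/50 0.7/0.9 pair exchanging at 200 s⁻¹ fuses into one peak at
0.80). Clean intensities are I_D = S(1−E) and I_A = γSE + χI_D, so the
standard correction inverts the synthesis exactly at zero noise; shot-like
noise is Gaussian with σ = √(channel intensity) scaled by a configurable
factor, and the donor bleaches in a single step at a geometrically
distributed frame. Every generator draws one independent substream per
trace/dataset from the master seed, so extending a simulation never
perturbs existing traces.

What the generators do *not* emulate: spectrometer artefacts (phase
drift, orientation selection, ESEEM), dye photophysics beyond χ/γ
(blinking, spectral shifts), multi-spin effects, and the TIRF
image-formation process — passing recovery tests therefore demonstrates
correctness of the inference pipeline under the stated generative
assumptions, not robustness to every instrumental artefact of real data.

## Problem sizes and numerical choices

The shipped analyses run at desk scale on one core: 30 dipolar traces of
213 points (16 ns steps to 3.4 µs), model-selection scans over 2–7
components with 10 starts each (a few minutes), bootstrap defaults of
1,000 iterations with smaller counts in the test suite, and smFRET runs of
100–200 traces × 300–400 frames. Degenerate inputs are rejected early with
explicit messages (empty axes, all-zero signals, too-short traces);
optimizer non-convergence is carried in the result objects rather than
raised, so pipelines report per-stage status.

## Known limitations

Raw-file ingestion covers plain-text two-column traces only (no vendor
binary formats); zero-time and phase correction are assumed done upstream.
The background's functional form is fixed to the 3-D homogeneous
exponential. The HMM is per-trace with pooled dwells; a global
shared-emission variant is out of scope, as are >2-state models and
photon-level likelihoods. The mechanistic three-state binding scheme that
motivates the bi-exponential low-FRET dwell fit is not itself fitted.
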