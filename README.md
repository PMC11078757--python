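# deerfret

Analysis of G-protein-coupled-receptor conformational ensembles from two
complementary single-pair distance experiments:

* **DEER (double electron–electron resonance).** The time-domain dipolar
  signal of a spin-labelled receptor encodes the distribution *P(r)* of
  label–label distances. `deerfret` fits a **global Gaussian mixture**
  jointly to many ligand/transducer conditions — component centers and
  widths are shared, populations, modulation depth λ ∈ [0.3, 0.7] and spin
  concentration are local — selects the component count by AICc (BIC
  reported alongside), quantifies uncertainty by residual bootstrap, flags
  population shifts by disjunct 95% confidence intervals, and cross-checks
  against Tikhonov-regularized model-free inversion.
* **smFRET (single-molecule Förster resonance energy transfer).** Raw
  donor/acceptor trajectories are corrected for crosstalk χ and detection
  factor γ via E = (1 + γ·I_D/(I_A − χ·I_D))⁻¹, filtered by the three
  standard quality criteria (SNR ≥ 4 for Cy3/Cy5 or ≥ 3 for Cy3/Cy7,
  single-step donor photobleaching, ≥ 2 s duration), pooled into histograms
  fitted with Gaussian peaks, and decoded with a two-state Gaussian-emission
  hidden Markov model for dwell-time kinetics (mono-/bi-exponential
  survival-curve fits, weighted-average dwell times, GDP-titration
  summaries).

A first-class synthetic-data module (`deerfret.simulate`) generates both
kinds of data with known ground truth — a 30-condition, six-component
TM4–TM6 distance ensemble and two-state FRET trajectories with fast
(< 100 ms) sub-state averaging and slow (> 100 ms) exchange — so every
pipeline stage is exercised by parameter recovery, and the two arms are
linked by the Förster law E = 1/(1 + (r/R₀)⁶).

The signal model for DEER is V(t) = (1 − λ + λ·(K P)(t))·B(t) with the
powder-averaged dipolar kernel
K(t, r) = ∫₀¹ cos[(1 − 3x²)·ω(r)·t] dx, ω(r) = 2π·52.04 MHz·nm³/r³, and a
3-D homogeneous exponential background B.

## Worked example

```sh
python examples/fret_histograms.py
```

```
antagonist-like   : 123/200 traces accepted, 18479 frames, peak E = 0.890 (sd 0.012)
full-agonist-like : 133/200 traces accepted, 19464 frames, peak E = 0.770 (sd 0.015)
```

Two hundred trajectories per condition are simulated from the shipped
schemes, roughly two thirds survive the quality filters, and the fitted
signal peak recovers each condition's ground-truth time-averaged
efficiency: 0.89 for the antagonist-bound receptor and 0.77 for the
full-agonist-bound one — the lower efficiency reports the larger
donor–acceptor distance of the activated state.

`examples/deer_global_fit.py`, `examples/deer_forward_and_inversion.py`
and `examples/fret_gdp_titration.py` walk through the DEER mixture fit
with bootstrap contrasts, the model-free inversion, and the two-state
kinetics of the receptor/G-protein cycle.

A thin CLI wraps the same pipelines:

```sh
deerfret synth deer --seed 1 --out runs/deer
deerfret deerfit --manifest runs/deer/manifest.csv --k 6 --seed 1 --out report.json
deerfret fretq --traces traces.csv --peaks 2 --out runs/fret
```

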