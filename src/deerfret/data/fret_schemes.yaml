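# Named generative smFRET scheme fixtures (synthetic ground truths).
#
# Each scheme lists its slow conformational states (observed mean FRET
# efficiency; optionally fast sub-states whose within-frame average defines
# the observed mean), slow exit rates in s^-1, the per-frame donor
# photobleach probability, intensity scale, and the dye pair whose chi/gamma
# the simulator inverts.  Values are synthetic stand-ins parameterized to the
# reported peak positions.

antagonist_cy3cy5:
  # time-averaged inactive ensemble; single observed peak at E = 0.89
  pair: Cy3/Cy5
  states:
    - {name: averaged_inactive, mean_e: 0.89}
  photobleach_rate: 0.006
  scale: 1000.0

agonist_cy3cy5:
  # reference full agonist; time-averaged peak shifted to E = 0.77
  pair: Cy3/Cy5
  states:
    - {name: averaged_active, mean_e: 0.77}
  photobleach_rate: 0.006
  scale: 1000.0

cy3cy7_slow_exchange:
  # slow (>100 ms) exchange resolved as two peaks; high (inactive) at 0.8
  pair: Cy3/Cy7
  states:
    - {name: active_low, mean_e: 0.62}
    - {name: inactive_high, mean_e: 0.80}
  exit_rates: [0.4, 0.4]
  photobleach_rate: 0.004
  scale: 1000.0

ternary_nucleotide_free:
  # nucleotide-free ternary complex: low-FRET state at 0.5, unbound at 0.77
  pair: Cy3/Cy5
  states:
    - {name: bound_low, mean_e: 0.50}
    - {name: unbound_high, mean_e: 0.77}
  exit_rates: [0.3, 0.5]
  photobleach_rate: 0.004
  scale: 1000.0

ternary_gdp_saturated:
  # GDP-bound complex: low-FRET state shifted to 0.6, faster dissociation
  pair: Cy3/Cy5
  states:
    - {name: bound_low_gdp, mean_e: 0.60}
    - {name: unbound_high, mean_e: 0.77}
  exit_rates: [1.2, 0.5]
  photobleach_rate: 0.004
  scale: 1000.0
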