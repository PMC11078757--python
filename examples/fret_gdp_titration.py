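"""Two-state kinetics of the receptor/G-protein cycle across GDP levels.

Simulates trajectories from GDP-dependent schemes (GDP destabilizes the
bound low-FRET complex and shifts its efficiency from 0.5 toward 0.6),
decodes each trace with the two-state hidden Markov model, and summarizes
the low-FRET peak center/area and dwell times per concentration.
"""

from deerfret import (
    correct_trace,
    filter_traces,
    gdp_titration_summary,
    gdp_titration_schemes,
    simulate_fret_traces,
)

concs = [0.0, 25.0, 100.0]
schemes = gdp_titration_schemes(concs)
runs = {}
for c in concs:
    traces = simulate_fret_traces(schemes[c], n_traces=120, n_frames=400,
                                  seed=7)
    accepted, _ = filter_traces(traces)
    runs[c] = [correct_trace(t) for t in accepted]

summary = gdp_titration_summary(runs, seed=7)
print(" GDP (uM)  low-FRET E   low area   tau_high (s)  tau_low (s)   traces")
for p in summary.points:
    area = "  n/a " if p.low_area is None else f"{p.low_area:6.3f}"
    th = "  n/a " if p.high_dwell_tau is None else f"{p.high_dwell_tau:6.2f}"
    tl = "  n/a " if p.low_dwell_tau is None else f"{p.low_dwell_tau:6.2f}"
    print(f"{p.gdp_um:8.1f}   {p.low_center:8.3f}   {area}     {th}       {tl}"
          f"      {p.n_traces:4d}")
print("rising GDP shifts the bound-state efficiency toward 0.6 and shrinks")
print("the low-FRET occupancy as the nucleotide-bound complex dissociates")
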