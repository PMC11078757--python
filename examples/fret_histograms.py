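"""Pooled smFRET histograms for antagonist- and agonist-like conditions.

Simulates donor/acceptor trajectories from the shipped Cy3/Cy5 schemes,
applies the three trace-quality criteria (SNR, single-step donor bleach,
>= 2 s), corrects for crosstalk and gamma, and fits one signal Gaussian
plus a broad noise peak.  The peak centers report the time-averaged FRET
efficiency of each liganded state.
"""

from deerfret import (
    build_fret_histogram,
    correct_trace,
    filter_traces,
    fit_histogram,
    load_fret_scheme,
    simulate_fret_traces,
)

for name, label in [("antagonist_cy3cy5", "antagonist-like"),
                    ("agonist_cy3cy5", "full-agonist-like")]:
    scheme = load_fret_scheme(name)
    traces = simulate_fret_traces(scheme, n_traces=200, n_frames=300, seed=2)
    accepted, decisions = filter_traces(traces)
    corrected = [correct_trace(t) for t in accepted]
    edges, density = build_fret_histogram(corrected)
    fit = fit_histogram(edges, density, n_signal_peaks=1,
                        include_noise_peak=True)
    peak = fit.signal_peaks[0]
    n_frames = sum(int(c.valid.sum()) for c in corrected)
    print(f"{label:18s}: {len(accepted):3d}/{len(traces)} traces accepted, "
          f"{n_frames} frames, peak E = {peak.center:.3f} (sd {peak.sd:.3f})")

print("the lower full-agonist peak reflects the larger time-averaged")
print("donor-acceptor distance of the activated receptor")
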