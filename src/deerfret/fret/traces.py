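"""From raw donor/acceptor intensity trajectories to corrected FRET histograms.

Implements the standard single-molecule corrections (donor->acceptor
crosstalk chi, detection/quantum-yield factor gamma), the three trace-quality
criteria (signal-to-noise ratio, single-step donor photobleaching, minimum
duration), histogram pooling and Gaussian peak fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "DyePairConstants",
    "CY3_CY5",
    "CY3_CY7",
    "FretTrace",
    "CorrectedTrace",
    "FilterDecision",
    "HistogramFit",
    "GaussianPeak",
    "fret_efficiency",
    "correct_trace",
    "estimate_gamma",
    "trace_snr",
    "detect_bleach_steps",
    "donor_bleach_frame",
    "filter_traces",
    "build_fret_histogram",
    "fit_histogram",
]


@dataclass(frozen=True)
class DyePairConstants:
    """Dye-pair correction constants and Forster radius.

    chi is the leakage of donor emission into the acceptor channel; gamma
    corrects for unequal quantum yield / detection efficiency between the
    channels; R0 is the distance (Angstrom) at which E = 0.5.
    """

    name: str
    crosstalk: float
    gamma: float
    forster_radius: float
    snr_threshold: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.crosstalk < 1.0):
            raise ValueError("crosstalk must lie in [0, 1)")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")


CY3_CY5 = DyePairConstants("Cy3/Cy5", crosstalk=0.05, gamma=1.0,
                           forster_radius=55.0, snr_threshold=4.0)
CY3_CY7 = DyePairConstants("Cy3/Cy7", crosstalk=0.05, gamma=0.2,
                           forster_radius=40.0, snr_threshold=3.0)


@dataclass
class FretTrace:
    """Paired donor/acceptor intensity series, one immobilized molecule."""

    donor: np.ndarray
    acceptor: np.ndarray
    pair: DyePairConstants
    frame_interval: float = 0.1
    trace_id: str = ""

    def __post_init__(self) -> None:
        d = np.asarray(self.donor, dtype=float)
        a = np.asarray(self.acceptor, dtype=float)
        if d.shape != a.shape or d.ndim != 1:
            raise ValueError("donor and acceptor channels must be equal-length 1-D")
        if self.frame_interval <= 0:
            raise ValueError("frame interval must be positive")
        self.donor, self.acceptor = d, a

    @property
    def n_frames(self) -> int:
        return self.donor.size

    @property
    def total(self) -> np.ndarray:
        return self.donor + self.acceptor


@dataclass
class CorrectedTrace:
    """Per-frame corrected FRET efficiency with a validity mask.

    Frames after the donor photobleach, or where the crosstalk-corrected
    acceptor signal is non-positive, are masked invalid.
    """

    efficiency: np.ndarray
    valid: np.ndarray
    frame_interval: float = 0.1
    trace_id: str = ""

    @property
    def valid_efficiencies(self) -> np.ndarray:
        return self.efficiency[self.valid]


@dataclass
class FilterDecision:
    snr: float
    n_bleach_steps: int
    duration_s: float
    accepted: bool
    reasons: list[str] = field(default_factory=list)
    trace_id: str = ""


@dataclass(frozen=True)
class GaussianPeak:
    center: float
    sd: float
    area: float
    role: str  # "signal" or "noise"


@dataclass
class HistogramFit:
    bin_edges: np.ndarray
    density: np.ndarray
    peaks: list[GaussianPeak]
    rss: float
    converged: bool

    @property
    def signal_peaks(self) -> list[GaussianPeak]:
        return [p for p in self.peaks if p.role == "signal"]


def fret_efficiency(donor: np.ndarray, acceptor: np.ndarray,
                    pair: DyePairConstants) -> tuple[np.ndarray, np.ndarray]:
    """Corrected efficiency E = (1 + gamma * I_D / (I_A - chi * I_D))^-1.

    Returns (E, valid); frames where I_A - chi*I_D <= 0 are invalid and E is
    NaN there.
    """
    donor = np.asarray(donor, dtype=float)
    acceptor = np.asarray(acceptor, dtype=float)
    denom = acceptor - pair.crosstalk * donor
    valid = denom > 0
    e = np.full(donor.shape, np.nan)
    e[valid] = 1.0 / (1.0 + pair.gamma * donor[valid] / denom[valid])
    return e, valid


def correct_trace(trace: FretTrace) -> CorrectedTrace:
    """Corrected efficiency restricted to the pre-donor-bleach window."""
    e, valid = fret_efficiency(trace.donor, trace.acceptor, trace.pair)
    bleach = donor_bleach_frame(trace)
    if bleach is not None:
        valid = valid.copy()
        valid[bleach:] = False
    return CorrectedTrace(efficiency=e, valid=valid,
                          frame_interval=trace.frame_interval,
                          trace_id=trace.trace_id)


def estimate_gamma(trace: FretTrace, bleach_frame: int, window: int = 10) -> float:
    """gamma = dI_A / dI_D across an acceptor photobleach.

    Windowed means ``window`` frames either side of the bleach, excluding the
    step frame itself.
    """
    lo = max(0, bleach_frame - window)
    hi = min(trace.n_frames, bleach_frame + 1 + window)
    if bleach_frame - lo < 2 or hi - (bleach_frame + 1) < 2:
        raise ValueError("not enough frames around the acceptor bleach")
    d_a = np.mean(trace.acceptor[lo:bleach_frame]) - np.mean(trace.acceptor[bleach_frame + 1:hi])
    d_d = np.mean(trace.donor[bleach_frame + 1:hi]) - np.mean(trace.donor[lo:bleach_frame])
    if d_d == 0:
        raise ZeroDivisionError("donor intensity change is zero at the acceptor bleach")
    return d_a / d_d


def trace_snr(trace: FretTrace) -> float:
    """Mean of total intensity before the donor photobleach over its sd."""
    bleach = donor_bleach_frame(trace)
    pre = trace.total[:bleach] if bleach is not None else trace.total
    if pre.size < 2:
        raise ValueError("need at least two pre-bleach frames")
    sd = float(np.std(pre, ddof=1))
    if sd == 0:
        return np.inf
    return float(np.mean(pre)) / sd


def _split_sse(x: np.ndarray) -> tuple[int, float]:
    """Best single change-point by residual SSE of a two-segment mean model."""
    n = x.size
    c1 = np.cumsum(x)
    c2 = np.cumsum(x * x)
    ks = np.arange(1, n)
    left = c2[ks - 1] - c1[ks - 1] ** 2 / ks
    rs1 = c1[-1] - c1[ks - 1]
    rs2 = c2[-1] - c2[ks - 1]
    right = rs2 - rs1**2 / (n - ks)
    sse = left + right
    k = int(np.argmin(sse))
    return ks[k], float(sse[k])


def _segment(x: np.ndarray, min_size: int = 2) -> list[int]:
    """Binary segmentation with BIC stopping; returns sorted change-points."""
    n = x.size
    points: list[int] = []

    def bic(sse: float, n_seg: int) -> float:
        sse = max(sse, 1e-12 * n)
        return n * np.log(sse / n) + 2 * n_seg * np.log(n)

    def recurse(lo: int, hi: int) -> None:
        seg = x[lo:hi]
        if seg.size < 2 * min_size:
            return
        sse0 = float(np.sum((seg - seg.mean()) ** 2))
        k, sse1 = _split_sse(seg)
        if k < min_size or seg.size - k < min_size:
            return
        # accept split if the local two-segment BIC beats one segment
        if bic(sse1, 2) < bic(sse0, 1):
            points.append(lo + k)
            recurse(lo, lo + k)
            recurse(lo + k, hi)

    recurse(0, n)
    return sorted(points)


def detect_bleach_steps(intensity: np.ndarray) -> tuple[list[int], int]:
    """Photobleach steps via piecewise-constant change-point detection.

    A bleach step is an irreversible downward step: the drop exceeds 20% of
    the initial level and no later segment recovers appreciably above the
    post-step level.  Reversible intensity excursions (e.g. donor
    anticorrelation during FRET state transitions) are not counted.  A flat
    trace yields zero steps.
    """
    x = np.asarray(intensity, dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 frames for step detection")
    cps = _segment(x)
    if not cps:
        return [], 0
    bounds = [0, *cps, x.size]
    means = np.array([float(np.mean(x[bounds[i]:bounds[i + 1]]))
                      for i in range(len(bounds) - 1)])
    ref = abs(means[0]) if means[0] != 0 else 1.0
    down = []
    for i, cp in enumerate(cps):
        m0, m1 = means[i], means[i + 1]
        if m0 - m1 <= 0.2 * ref:
            continue
        later = means[i + 2:]
        if later.size and later.max() > m1 + 0.25 * ref:
            continue  # intensity recovers: a state transition, not a bleach
        down.append(cp)
    return down, len(down)


def donor_bleach_frame(trace: FretTrace) -> int | None:
    """First detected downward donor step, or None if the donor never bleaches."""
    if trace.n_frames < 10:
        return None
    steps, n = detect_bleach_steps(trace.donor)
    return steps[0] if n else None


def filter_traces(traces: list[FretTrace],
                  pair: DyePairConstants | None = None,
                  min_duration_s: float = 2.0,
                  ) -> tuple[list[FretTrace], list[FilterDecision]]:
    """Apply the three quality criteria; returns (accepted, decisions).

    A trace passes iff (1) SNR of the pre-bleach total intensity meets the
    dye pair's threshold (4 for Cy3/Cy5, 3 for Cy3/Cy7), (2) the donor trace
    shows exactly one photobleach step, and (3) the pre-bleach window lasts
    at least ``min_duration_s`` seconds.
    """
    accepted: list[FretTrace] = []
    decisions: list[FilterDecision] = []
    for trace in traces:
        p = pair or trace.pair
        reasons: list[str] = []
        try:
            steps, n_steps = detect_bleach_steps(trace.donor)
        except ValueError:
            steps, n_steps = [], 0
        bleach = steps[0] if steps else trace.n_frames
        duration = bleach * trace.frame_interval
        try:
            snr = trace_snr(trace)
        except ValueError:
            snr = 0.0
        if snr < p.snr_threshold:
            reasons.append(f"snr {snr:.2f} < {p.snr_threshold}")
        if n_steps != 1:
            reasons.append(f"donor bleach steps = {n_steps}, need exactly 1")
        if duration < min_duration_s:
            reasons.append(f"pre-bleach duration {duration:.1f} s < {min_duration_s} s")
        ok = not reasons
        decisions.append(FilterDecision(snr=snr, n_bleach_steps=n_steps,
                                        duration_s=duration, accepted=ok,
                                        reasons=reasons, trace_id=trace.trace_id))
        if ok:
            accepted.append(trace)
    return accepted, decisions


def build_fret_histogram(corrected: list[CorrectedTrace], bin_width: float = 0.02,
                         e_range: tuple[float, float] = (-0.2, 1.2),
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Pool valid frames from all traces into a unit-area density histogram."""
    if not corrected:
        raise ValueError("no corrected traces to pool")
    pooled = np.concatenate([c.valid_efficiencies for c in corrected])
    pooled = pooled[np.isfinite(pooled)]
    if pooled.size == 0:
        raise ValueError("no valid frames in any trace")
    n_bins = int(round((e_range[1] - e_range[0]) / bin_width))
    edges = e_range[0] + bin_width * np.arange(n_bins + 1)
    density, _ = np.histogram(pooled, bins=edges, density=True)
    return edges, density


def _mixture_density(x: np.ndarray, params: np.ndarray, n_peaks: int) -> np.ndarray:
    out = np.zeros_like(x)
    for i in range(n_peaks):
        a, mu, sd = params[3 * i:3 * i + 3]
        out += a / (sd * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((x - mu) / sd) ** 2)
    return out


def fit_histogram(bin_edges: np.ndarray, density: np.ndarray,
                  n_signal_peaks: int = 1, include_noise_peak: bool = True,
                  noise_min_sd: float = 0.15) -> HistogramFit:
    """Least-squares Gaussian peaks on a binned FRET density.

    ``n_signal_peaks`` (1 or 2) narrow signal Gaussians plus an optional
    broad noise component constrained to sd >= ``noise_min_sd``.  Peaks are
    returned sorted by center (signal peaks first).
    """
    if n_signal_peaks not in (1, 2):
        raise ValueError("n_signal_peaks must be 1 or 2")
    x = 0.5 * (bin_edges[:-1] + bin_edges[1:])
    y = np.asarray(density, dtype=float)
    n_peaks = n_signal_peaks + int(include_noise_peak)

    # initial guesses: highest-density bins for signal, broad center for noise
    order = np.argsort(y)[::-1]
    centers0 = [x[order[0]]]
    if n_signal_peaks == 2:
        # second init away from the first maximum
        far = order[np.abs(x[order] - centers0[0]) > 0.1]
        centers0.append(x[far[0]] if far.size else centers0[0] + 0.2)
    p0, lo, hi = [], [], []
    for c0 in centers0:
        p0 += [0.5, c0, 0.05]
        lo += [0.0, x[0], 0.01]
        hi += [np.inf, x[-1], 0.3]
    if include_noise_peak:
        p0 += [0.2, 0.5, 0.3]
        lo += [0.0, x[0], noise_min_sd]
        hi += [np.inf, x[-1], 2.0]

    def resid(p: np.ndarray) -> np.ndarray:
        return _mixture_density(x, p, n_peaks) - y

    sol = least_squares(resid, p0, bounds=(lo, hi))
    peaks = []
    for i in range(n_peaks):
        a, mu, sd = sol.x[3 * i:3 * i + 3]
        role = "noise" if (include_noise_peak and i == n_peaks - 1) else "signal"
        peaks.append(GaussianPeak(center=float(mu), sd=float(sd),
                                  area=float(a), role=role))
    peaks.sort(key=lambda p: (p.role != "signal", p.center))
    return HistogramFit(bin_edges=np.asarray(bin_edges), density=y, peaks=peaks,
                        rss=float(2 * sol.cost), converged=bool(sol.success))
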