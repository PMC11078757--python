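"""Two-state hidden-Markov kinetics of corrected FRET traces.

Each trace is modelled as a two-state Markov chain with Gaussian emissions
(low- and high-FRET states), fitted per trace by Baum-Welch EM and decoded
by Viterbi.  Dwell times are maximal constant-state runs; first and last
runs are censored (the entry/exit times are not observed).  Dwell-time
distributions are summarized by least-squares fits of the empirical survival
curve to mono- or bi-exponential decays, the field's "cumulative frequency
count" convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .traces import CorrectedTrace, GaussianPeak, build_fret_histogram, fit_histogram

__all__ = [
    "TwoStateHmm",
    "StatePath",
    "Dwell",
    "DwellSet",
    "ExpFit",
    "TitrationPoint",
    "TitrationSummary",
    "fit_two_state_hmm",
    "select_transitioning",
    "extract_dwells",
    "pool_dwells",
    "fit_dwell_exponential",
    "dwell_mle_mean",
    "gdp_titration_summary",
]

LOW, HIGH = 0, 1


@dataclass
class TwoStateHmm:
    """Gaussian-emission two-state HMM; state 0 is low-FRET, state 1 high."""

    means: np.ndarray           # [2], ordered low < high
    sds: np.ndarray             # [2]
    transition: np.ndarray      # [2, 2] per-frame transition probabilities
    initial: np.ndarray         # [2]
    log_likelihood: float
    n_iter: int
    converged: bool
    degenerate: bool = False


@dataclass
class StatePath:
    """Frame-wise Viterbi state labels for one trace."""

    states: np.ndarray          # int array of LOW/HIGH
    frame_interval: float
    trace_id: str = ""

    @property
    def n_transitions(self) -> int:
        return int(np.count_nonzero(np.diff(self.states)))


@dataclass(frozen=True)
class Dwell:
    state: int
    duration_s: float
    censored: bool


@dataclass
class DwellSet:
    dwells: list[Dwell]
    frame_interval: float

    def durations(self, state: int, include_censored: bool = False) -> np.ndarray:
        return np.array([d.duration_s for d in self.dwells
                         if d.state == state and (include_censored or not d.censored)])

    @property
    def total_duration(self) -> float:
        return sum(d.duration_s for d in self.dwells)


@dataclass
class ExpFit:
    """Survival-curve exponential fit, S(t) = sum_i A_i exp(-t / tau_i)."""

    order: int
    amplitudes: np.ndarray
    taus: np.ndarray
    rss: float
    n_points: int

    @property
    def weighted_mean_tau(self) -> float:
        return float(np.sum(self.amplitudes * self.taus) / np.sum(self.amplitudes))

    @property
    def aicc(self) -> float:
        n, k = self.n_points, 2 * self.order
        if n - k - 1 <= 0:
            return np.inf
        return n * np.log(max(self.rss, 1e-300) / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def _emission_loglik(e: np.ndarray, means: np.ndarray, sds: np.ndarray) -> np.ndarray:
    """[n, 2] log emission densities."""
    z = (e[:, None] - means[None, :]) / sds[None, :]
    return -0.5 * z**2 - np.log(sds[None, :]) - 0.5 * np.log(2 * np.pi)


def _forward_backward(logb: np.ndarray, trans: np.ndarray, init: np.ndarray):
    n = logb.shape[0]
    b = np.exp(logb - logb.max(axis=1, keepdims=True))
    alpha = np.empty((n, 2))
    scale = np.empty(n)
    alpha[0] = init * b[0]
    scale[0] = alpha[0].sum()
    alpha[0] /= scale[0]
    for i in range(1, n):
        alpha[i] = (alpha[i - 1] @ trans) * b[i]
        scale[i] = alpha[i].sum()
        alpha[i] /= scale[i]
    beta = np.empty((n, 2))
    beta[-1] = 1.0
    for i in range(n - 2, -1, -1):
        beta[i] = trans @ (b[i + 1] * beta[i + 1]) / scale[i + 1]
    loglik = float(np.sum(np.log(scale)) + np.sum(logb.max(axis=1)))
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    # expected transition counts
    xi = np.zeros((2, 2))
    for i in range(n - 1):
        m = np.outer(alpha[i], b[i + 1] * beta[i + 1]) * trans / scale[i + 1]
        xi += m
    return gamma, xi, loglik


def fit_two_state_hmm(trace: CorrectedTrace, seed: int = 0,
                      max_iter: int = 500, tol: float = 1e-6,
                      min_sd: float = 1e-4,
                      ) -> tuple[TwoStateHmm, StatePath]:
    """Baum-Welch EM then Viterbi decoding on the valid frames of one trace.

    Means are initialized at the 25th/75th percentiles of the efficiencies
    and the sds at half the interquartile range; EM runs until the
    log-likelihood improves by less than ``tol`` or ``max_iter`` sweeps.
    A trace whose two emission means collapse is flagged degenerate.
    """
    e = trace.valid_efficiencies
    e = e[np.isfinite(e)]
    if e.size < 20:
        raise ValueError("need at least 20 valid frames for HMM fitting")
    q25, q75 = np.percentile(e, [25, 75])
    means = np.array([q25, q75], dtype=float)
    iqr = max(q75 - q25, 1e-3)
    sds = np.full(2, max(iqr / 2, min_sd))
    trans = np.array([[0.9, 0.1], [0.1, 0.9]])
    init = np.array([0.5, 0.5])

    loglik_prev = -np.inf
    loglik = -np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        logb = _emission_loglik(e, means, sds)
        gamma, xi, loglik = _forward_backward(logb, trans, init)
        # M step
        w = gamma.sum(axis=0)
        means = (gamma * e[:, None]).sum(axis=0) / w
        sds = np.sqrt(((gamma * (e[:, None] - means[None, :]) ** 2).sum(axis=0)) / w)
        sds = np.maximum(sds, min_sd)
        rows = xi.sum(axis=1, keepdims=True)
        if np.all(rows > 0):
            trans = xi / rows
        init = gamma[0]
        if loglik - loglik_prev < tol and n_iter > 1:
            break
        loglik_prev = loglik

    # order states low < high
    if means[0] > means[1]:
        means, sds = means[::-1].copy(), sds[::-1].copy()
        trans = trans[::-1, ::-1].copy()
        init = init[::-1].copy()

    degenerate = abs(means[1] - means[0]) < 0.02
    hmm = TwoStateHmm(means=means, sds=sds, transition=trans, initial=init,
                      log_likelihood=loglik, n_iter=n_iter,
                      converged=n_iter < max_iter, degenerate=degenerate)
    path = _viterbi(e, hmm, trace)
    return hmm, path


def _viterbi(e: np.ndarray, hmm: TwoStateHmm, trace: CorrectedTrace) -> StatePath:
    logb = _emission_loglik(e, hmm.means, hmm.sds)
    log_trans = np.log(np.maximum(hmm.transition, 1e-300))
    log_init = np.log(np.maximum(hmm.initial, 1e-300))
    n = e.size
    delta = np.empty((n, 2))
    psi = np.zeros((n, 2), dtype=int)
    delta[0] = log_init + logb[0]
    for i in range(1, n):
        trans_scores = delta[i - 1][:, None] + log_trans
        psi[i] = np.argmax(trans_scores, axis=0)
        delta[i] = trans_scores[psi[i], [0, 1]] + logb[i]
    states = np.empty(n, dtype=int)
    states[-1] = int(np.argmax(delta[-1]))
    for i in range(n - 2, -1, -1):
        states[i] = psi[i + 1, states[i + 1]]
    return StatePath(states=states, frame_interval=trace.frame_interval,
                     trace_id=trace.trace_id)


def select_transitioning(paths: list[StatePath]) -> list[StatePath]:
    """Keep only traces with at least one low/high transition."""
    return [p for p in paths if p.n_transitions >= 1]


def extract_dwells(path: StatePath, frame_interval: float | None = None) -> DwellSet:
    """Maximal constant-state runs in seconds; boundary runs flagged censored."""
    if path.states.size == 0:
        raise ValueError("empty state path")
    dt = frame_interval if frame_interval is not None else path.frame_interval
    s = path.states
    change = np.flatnonzero(np.diff(s)) + 1
    bounds = np.concatenate([[0], change, [s.size]])
    dwells = []
    n_runs = bounds.size - 1
    for i in range(n_runs):
        lo, hi = bounds[i], bounds[i + 1]
        dwells.append(Dwell(state=int(s[lo]), duration_s=float((hi - lo) * dt),
                            censored=(i == 0 or i == n_runs - 1)))
    return DwellSet(dwells=dwells, frame_interval=dt)


def pool_dwells(dwell_sets: list[DwellSet]) -> DwellSet:
    """Pool dwells across traces; never merges runs across trace boundaries."""
    if not dwell_sets:
        raise ValueError("no dwell sets to pool")
    dt = dwell_sets[0].frame_interval
    return DwellSet(dwells=[d for ds in dwell_sets for d in ds.dwells],
                    frame_interval=dt)


def _survival(durations: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    t = np.sort(durations)
    n = t.size
    s = 1.0 - np.arange(n) / n  # S(t_i-) = fraction with duration >= t_i
    return t, s


def fit_dwell_exponential(dwells: DwellSet, state: int, order: int = 1,
                          min_counts: tuple[int, int] = (30, 100)) -> ExpFit:
    """Least-squares fit of the empirical survival curve of uncensored dwells.

    order 1: S(t) = A exp(-t/tau); order 2: sum of two exponentials with the
    weighted-average time constant reported via ``weighted_mean_tau``.
    Requires at least 30 (order 1) / 100 (order 2) uncensored dwells.
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    durations = dwells.durations(state)
    need = min_counts[order - 1]
    if durations.size < need:
        raise ValueError(
            f"need at least {need} uncensored dwells for order {order}, "
            f"got {durations.size}")
    t, s = _survival(durations)
    tbar = float(np.mean(durations))

    if order == 1:
        p0 = [1.0, tbar]
        lo, hi = [0.0, 1e-6], [np.inf, np.inf]
    else:
        p0 = [0.5, tbar / 2, 0.5, tbar * 2]
        lo, hi = [0.0, 1e-6, 0.0, 1e-6], [np.inf, np.inf, np.inf, np.inf]

    def resid(p: np.ndarray) -> np.ndarray:
        model = np.zeros_like(t)
        for i in range(order):
            model = model + p[2 * i] * np.exp(-t / p[2 * i + 1])
        return model - s

    sol = least_squares(resid, p0, bounds=(lo, hi))
    amps = sol.x[0::2]
    taus = sol.x[1::2]
    idx = np.argsort(taus)
    return ExpFit(order=order, amplitudes=amps[idx], taus=taus[idx],
                  rss=float(2 * sol.cost), n_points=t.size)


def dwell_mle_mean(dwells: DwellSet, state: int) -> float:
    """Maximum-likelihood exponential mean of the uncensored dwells."""
    d = dwells.durations(state)
    if d.size == 0:
        raise ValueError("no uncensored dwells")
    return float(np.mean(d))


@dataclass
class TitrationPoint:
    gdp_um: float
    low_center: float | None
    low_area: float | None
    high_dwell_tau: float | None
    low_dwell_tau: float | None
    n_traces: int
    missing: list[str] = field(default_factory=list)


@dataclass
class TitrationSummary:
    points: list[TitrationPoint]

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([p.gdp_um for p in self.points])

    @property
    def low_areas(self) -> np.ndarray:
        return np.array([np.nan if p.low_area is None else p.low_area
                         for p in self.points])

    @property
    def low_centers(self) -> np.ndarray:
        return np.array([np.nan if p.low_center is None else p.low_center
                         for p in self.points])


def low_state_center(corrected: list[CorrectedTrace], paths: list[StatePath],
                     bin_width: float = 0.02) -> float:
    """Gaussian-fitted center of the HMM-assigned low-FRET frames."""
    low_e = []
    for c, p in zip(corrected, paths):
        e = c.valid_efficiencies
        e = e[np.isfinite(e)]
        low_e.append(e[p.states == LOW])
    pooled = np.concatenate(low_e)
    if pooled.size < 50:
        raise ValueError("too few low-state frames for a Gaussian fit")
    fake = CorrectedTrace(efficiency=pooled, valid=np.ones(pooled.size, bool))
    edges, density = build_fret_histogram([fake], bin_width=bin_width)
    fit = fit_histogram(edges, density, n_signal_peaks=1, include_noise_peak=False)
    return fit.signal_peaks[0].center


def gdp_titration_summary(condition_runs: dict[float, list[CorrectedTrace]],
                          seed: int = 0, dwell_orders: tuple[int, int] = (1, 2),
                          ) -> TitrationSummary:
    """Per-GDP-concentration summary of the receptor/G-protein binding cycle.

    For each concentration: decode every trace with the two-state HMM, keep
    transitioning traces, report (a) the low-FRET center from a Gaussian fit
    of HMM-assigned low frames, (b) the low-FRET peak area from a
    two-signal-plus-noise histogram fit of all frames, and (c) high/low dwell
    time constants (mono-/bi-exponential survival fits).  Missing quantities
    at a concentration are flagged, never silently dropped.
    """
    points = []
    for gdp in sorted(condition_runs):
        traces = condition_runs[gdp]
        missing: list[str] = []
        paths, kept_traces = [], []
        for i, c in enumerate(traces):
            try:
                hmm, path = fit_two_state_hmm(c, seed=seed + i)
            except ValueError:
                continue
            if hmm.degenerate:
                continue
            paths.append(path)
            kept_traces.append(c)
        trans_idx = [i for i, p in enumerate(paths) if p.n_transitions >= 1]
        sel_paths = [paths[i] for i in trans_idx]
        sel_traces = [kept_traces[i] for i in trans_idx]

        low_center = low_area = high_tau = low_tau = None
        if sel_paths:
            try:
                low_center = low_state_center(sel_traces, sel_paths)
            except ValueError:
                missing.append("low_center")
            try:
                edges, density = build_fret_histogram(sel_traces)
                hfit = fit_histogram(edges, density, n_signal_peaks=2,
                                     include_noise_peak=True)
                low_area = hfit.signal_peaks[0].area
            except ValueError:
                missing.append("low_area")
            dwells = pool_dwells([extract_dwells(p) for p in sel_paths])
            try:
                high_tau = fit_dwell_exponential(dwells, HIGH,
                                                 order=dwell_orders[0]).weighted_mean_tau
            except ValueError:
                missing.append("high_dwell_tau")
            try:
                low_tau = fit_dwell_exponential(dwells, LOW,
                                                order=dwell_orders[1]).weighted_mean_tau
            except ValueError:
                missing.append("low_dwell_tau")
        else:
            missing += ["low_center", "low_area", "high_dwell_tau", "low_dwell_tau"]
        points.append(TitrationPoint(gdp_um=gdp, low_center=low_center,
                                     low_area=low_area, high_dwell_tau=high_tau,
                                     low_dwell_tau=low_tau,
                                     n_traces=len(sel_paths), missing=missing))
    return TitrationSummary(points=points)
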