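"""Synthetic DEER datasets and smFRET trajectories with known ground truth.

The generators encode the study conditions this package is built around: a
six-component TM4-TM6 distance ensemble (components near 26/33/39/43/45/57
Angstrom) observed across 30 ligand/transducer conditions, and two-state
FRET trajectories in which slow (>100 ms) conformational exchange is
superimposed on fast (<100 ms) sub-state averaging, with donor->acceptor
crosstalk, a detection-efficiency gamma factor and single-step donor
photobleaching.

Random-stream layout: every generator derives one independent substream per
dataset/trace from the master seed (``numpy.random.SeedSequence.spawn``), so
increasing ``n_traces`` never perturbs previously generated traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .deer.forward import (
    DipolarSignal,
    DistanceAxis,
    GaussianComponent,
    MixtureModel,
    TimeAxis,
    default_distance_axis,
    default_time_axis,
    dipolar_kernel,
    forward_signal,
)
from .fret.traces import CY3_CY5, CY3_CY7, DyePairConstants, FretTrace

__all__ = [
    "EnsembleFixture",
    "FretState",
    "FretKineticScheme",
    "reference_ensemble",
    "simulate_deer_dataset",
    "simulate_fret_traces",
    "forster_efficiency",
    "load_fret_scheme",
    "gdp_titration_schemes",
    "REFERENCE_CENTERS",
    "REFERENCE_WIDTHS",
]

# Six-component ground truth: centers as reported for the TM4-TM6 ensemble;
# the 39/43 A widths are the reported 3.8/2 A pair.  The remaining widths are
# fixture choices: the inactive components are broad conformational
# ensembles, while the oligomeric/nonfunctional peaks at 45 and 57 A are
# kept narrow enough to be separable from the 43 A peak, mirroring the
# distinct long-distance peaks the six-component model resolves.
REFERENCE_CENTERS = np.array([26.0, 33.0, 39.0, 43.0, 45.0, 57.0])
REFERENCE_WIDTHS = np.array([5.0, 4.0, 3.8, 2.0, 2.5, 4.0])
REFERENCE_CONCENTRATIONS = {"ligand_only": 60.0, "Gi": 90.0, "barr1": 120.0}


@dataclass
class EnsembleFixture:
    """Ground-truth global mixture across conditions, for DEER simulation."""

    centers: np.ndarray
    widths: np.ndarray
    table: pd.DataFrame            # rows: condition, ligand, group, p*, modulation_depth
    concentrations: dict[str, float]
    noise_sd: float = 0.003

    def __post_init__(self) -> None:
        pop = self.population_matrix()
        if np.any(pop < 0) or not np.allclose(pop.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("fixture populations must be nonnegative rows summing to 1")

    @property
    def conditions(self) -> list[str]:
        return list(self.table["condition"])

    def population_matrix(self) -> np.ndarray:
        cols = [c for c in self.table.columns if c.startswith("p")]
        return self.table[cols].to_numpy(dtype=float)

    def to_mixture_model(self) -> MixtureModel:
        pops = self.population_matrix()
        return MixtureModel(
            components=[GaussianComponent(c, w)
                        for c, w in zip(self.centers, self.widths)],
            populations={cond: pops[i] for i, cond in enumerate(self.conditions)},
            modulation_depths=dict(zip(self.table["condition"],
                                       self.table["modulation_depth"].astype(float))),
            concentrations=dict(self.concentrations),
            condition_groups=dict(zip(self.table["condition"], self.table["group"])),
        )


def reference_ensemble(noise_sd: float = 0.003) -> EnsembleFixture:
    """The shipped 30-condition fixture (10 ligands x 3 transducer groups).

    Per-condition populations are synthetic stand-ins shaped by the reported
    narrative (antagonist mostly inactive, reference full agonist with a 25%
    summed active population, super-efficacy agonists mostly active,
    G protein boosting the active components); they live in an editable CSV.
    """
    with resources.files("deerfret.data").joinpath(
            "reference_populations.csv").open() as fh:
        table = pd.read_csv(fh)
    return EnsembleFixture(centers=REFERENCE_CENTERS.copy(),
                           widths=REFERENCE_WIDTHS.copy(),
                           table=table,
                           concentrations=dict(REFERENCE_CONCENTRATIONS),
                           noise_sd=noise_sd)


def simulate_deer_dataset(fixture: EnsembleFixture,
                          time: TimeAxis | None = None,
                          dist: DistanceAxis | None = None,
                          seed: int = 0) -> list[DipolarSignal]:
    """One noisy dipolar trace per fixture condition, reproducible per seed."""
    time = time or default_time_axis()
    dist = dist or default_distance_axis()
    model = fixture.to_mixture_model()
    kernel = dipolar_kernel(time, dist)
    streams = np.random.SeedSequence(seed).spawn(len(fixture.conditions))
    out = []
    for cond, ss in zip(fixture.conditions, streams):
        clean = forward_signal(model, cond, time, dist, kernel=kernel)
        rng = np.random.default_rng(ss)
        noisy = clean.amplitude + rng.normal(0.0, fixture.noise_sd, len(time)) \
            if fixture.noise_sd > 0 else clean.amplitude
        out.append(DipolarSignal(time=time, amplitude=noisy, condition=cond,
                                 group=model.condition_groups[cond],
                                 noise_sd=fixture.noise_sd))
    return out


# ---------------------------------------------------------------------------
# smFRET trajectory simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FretState:
    """A slow conformational state; its observed mean FRET efficiency.

    If fast sub-states are given (list of (E, population) with an exchange
    rate much faster than the frame rate), the observed efficiency is their
    within-frame time average, simulated at fine time resolution.
    """

    name: str
    mean_e: float
    substates: tuple[tuple[float, float], ...] = ()
    substate_exchange_rate: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.mean_e <= 1.0):
            raise ValueError("state mean E must lie in [0, 1]")
        if self.substates:
            pops = sum(p for _, p in self.substates)
            if abs(pops - 1.0) > 1e-9:
                raise ValueError("substate populations must sum to 1")


@dataclass
class FretKineticScheme:
    """Generative scheme for two-state (or static) FRET trajectories.

    ``exit_rates`` are the slow interconversion rates out of each state in
    s^-1 (ignored for a single state).  ``photobleach_rate`` is the per-frame
    donor bleach probability; ``scale`` the total emission intensity in
    arbitrary units; ``noise_scale`` multiplies the shot-like Gaussian noise
    sd sqrt(scale * channel_fraction) (0 switches noise off).
    """

    states: list[FretState]
    exit_rates: tuple[float, ...] = ()
    photobleach_rate: float = 0.006
    scale: float = 1000.0
    noise_scale: float = 1.0
    pair: DyePairConstants = CY3_CY5
    name: str = ""

    def __post_init__(self) -> None:
        if not 1 <= len(self.states) <= 2:
            raise ValueError("scheme supports one or two slow states")
        if len(self.states) == 2:
            if len(self.exit_rates) != 2 or any(r < 0 for r in self.exit_rates):
                raise ValueError("two-state scheme needs two nonnegative exit rates")


def _slow_state_path(scheme: FretKineticScheme, n_frames: int,
                     frame_interval: float, rng: np.random.Generator) -> np.ndarray:
    """Frame-sampled continuous-time two-state trajectory (state at frame midpoint)."""
    if len(scheme.states) == 1:
        return np.zeros(n_frames, dtype=int)
    k = np.asarray(scheme.exit_rates, dtype=float)
    occ = k[::-1] / k.sum() if k.sum() > 0 else np.array([0.5, 0.5])
    state = int(rng.random() < occ[1])
    t_total = n_frames * frame_interval
    jumps = []
    t = 0.0
    s = state
    while t < t_total:
        rate = k[s]
        t += np.inf if rate == 0 else rng.exponential(1.0 / rate)
        jumps.append(t)
        s = 1 - s
    mid = (np.arange(n_frames) + 0.5) * frame_interval
    n_jumps_before = np.searchsorted(jumps, mid)
    return (state + n_jumps_before) % 2


def _frame_efficiency(state: FretState, n_frames: int, frame_interval: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Per-frame true E for frames spent in one slow state."""
    if not state.substates or state.substate_exchange_rate <= 0:
        return np.full(n_frames, state.mean_e)
    # fine-grained two-substate averaging within each frame
    es = np.array([e for e, _ in state.substates])
    pops = np.array([p for _, p in state.substates])
    if es.size != 2:
        raise ValueError("fast averaging implemented for two sub-states")
    n_sub = 50
    dt = frame_interval / n_sub
    k_tot = state.substate_exchange_rate
    k01, k10 = k_tot * pops[1], k_tot * pops[0]
    p_stay0 = np.exp(-k01 * dt)
    p_stay1 = np.exp(-k10 * dt)
    s = int(rng.random() < pops[1])
    occ = np.empty(n_frames)
    for f in range(n_frames):
        acc = 0.0
        for _ in range(n_sub):
            acc += es[s]
            stay = p_stay0 if s == 0 else p_stay1
            if rng.random() > stay:
                s = 1 - s
        occ[f] = acc / n_sub
    return occ


def simulate_fret_traces(scheme: FretKineticScheme, n_traces: int, n_frames: int,
                         frame_interval: float = 0.1, seed: int = 0,
                         ) -> list[FretTrace]:
    """Donor/acceptor trajectories built so the standard corrections invert them.

    Clean intensities: I_D = scale * (1 - E), I_A = gamma * scale * E +
    chi * I_D, so ``fret_efficiency`` with the scheme's pair constants
    recovers the true E exactly at zero noise.  The donor bleaches in a
    single step at a geometrically distributed frame; both channels drop to
    baseline noise afterwards.
    """
    if n_traces < 1 or n_frames < 1:
        raise ValueError("need at least one trace and one frame")
    pair = scheme.pair
    streams = np.random.SeedSequence(seed).spawn(n_traces)
    traces = []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        slow = _slow_state_path(scheme, n_frames, frame_interval, rng)
        e_true = np.empty(n_frames)
        for s_idx, state in enumerate(scheme.states):
            mask = slow == s_idx
            if mask.any():
                e_true[mask] = _frame_efficiency(state, int(mask.sum()),
                                                 frame_interval, rng)
        if scheme.photobleach_rate > 0:
            bleach = int(rng.geometric(scheme.photobleach_rate))
        else:
            bleach = n_frames + 1
        S = scheme.scale
        i_d = S * (1.0 - e_true)
        i_a = pair.gamma * S * e_true + pair.crosstalk * i_d
        if bleach <= n_frames:
            i_d[bleach:] = 0.0
            i_a[bleach:] = 0.0
        if scheme.noise_scale > 0:
            sd_d = scheme.noise_scale * np.sqrt(np.maximum(i_d, 0.05 * S))
            sd_a = scheme.noise_scale * np.sqrt(np.maximum(i_a, 0.05 * S))
            i_d = i_d + rng.normal(0.0, 1.0, n_frames) * sd_d
            i_a = i_a + rng.normal(0.0, 1.0, n_frames) * sd_a
        traces.append(FretTrace(donor=i_d, acceptor=i_a, pair=pair,
                                frame_interval=frame_interval,
                                trace_id=f"{scheme.name or 'trace'}_{i:04d}"))
    return traces


def forster_efficiency(r: float | np.ndarray, r0: float) -> float | np.ndarray:
    """Forster law E = 1 / (1 + (r / R0)^6); r, R0 in Angstrom."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0) or r0 <= 0:
        raise ValueError("distances and Forster radius must be positive")
    e = 1.0 / (1.0 + (r / r0) ** 6)
    return float(e) if e.ndim == 0 else e


# ---------------------------------------------------------------------------
# Named scheme fixtures
# ---------------------------------------------------------------------------

_PAIRS = {"Cy3/Cy5": CY3_CY5, "Cy3/Cy7": CY3_CY7}


def load_fret_scheme(name: str) -> FretKineticScheme:
    """Load a named generative scheme from the shipped fixture file.

    Available: antagonist_cy3cy5 (time-averaged inactive, E 0.89),
    agonist_cy3cy5 (reference full agonist, E 0.77), cy3cy7_slow_exchange
    (two resolvable states, high at 0.8), ternary_nucleotide_free (low-FRET
    complex at 0.5) and ternary_gdp_saturated (low-FRET complex at 0.6).
    """
    with resources.files("deerfret.data").joinpath("fret_schemes.yaml").open() as fh:
        raw = yaml.safe_load(fh)
    if name not in raw:
        raise KeyError(f"unknown scheme {name!r}; available: {sorted(raw)}")
    return scheme_from_dict(raw[name], name=name)


def scheme_from_dict(cfg: dict, name: str = "") -> FretKineticScheme:
    states = [FretState(name=s.get("name", f"state{i}"), mean_e=float(s["mean_e"]),
                        substates=tuple(tuple(x) for x in s.get("substates", ())),
                        substate_exchange_rate=float(s.get("substate_exchange_rate", 0)))
              for i, s in enumerate(cfg["states"])]
    return FretKineticScheme(
        states=states,
        exit_rates=tuple(cfg.get("exit_rates", ())),
        photobleach_rate=float(cfg.get("photobleach_rate", 0.006)),
        scale=float(cfg.get("scale", 1000.0)),
        noise_scale=float(cfg.get("noise_scale", 1.0)),
        pair=_PAIRS[cfg.get("pair", "Cy3/Cy5")],
        name=name or cfg.get("name", ""),
    )


def gdp_titration_schemes(concentrations_um: list[float],
                          k_half_um: float = 50.0) -> dict[float, FretKineticScheme]:
    """GDP-dependent variants of the receptor/G-protein binding scheme.

    GDP destabilizes the bound (low-FRET) complex: the low->high exit rate
    grows with concentration, so low-state occupancy (histogram area) falls
    monotonically.  The low-FRET center shifts from 0.5 (nucleotide-free)
    toward 0.6 (GDP-bound) with a hyperbolic saturation at ``k_half_um``.
    """
    out = {}
    for c in concentrations_um:
        if c < 0:
            raise ValueError("GDP concentrations must be non-negative")
        frac = c / (c + k_half_um)
        low_e = 0.5 + 0.1 * frac
        k_low_exit = 0.3 * (1.0 + 3.0 * frac)
        out[c] = FretKineticScheme(
            states=[FretState("bound_low", low_e),
                    FretState("unbound_high", 0.77)],
            exit_rates=(k_low_exit, 0.5),
            photobleach_rate=0.004,
            pair=CY3_CY5,
            name=f"gdp_{c:g}uM",
        )
    return out
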