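"""Forward physics of the four-pulse DEER experiment.

A distance ensemble P(r) between two nitroxide spin labels modulates the
refocused echo through the powder-averaged dipolar kernel; an intermolecular
background multiplies the intramolecular form factor.  The full time-domain
model is

    V(t) = (1 - lambda + lambda * (K @ P) * dr) * B(t)

with modulation depth ``lambda`` (fraction of pumped spin pairs) and a 3-D
homogeneous exponential background B(t) whose rate scales with spin
concentration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import fresnel

# Nitroxide dipolar constant, MHz * nm^3 (community-standard value).
DIPOLAR_CONSTANT_MHZ_NM3 = 52.04

# Background rate per (uM of spins * unit modulation depth), us^-1.
BACKGROUND_RATE_PER_UM = 2.0e-4

__all__ = [
    "TimeAxis",
    "DistanceAxis",
    "GaussianComponent",
    "MixtureModel",
    "DipolarSignal",
    "dipolar_kernel",
    "evaluate_mixture",
    "background_decay",
    "forward_signal",
    "default_time_axis",
    "default_distance_axis",
]


@dataclass(frozen=True)
class TimeAxis:
    """Dipolar evolution times in microseconds, uniform, starting at zero."""

    t: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        if t.ndim != 1 or t.size < 2:
            raise ValueError("time axis needs at least two points")
        if abs(t[0]) > 1e-12:
            raise ValueError("time axis must start at t = 0")
        steps = np.diff(t)
        if np.any(steps <= 0):
            raise ValueError("time axis must be strictly increasing")
        if np.ptp(steps) > 1e-9:
            raise ValueError("time axis must be uniformly spaced")
        object.__setattr__(self, "t", t)

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def t_max(self) -> float:
        return float(self.t[-1])

    def __len__(self) -> int:
        return self.t.size


@dataclass(frozen=True)
class DistanceAxis:
    """Spin-spin distance grid in Angstrom."""

    r: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        if r.ndim != 1 or r.size < 2:
            raise ValueError("distance axis needs at least two points")
        if np.any(np.diff(r) <= 0):
            raise ValueError("distance axis must be strictly increasing")
        if r[0] < 15.0 or r[-1] > 110.0:
            raise ValueError("distance axis must lie within 15-110 Angstrom")
        object.__setattr__(self, "r", r)

    @property
    def r_min(self) -> float:
        return float(self.r[0])

    @property
    def r_max(self) -> float:
        return float(self.r[-1])

    def __len__(self) -> int:
        return self.r.size


def default_time_axis(t_max: float = 3.4, dt: float = 0.016) -> TimeAxis:
    """Simulation default: 16 ns steps out to ~3.4 us (tau2 minus dead time)."""
    n = int(np.floor(t_max / dt + 1e-9)) + 1
    return TimeAxis(np.arange(n) * dt)


def default_distance_axis(r_min: float = 15.0, r_max: float = 100.0,
                          dr: float = 0.5) -> DistanceAxis:
    n = int(round((r_max - r_min) / dr)) + 1
    return DistanceAxis(r_min + np.arange(n) * dr)


@dataclass(frozen=True)
class GaussianComponent:
    """One Gaussian distance component: center and standard deviation, Angstrom."""

    center: float
    width: float

    def __post_init__(self) -> None:
        if not (20.0 <= self.center <= 100.0):
            raise ValueError(f"center {self.center} outside the 20-100 A fit bounds")
        if not (2.0 <= self.width <= 20.0):
            raise ValueError(f"width {self.width} outside the 2-20 A fit bounds")


@dataclass
class MixtureModel:
    """Global Gaussian components plus per-condition local parameters.

    Components (centers, widths) are shared across all conditions; each
    condition carries its own population vector (sums to one) and modulation
    depth, and each transducer group a common spin concentration in uM.
    """

    components: list[GaussianComponent]
    populations: dict[str, np.ndarray]
    modulation_depths: dict[str, float]
    concentrations: dict[str, float]
    condition_groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        k = len(self.components)
        for cond, w in self.populations.items():
            w = np.asarray(w, dtype=float)
            if w.size != k:
                raise ValueError(f"{cond}: population vector length != {k}")
            if np.any(w < -1e-12):
                raise ValueError(f"{cond}: negative population weight")
            if abs(w.sum() - 1.0) > 1e-9:
                raise ValueError(f"{cond}: populations sum to {w.sum()}, not 1")
            self.populations[cond] = w
        for cond, lam in self.modulation_depths.items():
            if not (0.3 - 1e-9 <= lam <= 0.7 + 1e-9):
                raise ValueError(f"{cond}: modulation depth {lam} outside [0.3, 0.7]")
        for grp, c in self.concentrations.items():
            if not (25.0 - 1e-9 <= c <= 150.0 + 1e-9):
                raise ValueError(f"{grp}: concentration {c} uM outside [25, 150]")
        if not self.condition_groups:
            only = next(iter(self.concentrations))
            self.condition_groups = {c: only for c in self.populations}

    @property
    def conditions(self) -> list[str]:
        return list(self.populations)

    @property
    def n_components(self) -> int:
        return len(self.components)

    def concentration_of(self, condition: str) -> float:
        return self.concentrations[self.condition_groups[condition]]

    def sorted_by_center(self) -> "MixtureModel":
        order = np.argsort([c.center for c in self.components])
        return MixtureModel(
            components=[self.components[i] for i in order],
            populations={c: w[order] for c, w in self.populations.items()},
            modulation_depths=dict(self.modulation_depths),
            concentrations=dict(self.concentrations),
            condition_groups=dict(self.condition_groups),
        )


@dataclass
class DipolarSignal:
    """One normalized DEER time trace (V(0) = 1) with condition metadata."""

    time: TimeAxis
    amplitude: np.ndarray
    condition: str
    group: str = "none"
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        amp = np.asarray(self.amplitude, dtype=float)
        if amp.shape != self.time.t.shape:
            raise ValueError("amplitude length does not match time axis")
        if not np.all(np.isfinite(amp)):
            raise ValueError("amplitude contains non-finite values")
        self.amplitude = amp


def dipolar_frequency(r: np.ndarray) -> np.ndarray:
    """Angular dipolar frequency omega(r) in rad/us for r in Angstrom."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("distances must be positive")
    r_nm = r / 10.0
    return 2.0 * np.pi * DIPOLAR_CONSTANT_MHZ_NM3 / r_nm**3


def _kernel_fresnel(t: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Closed-form powder average via Fresnel integrals.

    int_0^1 cos((1-3x^2) w t) dx
      = sqrt(pi/(6wt)) [C(q) cos(wt) + S(q) sin(wt)],  q = sqrt(6wt/pi)
    """
    w = dipolar_frequency(r)
    wt = np.outer(t, w)
    out = np.ones_like(wt)
    nz = wt > 1e-12
    q = np.sqrt(6.0 * wt[nz] / np.pi)
    s, c = fresnel(q)
    out[nz] = (c * np.cos(wt[nz]) + s * np.sin(wt[nz])) / q
    return out


def _kernel_quadrature(t: np.ndarray, r: np.ndarray, nodes: int) -> np.ndarray:
    """Gauss-Legendre powder average over x = cos(theta) in [0, 1]."""
    x, wq = np.polynomial.legendre.leggauss(nodes)
    x = 0.5 * (x + 1.0)           # map [-1,1] -> [0,1]
    wq = 0.5 * wq
    w = dipolar_frequency(r)
    wt = np.outer(t, w)           # n_t x n_r
    # (1 - 3 x^2) factors enter per quadrature node
    acc = np.zeros_like(wt)
    for xi, wi in zip(1.0 - 3.0 * x**2, wq):
        acc += wi * np.cos(xi * wt)
    return acc


def dipolar_kernel(time: TimeAxis, dist: DistanceAxis, *,
                   method: str = "fresnel", nodes: int = 500) -> np.ndarray:
    """Powder-averaged dipolar kernel K[n_t, n_r].

    K[i, j] = int_0^1 cos((1 - 3 x^2) * omega(r_j) * t_i) dx, so K[0, :] = 1
    and |K| <= 1 everywhere.  ``method`` selects the Fresnel closed form
    (default) or direct Gauss-Legendre quadrature with ``nodes`` nodes.
    """
    t, r = time.t, dist.r
    if method == "fresnel":
        return _kernel_fresnel(t, r)
    if method == "quadrature":
        return _kernel_quadrature(t, r, nodes)
    raise ValueError(f"unknown kernel method: {method!r}")


def gaussian_basis(dist: DistanceAxis, components: list[GaussianComponent]) -> np.ndarray:
    """Matrix [n_r, K] of unit-area Gaussians renormalized on the truncated grid."""
    r = dist.r
    cols = []
    for comp in components:
        g = np.exp(-0.5 * ((r - comp.center) / comp.width) ** 2)
        area = np.trapezoid(g, r)
        if area <= 0:
            raise ValueError("Gaussian component has zero mass on the grid")
        cols.append(g / area)
    return np.column_stack(cols)


def evaluate_mixture(model: MixtureModel, condition: str,
                     dist: DistanceAxis) -> np.ndarray:
    """Distance distribution P(r) (1/Angstrom) for one condition; unit area."""
    if condition not in model.populations:
        raise KeyError(f"unknown condition {condition!r}")
    basis = gaussian_basis(dist, model.components)
    p = basis @ model.populations[condition]
    return p / np.trapezoid(p, dist.r)


def background_decay(time: TimeAxis, concentration: float, lam: float) -> np.ndarray:
    """3-D homogeneous intermolecular background B(t) = exp(-k t).

    The rate k = BACKGROUND_RATE_PER_UM * concentration * lambda (us^-1);
    the same constant is used by the simulator and the fitter.
    """
    if concentration < 0:
        raise ValueError("concentration must be non-negative")
    if not (0.0 <= lam <= 1.0):
        raise ValueError("modulation depth must lie in [0, 1]")
    k = BACKGROUND_RATE_PER_UM * concentration * lam
    return np.exp(-k * time.t)


def form_factor(model: MixtureModel, condition: str, time: TimeAxis,
                dist: DistanceAxis, kernel: np.ndarray | None = None) -> np.ndarray:
    """Intramolecular form factor F(t) = (K @ P) dr before depth scaling."""
    if kernel is None:
        kernel = dipolar_kernel(time, dist)
    p = evaluate_mixture(model, condition, dist)
    return np.trapezoid(kernel * p[None, :], dist.r, axis=1)


def forward_signal(model: MixtureModel, condition: str, time: TimeAxis,
                   dist: DistanceAxis, kernel: np.ndarray | None = None) -> DipolarSignal:
    """Noise-free DEER signal V(t) = (1 - lam + lam * F(t)) * B(t)."""
    lam = model.modulation_depths[condition]
    conc = model.concentration_of(condition)
    f = form_factor(model, condition, time, dist, kernel=kernel)
    b = background_decay(time, conc, lam)
    v = (1.0 - lam + lam * f) * b
    return DipolarSignal(time=time, amplitude=v, condition=condition,
                         group=model.condition_groups[condition])
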