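"""End-to-end orchestration: simulate/load -> fit -> summarize -> serialize.

Each run writes a JSON report (plus CSV tables) into its own output
directory; every report embeds the seed, a hash of the resolved
configuration and the package version, and re-running with the same config
reproduces identical JSON.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _version
from . import io as dfio
from .deer.fit import (
    GlobalFitSpec,
    bootstrap_ci,
    disjunct_intervals,
    global_fit,
    population_correlation,
    select_model,
)
from .deer.forward import DipolarSignal
from .fret.kinetics import (
    HIGH,
    LOW,
    extract_dwells,
    fit_dwell_exponential,
    fit_two_state_hmm,
    pool_dwells,
)
from .fret.traces import (
    build_fret_histogram,
    correct_trace,
    filter_traces,
    fit_histogram,
)

__all__ = ["RunConfig", "run_deer_pipeline", "run_fret_pipeline"]


@dataclass
class RunConfig:
    """Paths, seeds and parameter overrides for one pipeline invocation."""

    out_dir: str
    seed: int = 1
    manifest: str | None = None
    n_components: int | None = None
    k_range: tuple[int, int] = (2, 7)
    n_starts: int = 10
    bootstrap_iters: int = 1000
    reference_map: dict[str, str] = field(default_factory=dict)
    fret_pair: str = "Cy3/Cy5"
    histogram_peaks: int = 1
    extra: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.manifest is not None and not Path(self.manifest).exists():
            raise FileNotFoundError(self.manifest)

    def config_hash(self) -> str:
        # hash the analysis-relevant fields; the output location is not part
        # of the analysis identity
        fields = {k: v for k, v in self.__dict__.items() if k != "out_dir"}
        blob = json.dumps(fields, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _provenance(config: RunConfig) -> dict:
    return {"seed": config.seed, "config_hash": config.config_hash(),
            "package_version": _version}


def _dump(obj: dict, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float) + "\n")


def run_deer_pipeline(config: RunConfig,
                      datasets: list[DipolarSignal] | None = None) -> dict:
    """Global fit -> model selection -> bootstrap -> correlation -> contrasts.

    ``datasets`` may be passed directly (e.g. from the simulator); otherwise
    they are loaded from ``config.manifest``.  Partial stage failures are
    recorded per stage in the report, never silently dropped.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if datasets is None:
        if config.manifest is None:
            raise ValueError("need either datasets or a manifest path")
        datasets = dfio.read_deer_manifest(config.manifest)

    report: dict = {"provenance": _provenance(config), "stages": {}}
    stages = report["stages"]

    # model selection (skipped when a component count is pinned)
    spec = GlobalFitSpec(n_components=config.n_components or config.k_range[0],
                         n_starts=config.n_starts, seed=config.seed)
    if config.n_components is None:
        k_best, table, fits = select_model(datasets, *config.k_range, spec=spec)
        table.to_csv(out / "model_selection.csv", index=False)
        stages["select_model"] = {
            "status": "ok", "k_aicc": k_best, "k_bic": table.attrs["k_bic"],
            "criteria_agree": bool(table.attrs["criteria_agree"])}
        fit = fits[k_best]
    else:
        k_best = config.n_components
        fit = global_fit(datasets, spec)
        stages["select_model"] = {"status": "skipped", "k_fixed": k_best}

    stages["global_fit"] = {
        "status": "ok" if fit.converged else "not_converged",
        "rss": fit.rss, "aicc": fit.aicc, "bic": fit.bic,
        "n_params": fit.n_params,
        "centers": [c.center for c in fit.model.components],
        "widths": [c.width for c in fit.model.components],
        "message": fit.message,
    }

    # bootstrap uncertainty
    try:
        boot = bootstrap_ci(datasets, fit, n_iter=config.bootstrap_iters,
                            seed=config.seed)
        stages["bootstrap"] = {"status": "ok", "n_iter": boot.n_iter}
    except Exception as exc:  # report, do not mask
        boot = None
        stages["bootstrap"] = {"status": "failed", "error": str(exc)}

    # correlation analysis of populations across conditions
    conds = [d.condition for d in datasets]
    pops = np.stack([fit.model.populations[c] for c in conds])
    centers = np.array([c.center for c in fit.model.components])
    try:
        corr = population_correlation(pops, centers=centers)
        stages["correlation"] = {
            "status": "ok",
            "excluded_components": corr.excluded,
            "excluded_centers": [float(centers[i]) for i in corr.excluded]}
    except ValueError as exc:
        corr = None
        stages["correlation"] = {"status": "failed", "error": str(exc)}

    # condition table with significance stars vs. a matched reference
    rows = []
    for cond in conds:
        row = {"condition": cond}
        for j in range(len(centers)):
            row[f"pop_{centers[j]:.0f}A"] = float(pops[conds.index(cond), j])
            if boot is not None:
                lo, hi = boot.populations_ci[cond][j]
                row[f"pop_{centers[j]:.0f}A_lo"] = float(lo)
                row[f"pop_{centers[j]:.0f}A_hi"] = float(hi)
                ref = config.reference_map.get(cond)
                if ref is not None and ref in boot.populations_ci:
                    ref_ci = boot.populations_ci[ref][j]
                    star = disjunct_intervals((lo, hi),
                                              (float(ref_ci[0]), float(ref_ci[1])))
                    row[f"pop_{centers[j]:.0f}A_star"] = "*" if star else ""
        rows.append(row)
    cond_table = pd.DataFrame(rows)
    cond_table.to_csv(out / "condition_table.csv", index=False)

    report["model"] = {
        "k": k_best,
        "centers": [c.center for c in fit.model.components],
        "widths": [c.width for c in fit.model.components],
        "populations": {c: fit.model.populations[c].tolist() for c in conds},
        "modulation_depths": fit.model.modulation_depths,
        "concentrations": fit.model.concentrations,
    }
    _dump(report, out / "deer_report.json")
    return report


def run_fret_pipeline(config: RunConfig, traces=None) -> dict:
    """filter -> correct -> histogram -> HMM -> dwells, with per-stage counts."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if traces is None:
        if config.manifest is None:
            raise ValueError("need either traces or a manifest path")
        traces = dfio.read_fret_traces(config.manifest)

    report: dict = {"provenance": _provenance(config), "stages": {}}
    stages = report["stages"]

    accepted, decisions = filter_traces(traces)
    stages["filter"] = {
        "status": "ok" if accepted else "all_rejected",
        "n_in": len(traces), "n_accepted": len(accepted),
        "n_rejected": len(traces) - len(accepted)}
    if not accepted:
        _dump(report, out / "fret_report.json")
        return report

    corrected = [correct_trace(t) for t in accepted]
    stages["correct"] = {"status": "ok", "n_traces": len(corrected)}

    edges, density = build_fret_histogram(corrected)
    hfit = fit_histogram(edges, density, n_signal_peaks=config.histogram_peaks,
                         include_noise_peak=True)
    pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:],
                  "density": density}).to_csv(out / "fret_histogram.csv", index=False)
    stages["histogram"] = {
        "status": "ok" if hfit.converged else "not_converged",
        "signal_peaks": [{"center": p.center, "sd": p.sd, "area": p.area}
                         for p in hfit.signal_peaks]}

    hmm_paths = []
    n_degenerate = 0
    for i, c in enumerate(corrected):
        try:
            hmm, path = fit_two_state_hmm(c, seed=config.seed + i)
        except ValueError:
            continue
        if hmm.degenerate:
            n_degenerate += 1
            continue
        hmm_paths.append(path)
    transitioning = [p for p in hmm_paths if p.n_transitions >= 1]
    stages["hmm"] = {"status": "ok", "n_fitted": len(hmm_paths),
                     "n_degenerate": n_degenerate,
                     "n_transitioning": len(transitioning)}

    dwell_info: dict = {"status": "skipped"}
    if transitioning:
        dwells = pool_dwells([extract_dwells(p) for p in transitioning])
        dwell_info = {"status": "ok",
                      "n_dwells": len(dwells.dwells)}
        for state, name, order in ((HIGH, "high", 1), (LOW, "low", 2)):
            try:
                efit = fit_dwell_exponential(dwells, state, order=order)
                dwell_info[f"{name}_tau_s"] = efit.weighted_mean_tau
            except ValueError as exc:
                dwell_info[f"{name}_tau_s"] = None
                dwell_info[f"{name}_error"] = str(exc)
    stages["dwells"] = dwell_info

    _dump(report, out / "fret_report.json")
    return report
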