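"""Reproduction reports: the headline MI table, parameter sweeps, exports.

These functions back both the command-line interface and the reproduction
scripts; they only orchestrate the library modules.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .channel import (
    blahut_arimoto,
    build_channel,
    distinguishable_states,
    numerical_mi,
)
from .dynamics import SimulationEnsemble, density_distribution, simulate_population
from .optimal import no_feedback_baseline, optimal_smallnoise_mi, optimal_solution
from .params import QSParameters

__all__ = [
    "RunManifest",
    "table1_report",
    "sweep_report",
    "optimal_curves",
    "trajectory_frames",
    "write_simulation",
]


@dataclass
class RunManifest:
    """Provenance record written next to every command output."""

    command: str
    parameters: dict
    seed: int | None
    grids: dict
    outputs: list[str]
    version: str = __version__
    timestamp: str = field(
        default_factory=lambda: datetime.datetime.now(datetime.UTC).isoformat()
    )

    def write(self, path: Path | str) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                         default=str) + "\n")


def _params_dict(params: QSParameters) -> dict:
    return dataclasses.asdict(params)


def table1_report(
    params: QSParameters | None = None,
    n_rho: int = 512,
    n_m: int = 512,
    truncations: tuple[str, ...] = ("hard", "none"),
    unit_modes: tuple[str, ...] = ("raw", "number_density"),
) -> pd.DataFrame:
    """Numerical MI for {TF, sRNA} x {no feedback, optimal feedback}.

    Reported in every combination of Gaussian truncation mode and unit
    convention, with the implied number of distinguishable density states
    and the per-model information gain.
    """
    if params is None:
        params = QSParameters.table1()
    rows = []
    for units in unit_modes:
        p_u = params.with_(units=units)
        for kind in ("tf", "srna"):
            base = no_feedback_baseline(p_u, kind)
            opt = optimal_solution(p_u, kind)
            for trunc in truncations:
                mi_vals = {}
                for label, maps, stats in (
                    ("no_feedback", base.maps, base.stats),
                    ("optimal_feedback", opt.maps, opt.stats),
                ):
                    ch = build_channel(maps, stats, n_rho=n_rho, n_m=n_m,
                                       truncation=trunc)
                    mi = numerical_mi(ch).value
                    mi_vals[label] = mi
                    lo, hi = distinguishable_states(mi)
                    rows.append({
                        "regulation": kind,
                        "feedback": label,
                        "truncation": trunc,
                        "units": units,
                        "mi_bits": mi,
                        "states_low": lo,
                        "states_high": hi,
                    })
                rows[-1]["delta_bits"] = (
                    mi_vals["optimal_feedback"] - mi_vals["no_feedback"]
                )
                rows[-2]["delta_bits"] = rows[-1]["delta_bits"]
    return pd.DataFrame(rows)


def sweep_report(
    params: QSParameters | None = None,
    b_values: np.ndarray | None = None,
    f_int_plus_values: np.ndarray | None = None,
    kind: str = "srna",
    n_rho: int = 256,
    n_m: int = 256,
    truncation: str = "hard",
    capacity: bool = False,
    ba_tol: float = 1e-4,
    ba_max_iter: int = 100_000,
) -> pd.DataFrame:
    """Optimal MI, no-feedback MI, and their difference over (b, f_int_plus).

    Per-cell failures are recorded (``error`` column) and the sweep continues.
    Blahut-Arimoto capacity per cell is optional because it dominates runtime.
    """
    if params is None:
        params = QSParameters.table1()
    if b_values is None:
        b_values = np.linspace(0.0, 50.0, 16)
    if f_int_plus_values is None:
        f_int_plus_values = np.geomspace(1e-2, 1.0, 16)
    if np.any(np.asarray(f_int_plus_values) > 1.0):
        raise ValueError("sweep is over self-repression: f_int_plus <= 1")

    rows = []
    baseline_cache: dict[float, float] = {}
    for b in b_values:
        for fp in f_int_plus_values:
            cell = {"b": float(b), "f_int_plus": float(fp), "error": ""}
            try:
                p_c = params.with_(b=float(b), f_int_plus=float(fp))
                if float(b) not in baseline_cache:
                    base = no_feedback_baseline(p_c, kind)
                    ch0 = build_channel(base.maps, base.stats, n_rho=n_rho,
                                        n_m=n_m, truncation=truncation)
                    baseline_cache[float(b)] = numerical_mi(ch0).value
                cell["mi_no_feedback"] = baseline_cache[float(b)]
                opt = optimal_solution(p_c, kind)
                ch = build_channel(opt.maps, opt.stats, n_rho=n_rho, n_m=n_m,
                                   truncation=truncation)
                cell["mi_optimal"] = numerical_mi(ch).value
                cell["mi_optimal_smallnoise"] = optimal_smallnoise_mi(
                    p_c, opt.model
                )
                cell["delta_mi"] = cell["mi_optimal"] - cell["mi_no_feedback"]
                if capacity:
                    cell["capacity"] = blahut_arimoto(
                        ch, tol=ba_tol, max_iter=ba_max_iter
                    ).value
            except Exception as exc:  # noqa: BLE001 - sweep must continue
                cell["error"] = f"{type(exc).__name__}: {exc}"
            rows.append(cell)
    return pd.DataFrame(rows)


def optimal_curves(
    params: QSParameters | None = None,
    kind: str = "srna",
    n_points: int = 201,
) -> dict[str, pd.DataFrame]:
    """Tabulated optimal response curves (feedbacks, time courses, Fano)."""
    if params is None:
        params = QSParameters.table1()
    sol = optimal_solution(params, kind)
    m = np.linspace(params.m_minus, params.m_plus, n_points)
    f_minus = sol.f_ext_scale
    fb = pd.DataFrame({
        "m_nM": m,
        "f_int_star": sol.f_int_star(m),
        "f_ext_star_over_f_minus": sol.f_ext_star(m) / f_minus,
    })
    t = np.linspace(0.0, params.T, n_points)
    tc = pd.DataFrame({
        "t_over_T": t / params.T,
        "a_bar_star_nM": sol.a_bar_star(sol.profile.density(t)),
        "m_bar_star_nM": sol.mapping.time_course(t),
    })
    F1 = sol.model.fano(m, extrapolate=True)
    Fs = sol.stats.F_star(m)
    fano = pd.DataFrame({
        "m_nM": m,
        "fano_bare": F1,
        "fano_star": Fs,
        "tau_star_over_tau": Fs / F1,
    })
    return {"feedbacks": fb, "time_courses": tc, "fano": fano}


def trajectory_frames(ens: SimulationEnsemble) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tidy (time, cell, m) trajectories plus the shared (time, a, rho) table."""
    n_t, n_c = ens.m.shape
    cells = pd.DataFrame({
        "time_s": np.repeat(ens.t, n_c),
        "cell_id": np.tile(np.arange(n_c), n_t),
        "m_nM": ens.m.ravel(),
    })
    env = pd.DataFrame({
        "time_s": ens.t,
        "a_nM": ens.a,
        "rho_per_um3": ens.rho,
        "m_det_nM": ens.m_det,
    })
    return cells, env


def write_simulation(
    ens: SimulationEnsemble, out_dir: Path | str, command: str = "simulate"
) -> list[str]:
    """Write trajectory CSVs and a JSON manifest; returns the file list."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cells, env = trajectory_frames(ens)
    paths = [out / "trajectories.csv", out / "environment.csv"]
    cells.to_csv(paths[0], index=False)
    env.to_csv(paths[1], index=False)
    manifest = RunManifest(
        command=command,
        parameters=_params_dict(ens.params),
        seed=ens.seed,
        grids={"dt_s": ens.dt, "n_cells": ens.n_cells, "mode": ens.mode},
        outputs=[str(p) for p in paths],
    )
    manifest.write(out / "manifest.json")
    return [str(p) for p in paths] + [str(out / "manifest.json")]
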