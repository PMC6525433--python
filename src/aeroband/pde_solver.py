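"""Finite-volume integrator for the coupled transport / oxygen equations.

The model couples two hyperbolic advection–reaction equations for right- and
left-moving bacteria,

    dR/dt + v dR/dx = -f_RL R + f_LR L
    dL/dt - v dL/dx = +f_RL R - f_LR L,

to a diffusion–consumption equation for dissolved oxygen,

    dC/dt = D d²C/dx² - K θ(C) B,      B = R + L,

on the capillary [0, S].  Walls reflect swimmers (left-movers reaching x=0
turn right and vice versa), so total bacteria are conserved; oxygen holds the
meniscus value C_o at x=0 and is sealed (zero flux) at x=S, starting from an
oxygen-free capillary.

Discretisation is a first-order conservative upwind finite-volume scheme with
forward-Euler time stepping, integrated dimensionally.  The band feedback loop
re-detects the FWHM band from the current density profile before every
transport update, because the reversal frequency inside the band differs from
outside.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from .band_analysis import BandTrace, detect_band_fwhm
from .core_model import (
    ModelParameters,
    SpatialGrid,
    consumption_gate,
    micromolar_to_percent,
    reversal_frequencies,
)

__all__ = [
    "SimulationState",
    "SimulationResult",
    "SolverInstabilityError",
    "initialize",
    "stable_dt",
    "advect_react_step",
    "diffuse_consume_step",
    "run_simulation",
    "write_snapshots_csv",
    "write_run_metadata",
]

logger = logging.getLogger(__name__)

#: simulated seconds without a qualifying band before a warning is logged
BAND_ABSENT_WARN_S = 30.0


class SolverInstabilityError(RuntimeError):
    """Raised when a step produces NaN or negative densities that adaptive
    time-step halving cannot cure (signals a CFL violation)."""


@dataclass
class SimulationState:
    """Solver state at one instant: per-cell right-movers, left-movers, oxygen.

    ``R`` and ``L`` are densities in cells/ml, ``C`` is dissolved oxygen in μM
    (convert to percent with the Henry factor for reporting and switch logic).
    """

    t: float
    R: np.ndarray
    L: np.ndarray
    C: np.ndarray

    @property
    def B(self) -> np.ndarray:
        """Total bacterial density R + L (derived, never stored)."""
        return self.R + self.L

    def copy(self) -> "SimulationState":
        return SimulationState(self.t, self.R.copy(), self.L.copy(), self.C.copy())


@dataclass
class SimulationResult:
    """Output of :func:`run_simulation`."""

    params: ModelParameters
    grid: SpatialGrid
    snapshots: List[SimulationState]
    band_trace: BandTrace
    mass_history: np.ndarray  # total bacteria (per unit cross-section) at output times
    output_times: np.ndarray
    n_steps: int
    dt_nominal: float
    dt_min_used: float
    conservation_error: float  # max relative deviation of mass from initial

    def snapshot_at(self, t: float) -> SimulationState:
        """Snapshot recorded closest to time ``t``."""
        ts = np.array([s.t for s in self.snapshots])
        return self.snapshots[int(np.argmin(np.abs(ts - t)))]


def initialize(params: ModelParameters, grid: SpatialGrid) -> SimulationState:
    """Initial state: uniform bacteria split 50/50 by direction, no oxygen.

    The capillary is equilibrated under nitrogen before air is applied, so
    C(x,0) = 0 everywhere; bacteria are uniform at B_o.  The even R/L split is
    reaction-neutral at t=0 and any other split with R+L=B_o relaxes quickly.
    """
    half = np.full(grid.n_cells, params.B_o / 2.0)
    return SimulationState(t=0.0, R=half.copy(), L=half.copy(), C=np.zeros(grid.n_cells))


def stable_dt(params: ModelParameters, grid: SpatialGrid, safety: float = 0.9) -> float:
    """Stable explicit time step: ``safety * min(dx/v, dx²/(2D))``.

    The advective bound is the CFL condition for the upwind scheme; the
    diffusive bound is the forward-Euler limit for explicit diffusion.  With
    the base parameters diffusion is binding.  During stepping the step is
    additionally halved and retried if it would drive any density negative.
    """
    if not (0 < safety <= 1):
        raise ValueError(f"safety must be in (0, 1], got {safety}")
    return safety * min(grid.dx / params.v, grid.dx**2 / (2.0 * params.D))


def _advect_upwind(
    R: np.ndarray, L: np.ndarray, v: float, dt: float, grid: SpatialGrid
) -> Tuple[np.ndarray, np.ndarray]:
    """Conservative upwind advection of R (rightward) and L (leftward) with
    reflecting walls: the R flux leaving through x=S feeds L, and the L flux
    leaving through x=0 feeds R."""
    r = v * dt / grid.dx
    Rn = np.empty_like(R)
    Ln = np.empty_like(L)
    # R: flux through interface i+1/2 is v*R[i] (upwind from the left)
    Rn[0] = R[0] + r * (L[0] - R[0])  # inflow at x=0 is the reflected L flux
    Rn[1:] = R[1:] + r * (R[:-1] - R[1:])
    # L: flux through interface i-1/2 is v*L[i] (upwind from the right)
    Ln[-1] = L[-1] + r * (R[-1] - L[-1])  # inflow at x=S is the reflected R flux
    Ln[:-1] = L[:-1] + r * (L[1:] - L[:-1])
    return Rn, Ln


def advect_react_step(
    state: SimulationState,
    band: Optional[Tuple[float, float]],
    params: ModelParameters,
    grid: SpatialGrid,
    dt: float,
) -> Tuple[np.ndarray, np.ndarray]:
    """One forward-Euler transport step: upwind advection then reversal exchange.

    ``band`` is the current FWHM interval (xL, xR) or None; cells whose centers
    lie inside it use the in-band maximum reversal frequency.  Returns the
    updated ``(R, L)``; raises :class:`SolverInstabilityError` on negative
    densities (CFL violation).
    """
    Rn, Ln = _advect_upwind(state.R, state.L, params.v, dt, grid)
    if band is None:
        inside = False
    else:
        inside = (grid.centers >= band[0]) & (grid.centers <= band[1])
    C_pct = micromolar_to_percent(state.C, params.henry_factor)
    f_rl, f_lr = reversal_frequencies(C_pct, params, inside)
    exchange = dt * (f_rl * Rn - f_lr * Ln)
    Rn -= exchange
    Ln += exchange
    if np.any(Rn < 0) or np.any(Ln < 0) or np.any(np.isnan(Rn)) or np.any(np.isnan(Ln)):
        raise SolverInstabilityError(
            f"negative or NaN density after transport step at t={state.t:.4f}s "
            f"(dt={dt:.3e}s): CFL violation"
        )
    return Rn, Ln


def diffuse_consume_step(
    state: SimulationState,
    params: ModelParameters,
    grid: SpatialGrid,
    dt: float,
    B: Optional[np.ndarray] = None,
) -> np.ndarray:
    """One explicit finite-volume step of oxygen diffusion and consumption.

    Dirichlet value C_o (in μM) at the meniscus face x=0, zero flux at the
    sealed end x=S.  Consumption K·θ(C)·B·dt is clamped per cell to the oxygen
    actually available, so C never goes negative.  Returns the updated C.
    """
    C = state.C
    if B is None:
        B = state.B
    dx2 = grid.dx**2
    mu = params.D * dt / dx2
    Cn = np.empty_like(C)
    # boundary face x=0 holds C_o; gradient over the half cell to the first center
    Cn[0] = C[0] + mu * (C[1] - 3.0 * C[0] + 2.0 * params.C_o_uM)
    Cn[1:-1] = C[1:-1] + mu * (C[2:] - 2.0 * C[1:-1] + C[:-2])
    Cn[-1] = C[-1] + mu * (C[-2] - C[-1])  # sealed: no flux through x=S
    demand = params.K * B * dt * consumption_gate(Cn)
    Cn -= np.minimum(demand, np.maximum(Cn, 0.0))
    return Cn


def run_simulation(
    params: ModelParameters,
    grid: SpatialGrid,
    t_end: float,
    output_times: Optional[Sequence[float]] = None,
    *,
    safety: float = 0.9,
    min_peak_ratio: float = 1.5,
    max_halvings: int = 40,
) -> SimulationResult:
    """Integrate the coupled model to ``t_end`` with the band feedback loop.

    Each step: detect the band by FWHM from the current density profile, apply
    the transport update using that band for the in-band frequency override,
    then the oxygen update, then advance time.  The nominal step from
    :func:`stable_dt` is clipped to land exactly on every requested output time
    (snapshots are recorded there) and halved-and-retried if a step would
    produce negative values.  The band trace is recorded at every step.
    """
    if t_end <= 0:
        raise ValueError(f"t_end must be positive, got {t_end}")
    if output_times is None:
        output_times = [0.0, t_end]
    outs = np.unique(np.asarray(list(output_times), dtype=float))
    if outs.size and (outs[0] < 0 or outs[-1] > t_end):
        raise ValueError("output_times must lie within [0, t_end]")

    state = initialize(params, grid)
    dt0 = stable_dt(params, grid, safety)
    logger.info(
        "run: n_cells=%d dx=%.4f μm, dt=%.4e s (advective bound %.4e, diffusive %.4e)",
        grid.n_cells, grid.dx, dt0, grid.dx / params.v, grid.dx**2 / (2 * params.D),
    )

    mass0 = float(np.sum(state.B)) * grid.dx
    snapshots: List[SimulationState] = []
    mass_history: List[float] = []
    tr_t: List[float] = []
    tr_xL: List[float] = []
    tr_xR: List[float] = []
    tr_present: List[bool] = []
    tr_peak: List[float] = []
    max_mass_err = 0.0
    dt_min_used = dt0
    n_steps = 0

    def record_trace(band: Optional[Tuple[float, float]]) -> None:
        tr_t.append(state.t)
        tr_present.append(band is not None)
        tr_xL.append(band[0] if band is not None else np.nan)
        tr_xR.append(band[1] if band is not None else np.nan)
        tr_peak.append(float(state.B.max()) / params.B_o)

    def maybe_snapshot() -> None:
        nonlocal max_mass_err
        if out_idx[0] < outs.size and abs(state.t - outs[out_idx[0]]) <= 1e-9 * max(1.0, t_end):
            snapshots.append(state.copy())
            mass = float(np.sum(state.B)) * grid.dx
            mass_history.append(mass)
            max_mass_err = max(max_mass_err, abs(mass - mass0) / mass0)
            out_idx[0] += 1

    out_idx = [0]
    band = detect_band_fwhm(state.B, grid, min_peak_ratio)
    record_trace(band)
    maybe_snapshot()

    eps = 1e-9 * max(1.0, t_end)
    while state.t < t_end - eps:
        t_next = outs[out_idx[0]] if out_idx[0] < outs.size else t_end
        dt = min(dt0, t_next - state.t, t_end - state.t)
        for attempt in range(max_halvings + 1):
            try:
                R, L = advect_react_step(state, band, params, grid, dt)
            except SolverInstabilityError:
                if attempt == max_halvings:
                    raise
                dt /= 2.0
                continue
            C = diffuse_consume_step(state, params, grid, dt, B=R + L)
            if np.any(np.isnan(C)) or np.any(C < 0):
                if attempt == max_halvings:
                    raise SolverInstabilityError(
                        f"oxygen field unstable at t={state.t:.4f}s (dt={dt:.3e}s)"
                    )
                dt /= 2.0
                continue
            break
        dt_min_used = min(dt_min_used, dt)
        target = state.t + dt
        state.R, state.L, state.C = R, L, C
        # land exactly on scheduled times so readouts need no interpolation in t
        state.t = t_next if abs(target - t_next) <= eps else target
        n_steps += 1
        band = detect_band_fwhm(state.B, grid, min_peak_ratio)
        record_trace(band)
        maybe_snapshot()

    trace = BandTrace(
        times=np.array(tr_t),
        xL=np.array(tr_xL),
        xR=np.array(tr_xR),
        present=np.array(tr_present),
        peak_B_norm=np.array(tr_peak),
    )
    _warn_band_gaps(trace)
    logger.info(
        "run complete: %d steps to t=%.1f s, conservation error %.3e",
        n_steps, state.t, max_mass_err,
    )
    return SimulationResult(
        params=params,
        grid=grid,
        snapshots=snapshots,
        band_trace=trace,
        mass_history=np.array(mass_history),
        output_times=outs,
        n_steps=n_steps,
        dt_nominal=dt0,
        dt_min_used=dt_min_used,
        conservation_error=max_mass_err,
    )


def _warn_band_gaps(trace: BandTrace) -> None:
    """Log a warning if no band qualifies for a contiguous stretch ≥ 30 s."""
    t = trace.times
    absent = ~trace.present
    if not absent.any():
        return
    # longest contiguous absent stretch
    longest = 0.0
    start = None
    for i in range(absent.size):
        if absent[i] and start is None:
            start = t[i]
        elif not absent[i] and start is not None:
            longest = max(longest, t[i - 1] - start)
            start = None
    if start is not None:
        longest = max(longest, t[-1] - start)
    if longest >= BAND_ABSENT_WARN_S:
        logger.warning(
            "band failed to qualify for %.0f s of simulated time", longest
        )


# -- writers ----------------------------------------------------------------


def write_snapshots_csv(result: SimulationResult, path: Union[str, Path]) -> None:
    """Write all snapshots as long-format CSV: (t_s, x_um, R, L, B_norm, C_percent).

    B_norm is B/B_o, matching the usual normalisation of profile plots.
    """
    import pandas as pd

    frames = []
    p = result.params
    for s in result.snapshots:
        frames.append(
            pd.DataFrame(
                {
                    "t_s": s.t,
                    "x_um": result.grid.centers,
                    "R": s.R,
                    "L": s.L,
                    "B_norm": s.B / p.B_o,
                    "C_percent": micromolar_to_percent(s.C, p.henry_factor),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_run_metadata(result: SimulationResult, path: Union[str, Path]) -> None:
    """Write run metadata (parameters, grid, step statistics) as JSON."""
    meta = {
        "params": result.params.to_dict(),
        "grid": {"n_cells": result.grid.n_cells, "dx_um": result.grid.dx, "S_um": result.grid.S},
        "n_steps": result.n_steps,
        "dt_nominal_s": result.dt_nominal,
        "dt_min_used_s": result.dt_min_used,
        "conservation_error": result.conservation_error,
        "output_times_s": list(map(float, result.output_times)),
    }
    Path(path).write_text(json.dumps(meta, indent=2) + "\n")
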