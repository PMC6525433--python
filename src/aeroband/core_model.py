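"""Model parameters, unit conversions, and the reversal-frequency switching law.

The aerotaxis model of *Azospirillum brasilense* tracks right- and left-swimming
cells whose reversal frequency switches between a low value ``F_min`` and a high
value (``F_max`` outside the band, ``F_max_band`` inside it) at four threshold
oxygen concentrations, the "C-switches"::

    C_hat_min < C_min < C_max < C_hat_max

Right-movers reverse at the high frequency when ``C_hat_min < C < C_max``;
left-movers when ``C_min < C < C_hat_max``.  In the overlap window
``(C_min, C_max)`` both directions reverse rapidly, which traps cells there and
forms the aerotactic band.  Outside the detectable range (below ``C_hat_min`` or
above ``C_hat_max``) both frequencies drop to ``F_min``, runs predominate, and
cells leave.

All switch thresholds are stored and compared in percent of air oxygen; dissolved
oxygen in μM appears only in the oxygen PDE and in reporting, via Henry's law
(``henry_factor`` μM per unit fraction of air oxygen, i.e. 13 μM per 1% at the
default factor of 1300).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Union

import numpy as np

__all__ = [
    "ModelParameters",
    "SpatialGrid",
    "percent_to_micromolar",
    "micromolar_to_percent",
    "reversal_frequency_rl",
    "reversal_frequency_lr",
    "reversal_frequencies",
    "consumption_gate",
]


@dataclass(frozen=True)
class ModelParameters:
    """Physical parameters of the band-formation model.

    Defaults are the experimentally determined base values for wild-type
    (Sp7) *A. brasilense*.

    Parameters
    ----------
    B_o : float
        Total bacteria concentration, cells/ml.
    C_o : float
        Oxygen fraction at the meniscus, percent of air oxygen.
    D : float
        Oxygen diffusion coefficient in water, μm²/s.
    K : float
        Per-cell oxygen consumption rate, μM·ml/(s·cell).
    v : float
        Swimming speed, μm/s.
    F_max_band : float
        Maximum reversal frequency inside the band, 1/s.
    F_max : float
        Maximum reversal frequency outside the band, 1/s.
    F_min : float
        Minimum reversal frequency, 1/s.
    C_hat_max, C_max, C_min, C_hat_min : float
        The four C-switches, percent of air oxygen (see module docstring).
    S : float
        Capillary length, μm.
    henry_factor : float
        Dissolved-oxygen conversion, μM per unit fraction of air oxygen.
    """

    B_o: float = 7e8
    C_o: float = 21.0
    D: float = 2000.0
    K: float = 4e-9
    v: float = 20.0
    F_max_band: float = 0.96
    F_max: float = 0.65
    F_min: float = 0.35
    C_hat_max: float = 10.0
    C_max: float = 2.0
    C_min: float = 0.3
    C_hat_min: float = 0.01
    S: float = 5000.0
    henry_factor: float = 1300.0

    def __post_init__(self) -> None:
        if not (self.C_hat_min < self.C_min < self.C_max < self.C_hat_max):
            raise ValueError(
                "switch ordering violated: require "
                f"C_hat_min < C_min < C_max < C_hat_max, got "
                f"{self.C_hat_min} < {self.C_min} < {self.C_max} < {self.C_hat_max}"
            )
        if not (0 < self.F_min <= self.F_max <= self.F_max_band):
            raise ValueError(
                "frequency ordering violated: require 0 < F_min <= F_max <= F_max_band, "
                f"got F_min={self.F_min}, F_max={self.F_max}, F_max_band={self.F_max_band}"
            )
        for name in ("B_o", "C_o", "D", "K", "v", "S", "henry_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive, got {getattr(self, name)}")

    # -- derived quantities -------------------------------------------------

    @property
    def C_o_uM(self) -> float:
        """Dissolved-oxygen boundary value at the meniscus, μM."""
        return percent_to_micromolar(self.C_o, self.henry_factor)

    def replace(self, **changes: float) -> "ModelParameters":
        """Return a copy with the given fields changed (invariants re-checked)."""
        return dataclasses.replace(self, **changes)

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "ModelParameters":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in d.items()})

    def to_json(self, path: Union[str, Path, None] = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: Union[str, Path]) -> "ModelParameters":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.from_dict(json.loads(text))

    def to_config(self, path: Union[str, Path, None] = None) -> str:
        """Serialise to a flat ``key = value`` text config (one line per field)."""
        lines = [f"{k} = {v!r}" for k, v in self.to_dict().items()]
        text = "\n".join(lines) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_config(cls, source: Union[str, Path]) -> "ModelParameters":
        """Parse a flat key–value config file (``#`` comments and blanks ignored)."""
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        values: dict[str, float] = {}
        for lineno, raw in enumerate(text.splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"config line {lineno}: expected 'key = value', got {raw!r}")
            key, _, val = line.partition("=")
            values[key.strip()] = float(val)
        return cls.from_dict(values)


@dataclass(frozen=True)
class SpatialGrid:
    """Uniform 1-D control-volume mesh over the capillary ``[0, S]``.

    Cell centers sit at ``(i + 1/2) * dx``; fluxes live on the ``n_cells + 1``
    interfaces.
    """

    n_cells: int
    S: float
    dx: float = field(init=False)
    centers: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.n_cells < 2:
            raise ValueError(f"need at least 2 cells, got {self.n_cells}")
        if self.S <= 0:
            raise ValueError(f"domain length must be positive, got {self.S}")
        dx = self.S / self.n_cells
        object.__setattr__(self, "dx", dx)
        centers = (np.arange(self.n_cells) + 0.5) * dx
        centers.setflags(write=False)
        object.__setattr__(self, "centers", centers)

    @classmethod
    def from_cells_per_mm(cls, S: float, cells_per_mm: float = 128.0) -> "SpatialGrid":
        """Build a grid with a given resolution (cells per mm of capillary)."""
        n = int(round(S / 1000.0 * cells_per_mm))
        return cls(n_cells=n, S=S)


# -- unit conversion --------------------------------------------------------


def percent_to_micromolar(p, henry_factor: float):
    """Convert oxygen percent of air to dissolved oxygen in water, μM.

    By Henry's law the conversion is linear: ``(p / 100) * henry_factor``;
    1% of oxygen in air corresponds to 13 μM at the default factor 1300.
    """
    if henry_factor <= 0:
        raise ValueError(f"henry_factor must be positive, got {henry_factor}")
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError("oxygen percent must be non-negative")
    out = p / 100.0 * henry_factor
    return float(out) if out.ndim == 0 else out


def micromolar_to_percent(c_uM, henry_factor: float):
    """Inverse of :func:`percent_to_micromolar` (no sign check: round-off
    undershoot below zero is tolerated in reporting)."""
    if henry_factor <= 0:
        raise ValueError(f"henry_factor must be positive, got {henry_factor}")
    c_uM = np.asarray(c_uM, dtype=float)
    out = c_uM / henry_factor * 100.0
    return float(out) if out.ndim == 0 else out


# -- reversal-frequency switching law ---------------------------------------


def reversal_frequencies(C_percent, params: ModelParameters, inside_band):
    """Vectorised reversal frequencies ``(f_RL, f_LR)`` at oxygen level ``C``.

    ``C_percent`` is oxygen in percent of air; ``inside_band`` is a boolean
    (scalar or per-cell) selecting ``F_max_band`` over ``F_max`` for the
    high-frequency branch.  Thresholds are strict: exact equality with a switch
    value falls to ``F_min``.
    """
    C = np.asarray(C_percent, dtype=float)
    high = np.where(inside_band, params.F_max_band, params.F_max)
    f_rl = np.where((C > params.C_hat_min) & (C < params.C_max), high, params.F_min)
    f_lr = np.where((C > params.C_min) & (C < params.C_hat_max), high, params.F_min)
    return f_rl, f_lr


def reversal_frequency_rl(C_percent: float, params: ModelParameters, inside_band: bool = False) -> float:
    """Right-to-left reversal frequency, 1/s: high for C_hat_min < C < C_max."""
    f_rl, _ = reversal_frequencies(C_percent, params, inside_band)
    return float(f_rl)


def reversal_frequency_lr(C_percent: float, params: ModelParameters, inside_band: bool = False) -> float:
    """Left-to-right reversal frequency, 1/s: high for C_min < C < C_hat_max."""
    _, f_lr = reversal_frequencies(C_percent, params, inside_band)
    return float(f_lr)


def consumption_gate(C_uM):
    """Depletion gate θ(C): 1 where oxygen remains (C > 0), 0 otherwise.

    Consumption stops once a cell's oxygen is exhausted; the gate also zeroes
    consumption for any round-off undershoot below zero.
    """
    C = np.asarray(C_uM, dtype=float)
    out = np.where(C > 0, 1.0, 0.0)
    return float(out) if out.ndim == 0 else out
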