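"""Parameter containers for the phase-field migrating-cell model.

The model couples a phase field ``phi`` (1 inside the cell, 0 outside, with a
diffuse interface of width ``epsilon``) to three signaling fields: an excitable
pair ``U -> V`` that amplifies edge noise into transient protrusion signals,
and a mass-conserved bistable polarity field ``W`` whose wave-pinning dynamics
maintain a stable front/rear asymmetry.  All parameter groups are plain
dataclasses with validation, YAML round-trip, and documented defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Any

import numpy as np
import yaml

__all__ = [
    "GridSpec",
    "MechanicalParams",
    "KineticParams",
    "NoiseParams",
    "TimeScale",
    "ModelVariant",
    "SimulationConfig",
    "load_config",
    "save_config",
]


class ConfigError(ValueError):
    """Raised when a parameter violates its documented invariant."""


@dataclass
class GridSpec:
    """Periodic square-lattice discretization.

    dx is in micrometres, dt in simulation time units (multiply by
    ``TimeScale.tau_prime`` for seconds).  ``dt`` must satisfy the explicit
    Euler stability bounds checked by :func:`SimulationConfig.validate`.
    """

    nx: int = 128
    ny: int = 128
    dx: float = 0.3
    dt: float = 0.005

    def validate(self) -> None:
        if self.nx < 32 or self.ny < 32:
            raise ConfigError("grid must be at least 32x32")
        if self.dx <= 0 or self.dt <= 0:
            raise ConfigError("dx and dt must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    @property
    def cell_area(self) -> float:
        return self.dx * self.dx


@dataclass
class MechanicalParams:
    """Interface mechanics of the phase-field equation.

    tau   : viscous friction coefficient [pN s/um^2]
    eta   : surface tension [pN]
    epsilon : interface width [um]
    M     : area-constraint strength [pN/um^3]
    A0    : target cell area [um^2] (~5 um radius disk)
    a_W   : protrusive force per unit W at the boundary [pN/um]
    """

    tau: float = 0.83
    eta: float = 1.0
    epsilon: float = 1.0
    M: float = 0.5
    A0: float = 78.83
    a_W: float = 2.4

    def validate(self) -> None:
        for name in ("tau", "eta", "epsilon", "M", "A0", "a_W"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"mechanical parameter {name} must be > 0")


@dataclass
class KineticParams:
    """Reaction-diffusion kinetics of the U, V, W fields.

    alpha, beta : U<->V conversion rates (saturating in the global means
        <phi V W> and <phi U> through K_k and K_p respectively)
    s, gamma    : basal supply and decay of U (rest state U = s/gamma)
    mu          : decay of V
    k_W1        : strength of the bistable W reaction
    rho         : autocatalysis strength in the W cubic; the nonzero roots of
                  -rho W^3 + rho W* W^2 - W = 0 exist iff W*^2 > 4/rho
    zeta        : V -> W coupling (local protrusions feed polarity)
    W_tot       : conserved total protrusive capacity, shared between the
                  membrane-bound field W and the well-mixed pool W*
    chi_U       : boundary-flux coefficient removing U at the interface
    D_U, D_V, D_W : diffusivities [um^2 / simulation time unit]
    """

    alpha: float = 2.0
    beta: float = 0.5
    K_k: float = 0.3
    K_p: float = 1.0
    s: float = 0.1
    gamma: float = 0.1
    mu: float = 0.5
    k_W1: float = 90.0
    rho: float = 5.5556
    zeta: float = 5.0
    W_tot: float = 80.0
    chi_U: float = 50.0
    D_U: float = 1.0
    D_V: float = 0.5
    D_W: float = 3.0

    def validate(self) -> None:
        for f_ in dataclasses.fields(self):
            if getattr(self, f_.name) < 0:
                raise ConfigError(f"kinetic parameter {f_.name} must be >= 0")
        if self.k_W1 > 0 and self.rho <= 0:
            raise ConfigError("rho must be > 0 when k_W1 > 0")

    @property
    def rest_U(self) -> float:
        """Analytic rest state of U (V = 0, noise off)."""
        return self.s / self.gamma


@dataclass
class NoiseParams:
    """Ornstein-Uhlenbeck edge noise.

    theta is the correlation time in simulation time units and sigma the
    stationary standard deviation; the per-site OU stream enters the U
    equation with a minus sign and the V equation with a plus sign so that
    noise converts U into V without creating mass.
    """

    theta: float = 1.4
    sigma: float = 0.075
    seed: int = 0

    def validate(self) -> None:
        if self.theta <= 0:
            raise ConfigError("noise correlation time theta must be > 0")
        if self.sigma < 0:
            raise ConfigError("noise amplitude sigma must be >= 0")


@dataclass
class TimeScale:
    """Conversion between simulation time and seconds.

    One factor serves both roles it plays in the model: it multiplies the
    signaling time derivatives and converts simulation time stamps into
    seconds when trajectories are reported (real seconds = tau_prime * t_sim).
    """

    tau_prime: float = 10.0

    def validate(self) -> None:
        if self.tau_prime <= 0:
            raise ConfigError("tau_prime must be > 0")


class ModelVariant(str, Enum):
    """Which signaling fields drive the protrusive force.

    full         : U, V, W all evolve; F_prot = a_W * W
    one_variable : only the polarity field W evolves (U, V frozen)
    two_variable : only the excitable pair evolves; F_prot = a_W * V
    """

    FULL = "full"
    ONE_VARIABLE = "one_variable"
    TWO_VARIABLE = "two_variable"


@dataclass
class SimulationConfig:
    grid: GridSpec = field(default_factory=GridSpec)
    mechanics: MechanicalParams = field(default_factory=MechanicalParams)
    kinetics: KineticParams = field(default_factory=KineticParams)
    noise: NoiseParams = field(default_factory=NoiseParams)
    timescale: TimeScale = field(default_factory=TimeScale)
    variant: ModelVariant = ModelVariant.FULL

    def validate(self) -> None:
        self.grid.validate()
        self.mechanics.validate()
        self.kinetics.validate()
        self.noise.validate()
        self.timescale.validate()
        dt_max = self.stability_limit()
        if self.grid.dt > dt_max:
            raise ConfigError(
                f"dt={self.grid.dt} exceeds the explicit stability bound "
                f"{dt_max:.3g} (diffusive/interface limit)"
            )
        if self.noise.sigma > 0 and self.grid.dt >= self.noise.theta:
            raise ConfigError("dt must be smaller than the noise correlation time")

    def stability_limit(self) -> float:
        """Most restrictive explicit-Euler bound, in simulation time units.

        Three bounds are combined: signaling diffusion dx^2 tau'/(4 D_max),
        the phase-field diffusive bound tau dx^2/(4 eta), and the stiff
        double-well reaction bound 2 tau eps^2/(eta max|G''|) with
        max|G''| = 36.
        """
        g, m, k, ts = self.grid, self.mechanics, self.kinetics, self.timescale
        d_max = max(k.D_U, k.D_V, k.D_W, 1e-12)
        bounds = (
            g.dx**2 * ts.tau_prime / (4.0 * d_max),
            m.tau * g.dx**2 / (4.0 * m.eta),
            2.0 * m.tau * m.epsilon**2 / (36.0 * m.eta),
        )
        return min(bounds)

    # -- flat key-value round trip -------------------------------------------

    def to_flat_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {}
        for group in ("grid", "mechanics", "kinetics", "noise", "timescale"):
            for f_ in dataclasses.fields(getattr(self, group)):
                out[f_.name] = getattr(getattr(self, group), f_.name)
        out["variant"] = self.variant.value
        return out

    @classmethod
    def from_flat_dict(cls, data: dict[str, Any]) -> "SimulationConfig":
        cfg = cls()
        groups = [cfg.grid, cfg.mechanics, cfg.kinetics, cfg.noise, cfg.timescale]
        known = {f_.name: g for g in groups for f_ in dataclasses.fields(g)}
        for key, value in data.items():
            if key == "variant":
                cfg.variant = ModelVariant(value)
            elif key in known:
                target = known[key]
                kind = type(getattr(target, key))
                setattr(target, key, kind(value))
            else:
                raise ConfigError(f"unknown configuration key: {key!r}")
        return cfg

    def replace(self, **kwargs: Any) -> "SimulationConfig":
        """Return a copy with flat parameter overrides applied."""
        data = self.to_flat_dict()
        data.update(kwargs)
        return SimulationConfig.from_flat_dict(data)


def load_config(path: str | Path) -> SimulationConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return SimulationConfig.from_flat_dict(data)


def save_config(config: SimulationConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_flat_dict(), fh, sort_keys=True)
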