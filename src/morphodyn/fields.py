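"""Field state, the double-well potential, and the conserved polarity pool.

The cell interior is tracked by a phase field ``phi`` whose bulk energy is the
double well G(phi) = 18 phi^2 (1-phi)^2 with minima at 0 (outside) and 1
(inside).  The polarity field W shares a conserved total W_tot with a fast,
well-mixed reciprocal pool W*; W* is *defined* by the conservation relation

    W* = (W_tot - integral(phi W) dr) / (integral(phi) dr)

and recomputed after every W update, so the identity holds exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import GridSpec, KineticParams, MechanicalParams

__all__ = [
    "DegenerateStateError",
    "FieldState",
    "double_well_derivative",
    "polarity_steady_states",
    "reciprocal_pool",
    "initial_state",
    "laplacian",
    "gradient_magnitude",
    "div_phi_grad",
]


class DegenerateStateError(RuntimeError):
    """The phase field no longer contains a cell (area below tolerance)."""


def double_well_derivative(phi: np.ndarray | float) -> np.ndarray | float:
    """G'(phi) for G(phi) = 18 phi^2 (1 - phi)^2.

    G' = 36 phi (1 - phi)(1 - 2 phi); roots at 0, 1/2 and 1, odd-symmetric
    about phi = 1/2.
    """
    return 36.0 * phi * (1.0 - phi) * (1.0 - 2.0 * phi)


def polarity_steady_states(rho: float, wstar: float) -> dict:
    """Real roots of the W reaction cubic -rho W^3 + rho W* W^2 - W = 0.

    Besides W = 0 the nonzero roots are (rho W* +- sqrt(rho^2 W*^2 - 4 rho))
    / (2 rho).  The system is bistable (two stable states separated by the
    middle root) iff W*^2 > 4 / rho.
    """
    if rho <= 0:
        raise ValueError("rho must be > 0")
    roots = [0.0]
    disc = rho * rho * wstar * wstar - 4.0 * rho
    bistable = wstar * wstar > 4.0 / rho
    if disc >= 0.0:
        sq = float(np.sqrt(disc))
        roots.extend(sorted(((rho * wstar - sq) / (2 * rho), (rho * wstar + sq) / (2 * rho))))
    return {"roots": roots, "bistable": bistable}


_AREA_TOL = 1e-9


def reciprocal_pool(phi: np.ndarray, W: np.ndarray, W_tot: float, dx: float) -> float:
    """Well-mixed pool W* implied by conservation of W_tot.

    May legitimately be negative mid-transient (logged by the stepper, not an
    error); an empty cell is degenerate.
    """
    da = dx * dx
    area = float(phi.sum()) * da
    if area < _AREA_TOL:
        raise DegenerateStateError("phase field is empty; W* undefined")
    bound = float((phi * W).sum()) * da
    return (W_tot - bound) / area


@dataclass
class FieldState:
    """All scalar fields of the model at one instant (simulation time t)."""

    phi: np.ndarray
    U: np.ndarray
    V: np.ndarray
    W: np.ndarray
    noise: np.ndarray
    wstar: float
    t: float = 0.0

    def copy(self) -> "FieldState":
        return FieldState(
            self.phi.copy(), self.U.copy(), self.V.copy(), self.W.copy(),
            self.noise.copy(), self.wstar, self.t,
        )


def initial_state(
    grid: GridSpec,
    mech: MechanicalParams,
    kin: KineticParams,
    polarity: str = "crescent",
    direction_deg: float = 0.0,
    cap_fraction: float = 0.35,
) -> FieldState:
    """Initial condition: a centred tanh disk at the target area.

    phi follows the 1D equilibrium interface profile (1 - tanh(3 r'/eps))/2
    around radius sqrt(A0/pi); U sits at its rest state s/gamma and V = 0.

    polarity = "crescent" (default) seeds W at its high-branch root over a
    boundary cap spanning ``cap_fraction`` of the cell diameter towards
    ``direction_deg`` — a polarized start whose survival is governed by the
    wave-pinning condition (the seed decays for W*^2 < 4/rho, e.g. at low
    W_tot).  polarity = "none" puts all protrusive capacity in the pool
    (W = 0); with the default reaction strengths that state is dynamically
    locked (the nucleation barrier exceeds what edge noise can provide).
    """
    ny, nx = grid.shape
    y = (np.arange(ny) - ny / 2.0) * grid.dx
    x = (np.arange(nx) - nx / 2.0) * grid.dx
    yy, xx = np.meshgrid(y, x, indexing="ij")
    r = np.sqrt(xx**2 + yy**2)
    r0 = np.sqrt(mech.A0 / np.pi)
    phi = 0.5 * (1.0 - np.tanh(3.0 * (r - r0) / mech.epsilon))
    U = np.full(grid.shape, kin.rest_U)
    V = np.zeros(grid.shape)
    W = np.zeros(grid.shape)
    if polarity == "crescent":
        ang = np.deg2rad(direction_deg)
        axis = xx * np.cos(ang) + yy * np.sin(ang)  # distance along direction
        cap = (phi > 0.25) & (axis > r0 * (1.0 - 2.0 * cap_fraction))
        if cap.any() and kin.k_W1 > 0 and kin.rho > 0:
            # seed at the high-branch root of the pre-seed pool value; the
            # bistable dynamics relax it to the pinned profile, and the seed
            # simply decays when the bistability condition fails (low W_tot)
            wstar0 = reciprocal_pool(phi, W, kin.W_tot, grid.dx)
            roots = polarity_steady_states(kin.rho, wstar0)["roots"]
            if len(roots) == 3:
                W[cap] = roots[2]
    elif polarity != "none":
        raise ValueError(f"unknown polarity mode {polarity!r}")
    noise = np.zeros(grid.shape)
    wstar = reciprocal_pool(phi, W, kin.W_tot, grid.dx)
    return FieldState(phi, U, V, W, noise, wstar, 0.0)


# -- periodic finite-difference stencils -------------------------------------


def laplacian(f: np.ndarray, dx: float) -> np.ndarray:
    """5-point periodic Laplacian."""
    return (
        np.roll(f, 1, 0) + np.roll(f, -1, 0) + np.roll(f, 1, 1) + np.roll(f, -1, 1)
        - 4.0 * f
    ) / (dx * dx)


def gradient_magnitude(f: np.ndarray, dx: float) -> np.ndarray:
    """|grad f| from central differences on the periodic lattice."""
    gy = (np.roll(f, -1, 0) - np.roll(f, 1, 0)) / (2.0 * dx)
    gx = (np.roll(f, -1, 1) - np.roll(f, 1, 1)) / (2.0 * dx)
    return np.sqrt(gx * gx + gy * gy)


def div_phi_grad(phi: np.ndarray, f: np.ndarray, dx: float) -> np.ndarray:
    """Conservative stencil for div(phi grad f) with face-averaged phi.

    Fluxes vanish with phi, so no signal leaks outside the cell; the discrete
    operator sums to zero over the periodic domain (exact flux balance).
    """
    inv2 = 1.0 / (dx * dx)
    out = np.zeros_like(f)
    for axis in (0, 1):
        phi_p = 0.5 * (phi + np.roll(phi, -1, axis))
        phi_m = 0.5 * (phi + np.roll(phi, 1, axis))
        flux = phi_p * (np.roll(f, -1, axis) - f) - phi_m * (f - np.roll(f, 1, axis))
        out += flux * inv2
    return out
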