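"""Explicit time stepping of the coupled phase-field / signaling dynamics.

One step integrates, with explicit Euler on the periodic lattice,

    tau  d(phi)/dt  = eta (lap phi - G'(phi)/eps^2)
                      - M (int phi dr - A0) |grad phi| + F_prot |grad phi|
    tau' d(phi U)/dt = phi (-R_k + R_p + s - gamma U) + D_U div(phi grad U)
                       - phi N - chi_U U |grad phi|^2 / int |grad phi|^2 dr
    tau' d(phi V)/dt = phi (+R_k - R_p - mu V) + D_V div(phi grad V) + phi N
    tau' d(phi W)/dt = phi (k_W1 (-rho W^3 + rho W^2 W* - W) + zeta V)
                       + D_W div(phi grad W)

with the saturating conversion rates

    R_k = alpha U V W / (K_k + <phi V W>),   R_p = beta U V / (K_p + <phi U>),

global means <phi X> = int phi X dr / int phi dr, and the protrusive force
F_prot = a_W W (full model) or a_W V (two-variable limit).  The signaling
equations advance the products phi*U etc.; concentrations are recovered by
division where phi exceeds a small cutoff.  W* is recomputed from the
conservation relation after every W update, so

    int phi W dr + W* int phi dr = W_tot

holds exactly at the end of each step.  Real-time stamps are tau' * t_sim.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .fields import (
    DegenerateStateError,
    FieldState,
    div_phi_grad,
    double_well_derivative,
    gradient_magnitude,
    initial_state,
    laplacian,
    reciprocal_pool,
)
from .noise import OUNoise
from .params import ModelVariant, SimulationConfig

logger = logging.getLogger(__name__)

__all__ = [
    "InstabilityError",
    "Trajectory",
    "step_fields",
    "run_simulation",
    "periodic_label",
    "periodic_centroid",
]

# Concentrations are recovered from phi*X only where the cell is present.
PHI_CUT = 1e-3
# Pointwise band a stable phase field must stay inside.
PHI_MIN, PHI_MAX = -0.05, 1.05
# A connected component below this area [um^2] is not counted as a fragment.
FRAGMENT_MIN_AREA = 0.5
# The run is declared extinct below this total area [um^2].
EXTINCTION_AREA = 1.0


class InstabilityError(RuntimeError):
    """The explicit scheme blew up; the message names the violated bound."""


def _phi_means(phi: np.ndarray, fields: dict[str, np.ndarray], da: float) -> dict[str, float]:
    area = float(phi.sum()) * da
    return {k: float((phi * v).sum()) * da / area for k, v in fields.items()}


def step_fields(state: FieldState, config: SimulationConfig, noise_field: np.ndarray | None = None) -> FieldState:
    """Advance all fields by one explicit Euler step (pure function).

    ``noise_field`` is the already-updated OU field for this step; ``None``
    means noise off.  Raises :class:`InstabilityError` on NaN/overflow or a
    phase-field excursion outside [-0.05, 1.05].
    """
    g, mech, kin, ts = config.grid, config.mechanics, config.kinetics, config.timescale
    dt, dx, da = g.dt, g.dx, g.cell_area
    variant = config.variant
    phi, U, V, W = state.phi, state.U, state.V, state.W
    N = noise_field if noise_field is not None else 0.0

    grad_phi = gradient_magnitude(phi, dx)
    area = float(phi.sum()) * da

    # --- interface mechanics -------------------------------------------------
    force = mech.a_W * (V if variant is ModelVariant.TWO_VARIABLE else W)
    rhs_phi = (
        mech.eta * (laplacian(phi, dx) - double_well_derivative(phi) / mech.epsilon**2)
        - mech.M * (area - mech.A0) * grad_phi
        + force * grad_phi
    )
    new_phi = phi + (dt / mech.tau) * rhs_phi

    # --- signaling -----------------------------------------------------------
    evolve_uv = variant is not ModelVariant.ONE_VARIABLE
    evolve_w = variant is not ModelVariant.TWO_VARIABLE

    if evolve_uv:
        means = _phi_means(phi, {"VW": V * W, "U": U}, da)
        r_kinase = kin.alpha * U * V * W / (kin.K_k + means["VW"])
        r_phosph = kin.beta * U * V / (kin.K_p + means["U"])
        grad2 = grad_phi * grad_phi
        grad2_int = float(grad2.sum()) * da
        edge_flux = kin.chi_U * U * grad2 / grad2_int if grad2_int > 0 else 0.0
        rhs_u = (
            phi * (-r_kinase + r_phosph + kin.s - kin.gamma * U)
            + kin.D_U * div_phi_grad(phi, U, dx)
            - phi * N
            - edge_flux
        )
        rhs_v = (
            phi * (r_kinase - r_phosph - kin.mu * V)
            + kin.D_V * div_phi_grad(phi, V, dx)
            + phi * N
        )
        new_pu = phi * U + (dt / ts.tau_prime) * rhs_u
        new_pv = phi * V + (dt / ts.tau_prime) * rhs_v
        inside = new_phi > PHI_CUT
        new_U = np.where(inside, new_pu / np.where(inside, new_phi, 1.0), 0.0)
        new_V = np.where(inside, new_pv / np.where(inside, new_phi, 1.0), 0.0)
    else:
        new_U, new_V = U, V

    if evolve_w:
        cubic = kin.k_W1 * (-kin.rho * W**3 + kin.rho * W**2 * state.wstar - W)
        rhs_w = phi * (cubic + kin.zeta * V) + kin.D_W * div_phi_grad(phi, W, dx)
        new_pw = phi * W + (dt / ts.tau_prime) * rhs_w
        inside = new_phi > PHI_CUT
        new_W = np.where(inside, new_pw / np.where(inside, new_phi, 1.0), 0.0)
    else:
        new_W = W

    # --- sanity and conservation --------------------------------------------
    if not np.isfinite(new_phi).all():
        raise InstabilityError(
            f"non-finite phase field at t={state.t:.3f}; dt={dt} vs stability "
            f"bound {config.stability_limit():.3g}"
        )
    pmin, pmax = float(new_phi.min()), float(new_phi.max())
    if pmin < PHI_MIN or pmax > PHI_MAX:
        raise InstabilityError(
            f"phase field left [{PHI_MIN}, {PHI_MAX}] (range [{pmin:.3f}, {pmax:.3f}]) "
            f"at t={state.t:.3f}; dt={dt} vs stability bound {config.stability_limit():.3g}"
        )
    if not (np.isfinite(new_U).all() and np.isfinite(new_V).all() and np.isfinite(new_W).all()):
        raise InstabilityError(f"non-finite signaling field at t={state.t:.3f}")

    wstar = reciprocal_pool(new_phi, new_W, kin.W_tot, dx)
    if wstar < 0:
        logger.warning("reciprocal pool W* went negative (%.4g) at t=%.3f", wstar, state.t)

    noise_out = noise_field if noise_field is not None else state.noise
    return FieldState(new_phi, new_U, new_V, new_W, np.asarray(noise_out, dtype=float) if np.ndim(noise_out) else state.noise, wstar, state.t + dt)


# -- periodic-lattice helpers -------------------------------------------------


def periodic_label(mask: np.ndarray) -> tuple[np.ndarray, int]:
    """Connected-component labels that respect the periodic boundary.

    Plain labelling splits a cell straddling the box edge in two; labels
    touching across opposite edges are merged with union-find.
    """
    labels, n = ndimage.label(mask)
    if n <= 1:
        return labels, n
    parent = list(range(n + 1))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    for sl_a, sl_b in (((0, slice(None)), (-1, slice(None))), ((slice(None), 0), (slice(None), -1))):
        edge_a, edge_b = labels[sl_a], labels[sl_b]
        both = (edge_a > 0) & (edge_b > 0)
        for a, b in zip(edge_a[both], edge_b[both]):
            union(int(a), int(b))
    remap = np.zeros(n + 1, dtype=labels.dtype)
    roots = sorted({find(i) for i in range(1, n + 1)})
    for new, root in enumerate(roots, start=1):
        for i in range(1, n + 1):
            if find(i) == root:
                remap[i] = new
    return remap[labels], len(roots)


def periodic_centroid(weight: np.ndarray, dx: float) -> np.ndarray:
    """Mass centroid (row, col) in um on the periodic box, via circular means."""
    out = np.empty(2)
    total = weight.sum()
    for axis in (0, 1):
        n = weight.shape[axis]
        theta = 2.0 * np.pi * np.arange(n) / n
        marg = weight.sum(axis=1 - axis)
        ang = np.arctan2((marg * np.sin(theta)).sum() / total, (marg * np.cos(theta)).sum() / total)
        out[axis] = (ang % (2.0 * np.pi)) * n / (2.0 * np.pi) * dx
    return out


@dataclass
class Trajectory:
    """Sampled output of one simulation run.

    times are in seconds (tau' * simulation time); ``centroid`` is unwrapped
    across the periodic boundary so displacement statistics are meaningful.
    Field stacks are float32, shape (T, ny, nx).
    """

    times: np.ndarray
    phi: np.ndarray
    U: np.ndarray | None
    V: np.ndarray | None
    W: np.ndarray | None
    centroid: np.ndarray
    wstar: np.ndarray
    area: np.ndarray
    fragmentation_events: list[dict] = field(default_factory=list)
    config: SimulationConfig | None = None
    seed: int | None = None
    extinct: bool = False

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def frame_interval(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else 0.0


def run_simulation(
    config: SimulationConfig,
    duration: float,
    sample_interval: float = 5.0,
    seed: int = 0,
    store_fields: bool = True,
    initial: FieldState | None = None,
    polarity: str = "crescent",
) -> Trajectory:
    """Integrate for ``duration`` seconds of real time, sampling periodically.

    duration and sample_interval are in seconds; internally the clock runs in
    simulation units (seconds / tau').  Fragmentation (more than one connected
    component of phi > 0.5 above a minimum area) is logged per sampled frame;
    extinction (total area below tolerance) ends the run early.
    """
    config.validate()
    if duration < sample_interval:
        raise ValueError("duration must be at least one sample interval")
    g, ts = config.grid, config.timescale
    if initial is not None:
        state = initial.copy()
    else:
        # the seed fixes both the noise stream and the initial polarity axis
        direction = float(np.random.default_rng(seed).uniform(0.0, 360.0))
        state = initial_state(
            g, config.mechanics, config.kinetics, polarity=polarity, direction_deg=direction
        )
    noise = OUNoise(g.shape, config.noise, seed=seed)
    state.noise = noise.state.copy()

    t_end_sim = duration / ts.tau_prime
    sample_sim = sample_interval / ts.tau_prime
    n_steps = int(round(t_end_sim / g.dt))
    steps_per_sample = max(1, int(round(sample_sim / g.dt)))

    times, phis, us, vs, ws = [], [], [], [], []
    cents, wstars, areas, frag_events = [], [], [], []
    extinct = False

    def sample(idx: int) -> None:
        da = g.cell_area
        area = float(state.phi.sum()) * da
        times.append(ts.tau_prime * state.t)
        areas.append(area)
        wstars.append(state.wstar)
        cents.append(periodic_centroid(state.phi, g.dx))
        if store_fields:
            phis.append(state.phi.astype(np.float32))
            us.append(state.U.astype(np.float32))
            vs.append(state.V.astype(np.float32))
            ws.append(state.W.astype(np.float32))
        else:
            phis.append((state.phi >= 0.5).astype(np.float32))
        labels, n_comp = periodic_label(state.phi >= 0.5)
        if n_comp > 1:
            sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n_comp + 1)) * da
            big = sizes[sizes >= FRAGMENT_MIN_AREA]
            if len(big) > 1:
                frag_events.append({"frame": idx, "t": ts.tau_prime * state.t, "areas": sorted(big, reverse=True)})
                logger.info("fragmentation at t=%.1f s: %d components", ts.tau_prime * state.t, len(big))

    sample(0)
    for step in range(1, n_steps + 1):
        n_field = noise.step(g.dt) if config.noise.sigma > 0 else None
        state = step_fields(state, config, n_field)
        if float(state.phi.sum()) * g.cell_area < EXTINCTION_AREA:
            logger.warning("extinction at t=%.1f s", ts.tau_prime * state.t)
            extinct = True
            break
        if step % steps_per_sample == 0:
            sample(len(times))

    # unwrap the centroid across the periodic boundary
    cents_arr = np.asarray(cents)
    box = np.array([g.ny * g.dx, g.nx * g.dx])
    deltas = np.diff(cents_arr, axis=0)
    deltas = (deltas + box / 2.0) % box - box / 2.0
    unwrapped = np.vstack([cents_arr[:1], cents_arr[:1] + np.cumsum(deltas, axis=0)])

    return Trajectory(
        times=np.asarray(times),
        phi=np.asarray(phis),
        U=np.asarray(us) if us else None,
        V=np.asarray(vs) if vs else None,
        W=np.asarray(ws) if ws else None,
        centroid=unwrapped,
        wstar=np.asarray(wstars),
        area=np.asarray(areas),
        fragmentation_events=frag_events,
        config=config,
        seed=seed,
        extinct=extinct,
    )
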