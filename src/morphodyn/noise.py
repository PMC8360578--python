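"""Per-site Ornstein-Uhlenbeck edge noise.

The edge-fluctuation source N(r, t) is modelled as independent OU processes
on every lattice site, the minimal two-parameter colored noise: correlation
time ``theta`` and stationary standard deviation ``sigma``.  The exact
discretization

    N(t + dt) = N(t) e^{-dt/theta} + sigma sqrt(1 - e^{-2 dt/theta}) xi

is used so the stationary law is reproduced for any stable dt.  The same
stream enters the U equation with a minus sign and the V equation with a plus
sign, converting U into V without creating mass.
"""

from __future__ import annotations

import numpy as np

from .params import NoiseParams

__all__ = ["OUNoise", "ou_noise_update"]


def ou_noise_update(
    noise: np.ndarray, params: NoiseParams, dt: float, rng: np.random.Generator
) -> np.ndarray:
    """One exact OU step for every site; identical seed => identical stream."""
    if dt >= params.theta and params.sigma > 0:
        raise ValueError("dt must be smaller than the noise correlation time theta")
    if params.sigma == 0.0:
        return np.zeros_like(noise)
    decay = np.exp(-dt / params.theta)
    kick = params.sigma * np.sqrt(1.0 - decay * decay)
    return noise * decay + kick * rng.standard_normal(noise.shape)


class OUNoise:
    """Stateful wrapper carrying the RNG; draws the stationary law at t=0."""

    def __init__(self, shape: tuple[int, int], params: NoiseParams, seed: int | None = None):
        self.params = params
        self.rng = np.random.default_rng(params.seed if seed is None else seed)
        if params.sigma > 0:
            self.state = params.sigma * self.rng.standard_normal(shape)
        else:
            self.state = np.zeros(shape)

    def step(self, dt: float) -> np.ndarray:
        self.state = ou_noise_update(self.state, self.params, dt, self.rng)
        return self.state
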