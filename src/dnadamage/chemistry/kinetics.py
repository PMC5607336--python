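"""Encounter-distance kinetics.

The rate tables quote thermal rate constants k in 1/(M s). The simulator
realises them as encounter radii through the diffusion-controlled
(Smoluchowski) inversion R = k / (4 pi D' N_A), with D' the mutual diffusion
coefficient; a pair reacts when it comes within R. Within-step encounters
that the end-of-step positions miss are recovered with the Brownian-bridge
first-passage probability.
"""

from __future__ import annotations

import numpy as np

from ..constants import AVOGADRO
from ..errors import ConfigurationError

_M3_PER_LITRE = 1e-3
_NM_PER_M = 1e9


def rate_to_reaction_radius(rate_m_s: float, d_mutual_m2_s: float) -> float:
    """Encounter radius (nm) reproducing the rate constant.

    k [1/(M s)] is first converted to m^3/(mol s); then
    R = k / (4 pi D' N_A) in metres.
    """
    if rate_m_s < 0:
        raise ConfigurationError("rate must be >= 0")
    if d_mutual_m2_s <= 0:
        raise ConfigurationError(
            "mutual diffusion coefficient must be positive; a mobile-static "
            "pair uses the mobile species' coefficient")
    k_si = rate_m_s * _M3_PER_LITRE  # m^3 mol^-1 s^-1
    r_m = k_si / (4.0 * np.pi * d_mutual_m2_s * AVOGADRO)
    return r_m * _NM_PER_M


def brownian_bridge_reaction_prob(d_start_nm, d_end_nm, radius_nm,
                                  d_mutual_m2_s, dt_s):
    """Probability that a pair touched during the step given its endpoints.

    Standard first-passage form for a Brownian bridge against an absorbing
    sphere: P = exp(-(d0 - R)(d1 - R) / (D' dt)), clamped to [0, 1]; an
    endpoint already at or inside R gives P = 1.
    """
    if np.any(np.asarray(dt_s) <= 0):
        raise ConfigurationError("time step must be positive")
    d0 = (np.asarray(d_start_nm, dtype=float) - radius_nm) / _NM_PER_M
    d1 = (np.asarray(d_end_nm, dtype=float) - radius_nm) / _NM_PER_M
    p = np.exp(-np.clip(d0, 0.0, None) * np.clip(d1, 0.0, None)
               / (d_mutual_m2_s * dt_s))
    return np.clip(p, 0.0, 1.0)
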