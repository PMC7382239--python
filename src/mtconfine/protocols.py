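"""Canonical simulation protocols.

The study contrasts two in-plane geometries (rectangle vs square,
equal depth) under two severing regimes (wild-type P_cross = 0.005 vs
katanin-mutant P_cross = 0), quantified per replicate by the
face-averaged S2 and dominant angle ThetaS2.  ``severing_shape_cohort``
runs that full 2 x 2 grid; ``severing_time_trials`` measures the
waiting-time law of a single persistent crossover.  Problem sizes
(t_steps, replicate count) are arguments so the protocols scale from
smoke tests to full reproductions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict

import numpy as np

from .geometry import make_domain
from .interactions import apply_severing
from .params import SimulationParams
from .quantify import face_order_parameters
from .simulator import new_state, run

__all__ = ["CohortResult", "severing_shape_cohort", "severing_time_trials",
           "nematic_circular_mean"]

RECT_DIMS = dict(lx=40.0, ly=15.0, lz=15.0)
SQUARE_DIMS = dict(lx=20.0, ly=20.0, lz=15.0)
P_CROSS_WILDTYPE = 0.005
P_CROSS_MUTANT = 0.0


@dataclass
class CohortResult:
    """Per-cell replicate metrics of the shape x severing grid.

    Keys are 'rect_sev', 'rect_nosev', 'square_sev', 'square_nosev';
    ``s2`` and ``theta`` hold one value per replicate (face-averaged).
    ``all_inside`` records whether every vertex of every final state
    satisfied the confinement invariant.
    """
    s2: Dict[str, np.ndarray] = field(default_factory=dict)
    theta: Dict[str, np.ndarray] = field(default_factory=dict)
    t_steps: int = 0
    r_replicates: int = 0
    all_inside: bool = True


def severing_shape_cohort(seed: int = 1000, t_steps: int = 2000,
                          r_replicates: int = 20,
                          shell_depth: float = 0.5) -> CohortResult:
    """Run rectangle and square domains with and without crossover
    severing; R replicates each, seeded seed, seed+1, ..."""
    domains = {
        "rect": make_domain("box", **RECT_DIMS),
        "square": make_domain("box", **SQUARE_DIMS),
    }
    conditions = {"sev": P_CROSS_WILDTYPE, "nosev": P_CROSS_MUTANT}
    out = CohortResult(t_steps=t_steps, r_replicates=r_replicates)
    for dname, domain in domains.items():
        for cname, p_cross in conditions.items():
            params = SimulationParams(t_steps=t_steps, p_cross=p_cross,
                                      r_replicates=r_replicates, seed=seed)
            s2s = np.empty(r_replicates)
            thetas = np.empty(r_replicates)
            for i in range(r_replicates):
                state = run(params, domain, seed=seed + i).final_state
                for mt in state.mts.values():
                    if not domain.contains_many(mt.as_array()).all():
                        out.all_inside = False
                fp = face_order_parameters(state, domain, shell_depth)
                s2s[i] = fp.s2_mean
                thetas[i] = (fp.theta_mean if fp.theta_mean is not None
                             else np.nan)
            key = f"{dname}_{cname}"
            out.s2[key] = s2s
            out.theta[key] = thetas
    return out


def severing_time_trials(p_cross: float, n_trials: int, seed: int = 0
                         ) -> np.ndarray:
    """Monte-Carlo waiting times (in steps) until a single persistent
    crossover is severed; the law is geometric,
    P(severed by t) = 1 - (1 - P_cross)^t."""
    if not 0.0 < p_cross <= 1.0:
        raise ValueError("p_cross must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    domain = make_domain("box", **RECT_DIMS)
    params = SimulationParams(t_steps=0, p_cross=p_cross, k_nuc=0.0,
                              p_spont_cat=0.0, p_rescue=0.0,
                              r_replicates=1)
    times = np.empty(n_trials)
    ell = params.element_length
    for k in range(n_trials):
        state = new_state(domain, params)
        crossing = state.add_mt(
            [(-1.0 + i * ell, 0.0, 0.0) for i in range(11)], (1.0, 0.0, 0.0))
        host = state.add_mt(
            [(0.0, -1.0 + i * ell, 0.05) for i in range(11)],
            (0.0, 1.0, 0.0))
        rec = state.add_crossover(crossing.id, 4, host.id)
        t = 0
        while rec.alive:
            t += 1
            apply_severing(state, params, rng)
        times[k] = t
    return times


def nematic_circular_mean(theta_deg) -> float:
    """Axis (in degrees, (-90, 90]) of the mean nematic resultant of a
    sample of 180-degree-periodic angles."""
    t = np.radians(np.asarray(theta_deg, float))
    c = np.nanmean(np.cos(2 * t))
    s = np.nanmean(np.sin(2 * t))
    ang = 0.5 * math.degrees(math.atan2(s, c))
    if ang <= -90.0:
        ang += 180.0
    return ang
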