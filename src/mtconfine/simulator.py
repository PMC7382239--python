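"""Fixed-time-step stochastic engine for confined microtubule arrays.

Each step performs one synchronous pass:

1. nucleation — a Poisson(k_nuc) number of fresh two-vertex MTs at
   random positions/orientations;
2. per-MT dynamics in id order — spontaneous plus-end transitions
   (catastrophe / rescue), then a growth or shrinkage move; growth
   resolves membrane encounters (tangential deflection or edge
   catastrophe) before MT–MT contacts (bundling / induced catastrophe /
   crossover); shrinking minus ends created by severing lose one
   element per step;
3. katanin severing over all registered crossovers;
4. step counter increment (the spatial hash is maintained
   incrementally and stays consistent throughout).

Identical (domain, params, seed) reproduce bit-identical trajectories:
a single PCG64 generator drives every draw in a fixed order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from . import interactions
from .geometry import ConfinementDomain
from .params import SimulationParams
from .state import GROWING, SHRINKING, Microtubule, SimulationState

__all__ = ["nucleate", "grow_tip", "shrink_tip", "step", "run",
           "run_replicates", "new_state", "TrajectorySummary"]


def new_state(domain: ConfinementDomain,
              params: SimulationParams) -> SimulationState:
    return SimulationState(domain, params)


def _random_unit(rng):
    while True:
        v = rng.standard_normal(3)
        n = math.sqrt(v[0] * v[0] + v[1] * v[1] + v[2] * v[2])
        if n > 1e-12:
            return (v[0] / n, v[1] / n, v[2] / n)


def _tangent_frame(n):
    """Two orthonormal vectors spanning the plane perpendicular to n."""
    ax = (1.0, 0.0, 0.0) if abs(n[0]) < 0.9 else (0.0, 1.0, 0.0)
    ux = ax[1] * n[2] - ax[2] * n[1]
    uy = ax[2] * n[0] - ax[0] * n[2]
    uz = ax[0] * n[1] - ax[1] * n[0]
    inv = 1.0 / math.sqrt(ux * ux + uy * uy + uz * uz)
    u = (ux * inv, uy * inv, uz * inv)
    v = (n[1] * u[2] - n[2] * u[1], n[2] * u[0] - n[0] * u[2],
         n[0] * u[1] - n[1] * u[0])
    return u, v


def nucleate(state: SimulationState, params: SimulationParams, rng):
    """Create Poisson(k_nuc) new two-vertex MTs this step.

    Volume mode: uniform interior point, isotropic orientation (redrawn
    if the second vertex would leave the domain).  Surface mode:
    uniform membrane point with a random tangent-plane orientation,
    tilted minimally inward where the membrane curves away.
    """
    if params.k_nuc <= 0.0:
        return state
    count = rng.poisson(params.k_nuc)
    ell = params.element_length
    domain = state.domain
    for _ in range(count):
        if params.nucleation_mode == "volume":
            p = domain.sample_point(rng)
            for _ in range(1000):
                d = _random_unit(rng)
                q = (p[0] + ell * d[0], p[1] + ell * d[1], p[2] + ell * d[2])
                if domain.contains_xyz(*q):
                    break
        else:
            p, n = domain.sample_surface(rng)
            u, v = _tangent_frame(n)
            phi = 2.0 * math.pi * rng.random()
            t = (math.cos(phi) * u[0] + math.sin(phi) * v[0],
                 math.cos(phi) * u[1] + math.sin(phi) * v[1],
                 math.cos(phi) * u[2] + math.sin(phi) * v[2])
            d, q = t, (p[0] + ell * t[0], p[1] + ell * t[1], p[2] + ell * t[2])
            if not domain.contains_xyz(*q):
                # tilt the tangent direction inward by the smallest angle
                # that keeps the second vertex inside (exact chord on a
                # sphere); bisection on the tilt angle
                lo, hi = 0.0, math.pi / 2.0
                for _ in range(40):
                    mid = 0.5 * (lo + hi)
                    c, s = math.cos(mid), math.sin(mid)
                    d = (c * t[0] - s * n[0], c * t[1] - s * n[1],
                         c * t[2] - s * n[2])
                    q = (p[0] + ell * d[0], p[1] + ell * d[1],
                         p[2] + ell * d[2])
                    if domain.contains_xyz(*q):
                        hi = mid
                    else:
                        lo = mid
                c, s = math.cos(hi), math.sin(hi)
                d = (c * t[0] - s * n[0], c * t[1] - s * n[1],
                     c * t[2] - s * n[2])
                q = (p[0] + ell * d[0], p[1] + ell * d[1], p[2] + ell * d[2])
        state.add_mt([p, q], d)
        state.counters["nucleated"] += 1
    return state


def _advance_on_boundary(mt, state, params, rng, d):
    """Growth step that would exit the membrane: deflect tangentially
    when the incidence is shallow, else edge catastrophe with
    probability P_edge_cat.  Returns the event name."""
    domain = state.domain
    ell = params.element_length
    tip = mt.vertices[-1]
    sin_edge = math.sin(math.radians(params.theta_edge))
    for _ in range(4):
        t_exit, n = domain.ray_exit(tip, d)
        dot = d[0] * n[0] + d[1] * n[1] + d[2] * n[2]
        tx, ty, tz = d[0] - dot * n[0], d[1] - dot * n[1], d[2] - dot * n[2]
        tnorm = math.sqrt(tx * tx + ty * ty + tz * tz)
        degenerate = tnorm < 1e-9
        if dot >= sin_edge or degenerate:
            if rng.random() < params.p_edge_cat:
                mt.plus_state = SHRINKING
                return "boundary_catastrophe"
            if degenerate:
                # no tangential component to keep: slide in a random
                # membrane-tangent direction
                u, v = _tangent_frame(n)
                phi = 2.0 * math.pi * rng.random()
                tx = math.cos(phi) * u[0] + math.sin(phi) * v[0]
                ty = math.cos(phi) * u[1] + math.sin(phi) * v[1]
                tz = math.cos(phi) * u[2] + math.sin(phi) * v[2]
                tnorm = 1.0
        d = (tx / tnorm, ty / tnorm, tz / tnorm)
        q = (tip[0] + ell * d[0], tip[1] + ell * d[1], tip[2] + ell * d[2])
        if domain.contains_xyz(*q):
            state.append_element(mt, q, d)
            return "boundary_deflected"
    # could not place a full element this step; keep the slid direction
    mt.plus_dir = d
    return "boundary_deflected"


def grow_tip(mt: Microtubule, state: SimulationState,
             params: SimulationParams, rng) -> str:
    """Advance a growing plus end by one element.

    Resolution priority: membrane first (deflection or edge
    catastrophe), then MT–MT contact (bundle / induced catastrophe /
    crossover), else plain extension.  Returns one of "extended",
    "bundled", "catastrophe", "crossover", "boundary_deflected",
    "boundary_catastrophe".
    """
    if mt.plus_state != GROWING:
        raise ValueError("grow_tip requires a growing plus end")
    ell = params.element_length
    tip = mt.vertices[-1]
    d = mt.plus_dir
    q = (tip[0] + ell * d[0], tip[1] + ell * d[1], tip[2] + ell * d[2])
    if not state.domain.contains_xyz(*q):
        event = _advance_on_boundary(mt, state, params, rng, d)
    else:
        refs = mt.grid_refs
        exclude = refs[-2:] if len(refs) >= 2 else refs
        entry, _dist = state.nearest_contact(q[0], q[1], q[2],
                                             params.d_contact, exclude)
        if entry is None:
            state.append_element(mt, q, d)
            event = "extended"
        else:
            outcome = interactions.resolve_contact(mt, entry, state, params,
                                                   rng, q)
            event = {"bundle": "bundled",
                     "induced_catastrophe": "catastrophe",
                     "crossover": "crossover"}[outcome]
    state.counters[event] += 1
    return event


def shrink_tip(mt: Microtubule, state: SimulationState,
               params: SimulationParams) -> str:
    """Remove one element from the shrinking plus end; the MT dies when
    no element remains."""
    state.pop_plus_element(mt)
    if mt.n_elements < 1:
        state.kill_mt(mt)
        return "died"
    return "shortened"


def _shrink_minus(mt, state):
    state.pop_minus_element(mt)
    if mt.n_elements < 1:
        state.kill_mt(mt)
        return "died"
    return "shortened"


def step(state: SimulationState, params: SimulationParams, rng):
    """One synchronous pass: nucleation, per-MT dynamics in id order,
    then crossover severing."""
    nucleate(state, params, rng)
    treadmill = (params.minus_shrink_every > 0
                 and state.step % params.minus_shrink_every == 0)
    for mt in list(state.mts.values()):
        # spontaneous plus-end transitions
        if mt.plus_state == GROWING:
            if params.p_spont_cat > 0.0 and rng.random() < params.p_spont_cat:
                mt.plus_state = SHRINKING
        else:
            if params.p_rescue > 0.0 and rng.random() < params.p_rescue:
                mt.plus_state = GROWING
        if mt.plus_state == GROWING:
            grow_tip(mt, state, params, rng)
        else:
            if shrink_tip(mt, state, params) == "died":
                continue
        if mt.minus_state == SHRINKING or treadmill:
            _shrink_minus(mt, state)
    interactions.apply_severing(state, params, rng)
    state.step += 1
    return state


@dataclass
class TrajectorySummary:
    """One replicate: final state plus periodic polyline snapshots."""
    seed: int
    final_state: SimulationState
    snapshot_steps: List[int] = field(default_factory=list)
    snapshots: List[list] = field(default_factory=list)  # polylines()


def run(params: SimulationParams, domain: ConfinementDomain,
        snapshot_every: Optional[int] = None,
        seed: Optional[int] = None) -> TrajectorySummary:
    """Run one trajectory of params.t_steps steps."""
    if seed is None:
        seed = params.seed
    rng = np.random.Generator(np.random.PCG64(seed))
    state = new_state(domain, params)
    summary = TrajectorySummary(seed=seed, final_state=state)
    for _ in range(params.t_steps):
        step(state, params, rng)
        if snapshot_every and state.step % snapshot_every == 0:
            summary.snapshot_steps.append(state.step)
            summary.snapshots.append(state.polylines())
    return summary


def run_replicates(params: SimulationParams, domain: ConfinementDomain,
                   snapshot_every: Optional[int] = None
                   ) -> List[TrajectorySummary]:
    """R independent replicates seeded seed, seed+1, ..., seed+R-1."""
    return [run(params, domain, snapshot_every, seed=params.seed + i)
            for i in range(params.r_replicates)]
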