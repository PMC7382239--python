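"""Microtubule–microtubule interaction rules.

A growing plus end that comes within the contact radius of a foreign
element resolves the encounter by the collision angle theta (nematic,
in [0, 90] degrees):

* theta < alpha — the tip *bundles* (zippers): its growth direction is
  re-aligned with the target, with the sign chosen to minimize turning.
* theta >= alpha — with probability P_cat the tip undergoes an *induced
  catastrophe* (switches to shrinking); otherwise it grows straight
  over the target, a *crossover*, and the crossing is registered.

Registered crossovers model katanin substrate sites: at every later
step each live record is severed independently with probability
P_cross.  Severing splits the crossing MT at the cut element; the
minus-side fragment keeps its identity and starts shrinking from the
new plus end, the plus-side fragment gets a fresh identity and starts
shrinking from its new minus end.  Only the crossing (later-arriving)
MT is ever severed; the host is untouched.
"""

from __future__ import annotations

import math

from .state import (SHRINKING, CrossoverRecord, Microtubule,
                    SimulationState)

__all__ = ["CrossoverRecord", "interaction_angle", "resolve_contact",
           "apply_severing", "sever_mt"]

_RAD2DEG = 180.0 / math.pi


def interaction_angle(d1, d2) -> float:
    """Nematic angle between two unit orientation vectors, degrees in
    [0, 90]; antiparallel counts as parallel."""
    n1 = d1[0] * d1[0] + d1[1] * d1[1] + d1[2] * d1[2]
    n2 = d2[0] * d2[0] + d2[1] * d2[1] + d2[2] * d2[2]
    if abs(n1 - 1.0) > 1e-6 or abs(n2 - 1.0) > 1e-6:
        raise ValueError("interaction_angle expects unit vectors")
    dot = abs(d1[0] * d2[0] + d1[1] * d2[1] + d1[2] * d2[2])
    if dot > 1.0:
        dot = 1.0
    return math.acos(dot) * _RAD2DEG


def resolve_contact(mt: Microtubule, entry, state: SimulationState, params,
                    rng, proposed):
    """Resolve a detected tip contact with a foreign element.

    ``entry`` is the spatial-hash entry of the contacted element;
    ``proposed`` is the already-validated (in-domain) tip advance along
    the current growth direction.  Returns "bundle",
    "induced_catastrophe" or "crossover".
    """
    ell = params.element_length
    dx, dy, dz = entry[4] - entry[1], entry[5] - entry[2], entry[6] - entry[3]
    inv = 1.0 / math.sqrt(dx * dx + dy * dy + dz * dz)
    tdir = (dx * inv, dy * inv, dz * inv)
    d = mt.plus_dir
    theta = interaction_angle(d, tdir)

    if theta < params.alpha:
        # zipper: re-align with the target, minimal turning angle
        dot = d[0] * tdir[0] + d[1] * tdir[1] + d[2] * tdir[2]
        sign = 1.0 if dot >= 0.0 else -1.0
        nd = (sign * tdir[0], sign * tdir[1], sign * tdir[2])
        tip = mt.vertices[-1]
        p_new = (tip[0] + ell * nd[0], tip[1] + ell * nd[1],
                 tip[2] + ell * nd[2])
        if state.domain.contains_xyz(*p_new):
            state.append_element(mt, p_new, nd)
        else:
            # bundled direction runs into the membrane: slide along it
            from .simulator import _advance_on_boundary
            _advance_on_boundary(mt, state, params, rng, nd)
        return "bundle"

    if rng.random() < params.p_cat:
        mt.plus_state = SHRINKING
        return "induced_catastrophe"

    # unimpeded growth over the target: register the crossover
    state.append_element(mt, proposed, d)
    state.add_crossover(mt.id, mt.n_elements - 1, entry[0])
    return "crossover"


def sever_mt(state: SimulationState, mt: Microtubule, cut_index: int,
             current_plus_dir=None):
    """Split ``mt`` at element ``cut_index``.

    Elements [0, cut_index) stay with the original MT (fragment A),
    whose new plus end at the cut starts shrinking; elements
    [cut_index, n) move to a fresh MT (fragment B) whose new minus end
    shrinks while its plus end keeps the pre-severing state.  Total
    element count is conserved.  Returns the new fragment (or None when
    the cut is at the minus end, in which case the original MT simply
    becomes fragment B semantics under its own shrinking minus end).
    """
    n = mt.n_elements
    if not 0 <= cut_index < n:
        raise ValueError(f"cut_index {cut_index} out of range [0, {n})")

    if cut_index == 0:
        # no minus-side fragment: the whole MT just loses its minus anchor
        mt.minus_state = SHRINKING
        return None

    verts_b = mt.vertices[cut_index:]
    refs_b = mt.grid_refs[cut_index:]
    del mt.vertices[cut_index + 1:]
    del mt.grid_refs[cut_index:]

    frag = Microtubule(state.next_id, verts_b, mt.plus_dir,
                       plus_state=mt.plus_state, minus_state=SHRINKING,
                       birth_step=state.step)
    state.next_id += 1
    state.mts[frag.id] = frag
    # re-key the moved elements under the new id
    for entry in refs_b:
        state._grid_remove(entry)
        new_entry = (frag.id,) + entry[1:]
        frag.grid_refs.append(new_entry)
        state._grid_add(new_entry)

    # fragment A: new plus end at the cut, shrinking
    mt.plus_state = SHRINKING
    mt.plus_dir = mt.element_dir(mt.n_elements - 1)

    # move crossing-side records beyond the cut onto the fragment
    recs = state.by_crossing.get(mt.id)
    if recs:
        keep, moved = [], []
        for rec in recs:
            if not rec.alive:
                continue
            if rec.crossing_element_index >= cut_index:
                rec.crossing_element_index -= cut_index
                rec.crossing_mt_id = frag.id
                moved.append(rec)
            else:
                keep.append(rec)
        state.by_crossing[mt.id] = keep
        if moved:
            state.by_crossing.setdefault(frag.id, []).extend(moved)
    return frag


def apply_severing(state: SimulationState, params, rng):
    """Test every live crossover record with probability P_cross and
    sever on success.  Records are processed in creation order; several
    severings of the same MT within one step are resolved sequentially
    (indices re-mapped as fragments are created)."""
    p = params.p_cross
    if p > 0.0 and state.crossovers:
        for rec in list(state.crossovers):
            if not rec.alive:
                continue
            if rng.random() >= p:
                continue
            mt = state.mts.get(rec.crossing_mt_id)
            if mt is None:  # pragma: no cover - registry kept consistent
                rec.alive = False
                continue
            rec.alive = False
            sever_mt(state, mt, rec.crossing_element_index)
            state.counters["severed"] += 1
    state.compact_crossovers()
    return state
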