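"""Mutable simulation state: microtubules, crossover registry, spatial hash.

A microtubule is an ordered chain of vertices (minus end first) with a
fixed element length; only the two ends ever change, so the spatial hash
of elements is maintained incrementally.  Crossover records — crossings
of one microtubule over another, eligible for katanin severing at every
later step — are indexed both by the crossing and the host microtubule
so that end-shrinkage and death can retire them cheaply.
"""

from __future__ import annotations

import math
from typing import Dict, List

import numpy as np

GROWING = "growing"
SHRINKING = "shrinking"
STATIC = "static"


class CrossoverRecord:
    """A registered crossing of one MT over another.

    ``crossing_element_index`` indexes the element of the *crossing*
    (later-arriving) MT that lies over the host; it is kept current
    under end-shrinkage and severing.  The record dies as soon as the
    crossing element or the host MT no longer exists.
    """

    __slots__ = ("crossing_mt_id", "crossing_element_index", "host_mt_id",
                 "created_step", "alive")

    def __init__(self, crossing_mt_id, crossing_element_index, host_mt_id,
                 created_step):
        if crossing_mt_id == host_mt_id:
            raise ValueError("a microtubule cannot cross itself")
        self.crossing_mt_id = crossing_mt_id
        self.crossing_element_index = crossing_element_index
        self.host_mt_id = host_mt_id
        self.created_step = created_step
        self.alive = True

    def __repr__(self):  # pragma: no cover
        return (f"CrossoverRecord(crossing={self.crossing_mt_id}"
                f"[{self.crossing_element_index}], host={self.host_mt_id}, "
                f"step={self.created_step}, alive={self.alive})")


class Microtubule:
    """Chain of fixed-length elements with dynamic plus/minus ends."""

    __slots__ = ("id", "vertices", "plus_state", "minus_state", "birth_step",
                 "plus_dir", "grid_refs")

    def __init__(self, mt_id, vertices, plus_dir, plus_state=GROWING,
                 minus_state=STATIC, birth_step=0):
        self.id = mt_id
        self.vertices: List[tuple] = vertices
        self.plus_state = plus_state
        self.minus_state = minus_state
        self.birth_step = birth_step
        self.plus_dir = plus_dir
        self.grid_refs: List[tuple] = []

    @property
    def n_elements(self) -> int:
        return len(self.vertices) - 1

    def element_dir(self, i: int) -> tuple:
        (x0, y0, z0), (x1, y1, z1) = self.vertices[i], self.vertices[i + 1]
        dx, dy, dz = x1 - x0, y1 - y0, z1 - z0
        inv = 1.0 / math.sqrt(dx * dx + dy * dy + dz * dz)
        return (dx * inv, dy * inv, dz * inv)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.vertices, dtype=float)


class SimulationState:
    """All live microtubules plus the crossover registry and the element
    spatial hash (grid cell size >= max(element_length, d_contact))."""

    def __init__(self, domain, params):
        self.domain = domain
        self.step = 0
        self.mts: Dict[int, Microtubule] = {}
        self.next_id = 0
        self.crossovers: List[CrossoverRecord] = []
        self.by_crossing: Dict[int, List[CrossoverRecord]] = {}
        self.by_host: Dict[int, List[CrossoverRecord]] = {}
        self.cell_size = max(params.element_length, params.d_contact)
        self._inv_cell = 1.0 / self.cell_size
        self.grid: Dict[tuple, list] = {}
        # cumulative event counters for the run log
        self.counters = {
            "nucleated": 0, "extended": 0, "bundled": 0, "catastrophe": 0,
            "crossover": 0, "boundary_deflected": 0,
            "boundary_catastrophe": 0, "severed": 0, "died": 0,
        }

    # -- spatial hash --------------------------------------------------
    def cell_key(self, x, y, z):
        ic = self._inv_cell
        return (int(math.floor(x * ic)), int(math.floor(y * ic)),
                int(math.floor(z * ic)))

    def _entry_key(self, entry):
        mx = (entry[1] + entry[4]) * 0.5
        my = (entry[2] + entry[5]) * 0.5
        mz = (entry[3] + entry[6]) * 0.5
        return self.cell_key(mx, my, mz)

    def _grid_add(self, entry):
        key = self._entry_key(entry)
        lst = self.grid.get(key)
        if lst is None:
            self.grid[key] = [entry]
        else:
            lst.append(entry)

    def _grid_remove(self, entry):
        key = self._entry_key(entry)
        lst = self.grid[key]
        lst.remove(entry)
        if not lst:
            del self.grid[key]

    def iter_entries(self):
        for lst in self.grid.values():
            yield from lst

    # -- microtubule lifecycle -----------------------------------------
    def add_mt(self, vertices, plus_dir, plus_state=GROWING,
               minus_state=STATIC) -> Microtubule:
        mt = Microtubule(self.next_id, list(vertices), plus_dir,
                         plus_state, minus_state, birth_step=self.step)
        self.next_id += 1
        self.mts[mt.id] = mt
        for i in range(mt.n_elements):
            (x0, y0, z0), (x1, y1, z1) = mt.vertices[i], mt.vertices[i + 1]
            entry = (mt.id, x0, y0, z0, x1, y1, z1)
            mt.grid_refs.append(entry)
            self._grid_add(entry)
        return mt

    def append_element(self, mt: Microtubule, p_new: tuple, plus_dir: tuple):
        x0, y0, z0 = mt.vertices[-1]
        entry = (mt.id, x0, y0, z0, p_new[0], p_new[1], p_new[2])
        mt.vertices.append(p_new)
        mt.grid_refs.append(entry)
        mt.plus_dir = plus_dir
        self._grid_add(entry)

    def pop_plus_element(self, mt: Microtubule):
        self._grid_remove(mt.grid_refs.pop())
        mt.vertices.pop()
        n = mt.n_elements
        recs = self.by_crossing.get(mt.id)
        if recs:
            for rec in recs:
                if rec.alive and rec.crossing_element_index >= n:
                    rec.alive = False
        if n >= 1:
            mt.plus_dir = mt.element_dir(n - 1)

    def pop_minus_element(self, mt: Microtubule):
        self._grid_remove(mt.grid_refs.pop(0))
        mt.vertices.pop(0)
        recs = self.by_crossing.get(mt.id)
        if recs:
            for rec in recs:
                if rec.alive:
                    rec.crossing_element_index -= 1
                    if rec.crossing_element_index < 0:
                        rec.alive = False

    def kill_mt(self, mt: Microtubule):
        for entry in mt.grid_refs:
            self._grid_remove(entry)
        mt.grid_refs.clear()
        for rec in self.by_crossing.pop(mt.id, ()):
            rec.alive = False
        for rec in self.by_host.pop(mt.id, ()):
            rec.alive = False
        del self.mts[mt.id]
        self.counters["died"] += 1

    # -- crossover registry --------------------------------------------
    def add_crossover(self, crossing_mt_id, element_index, host_mt_id):
        rec = CrossoverRecord(crossing_mt_id, element_index, host_mt_id,
                              self.step)
        self.crossovers.append(rec)
        self.by_crossing.setdefault(crossing_mt_id, []).append(rec)
        self.by_host.setdefault(host_mt_id, []).append(rec)
        return rec

    def compact_crossovers(self):
        """Drop dead records and rebuild the per-MT indices."""
        alive = [r for r in self.crossovers if r.alive]
        self.crossovers = alive
        self.by_crossing = {}
        self.by_host = {}
        for rec in alive:
            self.by_crossing.setdefault(rec.crossing_mt_id, []).append(rec)
            self.by_host.setdefault(rec.host_mt_id, []).append(rec)

    # -- queries --------------------------------------------------------
    def nearest_contact(self, px, py, pz, d_contact, exclude=()):
        """Nearest grid entry within d_contact of point p, skipping the
        entries in ``exclude`` (identity comparison).  Returns (entry,
        distance) or (None, inf)."""
        ic = self._inv_cell
        cx = int(math.floor(px * ic))
        cy = int(math.floor(py * ic))
        cz = int(math.floor(pz * ic))
        grid_get = self.grid.get
        best = None
        best_d2 = d_contact * d_contact
        for ox in (-1, 0, 1):
            for oy in (-1, 0, 1):
                for oz in (-1, 0, 1):
                    lst = grid_get((cx + ox, cy + oy, cz + oz))
                    if not lst:
                        continue
                    for e in lst:
                        skip = False
                        for ex in exclude:
                            if e is ex:
                                skip = True
                                break
                        if skip:
                            continue
                        # point-to-segment squared distance
                        ax, ay, az = e[1], e[2], e[3]
                        bx, by, bz = e[4] - ax, e[5] - ay, e[6] - az
                        wx, wy, wz = px - ax, py - ay, pz - az
                        bb = bx * bx + by * by + bz * bz
                        t = (wx * bx + wy * by + wz * bz) / bb
                        if t < 0.0:
                            t = 0.0
                        elif t > 1.0:
                            t = 1.0
                        qx, qy, qz = wx - t * bx, wy - t * by, wz - t * bz
                        d2 = qx * qx + qy * qy + qz * qz
                        if d2 < best_d2:
                            best_d2 = d2
                            best = e
        return best, math.sqrt(best_d2) if best is not None else math.inf

    # -- summaries -------------------------------------------------------
    def total_elements(self) -> int:
        return sum(mt.n_elements for mt in self.mts.values())

    def total_length(self, element_length: float) -> float:
        return self.total_elements() * element_length

    def polylines(self):
        """Lightweight snapshot: list of (id, vertex array, plus_state)."""
        return [(mt.id, mt.as_array(), mt.plus_state)
                for mt in self.mts.values()]
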