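"""File formats, run configuration and experiment orchestration.

Snapshots go to legacy ASCII VTK PolyData (one polyline per
microtubule, with mt_id and plus_state cell scalars), tabular results
to CSV, configuration to TOML, images to TIFF.  Every artifact embeds
the configuration and seed that produced it, so a results tree is fully
reproducible from the files alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Tuple

import numpy as np
import pandas as pd

try:
    import tomllib
except ModuleNotFoundError:  # pragma: no cover - py<3.11
    import tomli as tomllib

from . import __version__
from .geometry import ConfinementDomain, make_domain
from .params import SimulationParams
from .quantify import face_order_parameters
from .simulator import run
from .stats import ks_two_sample, uniformity_test

__all__ = ["write_vtk_polylines", "read_vtk_polylines", "load_config",
           "domain_from_dict", "ExperimentSpec", "run_experiment"]

_STATE_CODE = {"growing": 1, "shrinking": 0}
_CODE_STATE = {v: k for k, v in _STATE_CODE.items()}


def _polylines_of(state_or_polylines):
    if hasattr(state_or_polylines, "polylines"):
        return state_or_polylines.polylines()
    return state_or_polylines


def write_vtk_polylines(state, path, title: str = "mtconfine snapshot"):
    """Write microtubules as legacy ASCII VTK PolyData.

    POINTS hold the vertices in µm, LINES one polyline per MT, and
    CELL_DATA carries the mt_id and plus_state (1 = growing,
    0 = shrinking) scalars.  Coordinates are printed with 6 decimals,
    so write -> read -> write is byte-identical.
    """
    polylines = _polylines_of(state)
    lines = ["# vtk DataFile Version 3.0", title[:255], "ASCII",
             "DATASET POLYDATA"]
    n_pts = sum(len(v) for _, v, _ in polylines)
    lines.append(f"POINTS {n_pts} float")
    for _, verts, _ in polylines:
        for x, y, z in np.asarray(verts, float):
            lines.append(f"{x:.6f} {y:.6f} {z:.6f}")
    n_mt = len(polylines)
    conn_size = sum(len(v) + 1 for _, v, _ in polylines)
    lines.append(f"LINES {n_mt} {conn_size}")
    offset = 0
    for _, verts, _ in polylines:
        k = len(verts)
        lines.append(" ".join([str(k)] + [str(offset + i) for i in range(k)]))
        offset += k
    lines.append(f"CELL_DATA {n_mt}")
    lines.append("SCALARS mt_id int 1")
    lines.append("LOOKUP_TABLE default")
    for mt_id, _, _ in polylines:
        lines.append(str(int(mt_id)))
    lines.append("SCALARS plus_state int 1")
    lines.append("LOOKUP_TABLE default")
    for _, _, ps in polylines:
        lines.append(str(_STATE_CODE.get(ps, 0)))
    Path(path).write_text("\n".join(lines) + "\n")
    return path


def read_vtk_polylines(path):
    """Read a file written by :func:`write_vtk_polylines`; returns a
    list of (mt_id, (n, 3) vertex array, plus_state) tuples."""
    tokens = Path(path).read_text().split("\n")
    it = iter(tokens)
    points = None
    conn: List[List[int]] = []
    mt_ids: List[int] = []
    states: List[int] = []
    line = next(it)
    if not line.startswith("# vtk DataFile"):
        raise ValueError(f"{path}: not a legacy VTK file")
    next(it)  # title
    if next(it).strip() != "ASCII":
        raise ValueError(f"{path}: only ASCII VTK is supported")
    if next(it).strip() != "DATASET POLYDATA":
        raise ValueError(f"{path}: expected POLYDATA")
    for line in it:
        parts = line.split()
        if not parts:
            continue
        if parts[0] == "POINTS":
            n = int(parts[1])
            vals = []
            while len(vals) < 3 * n:
                vals.extend(float(v) for v in next(it).split())
            points = np.array(vals).reshape(n, 3)
        elif parts[0] == "LINES":
            m = int(parts[1])
            for _ in range(m):
                row = [int(v) for v in next(it).split()]
                if row[0] != len(row) - 1:
                    raise ValueError(f"{path}: bad connectivity row")
                conn.append(row[1:])
        elif parts[0] == "SCALARS":
            name = parts[1]
            next(it)  # LOOKUP_TABLE
            vals = [int(next(it)) for _ in range(len(conn))]
            if name == "mt_id":
                mt_ids = vals
            elif name == "plus_state":
                states = vals
    if points is None:
        raise ValueError(f"{path}: no POINTS section")
    if not mt_ids:
        mt_ids = list(range(len(conn)))
    if not states:
        states = [1] * len(conn)
    return [(mt_ids[i], points[idx], _CODE_STATE.get(states[i], "growing"))
            for i, idx in enumerate(conn)]


# -- configuration -----------------------------------------------------

def domain_from_dict(d: dict) -> ConfinementDomain:
    d = dict(d)
    kind = d.pop("kind")
    return make_domain(kind, **d)


def load_config(path) -> Tuple[ConfinementDomain, SimulationParams, dict]:
    """Read a TOML run configuration.

    Expected tables: ``[domain]`` (kind + dimensions in µm),
    ``[params]`` (SimulationParams fields), and an optional
    ``[experiment]`` table used by :class:`ExperimentSpec`.
    """
    with open(path, "rb") as fh:
        cfg = tomllib.load(fh)
    if "domain" not in cfg:
        raise ValueError(f"{path}: missing [domain] table")
    domain = domain_from_dict(cfg["domain"])
    params = SimulationParams.from_dict(cfg.get("params", {}))
    return domain, params, cfg.get("experiment", {})


# -- experiment orchestration ------------------------------------------

@dataclass
class ExperimentCell:
    """One (domain, params) condition of an experiment grid."""
    label: str
    domain: ConfinementDomain
    params: SimulationParams


@dataclass
class ExperimentSpec:
    """A grid of simulation conditions: shapes x severing probabilities
    (x optional rectangle aspect ratios), each run for R replicates."""
    name: str
    cells: List[ExperimentCell]
    out_dir: Path
    snapshot_every: int = 0
    shell_depth: float = 0.5

    @classmethod
    def from_toml(cls, path) -> "ExperimentSpec":
        with open(path, "rb") as fh:
            cfg = tomllib.load(fh)
        exp = cfg.get("experiment", {})
        base = cfg.get("params", {})
        domains = cfg.get("domains")
        if domains is None:
            domains = [cfg["domain"]]
        p_cross_values = exp.get("p_cross_values", [base.get("p_cross",
                                                             0.005)])
        aspect_ratios = exp.get("aspect_ratios", [])
        cells = []
        domain_dicts = list(domains)
        for ratio in aspect_ratios:
            ly = exp.get("aspect_ly", 15.0)
            lz = exp.get("aspect_lz", 15.0)
            domain_dicts.append({"kind": "box", "lx": ratio * ly, "ly": ly,
                                 "lz": lz, "label": f"aspect_{ratio:g}"})
        for dd in domain_dicts:
            dd = dict(dd)
            label_base = dd.pop("label", None) or dd["kind"]
            domain = domain_from_dict(dd)
            for pc in p_cross_values:
                pdict = dict(base)
                pdict["p_cross"] = pc
                params = SimulationParams.from_dict(pdict)
                cells.append(ExperimentCell(
                    f"{label_base}_pcross_{pc:g}", domain, params))
        return cls(name=exp.get("name", Path(path).stem), cells=cells,
                   out_dir=Path(exp.get("out_dir", "results")),
                   snapshot_every=int(exp.get("snapshot_every", 0)),
                   shell_depth=float(exp.get("shell_depth", 0.5)))


def _cell_provenance(spec: ExperimentSpec, cell: ExperimentCell) -> dict:
    return {"experiment": spec.name, "cell": cell.label,
            "domain": cell.domain.describe(),
            "params": cell.params.to_dict(),
            "mtconfine_version": __version__}


def run_experiment(spec: ExperimentSpec, progress=None) -> pd.DataFrame:
    """Run every cell of the grid, quantify each replicate on both
    analysis faces and write the results tree.

    Layout: ``<out_dir>/<cell>/rep<i>.vtk`` final snapshots (plus
    periodic ones when ``snapshot_every`` > 0), ``quantify.csv`` per
    cell, an aggregate ``quantify.csv`` and ``stats.csv`` at the root
    and a JSON run log per cell.  A cell whose ``done.json`` marker
    exists is skipped, so interrupted experiments resume.
    """
    spec.out_dir.mkdir(parents=True, exist_ok=True)
    frames = []
    for cell in spec.cells:
        cell_dir = spec.out_dir / cell.label
        done = cell_dir / "done.json"
        csv_path = cell_dir / "quantify.csv"
        if done.exists():
            frames.append(pd.read_csv(csv_path))
            continue
        cell_dir.mkdir(parents=True, exist_ok=True)
        prov = _cell_provenance(spec, cell)
        rows = []
        for i in range(cell.params.r_replicates):
            seed = cell.params.seed + i
            summary = run(cell.params, cell.domain,
                          snapshot_every=spec.snapshot_every or None,
                          seed=seed)
            title = (f"mtconfine cell={cell.label} seed={seed} "
                     f"params={json.dumps(cell.params.to_dict())}")
            write_vtk_polylines(summary.final_state,
                                cell_dir / f"rep{i}.vtk", title=title)
            for s_step, polys in zip(summary.snapshot_steps,
                                     summary.snapshots):
                if s_step == cell.params.t_steps:
                    continue
                write_vtk_polylines(polys,
                                    cell_dir / f"rep{i}_step{s_step}.vtk",
                                    title=title)
            fp = face_order_parameters(summary.final_state, cell.domain,
                                       spec.shell_depth)
            for face_name, r in (("top", fp.top), ("bottom", fp.bottom)):
                rows.append({"experiment": spec.name, "cell": cell.label,
                             "replicate": i, "seed": seed,
                             "face": face_name, "s2": r.s2,
                             "theta_s2": r.theta_s2,
                             "n_segments": r.n_segments,
                             "total_weight": r.total_weight})
            rows.append({"experiment": spec.name, "cell": cell.label,
                         "replicate": i, "seed": seed, "face": "both",
                         "s2": fp.s2_mean, "theta_s2": fp.theta_mean,
                         "n_segments": fp.top.n_segments
                         + fp.bottom.n_segments,
                         "total_weight": fp.top.total_weight
                         + fp.bottom.total_weight})
            if progress is not None:
                progress(cell.label, i)
        df = pd.DataFrame(rows)
        df.to_csv(csv_path, index=False)
        done.write_text(json.dumps(prov, indent=2))
        frames.append(df)
    agg = pd.concat(frames, ignore_index=True)
    agg.to_csv(spec.out_dir / "quantify.csv", index=False)
    _write_stats(spec, agg)
    return agg


def _write_stats(spec: ExperimentSpec, agg: pd.DataFrame):
    """Pairwise KS on S2 plus per-cell angle-uniformity Kuiper tests."""
    both = agg[agg["face"] == "both"]
    cells = sorted(both["cell"].unique())
    rows = []
    rng = np.random.default_rng(0)
    for cell in cells:
        sub = both[both["cell"] == cell]
        angles = sub["theta_s2"].dropna().to_numpy()
        if len(angles) >= 5:
            ur = uniformity_test(angles, rng=rng)
            rows.append({"kind": "uniformity_kuiper", "cell_a": cell,
                         "cell_b": "uniform", "metric": "theta_s2",
                         "statistic": float("nan"), "p_value": ur.median_p,
                         "n1": ur.n, "n2": ur.n})
    for i, ca in enumerate(cells):
        for cb in cells[i + 1:]:
            xa = both[both["cell"] == ca]["s2"].dropna().to_numpy()
            xb = both[both["cell"] == cb]["s2"].dropna().to_numpy()
            if len(xa) >= 2 and len(xb) >= 2:
                t = ks_two_sample(xa, xb, rng=rng)
                rows.append({"kind": "ks", "cell_a": ca, "cell_b": cb,
                             "metric": "s2", "statistic": t.statistic,
                             "p_value": t.p_value, "n1": t.n1, "n2": t.n2})
    pd.DataFrame(rows).to_csv(spec.out_dir / "stats.csv", index=False)
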