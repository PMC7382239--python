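"""Confining domain geometries.

Microtubules self-organize inside a closed convex region — the microwell
or (walled) cell that confines the array. Four shapes are supported:
sphere, rectangular box (a box with equal x/y extent is the "square"
domain), equilateral triangular prism and cylinder. All lengths are in
micrometres, the domain is centred at the origin, the rectangle's long
axis is +x and the imaging/analysis axis is z.

The primitives here are the ones the simulation engine needs to keep
filaments inside the membrane: a closed-set containment test, the first
exit point of a growth step along a ray (with the outward normal and the
incidence angle at the hit), and the tangential deflection applied when a
growing tip meets the membrane at a shallow angle. ``analysis_faces``
exposes the two opposite z-extremal faces on which the 2D order
parameter is measured.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfinementDomain",
    "Sphere",
    "Box",
    "TriangularPrism",
    "Cylinder",
    "Face",
    "BoundaryHit",
    "DegenerateDeflection",
    "make_domain",
    "deflect",
    "boundary_hit",
]

_EPS = 1e-9
_SQRT3 = math.sqrt(3.0)


class DegenerateDeflection(ValueError):
    """Raised when a tip hits the membrane head-on and no tangential
    continuation exists; the caller must fall back to a catastrophe."""


@dataclass(frozen=True)
class Face:
    """One of the two opposite analysis faces of a domain.

    ``kind`` is ``"plane"`` for flat faces (boxes, prisms, cylinder caps)
    and ``"cap"`` for the hemispherical caps of a sphere.  ``z`` is the
    plane height for flat faces; ``zsign`` selects the hemisphere for
    caps.  ``axis_u``/``axis_v`` form the in-plane orthonormal frame:
    ``axis_u`` is the 0-degree reference (the domain's +x, i.e. the
    rectangle's long axis).
    """

    name: str
    kind: str  # "plane" | "cap"
    zsign: int
    z: float
    radius: float = 0.0  # sphere radius for caps
    axis_u: tuple = (1.0, 0.0, 0.0)
    axis_v: tuple = (0.0, 1.0, 0.0)


@dataclass(frozen=True)
class BoundaryHit:
    hit_point: tuple
    outward_normal: tuple
    incidence_angle: float  # degrees; 0 = grazing, 90 = head-on
    t: float  # distance from the ray origin to the hit


class ConfinementDomain:
    """Abstract convex confinement region centred at the origin."""

    kind: str = "abstract"

    # -- containment ---------------------------------------------------
    def contains_xyz(self, x: float, y: float, z: float) -> bool:
        raise NotImplementedError

    def contains(self, p) -> bool:
        """Closed-set containment: boundary points count as inside."""
        x, y, z = float(p[0]), float(p[1]), float(p[2])
        if not (math.isfinite(x) and math.isfinite(y) and math.isfinite(z)):
            raise ValueError(f"non-finite point {p!r}")
        return self.contains_xyz(x, y, z)

    def contains_many(self, pts: np.ndarray) -> np.ndarray:
        """Vectorized containment for an (n, 3) array."""
        raise NotImplementedError

    # -- ray exit ------------------------------------------------------
    def ray_exit(self, p, d):
        """Smallest t > 0 at which p + t*d leaves the domain, and the
        outward unit normal there. p must be inside."""
        raise NotImplementedError

    # -- sampling ------------------------------------------------------
    def bbox(self):
        """Axis-aligned ((xmin, ymin, zmin), (xmax, ymax, zmax))."""
        raise NotImplementedError

    def sample_point(self, rng) -> tuple:
        """Uniform interior point (rejection from the bounding box)."""
        (x0, y0, z0), (x1, y1, z1) = self.bbox()
        for _ in range(10000):
            x = x0 + (x1 - x0) * rng.random()
            y = y0 + (y1 - y0) * rng.random()
            z = z0 + (z1 - z0) * rng.random()
            if self.contains_xyz(x, y, z):
                return (x, y, z)
        raise RuntimeError("rejection sampling failed")  # pragma: no cover

    def sample_surface(self, rng):
        """Uniform boundary point and its outward unit normal."""
        raise NotImplementedError

    def analysis_faces(self) -> tuple:
        """The two opposite faces perpendicular to the analysis (z) axis."""
        raise NotImplementedError

    def describe(self) -> dict:
        raise NotImplementedError


def _check_positive(**dims):
    for name, v in dims.items():
        if not (v > 0):
            raise ValueError(f"{name} must be strictly positive, got {v}")


class Sphere(ConfinementDomain):
    kind = "sphere"

    def __init__(self, radius: float):
        _check_positive(radius=radius)
        self.radius = float(radius)

    def contains_xyz(self, x, y, z):
        return x * x + y * y + z * z <= self.radius * self.radius + _EPS

    def contains_many(self, pts):
        pts = np.asarray(pts, float)
        return np.einsum("ij,ij->i", pts, pts) <= self.radius**2 + _EPS

    def ray_exit(self, p, d):
        # |p + t d|^2 = r^2, take the positive root
        px, py, pz = p
        dx, dy, dz = d
        b = px * dx + py * dy + pz * dz
        c = px * px + py * py + pz * pz - self.radius * self.radius
        disc = b * b - c
        t = -b + math.sqrt(max(disc, 0.0))
        hx, hy, hz = px + t * dx, py + t * dy, pz + t * dz
        inv = 1.0 / math.sqrt(hx * hx + hy * hy + hz * hz)
        return t, (hx * inv, hy * inv, hz * inv)

    def bbox(self):
        r = self.radius
        return (-r, -r, -r), (r, r, r)

    def sample_surface(self, rng):
        v = rng.standard_normal(3)
        n = v / np.linalg.norm(v)
        r = self.radius
        return (r * n[0], r * n[1], r * n[2]), (n[0], n[1], n[2])

    def analysis_faces(self):
        return (
            Face("top", "cap", +1, 0.0, radius=self.radius),
            Face("bottom", "cap", -1, 0.0, radius=self.radius),
        )

    def describe(self):
        return {"kind": self.kind, "radius": self.radius}


class Box(ConfinementDomain):
    """Rectangular box; Lx = Ly gives the square domain, Lx > Ly the
    rectangle (long axis +x by convention)."""

    kind = "box"

    def __init__(self, lx: float, ly: float, lz: float):
        _check_positive(lx=lx, ly=ly, lz=lz)
        self.lx, self.ly, self.lz = float(lx), float(ly), float(lz)
        self.hx, self.hy, self.hz = lx / 2.0, ly / 2.0, lz / 2.0

    def contains_xyz(self, x, y, z):
        return (
            -self.hx - _EPS <= x <= self.hx + _EPS
            and -self.hy - _EPS <= y <= self.hy + _EPS
            and -self.hz - _EPS <= z <= self.hz + _EPS
        )

    def contains_many(self, pts):
        pts = np.asarray(pts, float)
        h = np.array([self.hx, self.hy, self.hz])
        return np.all(np.abs(pts) <= h + _EPS, axis=1)

    def ray_exit(self, p, d):
        best_t, best_n = math.inf, (1.0, 0.0, 0.0)
        for axis, (pi, di, h) in enumerate(
            zip(p, d, (self.hx, self.hy, self.hz))
        ):
            if di > _EPS:
                t = (h - pi) / di
                n = [0.0, 0.0, 0.0]
                n[axis] = 1.0
            elif di < -_EPS:
                t = (-h - pi) / di
                n = [0.0, 0.0, 0.0]
                n[axis] = -1.0
            else:
                continue
            if t < best_t:
                best_t, best_n = t, tuple(n)
        return best_t, best_n

    def bbox(self):
        return (-self.hx, -self.hy, -self.hz), (self.hx, self.hy, self.hz)

    def sample_surface(self, rng):
        areas = np.array(
            [self.ly * self.lz, self.lx * self.lz, self.lx * self.ly]
        )
        axis = int(rng.choice(3, p=areas / areas.sum()))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        p = [
            (2 * rng.random() - 1) * self.hx,
            (2 * rng.random() - 1) * self.hy,
            (2 * rng.random() - 1) * self.hz,
        ]
        p[axis] = sign * (self.hx, self.hy, self.hz)[axis]
        n = [0.0, 0.0, 0.0]
        n[axis] = sign
        return tuple(p), tuple(n)

    def analysis_faces(self):
        return (
            Face("top", "plane", +1, self.hz),
            Face("bottom", "plane", -1, -self.hz),
        )

    def describe(self):
        return {"kind": self.kind, "lx": self.lx, "ly": self.ly, "lz": self.lz}


class TriangularPrism(ConfinementDomain):
    """Equilateral triangular prism, one side parallel to +x, centroid at
    the origin; ``side`` is the triangle edge length, ``height`` the z
    extent."""

    kind = "triangular_prism"

    def __init__(self, side: float, height: float):
        _check_positive(side=side, height=height)
        self.side, self.height = float(side), float(height)
        self.hz = height / 2.0
        self.r_in = side / (2.0 * _SQRT3)  # inradius
        # outward normals of the three lateral faces (unit, z = 0)
        self._normals = (
            (0.0, -1.0, 0.0),
            (_SQRT3 / 2.0, 0.5, 0.0),
            (-_SQRT3 / 2.0, 0.5, 0.0),
        )

    def contains_xyz(self, x, y, z):
        if abs(z) > self.hz + _EPS:
            return False
        r = self.r_in + _EPS
        for nx, ny, _ in self._normals:
            if nx * x + ny * y > r:
                return False
        return True

    def contains_many(self, pts):
        pts = np.asarray(pts, float)
        ok = np.abs(pts[:, 2]) <= self.hz + _EPS
        for nx, ny, _ in self._normals:
            ok &= nx * pts[:, 0] + ny * pts[:, 1] <= self.r_in + _EPS
        return ok

    def _planes(self):
        for n in self._normals:
            yield n, self.r_in
        yield (0.0, 0.0, 1.0), self.hz
        yield (0.0, 0.0, -1.0), self.hz

    def ray_exit(self, p, d):
        best_t, best_n = math.inf, (0.0, 0.0, 1.0)
        for n, b in self._planes():
            dn = n[0] * d[0] + n[1] * d[1] + n[2] * d[2]
            if dn > _EPS:
                t = (b - (n[0] * p[0] + n[1] * p[1] + n[2] * p[2])) / dn
                if t < best_t:
                    best_t, best_n = t, n
        return best_t, best_n

    def bbox(self):
        a = self.side
        y_top = a / _SQRT3
        return (-a / 2, -self.r_in, -self.hz), (a / 2, y_top, self.hz)

    def sample_surface(self, rng):
        tri_area = _SQRT3 / 4.0 * self.side**2
        lat_area = self.side * self.height
        areas = np.array([lat_area] * 3 + [tri_area] * 2)
        i = int(rng.choice(5, p=areas / areas.sum()))
        if i < 3:
            n = self._normals[i]
            # base point on the face: inradius along n, spread along the edge
            tx, ty = -n[1], n[0]  # edge direction
            s = (rng.random() - 0.5) * self.side
            z = (2 * rng.random() - 1) * self.hz
            return (
                (self.r_in * n[0] + s * tx, self.r_in * n[1] + s * ty, z),
                n,
            )
        sign = 1.0 if i == 3 else -1.0
        while True:
            x, y, _ = self.sample_point(rng)
            return (x, y, sign * self.hz), (0.0, 0.0, sign)

    def analysis_faces(self):
        return (
            Face("top", "plane", +1, self.hz),
            Face("bottom", "plane", -1, -self.hz),
        )

    def describe(self):
        return {"kind": self.kind, "side": self.side, "height": self.height}


class Cylinder(ConfinementDomain):
    """Circular cylinder with axis z."""

    kind = "cylinder"

    def __init__(self, radius: float, height: float):
        _check_positive(radius=radius, height=height)
        self.radius, self.height = float(radius), float(height)
        self.hz = height / 2.0

    def contains_xyz(self, x, y, z):
        return (
            abs(z) <= self.hz + _EPS
            and x * x + y * y <= self.radius * self.radius + _EPS
        )

    def contains_many(self, pts):
        pts = np.asarray(pts, float)
        return (np.abs(pts[:, 2]) <= self.hz + _EPS) & (
            pts[:, 0] ** 2 + pts[:, 1] ** 2 <= self.radius**2 + _EPS
        )

    def ray_exit(self, p, d):
        best_t, best_n = math.inf, (0.0, 0.0, 1.0)
        # caps
        if d[2] > _EPS:
            best_t, best_n = (self.hz - p[2]) / d[2], (0.0, 0.0, 1.0)
        elif d[2] < -_EPS:
            best_t, best_n = (-self.hz - p[2]) / d[2], (0.0, 0.0, -1.0)
        # lateral surface: (px + t dx)^2 + (py + t dy)^2 = r^2
        a = d[0] * d[0] + d[1] * d[1]
        if a > _EPS * _EPS:
            b = (p[0] * d[0] + p[1] * d[1]) / a
            c = (p[0] * p[0] + p[1] * p[1] - self.radius**2) / a
            disc = b * b - c
            t = -b + math.sqrt(max(disc, 0.0))
            if t < best_t:
                hx, hy = p[0] + t * d[0], p[1] + t * d[1]
                inv = 1.0 / math.hypot(hx, hy)
                best_t, best_n = t, (hx * inv, hy * inv, 0.0)
        return best_t, best_n

    def bbox(self):
        r = self.radius
        return (-r, -r, -self.hz), (r, r, self.hz)

    def sample_surface(self, rng):
        lat = 2 * math.pi * self.radius * self.height
        cap = math.pi * self.radius**2
        u = rng.random() * (lat + 2 * cap)
        if u < lat:
            phi = 2 * math.pi * rng.random()
            z = (2 * rng.random() - 1) * self.hz
            n = (math.cos(phi), math.sin(phi), 0.0)
            return (self.radius * n[0], self.radius * n[1], z), n
        sign = 1.0 if u < lat + cap else -1.0
        while True:
            r = self.radius * math.sqrt(rng.random())
            phi = 2 * math.pi * rng.random()
            return (
                (r * math.cos(phi), r * math.sin(phi), sign * self.hz),
                (0.0, 0.0, sign),
            )

    def analysis_faces(self):
        return (
            Face("top", "plane", +1, self.hz),
            Face("bottom", "plane", -1, -self.hz),
        )

    def describe(self):
        return {"kind": self.kind, "radius": self.radius, "height": self.height}


_KINDS = {
    "sphere": Sphere,
    "box": Box,
    "triangular_prism": TriangularPrism,
    "cylinder": Cylinder,
}


def make_domain(kind: str, **dims) -> ConfinementDomain:
    """Factory from a shape name and its dimensions in micrometres.

    >>> make_domain("box", lx=40, ly=15, lz=15).contains((0, 0, 0))
    True
    """
    try:
        cls = _KINDS[kind]
    except KeyError:
        raise ValueError(
            f"unknown domain kind {kind!r}; choose from {sorted(_KINDS)}"
        ) from None
    return cls(**dims)


def boundary_hit(domain, p_inside, direction, step_len):
    """First membrane intersection of a growth step, or None.

    Returns None when ``p_inside + step_len * direction`` stays inside;
    otherwise a :class:`BoundaryHit` with the hit point, the outward unit
    normal and the incidence angle in degrees (0 = grazing the membrane,
    90 = head-on).
    """
    if not domain.contains(p_inside):
        raise ValueError(f"ray origin {p_inside!r} is outside the domain")
    if step_len <= 0:
        raise ValueError("step_len must be positive")
    px, py, pz = float(p_inside[0]), float(p_inside[1]), float(p_inside[2])
    dx, dy, dz = float(direction[0]), float(direction[1]), float(direction[2])
    norm = math.sqrt(dx * dx + dy * dy + dz * dz)
    if abs(norm - 1.0) > 1e-6:
        raise ValueError("direction must be a unit vector")
    qx, qy, qz = px + step_len * dx, py + step_len * dy, pz + step_len * dz
    if domain.contains_xyz(qx, qy, qz):
        return None
    t, n = domain.ray_exit((px, py, pz), (dx, dy, dz))
    t = min(max(t, 0.0), step_len)
    cos_to_normal = dx * n[0] + dy * n[1] + dz * n[2]
    incidence = math.degrees(math.asin(min(max(cos_to_normal, -1.0), 1.0)))
    return BoundaryHit(
        hit_point=(px + t * dx, py + t * dy, pz + t * dz),
        outward_normal=n,
        incidence_angle=incidence,
        t=t,
    )


def deflect(direction, outward_normal):
    """Project a growth direction into the membrane tangent plane.

    Returns the unit vector along ``direction - (direction . n) n``.
    Raises :class:`DegenerateDeflection` on a head-on hit (no tangential
    component), in which case the caller triggers a catastrophe.
    """
    dx, dy, dz = direction
    nx, ny, nz = outward_normal
    dot = dx * nx + dy * ny + dz * nz
    tx, ty, tz = dx - dot * nx, dy - dot * ny, dz - dot * nz
    norm = math.sqrt(tx * tx + ty * ty + tz * tz)
    if norm < 1e-9:
        raise DegenerateDeflection("head-on membrane hit")
    return (tx / norm, ty / norm, tz / norm)
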