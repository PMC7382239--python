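"""Array-order quantification.

Two routes measure the alignment of a microtubule array, mirroring how
confocal data of confined protoplasts are analysed:

*Segment route.*  Elements near one of the two opposite analysis faces
are orthogonally projected into the face plane and summarized by the 2D
nematic order parameter

    S2      = |< exp(2 i theta) >_w|          (0 isotropic .. 1 aligned)
    ThetaS2 = 1/2 arg < exp(2 i theta) >_w    (dominant axis, degrees)

with theta the segment angle to the face's 0-degree reference (the
domain's +x, i.e. the rectangle's long axis) and weights w the
projected segment lengths.

*Image route.*  A grayscale image is summarized by the intensity-
gradient nematic tensor: per-pixel fibril orientations (gradients
rotated by 90 degrees) are averaged into a unit-trace second-moment
tensor weighted by gradient magnitude; anisotropy is the eigenvalue
difference and the angle the principal axis.  This is the standard
fibril-anisotropy measure used for cytoskeletal images, and it is
invariant to affine intensity rescaling.

``render_image`` closes the loop: it rasterizes projected segments into
a synthetic maximum-intensity-projection-like image (Gaussian PSF,
optional Poisson noise) so both routes can be cross-validated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import polygon2mask

from .geometry import Face

__all__ = [
    "OrderParameterResult", "FacePairResult", "ImageAnisotropyResult",
    "face_projection", "s2_order", "face_order_parameters",
    "nematic_tensor_image", "render_image", "fixtures",
    "parallel_array", "orthogonal_grid", "isotropic", "diagonal_square",
]

_S2_TOL = 1e-9


@dataclass(frozen=True)
class OrderParameterResult:
    """S2 in [0, 1] and the dominant axis ThetaS2 in (-90, 90] degrees;
    ``theta_s2`` is None when the direction is undefined (S2 ~ 0 or no
    segments)."""
    s2: float
    theta_s2: Optional[float]
    n_segments: int
    total_weight: float

    @property
    def defined(self) -> bool:
        return self.n_segments > 0 and self.total_weight > 0.0


@dataclass(frozen=True)
class FacePairResult:
    """Per-face order parameters plus the weight-weighted aggregate over
    the two opposite faces."""
    top: OrderParameterResult
    bottom: OrderParameterResult
    s2_mean: float
    theta_mean: Optional[float]


@dataclass(frozen=True)
class ImageAnisotropyResult:
    """anisotropy = lambda1 - lambda2 of the unit-trace nematic tensor;
    angle = principal axis in (-90, 90] degrees."""
    anisotropy: float
    angle: Optional[float]
    n_pixels: int

    @property
    def defined(self) -> bool:
        return self.n_pixels > 0 and math.isfinite(self.anisotropy)


def _as_polylines(obj):
    """Accept a SimulationState, a TrajectorySummary-final-state, or a
    list of polylines / vertex arrays; yield (n, 3) float arrays."""
    if hasattr(obj, "polylines"):
        obj = obj.polylines()
    out = []
    for item in obj:
        if isinstance(item, tuple) and len(item) == 3:
            out.append(np.asarray(item[1], float))
        else:
            out.append(np.asarray(item, float))
    return out


def face_projection(state, face: Face, shell_depth: float = 0.5) -> np.ndarray:
    """Project element portions within ``shell_depth`` of a face into
    its in-plane frame.

    Returns an (n, 4) array of 2D segments [x0, y0, x1, y1]; the weight
    of a segment is its projected length.  For planar faces elements
    are clipped exactly to the shell slab; for spherical caps whole
    elements are selected by their midpoint (elements are much shorter
    than the shell).
    """
    if shell_depth <= 0:
        raise ValueError("shell_depth must be positive")
    segs = []
    for verts in _as_polylines(state):
        if len(verts) < 2:
            continue
        p0, p1 = verts[:-1], verts[1:]
        if face.kind == "plane":
            z0, z1 = p0[:, 2], p1[:, 2]
            lo, hi = face.z - shell_depth, face.z + shell_depth
            dz = z1 - z0
            flat = np.abs(dz) < 1e-12
            with np.errstate(divide="ignore", invalid="ignore"):
                ta = (lo - z0) / dz
                tb = (hi - z0) / dz
            t0 = np.minimum(ta, tb)
            t1 = np.maximum(ta, tb)
            inside_flat = (z0 > lo) & (z0 < hi)
            t0 = np.where(flat, np.where(inside_flat, 0.0, 1.0), t0)
            t1 = np.where(flat, np.where(inside_flat, 1.0, 1.0), t1)
            t0 = np.clip(t0, 0.0, 1.0)
            t1 = np.clip(t1, 0.0, 1.0)
            keep = t1 - t0 > 1e-12
            if not np.any(keep):
                continue
            a = p0[keep] + t0[keep, None] * (p1[keep] - p0[keep])
            b = p0[keep] + t1[keep, None] * (p1[keep] - p0[keep])
        else:  # spherical cap
            mid = 0.5 * (p0 + p1)
            r = np.linalg.norm(mid, axis=1)
            keep = (np.abs(face.radius - r) < shell_depth) & (
                mid[:, 2] * face.zsign >= 0.0)
            if not np.any(keep):
                continue
            a, b = p0[keep], p1[keep]
        u = np.asarray(face.axis_u)
        v = np.asarray(face.axis_v)
        segs.append(np.column_stack([a @ u, a @ v, b @ u, b @ v]))
    if not segs:
        return np.empty((0, 4))
    out = np.vstack(segs)
    length = np.hypot(out[:, 2] - out[:, 0], out[:, 3] - out[:, 1])
    return out[length > 1e-12]


def s2_order(segments: np.ndarray) -> OrderParameterResult:
    """Weighted 2D nematic order parameter of (n, 4) segments.

    Weights are segment lengths; the result is invariant to segment
    ordering, to per-segment orientation flips and to uniform weight
    rescaling, and rotates with the frame.
    """
    segments = np.asarray(segments, float)
    if segments.size == 0:
        return OrderParameterResult(float("nan"), None, 0, 0.0)
    dx = segments[:, 2] - segments[:, 0]
    dy = segments[:, 3] - segments[:, 1]
    w = np.hypot(dx, dy)
    total = float(w.sum())
    if total <= 0.0:
        return OrderParameterResult(float("nan"), None, len(segments), 0.0)
    # algebraic double-angle form: cos2t = (dx^2-dy^2)/L^2, sin2t = 2dxdy/L^2
    # (trig-free, so symmetric configurations cancel exactly)
    l2 = dx * dx + dy * dy
    c = float(np.sum(w * (dx * dx - dy * dy) / l2) / total)
    s = float(np.sum(w * (2.0 * dx * dy) / l2) / total)
    s2 = math.hypot(c, s)
    if s2 > _S2_TOL:
        ang = 0.5 * math.degrees(math.atan2(s, c))
        if ang <= -90.0:
            ang += 180.0
        theta_s2 = ang
    else:
        theta_s2 = None
    return OrderParameterResult(min(s2, 1.0), theta_s2, len(segments), total)


def face_order_parameters(state, domain, shell_depth: float = 0.5
                          ) -> FacePairResult:
    """Order parameter on both opposite analysis faces, plus the
    weight-weighted mean S2 and the axis of the combined nematic
    resultant."""
    top_face, bottom_face = domain.analysis_faces()
    res = []
    vecs = []
    for face in (top_face, bottom_face):
        segs = face_projection(state, face, shell_depth)
        r = s2_order(segs)
        res.append(r)
        if r.defined and r.theta_s2 is not None:
            two_t = math.radians(2.0 * r.theta_s2)
            vecs.append((r.total_weight * r.s2 * math.cos(two_t),
                         r.total_weight * r.s2 * math.sin(two_t),
                         r.total_weight))
    top, bottom = res
    w_tot = sum(r.total_weight for r in res if r.defined)
    if w_tot > 0:
        s2_mean = sum(r.s2 * r.total_weight for r in res if r.defined) / w_tot
    else:
        s2_mean = float("nan")
    if vecs:
        cx = sum(v[0] for v in vecs)
        cy = sum(v[1] for v in vecs)
        ang = 0.5 * math.degrees(math.atan2(cy, cx))
        if ang <= -90.0:
            ang += 180.0
        theta_mean = ang
    else:
        theta_mean = None
    return FacePairResult(top, bottom, s2_mean, theta_mean)


def nematic_tensor_image(image: np.ndarray, roi=None,
                         eps: Optional[float] = None
                         ) -> ImageAnisotropyResult:
    """Intensity-gradient nematic tensor of a grayscale image.

    Per-pixel gradients are taken by central differences; the fibril
    orientation at a pixel is the gradient rotated by 90 degrees; the
    unit-trace tensor averages fibril outer products weighted by the
    gradient magnitude.  ``roi`` is an optional polygon, an (n, 2)
    array of (row, col) vertices; it must cover at least 9 pixels.  An
    all-constant image has no gradients and yields an undefined result.
    """
    image = np.asarray(image, float)
    if image.ndim != 2:
        raise ValueError("expected a 2D grayscale image")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    if roi is not None:
        mask = polygon2mask(image.shape, np.asarray(roi, float))
    else:
        mask = np.ones(image.shape, bool)
    if mask.sum() < 9:
        raise ValueError("ROI must cover at least 9 pixels")
    gy, gx = np.gradient(image)
    g = np.hypot(gx, gy)
    if eps is None:
        gmax = g[mask].max() if mask.any() else 0.0
        eps = 1e-9 * gmax
    valid = mask & (g > eps) if eps > 0 else mask & (g > 0)
    n = int(valid.sum())
    if n == 0:
        return ImageAnisotropyResult(float("nan"), None, 0)
    gxv, gyv, gv = gx[valid], gy[valid], g[valid]
    # fibril unit vector f = (-gy, gx)/|g|; tensor entries weighted by |g|
    wsum = gv.sum()
    mxx = float(np.sum(gyv * gyv / gv) / wsum)
    myy = float(np.sum(gxv * gxv / gv) / wsum)
    mxy = float(np.sum(-gxv * gyv / gv) / wsum)
    aniso = math.hypot(mxx - myy, 2.0 * mxy)
    if aniso > _S2_TOL:
        ang = 0.5 * math.degrees(math.atan2(2.0 * mxy, mxx - myy))
        if ang <= -90.0:
            ang += 180.0
    else:
        ang = None
    return ImageAnisotropyResult(min(aniso, 1.0), ang, n)


def render_image(state=None, face: Optional[Face] = None,
                 psf_sigma: float = 0.15, pixel_size: float = 0.1,
                 noise: float = 0.0, rng=None, shell_depth: float = 0.5,
                 segments: Optional[np.ndarray] = None,
                 extent=None) -> np.ndarray:
    """Rasterize projected elements into a synthetic fluorescence image.

    Unit intensity per unit filament length, convolved with a Gaussian
    PSF of ``psf_sigma`` (µm); ``noise`` > 0 adds Poisson shot noise
    with that many expected photons per unit intensity (deterministic
    given ``rng``).  The image axes are (row = y, col = x) in the face
    frame; ``extent`` ((xmin, xmax), (ymin, ymax)) defaults to the
    segment bounding box padded by 1 µm.
    """
    if segments is None:
        if state is None or face is None:
            raise ValueError("provide either segments or (state, face)")
        segments = face_projection(state, face, shell_depth)
    segments = np.asarray(segments, float)
    if extent is None:
        if segments.size:
            xs = np.concatenate([segments[:, 0], segments[:, 2]])
            ys = np.concatenate([segments[:, 1], segments[:, 3]])
            extent = ((xs.min() - 1.0, xs.max() + 1.0),
                      (ys.min() - 1.0, ys.max() + 1.0))
        else:
            extent = ((-1.0, 1.0), (-1.0, 1.0))
    (x0, x1), (y0, y1) = extent
    nx = max(int(math.ceil((x1 - x0) / pixel_size)), 4)
    ny = max(int(math.ceil((y1 - y0) / pixel_size)), 4)
    img = np.zeros((ny, nx))
    ds = pixel_size / 2.0
    for sx0, sy0, sx1, sy1 in segments:
        length = math.hypot(sx1 - sx0, sy1 - sy0)
        k = max(int(math.ceil(length / ds)), 1)
        t = (np.arange(k) + 0.5) / k
        px = sx0 + t * (sx1 - sx0)
        py = sy0 + t * (sy1 - sy0)
        # bilinear splat to the four neighbouring pixel centres
        fx = (px - x0) / pixel_size - 0.5
        fy = (py - y0) / pixel_size - 0.5
        ix = np.floor(fx).astype(int)
        iy = np.floor(fy).astype(int)
        wx = fx - ix
        wy = fy - iy
        amp = length / k
        for dx_, dy_, w in ((0, 0, (1 - wx) * (1 - wy)),
                            (1, 0, wx * (1 - wy)),
                            (0, 1, (1 - wx) * wy),
                            (1, 1, wx * wy)):
            np.add.at(img,
                      (np.clip(iy + dy_, 0, ny - 1),
                       np.clip(ix + dx_, 0, nx - 1)),
                      amp * w)
    img = gaussian_filter(img, sigma=psf_sigma / pixel_size)
    if noise > 0.0:
        if rng is None:
            rng = np.random.default_rng(0)
        img = rng.poisson(img * noise).astype(float) / noise
    return img


# -- canonical synthetic segment sets ----------------------------------

def parallel_array(theta0: float, n: int, length: float = 1.0,
                   rng=None) -> np.ndarray:
    """n unit segments all at angle theta0 (degrees): S2 = 1 exactly."""
    if rng is None:
        rng = np.random.default_rng(0)
    t = math.radians(theta0)
    origins = rng.uniform(-5.0, 5.0, size=(n, 2))
    c, s = math.cos(t), math.sin(t)
    # snap axis-aligned directions so symmetric fixtures cancel exactly
    if abs(c) < 1e-15:
        c = 0.0
    if abs(s) < 1e-15:
        s = 0.0
    d = np.array([c, s]) * length
    return np.column_stack([origins, origins + d])


def orthogonal_grid(n: int, length: float = 1.0, rng=None) -> np.ndarray:
    """n segments at 0 degrees plus n at 90: S2 = 0 by cancellation."""
    if rng is None:
        rng = np.random.default_rng(0)
    a = parallel_array(0.0, n, length, rng)
    b = parallel_array(90.0, n, length, rng)
    return np.vstack([a, b])


def isotropic(n: int, length: float = 1.0, rng=None) -> np.ndarray:
    """n unit segments at uniform angles; E[S2] ~ sqrt(pi / (4 n))."""
    if rng is None:
        rng = np.random.default_rng(0)
    theta = rng.uniform(0.0, math.pi, size=n)
    origins = rng.uniform(-5.0, 5.0, size=(n, 2))
    d = length * np.column_stack([np.cos(theta), np.sin(theta)])
    return np.column_stack([origins, origins + d])


def diagonal_square(n: int, bias: float = 1.0, length: float = 1.0,
                    rng=None) -> np.ndarray:
    """Segments along both diagonals of a square (+45 / -45 degrees);
    the +45 family carries ``bias`` times the weight of the other, so
    S2 = (bias - 1) / (bias + 1)."""
    if rng is None:
        rng = np.random.default_rng(0)
    a = parallel_array(45.0, n, length * bias, rng)
    b = parallel_array(-45.0, n, length, rng)
    return np.vstack([a, b])


_FIXTURES = {
    "parallel_array": parallel_array,
    "orthogonal_grid": orthogonal_grid,
    "isotropic": isotropic,
    "diagonal_square": diagonal_square,
}


def fixtures(name: str, seed: int = 0, **kwargs) -> np.ndarray:
    """Canonical synthetic segment sets by name, seeded."""
    try:
        fn = _FIXTURES[name]
    except KeyError:
        raise ValueError(
            f"unknown fixture {name!r}; choose from {sorted(_FIXTURES)}"
        ) from None
    return fn(rng=np.random.default_rng(seed), **kwargs)
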