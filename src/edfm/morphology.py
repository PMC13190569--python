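"""Morphological half of the growth loop.

NURBS organ surfaces (evaluation, area quadrature, least-squares fitting
from point clouds, affine rescaling to a target size), the logistic
organ-expansion law on physiological development time, and canopy light
interception by vertical-beam ray casting with a Beer-Lambert closed
form as an independent cross-check.

Coordinates are right-handed with z up, metres internally; organ sizes
at the trait-reporting boundary are cm (leaf length / internode length)
and cm2 (leaf area).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .errors import FitError, InvalidArgumentError

__all__ = [
    "GrowthParams",
    "NurbsSurface",
    "CanopyScene",
    "InterceptionResult",
    "logistic_size",
    "clamped_uniform_knots",
    "eval_surface",
    "surface_area",
    "fit_leaf_surface",
    "scale_organ_to_size",
    "tessellate",
    "nurbs_plane",
    "nurbs_cylinder_patch",
    "nurbs_leaf_template",
    "light_interception",
    "beer_lambert_fraction",
    "make_horizontal_leaf_canopy",
    "render_canopy_image",
    "sample_scene_points",
    "export_scene_obj",
]


# --------------------------------------------------------------------------
# Logistic organ expansion on thermal time
# --------------------------------------------------------------------------


@dataclass
class GrowthParams:
    """Logistic growth law parameters.

    ``size_max`` is the asymptote (cm2 for leaf area, cm for internode
    length), ``k`` the rate per physiological day, ``pdt_mid`` the
    physiological day of the inflection (half of the asymptote).
    """

    size_max: float
    k: float = 0.15
    pdt_mid: float = 20.0

    def __post_init__(self) -> None:
        if self.size_max <= 0 or self.k <= 0 or self.pdt_mid <= 0:
            raise InvalidArgumentError("size_max, k and pdt_mid must be positive")


def logistic_size(pdt: float | np.ndarray, params: GrowthParams) -> float | np.ndarray:
    """Potential organ size L(PDT) = size_max / (1 + exp(-k (PDT - pdt_mid)))."""
    return params.size_max / (1.0 + np.exp(-params.k * (np.asarray(pdt, float) - params.pdt_mid)))


# --------------------------------------------------------------------------
# NURBS basis machinery (Cox-de Boor, clamped knots on [0, 1])
# --------------------------------------------------------------------------


def clamped_uniform_knots(n_ctrl: int, degree: int) -> np.ndarray:
    """Clamped uniform knot vector on [0, 1] for ``n_ctrl`` control points."""
    if n_ctrl < degree + 1:
        raise InvalidArgumentError("need at least degree+1 control points")
    n_interior = n_ctrl - degree - 1
    interior = np.arange(1, n_interior + 1) / (n_interior + 1)
    return np.concatenate([np.zeros(degree + 1), interior, np.ones(degree + 1)])


def _find_span(n_ctrl: int, degree: int, u: float, knots: np.ndarray) -> int:
    if u >= knots[n_ctrl]:
        return n_ctrl - 1
    lo, hi = degree, n_ctrl
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if u < knots[mid]:
            hi = mid
        else:
            lo = mid
    return lo


def _basis_funs(span: int, u: float, degree: int, knots: np.ndarray) -> np.ndarray:
    """Nonzero B-spline basis values N_{span-degree..span} at u."""
    N = np.zeros(degree + 1)
    N[0] = 1.0
    left = np.zeros(degree + 1)
    right = np.zeros(degree + 1)
    for j in range(1, degree + 1):
        left[j] = u - knots[span + 1 - j]
        right[j] = knots[span + j] - u
        saved = 0.0
        for r in range(j):
            temp = N[r] / (right[r + 1] + left[j - r])
            N[r] = saved + right[r + 1] * temp
            saved = left[j - r] * temp
        N[j] = saved
    return N


def _ders_basis_funs(
    span: int, u: float, degree: int, n_ders: int, knots: np.ndarray
) -> np.ndarray:
    """Nonzero basis values and derivatives up to order n_ders (rows)."""
    ndu = np.zeros((degree + 1, degree + 1))
    ndu[0, 0] = 1.0
    left = np.zeros(degree + 1)
    right = np.zeros(degree + 1)
    for j in range(1, degree + 1):
        left[j] = u - knots[span + 1 - j]
        right[j] = knots[span + j] - u
        saved = 0.0
        for r in range(j):
            ndu[j, r] = right[r + 1] + left[j - r]
            temp = ndu[r, j - 1] / ndu[j, r]
            ndu[r, j] = saved + right[r + 1] * temp
            saved = left[j - r] * temp
        ndu[j, j] = saved
    ders = np.zeros((n_ders + 1, degree + 1))
    ders[0] = ndu[:, degree]
    a = np.zeros((2, degree + 1))
    for r in range(degree + 1):
        s1, s2 = 0, 1
        a[0, 0] = 1.0
        for k in range(1, n_ders + 1):
            d = 0.0
            rk, pk = r - k, degree - k
            if r >= k:
                a[s2, 0] = a[s1, 0] / ndu[pk + 1, rk]
                d = a[s2, 0] * ndu[rk, pk]
            j1 = 1 if rk >= -1 else -rk
            j2 = k - 1 if r - 1 <= pk else degree - r
            for j in range(j1, j2 + 1):
                a[s2, j] = (a[s1, j] - a[s1, j - 1]) / ndu[pk + 1, rk + j]
                d += a[s2, j] * ndu[rk + j, pk]
            if r <= pk:
                a[s2, k] = -a[s1, k - 1] / ndu[pk + 1, r]
                d += a[s2, k] * ndu[r, pk]
            ders[k, r] = d
            s1, s2 = s2, s1
    fac = float(degree)
    for k in range(1, n_ders + 1):
        ders[k] *= fac
        fac *= degree - k
    return ders


def basis_row(knots: np.ndarray, degree: int, n_ctrl: int, u: float) -> np.ndarray:
    """Full-length basis vector (N_0(u), ..., N_{n_ctrl-1}(u))."""
    span = _find_span(n_ctrl, degree, u, knots)
    row = np.zeros(n_ctrl)
    row[span - degree : span + 1] = _basis_funs(span, u, degree, knots)
    return row


@dataclass
class NurbsSurface:
    """Tensor-product NURBS surface with clamped knot vectors on [0,1]^2.

    ``control_points`` has shape (nu, nv, 3); ``weights`` shape (nu, nv).
    """

    degree_u: int
    degree_v: int
    control_points: np.ndarray
    weights: np.ndarray | None = None
    knots_u: np.ndarray = field(default=None)  # type: ignore[assignment]
    knots_v: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.control_points = np.asarray(self.control_points, dtype=float)
        if self.control_points.ndim != 3 or self.control_points.shape[2] != 3:
            raise InvalidArgumentError("control_points must have shape (nu, nv, 3)")
        nu, nv, _ = self.control_points.shape
        if nu < self.degree_u + 1 or nv < self.degree_v + 1:
            raise InvalidArgumentError("control grid smaller than degree+1")
        if self.weights is None:
            self.weights = np.ones((nu, nv))
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (nu, nv):
            raise InvalidArgumentError("weights must match the control grid")
        if np.any(self.weights <= 0):
            raise InvalidArgumentError("weights must be positive")
        if self.knots_u is None:
            self.knots_u = clamped_uniform_knots(nu, self.degree_u)
        if self.knots_v is None:
            self.knots_v = clamped_uniform_knots(nv, self.degree_v)
        self.knots_u = np.asarray(self.knots_u, dtype=float)
        self.knots_v = np.asarray(self.knots_v, dtype=float)
        for knots, n, p, name in (
            (self.knots_u, nu, self.degree_u, "u"),
            (self.knots_v, nv, self.degree_v, "v"),
        ):
            if len(knots) != n + p + 1:
                raise InvalidArgumentError(f"knot vector {name} has wrong length")
            if np.any(np.diff(knots) < 0):
                raise InvalidArgumentError(f"knot vector {name} must be nondecreasing")

    @property
    def shape(self) -> tuple[int, int]:
        return self.control_points.shape[:2]


def eval_surface(surface: NurbsSurface, u: float, v: float) -> np.ndarray:
    """Rational de Boor evaluation of S(u, v); clamped knots interpolate corners."""
    if not (0.0 <= u <= 1.0 and 0.0 <= v <= 1.0):
        raise InvalidArgumentError("u and v must lie in [0, 1]")
    nu, nv = surface.shape
    Nu = basis_row(surface.knots_u, surface.degree_u, nu, u)
    Nv = basis_row(surface.knots_v, surface.degree_v, nv, v)
    wb = surface.weights * np.outer(Nu, Nv)
    denom = wb.sum()
    return np.einsum("ij,ijk->k", wb, surface.control_points) / denom


def _surface_derivs(surface: NurbsSurface, u: float, v: float):
    """S, dS/du, dS/dv at (u, v) via the quotient rule on the homogeneous form."""
    nu, nv = surface.shape
    su = _find_span(nu, surface.degree_u, u, surface.knots_u)
    sv = _find_span(nv, surface.degree_v, v, surface.knots_v)
    du = _ders_basis_funs(su, u, surface.degree_u, 1, surface.knots_u)
    dv = _ders_basis_funs(sv, v, surface.degree_v, 1, surface.knots_v)
    iu = slice(su - surface.degree_u, su + 1)
    iv = slice(sv - surface.degree_v, sv + 1)
    w = surface.weights[iu, iv]
    p = surface.control_points[iu, iv]
    pw = p * w[..., None]

    def comb(bu, bv, arr):
        return np.einsum("i,j,ij...->...", bu, bv, arr)

    A = comb(du[0], dv[0], pw)
    W = comb(du[0], dv[0], w)
    Au = comb(du[1], dv[0], pw)
    Wu = comb(du[1], dv[0], w)
    Av = comb(du[0], dv[1], pw)
    Wv = comb(du[0], dv[1], w)
    S = A / W
    return S, (Au - Wu * S) / W, (Av - Wv * S) / W


def _span_nodes(knots: np.ndarray, order: int) -> tuple[np.ndarray, np.ndarray]:
    """Composite Gauss-Legendre nodes/weights over the distinct knot spans."""
    x, w = np.polynomial.legendre.leggauss(order)
    breaks = np.unique(knots)
    nodes, wts = [], []
    for a, b in zip(breaks[:-1], breaks[1:]):
        h = b - a
        nodes.append(a + 0.5 * h * (x + 1.0))
        wts.append(0.5 * h * w)
    return np.concatenate(nodes), np.concatenate(wts)


def surface_area(surface: NurbsSurface, quadrature_order: int = 16) -> float:
    """Surface area by Gauss-Legendre quadrature of |S_u x S_v| over [0,1]^2.

    Quadrature is composite over the knot spans so the integrand is
    smooth within every cell; accuracy increases with the order.
    """
    un, uw = _span_nodes(surface.knots_u, quadrature_order)
    vn, vw = _span_nodes(surface.knots_v, quadrature_order)
    area = 0.0
    for ui, wu in zip(un, uw):
        for vi, wv in zip(vn, vw):
            _, su, sv = _surface_derivs(surface, ui, vi)
            area += wu * wv * np.linalg.norm(np.cross(su, sv))
    return float(area)


# --------------------------------------------------------------------------
# Surface builders
# --------------------------------------------------------------------------


def nurbs_plane(width: float, length: float, grid: tuple[int, int] = (6, 4),
                degree_u: int = 3, degree_v: int = 2) -> NurbsSurface:
    """Planar rectangle in the xy-plane: u along length (x), v along width (y)."""
    nu, nv = grid
    x = np.linspace(0.0, length, nu)
    y = np.linspace(0.0, width, nv)
    cp = np.zeros((nu, nv, 3))
    cp[..., 0] = x[:, None]
    cp[..., 1] = y[None, :]
    return NurbsSurface(min(degree_u, nu - 1), min(degree_v, nv - 1), cp)


def nurbs_cylinder_patch(radius: float, length: float, sweep_deg: float = 90.0) -> NurbsSurface:
    """Circular-arc extrusion along z, exact via rational quadratic arcs.

    The arc (u direction) is a single degree-2 rational segment, exact
    for sweeps below 180 degrees; v runs along the axis.
    """
    if not 0 < sweep_deg < 180:
        raise InvalidArgumentError("sweep_deg must be in (0, 180)")
    half = math.radians(sweep_deg) / 2.0
    w_mid = math.cos(half)
    p0 = np.array([radius * math.cos(-half), radius * math.sin(-half)])
    p2 = np.array([radius * math.cos(half), radius * math.sin(half)])
    # middle control point: intersection of tangents at p0 and p2
    p1 = np.array([radius / math.cos(half), 0.0])
    arc = np.stack([p0, p1, p2])
    cp = np.zeros((3, 2, 3))
    cp[:, 0, :2] = arc
    cp[:, 1, :2] = arc
    cp[:, 1, 2] = length
    weights = np.array([[1.0, 1.0], [w_mid, w_mid], [1.0, 1.0]])
    return NurbsSurface(2, 1, cp, weights)


def nurbs_leaf_template(
    length: float,
    max_width: float,
    inclination_deg: float = 45.0,
    arch: float = 0.25,
    grid: tuple[int, int] = (6, 4),
) -> NurbsSurface:
    """Maize-like lamina: quadratic-arc midrib in a vertical plane, sine width.

    The midrib rises at ``inclination_deg`` from horizontal and arches
    over by ``arch`` (fraction of length of downward tip droop); lamina
    half-width follows a sine bump peaking mid-blade. Base at origin,
    midrib initially along +x.
    """
    nu, nv = grid
    s = np.linspace(0.0, 1.0, nu)
    inc = math.radians(inclination_deg)
    # quadratic arc: straight climb minus a droop term growing as s^2
    x = length * s * math.cos(inc)
    z = length * (s * math.sin(inc) - arch * s**2)
    half_w = 0.5 * max_width * np.sin(np.pi * np.clip(s, 0.0, 1.0)) + 1e-4 * max_width
    t = np.linspace(-1.0, 1.0, nv)
    cp = np.zeros((nu, nv, 3))
    cp[..., 0] = x[:, None]
    cp[..., 1] = half_w[:, None] * t[None, :]
    cp[..., 2] = z[:, None]
    return NurbsSurface(min(3, nu - 1), min(2, nv - 1), cp)


# --------------------------------------------------------------------------
# Fitting and rescaling
# --------------------------------------------------------------------------


def fit_leaf_surface(
    leaf_points: np.ndarray,
    control_grid: tuple[int, int] = (6, 4),
    degree_u: int = 3,
    degree_v: int = 2,
    params_uv: np.ndarray | None = None,
) -> tuple[NurbsSurface, float]:
    """Least-squares NURBS fit (unit weights) to a leaf point cloud.

    Points are parameterized by min-max-normalized projection onto the
    cloud's first two principal axes (exact only for planar laminae;
    pass ``params_uv`` with known per-point (u, v) parameters to fit in
    a fixed parameterization); control points solve the linear
    least-squares system on the tensor-product basis. Returns the
    surface and the RMS residual.
    """
    pts = np.asarray(leaf_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise InvalidArgumentError("leaf_points must be (N, 3)")
    nu, nv = control_grid
    if pts.shape[0] < nu * nv:
        raise FitError(f"need at least {nu * nv} points for a {nu}x{nv} control grid")
    degree_u = min(degree_u, nu - 1)
    degree_v = min(degree_v, nv - 1)
    if params_uv is not None:
        uv = np.asarray(params_uv, dtype=float)
        if uv.shape != (pts.shape[0], 2) or uv.min() < 0 or uv.max() > 1:
            raise InvalidArgumentError("params_uv must be (N, 2) values in [0, 1]")
    else:
        center = pts.mean(axis=0)
        _, sv, vt = np.linalg.svd(pts - center, full_matrices=False)
        proj = (pts - center) @ vt[:2].T
        spans = proj.max(axis=0) - proj.min(axis=0)
        if np.any(spans <= 0) or sv[1] < 1e-12 * max(sv[0], 1e-300):
            raise FitError("degenerate parameterization: points do not span a surface")
        uv = (proj - proj.min(axis=0)) / spans
    ku = clamped_uniform_knots(nu, degree_u)
    kv = clamped_uniform_knots(nv, degree_v)
    bu = np.array([basis_row(ku, degree_u, nu, u) for u in uv[:, 0]])
    bv = np.array([basis_row(kv, degree_v, nv, v) for v in uv[:, 1]])
    design = np.einsum("ni,nj->nij", bu, bv).reshape(pts.shape[0], nu * nv)
    sol, _, rank, _ = np.linalg.lstsq(design, pts, rcond=None)
    if rank < nu * nv:
        raise FitError(
            f"rank-deficient fit (rank {rank} < {nu * nv}); "
            "use a coarser control grid or more points"
        )
    surface = NurbsSurface(degree_u, degree_v, sol.reshape(nu, nv, 3),
                           knots_u=ku, knots_v=kv)
    resid = design @ sol - pts
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return surface, rms


def _axial_extent(surface: NurbsSurface) -> float:
    z = surface.control_points[..., 2]
    return float(z.max() - z.min())


def scale_organ_to_size(
    surface: NurbsSurface, organ_type: str, target: float
) -> NurbsSurface:
    """Affine-scale a surface about the organ base to a target size.

    Leaves scale uniformly until ``surface_area`` matches the target
    (1-D root find on the scale factor); internodes scale the z axis so
    the axial extent equals the target exactly. ``target`` is in the
    surface's own length units.
    """
    if target <= 0:
        raise InvalidArgumentError("target size must be positive")
    cp = surface.control_points.copy()
    if organ_type == "internode":
        current = _axial_extent(surface)
        if current <= 0:
            raise InvalidArgumentError("internode surface has zero axial extent")
        zmin = cp[..., 2].min()
        cp[..., 2] = zmin + (cp[..., 2] - zmin) * (target / current)
        return NurbsSurface(surface.degree_u, surface.degree_v, cp, surface.weights.copy(),
                            surface.knots_u.copy(), surface.knots_v.copy())
    if organ_type != "leaf":
        raise InvalidArgumentError(f"unknown organ_type {organ_type!r}")
    current = surface_area(surface, quadrature_order=12)
    if current <= 0:
        raise InvalidArgumentError("leaf surface has zero area")
    base = cp[0].mean(axis=0)  # attachment row (u = 0)

    def scaled(s: float) -> NurbsSurface:
        return NurbsSurface(
            surface.degree_u, surface.degree_v, base + (cp - base) * s,
            surface.weights.copy(), surface.knots_u.copy(), surface.knots_v.copy(),
        )

    s0 = math.sqrt(target / current)
    # area is homogeneous of degree 2 under uniform scaling, so s0 is already
    # the root; brentq tightens it against quadrature round-off
    f = lambda s: surface_area(scaled(s), quadrature_order=12) - target
    lo, hi = s0 * 0.999, s0 * 1.001
    if f(lo) * f(hi) < 0:
        s0 = brentq(f, lo, hi, xtol=1e-12)
    return scaled(s0)


def tessellate(surface: NurbsSurface, nu: int = 10, nv: int = 6) -> np.ndarray:
    """Triangulate by sampling a (nu+1)x(nv+1) parameter grid; returns (M,3,3)."""
    us = np.linspace(0.0, 1.0, nu + 1)
    vs = np.linspace(0.0, 1.0, nv + 1)
    grid = np.array([[eval_surface(surface, u, v) for v in vs] for u in us])
    tris = []
    for i in range(nu):
        for j in range(nv):
            a, b = grid[i, j], grid[i + 1, j]
            c, d = grid[i + 1, j + 1], grid[i, j + 1]
            tris.append([a, b, c])
            tris.append([a, c, d])
    return np.array(tris)


# --------------------------------------------------------------------------
# Canopy scene and light interception
# --------------------------------------------------------------------------


@dataclass
class CanopyScene:
    """Triangulated organ surfaces over a rectangular ground footprint.

    ``organs`` maps organ id -> (M, 3, 3) triangle array (metres);
    ``footprint`` is (xmin, ymin, xmax, ymax) in metres.
    """

    organs: dict[str, np.ndarray]
    footprint: tuple[float, float, float, float]

    @property
    def footprint_area(self) -> float:
        x0, y0, x1, y1 = self.footprint
        return (x1 - x0) * (y1 - y0)


@dataclass
class InterceptionResult:
    per_organ: dict[str, float]  # intercepted PAR, mol per day
    total: float
    fraction: float
    mc_se: float  # Monte-Carlo standard error of the fraction
    n_rays: int


def _ray_hits(tris: np.ndarray, xy: np.ndarray, chunk_elems: int = 4_000_000):
    """First-hit (highest z) triangle index for vertical rays; -1 for a miss.

    Triangles whose xy bounding box misses the ray window are culled
    before the barycentric tests; indices returned refer to the full
    input array.
    """
    xy = np.asarray(xy, dtype=float)
    n = len(xy)
    hit_idx = np.full(n, -1, dtype=np.int64)
    xy_min = xy.min(axis=0)
    xy_max = xy.max(axis=0)
    t_lo = tris[..., :2].min(axis=1)
    t_hi = tris[..., :2].max(axis=1)
    keep = np.flatnonzero(
        (t_hi[:, 0] >= xy_min[0]) & (t_lo[:, 0] <= xy_max[0])
        & (t_hi[:, 1] >= xy_min[1]) & (t_lo[:, 1] <= xy_max[1])
    )
    if keep.size == 0:
        return hit_idx
    sub = tris[keep]
    m = len(sub)
    a, b, c = sub[:, 0], sub[:, 1], sub[:, 2]
    v0 = (c - a)[:, :2]
    v1 = (b - a)[:, :2]
    d00 = np.einsum("ij,ij->i", v0, v0)
    d01 = np.einsum("ij,ij->i", v0, v1)
    d11 = np.einsum("ij,ij->i", v1, v1)
    denom = d00 * d11 - d01 * d01
    valid = np.abs(denom) > 1e-18
    inv = np.where(valid, 1.0 / np.where(valid, denom, 1.0), 0.0)
    # affine forms: bary(p) = G @ p + h, computed per chunk by matmul
    g20 = v0 * inv[:, None]  # used via dot with p
    g21 = v1 * inv[:, None]
    a0 = np.einsum("ij,ij->i", a[:, :2], v0) * inv
    a1 = np.einsum("ij,ij->i", a[:, :2], v1) * inv
    za, zb, zc = a[:, 2], b[:, 2], c[:, 2]
    chunk = max(16, chunk_elems // max(m, 1))
    eps = 1e-9
    neg_inf = -np.inf
    for start in range(0, n, chunk):
        p = xy[start : start + chunk]
        d20 = p @ g20.T - a0  # (c, m), scaled by 1/denom already
        d21 = p @ g21.T - a1
        ba = d11 * d20 - d01 * d21
        bb = d00 * d21 - d01 * d20
        inside = valid & (ba >= -eps) & (bb >= -eps) & (ba + bb <= 1 + eps)
        z = za + ba * (zc - za) + bb * (zb - za)
        z[~inside] = neg_inf
        best = np.argmax(z, axis=1)
        rows = np.arange(len(p))
        found = np.isfinite(z[rows, best])
        hit_idx[start : start + len(p)] = np.where(found, keep[best], -1)
    return hit_idx


def light_interception(
    scene: CanopyScene,
    par_above: float,
    n_rays: int = 20_000,
    seed: int = 0,
) -> InterceptionResult:
    """Vertical-beam ray cast on a jittered grid over the footprint.

    Each ray carries an equal share of the incoming PAR flux
    (par_above, mol m-2 d-1, times the footprint area); the first organ
    hit from above absorbs it (opaque leaves, no transmittance). The
    Monte-Carlo standard error of the intercepted fraction is reported.
    """
    if n_rays < 100:
        raise InvalidArgumentError("n_rays must be at least 100")
    if not scene.organs or all(len(t) == 0 for t in scene.organs.values()):
        return InterceptionResult({k: 0.0 for k in scene.organs}, 0.0, 0.0, 0.0, n_rays)
    rng = np.random.default_rng(seed)
    x0, y0, x1, y1 = scene.footprint
    gx = max(1, int(round(math.sqrt(n_rays * (x1 - x0) / max(y1 - y0, 1e-12)))))
    gy = max(1, int(math.ceil(n_rays / gx)))
    n = gx * gy
    ix, iy = np.meshgrid(np.arange(gx), np.arange(gy), indexing="ij")
    jit = rng.random((2, gx, gy))
    xs = x0 + (ix + jit[0]) * (x1 - x0) / gx
    ys = y0 + (iy + jit[1]) * (y1 - y0) / gy
    xy = np.column_stack([xs.ravel(), ys.ravel()])

    names = list(scene.organs)
    tris = np.concatenate([scene.organs[k] for k in names], axis=0)
    organ_of = np.concatenate(
        [np.full(len(scene.organs[k]), i) for i, k in enumerate(names)]
    )
    hit = _ray_hits(tris, xy)
    hit_mask = hit >= 0
    per_ray_par = par_above * scene.footprint_area / n
    counts = np.bincount(organ_of[hit[hit_mask]], minlength=len(names))
    per_organ = {k: float(c * per_ray_par) for k, c in zip(names, counts)}
    frac = float(hit_mask.mean())
    se = math.sqrt(max(frac * (1 - frac), 0.0) / n)
    return InterceptionResult(per_organ, float(hit_mask.sum() * per_ray_par), frac, se, n)


def beer_lambert_fraction(lai: float, extinction_k: float) -> float:
    """Closed-form intercepted fraction 1 - exp(-k LAI); oracle for the ray cast."""
    if lai < 0:
        raise InvalidArgumentError("lai must be >= 0")
    return 1.0 - math.exp(-extinction_k * lai)


def make_horizontal_leaf_canopy(
    lai: float,
    side: float = 4.0,
    leaf_side: float = 0.08,
    seed: int = 0,
    z_range: tuple[float, float] = (0.5, 1.5),
) -> CanopyScene:
    """Randomized horizontal-leaf canopy for the Beer-Lambert cross-check.

    Square leaves with centers uniform over a ``side`` x ``side`` plot;
    the scene footprint is inset by half a leaf so every ray sees the
    same coverage probability (no edge bias), making the expected
    intercepted fraction 1 - (1 - a/A)^n ~ 1 - exp(-LAI) for horizontal
    leaves (extinction coefficient 1).
    """
    rng = np.random.default_rng(seed)
    a = leaf_side**2
    n_leaves = max(1, int(round(lai * side**2 / a)))
    centers = rng.random((n_leaves, 2)) * side
    zs = rng.uniform(*z_range, n_leaves)
    h = leaf_side / 2
    tris = np.empty((2 * n_leaves, 3, 3))
    for i, ((cx, cy), z) in enumerate(zip(centers, zs)):
        p = np.array(
            [[cx - h, cy - h, z], [cx + h, cy - h, z], [cx + h, cy + h, z], [cx - h, cy + h, z]]
        )
        tris[2 * i] = p[[0, 1, 2]]
        tris[2 * i + 1] = p[[0, 2, 3]]
    footprint = (h, h, side - h, side - h)
    return CanopyScene({"leaves": tris}, footprint)


# --------------------------------------------------------------------------
# Rendering, sampling and export helpers
# --------------------------------------------------------------------------


def render_canopy_image(
    scene: CanopyScene,
    resolution: int = 64,
    plant_color: tuple[float, float, float] = (0.15, 0.65, 0.2),
    soil_color: tuple[float, float, float] = (0.45, 0.33, 0.22),
) -> np.ndarray:
    """Flat-shaded orthographic top-down raster of the canopy, floats in [0,1]."""
    img = np.empty((resolution, resolution, 3))
    img[:] = soil_color
    if scene.organs and any(len(t) for t in scene.organs.values()):
        x0, y0, x1, y1 = scene.footprint
        xs = x0 + (np.arange(resolution) + 0.5) * (x1 - x0) / resolution
        ys = y0 + (np.arange(resolution) + 0.5) * (y1 - y0) / resolution
        gx, gy = np.meshgrid(xs, ys, indexing="ij")
        xy = np.column_stack([gx.ravel(), gy.ravel()])
        tris = np.concatenate([t for t in scene.organs.values() if len(t)], axis=0)
        hit = (_ray_hits(tris, xy) >= 0).reshape(resolution, resolution)
        img[hit] = plant_color
    return img


def sample_scene_points(scene: CanopyScene, n_points: int, seed: int = 0) -> np.ndarray:
    """Area-weighted uniform sampling of points on the scene's triangles."""
    tris = np.concatenate([t for t in scene.organs.values() if len(t)], axis=0)
    if len(tris) == 0:
        raise InvalidArgumentError("scene has no triangles to sample")
    ab = tris[:, 1] - tris[:, 0]
    ac = tris[:, 2] - tris[:, 0]
    areas = 0.5 * np.linalg.norm(np.cross(ab, ac), axis=1)
    if areas.sum() <= 0:
        raise InvalidArgumentError("scene triangles are degenerate")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(tris), size=n_points, p=areas / areas.sum())
    r1 = np.sqrt(rng.random(n_points))
    r2 = rng.random(n_points)
    a, b, c = tris[idx, 0], tris[idx, 1], tris[idx, 2]
    return (1 - r1)[:, None] * a + (r1 * (1 - r2))[:, None] * b + (r1 * r2)[:, None] * c


def export_scene_obj(scene: CanopyScene, path: str) -> None:
    """Export the triangulated canopy as a Wavefront OBJ via trimesh."""
    import trimesh

    meshes = []
    for tris in scene.organs.values():
        if len(tris) == 0:
            continue
        verts = tris.reshape(-1, 3)
        faces = np.arange(len(verts)).reshape(-1, 3)
        meshes.append(trimesh.Trimesh(vertices=verts, faces=faces, process=False))
    if not meshes:
        raise InvalidArgumentError("empty scene cannot be exported")
    trimesh.util.concatenate(meshes).export(path, file_type="obj")
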