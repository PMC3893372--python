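"""Laplacian cortical-thickness mapping on 2D sections.

The cortical ribbon — the grey-matter band between the traced pial (outer)
and grey/white (inner) boundaries — is rasterized onto a pixel grid, and the
harmonic potential phi is solved with Dirichlet values +1 on the inner and
-1 on the outer boundary. Thickness at a point is the length of the field
line (integral curve of grad phi) through it; thickness and signed curvature
are sampled on the phi = 0 midline, the natural medial surface of the
ribbon.

The Laplace solve uses a boundary-fitted five-point stencil: interior cells
adjacent to a boundary see the Dirichlet value at the sub-pixel distance
where the stencil arm crosses the traced contour (Shortley-Weller), so the
potential is second-order accurate despite the rasterized boundary.

Coordinates: contours are (x, y) in pixels with y pointing down; raster
arrays are indexed (row, col) = (y, x). Physical units enter only through
``pixel_size`` (micrometres per pixel).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, sparse
from scipy.ndimage import map_coordinates
from scipy.sparse.linalg import spsolve
from shapely.geometry import LineString, Point, Polygon
from skimage import draw as skdraw
from skimage import measure as skmeasure

from .errors import (
    DegenerateGradientError,
    EmptyRibbonError,
    InsufficientCurveError,
    InvalidGeometryError,
    NoMidlineError,
    SolverFailureError,
)

# raster labels
OUTSIDE = 0
GREY = 1
INNER_BOUNDARY = 2
OUTER_BOUNDARY = 3


@dataclass
class ContourPair:
    """One slide's ordered outer and inner cortical contours.

    outer is the lamina I/II (pial-side) boundary, inner the grey/white
    boundary. ``closed`` marks ring contours (full annular ribbons); open
    contours describe a band segment. If None, closure is auto-detected
    from the endpoint gap.
    """

    outer: np.ndarray  # (N, 2) float, (x, y) px
    inner: np.ndarray  # (M, 2) float, (x, y) px
    pixel_size: float  # um / px
    slide_id: str = "slide"
    closed: bool | None = None

    def __post_init__(self):
        self.outer = np.asarray(self.outer, dtype=float)
        self.inner = np.asarray(self.inner, dtype=float)
        if self.outer.ndim != 2 or self.outer.shape[1] != 2 or len(self.outer) < 3:
            raise InvalidGeometryError("outer contour needs >= 3 (x, y) points")
        if self.inner.ndim != 2 or self.inner.shape[1] != 2 or len(self.inner) < 3:
            raise InvalidGeometryError("inner contour needs >= 3 (x, y) points")
        if not np.isfinite(self.outer).all() or not np.isfinite(self.inner).all():
            raise InvalidGeometryError("contour coordinates must be finite")
        if self.pixel_size <= 0:
            raise InvalidGeometryError("pixel_size must be positive")
        if self.closed is None:
            self.closed = _looks_closed(self.outer) and _looks_closed(self.inner)

    def validate(self) -> None:
        """Check simplicity and mutual non-intersection of the contours."""
        lo = _as_line(self.outer, self.closed)
        li = _as_line(self.inner, self.closed)
        if not lo.is_simple:
            raise InvalidGeometryError("outer contour self-intersects")
        if not li.is_simple:
            raise InvalidGeometryError("inner contour self-intersects")
        if lo.intersects(li):
            raise InvalidGeometryError("outer and inner contours intersect")


def _looks_closed(pts: np.ndarray) -> bool:
    gap = np.hypot(*(pts[0] - pts[-1]))
    seg = np.hypot(*np.diff(pts, axis=0).T)
    return gap <= max(3.0 * np.median(seg), 1e-9)


def _as_line(pts: np.ndarray, closed: bool) -> LineString:
    if closed and not np.allclose(pts[0], pts[-1]):
        pts = np.vstack([pts, pts[0]])
    return LineString(pts)


def _close_rc(rc_pts: np.ndarray, closed: bool) -> np.ndarray:
    if closed and not np.allclose(rc_pts[0], rc_pts[-1]):
        return np.vstack([rc_pts, rc_pts[:1]])
    return rc_pts


@dataclass
class GreyMatterGrid:
    """Label raster for the PDE solve: outside / grey / inner / outer.

    Carries the contour polylines in cell coordinates so the solver can
    place Dirichlet values at sub-pixel arm crossings, plus the raw
    between-contours fill count (``ribbon_area_px``) for area checks.
    """

    labels: np.ndarray  # 2D uint8 with the module label constants
    origin: tuple[float, float]  # (x0, y0) px of cell (0, 0) center
    spacing: float  # px per cell
    pixel_size: float  # um per px
    slide_id: str = "slide"
    inner_rc: np.ndarray | None = None  # (M, 2) contour in (row, col) cells
    outer_rc: np.ndarray | None = None
    closed: bool = False
    ribbon_area_px: float = 0.0  # fill count x spacing^2, in px^2

    @property
    def n_grey(self) -> int:
        return int(np.sum(self.labels == GREY))

    def to_rc(self, xy: np.ndarray) -> np.ndarray:
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        x0, y0 = self.origin
        return np.column_stack(
            [(xy[:, 1] - y0) / self.spacing, (xy[:, 0] - x0) / self.spacing]
        )

    def to_xy(self, rc: np.ndarray) -> np.ndarray:
        rc = np.atleast_2d(np.asarray(rc, dtype=float))
        x0, y0 = self.origin
        return np.column_stack(
            [rc[:, 1] * self.spacing + x0, rc[:, 0] * self.spacing + y0]
        )


def rasterize_ribbon(cp: ContourPair, grid_spacing: float = 1.0) -> GreyMatterGrid:
    """Rasterize a contour pair into a labelled grey-matter grid.

    Grey cells are those strictly between the contours; contour polylines
    are burned in as boundary cells, a cell claimed by both contours going
    to the nearer one. Grey components not touching both boundaries are
    discarded.
    """
    cp.validate()
    if grid_spacing <= 0:
        raise ValueError("grid_spacing must be positive")

    allpts = np.vstack([cp.outer, cp.inner])
    pad = 4
    x0 = np.floor(allpts[:, 0].min() / grid_spacing) * grid_spacing - pad * grid_spacing
    y0 = np.floor(allpts[:, 1].min() / grid_spacing) * grid_spacing - pad * grid_spacing
    ncols = int(np.ceil((allpts[:, 0].max() - x0) / grid_spacing)) + pad + 1
    nrows = int(np.ceil((allpts[:, 1].max() - y0) / grid_spacing)) + pad + 1
    shape = (nrows, ncols)

    def rc(pts):
        return np.column_stack(
            [(pts[:, 1] - y0) / grid_spacing, (pts[:, 0] - x0) / grid_spacing]
        )

    rc_outer, rc_inner = rc(cp.outer), rc(cp.inner)

    if cp.closed:
        po = Polygon(cp.outer)
        pi = Polygon(cp.inner)
        if not po.contains(pi):
            if pi.contains(po):
                raise InvalidGeometryError(
                    "inner contour encloses outer contour (contours swapped?)"
                )
            raise InvalidGeometryError("inner contour does not lie inside outer")
        fill = skmeasure.grid_points_in_poly(shape, rc_outer) & ~skmeasure.grid_points_in_poly(
            shape, rc_inner
        )
    else:
        band = np.vstack([rc_outer, rc_inner[::-1]])
        if not Polygon(np.vstack([cp.outer, cp.inner[::-1]])).is_valid:
            raise InvalidGeometryError("ribbon band polygon is invalid (offsets cross?)")
        fill = skmeasure.grid_points_in_poly(shape, band)

    bnd_o = _burn_polyline(rc_outer, shape, cp.closed)
    bnd_i = _burn_polyline(rc_inner, shape, cp.closed)
    both = bnd_o & bnd_i
    if both.any():
        lo = _as_line(cp.outer, cp.closed)
        li = _as_line(cp.inner, cp.closed)
        for r, c in np.argwhere(both):
            p = Point(c * grid_spacing + x0, r * grid_spacing + y0)
            if lo.distance(p) <= li.distance(p):
                bnd_i[r, c] = False
            else:
                bnd_o[r, c] = False

    labels = np.zeros(shape, dtype=np.uint8)
    labels[fill] = GREY
    labels[bnd_i] = INNER_BOUNDARY
    labels[bnd_o] = OUTER_BOUNDARY

    grey = labels == GREY
    if not grey.any():
        raise EmptyRibbonError("no grey interior between the contours")

    # keep only grey components 4-adjacent to both boundary sets
    comp, ncomp = ndimage.label(grey, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    near_i = ndimage.binary_dilation(labels == INNER_BOUNDARY)
    near_o = ndimage.binary_dilation(labels == OUTER_BOUNDARY)
    keep = np.zeros(ncomp + 1, dtype=bool)
    for k in range(1, ncomp + 1):
        m = comp == k
        if (m & near_i).any() and (m & near_o).any():
            keep[k] = True
    if not keep.any():
        raise EmptyRibbonError("no grey component connects the two boundaries")
    labels[grey & ~keep[comp]] = OUTSIDE

    return GreyMatterGrid(
        labels,
        (x0, y0),
        grid_spacing,
        cp.pixel_size,
        cp.slide_id,
        inner_rc=_close_rc(rc_inner, cp.closed),
        outer_rc=_close_rc(rc_outer, cp.closed),
        closed=bool(cp.closed),
        ribbon_area_px=float(fill.sum()) * grid_spacing**2,
    )


def _burn_polyline(rc_pts: np.ndarray, shape: tuple[int, int], closed: bool) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    pts = np.vstack([rc_pts, rc_pts[:1]]) if closed else rc_pts
    ri = np.clip(np.rint(pts[:, 0]).astype(int), 0, shape[0] - 1)
    ci = np.clip(np.rint(pts[:, 1]).astype(int), 0, shape[1] - 1)
    for k in range(len(pts) - 1):
        rr, cc = skdraw.line(ri[k], ci[k], ri[k + 1], ci[k + 1])
        mask[rr, cc] = True
    return mask


# ---------------------------------------------------------------------------
# Laplace solve (boundary-fitted five-point stencil)


def _shift(a: np.ndarray, dr: int, dc: int) -> np.ndarray:
    """Array shifted so [r, c] reads a[r+dr, c+dc]; NaN past the edge."""
    out = np.full_like(a, np.nan)
    rs = slice(max(dr, 0), a.shape[0] + min(dr, 0))
    rd = slice(max(-dr, 0), a.shape[0] + min(-dr, 0))
    cs = slice(max(dc, 0), a.shape[1] + min(dc, 0))
    cd = slice(max(-dc, 0), a.shape[1] + min(-dc, 0))
    out[rd, cd] = a[rs, cs]
    return out


def _arm_crossings(
    starts: np.ndarray, direction: tuple[int, int], segs: np.ndarray, reach: float
) -> np.ndarray:
    """Crossing parameter t in (0, reach] of axis arms with contour segments.

    ``starts`` is (n, 2) cell coords, ``direction`` a unit axis step,
    ``segs`` (m, 2, 2) contour segments. Returns per-arm minimum t, inf
    where no crossing.
    """
    if len(starts) == 0 or len(segs) == 0:
        return np.full(len(starts), np.inf)
    d = np.asarray(direction, dtype=float)
    a = segs[:, 0, :]  # (m, 2)
    sv = segs[:, 1, :] - a  # (m, 2)
    # p + t d = a + u sv
    denom = d[0] * sv[:, 1] - d[1] * sv[:, 0]  # (m,)
    ok_den = np.abs(denom) > 1e-12
    out = np.full(len(starts), np.inf)
    # chunk arms to bound memory
    for lo in range(0, len(starts), 2048):
        p = starts[lo : lo + 2048]
        ap0 = a[None, :, 0] - p[:, None, 0]
        ap1 = a[None, :, 1] - p[:, None, 1]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (ap0 * sv[None, :, 1] - ap1 * sv[None, :, 0]) / denom[None, :]
            u = (ap0 * d[1] - ap1 * d[0]) / -denom[None, :]
        valid = ok_den[None, :] & (t > 1e-9) & (t <= reach) & (u >= -1e-9) & (u <= 1 + 1e-9)
        t = np.where(valid, t, np.inf)
        out[lo : lo + 2048] = t.min(axis=1)
    return out


@dataclass
class PotentialField:
    """Harmonic potential phi on the grey-matter raster.

    ``phi`` is the contract view: +1 on inner-boundary cells, -1 on
    outer-boundary cells, the solved potential on grey, NaN outside.
    ``phi_trace`` replaces boundary-cell values with first-order estimates
    of the potential at the cell *center* (a boundary cell center is not
    exactly on the traced contour), which is what interpolation and
    field-line tracing want; it is extended outward by nearest fill.
    """

    phi: np.ndarray
    labels: np.ndarray
    origin: tuple[float, float]
    spacing: float
    pixel_size: float
    slide_id: str = "slide"
    phi_trace: np.ndarray | None = None
    _filled: np.ndarray | None = field(default=None, repr=False, compare=False)
    _grad: tuple[np.ndarray, np.ndarray] | None = field(default=None, repr=False, compare=False)

    @property
    def phi_filled(self) -> np.ndarray:
        """phi extended outward: linear extrapolation for a few rings (so
        finite differences at the boundary ring see the true slope), then
        nearest fill for the far field."""
        if self._filled is None:
            src = self.phi_trace if self.phi_trace is not None else self.phi
            out = src.copy()
            for _ in range(3):
                known = np.isfinite(out)
                if known.all():
                    break
                acc = np.zeros_like(out)
                cnt = np.zeros(out.shape)
                for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                    n1 = _shift(out, dr, dc)
                    n2 = _shift(out, 2 * dr, 2 * dc)
                    cand = 2.0 * n1 - n2
                    good = ~known & np.isfinite(cand)
                    acc[good] += cand[good]
                    cnt[good] += 1
                newly = cnt > 0
                out[newly] = acc[newly] / cnt[newly]
            nan = ~np.isfinite(out)
            if nan.any():
                _, (ir, ic) = ndimage.distance_transform_edt(nan, return_indices=True)
                out = out[ir, ic]
            self._filled = np.clip(out, -1.5, 1.5)
        return self._filled

    @property
    def grad(self) -> tuple[np.ndarray, np.ndarray]:
        """(d phi / d row, d phi / d col) per grid cell."""
        if self._grad is None:
            gr, gc = np.gradient(self.phi_filled)
            self._grad = (gr, gc)
        return self._grad

    def interp_phi(self, rc: np.ndarray) -> np.ndarray:
        rc = np.atleast_2d(rc)
        return map_coordinates(self.phi_filled, [rc[:, 0], rc[:, 1]], order=1, mode="nearest")

    def interp_grad(self, rc: np.ndarray) -> np.ndarray:
        rc = np.atleast_2d(rc)
        gr, gc = self.grad
        dr = map_coordinates(gr, [rc[:, 0], rc[:, 1]], order=1, mode="nearest")
        dc = map_coordinates(gc, [rc[:, 0], rc[:, 1]], order=1, mode="nearest")
        return np.column_stack([dr, dc])

    def to_rc(self, xy):
        return GreyMatterGrid.to_rc(self, xy)

    def to_xy(self, rc):
        return GreyMatterGrid.to_xy(self, rc)


def solve_laplace(grid: GreyMatterGrid, tol: float = 1e-6) -> PotentialField:
    """Solve Laplace's equation on the grey interior.

    Five-point stencil; where a stencil arm leaves the grey set, the
    Dirichlet value (+1 inner / -1 outer) is applied at the sub-pixel
    distance where the arm crosses the traced contour (Shortley-Weller
    unequal arms). Arms that leave the domain without crossing a contour
    (the open ends of band ribbons) get a zero-flux mirror condition. The
    sparse interior system is solved directly.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    lab = grid.labels
    grey = lab == GREY
    n = int(grey.sum())

    phi = np.full(lab.shape, np.nan, dtype=float)
    phi[lab == INNER_BOUNDARY] = 1.0
    phi[lab == OUTER_BOUNDARY] = -1.0
    if n == 0:
        return PotentialField(
            phi, lab, grid.origin, grid.spacing, grid.pixel_size, grid.slide_id
        )

    idx = -np.ones(lab.shape, dtype=np.int64)
    idx[grey] = np.arange(n)
    rr, cc = np.nonzero(grey)
    cells = np.column_stack([rr, cc]).astype(float)

    seg_i = seg_o = None
    if grid.inner_rc is not None and len(grid.inner_rc) > 1:
        seg_i = np.stack([grid.inner_rc[:-1], grid.inner_rc[1:]], axis=1)
    if grid.outer_rc is not None and len(grid.outer_rc) > 1:
        seg_o = np.stack([grid.outer_rc[:-1], grid.outer_rc[1:]], axis=1)

    padded = np.pad(lab, 1, constant_values=OUTSIDE)
    pidx = np.pad(idx, 1, constant_values=-1)

    # per-direction arm data
    REACH, HMIN = 2.0, 0.1
    dirs = ((-1, 0), (1, 0), (0, -1), (0, 1))
    h = np.ones((4, n))
    kind = np.zeros((4, n), dtype=np.int8)  # 0 grey, 1 dirichlet, 2 neumann
    bval = np.zeros((4, n))
    nidx = np.full((4, n), -1, dtype=np.int64)

    for k, (dr, dc) in enumerate(dirs):
        nl = padded[rr + 1 + dr, cc + 1 + dc]
        nidx[k] = pidx[rr + 1 + dr, cc + 1 + dc]
        non_grey = nl != GREY
        kind[k, ~non_grey] = 0
        if non_grey.any():
            sub = np.flatnonzero(non_grey)
            ti = (
                _arm_crossings(cells[sub], (dr, dc), seg_i, REACH)
                if seg_i is not None
                else np.full(len(sub), np.inf)
            )
            to = (
                _arm_crossings(cells[sub], (dr, dc), seg_o, REACH)
                if seg_o is not None
                else np.full(len(sub), np.inf)
            )
            tmin = np.minimum(ti, to)
            crossed = np.isfinite(tmin)
            is_inner = ti <= to
            # crossing found: Dirichlet at sub-pixel distance
            kind[k, sub[crossed]] = 1
            h[k, sub[crossed]] = np.clip(tmin[crossed], HMIN, REACH)
            bval[k, sub[crossed]] = np.where(is_inner[crossed], 1.0, -1.0)
            # no crossing: labelled boundary cell -> Dirichlet at unit arm,
            # otherwise open-end mirror
            nc = sub[~crossed]
            lab_nc = nl[sub][~crossed]
            dir_b = (lab_nc == INNER_BOUNDARY) | (lab_nc == OUTER_BOUNDARY)
            kind[k, nc[dir_b]] = 1
            bval[k, nc[dir_b]] = np.where(lab_nc[dir_b] == INNER_BOUNDARY, 1.0, -1.0)
            kind[k, nc[~dir_b]] = 2

    # mirror arms take the opposite arm's length so weights stay balanced
    for k, ko in ((0, 1), (1, 0), (2, 3), (3, 2)):
        mir = kind[k] == 2
        h[k, mir] = h[ko, mir]

    diag = np.zeros(n)
    rhs = np.zeros(n)
    rows_off, cols_off, vals_off = [], [], []
    for k, ko in ((0, 1), (1, 0), (2, 3), (3, 2)):
        w = 2.0 / (h[k] * (h[k] + h[ko]))
        live = kind[k] != 2
        diag += np.where(live, w, 0.0)
        d_mask = kind[k] == 1
        rhs += np.where(d_mask, w * bval[k], 0.0)
        g_mask = kind[k] == 0
        rows_off.append(np.flatnonzero(g_mask))
        cols_off.append(nidx[k, g_mask])
        vals_off.append(-w[g_mask])

    rows = np.concatenate([np.arange(n)] + rows_off)
    cols = np.concatenate([np.arange(n)] + cols_off)
    vals = np.concatenate([diag] + vals_off)
    A = sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))

    x = spsolve(A, rhs)
    resid = float(np.abs(A @ x - rhs).max()) if n else 0.0
    if not np.isfinite(x).all() or resid > max(tol, 1e-9 * max(1.0, np.abs(rhs).max())):
        raise SolverFailureError(
            f"Laplace solve residual {resid:.3e} exceeds tolerance {tol:.3e}", resid
        )

    phi[grey] = np.clip(x, -1.0, 1.0)
    fld = PotentialField(
        phi, lab, grid.origin, grid.spacing, grid.pixel_size, grid.slide_id
    )
    fld.phi_trace = _boundary_centered_phi(fld, grid)
    fld._filled = None
    fld._grad = None
    return fld


def _boundary_centered_phi(field: PotentialField, grid: GreyMatterGrid) -> np.ndarray:
    """phi with boundary-cell values moved from the contour to cell centers.

    A boundary cell holds +-1, but its center sits up to half a cell off
    the traced contour; for interpolation we shift its value by the local
    gradient times the center-to-contour distance (signed toward grey).
    """
    phi = field.phi.copy()
    gr, gc = np.gradient(np.where(np.isfinite(phi), phi, 0.0))
    gmag = np.hypot(gr, gc)

    # ribbon region polygon, in (x, y) = (col, row) cell coordinates
    if grid.inner_rc is None or grid.outer_rc is None:
        return phi
    if grid.closed:
        region = Polygon(grid.outer_rc[:, ::-1], [grid.inner_rc[:, ::-1]])
    else:
        region = Polygon(np.vstack([grid.outer_rc, grid.inner_rc[::-1]])[:, ::-1])
    if not region.is_valid:
        region = region.buffer(0)

    import shapely

    # local gradient magnitude: 3x3 mean over grey cells
    grey = field.labels == GREY
    num = ndimage.uniform_filter(np.where(grey, gmag, 0.0), 3)
    den = ndimage.uniform_filter(grey.astype(float), 3)
    with np.errstate(invalid="ignore", divide="ignore"):
        gloc = np.where(den > 0, num / den, 0.0)

    for lab_val, line_rc, base in (
        (INNER_BOUNDARY, grid.inner_rc, 1.0),
        (OUTER_BOUNDARY, grid.outer_rc, -1.0),
    ):
        cells = np.argwhere(field.labels == lab_val)
        if len(cells) == 0:
            continue
        line = LineString(line_rc[:, ::-1])
        pts = shapely.points(cells[:, 1], cells[:, 0])
        d = shapely.distance(line, pts)
        inside = shapely.contains(region, pts)
        # |phi| < 1 on the grey side of the contour, > 1 beyond it
        side = np.where(inside, -1.0, 1.0)
        g = gloc[cells[:, 0], cells[:, 1]]
        phi[cells[:, 0], cells[:, 1]] = base * (1.0 + side * g * d)
    return phi


# ---------------------------------------------------------------------------
# field-line tracing


def _trace_batch(
    field: PotentialField,
    starts_rc: np.ndarray,
    sign: int,
    step: float = 0.25,
    eps: float = 0.02,
    grad_floor: float = 1e-8,
    max_steps: int | None = None,
    keep_path: bool = False,
):
    """RK4-integrate field lines from many starts toward one boundary.

    sign=+1 advances up the potential toward the inner (phi=+1) boundary,
    sign=-1 toward the outer. Integration stops once sign*phi exceeds
    1 - eps; the remaining distance to the +-1 level set is added by linear
    extrapolation along the local gradient. Returns lengths in grid cells
    (NaN where tracing failed) and, optionally, the paths.
    """
    pts = np.atleast_2d(np.asarray(starts_rc, dtype=float)).copy()
    npts = len(pts)
    if max_steps is None:
        max_steps = int(4 * (field.phi.shape[0] + field.phi.shape[1]) / step) + 100

    lengths = np.zeros(npts)
    active = np.ones(npts, dtype=bool)
    failed = np.zeros(npts, dtype=bool)
    paths = [[p.copy()] for p in pts] if keep_path else None
    lab = field.labels
    nr, nc = lab.shape

    def unit_grad(p):
        g = field.interp_grad(p)
        mag = np.hypot(g[:, 0], g[:, 1])
        bad = mag < grad_floor
        mag = np.where(bad, 1.0, mag)
        return sign * g / mag[:, None], bad

    def left_grey(p):
        r = np.clip(np.rint(p[:, 0]).astype(int), 0, nr - 1)
        c = np.clip(np.rint(p[:, 1]).astype(int), 0, nc - 1)
        return lab[r, c] != GREY

    for _ in range(max_steps):
        if not active.any():
            break
        p = pts[active]
        k1, b1 = unit_grad(p)
        k2, b2 = unit_grad(p + 0.5 * step * k1)
        k3, b3 = unit_grad(p + 0.5 * step * k2)
        k4, b4 = unit_grad(p + step * k3)
        bad = b1 | b2 | b3 | b4
        newp = p + (step / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        pts[active] = newp
        lengths[active] += step

        ai = np.flatnonzero(active)
        if keep_path:
            for j, i in enumerate(ai):
                paths[i].append(newp[j].copy())
        phi_now = sign * field.interp_phi(newp)
        done = (phi_now >= 1.0 - eps) | left_grey(newp)
        failed[ai[bad]] = True
        active[ai[bad | done]] = False

    failed |= active  # ran out of steps

    # extrapolate the last segment to the +-1 level set
    g = field.interp_grad(pts)
    mag = np.maximum(np.hypot(g[:, 0], g[:, 1]), grad_floor)
    phi_end = sign * field.interp_phi(pts)
    # a trace that exited the domain while still far from the boundary in
    # potential (an open-end cap) cannot be extrapolated honestly
    failed |= (1.0 - phi_end) > 0.3
    resid = np.clip(1.0 - phi_end, 0.0, None) / mag
    lengths = lengths + resid
    if keep_path:
        u = sign * g / mag[:, None]
        for i in range(npts):
            paths[i].append(pts[i] + u[i] * resid[i])
    lengths[failed] = np.nan
    if keep_path:
        return lengths, pts, paths
    return lengths, pts


def trace_field_line(
    field: PotentialField,
    start_xy,
    step: float = 0.25,
    eps: float = 0.02,
) -> tuple[np.ndarray, float]:
    """Trace the full field line through ``start_xy`` (px coordinates).

    Returns the polyline (in (x, y) px) running from the inner to the outer
    boundary, and its length in micrometres — the cortical thickness at
    that point.
    """
    rc = field.to_rc(np.asarray(start_xy, dtype=float))
    r, c = int(round(rc[0, 0])), int(round(rc[0, 1]))
    if not (
        0 <= r < field.labels.shape[0]
        and 0 <= c < field.labels.shape[1]
        and field.labels[r, c] == GREY
    ):
        raise ValueError("start point is not strictly inside the grey matter")

    g = field.interp_grad(rc)
    if np.hypot(g[0, 0], g[0, 1]) < 1e-8:
        raise DegenerateGradientError("gradient magnitude below floor at start point")

    len_in, _, paths_in = _trace_batch(field, rc, +1, step, eps, keep_path=True)
    len_out, _, paths_out = _trace_batch(field, rc, -1, step, eps, keep_path=True)
    if np.isnan(len_in[0]) or np.isnan(len_out[0]):
        raise DegenerateGradientError("field line tracing failed (flat gradient region)")

    path = np.vstack([np.array(paths_in[0])[::-1], np.array(paths_out[0])[1:]])
    length_um = float((len_in[0] + len_out[0]) * field.spacing * field.pixel_size)
    return field.to_xy(path), length_um


# ---------------------------------------------------------------------------
# midline extraction and curvature


@dataclass
class MidlineProfile:
    """Samples on the phi = 0 midline: position, thickness, curvature."""

    slide_id: str
    points: np.ndarray  # (N, 2) (x, y) px
    arc_s: np.ndarray  # um, strictly increasing
    t: np.ndarray  # um
    kappa: np.ndarray  # 1/mm, >0 convex toward the pial surface (gyral crest)
    closed: bool = False

    def __len__(self):
        return len(self.arc_s)

    @property
    def total_length(self) -> float:
        return float(self.arc_s[-1] - self.arc_s[0]) if len(self.arc_s) else 0.0

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "slide_id": self.slide_id,
                "sample_index": np.arange(len(self.arc_s)),
                "x_px": self.points[:, 0],
                "y_px": self.points[:, 1],
                "arc_s_um": self.arc_s,
                "t_um": self.t,
                "kappa_per_mm": self.kappa,
            }
        )


def midline_profile(
    field: PotentialField,
    sample_step: float,
    curvature_window: float = 2000.0,
    trim: float = 0.0,
    trace_step: float = 0.25,
    trace_eps: float = 0.02,
) -> MidlineProfile:
    """Extract the phi=0 midline and sample thickness and curvature on it.

    ``sample_step``, ``curvature_window`` and ``trim`` are in micrometres;
    ``trim`` discards samples within that arc distance of the open ends of
    a band ribbon (where the zero-flux end condition distorts t).
    """
    if sample_step <= 0:
        raise ValueError("sample_step must be positive")
    um_per_cell = field.spacing * field.pixel_size

    grey_like = field.labels != OUTSIDE
    contours = [
        c
        for c in skmeasure.find_contours(field.phi_filled, 0.0)
        if len(c) >= 2 and _mostly_inside(c, grey_like)
    ]
    if not contours:
        raise NoMidlineError("phi = 0 level set is empty")
    # longest piece by arc length (slides hold one ribbon)
    lens = [np.hypot(*np.diff(c, axis=0).T).sum() for c in contours]
    curve = contours[int(np.argmax(lens))]

    closed = bool(np.allclose(curve[0], curve[-1]))
    if closed:
        curve = curve[:-1]

    seg = np.hypot(*np.diff(curve, axis=0).T) * um_per_cell
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1] + (np.hypot(*(curve[0] - curve[-1])) * um_per_cell if closed else 0.0)

    lo = trim if not closed else 0.0
    hi = (total - trim) if not closed else total - 1e-9
    if hi <= lo:
        raise NoMidlineError("midline shorter than twice the trim margin")
    targets = np.arange(lo, hi, sample_step)
    if closed:
        curve_i = np.vstack([curve, curve[:1]])
        s_i = np.concatenate([s, [total]])
    else:
        curve_i, s_i = curve, s
    rc = np.column_stack(
        [np.interp(targets, s_i, curve_i[:, 0]), np.interp(targets, s_i, curve_i[:, 1])]
    )

    len_in, _ = _trace_batch(field, rc, +1, trace_step, trace_eps)
    len_out, _ = _trace_batch(field, rc, -1, trace_step, trace_eps)
    t = (len_in + len_out) * um_per_cell

    ok = np.isfinite(t) & (t > 0)
    if not ok.all():
        warnings.warn(
            f"{(~ok).sum()} of {len(ok)} midline samples dropped (degenerate field line)"
        )
    rc, targets, t = rc[ok], targets[ok], t[ok]
    if len(rc) < 2:
        raise NoMidlineError("too few valid midline samples")

    xy = field.to_xy(rc)
    outward = -field.interp_grad(rc)  # toward the outer (pial) contour
    outward_xy = np.column_stack([outward[:, 1], outward[:, 0]])  # (dr,dc)->(dx,dy)
    kap = curvature(
        xy,
        curvature_window,
        field.pixel_size,
        outward=outward_xy,
        closed=closed and bool(ok.all()),
    )
    return MidlineProfile(field.slide_id, xy, targets, t, kap, closed=closed)


def _mostly_inside(curve_rc: np.ndarray, mask: np.ndarray) -> bool:
    r = np.clip(np.rint(curve_rc[:, 0]).astype(int), 0, mask.shape[0] - 1)
    c = np.clip(np.rint(curve_rc[:, 1]).astype(int), 0, mask.shape[1] - 1)
    return mask[r, c].mean() > 0.5


def curvature(
    points,
    window: float,
    pixel_size: float = 1.0,
    outward: np.ndarray | None = None,
    closed: bool = False,
) -> np.ndarray:
    """Signed curvature (1/mm) along an ordered curve, by sliding-arc fit.

    A circle is fit (Kasa least squares) to the points within an arc-length
    window (um) centred on each sample. The sign is positive where the curve
    is convex toward ``outward`` (the pial side: gyral crest), negative in
    sulcal fundi. Without ``outward``, the left-normal orientation of the
    curve fixes the sign.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or len(pts) < 3:
        raise InsufficientCurveError("curvature needs at least 3 points")
    n = len(pts)

    seg = np.hypot(*np.diff(pts, axis=0).T) * pixel_size
    s = np.concatenate([[0.0], np.cumsum(seg)])
    half = max(window / 2.0, 1.5 * max(np.median(seg), 1e-9))

    if closed:
        total = s[-1] + np.hypot(*(pts[0] - pts[-1])) * pixel_size
        ext_pts = np.vstack([pts, pts, pts])
        ext_s = np.concatenate([s - total, s, s + total])
        base = n
    else:
        ext_pts, ext_s, base = pts, s, 0

    kappa = np.zeros(n)
    for i in range(n):
        c0 = s[i]
        j0 = np.searchsorted(ext_s, c0 - half, side="left")
        j1 = np.searchsorted(ext_s, c0 + half, side="right")
        w = ext_pts[j0:j1]
        if len(w) < 3:
            continue
        kappa[i] = _kasa_signed(w, pts[i], None if outward is None else outward[i])
    return kappa / (pixel_size / 1000.0)  # 1/px-units -> 1/mm via um scale


def _kasa_signed(w: np.ndarray, p: np.ndarray, outward: np.ndarray | None) -> float:
    """Curvature in 1/(point units) from a Kasa circle fit, with sign."""
    x, y = w[:, 0] - p[0], w[:, 1] - p[1]  # center to tame conditioning
    # collinear windows have no curvature; the algebraic fit is unstable there
    xc, yc = x - x.mean(), y - y.mean()
    cov = np.array([[xc @ xc, xc @ yc], [xc @ yc, yc @ yc]])
    ev = np.linalg.eigvalsh(cov)
    if ev[0] <= 1e-10 * max(ev[1], 1e-30):
        return 0.0
    A = np.column_stack([x, y, np.ones(len(w))])
    b = -(x**2 + y**2)
    try:
        coef, *_ = np.linalg.lstsq(A, b, rcond=None)
    except np.linalg.LinAlgError:
        return 0.0
    cx, cy = -coef[0] / 2.0, -coef[1] / 2.0
    r2 = cx * cx + cy * cy - coef[2]
    if not np.isfinite(r2) or r2 <= 1e-12:
        return 0.0
    r = float(np.sqrt(r2))
    if r > 1e6:
        return 0.0
    if outward is not None and np.hypot(*outward) > 0:
        # center on the inner side <=> convex toward the pial surface
        sgn = np.sign(-(cx * outward[0] + cy * outward[1]))
    else:
        t0 = w[-1] - w[0]
        nrm = np.array([-t0[1], t0[0]])
        sgn = np.sign(cx * nrm[0] + cy * nrm[1])
    return float(sgn) / r
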