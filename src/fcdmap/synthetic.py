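"""Phantoms with analytic ground truth for every pipeline stage.

Three families:

* cortical ribbon phantoms — contour pairs of prescribed, spatially varying
  thickness, optionally with implanted thin foci (synthetic dysplasias);
* Boolean germ-grain cell fields — Poisson germs decorated with convex
  grains, rendered dark-on-light with additive Gaussian noise;
* rater-mask pairs with controlled pixelwise disagreement.

Every phantom carries its ground truth next to the rendered geometry or
image; no pipeline stage ever reads the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LineString
from skimage import draw as skdraw

from .errors import InvalidGeometryError
from .ribbon import ContourPair, curvature

__all__ = [
    "RibbonPhantom",
    "make_annulus_phantom",
    "make_gyral_ribbon",
    "make_thickness_pair",
    "DiskGrainSpec",
    "BooleanFieldTruth",
    "simulate_boolean_field",
    "make_disjoint_disks",
    "make_rater_masks",
]


# ---------------------------------------------------------------------------
# ribbon phantoms


@dataclass
class RibbonPhantom:
    """A contour pair plus the analytic truth it was built from.

    ``centerline`` and ``center_s`` parametrize the ribbon's spine;
    ``true_t`` is the prescribed full thickness (um) at each spine sample,
    after focus implantation. ``curvature_sign`` labels each spine sample
    {+1 crest, -1 sulcus, 0 flat} by the spine's convexity toward the outer
    contour. ``foci`` are (s_start_um, s_end_um, multiplier) intervals in
    spine arc length.
    """

    contour_pair: ContourPair
    centerline: np.ndarray  # (N, 2) px
    center_s: np.ndarray  # um, arc length along the spine
    true_t: np.ndarray  # um
    curvature_sign: np.ndarray  # int in {-1, 0, +1}
    foci: list[tuple[float, float, float]] = field(default_factory=list)

    def true_thickness(self, s_um) -> np.ndarray:
        """Prescribed thickness at spine arc position(s) s_um."""
        return np.interp(np.asarray(s_um, dtype=float), self.center_s, self.true_t)

    def project_to_spine(self, points_xy) -> np.ndarray:
        """Spine arc position (um) of the nearest spine sample to each point."""
        pts = np.atleast_2d(np.asarray(points_xy, dtype=float))
        d2 = (
            (pts[:, None, 0] - self.centerline[None, :, 0]) ** 2
            + (pts[:, None, 1] - self.centerline[None, :, 1]) ** 2
        )
        return self.center_s[np.argmin(d2, axis=1)]

    def in_focus(self, points_xy) -> np.ndarray:
        """Boolean per point: does it lie within an implanted focus?"""
        s = self.project_to_spine(points_xy)
        out = np.zeros(len(s), dtype=bool)
        for s0, s1, _ in self.foci:
            out |= (s >= s0) & (s <= s1)
        return out


def make_annulus_phantom(
    r_inner: float,
    r_outer: float,
    n_points: int = 720,
    pixel_size: float = 10.0,
    slide_id: str = "annulus",
) -> RibbonPhantom:
    """Concentric-circle ribbon: thickness is r_outer - r_inner everywhere.

    The analytic potential is phi(r) = a + b ln r, whose zero level sits at
    the geometric-mean radius sqrt(r_inner * r_outer).
    """
    if not 0 < r_inner < r_outer:
        raise InvalidGeometryError("need 0 < r_inner < r_outer")
    if n_points < 8:
        raise InvalidGeometryError("n_points too small to describe a circle")
    th = np.linspace(0.0, 2 * np.pi, n_points, endpoint=False)
    c = r_outer + 5.0
    outer = np.column_stack([c + r_outer * np.cos(th), c + r_outer * np.sin(th)])
    inner = np.column_stack([c + r_inner * np.cos(th), c + r_inner * np.sin(th)])
    cp = ContourPair(outer, inner, pixel_size, slide_id, closed=True)

    r_mid = np.sqrt(r_inner * r_outer)
    spine = np.column_stack([c + r_mid * np.cos(th), c + r_mid * np.sin(th)])
    s = np.concatenate([[0.0], np.cumsum(np.hypot(*np.diff(spine, axis=0).T))]) * pixel_size
    t = np.full(n_points, (r_outer - r_inner) * pixel_size)
    sign = np.ones(n_points, dtype=int)  # everywhere convex toward the outer circle
    return RibbonPhantom(cp, spine, s, t, sign, [])


def make_gyral_ribbon(
    centerline: np.ndarray,
    thickness_profile: np.ndarray,
    foci: list[tuple[float, float, float]] | None = None,
    pixel_size: float = 25.0,
    taper: float = 400.0,
    flat_kappa: float = 0.05,
    slide_id: str = "ribbon",
) -> RibbonPhantom:
    """Band ribbon built by offsetting a centerline by half the thickness.

    ``centerline`` is (N, 2) in px; ``thickness_profile`` the full thickness
    in px per centerline point. ``foci`` are (s_start_um, s_end_um,
    multiplier) intervals; the multiplier ramps in and out over ``taper``
    um *inside* the interval (cosine taper), so the implanted interval is
    exactly where the profile is scaled. The outer contour is on the left
    of the direction of travel. Offsets that self-intersect are rejected.
    """
    cl = np.asarray(centerline, dtype=float)
    prof = np.asarray(thickness_profile, dtype=float).copy()
    if cl.ndim != 2 or len(cl) < 3 or len(prof) != len(cl):
        raise InvalidGeometryError("centerline and thickness_profile shape mismatch")
    if (prof <= 0).any():
        raise InvalidGeometryError("thickness_profile must be positive")

    s_um = (
        np.concatenate([[0.0], np.cumsum(np.hypot(*np.diff(cl, axis=0).T))]) * pixel_size
    )
    foci = list(foci or [])
    for s0, s1, mult in foci:
        if s1 <= s0:
            raise InvalidGeometryError("focus interval must have positive length")
        ramp = np.clip(
            np.minimum(s_um - s0, s1 - s_um) / max(taper, 1e-9), 0.0, 1.0
        )
        depth = 0.5 - 0.5 * np.cos(np.pi * ramp)  # 0 at edges, 1 in the core
        inside = (s_um >= s0) & (s_um <= s1)
        prof = np.where(inside, prof * (1.0 + (mult - 1.0) * depth), prof)

    tang = np.gradient(cl, axis=0)
    tang /= np.maximum(np.hypot(tang[:, 0], tang[:, 1]), 1e-12)[:, None]
    normal = np.column_stack([-tang[:, 1], tang[:, 0]])  # left of travel = outer side
    outer = cl + normal * (prof / 2.0)[:, None]
    inner = cl - normal * (prof / 2.0)[:, None]

    for name, c in (("outer", outer), ("inner", inner)):
        if not LineString(c).is_simple:
            raise InvalidGeometryError(f"{name} offset curve self-intersects")
    if LineString(outer).intersects(LineString(inner)):
        raise InvalidGeometryError("offset curves cross (thickness too large for bend)")
    from shapely.geometry import Polygon

    if not Polygon(np.vstack([outer, inner[::-1]])).is_valid:
        raise InvalidGeometryError(
            "offset band degenerates (thickness exceeds the bend radius)"
        )

    cp = ContourPair(outer, inner, pixel_size, slide_id, closed=False)
    kap = curvature(cl, window=2000.0, pixel_size=pixel_size, outward=normal)
    sign = np.zeros(len(cl), dtype=int)
    sign[kap > flat_kappa] = 1
    sign[kap < -flat_kappa] = -1
    return RibbonPhantom(cp, cl, s_um, prof * pixel_size, sign, foci)


def make_thickness_pair(
    seed: int,
    focus_multiplier: float | None = 0.7,
    focus_length: float = 6000.0,
    baseline_t: float = 1500.0,
    modulation: float = 0.05,
    null_jitter: float = 0.015,
    pixel_size: float = 25.0,
    length_um: float = 24000.0,
    sinus_amp_um: float = 1200.0,
    sinus_period_um: float = 12000.0,
    slide_id: str = "pair",
) -> tuple[RibbonPhantom, RibbonPhantom]:
    """(case, control) gyral-ribbon phantoms for a detection experiment.

    Both share a sinusoidal spine and a smoothly modulated thickness
    profile (+-``modulation`` about ``baseline_t`` um). The case carries an
    implanted focus of the given multiplier and length at a random interior
    position, or — with ``focus_multiplier=None`` — only an independent
    smooth jitter of relative sd ``null_jitter`` (a null case).
    """
    rng = np.random.default_rng(seed)
    n = int(round(length_um / pixel_size)) // 2  # spine sampled every 2 px
    x = np.linspace(0.0, length_um / pixel_size, n)
    y = (sinus_amp_um / pixel_size) * np.sin(
        2 * np.pi * x * pixel_size / sinus_period_um + rng.uniform(0, 2 * np.pi)
    )
    off = sinus_amp_um / pixel_size + baseline_t / pixel_size + 10
    cl = np.column_stack([x + 10, y + off])
    s_um = np.concatenate([[0.0], np.cumsum(np.hypot(*np.diff(cl, axis=0).T))]) * pixel_size

    # thickness fluctuates on a 2-6 mm scale so one slide's midline carries
    # several independent excursions; quantile and medcouple estimates on
    # the control sample are then stable, as they are on real sections
    # whose ribbons run far longer than a phantom's
    prof = np.full(n, baseline_t / pixel_size)
    for _ in range(3):
        per = rng.uniform(2000.0, 6000.0)
        ph = rng.uniform(0, 2 * np.pi)
        prof = prof * (1.0 + (modulation / 1.6) * np.sin(2 * np.pi * s_um / per + ph))

    control = make_gyral_ribbon(
        cl, prof, [], pixel_size=pixel_size, slide_id=f"{slide_id}-control"
    )

    if focus_multiplier is None:
        jit = np.ones(n)
        for _ in range(2):
            per = rng.uniform(3000.0, 9000.0)
            ph = rng.uniform(0, 2 * np.pi)
            jit *= 1.0 + null_jitter * np.sin(2 * np.pi * s_um / per + ph)
        case = make_gyral_ribbon(
            cl, prof * jit, [], pixel_size=pixel_size, slide_id=f"{slide_id}-case"
        )
    else:
        margin = 0.15 * s_um[-1]
        s0 = rng.uniform(margin, s_um[-1] - margin - focus_length)
        case = make_gyral_ribbon(
            cl,
            prof,
            [(s0, s0 + focus_length, focus_multiplier)],
            pixel_size=pixel_size,
            slide_id=f"{slide_id}-case",
        )
    return case, control


# ---------------------------------------------------------------------------
# Boolean germ-grain fields


@dataclass
class DiskGrainSpec:
    """Disk grains with a fixed or uniformly distributed radius (px)."""

    radius: float | tuple[float, float] = 6.0

    @property
    def max_radius(self) -> float:
        return float(self.radius if np.isscalar(self.radius) else self.radius[1])

    @property
    def mean_area(self) -> float:
        """E[pi R^2] in px^2."""
        if np.isscalar(self.radius):
            return float(np.pi * self.radius**2)
        lo, hi = self.radius
        return float(np.pi * (hi**3 - lo**3) / (3.0 * (hi - lo)))

    @property
    def mean_perimeter(self) -> float:
        """E[2 pi R] in px."""
        if np.isscalar(self.radius):
            return float(2 * np.pi * self.radius)
        lo, hi = self.radius
        return float(np.pi * (lo + hi))

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if np.isscalar(self.radius):
            return np.full(n, float(self.radius))
        lo, hi = self.radius
        return rng.uniform(lo, hi, size=n)


@dataclass
class BooleanFieldTruth:
    """Ground truth of one Boolean-model realization."""

    germs: np.ndarray  # (n, 2) (x, y) px, may lie outside the window
    radii: np.ndarray  # px
    lambda_true: float  # germs per px^2
    window: tuple[int, int]  # (width, height) px
    grain_spec: DiskGrainSpec
    pixel_size: float = 1.0

    def render_mask(self, supersample: int = 1) -> np.ndarray:
        """Binary union of grains clipped to the window (row, col) raster.

        ``supersample`` > 1 renders on a grid that many times finer (the
        raster pixel is then 1/supersample of a window pixel), preserving
        sub-pixel gaps and holes that a native-resolution raster destroys;
        pass ``pixel_size/supersample`` downstream when measuring it.
        """
        w, h = self.window
        ss = int(supersample)
        mask = np.zeros((h * ss, w * ss), dtype=bool)
        for (x, y), r in zip(self.germs, self.radii):
            rr, cc = skdraw.disk((y * ss, x * ss), r * ss, shape=mask.shape)
            mask[rr, cc] = True
        return mask


def simulate_boolean_field(
    lambda_true: float,
    grain_spec: DiskGrainSpec,
    window: tuple[int, int],
    noise_sd: float = 0.0,
    seed: int = 0,
    background: float = 200.0,
    foreground: float = 60.0,
    pixel_size: float = 1.0,
) -> tuple[np.ndarray, BooleanFieldTruth]:
    """Render a Boolean germ-grain field as a noisy grayscale image.

    Germs are simulated on the window dilated by the maximum grain radius
    (minus-sampling edge correction), so coverage statistics inside the
    window are unbiased. Grains are stamped dark on a light background;
    i.i.d. Gaussian noise of sd ``noise_sd`` is added. Same seed, same
    image.
    """
    if lambda_true < 0:
        raise ValueError("lambda_true must be >= 0")
    w, h = window
    if w <= 0 or h <= 0:
        raise ValueError("window must be nonempty")
    rng = np.random.default_rng(seed)
    rmax = grain_spec.max_radius
    area_ext = (w + 2 * rmax) * (h + 2 * rmax)
    n = rng.poisson(lambda_true * area_ext) if lambda_true > 0 else 0
    germs = np.column_stack(
        [rng.uniform(-rmax, w + rmax, n), rng.uniform(-rmax, h + rmax, n)]
    )
    radii = grain_spec.sample(rng, n)
    truth = BooleanFieldTruth(germs, radii, lambda_true, window, grain_spec, pixel_size)

    mask = truth.render_mask()
    img = np.full((h, w), float(background))
    img[mask] = float(foreground)
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return img.astype(np.float32), truth


def make_disjoint_disks(
    n: int,
    radius: float,
    shape: tuple[int, int],
    min_gap: float = 4.0,
    seed: int = 0,
    max_tries: int = 100_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Dart-throw ``n`` non-overlapping disks; returns (centers_xy, mask)."""
    rng = np.random.default_rng(seed)
    h, w = shape
    margin = radius + 2
    centers: list[tuple[float, float]] = []
    tries = 0
    while len(centers) < n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError("could not place disjoint disks; window too crowded")
        x = rng.uniform(margin, w - margin)
        y = rng.uniform(margin, h - margin)
        if all((x - cx) ** 2 + (y - cy) ** 2 >= (2 * radius + min_gap) ** 2 for cx, cy in centers):
            centers.append((x, y))
    cxy = np.array(centers)
    mask = np.zeros(shape, dtype=bool)
    for x, y in cxy:
        rr, cc = skdraw.disk((y, x), radius, shape=shape)
        mask[rr, cc] = True
    return cxy, mask


# ---------------------------------------------------------------------------
# rater masks


def make_rater_masks(
    base_mask: np.ndarray, flip_prob: float, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Two rater masks: the base with independent pixelwise label flips."""
    if not 0.0 <= flip_prob <= 1.0:
        raise ValueError("flip_prob must be in [0, 1]")
    base = np.asarray(base_mask, dtype=bool)
    rng = np.random.default_rng(seed)
    a = base ^ (rng.random(base.shape) < flip_prob)
    b = base ^ (rng.random(base.shape) < flip_prob)
    return a, b
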