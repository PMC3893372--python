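"""Seeded validation experiments on phantoms with analytic ground truth.

Each function runs one recovery or calibration study end-to-end — generate
a phantom, run the pipeline stage under test, score against the phantom's
truth — and returns plain numbers. The test suite and the acceptance
script both drive these, so the measured quantities come from exactly one
code path.
"""

from __future__ import annotations

import warnings

import numpy as np

from .agreement import gwet_ac1
from .detection import adjusted_fences, flag_thin_regions, flagged_fraction, medcouple
from .ribbon import GREY, midline_profile, rasterize_ribbon, solve_laplace
from .segmentation import CellImage, SegmentationConfig, segment_neurons
from .spatial import fit_boolean, granulometry
from .synthetic import (
    DiskGrainSpec,
    make_annulus_phantom,
    make_disjoint_disks,
    make_rater_masks,
    make_thickness_pair,
    simulate_boolean_field,
)

ANNULUS = dict(r_inner=40.0, r_outer=70.0, pixel_size=10.0)


def annulus_thickness_accuracy(sample_step: float = 20.0) -> dict:
    """Midline thickness and radius on the analytic annulus phantom.

    True thickness is 300 um everywhere; the phi=0 midline sits at the
    geometric-mean radius sqrt(40*70) px. Returns worst-case relative
    errors plus the Laplace log-fit deviation.
    """
    ph = make_annulus_phantom(**ANNULUS)
    grid = rasterize_ribbon(ph.contour_pair)
    fld = solve_laplace(grid)
    prof = midline_profile(fld, sample_step=sample_step)

    true_t = (ANNULUS["r_outer"] - ANNULUS["r_inner"]) * ANNULUS["pixel_size"]
    r_true = np.sqrt(ANNULUS["r_inner"] * ANNULUS["r_outer"])
    center = ANNULUS["r_outer"] + 5.0
    r_mid = np.hypot(prof.points[:, 0] - center, prof.points[:, 1] - center)

    rr, cc = np.nonzero(fld.labels == GREY)
    r_px = np.hypot(cc + fld.origin[0], rr + fld.origin[1] * 1.0)
    r_px = np.hypot(cc + fld.origin[0] - center, rr + fld.origin[1] - center)
    phi = fld.phi[rr, cc]
    design = np.column_stack([np.ones_like(r_px), np.log(r_px)])
    coef, *_ = np.linalg.lstsq(design, phi, rcond=None)
    log_dev = float(np.abs(phi - design @ coef).max())

    return {
        "t_um": prof.t,
        "max_t_rel_err": float(np.abs(prof.t / true_t - 1.0).max()),
        "mean_t_um": float(prof.t.mean()),
        "midline_radius_px": float(r_mid.mean()),
        "max_radius_rel_err": float(np.abs(r_mid / r_true - 1.0).max()),
        "log_fit_max_dev": log_dev,
        "kappa_per_mm": prof.kappa,
    }


def band_linearity(width_px: float = 20.0, length_px: int = 200, pixel_size: float = 10.0) -> dict:
    """phi linearity and thickness on a parallel-band ribbon."""
    from .synthetic import make_gyral_ribbon

    cl = np.column_stack(
        [np.arange(length_px, dtype=float) + 5, np.full(length_px, 40.0)]
    )
    rb = make_gyral_ribbon(cl, np.full(length_px, width_px), pixel_size=pixel_size)
    fld = solve_laplace(rasterize_ribbon(rb.contour_pair))
    rr, cc = np.nonzero(fld.labels == GREY)
    y = rr + fld.origin[1]
    phi = fld.phi[rr, cc]
    design = np.column_stack([np.ones_like(y), y])
    coef, *_ = np.linalg.lstsq(design, phi, rcond=None)
    lin_dev = float(np.abs(phi - design @ coef).max())
    prof = midline_profile(fld, sample_step=2.0 * pixel_size, trim=30.0 * pixel_size)
    true_t = width_px * pixel_size
    return {
        "linear_fit_max_dev": lin_dev,
        "max_t_rel_err": float(np.abs(prof.t / true_t - 1.0).max()),
    }


def medcouple_oracle_check(n_samples: int = 200, max_n: int = 50, seed: int = 0) -> dict:
    """Package medcouple vs an independent brute-force kernel-median oracle."""

    def oracle(x):
        x = np.sort(np.asarray(x, float))
        m = np.median(x)
        vals = []
        zero_i = [i for i, v in enumerate(x) if v == m]
        k = len(zero_i)
        for i, xi in enumerate(x):
            for j, xj in enumerate(x):
                if xi > m or xj < m:
                    continue
                if xi == m and xj == m:
                    p = zero_i.index(i)
                    q = zero_i.index(j)
                    vals.append(float(np.sign(p + q - (k - 1))))
                else:
                    vals.append(((xj - m) - (m - xi)) / (xj - xi))
        return float(np.median(vals))

    rng = np.random.default_rng(seed)
    worst = 0.0
    for trial in range(n_samples):
        n = int(rng.integers(3, max_n + 1))
        if trial % 3 == 0:
            x = rng.integers(0, 6, n).astype(float)
        else:
            x = rng.lognormal(0.0, 1.0, n)
        if x.min() == x.max():
            continue
        worst = max(worst, abs(medcouple(x) - oracle(x)))
    return {"max_abs_diff": worst}


def _profile_of(phantom, sample_step=200.0, trim=1000.0):
    fld = solve_laplace(rasterize_ribbon(phantom.contour_pair))
    return midline_profile(fld, sample_step=sample_step, trim=trim)


def focus_recovery(
    n_seeds: int = 50,
    seed0: int = 0,
    focus_multiplier: float = 0.7,
    focus_length: float = 6000.0,
    min_jaccard: float = 0.8,
) -> dict:
    """Implanted-focus detection study over seeded phantom pairs.

    For each seed: build a (case, control) gyral-ribbon pair, run the full
    thickness + fence + flagging pipeline, and score the interval Jaccard
    between flagged samples and the implanted focus. Returns the per-seed
    Jaccards and the fraction of seeds detected at ``min_jaccard``.
    """
    jacs = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for k in range(n_seeds):
            case, ctrl = make_thickness_pair(
                seed0 + k,
                focus_multiplier=focus_multiplier,
                focus_length=focus_length,
            )
            pc, pk = _profile_of(case), _profile_of(ctrl)
            fences = adjusted_fences(pk.t)
            regions = flag_thin_regions(pc, fences, min_len=1000.0)
            truth = case.in_focus(pc.points)
            flagged = np.zeros(len(pc), dtype=bool)
            for r in regions:
                flagged |= (pc.arc_s >= r.s_start) & (pc.arc_s <= r.s_end)
            union = (truth | flagged).sum()
            jacs.append(float((truth & flagged).sum() / union) if union else 0.0)
    jacs = np.asarray(jacs)
    return {
        "jaccards": jacs,
        "detection_rate": float(np.mean(jacs >= min_jaccard)),
        "mean_jaccard": float(jacs.mean()),
    }


def null_calibration(
    n_seeds: int = 50, seed0: int = 0, noise_rel_sd: float = 0.01
) -> dict:
    """False-alarm study: case = control thickness + i.i.d. sample noise.

    One phantom per seed; its measured profile serves as the control, and
    the case is the same profile with independent Gaussian noise
    (``noise_rel_sd`` of the median thickness) added per sample. Returns
    flagged arc-length fractions per seed.
    """
    fracs = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for k in range(n_seeds):
            _, ctrl = make_thickness_pair(seed0 + k, focus_multiplier=None, null_jitter=0.0)
            prof = _profile_of(ctrl)
            rng = np.random.default_rng(seed0 + 10_000 + k)
            noisy = prof.t + rng.normal(0.0, noise_rel_sd * np.median(prof.t), len(prof))
            case = type(prof)(
                prof.slide_id, prof.points, prof.arc_s, noisy, prof.kappa, prof.closed
            )
            regions = flag_thin_regions(case, adjusted_fences(prof.t), min_len=1000.0)
            fracs.append(flagged_fraction(regions, case))
    fracs = np.asarray(fracs)
    return {"fractions": fracs, "max_fraction": float(fracs.max()), "mean_fraction": float(fracs.mean())}


BOOLEAN = dict(lam=0.005, radius=6.0, window=(1000, 1000), supersample=4)


def boolean_recovery(n_seeds: int = 10, seed0: int = 0) -> dict:
    """Boolean-model parameter recovery on simulated germ-grain fields.

    Truth: intensity 0.005 germs/px^2, disk grains of radius 6 px, in a
    1000 x 1000 px window; the union mask is rendered at 4x sub-pixel
    resolution so near-tangencies keep their true topology. Returns mean
    relative errors of (lambda, A_bar, U_bar).
    """
    lam, r = BOOLEAN["lam"], BOOLEAN["radius"]
    ss = BOOLEAN["supersample"]
    ests = []
    for k in range(n_seeds):
        _, truth = simulate_boolean_field(
            lam, DiskGrainSpec(r), BOOLEAN["window"], 0.0, seed=seed0 + k
        )
        mask = truth.render_mask(supersample=ss)
        est = fit_boolean(mask, edge_margin=r, pixel_size=1.0 / ss)
        ests.append((est.lambda_hat, est.a_bar, est.u_bar))
    ests = np.asarray(ests).mean(axis=0)
    return {
        "lambda_hat": float(ests[0]),
        "a_bar": float(ests[1]),
        "u_bar": float(ests[2]),
        "lambda_rel_err": float(abs(ests[0] / lam - 1.0)),
        "a_rel_err": float(abs(ests[1] / (np.pi * r**2) - 1.0)),
        "u_rel_err": float(abs(ests[2] / (2 * np.pi * r) - 1.0)),
    }


def granulometry_mode_shift(seed: int = 0) -> dict:
    """Pattern-spectrum mode of radius-6 vs radius-5 Boolean fields.

    The qualitative contrast behind a downward shift of the neuronal size
    distribution: the smaller-grain field's spectrum peaks at a smaller
    structuring-element size.
    """
    out = {}
    for name, r in (("large", 6.0), ("small", 5.0)):
        _, truth = simulate_boolean_field(
            0.003, DiskGrainSpec(r), (600, 600), 0.0, seed=seed
        )
        mask = truth.render_mask()
        ps = granulometry(mask, np.arange(0.0, 13.0), pixel_size=1.0)
        out[name] = ps
    return {
        "mode_large": out["large"].mode_size,
        "mode_small": out["small"].mode_size,
        "shifted_down": out["small"].mode_size < out["large"].mode_size,
    }


def segmentation_recovery(n_seeds: int = 10, seed0: int = 0, noise_sd: float = 10.0) -> dict:
    """Object-count and Dice recovery on noisy disjoint-disk cell images.

    50 disks of radius 6 px (intensity 80 on background 200, Gaussian
    noise sd 10) per image; Dice is per true disk against its
    best-overlapping segmented object.
    """
    counts, dices = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for k in range(n_seeds):
            rng = np.random.default_rng(seed0 + k)
            centers, mask = make_disjoint_disks(50, 6.0, (512, 512), seed=seed0 + k)
            img = np.full((512, 512), 200.0)
            img[mask] = 80.0
            img = img + rng.normal(0.0, noise_sd, img.shape)
            labels = segment_neurons(CellImage(img, pixel_size=0.74), SegmentationConfig())
            counts.append(int(labels.max()))
            yy, xx = np.indices(labels.shape)
            ds = []
            for (x, y) in centers:
                true = (yy - y) ** 2 + (xx - x) ** 2 < 36.0
                labs, cnt = np.unique(labels[true & (labels > 0)], return_counts=True)
                if labs.size == 0:
                    ds.append(0.0)
                    continue
                pred = labels == labs[np.argmax(cnt)]
                ds.append(2.0 * np.sum(true & pred) / (true.sum() + pred.sum()))
            dices.append(float(np.mean(ds)))
    return {
        "counts": np.asarray(counts),
        "mean_count": float(np.mean(counts)),
        "mean_dice": float(np.mean(dices)),
    }


def ggmrf_edge_preservation(seed: int = 0) -> dict:
    """Max edge gradient after relaxation at p=1.1 vs p=2 on a noisy step."""
    from .segmentation import ggmrf_relax

    rng = np.random.default_rng(seed)
    step = np.full((64, 64), 200.0)
    step[:, 32:] = 100.0
    noisy = step + rng.normal(0.0, 10.0, step.shape)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        g = {}
        for p in (1.1, 2.0):
            out = ggmrf_relax(CellImage(noisy), p=p, sigma=10.0, beta=1.0, max_iter=40)
            g[p] = float(np.abs(np.gradient(out.intensities, axis=1)).max())
    return {"max_grad_p11": g[1.1], "max_grad_p20": g[2.0], "preserved": g[1.1] > g[2.0]}


def ac1_flip_curve(
    flip_probs=(0.0, 0.1, 0.2, 0.3), n_seeds: int = 10, seed0: int = 0
) -> dict:
    """Mean AC1 against rater-mask flip probability (expect monotone decay)."""
    rng = np.random.default_rng(seed0)
    base = rng.random((80, 80)) < 0.3
    means = []
    for p in flip_probs:
        vals = []
        for k in range(n_seeds):
            a, b = make_rater_masks(base, p, seed=seed0 + 97 * k + int(1000 * p))
            vals.append(gwet_ac1(a.ravel(), b.ravel(), categories=[False, True]).ac1)
        means.append(float(np.mean(vals)))
    return {"flip_probs": list(flip_probs), "mean_ac1": means}
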