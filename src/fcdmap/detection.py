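"""Robust-fence detection of focal cortical thinning.

For each matched slide pair, the control slide's thickness sample defines
skew-adjusted boxplot fences (Hubert & Vandervieren's medcouple-based
rule); contiguous runs of the case midline falling below the lower fence
are flagged as candidate dysplastic regions. Per-slide thickness means and
position x curvature difference maps summarize the cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientSampleError, UndefinedMedcoupleError
from .ribbon import MidlineProfile


def medcouple(sample) -> float:
    """Medcouple robust skewness: median of the pairwise kernel

        h(x_i, x_j) = ((x_j - m) - (m - x_i)) / (x_j - x_i),

    over pairs x_i <= m <= x_j, with the standard -1/0/+1 rule for pairs
    tied at the median m. Computed by exhaustive O(n^2) enumeration.
    """
    x = np.sort(np.asarray(sample, dtype=float))
    if x.size < 3:
        raise UndefinedMedcoupleError("medcouple needs n >= 3")
    if x[0] == x[-1]:
        raise UndefinedMedcoupleError("medcouple undefined for a constant sample")
    m = np.median(x)
    z = x - m
    plus = z[z >= 0]  # ascending, zeros first
    minus = z[z <= 0]  # ascending, zeros last
    k = int((z == 0).sum())

    rows = []
    for lo in range(0, plus.size, 1024):
        p = plus[lo : lo + 1024, None]
        with np.errstate(invalid="ignore", divide="ignore"):
            h = (p + minus[None, :]) / (p - minus[None, :])
        if k:  # tie block: p == 0 rows are 0..k-1, m == 0 cols are the last k
            for i in range(lo, min(lo + 1024, k)):
                j = np.arange(k)
                h[i - lo, minus.size - k :] = np.sign(i + j - (k - 1))
        rows.append(h.ravel())
    return float(np.median(np.concatenate(rows)))


@dataclass
class FenceResult:
    """Skew-adjusted boxplot fences for one thickness sample."""

    q1: float
    q2: float
    q3: float
    medcouple: float
    lower_fence: float
    upper_fence: float
    n: int


def adjusted_fences(sample, n_floor: int = 8, variant: str = "adjusted") -> FenceResult:
    """Outlier fences from a thickness sample.

    variant='adjusted' uses the medcouple-calibrated exponential factors

        MC >= 0:  [q1 - 1.5 e^{-4 MC} IQR,  q3 + 1.5 e^{+3 MC} IQR]
        MC <  0:  [q1 - 1.5 e^{-3 MC} IQR,  q3 + 1.5 e^{+4 MC} IQR]

    which reduce to Tukey's 1.5 IQR fences for a symmetric sample;
    variant='tukey' forces MC = 0 (sensitivity analysis). Quantiles are
    linear-interpolation (type-7) sample quantiles.
    """
    x = np.asarray(sample, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < n_floor:
        raise InsufficientSampleError(f"need at least {n_floor} samples, got {x.size}")
    q1, q2, q3 = np.quantile(x, [0.25, 0.5, 0.75])
    iqr = q3 - q1
    if variant == "tukey":
        mc = 0.0
    elif variant == "adjusted":
        mc = 0.0 if x.min() == x.max() else medcouple(x)
    else:
        raise ValueError(f"unknown fence variant {variant!r}")
    if mc >= 0:
        lo = q1 - 1.5 * np.exp(-4.0 * mc) * iqr
        hi = q3 + 1.5 * np.exp(3.0 * mc) * iqr
    else:
        lo = q1 - 1.5 * np.exp(-3.0 * mc) * iqr
        hi = q3 + 1.5 * np.exp(4.0 * mc) * iqr
    return FenceResult(float(q1), float(q2), float(q3), float(mc), float(lo), float(hi), x.size)


@dataclass
class DysplasiaRegion:
    """A contiguous below-fence run on a case midline."""

    slide_id: str
    s_start: float  # um
    s_end: float  # um
    mean_t: float  # um
    mean_kappa: float  # 1/mm
    n_samples: int

    @property
    def length(self) -> float:
        return self.s_end - self.s_start


def flag_thin_regions(
    case_profile: MidlineProfile,
    control_fences: FenceResult,
    min_len: float = 1000.0,
) -> list[DysplasiaRegion]:
    """Maximal contiguous runs with t below the control lower fence.

    Runs shorter than ``min_len`` um of arc are discarded. On closed
    midlines a run wrapping the arc origin is merged. Output is invariant
    to reversing the sampling direction.
    """
    t = case_profile.t
    s = case_profile.arc_s
    below = t < control_fences.lower_fence
    if not below.any():
        return []

    # maximal runs of consecutive below-fence samples
    edges = np.flatnonzero(np.diff(below.astype(int)))
    starts = [0] if below[0] else []
    starts += [int(e) + 1 for e in edges if below[e + 1]]
    ends = [int(e) for e in edges if below[e]]
    ends += [len(below) - 1] if below[-1] else []
    runs = list(zip(starts, ends))

    if case_profile.closed and len(runs) > 1 and below[0] and below[-1]:
        # merge the wrap-around run; represent it by the longer arm's span
        first, last = runs[0], runs[-1]
        runs = runs[1:-1]
        merged_idx = list(range(last[0], len(below))) + list(range(0, first[1] + 1))
        runs.append((last[0], first[1], merged_idx))

    out = []
    for run in runs:
        if len(run) == 3:
            i0, i1, idx = run
            length = (s[-1] - s[i0]) + (s[i1] - s[0]) + (s[1] - s[0])
        else:
            i0, i1 = run
            idx = list(range(i0, i1 + 1))
            length = s[i1] - s[i0]
        if length < min_len:
            continue
        out.append(
            DysplasiaRegion(
                case_profile.slide_id,
                float(s[i0]),
                float(s[i1]),
                float(np.mean(t[idx])),
                float(np.mean(case_profile.kappa[idx])),
                len(idx),
            )
        )
    return sorted(out, key=lambda r: r.s_start)


def flagged_fraction(
    regions: list[DysplasiaRegion], profile: MidlineProfile
) -> float:
    """Fraction of midline arc length covered by flagged regions."""
    total = profile.total_length
    if total <= 0:
        return 0.0
    cov = sum(min(r.length, total) for r in regions)
    return float(min(cov / total, 1.0))


def mean_thickness_by_slide(
    profiles: list[MidlineProfile], meta: pd.DataFrame
) -> pd.DataFrame:
    """Per-slide unweighted mean thickness, tagged with cohort metadata.

    ``meta`` must carry slide_id plus any of pair_id, group, y; the result
    has one row per profile (pair_id, group, y, mean_t, n_samples).
    """
    rows = [
        {"slide_id": p.slide_id, "mean_t": float(np.mean(p.t)), "n_samples": len(p)}
        for p in profiles
    ]
    df = pd.DataFrame(rows)
    return df.merge(meta, on="slide_id", how="left")


def position_curvature_map(
    case_samples: pd.DataFrame,
    control_samples: pd.DataFrame,
    y_bins: np.ndarray,
    kappa_bins: np.ndarray,
    n_min: int = 10,
) -> dict:
    """Binned mean thickness difference (case - control) over (y, kappa).

    Inputs are per-sample tables with columns y (mm), kappa (1/mm), t (um).
    Means are taken within each bin per group and differenced; bins where
    either group has fewer than ``n_min`` samples are NaN-masked. Returns
    a dict with bin edges, the delta-t grid, and per-group counts.
    """
    y_bins = np.asarray(y_bins, dtype=float)
    kappa_bins = np.asarray(kappa_bins, dtype=float)

    def binned(df):
        cnt, _, _ = np.histogram2d(df["y"], df["kappa"], bins=[y_bins, kappa_bins])
        tot, _, _ = np.histogram2d(
            df["y"], df["kappa"], bins=[y_bins, kappa_bins], weights=df["t"]
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(cnt > 0, tot / np.maximum(cnt, 1), np.nan), cnt

    mc, nc = binned(case_samples)
    mk, nk = binned(control_samples)
    delta = mc - mk
    delta[(nc < n_min) | (nk < n_min)] = np.nan
    return {
        "y_edges": y_bins,
        "kappa_edges": kappa_bins,
        "delta_t": delta,
        "n_case": nc,
        "n_control": nk,
    }
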