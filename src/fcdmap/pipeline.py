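"""End-to-end composition: cohort parsing, synthetic cohorts, full runs.

A run takes a slide manifest (CSV) whose rows point at contour files,
computes thickness profiles, positions slides on the stereotaxic y axis,
matches case to control slides, builds control fences, flags below-fence
case regions, and writes per-stage CSV outputs plus a JSON run record
embedding the configuration hash.
"""

from __future__ import annotations

import json
import warnings
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as fio
from .config import PipelineConfig
from .detection import (
    adjusted_fences,
    flag_thin_regions,
    mean_thickness_by_slide,
    position_curvature_map,
)
from .errors import PairingError
from .ribbon import midline_profile, rasterize_ribbon, solve_laplace
from .stereotaxic import SlidePosition, SlideSeries, assign_y, match_slides
from .synthetic import make_thickness_pair

# ---------------------------------------------------------------------------
# donor cohort table


def parse_cohort_table(source=None) -> tuple[pd.DataFrame, dict]:
    """Parse a donor table into a paired cohort manifest plus summary stats.

    ``source`` is a CSV path or DataFrame with columns (group, pair,
    atp_case, age, sex, seizures); None loads the packaged 7+7 donor
    table. Ages with a trailing dash (unknown decimal, e.g. "13.-") parse
    as .0 and are flagged in ``age_approx``. Raises on unpaired rows.
    Summary reports the maximum within-pair age gap and per-group seizure
    counts.
    """
    if source is None:
        with resources.files("fcdmap.data").joinpath("table1.csv").open("rb") as fh:
            df = pd.read_csv(fh)
    elif isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source)

    need = {"group", "pair", "atp_case", "age", "sex", "seizures"}
    if not need.issubset(df.columns):
        raise ValueError(f"cohort table lacks columns {need - set(df.columns)}")

    def parse_age(v):
        s = str(v).strip()
        approx = s.endswith(("-", "–", "—"))
        s = s.rstrip("-–—")
        if s.endswith("."):
            s = s + "0"
        return float(s), approx

    parsed = [parse_age(v) for v in df["age"]]
    df["age_years"] = [p[0] for p in parsed]
    df["age_approx"] = [p[1] for p in parsed]
    df["seizures"] = df["seizures"].astype(str).str.upper().eq("Y")

    groups = set(df["group"])
    if groups != {"asd", "control"}:
        raise PairingError(f"expected groups 'asd' and 'control', got {sorted(groups)}")
    gaps = {}
    for pair, sub in df.groupby("pair"):
        if sorted(sub["group"]) != ["asd", "control"]:
            raise PairingError(f"pair {pair} is not one asd + one control donor")
        a = sub[sub.group == "asd"]["age_years"].iloc[0]
        c = sub[sub.group == "control"]["age_years"].iloc[0]
        gaps[pair] = abs(a - c)

    summary = {
        "n_asd": int((df.group == "asd").sum()),
        "n_control": int((df.group == "control").sum()),
        "max_pair_age_gap": float(max(gaps.values())),
        "pair_age_gaps": {int(k): float(v) for k, v in gaps.items()},
        "seizures_asd": int(df[df.group == "asd"]["seizures"].sum()),
        "seizures_control": int(df[df.group == "control"]["seizures"].sum()),
    }
    return df, summary


# ---------------------------------------------------------------------------
# synthetic cohorts on disk


def build_synthetic_cohort(
    outdir,
    n_pairs: int = 7,
    slides_per_donor: int = 3,
    seed: int = 0,
    focus_multiplier: float = 0.6,
    pixel_size: float = 25.0,
) -> Path:
    """Write a phantom cohort (contour files + manifest CSV) to ``outdir``.

    Each pair gets ``slides_per_donor`` y-positions; the case donor's
    anterior slide carries an implanted thin focus, the rest are null
    twins. Returns the manifest path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    rng = np.random.default_rng(seed)
    for pair in range(1, n_pairs + 1):
        for k in range(slides_per_donor):
            sseed = int(rng.integers(0, 2**31 - 1))
            focal = k == 0  # anterior slide carries the focus
            case_ph, ctrl_ph = make_thickness_pair(
                sseed,
                focus_multiplier=focus_multiplier if focal else None,
                pixel_size=pixel_size,
                slide_id=f"p{pair}s{k}",
            )
            landmark = {0: "frontal_pole", slides_per_donor - 1: "occipital_pole"}.get(
                k, "AC" if k == slides_per_donor // 2 else ""
            )
            for group, ph in (("case", case_ph), ("control", ctrl_ph)):
                sid = f"{group}-p{pair}-s{k}"
                path = outdir / f"{sid}.csv"
                ph.contour_pair.slide_id = sid
                fio.write_contours(ph.contour_pair, path)
                rows.append(
                    {
                        "slide_id": sid,
                        "pair_id": pair,
                        "group": group,
                        "slide_index": k,
                        "landmark": landmark,
                        "contour_file": path.name,
                    }
                )
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


# ---------------------------------------------------------------------------
# full run


def _positions_for_donor(sub: pd.DataFrame) -> list[SlidePosition]:
    sub = sub.sort_values("slide_index")
    lm = {str(r.landmark): int(i) for i, (_, r) in enumerate(sub.iterrows()) if str(r.landmark) not in ("", "nan")}
    series = SlideSeries(
        slides=list(sub["slide_id"]),
        frontal_pole=lm.get("frontal_pole"),
        anterior_commissure=lm.get("AC", lm.get("anterior_commissure")),
        occipital_pole=lm.get("occipital_pole"),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # tiny synthetic series violate 1.2 mm spacing
        return assign_y(series)


def run_pipeline(manifest_path, config: PipelineConfig | None = None, outdir=None) -> dict:
    """Execute thickness -> matching -> fences -> region flagging.

    Writes profiles/, fences.csv, regions.csv, mean_t.csv, delta_t_map.csv
    and run.json into ``outdir`` and returns the run record. Fails fast,
    naming the stage and slide, when an input is missing or a stage
    errors.
    """
    cfg = config or PipelineConfig()
    manifest_path = Path(manifest_path)
    outdir = Path(outdir) if outdir else manifest_path.parent / "out"
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "profiles").mkdir(exist_ok=True)

    man = pd.read_csv(manifest_path).fillna({"landmark": ""})
    base = manifest_path.parent
    for _, row in man.iterrows():
        f = base / row.contour_file
        if not f.exists():
            raise FileNotFoundError(f"manifest references missing contour file: {f}")

    # thickness per slide
    profiles = {}
    for _, row in man.iterrows():
        try:
            cp, _ = fio.read_contours(base / row.contour_file)
            grid = rasterize_ribbon(cp)
            fld = solve_laplace(grid, tol=cfg.solver_tol)
            prof = midline_profile(
                fld,
                sample_step=cfg.sample_step_um,
                curvature_window=cfg.curvature_window_um,
                trim=cfg.trim_um,
            )
        except Exception as exc:
            raise RuntimeError(f"thickness stage failed on slide {row.slide_id}: {exc}") from exc
        profiles[row.slide_id] = prof
        fio.write_profile(prof, outdir / "profiles" / f"{row.slide_id}.csv")

    # stereotaxic positions per donor
    pos = {}
    for (pair, group), sub in man.groupby(["pair_id", "group"]):
        for sp in _positions_for_donor(sub):
            pos[sp.slide_id] = sp.y
    meta = man[["slide_id", "pair_id", "group"]].copy()
    meta["y"] = [pos[s] for s in meta.slide_id]

    # match case slides to control slides within each pair
    pairs = []
    for pair, sub in man.groupby("pair_id"):
        cases = [SlidePosition(s, pos[s]) for s in sub[sub.group == "case"].slide_id]
        ctrls = [SlidePosition(s, pos[s]) for s in sub[sub.group == "control"].slide_id]
        for cid, kid, dy in match_slides(cases, ctrls, max_dy=cfg.max_dy_mm):
            pairs.append({"pair_id": pair, "case_slide": cid, "control_slide": kid, "dy": dy})
    pairs = pd.DataFrame(pairs)

    # fences from each matched control slide; flag case regions
    fence_rows, region_rows = [], []
    for _, row in pairs.iterrows():
        ctrl_prof = profiles[row.control_slide]
        fences = adjusted_fences(ctrl_prof.t, variant=cfg.fence_variant)
        fence_rows.append(
            {
                "control_slide": row.control_slide,
                "q1": fences.q1,
                "q2": fences.q2,
                "q3": fences.q3,
                "medcouple": fences.medcouple,
                "lower_fence": fences.lower_fence,
                "upper_fence": fences.upper_fence,
                "n": fences.n,
            }
        )
        for reg in flag_thin_regions(
            profiles[row.case_slide], fences, min_len=cfg.min_region_len_um
        ):
            region_rows.append(
                {
                    "slide_id": reg.slide_id,
                    "control_slide": row.control_slide,
                    "s_start_um": reg.s_start,
                    "s_end_um": reg.s_end,
                    "mean_t_um": reg.mean_t,
                    "mean_kappa_per_mm": reg.mean_kappa,
                    "n_samples": reg.n_samples,
                }
            )

    mean_t = mean_thickness_by_slide(list(profiles.values()), meta)

    def samples(group):
        frames = []
        for _, r in meta[meta.group == group].iterrows():
            p = profiles[r.slide_id]
            frames.append(pd.DataFrame({"y": r.y, "kappa": p.kappa, "t": p.t}))
        return pd.concat(frames, ignore_index=True)

    y_edges = np.linspace(-106.0, 73.0, 13)
    k_edges = np.array([-np.inf, -0.1, 0.1, np.inf])
    dmap = position_curvature_map(samples("case"), samples("control"), y_edges, k_edges, n_min=5)

    # outputs, each stamped with the config hash
    stamp = {"config_hash": cfg.hash}
    pd.DataFrame(fence_rows).assign(**stamp).to_csv(outdir / "fences.csv", index=False)
    pd.DataFrame(region_rows).assign(**stamp).to_csv(outdir / "regions.csv", index=False)
    mean_t.assign(**stamp).to_csv(outdir / "mean_t.csv", index=False)
    pairs.assign(**stamp).to_csv(outdir / "matched_pairs.csv", index=False)

    dm = pd.DataFrame(
        dmap["delta_t"],
        index=[f"y[{y_edges[i]:.0f},{y_edges[i+1]:.0f})" for i in range(len(y_edges) - 1)],
        columns=["sulcus", "flat", "crest"],
    )
    dm.assign(**stamp).to_csv(outdir / "delta_t_map.csv")

    record = {
        "config_hash": cfg.hash,
        "config": json.loads(json.dumps(cfg.__dict__, default=lambda o: o.__dict__)),
        "n_slides": len(profiles),
        "n_matched_pairs": int(len(pairs)),
        "n_regions": len(region_rows),
        "outputs": sorted(p.name for p in outdir.iterdir() if p.is_file()),
    }
    (outdir / "run.json").write_text(json.dumps(record, indent=1))
    return record
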