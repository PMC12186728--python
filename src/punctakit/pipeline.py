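"""Batch orchestration: segment -> measure -> dynamics -> coloc -> texture.

``run_pipeline`` takes an :class:`AnalysisConfig` and a list of scenes
(paths or in-memory :class:`Scene` objects) tagged with group labels, runs
every analysis stage that the scene supports (dynamics needs >= 3 frames,
colocalization needs an "mrna" channel), and returns tidy per-punctum and
per-nucleus tables.  ``compare_groups`` runs the two-sided unpaired
Student t-test (2 groups) or one-way ANOVA (> 2 groups) on a per-nucleus
metric.  No multiple-testing correction is applied by default; a
Benjamini-Hochberg helper is provided for batched comparisons.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .config import AnalysisConfig
from .coloc_texture import (
    compartment_ratio,
    estimate_background,
    glcm_texture,
    manders_pearson,
    texture_to_frame,
)
from .dynamics import dynamics_to_frame, overlay_dynamics
from .io import Scene, read_scene, write_results
from .morpho import (
    measure_puncta,
    puncta_to_frame,
    summarize_nucleus,
)
from .segment import dual_threshold_profile, puncta_mask, segment_nuclei, segment_puncta

logger = logging.getLogger(__name__)

SceneInput = Union[Scene, str, Path]


@dataclass
class ResultBundle:
    puncta: pd.DataFrame
    nuclei: pd.DataFrame
    dynamics: pd.DataFrame
    coloc: pd.DataFrame
    texture: pd.DataFrame
    manifest: dict = field(default_factory=dict)

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "puncta": self.puncta,
            "nuclei": self.nuclei,
            "dynamics": self.dynamics,
            "coloc": self.coloc,
            "texture": self.texture,
        }


@dataclass
class GroupComparison:
    metric: str
    groups: list[str]
    means: list[float]
    sds: list[float]
    ns: list[int]
    test: Optional[str]
    statistic: Optional[float]
    p_value: Optional[float]


def _analyze_scene(
    scene: Scene, config: AnalysisConfig, scene_id: str, group: str
) -> dict[str, pd.DataFrame]:
    ps = scene.pixel_size_um
    rois = segment_nuclei(scene, config.nuclei)
    kept = [r for r in rois if not (config.nuclei.exclude_border and r.touches_border)]

    out: dict[str, pd.DataFrame] = {}
    tag = {"scene": scene_id, "group": group}

    labels, stubs = segment_puncta(scene, kept, config.aggregate, threshold="low")
    records = measure_puncta(labels, scene.channel("aggregate"), ps, assignments=stubs)
    punc_df = puncta_to_frame(records).assign(**tag)
    out["puncta"] = punc_df

    both_thresholds = (
        config.aggregate.threshold_low is not None
        and config.aggregate.threshold_high is not None
    )
    profile = (
        dual_threshold_profile(scene, kept, config.aggregate)
        if both_thresholds
        else pd.DataFrame(columns=["nucleus_id", "bulk_mfi_low", "puncta_mfi_high", "aggregation_index"])
    )
    if both_thresholds:
        _, stubs_high = segment_puncta(scene, kept, config.aggregate, threshold="high")
        high_counts = (
            stubs_high[~stubs_high["extranuclear"]].groupby("nucleus_id").size()
            if len(stubs_high)
            else pd.Series(dtype=int)
        )
    else:
        high_counts = pd.Series(dtype=int)

    nuc_rows = []
    for roi in kept:
        mine = [p for p in records if p.nucleus_id == roi.nucleus_id]
        prof_rows = profile[profile["nucleus_id"] == roi.nucleus_id]
        prof = prof_rows.iloc[0].to_dict() if len(prof_rows) else None
        summary = summarize_nucleus(
            mine, profile=prof, rules=config.classifier, nucleus_id=roi.nucleus_id
        )
        nuc_rows.append(
            {
                "nucleus_id": roi.nucleus_id,
                "nucleus_area_um2": roi.area_um2,
                "puncta_count": summary.puncta_count,
                "puncta_count_high": int(high_counts.get(roi.nucleus_id, 0)),
                "mean_area": summary.mean_area,
                "sd_area": summary.sd_area,
                "mean_circularity": summary.mean_circularity,
                "sd_circularity": summary.sd_circularity,
                "mean_mfi": summary.mean_mfi,
                "bulk_mfi_low": None if prof is None else prof.get("bulk_mfi_low"),
                "puncta_mfi_high": None if prof is None else prof.get("puncta_mfi_high"),
                "aggregation_index": summary.aggregation_index,
                "morphology_class": summary.morphology_class,
            }
        )
    out["nuclei"] = pd.DataFrame(nuc_rows).assign(**tag) if nuc_rows else pd.DataFrame()

    # dynamics (needs a time-lapse)
    if scene.n_frames >= 3 and scene.frame_interval_s:
        times = config.dynamics_times_s
        max_t = (scene.n_frames - 1) * scene.frame_interval_s
        if max(times) > max_t:
            times = (0.0, max_t / 2, max_t)
            logger.info(
                "scene %s: dynamics times %s exceed stack length; using %s",
                scene_id,
                config.dynamics_times_s,
                times,
            )
        dyn = overlay_dynamics(
            scene, kept, config.aggregate, times_s=times, colored=config.dynamics_colored
        )
        out["dynamics"] = dynamics_to_frame(dyn).assign(**tag)
    else:
        out["dynamics"] = pd.DataFrame()

    # colocalization + compartment ratio (needs an mrna channel)
    if scene.has_channel("mrna"):
        mrna = scene.channel("mrna")
        agg_mask = labels > 0
        thr_mrna = config.mrna.threshold_low
        mrna_mask = (
            puncta_mask(mrna, config.mrna, ps, thr_mrna)
            if thr_mrna is not None
            else np.zeros_like(agg_mask)
        )
        bg_a = estimate_background(scene.channel("aggregate"), kept)
        bg_b = estimate_background(mrna, kept)
        coloc_rows = []
        for roi in kept:
            res = manders_pearson(
                scene.channel("aggregate"),
                mrna,
                agg_mask,
                mrna_mask,
                roi,
                ps,
                background_a=bg_a,
                background_b=bg_b,
            )
            comp = compartment_ratio(mrna, roi)
            row = {
                "nucleus_id": roi.nucleus_id,
                "m1": res.m1,
                "m2": res.m2,
                "pearson_r": res.pearson_r,
                "overlap_area_um2": res.overlap_area_um2,
                "mrna_nuclear_mfi": comp.nuclear_mfi,
                "mrna_perinuclear_mfi": comp.perinuclear_mfi,
                "mrna_log2_nc_ratio": comp.log2_ratio,
            }
            coloc_rows.append(row)
        out["coloc"] = pd.DataFrame(coloc_rows).assign(**tag) if coloc_rows else pd.DataFrame()
    else:
        out["coloc"] = pd.DataFrame()

    # texture of the configured channel inside each nucleus
    tex_rows = []
    tex_channel = config.texture.channel
    if scene.has_channel(tex_channel):
        img = scene.channel(tex_channel)
        for roi in kept:
            try:
                res = glcm_texture(
                    img,
                    roi,
                    offset=config.texture.offset,
                    n_levels=config.texture.n_levels,
                    average_offsets=config.texture.average_offsets,
                    log_base=config.texture.log_base,
                )
            except ValueError:
                continue
            tex_rows.append(res)
    out["texture"] = (
        texture_to_frame(tex_rows).assign(**tag) if tex_rows else pd.DataFrame()
    )
    return out


def run_pipeline(
    config: AnalysisConfig,
    scenes: Sequence[tuple[SceneInput, str]],
    out_dir: Optional[str | Path] = None,
) -> ResultBundle:
    """Run every analysis stage over a batch of (scene, group) pairs.

    Deterministic given inputs and config.  When ``out_dir`` is given the
    tidy tables and a run manifest (config hash, version, applied
    thresholds) are written there as CSV/JSON.
    """
    collected: dict[str, list[pd.DataFrame]] = {
        k: [] for k in ("puncta", "nuclei", "dynamics", "coloc", "texture")
    }
    errors = []
    for i, (item, group) in enumerate(scenes):
        scene = item if isinstance(item, Scene) else read_scene(item, config)
        scene_id = scene.name or f"scene_{i:03d}"
        try:
            tables = _analyze_scene(scene, config, scene_id, group)
        except Exception as exc:  # collect per-scene failures, then abort
            errors.append(f"{scene_id}: {exc}")
            continue
        for key, df in tables.items():
            if len(df):
                collected[key].append(df)
    if errors:
        raise RuntimeError("pipeline failed on scenes:\n" + "\n".join(errors))

    def _concat(key: str) -> pd.DataFrame:
        frames = collected[key]
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()

    bundle = ResultBundle(
        puncta=_concat("puncta"),
        nuclei=_concat("nuclei"),
        dynamics=_concat("dynamics"),
        coloc=_concat("coloc"),
        texture=_concat("texture"),
        manifest={
            "software": f"punctakit {__version__}",
            "config_hash": config.content_hash(),
            "seed": config.seed,
            "n_scenes": len(scenes),
            "thresholds": {
                "aggregate_low": config.aggregate.threshold_low,
                "aggregate_high": config.aggregate.threshold_high,
                "mrna_low": config.mrna.threshold_low,
            },
        },
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        write_results(bundle.tables(), out_dir)
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(bundle.manifest, fh, indent=2)
    return bundle


def _per_unit_values(
    bundle_or_df: Union[ResultBundle, pd.DataFrame], metric: str, unit: str
) -> pd.DataFrame:
    if isinstance(bundle_or_df, ResultBundle):
        for table in bundle_or_df.tables().values():
            if metric in table.columns:
                df = table
                break
        else:
            raise KeyError(f"metric {metric!r} not found in any result table")
    else:
        df = bundle_or_df
        if metric not in df.columns:
            raise KeyError(f"metric {metric!r} not in data frame")
    df = df[["group", metric] + (["scene"] if "scene" in df.columns else [])].dropna(
        subset=[metric]
    )
    if unit == "scene" and "scene" in df.columns:
        df = df.groupby(["group", "scene"], as_index=False)[metric].mean()
    return df


def compare_groups(
    bundle_or_df: Union[ResultBundle, pd.DataFrame],
    metric: str,
    test: str = "auto",
    unit: str = "nucleus",
) -> GroupComparison:
    """Compare a per-nucleus (or per-scene) metric across groups.

    Two groups: two-sided unpaired Student t-test; more: one-way ANOVA.
    Descriptives are always reported; the test is null when any group has
    fewer than 2 values.
    """
    df = _per_unit_values(bundle_or_df, metric, unit)
    names = sorted(df["group"].unique())
    samples = [df.loc[df["group"] == g, metric].to_numpy(dtype=float) for g in names]
    means = [float(np.mean(s)) if len(s) else float("nan") for s in samples]
    sds = [float(np.std(s, ddof=1)) if len(s) > 1 else float("nan") for s in samples]
    ns = [int(len(s)) for s in samples]

    if len(names) < 2:
        raise ValueError("compare_groups needs at least 2 groups")
    if any(n < 2 for n in ns):
        return GroupComparison(metric, names, means, sds, ns, None, None, None)

    if test == "auto":
        test = "t_test" if len(names) == 2 else "anova"
    if test == "t_test":
        if len(names) != 2:
            raise ValueError("t_test requires exactly 2 groups")
        res = stats.ttest_ind(samples[0], samples[1], equal_var=True)
        statistic, p = float(res.statistic), float(res.pvalue)
    elif test == "anova":
        res = stats.f_oneway(*samples)
        statistic, p = float(res.statistic), float(res.pvalue)
    else:
        raise ValueError(f"unknown test {test!r}")
    return GroupComparison(metric, names, means, sds, ns, test, statistic, p)


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH-adjusted p-values (off by default in reporting; opt-in helper)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(list(p_values), method="fdr_bh")[1]
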