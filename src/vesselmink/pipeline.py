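"""End-to-end orchestration: z-stack → features, and cohorts → statistics.

``run_sample`` chains the two analysis stages (tubular-model conversion, then
Minkowski quantification) deterministically, writing every intermediate with a
JSON provenance sidecar.  ``run_cohort`` maps ``run_sample`` over a manifest,
assembles the cohort feature table and runs the statistics layer; failed
samples are logged and excluded with a count, mirroring the quality triage
any real acquisition pipeline needs.
"""

from __future__ import annotations

import traceback
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core_io import (
    FeatureVector,
    SampleTable,
    ZStack,
    get_logger,
    read_zstack,
    stage_timer,
    write_feature_table,
    write_sidecar,
    write_volume,
)
from .cohort_stats import anova_pairwise, age_groups, bootstrap_stepwise, pca, zscore
from .segmentation import FilterParams, segment
from .signatures import default_radii, extract_features, signature
from .thickness import local_thickness, mean_calibre_radius, thickness_stats

__all__ = ["run_sample", "run_cohort", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and sample id."""

    def __init__(self, stage: str, sample_id: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed for sample {sample_id!r}: {cause}")
        self.stage = stage
        self.sample_id = sample_id
        self.cause = cause


def _cfg_filter_params(config: dict) -> FilterParams:
    keys = FilterParams.__dataclass_fields__.keys()
    kwargs = {k: config[k] for k in keys if k in config}
    if "scales" in kwargs and kwargs["scales"] is not None:
        kwargs["scales"] = tuple(kwargs["scales"])
    return FilterParams(**kwargs)


def run_sample(stack: ZStack, config: dict | None = None,
               out_dir=None, sample_id: str = "sample") -> FeatureVector:
    """Full single-sample chain: segment → thickness → signature → features.

    ``config`` keys: any :class:`FilterParams` field, plus ``radii`` (explicit
    dilation grid) or ``radius_cap``.  With ``out_dir`` set, the mask,
    thickness map, signature CSV and feature CSV are written, each with a JSON
    provenance sidecar (parameters, package version).
    """
    config = dict(config or {})
    log = get_logger()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    params = _cfg_filter_params(config)

    def _stage(name, fn, *args, **kwargs):
        try:
            with stage_timer(f"{sample_id}:{name}"):
                return fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineError(name, sample_id, exc) from exc

    mask = _stage("segmentation", segment, stack, params)
    if not mask.occupancy.any():
        raise PipelineError("segmentation", sample_id,
                            RuntimeError("empty segmentation"))
    tmap = _stage("thickness", local_thickness, mask)
    stats = thickness_stats(tmap)
    if "radii" in config:
        radii = np.asarray(config["radii"], dtype=np.float64)
    else:
        radii = default_radii(mean_calibre_radius(tmap),
                              cap=int(config.get("radius_cap", 25)))
    sig = _stage("signature", signature, mask, radii)
    features = _stage("features", extract_features, sig)

    if out is not None:
        prov = {
            "version": __version__,
            "sample_id": sample_id,
            "filter_params": asdict(params),
            "radii": radii,
            "thickness_stats": stats,
            "segmentation_meta": {k: v for k, v in mask.meta.items()},
        }
        write_volume(mask, out / f"{sample_id}_mask.tif")
        write_sidecar(out / f"{sample_id}_mask.tif", prov)
        write_volume(tmap, out / f"{sample_id}_thickness.tif")
        write_sidecar(out / f"{sample_id}_thickness.tif", prov)
        sig.to_frame().to_csv(out / f"{sample_id}_signature.csv", index=False)
        features.as_series().to_frame("value").to_csv(out / f"{sample_id}_features.csv", index_label="feature")
    log.info("sample=%s features computed (%d radii)", sample_id, len(radii))
    return features


def run_cohort(manifest, config: dict | None = None, out_dir=None,
               seed: int = 0):
    """Run a whole cohort and its statistics.

    ``manifest`` is a list of ``(sample_id, stack_or_path, age)`` triples or a
    DataFrame with columns sample_id, path, age.  Individual sample failures
    are logged and excluded (reported in the summary); the run fails only if
    every sample fails.  Statistics stages are controlled by config flags
    ``pca``, ``anova``, ``stepwise`` (all on by default) with ``n_boot``,
    ``n_repeats``, ``p_enter``, ``p_remove``, ``min_age``, ``model_size_filter``.

    Returns ``(SampleTable, report_dict)``.
    """
    config = dict(config or {})
    log = get_logger()
    if isinstance(manifest, pd.DataFrame):
        manifest = [(r["sample_id"], r["path"], float(r["age"]))
                    for _, r in manifest.iterrows()]
    if not manifest:
        raise ValueError("empty manifest")
    ids, fvs, ages, failures = [], [], [], []
    for sample_id, item, age in manifest:
        try:
            stack = item if isinstance(item, ZStack) else read_zstack(item)
            fv = run_sample(stack, config, out_dir=out_dir, sample_id=str(sample_id))
            ids.append(str(sample_id))
            fvs.append(fv)
            ages.append(float(age))
        except Exception as exc:
            log.warning("sample %s excluded: %s", sample_id, exc)
            failures.append({"sample_id": str(sample_id), "error": str(exc),
                             "trace": traceback.format_exc(limit=2)})
    if not ids:
        raise RuntimeError(f"all {len(manifest)} samples failed")
    table = SampleTable.from_rows(ids, fvs, ages)
    report: dict = {
        "version": __version__,
        "n_samples": len(ids),
        "n_excluded": len(failures),
        "failures": failures,
        "seed": seed,
    }
    zt = None
    if config.get("pca", True) and len(table) >= 3:
        try:
            zt = zscore(table)
            res = pca(zt)
            report["pca"] = {
                "explained_variance_ratio": res.explained_variance_ratio.tolist(),
                "loadings_pc1": res.loadings["PC1"].to_dict(),
            }
        except ValueError as exc:
            report["pca"] = {"error": str(exc)}
    if config.get("anova", True):
        try:
            groups = age_groups(table.ages.to_numpy())
            aov = anova_pairwise(table, groups)
            sig = aov[aov["p_adj"] < 0.05]
            report["anova"] = {
                "n_tests": int(len(aov)),
                "n_significant": int(len(sig)),
                "significant": sig.to_dict("records"),
            }
        except ValueError as exc:
            report["anova"] = {"error": str(exc)}
    if config.get("stepwise", True):
        try:
            rep = bootstrap_stepwise(
                table,
                n_boot=int(config.get("n_boot", 3000)),
                n_repeats=int(config.get("n_repeats", 6)),
                model_size_filter=tuple(config.get("model_size_filter", (2, 4))),
                seed=seed,
                p_enter=float(config.get("p_enter", 0.05)),
                p_remove=float(config.get("p_remove", 0.1)),
                min_age=config.get("min_age", 40.0),
            )
            report["stepwise"] = rep.to_dict()
        except ValueError as exc:
            report["stepwise"] = {"error": str(exc)}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_feature_table(table, out / "cohort_features.csv")
        write_sidecar(out / "cohort_report", report)
    return table, report
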