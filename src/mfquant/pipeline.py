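"""Run configuration and the end-to-end pipeline.

One YAML-serializable config drives generate -> detect -> coloc ->
quantify -> stats. A single global seed fans out to per-stage child seeds
through a fixed scheme (``numpy`` generator seeded with the global seed),
so stages are individually rerunnable yet the whole run is deterministic:
identical config + seed produce byte-identical CSV outputs.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import __version__ as _version
from .core import CHAN_POST, CHAN_PRE, ParameterError
from .detect import DetectionParams, run_detection
from .coloc import shuffle_null
from .quantify import (
    percent_reduction,
    size_distribution,
    summaries_to_frame,
    summarize_mouse,
)
from .simulate import GroupSpec, NoiseSpec, make_cohort
from .stats import anova_two_way, ks_two_sample, mann_whitney
from .io import write_cluster_table, write_json, write_micrograph

logger = logging.getLogger("mfquant")


class GroupConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str
    n_mice: int = Field(ge=1)
    clusters_per_neuron_mean: float = Field(gt=0)
    puncta_per_cluster_mean: float = Field(ge=1, default=1.5)


class GeneratorConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    groups: list[GroupConfig] = Field(
        default_factory=lambda: [
            GroupConfig(name="ET", n_mice=5, clusters_per_neuron_mean=4.75),
            GroupConfig(name="CT", n_mice=7, clusters_per_neuron_mean=6.31,
                        puncta_per_cluster_mean=1.8),
        ]
    )
    image_shape: tuple[int, int] = (2000, 2000)
    panels_per_mouse: int = Field(ge=1, default=2)
    ca3_neurons_per_panel: tuple[int, int] = (8, 12)
    soma_radius_px: float = Field(gt=0, default=150.0)
    distractors_per_channel: int = Field(ge=0, default=50)
    noise_gaussian_sd: float = Field(ge=0, default=25.0)
    noise_baseline: float = Field(ge=0, default=100.0)
    noise_poisson: bool = False
    save_images: bool = False


class DetectionConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    threshold_post: int = Field(ge=0, le=65535, default=515)
    threshold_pre: int = Field(ge=0, le=65535, default=350)
    min_cluster_px: int = Field(ge=1, default=150)
    block_size: int = Field(ge=1, default=500)
    seed_stride: int = Field(ge=1, default=4)
    connectivity: int = Field(default=4)

    @field_validator("connectivity")
    @classmethod
    def _conn(cls, v: int) -> int:
        if v not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        return v

    def to_params(self) -> DetectionParams:
        return DetectionParams(**self.model_dump())


class ColocConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    max_lag: int = Field(ge=0, default=50)
    n_shuffles: int = Field(ge=1, default=200)
    mode: str = "shift"


class QuantifyConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    log_base: float = 10.0
    bins: int = Field(ge=1, default=30)
    punctum_area_px: float = Field(ge=1, default=200.0)


class RunConfig(BaseModel):
    """Full pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    seed: int = Field(ge=0, default=0)
    log_level: str = "INFO"
    generator: GeneratorConfig = Field(default_factory=GeneratorConfig)
    detection: DetectionConfig = Field(default_factory=DetectionConfig)
    coloc: ColocConfig = Field(default_factory=ColocConfig)
    quantify: QuantifyConfig = Field(default_factory=QuantifyConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=True)
        return path

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute all stages; write per-stage outputs and a manifest.

    Returns the manifest dict (also written as ``manifest.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.getLogger("mfquant").setLevel(config.log_level.upper())
    child = np.random.default_rng(config.seed).integers(0, 2**31, size=3)
    manifest: dict = {
        "package_version": _version,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }
    config.to_yaml(out / "config.yaml")

    # -- generate -----------------------------------------------------------
    stage = "generate"
    try:
        gen = config.generator
        cohort = make_cohort(
            [GroupSpec(**g.model_dump()) for g in gen.groups],
            panels_per_mouse=gen.panels_per_mouse,
            ca3_neurons_per_panel=tuple(gen.ca3_neurons_per_panel),
            image_shape=tuple(gen.image_shape),
            soma_radius_px=gen.soma_radius_px,
            distractors_per_channel=gen.distractors_per_channel,
            noise=NoiseSpec(
                gaussian_sd=gen.noise_gaussian_sd,
                baseline=gen.noise_baseline,
                poisson=gen.noise_poisson,
            ),
            seed=int(child[0]),
        )
        truth_rows = []
        for m in cohort:
            for p in m.panels:
                truth_rows.append(
                    {
                        "mouse_id": m.mouse_id,
                        "group": m.group,
                        "sex": m.sex,
                        "panel_id": p.panel_id,
                        "n_ca3_neurons": p.n_ca3_neurons,
                        "true_clusters": p.scene.n_true_clusters,
                    }
                )
                if gen.save_images:
                    write_micrograph(p.micrograph, out / f"{p.panel_id}.tif")
        pd.DataFrame(truth_rows).to_csv(out / "ground_truth.csv", index=False)
        manifest["stages"][stage] = {
            "n_mice": len(cohort),
            "n_panels": sum(len(m.panels) for m in cohort),
            "true_clusters_total": int(
                sum(r["true_clusters"] for r in truth_rows)
            ),
        }
    except Exception as e:  # noqa: BLE001
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e

    # -- detect -------------------------------------------------------------
    stage = "detect"
    try:
        params = config.detection.to_params()
        detected: dict[str, list] = {}
        n_detected = 0
        for m in cohort:
            tables = []
            for p in m.panels:
                t = run_detection(p.micrograph, params, image_id=p.panel_id)
                write_cluster_table(t, out / f"clusters_{p.panel_id}.csv")
                tables.append(t)
                n_detected += len(t)
            detected[m.mouse_id] = tables
        manifest["stages"][stage] = {"clusters_total": n_detected}
    except Exception as e:  # noqa: BLE001
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e

    # -- coloc (first panel, post vs pre) ------------------------------------
    stage = "coloc"
    try:
        first = cohort[0].panels[0].micrograph
        res = shuffle_null(
            first.channel(CHAN_POST),
            first.channel(CHAN_PRE),
            n_shuffles=config.coloc.n_shuffles,
            max_lag=config.coloc.max_lag,
            seed=int(child[1]),
            pair=(CHAN_POST, CHAN_PRE),
            mode=config.coloc.mode,
        )
        write_json(res.to_dict(), out / "xcorr.json")
        manifest["stages"][stage] = {
            "observed_peak": res.observed_peak,
            "p_value": res.p_value,
        }
    except Exception as e:  # noqa: BLE001
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e

    # -- quantify ------------------------------------------------------------
    stage = "quantify"
    try:
        summaries = []
        for m in cohort:
            summaries.append(
                summarize_mouse(
                    detected[m.mouse_id],
                    [p.n_ca3_neurons for p in m.panels],
                    mouse_id=m.mouse_id,
                    group=m.group,
                    sex=m.sex,
                )
            )
        sframe = summaries_to_frame(summaries)
        sframe.to_csv(out / "mouse_summary.csv", index=False)
        groups = [g.name for g in config.generator.groups]
        pooled = {}
        hist = {}
        for g in groups:
            tabs = [
                t
                for m in cohort
                if m.group == g
                for t in detected[m.mouse_id]
                if len(t)
            ]
            pooled[g] = np.concatenate([t.areas_px for t in tabs])
            dist = size_distribution(
                tabs,
                log_base=config.quantify.log_base,
                bins=config.quantify.bins,
                punctum_area_px=config.quantify.punctum_area_px,
            )
            hist[g] = {
                "bin_edges": dist.bin_edges.tolist(),
                "counts": dist.counts.tolist(),
                "log_base": dist.log_base,
                "punctum_line": dist.punctum_line,
            }
        write_json(hist, out / "size_histograms.json")
        manifest["stages"][stage] = {
            "group_mean_density": {
                g: float(sframe.loc[sframe.group == g, "clusters_per_neuron"].mean())
                for g in groups
            }
        }
    except Exception as e:  # noqa: BLE001
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e

    # -- stats ---------------------------------------------------------------
    stage = "stats"
    try:
        ga, gb = groups[0], groups[1]
        mw = mann_whitney(pooled[ga], pooled[gb])
        ks = ks_two_sample(pooled[ga], pooled[gb])
        try:
            an = anova_two_way(
                sframe.rename(columns={"clusters_per_neuron": "value"})
            )
        except ParameterError as err:  # e.g. single-mouse demo cohorts
            logger.warning("ANOVA skipped: %s", err)
            an = None
        mean_a = float(sframe.loc[sframe.group == ga, "clusters_per_neuron"].mean())
        mean_b = float(sframe.loc[sframe.group == gb, "clusters_per_neuron"].mean())
        report = {
            "mann_whitney_pooled_sizes": mw.to_dict(),
            "ks_pooled_sizes": ks.to_dict(),
            "anova_density": an.to_dict() if an is not None else None,
            "percent_reduction_density": percent_reduction(
                min(mean_a, mean_b), max(mean_a, mean_b)
            ),
            "group_means": {ga: mean_a, gb: mean_b},
        }
        write_json(report, out / "stats.json")
        manifest["stages"][stage] = {
            "anova_group_p": an.p_value if an is not None else None,
            "ks_p": ks.p_value,
        }
    except Exception as e:  # noqa: BLE001
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e

    write_json(manifest, out / "manifest.json")
    return manifest
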