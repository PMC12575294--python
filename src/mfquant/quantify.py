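"""Cluster-table aggregation: calibration, size distributions, densities.

Turns detected cluster tables into the measured quantities of interest:
areas in um^2, pooled log-size histograms, estimated puncta per cluster
(treating large clusters as aggregates of ~200-px elementary puncta), and
per-mouse cluster density normalized to the manually counted number of CA3
neurons, with panels summed before dividing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import ParameterError, PixelScale
from .detect import ClusterTable

logger = logging.getLogger("mfquant")

#: default elementary punctum size, px (~0.37 um^2 at the default scale)
PUNCTUM_AREA_PX = 200.0


def px_to_um2(area_px: float, scale: PixelScale) -> float:
    """Convert a pixel area to um^2 using the pixel calibration."""
    if area_px < 0:
        raise ParameterError("area_px must be >= 0")
    return float(area_px) * scale.pixel_area_um2


def puncta_per_cluster(
    area_px: float, punctum_area_px: float = PUNCTUM_AREA_PX
) -> int:
    """Estimated number of elementary puncta composing a cluster.

    ``max(1, round(area / punctum_area))`` with half rounded away from
    zero; a retained cluster is at least one punctum.
    """
    if punctum_area_px < 1:
        raise ParameterError("punctum_area_px must be >= 1")
    return max(1, math.floor(area_px / punctum_area_px + 0.5))


@dataclass
class SizeDistribution:
    """Pooled log-transformed cluster-size distribution."""

    areas_px: np.ndarray
    log_areas: np.ndarray
    bin_edges: np.ndarray
    counts: np.ndarray
    log_base: float
    punctum_area_px: float
    punctum_line: float  # log(punctum area): single-punctum reference

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left": self.bin_edges[:-1],
                "bin_right": self.bin_edges[1:],
                "count": self.counts,
            }
        )


def size_distribution(
    tables: Sequence[ClusterTable] | ClusterTable,
    log_base: float = 10.0,
    bins: int = 30,
    punctum_area_px: float = PUNCTUM_AREA_PX,
    bin_range: tuple[float, float] | None = None,
) -> SizeDistribution:
    """Pool cluster areas and histogram their logs.

    The histogram is over ``log_base``-logarithms of pixel areas; counts
    are invariant to the base (only edges rescale). The single-punctum
    reference line sits at ``log(punctum_area_px)``.
    """
    if isinstance(tables, ClusterTable):
        tables = [tables]
    areas = np.concatenate([t.areas_px for t in tables]) if tables else np.array([])
    if areas.size == 0:
        raise ParameterError("no clusters to pool")
    if log_base <= 0 or log_base == 1:
        raise ParameterError("log_base must be positive and != 1")
    log_areas = np.log(areas) / np.log(log_base)
    rng = None
    if bin_range is not None:
        rng = tuple(np.log(bin_range) / np.log(log_base))
    counts, edges = np.histogram(log_areas, bins=bins, range=rng)
    return SizeDistribution(
        areas_px=areas,
        log_areas=log_areas,
        bin_edges=edges,
        counts=counts,
        log_base=float(log_base),
        punctum_area_px=float(punctum_area_px),
        punctum_line=float(np.log(punctum_area_px) / np.log(log_base)),
    )


@dataclass
class PanelSummary:
    """Per-mouse (or per-panel) aggregate of detected clusters."""

    mouse_id: str
    group: str
    sex: str
    panel_id: str
    n_clusters: int
    n_ca3_neurons: int
    clusters_per_neuron: float
    median_area_px: float
    median_area_um2: float


def summarize_mouse(
    tables: Sequence[ClusterTable],
    n_ca3_neurons: Sequence[int],
    *,
    mouse_id: str,
    group: str = "",
    sex: str = "",
) -> PanelSummary:
    """Mouse-level summary across panels.

    Cluster counts and neuron counts are each summed over the mouse's
    panels before dividing, so the density is the ratio of totals (not the
    mean of per-panel ratios). Median cluster size is over the pooled
    clusters.
    """
    if len(tables) < 1 or len(tables) != len(n_ca3_neurons):
        raise ParameterError("need >= 1 panel with one neuron count each")
    if any(n < 1 for n in n_ca3_neurons):
        raise ParameterError("neuron counts must be >= 1 for normalization")
    n_clusters = sum(len(t) for t in tables)
    n_neurons = int(sum(n_ca3_neurons))
    areas = np.concatenate([t.areas_px for t in tables]) if n_clusters else np.array([])
    scale = tables[0].pixel_scale
    med_px = float(np.median(areas)) if areas.size else float("nan")
    return PanelSummary(
        mouse_id=mouse_id,
        group=group,
        sex=sex,
        panel_id="pooled",
        n_clusters=n_clusters,
        n_ca3_neurons=n_neurons,
        clusters_per_neuron=n_clusters / n_neurons,
        median_area_px=med_px,
        median_area_um2=px_to_um2(med_px, scale) if areas.size else float("nan"),
    )


def summaries_to_frame(summaries: Iterable[PanelSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mouse_id": s.mouse_id,
                "group": s.group,
                "sex": s.sex,
                "panel_id": s.panel_id,
                "n_clusters": s.n_clusters,
                "n_ca3_neurons": s.n_ca3_neurons,
                "clusters_per_neuron": s.clusters_per_neuron,
                "median_area_px": s.median_area_px,
                "median_area_um2": s.median_area_um2,
            }
            for s in summaries
        ]
    )


def percent_reduction(mean_a: float, mean_b: float) -> float:
    """Percent reduction of ``mean_a`` relative to reference ``mean_b``:
    ``100 * (1 - mean_a / mean_b)``."""
    if mean_b <= 0:
        raise ParameterError("reference mean must be positive")
    return 100.0 * (1.0 - mean_a / mean_b)
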