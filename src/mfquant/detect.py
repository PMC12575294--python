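"""Colocalized-cluster detection.

The detection core mirrors the original quantification procedure for large
tiled two-channel micrographs: each synaptic channel is thresholded
independently (strictly greater than the channel threshold), the binary
masks are combined with a pixel-wise AND, and connected clusters of
colocalized pixels are extracted by a flood fill seeded at every
``seed_stride``-th pixel of 500 x 500 blocks. Fills may cross block
boundaries, so a cluster straddling an edge is discovered once per block
that seeds it; duplicates are collapsed afterwards by the cluster's
canonical pixel (the member with the minimum row-major linear index).
Clusters smaller than ``min_cluster_px`` are then removed.

Block results are merge-order independent: the final cluster set does not
depend on block traversal order or on the block size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import (
    CHAN_POST,
    CHAN_PRE,
    UINT16_MAX,
    ChannelError,
    Micrograph,
    ParameterError,
    PixelScale,
)

logger = logging.getLogger("mfquant")

_OFFSETS_4 = ((-1, 0), (1, 0), (0, -1), (0, 1))
_OFFSETS_8 = _OFFSETS_4 + ((-1, -1), (-1, 1), (1, -1), (1, 1))


@dataclass(frozen=True)
class DetectionParams:
    """Tunable parameters of the detection core.

    Defaults are the values used for the 16-bit tiled panels the pipeline
    was built for: intensity thresholds 515 (postsynaptic, PSD-95-like) and
    350 (presynaptic, synaptotagmin-like), a 150-px minimum cluster size,
    500 x 500 processing blocks with flood-fill seeds at every 4th pixel,
    and 4-connectivity.
    """

    threshold_post: int = 515
    threshold_pre: int = 350
    min_cluster_px: int = 150
    block_size: int = 500
    seed_stride: int = 4
    connectivity: int = 4

    def __post_init__(self) -> None:
        for name in ("threshold_post", "threshold_pre"):
            t = getattr(self, name)
            if not (0 <= t <= UINT16_MAX):
                raise ParameterError(f"{name}={t} outside [0, {UINT16_MAX}]")
        if self.min_cluster_px < 1:
            raise ParameterError("min_cluster_px must be >= 1")
        if self.block_size < 1:
            raise ParameterError("block_size must be >= 1")
        if self.seed_stride < 1:
            raise ParameterError("seed_stride must be >= 1")
        if self.connectivity not in (4, 8):
            raise ParameterError("connectivity must be 4 or 8")


@dataclass
class Cluster:
    """One connected set of colocalized pixels."""

    id: int
    pixels: np.ndarray  # (n, 2) int array of (row, col)
    area_px: int
    area_um2: float
    centroid: tuple[float, float]
    canonical_pixel: tuple[int, int]
    source_blocks: frozenset[int]


@dataclass
class ClusterTable:
    """Detected clusters plus the parameters and provenance of the run.

    ``n_unassigned_px`` counts mask pixels not reached by any flood-fill
    seed (always 0 at stride 1); it is reported so users can audit
    potential misses of the strided seeding.
    """

    clusters: list[Cluster]
    params: DetectionParams
    image_id: str = ""
    pixel_scale: PixelScale = field(default_factory=PixelScale)
    image_shape: tuple[int, int] | None = None
    n_unassigned_px: int = 0

    def __len__(self) -> int:
        return len(self.clusters)

    @property
    def areas_px(self) -> np.ndarray:
        return np.array([c.area_px for c in self.clusters], dtype=int)

    @property
    def total_area_px(self) -> int:
        return int(self.areas_px.sum()) if self.clusters else 0

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "id": c.id,
                "area_px": c.area_px,
                "area_um2": c.area_um2,
                "centroid_row": c.centroid[0],
                "centroid_col": c.centroid[1],
                "canonical_row": c.canonical_pixel[0],
                "canonical_col": c.canonical_pixel[1],
                "n_source_blocks": len(c.source_blocks),
            }
            for c in self.clusters
        ]
        cols = [
            "id",
            "area_px",
            "area_um2",
            "centroid_row",
            "centroid_col",
            "canonical_row",
            "canonical_col",
            "n_source_blocks",
        ]
        return pd.DataFrame(rows, columns=cols)

    def label_image(self) -> np.ndarray:
        """Labeled mask (0 = background, cluster id elsewhere) for QC."""
        if self.image_shape is None:
            raise ParameterError("image_shape unknown; cannot rasterize")
        lab = np.zeros(self.image_shape, dtype=np.uint32)
        for c in self.clusters:
            lab[c.pixels[:, 0], c.pixels[:, 1]] = c.id
        return lab


# ---------------------------------------------------------------------------
# masking


def threshold_channel(channel: np.ndarray, threshold: float) -> np.ndarray:
    """Binary mask of pixels strictly above ``threshold``.

    The comparison is strict: a pixel exactly at the threshold is excluded.
    """
    channel = np.asarray(channel)
    if channel.ndim != 2:
        raise ParameterError("channel must be a 2D array")
    return channel > threshold


def and_mask(mask_a: np.ndarray, mask_b: np.ndarray) -> np.ndarray:
    """Pixel-wise AND of two equal-shape binary masks."""
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    if mask_a.shape != mask_b.shape:
        raise ParameterError(
            f"mask shapes differ: {mask_a.shape} vs {mask_b.shape}"
        )
    return mask_a & mask_b


# ---------------------------------------------------------------------------
# block flood fill


def _flood(
    flat_mask: np.ndarray,
    visited: np.ndarray,
    block_id: int,
    start: int,
    width: int,
    height: int,
    offsets: tuple[tuple[int, int], ...],
) -> np.ndarray:
    """Flood fill on the full image from one seed (linear index).

    Marks visited pixels with ``block_id`` so later seeds from the same
    block cannot rediscover the cluster; returns the member linear indices.
    """
    visited[start] = block_id
    stack = [start]
    members = [start]
    while stack:
        idx = stack.pop()
        r, c = divmod(idx, width)
        for dr, dc in offsets:
            rr = r + dr
            cc = c + dc
            if 0 <= rr < height and 0 <= cc < width:
                j = rr * width + cc
                if flat_mask[j] and visited[j] != block_id:
                    visited[j] = block_id
                    stack.append(j)
                    members.append(j)
    return np.asarray(members, dtype=np.int64)


def _make_cluster(
    cid: int,
    members: np.ndarray,
    width: int,
    pixel_scale: PixelScale,
    block_id: int,
) -> Cluster:
    rows, cols = np.divmod(members, width)
    canon = int(members.min())
    return Cluster(
        id=cid,
        pixels=np.column_stack([rows, cols]).astype(np.int64),
        area_px=int(members.size),
        area_um2=float(members.size * pixel_scale.pixel_area_um2),
        centroid=(float(rows.mean()), float(cols.mean())),
        canonical_pixel=(canon // width, canon % width),
        source_blocks=frozenset({block_id}),
    )


def detect_clusters(
    mask: np.ndarray,
    params: DetectionParams | None = None,
    *,
    pixel_scale: PixelScale | None = None,
    image_id: str = "",
    block_order: Sequence[int] | None = None,
) -> ClusterTable:
    """Extract connected clusters from a binary mask, block by block.

    The image is tiled into ``block_size`` x ``block_size`` blocks. Within
    each block, seed candidates are every ``seed_stride``-th pixel of the
    block in row-major linear order; each true, not-yet-visited seed starts
    a flood fill over the *full* image (fills cross block boundaries).
    Visited state is per block, so a cluster spanning several blocks is
    reported once per seeding block; run :func:`dedup_clusters` to collapse
    these duplicates. ``block_order`` permutes block traversal (the deduped
    result is invariant to it).

    Returns the raw, pre-dedup, pre-filter table.
    """
    params = params or DetectionParams()
    pixel_scale = pixel_scale or PixelScale()
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2 or mask.size == 0:
        raise ParameterError("mask must be a non-empty 2D array")
    height, width = mask.shape
    flat = mask.ravel()
    # visited[i] = id of the last block whose fill covered pixel i
    visited = np.full(mask.size, -1, dtype=np.int64)
    offsets = _OFFSETS_4 if params.connectivity == 4 else _OFFSETS_8

    bs = params.block_size
    n_brow = -(-height // bs)
    n_bcol = -(-width // bs)
    n_blocks = n_brow * n_bcol
    order = range(n_blocks) if block_order is None else list(block_order)
    if block_order is not None and sorted(order) != list(range(n_blocks)):
        raise ParameterError("block_order must be a permutation of all blocks")

    clusters: list[Cluster] = []
    cid = 0
    covered = np.zeros(mask.size, dtype=bool)  # any-block coverage, for audit
    for b in order:
        br, bc = divmod(b, n_bcol)
        r0, c0 = br * bs, bc * bs
        bh = min(bs, height - r0)
        bw = min(bs, width - c0)
        # every seed_stride-th pixel of the block in row-major linear order
        lin = np.arange(0, bh * bw, params.seed_stride)
        rows = r0 + lin // bw
        cols = c0 + lin % bw
        seeds = rows * width + cols
        seeds = seeds[flat[seeds]]
        for s in seeds:
            if visited[s] == b:
                continue
            members = _flood(flat, visited, b, int(s), width, height, offsets)
            cid += 1
            clusters.append(_make_cluster(cid, members, width, pixel_scale, b))
            covered[members] = True

    n_unassigned = int(flat.sum() - covered.sum())
    logger.debug(
        "detect_clusters: %d raw clusters, %d unassigned mask px",
        len(clusters),
        n_unassigned,
    )
    return ClusterTable(
        clusters=clusters,
        params=params,
        image_id=image_id,
        pixel_scale=pixel_scale,
        image_shape=(height, width),
        n_unassigned_px=n_unassigned,
    )


def dedup_clusters(table: ClusterTable) -> ClusterTable:
    """Collapse duplicate detections of the same cluster.

    Two records are the same cluster iff they share a canonical pixel (the
    member with minimum row-major linear index), which is independent of
    which block's seed discovered them. Output ids are reassigned in
    canonical-pixel raster order, making the table independent of block
    traversal order.
    """
    by_canon: dict[tuple[int, int], Cluster] = {}
    for c in table.clusters:
        prev = by_canon.get(c.canonical_pixel)
        if prev is None:
            by_canon[c.canonical_pixel] = c
        else:
            by_canon[c.canonical_pixel] = replace(
                prev, source_blocks=prev.source_blocks | c.source_blocks
            )
    merged = [by_canon[k] for k in sorted(by_canon)]
    merged = [replace(c, id=i + 1) for i, c in enumerate(merged)]
    return replace(table, clusters=merged)


def filter_small(
    table: ClusterTable, min_cluster_px: int | None = None
) -> ClusterTable:
    """Remove clusters strictly smaller than ``min_cluster_px``.

    A cluster exactly at the minimum is kept.
    """
    if min_cluster_px is None:
        min_cluster_px = table.params.min_cluster_px
    if min_cluster_px < 1:
        raise ParameterError("min_cluster_px must be >= 1")
    kept = [c for c in table.clusters if c.area_px >= min_cluster_px]
    return replace(table, clusters=kept)


def run_detection(
    image: Micrograph,
    params: DetectionParams | None = None,
    *,
    roi: np.ndarray | None = None,
    channel_post: str = CHAN_POST,
    channel_pre: str = CHAN_PRE,
    image_id: str = "",
) -> ClusterTable:
    """Full detection pipeline on a two-channel micrograph.

    threshold both synaptic channels -> pixel-wise AND -> block flood fill
    -> boundary dedup -> minimum-size filter. ``roi`` optionally restricts
    analysis to a region-of-interest mask (default: whole image).
    """
    params = params or DetectionParams()
    for name in (channel_post, channel_pre):
        if not image.has_channel(name):
            raise ChannelError(
                f"micrograph lacks required channel {name!r} "
                f"(has {image.channel_names})"
            )
    m_post = threshold_channel(image.channel(channel_post), params.threshold_post)
    m_pre = threshold_channel(image.channel(channel_pre), params.threshold_pre)
    coloc = and_mask(m_post, m_pre)
    if roi is not None:
        coloc = and_mask(coloc, roi)
    raw = detect_clusters(
        coloc, params, pixel_scale=image.pixel_scale, image_id=image_id
    )
    deduped = dedup_clusters(raw)
    final = filter_small(deduped, params.min_cluster_px)
    logger.info(
        "%s: AND-mask px=%d, raw=%d, deduped=%d, final=%d (unassigned px=%d)",
        image_id or "image",
        int(coloc.sum()),
        len(raw),
        len(deduped),
        len(final),
        raw.n_unassigned_px,
    )
    return final
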