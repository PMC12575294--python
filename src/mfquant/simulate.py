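"""Synthetic fluorescence micrographs with known ground truth.

Generates two-channel (optionally four-channel) 16-bit scenes that emulate
the statistical structure the detection pipeline assumes: dark circular
somata, colocalized synaptic clusters composed of one-to-several Gaussian
puncta concentrated in an annulus around soma perimeters, single-channel
distractor puncta, and additive background noise. Every scene retains its
ground truth (somata, clusters, puncta, per-cluster thresholded footprint),
so each downstream stage can be tested against known answers.

Punctum blobs are isotropic Gaussians whose radius is calibrated so the
above-threshold footprint matches a target pixel area (default 200 px,
the single-punctum size of ~0.37 um^2 at the default calibration).
"""

from __future__ import annotations

import logging
import math
from dataclasses import asdict, dataclass, field

import numpy as np

from .core import (
    CHAN_MF,
    CHAN_NUC,
    CHAN_POST,
    CHAN_PRE,
    DEFAULT_PIXEL_SCALE,
    UINT16_MAX,
    Micrograph,
    ParameterError,
    PixelScale,
)

logger = logging.getLogger("mfquant")

#: default group settings for cohorts: clusters per CA3 neuron
DENSITY_ET_LIKE = 4.75
DENSITY_CT_LIKE = 6.31


@dataclass(frozen=True)
class NoiseSpec:
    """Additive background model: baseline + Gaussian, optional shot noise.

    Defaults (baseline 100, sd 25 counts) keep the noise floor far below
    the default channel thresholds (515/350).
    """

    gaussian_sd: float = 25.0
    baseline: float = 100.0
    poisson: bool = False

    def __post_init__(self) -> None:
        if self.gaussian_sd < 0 or self.baseline < 0:
            raise ParameterError("noise parameters must be non-negative")


@dataclass
class Punctum:
    """One Gaussian blob; present in every channel listed in amplitude."""

    row: float
    col: float
    amplitude: dict[str, float]  # channel -> peak counts above baseline
    sigma: dict[str, float]  # channel -> Gaussian sigma, px


@dataclass
class ClusterTruth:
    """Ground truth for one generated colocalized cluster."""

    soma_index: int | None
    punctum_indices: list[int]
    center: tuple[float, float]
    footprint_px: int  # AND-mask area under ideal (noiseless) thresholding


@dataclass
class SynthScene:
    """Complete generative description of one synthetic micrograph."""

    image_shape: tuple[int, int]
    pixel_scale: PixelScale
    somata: list[tuple[float, float, float]]  # (row, col, radius px)
    clusters: list[ClusterTruth]
    puncta: list[Punctum]  # colocalized cluster puncta
    distractors: list[Punctum]  # single-channel puncta
    noise: NoiseSpec
    channels: tuple[str, ...]
    thresholds: dict[str, float]
    punctum_target_area_px: float
    seed: int
    n_skipped_clusters: int = 0

    @property
    def n_true_clusters(self) -> int:
        return len(self.clusters)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pixel_scale"] = {
            "microns_per_px_x": self.pixel_scale.microns_per_px_x,
            "microns_per_px_y": self.pixel_scale.microns_per_px_y,
        }
        return d


def footprint_radius(
    amplitude: float, threshold: float, target_area_px: float
) -> tuple[float, float]:
    """(radius, sigma) of a Gaussian blob whose strictly-above-threshold
    disc has area ``target_area_px``.

    Solves ``amplitude * exp(-r^2 / (2 sigma^2)) = threshold`` for the sigma
    that puts the crossing at ``r = sqrt(area / pi)``.
    """
    if amplitude <= threshold:
        raise ParameterError("punctum amplitude must exceed the threshold")
    r = math.sqrt(target_area_px / math.pi)
    sigma = r / math.sqrt(2.0 * math.log(amplitude / threshold))
    return r, sigma


def _too_close(
    pt: tuple[float, float], others: list[tuple[float, float, float]]
) -> bool:
    return any(
        (pt[0] - r) ** 2 + (pt[1] - c) ** 2 < d * d for r, c, d in others
    )


def make_scene(
    image_shape: tuple[int, int] = (2000, 2000),
    *,
    n_somata: int = 10,
    clusters_per_soma_mean: float = DENSITY_CT_LIKE,
    puncta_per_cluster_mean: float = 1.5,
    punctum_target_area_px: float = 200.0,
    soma_radius_px: float = 150.0,
    cluster_disc_radius_px: float | None = None,
    distractors_per_channel: int = 50,
    amplitude_post: float = 2500.0,
    amplitude_pre: float = 2000.0,
    thresholds: dict[str, float] | None = None,
    noise: NoiseSpec | None = None,
    channels: tuple[str, ...] = (CHAN_POST, CHAN_PRE),
    pixel_scale: PixelScale = DEFAULT_PIXEL_SCALE,
    seed: int = 0,
    max_tries: int = 200,
) -> SynthScene:
    """Draw a complete synthetic scene.

    Somata are placed by rejection sampling (non-overlapping bodies). Each
    soma receives a Poisson(``clusters_per_soma_mean``) number of clusters,
    each centred in a disc of radius ``cluster_disc_radius_px`` (default two
    punctum diameters) tangent to the soma perimeter. A cluster holds
    ``1 + Poisson(puncta_per_cluster_mean - 1)`` puncta placed so their
    above-threshold footprints form one connected component. Distractor
    puncta appear in a single channel only and are kept clear of clusters,
    so they never create colocalized signal. Cluster placements that cannot
    satisfy the non-overlap constraints after ``max_tries`` attempts are
    skipped (counted in ``n_skipped_clusters``).

    Identical parameters and seed yield a bit-identical scene.
    """
    rows, cols = image_shape
    if rows <= 0 or cols <= 0:
        raise ParameterError("image_shape must be positive")
    if n_somata < 0 or distractors_per_channel < 0:
        raise ParameterError("counts must be non-negative")
    if punctum_target_area_px < 1:
        raise ParameterError("punctum_target_area_px must be >= 1")
    if clusters_per_soma_mean < 0:
        raise ParameterError("clusters_per_soma_mean must be non-negative")
    if puncta_per_cluster_mean < 1:
        raise ParameterError("puncta_per_cluster_mean must be >= 1")
    noise = noise or NoiseSpec()
    thresholds = dict(thresholds or {CHAN_POST: 515.0, CHAN_PRE: 350.0})
    for ch in (CHAN_POST, CHAN_PRE):
        if ch not in thresholds:
            raise ParameterError(f"thresholds must include {ch!r}")
        if noise.baseline >= thresholds[ch]:
            raise ParameterError(
                "noise baseline must stay below the channel thresholds"
            )

    # blob calibration: the rendered image is blob + baseline (+ noise), so
    # the effective threshold for the blob alone is threshold - baseline
    amp = {CHAN_POST: amplitude_post, CHAN_PRE: amplitude_pre}
    if CHAN_MF in channels:
        amp[CHAN_MF] = amplitude_post
        thresholds.setdefault(CHAN_MF, thresholds[CHAN_POST])
    r_fp: dict[str, float] = {}
    sigma: dict[str, float] = {}
    for ch, a in amp.items():
        r_fp[ch], sigma[ch] = footprint_radius(
            a, thresholds[ch] - noise.baseline, punctum_target_area_px
        )
    r_max = max(r_fp.values())
    if cluster_disc_radius_px is None:
        cluster_disc_radius_px = 4.0 * math.sqrt(
            punctum_target_area_px / math.pi
        )  # two punctum diameters

    rng = np.random.default_rng(seed)

    # --- somata ------------------------------------------------------------
    somata: list[tuple[float, float, float]] = []
    margin = soma_radius_px + cluster_disc_radius_px + 4.0 * r_max
    for _ in range(n_somata):
        placed = False
        for _ in range(max_tries * 10):
            r = rng.uniform(margin, rows - margin) if rows > 2 * margin else rng.uniform(0, rows)
            c = rng.uniform(margin, cols - margin) if cols > 2 * margin else rng.uniform(0, cols)
            if not _too_close(
                (r, c), [(sr, sc, rad + soma_radius_px + 4) for sr, sc, rad in somata]
            ):
                somata.append((r, c, soma_radius_px))
                placed = True
                break
        if not placed:
            raise ParameterError(
                "could not place all somata; reduce n_somata or soma radius"
            )

    # --- clusters ----------------------------------------------------------
    # keep any two clusters' footprints disjoint so detection can recover
    # the true count exactly on noiseless renders
    clear_d = 2.0 * cluster_disc_radius_px + 4.0 * r_max + 6.0
    occupied: list[tuple[float, float, float]] = []  # (row, col, min distance)
    clusters: list[ClusterTruth] = []
    puncta: list[Punctum] = []
    n_skipped = 0
    edge = cluster_disc_radius_px + 4.0 * r_max
    # total count is Poisson(mean x somata); each cluster picks a random
    # soma and perimeter angle, retrying (soma included) on crowding so a
    # full perimeter does not silently deflate the realized density
    n_total = int(rng.poisson(clusters_per_soma_mean * n_somata)) if n_somata else 0
    for _ in range(n_total):
        ok = False
        for _ in range(max_tries):
            si = int(rng.integers(n_somata))
            sr, sc, srad = somata[si]
            ring = srad + cluster_disc_radius_px  # disc tangent to perimeter
            theta = rng.uniform(0.0, 2.0 * math.pi)
            cr = sr + ring * math.sin(theta)
            cc = sc + ring * math.cos(theta)
            if not (edge <= cr < rows - edge and edge <= cc < cols - edge):
                continue
            if not _too_close((cr, cc), occupied):
                ok = True
                break
        if not ok:
            n_skipped += 1
            continue
        occupied.append((cr, cc, clear_d))
        idxs = _place_cluster_puncta(
            rng,
            (cr, cc),
            cluster_disc_radius_px,
            puncta_per_cluster_mean,
            amp,
            sigma,
            min(r_fp.values()),
            puncta,
        )
        fp = _ideal_footprint(
            [puncta[i] for i in idxs], thresholds, noise.baseline
        )
        clusters.append(
            ClusterTruth(
                soma_index=si,
                punctum_indices=idxs,
                center=(cr, cc),
                footprint_px=fp,
            )
        )

    # --- distractors (single-channel) --------------------------------------
    distractors: list[Punctum] = []
    syn_channels = [ch for ch in (CHAN_POST, CHAN_PRE) if ch in channels]
    for ch in syn_channels:
        other_d = 2.0 * r_max + 6.0
        for _ in range(distractors_per_channel):
            for _ in range(max_tries):
                dr = rng.uniform(edge, rows - edge)
                dc = rng.uniform(edge, cols - edge)
                # clear of clusters and of opposite-channel distractors so no
                # accidental colocalization arises
                opp = [
                    (p.row, p.col, other_d)
                    for p in distractors
                    if ch not in p.amplitude
                ]
                if not _too_close((dr, dc), occupied + opp):
                    distractors.append(
                        Punctum(
                            row=dr,
                            col=dc,
                            amplitude={ch: amp[ch]},
                            sigma={ch: sigma[ch]},
                        )
                    )
                    break

    if n_skipped:
        logger.debug("make_scene: skipped %d crowded clusters", n_skipped)
    return SynthScene(
        image_shape=(rows, cols),
        pixel_scale=pixel_scale,
        somata=somata,
        clusters=clusters,
        puncta=puncta,
        distractors=distractors,
        noise=noise,
        channels=tuple(channels),
        thresholds=thresholds,
        punctum_target_area_px=punctum_target_area_px,
        seed=int(seed),
    n_skipped_clusters=n_skipped,
    )


def _place_cluster_puncta(
    rng: np.random.Generator,
    center: tuple[float, float],
    disc_radius: float,
    puncta_mean: float,
    amp: dict[str, float],
    sigma: dict[str, float],
    r_min: float,
    puncta: list[Punctum],
) -> list[int]:
    """Place 1 + Poisson(mean - 1) puncta with mutually-overlapping
    footprints inside the cluster disc; append to ``puncta``; return
    indices."""
    n_p = 1 + rng.poisson(puncta_mean - 1.0)
    coords: list[tuple[float, float]] = [center]
    step = 0.8 * r_min  # overlap guarantees a connected AND footprint
    for _ in range(n_p - 1):
        base = coords[rng.integers(len(coords))]
        for _ in range(50):
            theta = rng.uniform(0.0, 2.0 * math.pi)
            pr = base[0] + step * math.sin(theta)
            pc = base[1] + step * math.cos(theta)
            if (pr - center[0]) ** 2 + (pc - center[1]) ** 2 <= disc_radius**2:
                coords.append((pr, pc))
                break
        else:
            coords.append(base)  # stack on top: still connected
    idxs = []
    for pr, pc in coords:
        idxs.append(len(puncta))
        puncta.append(
            Punctum(row=pr, col=pc, amplitude=dict(amp), sigma=dict(sigma))
        )
    return idxs


def _render_blobs(
    acc: np.ndarray, blobs: list[Punctum], channel: str
) -> None:
    """Accumulate Gaussian blobs for one channel into a float image."""
    rows, cols = acc.shape
    for p in blobs:
        if channel not in p.amplitude:
            continue
        a = p.amplitude[channel]
        s = p.sigma[channel]
        ext = int(math.ceil(4.0 * s)) + 1
        r0 = max(0, int(p.row) - ext)
        r1 = min(rows, int(p.row) + ext + 1)
        c0 = max(0, int(p.col) - ext)
        c1 = min(cols, int(p.col) + ext + 1)
        if r0 >= r1 or c0 >= c1:
            continue
        yy = np.arange(r0, r1, dtype=float) - p.row
        xx = np.arange(c0, c1, dtype=float) - p.col
        g = a * np.exp(
            -(yy[:, None] ** 2 + xx[None, :] ** 2) / (2.0 * s * s)
        )
        acc[r0:r1, c0:c1] += g


def _ideal_footprint(
    members: list[Punctum], thresholds: dict[str, float], baseline: float
) -> int:
    """AND-mask pixel count of a cluster under noiseless thresholding."""
    smax = max(max(p.sigma.values()) for p in members)
    ext = int(math.ceil(4.0 * smax)) + 2
    r_lo = int(min(p.row for p in members)) - ext
    c_lo = int(min(p.col for p in members)) - ext
    r_hi = int(max(p.row for p in members)) + ext + 1
    c_hi = int(max(p.col for p in members)) + ext + 1
    shape = (r_hi - r_lo, c_hi - c_lo)
    mask = None
    for ch in (CHAN_POST, CHAN_PRE):
        # mirror the render exactly: float32 accumulation, baseline added,
        # counts rounded to integers before thresholding
        acc = np.zeros(shape, dtype=np.float32)
        shifted = [
            Punctum(p.row - r_lo, p.col - c_lo, p.amplitude, p.sigma)
            for p in members
        ]
        _render_blobs(acc, shifted, ch)
        acc += np.float32(baseline)
        m = np.rint(acc) > thresholds[ch]
        mask = m if mask is None else (mask & m)
    return int(mask.sum())


def render(scene: SynthScene) -> Micrograph:
    """Render a scene to a 16-bit multichannel micrograph.

    Colocalized puncta appear in both synaptic channels (and the
    mossy-fiber channel when present); distractors in one. Somata are
    rendered into the nuclear channel only, if requested. Noise: baseline +
    Gaussian(sd) per channel, optional Poisson resampling, clipped to
    16-bit. Deterministic for a given scene.
    """
    rows, cols = scene.image_shape
    planes = []
    rng = np.random.default_rng(np.random.SeedSequence([int(scene.seed), 7]))
    for ch in scene.channels:
        acc = np.zeros((rows, cols), dtype=np.float32)
        if ch == CHAN_NUC:
            _render_somata(acc, scene)
        else:
            _render_blobs(acc, scene.puncta, ch)
            _render_blobs(acc, scene.distractors, ch)
        acc += np.float32(scene.noise.baseline)
        if scene.noise.gaussian_sd > 0:
            noise = rng.standard_normal(acc.shape, dtype=np.float32)
            noise *= np.float32(scene.noise.gaussian_sd)
            acc += noise
        if scene.noise.poisson:
            np.clip(acc, 0.0, None, out=acc)
            acc = rng.poisson(acc).astype(np.float32)
        np.rint(acc, out=acc)
        np.clip(acc, 0, UINT16_MAX, out=acc)
        planes.append(acc.astype(np.uint16))
    return Micrograph(
        pixels=np.stack(planes),
        channel_names=scene.channels,
        pixel_scale=scene.pixel_scale,
    )


def _render_somata(acc: np.ndarray, scene: SynthScene) -> None:
    rows, cols = acc.shape
    for sr, sc, rad in scene.somata:
        r0 = max(0, int(sr - rad) - 1)
        r1 = min(rows, int(sr + rad) + 2)
        c0 = max(0, int(sc - rad) - 1)
        c1 = min(cols, int(sc + rad) + 2)
        yy = np.arange(r0, r1, dtype=float) - sr
        xx = np.arange(c0, c1, dtype=float) - sc
        inside = (yy[:, None] ** 2 + xx[None, :] ** 2) <= rad * rad
        acc[r0:r1, c0:c1][inside] += 3000.0


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class GroupSpec:
    """Per-group generator settings for a synthetic cohort."""

    name: str
    n_mice: int
    clusters_per_neuron_mean: float
    puncta_per_cluster_mean: float = 1.5

    def __post_init__(self) -> None:
        if self.n_mice < 1:
            raise ParameterError("n_mice must be >= 1")


@dataclass
class PanelRecord:
    panel_id: str
    micrograph: Micrograph
    scene: SynthScene
    n_ca3_neurons: int


@dataclass
class MouseRecord:
    mouse_id: str
    group: str
    sex: str
    panels: list[PanelRecord]


def make_cohort(
    group_specs: list[GroupSpec],
    *,
    panels_per_mouse: int = 2,
    ca3_neurons_per_panel: tuple[int, int] = (8, 12),
    image_shape: tuple[int, int] = (2000, 2000),
    soma_radius_px: float = 150.0,
    distractors_per_channel: int = 50,
    noise: NoiseSpec | None = None,
    seed: int = 0,
) -> list[MouseRecord]:
    """Generate a two-group cohort of synthetic mice for recovery tests.

    Each mouse gets ``panels_per_mouse`` panels; each panel's CA3-neuron
    count (= rendered somata) is drawn uniformly from
    ``ca3_neurons_per_panel`` (inclusive). Clusters per neuron follow the
    group's ``clusters_per_neuron_mean`` (Poisson per neuron). Sex
    alternates deterministically (M, F, M, ...) within each group so
    Group x Sex designs have no empty cells.
    """
    names = [g.name for g in group_specs]
    if len(set(names)) != len(names):
        raise ParameterError(f"overlapping group names: {names}")
    lo, hi = ca3_neurons_per_panel
    if lo < 1 or hi < lo:
        raise ParameterError("ca3_neurons_per_panel must be a valid range")
    rng = np.random.default_rng(seed)
    out: list[MouseRecord] = []
    for g in group_specs:
        for i in range(g.n_mice):
            mouse_id = f"{g.name}_m{i + 1:02d}"
            sex = "M" if i % 2 == 0 else "F"
            panels = []
            for p in range(panels_per_mouse):
                n_neu = int(rng.integers(lo, hi + 1))
                scene_seed = int(rng.integers(0, 2**31))
                scene = make_scene(
                    image_shape,
                    n_somata=n_neu,
                    clusters_per_soma_mean=g.clusters_per_neuron_mean,
                    puncta_per_cluster_mean=g.puncta_per_cluster_mean,
                    soma_radius_px=soma_radius_px,
                    distractors_per_channel=distractors_per_channel,
                    noise=noise,
                    seed=scene_seed,
                )
                panels.append(
                    PanelRecord(
                        panel_id=f"{mouse_id}_p{p + 1}",
                        micrograph=render(scene),
                        scene=scene,
                        n_ca3_neurons=n_neu,
                    )
                )
            out.append(
                MouseRecord(mouse_id=mouse_id, group=g.name, sex=sex, panels=panels)
            )
    return out
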