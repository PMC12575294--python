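"""TIFF / CSV / JSON readers and writers.

Images travel as single- or multi-page 16-bit grayscale TIFF (one page per
channel). Cluster tables are CSV with a units comment line; coordinates
are 0-based (row, col) and areas are reported in both px and um^2.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

from .core import Micrograph, ParameterError, PixelScale, ChannelError
from .detect import ClusterTable

logger = logging.getLogger("mfquant")


def write_micrograph(image: Micrograph, path: str | Path) -> Path:
    """Write all channels as pages of one 16-bit grayscale TIFF."""
    path = Path(path)
    tifffile.imwrite(path, image.pixels, photometric="minisblack")
    return path


def read_micrograph(
    path: str | Path | Sequence[str | Path],
    channel_map: Mapping[str, int] | Sequence[str],
    pixel_scale: PixelScale | None = None,
    *,
    strict: bool = False,
) -> Micrograph:
    """Read a multichannel micrograph from one multi-page TIFF or from one
    file per channel.

    ``channel_map`` maps channel names to page indices (dict) or lists the
    names in page/file order (sequence). Intensities are preserved
    bit-exactly for 16-bit input; other integer dtypes are converted with
    a warning, or rejected when ``strict``.
    """
    if isinstance(path, (str, Path)):
        stack = tifffile.imread(str(path))
        if stack.ndim == 2:
            stack = stack[None]
    else:
        stack = np.stack([tifffile.imread(str(p)) for p in path])
    if stack.ndim != 3:
        raise ParameterError(f"expected 2D pages, got array of shape {stack.shape}")
    if stack.dtype != np.uint16:
        if strict:
            raise ParameterError(
                f"non-16-bit input ({stack.dtype}) rejected in strict mode"
            )
        warnings.warn(
            f"converting {stack.dtype} input to uint16", stacklevel=2
        )
        stack = np.clip(stack, 0, 65535).astype(np.uint16)
    if isinstance(channel_map, Mapping):
        names = list(channel_map)
        idx = [channel_map[n] for n in names]
        if max(idx) >= stack.shape[0]:
            raise ChannelError(
                f"channel map refers to page {max(idx)} but file has "
                f"{stack.shape[0]} pages"
            )
        stack = stack[idx]
    else:
        names = list(channel_map)
        if len(names) != stack.shape[0]:
            raise ChannelError(
                f"{len(names)} channel names for {stack.shape[0]} pages"
            )
    return Micrograph(
        pixels=stack,
        channel_names=tuple(names),
        pixel_scale=pixel_scale or PixelScale(),
    )


_UNITS_COMMENT = (
    "# units: area_px in pixels, area_um2 in square microns; "
    "coordinates 0-based (row, col)\n"
)


def write_cluster_table(table: ClusterTable, path: str | Path) -> Path:
    """Cluster table as CSV with a header and a units comment line."""
    path = Path(path)
    df = table.to_dataframe()
    with open(path, "w") as fh:
        fh.write(_UNITS_COMMENT)
        df.to_csv(fh, index=False)
    return path


def read_cluster_table_frame(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_labeled_mask(table: ClusterTable, path: str | Path) -> Path:
    """Labeled cluster mask as a TIFF for visual QC."""
    path = Path(path)
    tifffile.imwrite(path, table.label_image(), photometric="minisblack")
    return path


def write_json(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
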