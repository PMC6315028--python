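"""Object-memory heatmaps, difference maps, normalized averages, profiles.

A memory map colors each (filtered) object's pixels with the proportion of
recalling participants who drew that object; background stays exactly 0.
Where objects overlap, the smallest-area object paints on top (foreground
priority — small objects nest inside large ones in labeled scenes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inventory import SceneInventory, minmax_scale, resample_nearest

logger = logging.getLogger(__name__)

__all__ = [
    "ObjectMap",
    "memory_map",
    "difference_map",
    "grand_average_map",
    "vertical_profile",
    "save_map_csv",
    "load_map_csv",
]

PROFILE_HEIGHT = 700  # rows in the common-resolution grid for averages


@dataclass
class ObjectMap:
    image_id: str  # or "grand"
    values: np.ndarray  # (height, width) float
    kind: str  # memory | difference | saliency | meaning | count | average

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]


def memory_map(
    inventory: SceneInventory, object_proportions: pd.DataFrame
) -> ObjectMap | None:
    """Per-pixel object recall-frequency map for one image.

    ``object_proportions`` comes from crowd.object_recall_proportions:
    rows (object_id, proportion, n_recallers). Pixels of each filtered
    object take its proportion; overlaps go to the smallest-area object;
    background is 0. Returns None (with a warning) if the image has zero
    recallers, since the proportion is then undefined.
    """
    props = object_proportions.set_index("object_id")
    if "n_recallers" in props.columns and (props["n_recallers"] == 0).all():
        logger.warning("image %s: no recallers; memory map undefined",
                       inventory.image.image_id)
        return None
    values = np.zeros((inventory.image.height, inventory.image.width), dtype=float)
    objs = [o for o in inventory.filtered_objects if o.object_id in props.index]
    # paint large first so the smallest-area object wins overlapping pixels
    objs.sort(key=lambda o: int(o.mask.sum()), reverse=True)
    for obj in objs:
        values[obj.mask] = float(props.loc[obj.object_id, "proportion"])
    return ObjectMap(inventory.image.image_id, values, "memory")


def difference_map(map_a: ObjectMap, map_b: ObjectMap) -> ObjectMap:
    """Pixel-wise a - b; positive where a's condition drew the object more."""
    if map_a.values.shape != map_b.values.shape:
        raise ValueError("maps must share resolution")
    return ObjectMap(map_a.image_id, map_a.values - map_b.values, "difference")


def grand_average_map(maps, count_map: np.ndarray) -> ObjectMap:
    """Across-image average map normalized by object coverage.

    Each per-image map is min-max scaled to [0, 1] and nearest-neighbor
    resampled to the count map's grid; the pixel-wise mean is divided by
    the (already [0, 1]-scaled) count map where coverage is nonzero, other
    pixels are set to 0 (no object can be recalled where none exists), and
    the result is min-max scaled.
    """
    maps = list(maps)
    if not maps:
        raise ValueError("empty map list")
    shape = count_map.shape
    acc = np.zeros(shape, dtype=float)
    for m in maps:
        v = minmax_scale(m.values)
        if v.shape != shape:
            v = resample_nearest(v, shape)
        acc += v
    mean = acc / len(maps)
    out = np.zeros(shape, dtype=float)
    nz = count_map > 0
    out[nz] = mean[nz] / count_map[nz]
    return ObjectMap("grand", minmax_scale(out), "average")


def vertical_profile(map_: ObjectMap, profile_height: int = PROFILE_HEIGHT) -> np.ndarray:
    """Row-mean vertical profile, min-max scaled to [0, 1].

    The map is nearest-neighbor resampled to ``profile_height`` rows
    (keeping its aspect) before taking row means. A constant map yields an
    all-zero profile (degenerate-scaling rule).
    """
    if profile_height < 1:
        raise ValueError("profile_height must be >= 1")
    v = map_.values
    if v.shape[0] != profile_height:
        new_w = max(1, round(v.shape[1] * profile_height / v.shape[0]))
        v = resample_nearest(v, (profile_height, new_w))
    return minmax_scale(v.mean(axis=1))


def profile_mass_centroid(profile: np.ndarray) -> float:
    """Center of mass of a vertical profile, as a fraction of its height.

    0 is the top row, 1 the bottom; > 0.5 indicates mass below the midline
    (a lower-visual-field bias).
    """
    total = profile.sum()
    if total == 0:
        return 0.5
    y = (np.arange(len(profile)) + 0.5) / len(profile)
    return float((profile * y).sum() / total)


def save_map_csv(map_: ObjectMap, path) -> None:
    np.savetxt(path, map_.values, delimiter=",")


def load_map_csv(path, image_id: str = "unknown", kind: str = "memory") -> ObjectMap:
    return ObjectMap(image_id, np.loadtxt(path, delimiter=",", ndmin=2), kind)
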