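"""Meaning maps, saliency ingestion, object-level scores, recall correlations.

Meaning maps are built from crowd ratings of circular image patches at two
scales: per-patch mean ratings are interpolated to full resolution with a
thin-plate spline, the two scale maps are averaged, an optional multiplicative
Gaussian center bias is applied, and the result is min-max scaled to [0, 1].
Saliency maps (e.g., from GBVS) are consumed as dense per-pixel matrices.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.interpolate import RBFInterpolator

from .inventory import SceneInventory, minmax_scale, resample_nearest
from .maps import ObjectMap
from .stats import CorrelationResult

logger = logging.getLogger(__name__)

__all__ = [
    "PatchGrid",
    "build_patch_grid",
    "default_patch_grids",
    "tps_interpolate",
    "build_meaning_map",
    "load_saliency_map",
    "object_model_scores",
    "recall_model_correlation",
]

# patch diameters/spacings (px) at the canonical 512-long-side resolution;
# spacing <= diameter / sqrt(2) guarantees every pixel is covered
SMALL_PATCH = {"diameter": 44, "spacing": 22}
LARGE_PATCH = {"diameter": 100, "spacing": 50}


@dataclass
class PatchGrid:
    image_id: str
    scale: str  # small | large
    patch_diameter: float
    centers: np.ndarray  # (n, 2) pixel coordinates, row-major order


def build_patch_grid(
    image_dims: tuple[int, int],
    patch_diameter: float,
    spacing: float,
    image_id: str = "",
    scale: str = "small",
) -> PatchGrid:
    """Uniform overlapping grid of circular-patch centers, row-major.

    Centers span the image from edge to edge at the given spacing; with
    spacing <= diameter/sqrt(2) every pixel lies inside at least one patch.
    """
    width, height = image_dims
    if patch_diameter > min(width, height):
        raise ValueError("patch diameter exceeds smaller image dimension")
    xs = np.arange(0.0, width + 1e-9, spacing)
    xs = np.minimum(xs, width)
    ys = np.arange(0.0, height + 1e-9, spacing)
    ys = np.minimum(ys, height)
    gx, gy = np.meshgrid(xs, ys)  # row-major: y outer, x inner
    centers = np.column_stack([gx.ravel(), gy.ravel()])
    return PatchGrid(image_id, scale, patch_diameter, centers)


def default_patch_grids(image_dims, image_id: str = "") -> dict[str, PatchGrid]:
    """The two default-scale grids for an image."""
    return {
        "small": build_patch_grid(image_dims, SMALL_PATCH["diameter"],
                                  SMALL_PATCH["spacing"], image_id, "small"),
        "large": build_patch_grid(image_dims, LARGE_PATCH["diameter"],
                                  LARGE_PATCH["spacing"], image_id, "large"),
    }


def tps_interpolate(
    centers: np.ndarray,
    values: np.ndarray,
    query: np.ndarray,
    smoothing: float = 0.0,
) -> np.ndarray:
    """Thin-plate-spline interpolation of scattered values.

    With smoothing 0 the interpolant passes through the control values
    exactly. Query points are evaluated in chunks to bound memory.
    """
    interp = RBFInterpolator(centers, values, kernel="thin_plate_spline",
                             smoothing=smoothing)
    out = np.empty(len(query))
    step = 20_000
    for i in range(0, len(query), step):
        out[i:i + step] = interp(query[i:i + step])
    return out


def _tps_field(
    centers: np.ndarray,
    values: np.ndarray,
    image_dims: tuple[int, int],
    smoothing: float,
    eval_stride: int,
) -> np.ndarray:
    """Evaluate the TPS on a (possibly subsampled) pixel grid, upsampling
    with nearest-neighbor; the interpolant is smooth so a small stride
    loses essentially nothing."""
    width, height = image_dims
    xs = np.arange(0, width, eval_stride) + 0.5
    ys = np.arange(0, height, eval_stride) + 0.5
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    coarse = tps_interpolate(centers, values, pts, smoothing).reshape(len(ys), len(xs))
    if eval_stride == 1:
        return coarse
    return resample_nearest(coarse, (height, width))


def center_bias_field(
    image_dims: tuple[int, int], sigma_frac: float = 0.5
) -> np.ndarray:
    """Centered Gaussian weight with SDs = sigma_frac * (width, height)."""
    width, height = image_dims
    x = (np.arange(width) + 0.5 - width / 2) / (sigma_frac * width)
    y = (np.arange(height) + 0.5 - height / 2) / (sigma_frac * height)
    return np.exp(-0.5 * (y[:, None] ** 2 + x[None, :] ** 2))


def build_meaning_map(
    patch_ratings: pd.DataFrame,
    grids: dict[str, PatchGrid],
    image_dims: tuple[int, int],
    center_bias_sigma: float | None = 0.5,
    smoothing: float = 0.0,
    min_ratings: int = 3,
    eval_stride: int = 4,
    image_id: str = "",
) -> ObjectMap:
    """Meaning map from two-scale circular patch ratings.

    ``patch_ratings`` columns: scale, cx, cy, worker_id, rating (1-6).
    Per scale, ratings are averaged per patch and TPS-interpolated to full
    resolution; the two scale maps are averaged, multiplied by a centered
    Gaussian (SD = center_bias_sigma x image dims; None disables), and
    min-max scaled to [0, 1].
    """
    width, height = image_dims
    for scale in ("small", "large"):
        if scale not in grids:
            raise ValueError(f"missing {scale}-scale grid")
    scale_maps = []
    for scale in ("small", "large"):
        sub = patch_ratings[patch_ratings["scale"] == scale]
        if sub.empty:
            raise ValueError(f"no ratings for {scale} scale")
        means = sub.groupby(["cx", "cy"], sort=True)["rating"].agg(["mean", "size"])
        short = means.index[means["size"] < min_ratings]
        if len(short):
            logger.warning("%d patches have < %d ratings", len(short), min_ratings)
        centers = np.array(list(means.index))
        scale_maps.append(
            _tps_field(centers, means["mean"].to_numpy(), image_dims,
                       smoothing, eval_stride)
        )
    combined = (scale_maps[0] + scale_maps[1]) / 2.0
    if center_bias_sigma is not None:
        combined = combined * center_bias_field(image_dims, center_bias_sigma)
    return ObjectMap(image_id, minmax_scale(combined), "meaning")


def load_saliency_map(source, image_dims: tuple[int, int],
                      image_id: str = "") -> ObjectMap:
    """Ingest an external per-pixel saliency map (array, CSV, or image file).

    The matrix is validated finite, resampled to the image resolution if
    needed, and min-max scaled to [0, 1].
    """
    if isinstance(source, np.ndarray):
        values = np.asarray(source, dtype=float)
    else:
        path = str(source)
        if path.endswith(".csv"):
            values = np.loadtxt(path, delimiter=",", ndmin=2)
        else:
            import imageio.v3 as iio

            values = np.asarray(iio.imread(path), dtype=float)
            if values.ndim == 3:
                values = values.mean(axis=2)
    if not np.all(np.isfinite(values)):
        raise ValueError("saliency map contains non-finite values")
    width, height = image_dims
    if values.shape != (height, width):
        values = resample_nearest(values, (height, width))
    return ObjectMap(image_id, minmax_scale(values), "saliency")


def object_model_scores(
    map_: ObjectMap, inventory: SceneInventory, mode: str = "mean"
) -> pd.DataFrame:
    """Per-object mean (or peak) map value over the object's mask pixels."""
    if mode not in {"mean", "peak"}:
        raise ValueError("mode must be 'mean' or 'peak'")
    values = map_.values
    rows = []
    for obj in inventory.filtered_objects:
        m = obj.mask
        if m.shape != values.shape:
            m = resample_nearest(m.astype(float), values.shape) > 0.5
        if not m.any():
            raise ValueError(f"object {obj.name!r}: empty mask at map resolution")
        pix = values[m]
        rows.append(
            {
                "image_id": inventory.image.image_id,
                "object_id": obj.object_id,
                "model": map_.kind,
                "mode": mode,
                "score": float(pix.max() if mode == "peak" else pix.mean()),
            }
        )
    return pd.DataFrame(rows)


def _rank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x)


def _residualize(y: np.ndarray, z: np.ndarray) -> np.ndarray:
    z1 = np.column_stack([np.ones(len(z)), z])
    beta, *_ = np.linalg.lstsq(z1, y, rcond=None)
    return y - z1 @ beta


def recall_model_correlation(
    recall_proportions,
    model_scores,
    control_scores=None,
    method: str = "simple",
    residualize: str = "predictor",
) -> CorrelationResult:
    """Rank correlation between object recall and a model score.

    All variables are converted to average ranks first. ``method``:

    - ``simple``: Spearman correlation, t-approximation p (df = n - 2).
    - ``semi_partial``: the control's ranks are regressed out of one
      variable only (``residualize`` chooses "predictor" or "outcome");
      df = n - 3.
    - ``partial``: control regressed out of both; df = n - 3.

    A constant control reduces both to the simple correlation.
    """
    y = np.asarray(recall_proportions, dtype=float)
    x = np.asarray(model_scores, dtype=float)
    if x.size != y.size:
        raise ValueError("length mismatch")
    n = x.size
    if n < 3:
        return CorrelationResult(np.nan, np.nan, n, method, flags=["n<3"])
    if np.all(x == x[0]) or np.all(y == y[0]):
        return CorrelationResult(np.nan, np.nan, n, method, flags=["constant-input"])
    rx, ry = _rank(x), _rank(y)

    controlled: tuple[str, ...] = ()
    df = n - 2
    if method == "simple" or control_scores is None:
        method = "simple"
    else:
        z = np.asarray(control_scores, dtype=float)
        if z.size != n:
            raise ValueError("control length mismatch")
        if np.all(z == z[0]):
            method = "simple"  # zero-variance control: falls back
        else:
            rz = _rank(z)
            controlled = ("control",)
            df = n - 3
            if method == "semi_partial":
                if residualize == "predictor":
                    rx = _residualize(rx, rz)
                elif residualize == "outcome":
                    ry = _residualize(ry, rz)
                else:
                    raise ValueError("residualize must be 'predictor' or 'outcome'")
            elif method == "partial":
                rx = _residualize(rx, rz)
                ry = _residualize(ry, rz)
            else:
                raise ValueError(f"unknown method {method!r}")

    rho = float(np.corrcoef(rx, ry)[0, 1])
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * math.sqrt(df / (1 - rho**2))
        p = 2.0 * sps.t.sf(abs(t), df)
    return CorrelationResult(rho, p, n, method, controlled)
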