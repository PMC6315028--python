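"""Spatial accuracy of drawn objects: displacement, size error, chance null.

All metrics are pure proportion arithmetic: |Δx| and Δwidth are fractions
of image width, |Δy| and Δheight fractions of image height, so results are
invariant to image resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "displacement_and_size",
    "condition_summary",
    "PlacementNullResult",
    "placement_permutation_null",
]


def displacement_and_size(
    aggregated_ellipses: pd.DataFrame, inventories: dict
) -> pd.DataFrame:
    """Per drawn object: centroid displacement and signed size error.

    ``aggregated_ellipses`` rows carry drawing_id, object_id, cx, cy, w, h
    in image-proportion units (see crowd.aggregate_ellipses).
    ``inventories`` maps image_id -> SceneInventory; object_ids are looked
    up across all inventories. Positive d_width means the object was drawn
    wider than in the original image.
    """
    truth = {}
    for inv in inventories.values():
        for obj in inv.objects:
            if obj.bounding_ellipse is not None:
                truth[obj.object_id] = obj.bounding_ellipse
    rows = []
    for rec in aggregated_ellipses.itertuples(index=False):
        if rec.object_id not in truth:
            raise KeyError(f"object {rec.object_id!r} absent from inventories")
        tx, ty, tw, th = truth[rec.object_id]
        rows.append(
            {
                "drawing_id": rec.drawing_id,
                "object_id": rec.object_id,
                "abs_dx": abs(rec.cx - tx),
                "abs_dy": abs(rec.cy - ty),
                "d_width": rec.w - tw,
                "d_height": rec.h - th,
            }
        )
    return pd.DataFrame(rows)


METRICS = ["abs_dx", "abs_dy", "d_width", "d_height"]


def condition_summary(records: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Summarize displacement records per image, then per condition.

    ``records`` must carry ``condition`` and ``image_id`` columns alongside
    the four metrics. Per-image means are computed first; condition-level
    means and SDs are taken across images (each image is one observation,
    matching the dots in the condition plots).
    """
    if records.empty:
        raise ValueError("no records to summarize")
    per_image = (
        records.groupby(["condition", "image_id"], sort=True)[METRICS]
        .mean()
        .reset_index()
    )
    per_condition = (
        per_image.groupby("condition", sort=True)[METRICS]
        .agg(["mean", "std", "count"])
    )
    return {"per_image": per_image, "per_condition": per_condition}


@dataclass
class PlacementNullResult:
    observed_mean_abs_dx: float
    observed_mean_abs_dy: float
    null_means_x: np.ndarray
    null_means_y: np.ndarray
    p_x: float
    p_y: float
    n_centroids_per_object: int
    n_iterations: int

    @property
    def chance_mean_abs_dx(self) -> float:
        return float(np.mean(self.null_means_x))

    @property
    def chance_mean_abs_dy(self) -> float:
        return float(np.mean(self.null_means_y))


def placement_permutation_null(
    inventories,
    observed_mean_abs_dx: float,
    observed_mean_abs_dy: float,
    n_centroids: int = 100,
    n_iterations: int = 1000,
    seed=None,
    rng: np.random.Generator | None = None,
    filtered_only: bool = True,
) -> PlacementNullResult:
    """Random-placement chance level for centroid displacement.

    Per iteration, ``n_centroids`` uniform points in the unit square are
    drawn for every (filtered) object in every inventory; the mean |Δx| and
    |Δy| to the true centroid, averaged over all objects, gives one null
    mean. One-sided p (observed closer than chance) with the add-one rule:
    p = (1 + #{null <= observed}) / (1 + n_iterations).
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    centroids = []
    for inv in inventories:
        objs = inv.filtered_objects if filtered_only else inv.objects
        for obj in objs:
            if obj.centroid is None:
                raise ValueError(f"object {obj.name!r}: geometry not computed")
            centroids.append(obj.centroid)
    true = np.asarray(centroids)  # (n_obj, 2)
    if len(true) == 0:
        raise ValueError("no objects with centroids")
    if rng is None:
        rng = np.random.default_rng(seed)

    null_x = np.empty(n_iterations)
    null_y = np.empty(n_iterations)
    for it in range(n_iterations):
        pts = rng.random((len(true), n_centroids, 2))
        d = np.abs(pts - true[:, np.newaxis, :])
        null_x[it] = d[..., 0].mean()
        null_y[it] = d[..., 1].mean()
    p_x = (1 + int(np.sum(null_x <= observed_mean_abs_dx))) / (1 + n_iterations)
    p_y = (1 + int(np.sum(null_y <= observed_mean_abs_dy))) / (1 + n_iterations)
    return PlacementNullResult(
        observed_mean_abs_dx=observed_mean_abs_dx,
        observed_mean_abs_dy=observed_mean_abs_dy,
        null_means_x=null_x,
        null_means_y=null_y,
        p_x=p_x,
        p_y=p_y,
        n_centroids_per_object=n_centroids,
        n_iterations=n_iterations,
    )
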