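"""Aggregate raw crowd-worker annotation tables into per-drawing scores.

Six scoring tasks are supported: 3AFC drawing-to-image matching, per-object
presence votes, free-text extra-object reports, ellipse placements,
boundary-extension ratings (-2..+2 plus "can't tell"), and typicality
ratings (1-5). Expected input schemas match the CSV layouts in the module
docstrings of each function.
"""

from __future__ import annotations

import logging
import re

import numpy as np
import pandas as pd

from .inventory import SceneInventory

logger = logging.getLogger(__name__)

__all__ = [
    "score_matching",
    "score_category_matching",
    "aggregate_presence",
    "object_recall_proportions",
    "count_extra_objects",
    "normalize_name",
    "aggregate_ellipses",
    "boundary_extension_scores",
    "typicality_scores",
]

PRESENCE_THRESHOLD = 3  # of 5 workers
EXTRA_AGREEMENT_THRESHOLD = 3  # of 5 workers


def score_matching(match_trials: pd.DataFrame) -> pd.DataFrame:
    """Per-drawing 3AFC matching score and recall success.

    ``match_trials`` columns: drawing_id, worker_id, chosen_image_id,
    correct_image_id. A drawing counts as a successful recall iff a strict
    majority of its workers chose the correct image (a 12/24 tie fails).
    """
    if match_trials.empty:
        return pd.DataFrame(
            columns=["drawing_id", "n_workers", "n_correct", "proportion_correct",
                     "recalled"]
        )
    t = match_trials.assign(
        correct=match_trials["chosen_image_id"] == match_trials["correct_image_id"]
    )
    g = t.groupby("drawing_id", sort=True)["correct"].agg(["size", "sum"])
    out = pd.DataFrame(
        {
            "drawing_id": g.index,
            "n_workers": g["size"].to_numpy(),
            "n_correct": g["sum"].astype(int).to_numpy(),
        }
    )
    out["proportion_correct"] = out["n_correct"] / out["n_workers"]
    out["recalled"] = out["n_correct"] > out["n_workers"] / 2
    return out.reset_index(drop=True)


def score_category_matching(match_trials: pd.DataFrame) -> pd.DataFrame:
    """Category-drawing matching: the mean over the two exemplar runs.

    ``match_trials`` must carry an ``exemplar_run`` column distinguishing the
    two runs (each run matching the drawing against one of the category's two
    study exemplars). A drawing with a single run gets that run's score with
    a warning. The ``recalled`` flag is not defined for category drawings.
    """
    scores = []
    for (drawing_id,), grp in match_trials.groupby(["drawing_id"], sort=True):
        run_props = []
        for _, run in grp.groupby("exemplar_run"):
            correct = run["chosen_image_id"] == run["correct_image_id"]
            run_props.append(correct.mean())
        if len(run_props) < 2:
            logger.warning("drawing %s: only %d exemplar run(s)",
                           drawing_id, len(run_props))
        scores.append(
            {"drawing_id": drawing_id, "proportion_correct": float(np.mean(run_props)),
             "n_runs": len(run_props)}
        )
    return pd.DataFrame(scores)


def aggregate_presence(
    presence_votes: pd.DataFrame,
    inventory: SceneInventory,
    threshold: int = PRESENCE_THRESHOLD,
) -> pd.DataFrame:
    """Per-drawing present-object sets from yes/no worker votes.

    ``presence_votes`` columns: drawing_id, object_id, worker_id, vote
    (boolean or {"yes","no"}). An object is present in a drawing iff at
    least ``threshold`` workers voted yes. Objects with fewer than
    ``threshold`` total votes are indeterminate and excluded (logged).

    Returns one row per drawing: present_object_ids (tuple),
    n_objects_drawn, proportion_of_image_objects over the filtered
    inventory.
    """
    votes = presence_votes.copy()
    if votes["vote"].dtype == object:
        votes["vote"] = votes["vote"].astype(str).str.strip().str.lower().eq("yes")
    filtered = list(inventory.filtered_object_ids)
    n_inv = len(filtered)
    rows = []
    for drawing_id, grp in votes.groupby("drawing_id", sort=True):
        agg = grp.groupby("object_id")["vote"].agg(["sum", "size"])
        indeterminate = agg.index[agg["size"] < threshold]
        for oid in indeterminate:
            logger.info("drawing %s object %s: only %d votes, excluded",
                        drawing_id, oid, agg.loc[oid, "size"])
        present = [
            oid for oid in filtered
            if oid in agg.index and agg.loc[oid, "size"] >= threshold
            and agg.loc[oid, "sum"] >= threshold
        ]
        rows.append(
            {
                "drawing_id": drawing_id,
                "present_object_ids": tuple(present),
                "n_objects_drawn": len(present),
                "proportion_of_image_objects": len(present) / n_inv if n_inv else np.nan,
            }
        )
    return pd.DataFrame(rows)


def object_recall_proportions(
    presence_results: pd.DataFrame,
    drawing_meta: pd.DataFrame,
    inventory: SceneInventory,
    recalled_ids=None,
) -> pd.DataFrame:
    """Per-object proportion of recalling participants who drew it.

    ``drawing_meta`` maps drawing_id -> participant_id, image_id.
    ``recalled_ids``: drawings that count toward the denominator (e.g.,
    those scored as successful recalls); defaults to all drawings of the
    image. Returns rows (image_id, object_id, n_drawn, n_recallers,
    proportion).
    """
    merged = presence_results.merge(drawing_meta, on="drawing_id")
    merged = merged[merged["image_id"] == inventory.image.image_id]
    if recalled_ids is not None:
        merged = merged[merged["drawing_id"].isin(set(recalled_ids))]
    n_recallers = merged["participant_id"].nunique()
    rows = []
    for oid in inventory.filtered_object_ids:
        n_drawn = int(
            merged["present_object_ids"].apply(lambda ids: oid in ids).sum()
        )
        rows.append(
            {
                "image_id": inventory.image.image_id,
                "object_id": oid,
                "n_drawn": n_drawn,
                "n_recallers": n_recallers,
                "proportion": n_drawn / n_recallers if n_recallers else np.nan,
            }
        )
    return pd.DataFrame(rows)


_WS = re.compile(r"\s+")


def normalize_name(name: str) -> str:
    """Conservative free-text object-name normalization.

    Trim, casefold, collapse whitespace, strip one trailing plural "s"
    (keeping "ss" words like "glass" intact). No synonym matching.
    """
    s = _WS.sub(" ", name.strip().casefold())
    if s.endswith("s") and not s.endswith("ss") and len(s) > 3:
        s = s[:-1]
    return s


def count_extra_objects(
    extra_reports: pd.DataFrame,
    agreement_threshold: int = EXTRA_AGREEMENT_THRESHOLD,
    synonym_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-drawing extra (not-in-image) objects agreed by enough workers.

    ``extra_reports`` columns: drawing_id, worker_id, names (list of
    free-text strings; empty list or ["none"] means no extras). A name
    counts iff >= ``agreement_threshold`` workers reported it (after
    normalization and optional synonym mapping).
    """
    rows = []
    for drawing_id, grp in extra_reports.groupby("drawing_id", sort=True):
        counts: dict[str, set] = {}
        for _, rec in grp.iterrows():
            names = rec["names"] or []
            for raw in names:
                norm = normalize_name(str(raw))
                if norm in {"", "none"}:
                    continue
                if synonym_map:
                    norm = synonym_map.get(norm, norm)
                counts.setdefault(norm, set()).add(rec["worker_id"])
        agreed = sorted(
            name for name, workers in counts.items()
            if len(workers) >= agreement_threshold
        )
        rows.append(
            {"drawing_id": drawing_id, "extra_names": tuple(agreed),
             "n_extras": len(agreed)}
        )
    return pd.DataFrame(rows)


def aggregate_ellipses(ellipse_annotations: pd.DataFrame) -> pd.DataFrame:
    """Mean worker ellipse per (drawing, object), in image-proportion units.

    ``ellipse_annotations`` columns: drawing_id, object_id, worker_id,
    cx, cy, w, h (drawing-canvas pixels) and frame_x0, frame_y0, frame_w,
    frame_h describing the drawing frame rectangle within the canvas. Each
    annotation is linearly mapped from the frame to the unit square, then
    centers/widths/heights are averaged over workers.
    """
    df = ellipse_annotations
    required = {"frame_x0", "frame_y0", "frame_w", "frame_h"}
    if not required.issubset(df.columns) or df[list(required)].isna().any().any():
        raise ValueError("missing drawing frame rectangle; cannot transform")
    if (df["frame_w"] <= 0).any() or (df["frame_h"] <= 0).any():
        raise ValueError("frame rectangle must have positive extent")
    t = pd.DataFrame(
        {
            "drawing_id": df["drawing_id"],
            "object_id": df["object_id"],
            "cx": (df["cx"] - df["frame_x0"]) / df["frame_w"],
            "cy": (df["cy"] - df["frame_y0"]) / df["frame_h"],
            "w": df["w"] / df["frame_w"],
            "h": df["h"] / df["frame_h"],
        }
    )
    agg = (
        t.groupby(["drawing_id", "object_id"], sort=True)
        .agg(cx=("cx", "mean"), cy=("cy", "mean"), w=("w", "mean"),
             h=("h", "mean"), n_annotations=("cx", "size"))
        .reset_index()
    )
    return agg


def boundary_extension_scores(ratings: pd.DataFrame) -> pd.DataFrame:
    """Per-drawing mean boundary-extension rating.

    ``ratings`` columns: drawing_id, worker_id, rating with integer values
    in -2..2 or the string "cant_tell". "Can't tell" responses are excluded
    from the mean; a drawing whose responses are all excluded gets NaN.
    """
    df = ratings.copy()
    cant = df["rating"].astype(str).str.replace("'", "").str.lower().isin(
        {"cant_tell", "cant tell"}
    )
    numeric = pd.to_numeric(df.loc[~cant, "rating"], errors="raise")
    if ((numeric < -2) | (numeric > 2)).any():
        raise ValueError("boundary-extension ratings must lie in -2..2")
    df["value"] = np.nan
    df.loc[~cant, "value"] = numeric.astype(float)
    out = (
        df.groupby("drawing_id", sort=True)["value"]
        .agg(mean_score="mean", n_valid="count")
        .reset_index()
    )
    return out


def typicality_scores(ratings: pd.DataFrame) -> pd.DataFrame:
    """Per-image mean typicality rating (scale 1 = poor to 5 = good example)."""
    values = pd.to_numeric(ratings["rating"], errors="raise")
    if ((values < 1) | (values > 5)).any():
        raise ValueError("typicality ratings must lie in 1..5")
    out = (
        ratings.assign(rating=values)
        .groupby("image_id", sort=True)["rating"]
        .agg(mean_rating="mean", n_ratings="count")
        .reset_index()
    )
    return out
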