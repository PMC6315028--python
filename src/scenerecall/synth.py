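"""Synthetic scenes, drawings, and noisy crowd annotations.

The generator emulates the statistical structure the analysis assumes: scenes
with 6-50 labeled objects (mean 21.1) at a 512-px long side; four drawing
conditions whose parameters default to the study's reported behavior (image
recall rates, object-drawn proportions, centroid displacement, size bias,
extra-object rates, matcher accuracy); and crowd workers with configurable
3AFC accuracy, presence-vote sensitivity/specificity, ellipse jitter, and
rating noise. Everything is deterministic under a fixed seed, with one RNG
stream per stage.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import brentq

from .inventory import (
    SceneImage,
    SceneInventory,
    SceneObject,
    filter_objects,
    object_geometry,
)

__all__ = [
    "ConditionParams",
    "WorkerNoise",
    "DrawingContent",
    "SyntheticScene",
    "DEFAULT_CONDITIONS",
    "DEFAULT_WORKER_COUNTS",
    "stage_rng",
    "generate_scene",
    "generate_study_scenes",
    "field_object_scores",
    "simulate_study",
    "simulate_crowd",
    "simulate_patch_ratings",
    "simulate_recognition",
]

CANVAS = (600, 500)  # drawing-canvas pixels (w, h)
FRAME = (50, 40, 500, 400)  # frame rectangle (x0, y0, w, h) within the canvas

CATEGORIES = [
    "kitchen", "bedroom", "living room", "bathroom", "office", "classroom",
    "restaurant", "amusement park", "golf course", "desert", "mountain",
    "beach", "forest", "street", "highway", "playground", "garden", "farm",
    "harbor", "airport", "castle", "church", "library", "museum", "gym",
    "supermarket", "bridge", "lighthouse", "stadium", "train station",
]

OBJECT_NAME_POOL = [
    "table", "chair", "lamp", "window", "door", "plant", "picture", "shelf",
    "rug", "clock", "mirror", "cushion", "vase", "box", "basket", "bottle",
    "bowl", "sign", "bench", "fence", "rock", "bush", "cart", "bag",
]

EXTRA_NAME_POOL = [
    "cactus", "window", "building", "sun", "tree", "person", "cloud",
    "dining table", "flag", "car", "bird", "dog", "flower", "moon",
    "bicycle", "umbrella", "street lamp", "mailbox", "cat", "boat",
    "mountain", "river", "fire hydrant", "awning", "balloon", "kite",
    "trash can", "fountain", "statue", "ladder", "swing", "truck",
    "airplane", "tent", "camp fire", "sunflower", "path", "pond",
    "stairs", "chimney",
]


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """One reproducible RNG stream per (seed, stage name)."""
    return np.random.default_rng([int(seed) % 2**31, zlib.crc32(stage.encode())])


# ---------------------------------------------------------------------------
# Parameter containers


@dataclass
class ConditionParams:
    """Generative parameters of one drawing condition.

    Defaults (see DEFAULT_CONDITIONS) encode the study conditions: the mean
    displacement is the expected absolute centroid error per axis in
    image-proportion units (converted internally to a Gaussian SD via
    E|N(0, s)| = s*sqrt(2/pi)); size biases are signed mean errors; the
    extra-object rate is a Poisson mean per drawing.
    """

    condition: str
    image_recall_prob: float = 1.0
    image_recall_prob_low: float | None = None  # low-memorability half
    image_recall_prob_high: float | None = None
    mean_object_recall_prob: float = 0.374
    # (intercept, saliency_w, meaning_w, lower_field_w); intercept None means
    # "solve so the mean recall probability hits mean_object_recall_prob"
    object_recall_logit_weights: tuple = (None, 1.0, 0.6, 0.8)
    mean_abs_dx: float = 0.065
    mean_abs_dy: float = 0.099
    size_bias_w: float = 0.021
    size_bias_h: float = 0.034
    size_noise_sd: float = 0.02
    extra_object_rate: float = 0.0
    match_accuracy: float = 0.843

    def recall_prob_for(self, memorability_half: str | None) -> float:
        if memorability_half == "low" and self.image_recall_prob_low is not None:
            return self.image_recall_prob_low
        if memorability_half == "high" and self.image_recall_prob_high is not None:
            return self.image_recall_prob_high
        return self.image_recall_prob

    @property
    def sigma_dx(self) -> float:
        return self.mean_abs_dx * math.sqrt(math.pi / 2)

    @property
    def sigma_dy(self) -> float:
        return self.mean_abs_dy * math.sqrt(math.pi / 2)


#: study conditions: recall rates, drawn-object proportions, displacement,
#: size bias, extras per drawing, and 3AFC matcher accuracy per condition
DEFAULT_CONDITIONS: dict[str, ConditionParams] = {
    "delayed_recall": ConditionParams(
        condition="delayed_recall",
        image_recall_prob=12.1 / 30,
        image_recall_prob_low=5.70 / 15,
        image_recall_prob_high=6.43 / 15,
        mean_object_recall_prob=0.374,
        mean_abs_dx=0.065, mean_abs_dy=0.099,
        size_bias_w=0.021, size_bias_h=0.034,
        extra_object_rate=1.83 / 12.1,  # per drawing; ~12.1 drawings/participant
        match_accuracy=0.843,
    ),
    "immediate_recall": ConditionParams(
        condition="immediate_recall",
        image_recall_prob=1.0,
        mean_object_recall_prob=0.421,
        mean_abs_dx=0.047, mean_abs_dy=0.070,
        size_bias_w=0.013, size_bias_h=0.026,
        extra_object_rate=1.11 / 30,
        match_accuracy=0.960,
    ),
    "image_drawing": ConditionParams(
        condition="image_drawing",
        image_recall_prob=1.0,
        mean_object_recall_prob=0.515,
        object_recall_logit_weights=(None, 1.0, 0.6, 0.2),
        mean_abs_dx=0.045, mean_abs_dy=0.066,
        size_bias_w=0.020, size_bias_h=0.034,
        extra_object_rate=1.80 / 30,
        match_accuracy=0.925,
    ),
    "category_drawing": ConditionParams(
        condition="category_drawing",
        image_recall_prob=1.0,
        mean_object_recall_prob=0.265,
        object_recall_logit_weights=(None, 0.5, 0.8, 0.0),
        mean_abs_dx=0.12, mean_abs_dy=0.14,
        size_bias_w=0.03, size_bias_h=0.04,
        extra_object_rate=58.4 / 30,
        match_accuracy=0.307,
    ),
}


@dataclass
class WorkerNoise:
    """Crowd-worker noise model across the scoring tasks."""

    match_accuracy: float | None = None  # None: use the condition's accuracy
    presence_sensitivity: float = 0.97
    presence_specificity: float = 0.97
    ellipse_center_sd: float = 0.01  # image-proportion units
    ellipse_size_sd: float = 0.01
    rating_sd: float = 0.5  # scale units
    extra_sensitivity: float = 0.95
    spurious_extra_rate: float = 0.02  # per worker per drawing
    cant_tell_rate: float = 0.05

    def __post_init__(self):
        if self.match_accuracy is not None and not (1 / 3 <= self.match_accuracy <= 1):
            raise ValueError("match_accuracy must lie in [1/3, 1] (3AFC floor)")


NOISELESS = WorkerNoise(
    match_accuracy=1.0, presence_sensitivity=1.0, presence_specificity=1.0,
    ellipse_center_sd=0.0, ellipse_size_sd=0.0, rating_sd=0.0,
    extra_sensitivity=1.0, spurious_extra_rate=0.0, cant_tell_rate=0.0,
)

DEFAULT_WORKER_COUNTS = {
    "match": 24, "presence": 5, "extras": 5, "ellipses": 5,
    "boundary": 7, "typicality": 24,
}


@dataclass
class DrawingContent:
    """Ground-truth content of one simulated drawing."""

    drawing_id: str
    condition: str
    participant_id: str
    image_id: str
    category: str
    memorability_half: str | None
    # (object_id, (cx, cy), width, height) in image-proportion units
    drawn_objects: list = field(default_factory=list)
    extra_objects: list = field(default_factory=list)


@dataclass
class SyntheticScene:
    inventory: SceneInventory
    saliency: np.ndarray  # latent per-pixel field in [0, 1]
    meaning: np.ndarray


# ---------------------------------------------------------------------------
# Scene generation


def _smooth_field(shape: tuple[int, int], rng: np.random.Generator,
                  coarse=(6, 8), center_bias: float = 0.35) -> np.ndarray:
    noise = rng.standard_normal(coarse)
    zoom = (shape[0] / coarse[0], shape[1] / coarse[1])
    f = ndimage.zoom(noise, zoom, order=3)[: shape[0], : shape[1]]
    f = (f - f.min()) / (f.max() - f.min() + 1e-12)
    h, w = shape
    y = (np.arange(h) + 0.5 - h / 2) / (0.35 * h)
    x = (np.arange(w) + 0.5 - w / 2) / (0.35 * w)
    bump = np.exp(-0.5 * (y[:, None] ** 2 + x[None, :] ** 2))
    f = (1 - center_bias) * f + center_bias * bump
    return ((f - f.min()) / (f.max() - f.min() + 1e-12)).astype(np.float32)


def _rect_polygon(cx, cy, w, h):
    return np.array([
        [cx - w / 2, cy - h / 2], [cx + w / 2, cy - h / 2],
        [cx + w / 2, cy + h / 2], [cx - w / 2, cy + h / 2],
    ])


def _ellipse_polygon(cx, cy, w, h, n=16):
    th = np.linspace(0, 2 * math.pi, n, endpoint=False)
    return np.column_stack([cx + w / 2 * np.cos(th), cy + h / 2 * np.sin(th)])


def generate_scene(
    k_objects: int,
    image_dims: tuple[int, int] = (512, 384),
    seed=None,
    rng: np.random.Generator | None = None,
    image_id: str = "scene",
    category: str = "",
    n_space_defining: int = 0,
    min_center_distance: float = 45.0,
    max_retries: int = 500,
    **image_kwargs,
) -> SyntheticScene:
    """One synthetic scene with latent saliency and meaning fields.

    Places ``k_objects`` non-degenerate rectangles/ellipses (all with mask
    equivalent diameter >= the 50-px inclusion threshold) with limited
    overlap (pairwise center distance >= ``min_center_distance``).
    Optionally prepends ``n_space_defining`` full-frame surface outlines
    ("wall"), which the inclusion filter must drop.
    """
    if not (1 <= k_objects <= 60):
        raise ValueError("k_objects must lie in 1..60")
    if rng is None:
        rng = np.random.default_rng(seed)
    width, height = image_dims

    objects: list[SceneObject] = []
    for j in range(n_space_defining):
        objects.append(
            SceneObject(
                object_id=f"{image_id}:wall{j}",
                name="wall",
                polygon=_rect_polygon(width / 2, height / 2, width, height),
                space_defining=True,
            )
        )

    # denser scenes get smaller objects and tighter spacing so that up to
    # 50-60 outlines still pack into the frame
    area = width * height
    max_dim = float(np.clip(math.sqrt(1.2 * area / k_objects), 70, 170))
    min_center_distance = min(min_center_distance,
                              math.sqrt(area / (3.5 * k_objects)))
    centers: list[tuple[float, float]] = []
    for i in range(k_objects):
        placed = False
        for _ in range(max_retries):
            w = rng.uniform(60, max_dim)
            h = rng.uniform(60, max_dim)
            cx = rng.uniform(w / 2 + 1, width - w / 2 - 1)
            cy = rng.uniform(h / 2 + 1, height - h / 2 - 1)
            if all(
                (cx - px) ** 2 + (cy - py) ** 2 >= min_center_distance**2
                for px, py in centers
            ):
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place object {i + 1}/{k_objects} after "
                f"{max_retries} retries"
            )
        centers.append((cx, cy))
        shape_fn = _rect_polygon if rng.random() < 0.5 else _ellipse_polygon
        name = OBJECT_NAME_POOL[int(rng.integers(len(OBJECT_NAME_POOL)))]
        objects.append(
            SceneObject(
                object_id=f"{image_id}:obj{i}",
                name=name,
                polygon=shape_fn(cx, cy, w, h),
            )
        )

    image = SceneImage(image_id=image_id, category=category, width=width,
                       height=height, **image_kwargs)
    inv = SceneInventory(image=image, objects=objects)
    for o in inv.objects:
        object_geometry(o, image_dims)
    inv.filtered_object_ids = filter_objects(inv)
    saliency = _smooth_field((height, width), rng)
    meaning = _smooth_field((height, width), rng)
    return SyntheticScene(inv, saliency, meaning)


def generate_study_scenes(
    seed: int,
    n_categories: int = 30,
    image_dims: tuple[int, int] = (512, 384),
    k_mean: float = 21.1,
    k_sd: float = 10.4,
    k_min: int = 6,
    k_max: int = 50,
) -> tuple[dict[str, SyntheticScene], pd.DataFrame]:
    """The full stimulus set: high/low study images + medium foils.

    Per category, three images are generated with object counts drawn from
    a clipped normal (mean 21.1, SD 10.4, range 6-50) and memorability hit
    rates drawn from the per-role distributions (high 85.1 +/- 5.65%, low
    41.3 +/- 9.6%, medium 65.9 +/- 6.39%). Returns the scenes keyed by
    image_id and a manifest DataFrame.
    """
    rng = stage_rng(seed, "scenes")
    hr_params = {"high": (0.851, 0.0565), "low": (0.413, 0.096),
                 "medium_foil": (0.659, 0.0639)}
    scenes: dict[str, SyntheticScene] = {}
    manifest = []
    for ci in range(n_categories):
        category = CATEGORIES[ci % len(CATEGORIES)]
        for role in ("high", "low", "medium_foil"):
            image_id = f"{category.replace(' ', '_')}-{ci:02d}-{role}"
            k = int(np.clip(round(rng.normal(k_mean, k_sd)), k_min, k_max))
            mu, sd = hr_params[role]
            hr = float(np.clip(rng.normal(mu, sd), 0.0, 1.0))
            scene = generate_scene(
                k, image_dims, rng=rng, image_id=image_id, category=category,
                n_space_defining=1, role=role, memorability_hr=hr,
                memorability_fa=float(np.clip(rng.normal(0.10, 0.03), 0, 1)),
            )
            scenes[image_id] = scene
            manifest.append(
                {"image_id": image_id, "category": category, "role": role,
                 "width": image_dims[0], "height": image_dims[1],
                 "memorability_hr": hr, "n_objects": k}
            )
    return scenes, pd.DataFrame(manifest)


# ---------------------------------------------------------------------------
# Drawing simulation


def field_object_scores(scene: SyntheticScene) -> pd.DataFrame:
    """Latent mean saliency/meaning per filtered object, plus centroid y."""
    rows = []
    for obj in scene.inventory.filtered_objects:
        rows.append(
            {
                "image_id": scene.inventory.image.image_id,
                "object_id": obj.object_id,
                "saliency": float(scene.saliency[obj.mask].mean()),
                "meaning": float(scene.meaning[obj.mask].mean()),
                "cy": obj.centroid[1],
            }
        )
    return pd.DataFrame(rows)


def _solve_intercept(scores: pd.DataFrame, params: ConditionParams) -> float:
    """Intercept making the mean logistic recall probability hit the target."""
    _, ws, wm, wl = params.object_recall_logit_weights
    lin = (ws * scores["saliency"] + wm * scores["meaning"]
           + wl * scores["cy"]).to_numpy()

    def gap(b0):
        return np.mean(1.0 / (1.0 + np.exp(-(b0 + lin)))) - params.mean_object_recall_prob

    return brentq(gap, -20.0, 20.0)


def object_recall_probabilities(
    scenes: dict[str, SyntheticScene], params: ConditionParams
) -> pd.DataFrame:
    """Per-object probability of being drawn, given the image is drawn."""
    study = {k: s for k, s in scenes.items() if s.inventory.image.role != "medium_foil"}
    scores = pd.concat([field_object_scores(s) for s in study.values()],
                       ignore_index=True)
    b0, ws, wm, wl = params.object_recall_logit_weights
    if b0 is None and not (0.0 < params.mean_object_recall_prob < 1.0):
        # saturated target (e.g., the noiseless limit): probability is flat
        scores["p_drawn"] = params.mean_object_recall_prob
        return scores
    if b0 is None:
        b0 = _solve_intercept(scores, params)
    lin = b0 + ws * scores["saliency"] + wm * scores["meaning"] + wl * scores["cy"]
    scores["p_drawn"] = 1.0 / (1.0 + np.exp(-lin))
    return scores


def _study_assignment(manifest: pd.DataFrame, n_participants: int) -> pd.DataFrame:
    """Counterbalanced study lists: one image per category per participant,
    alternating which half sees the high- vs low-memorability exemplar."""
    cats = sorted(manifest.loc[manifest["role"] != "medium_foil", "category"].unique())
    by_cat = {
        (r.category, r.role): r.image_id
        for r in manifest.itertuples() if r.role != "medium_foil"
    }
    rows = []
    for p in range(n_participants):
        for ci, cat in enumerate(cats):
            half = "high" if (p + ci) % 2 == 0 else "low"
            rows.append(
                {"participant_id": f"P{p:02d}", "category": cat,
                 "image_id": by_cat[(cat, half)], "memorability_half": half}
            )
    return pd.DataFrame(rows)


def simulate_study(
    scenes: dict[str, SyntheticScene],
    manifest: pd.DataFrame,
    params: ConditionParams,
    n_participants: int,
    seed: int,
) -> list[DrawingContent]:
    """Simulate one drawing condition for all participants.

    Per participant x studied image: the image is drawn with the
    condition's (memorability-half-specific) recall probability; within a
    drawn image each filtered object is included with its logistic recall
    probability; drawn centroids get independent Gaussian displacement per
    axis (SD = mean_abs * sqrt(pi/2)); drawn sizes get Gaussian error with
    the condition's signed mean bias; extra objects are Poisson with names
    from a category lexicon.
    """
    rng = stage_rng(seed, f"study:{params.condition}")
    probs = object_recall_probabilities(scenes, params)
    p_drawn = dict(zip(probs["object_id"], probs["p_drawn"]))
    assignment = _study_assignment(manifest, n_participants)

    contents: list[DrawingContent] = []
    for rec in assignment.itertuples(index=False):
        p_img = params.recall_prob_for(rec.memorability_half)
        if rng.random() >= p_img:
            continue
        scene = scenes[rec.image_id]
        drawing_id = f"{params.condition}:{rec.participant_id}:{rec.image_id}"
        drawn = []
        for obj in scene.inventory.filtered_objects:
            if rng.random() < p_drawn[obj.object_id]:
                ex, ey, ew, eh = obj.bounding_ellipse
                cx = ex + rng.normal(0.0, params.sigma_dx)
                cy = ey + rng.normal(0.0, params.sigma_dy)
                w = ew + rng.normal(params.size_bias_w, params.size_noise_sd)
                h = eh + rng.normal(params.size_bias_h, params.size_noise_sd)
                drawn.append(
                    (obj.object_id,
                     (float(np.clip(cx, 0, 1)), float(np.clip(cy, 0, 1))),
                     float(np.clip(w, 0.01, 1.5)), float(np.clip(h, 0.01, 1.5)))
                )
        n_extra = int(rng.poisson(params.extra_object_rate))
        extras = [
            EXTRA_NAME_POOL[int(rng.integers(len(EXTRA_NAME_POOL)))]
            for _ in range(n_extra)
        ]
        contents.append(
            DrawingContent(
                drawing_id=drawing_id, condition=params.condition,
                participant_id=rec.participant_id, image_id=rec.image_id,
                category=rec.category, memorability_half=rec.memorability_half,
                drawn_objects=drawn, extra_objects=extras,
            )
        )
    return contents


def contents_meta(contents) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"drawing_id": c.drawing_id, "condition": c.condition,
             "participant_id": c.participant_id, "image_id": c.image_id,
             "category": c.category, "memorability_half": c.memorability_half}
            for c in contents
        ]
    )


# ---------------------------------------------------------------------------
# Crowd simulation


def simulate_crowd(
    contents: list[DrawingContent],
    scenes: dict[str, SyntheticScene],
    noise: WorkerNoise,
    seed: int,
    condition_params: dict[str, ConditionParams] | None = None,
    worker_counts: dict[str, int] | None = None,
) -> dict[str, pd.DataFrame]:
    """Noisy crowd annotation tables for all six scoring tasks.

    Returns a dict of DataFrames: match_trials, presence_votes,
    extra_reports, ellipses, boundary_ratings, typicality_ratings. Match
    accuracy per drawing comes from ``noise.match_accuracy`` when set, else
    from its condition's parameters.
    """
    counts = dict(DEFAULT_WORKER_COUNTS)
    if worker_counts:
        counts.update(worker_counts)
    if any(v < 1 for v in counts.values()):
        raise ValueError("worker counts must be >= 1")
    if condition_params is None:
        condition_params = DEFAULT_CONDITIONS
    rng = stage_rng(seed, "crowd")

    by_category: dict[str, list[str]] = {}
    for image_id, scene in scenes.items():
        by_category.setdefault(scene.inventory.image.category, []).append(image_id)

    match_rows, presence_rows, extra_rows, ellipse_rows, boundary_rows = (
        [], [], [], [], [])
    fx0, fy0, fw, fh = FRAME
    for c in contents:
        acc = noise.match_accuracy
        if acc is None:
            acc = condition_params[c.condition].match_accuracy
        triple = by_category[c.category]
        if c.condition == "category_drawing":
            # matched separately against each of the two study exemplars
            pair = [i for i in triple
                    if scenes[i].inventory.image.role != "medium_foil"]
            for run, correct in enumerate(sorted(pair)):
                foils = [i for i in triple if i != correct]
                for w in range(counts["match"]):
                    if rng.random() < acc:
                        chosen = correct
                    else:
                        chosen = foils[int(rng.integers(len(foils)))]
                    match_rows.append(
                        {"drawing_id": c.drawing_id, "worker_id": f"mw{run}-{w}",
                         "chosen_image_id": chosen, "correct_image_id": correct,
                         "exemplar_run": run}
                    )
        else:
            foils = [i for i in triple if i != c.image_id]
            for w in range(counts["match"]):
                if rng.random() < acc:
                    chosen = c.image_id
                else:
                    chosen = foils[int(rng.integers(len(foils)))] if foils else c.image_id
                match_rows.append(
                    {"drawing_id": c.drawing_id, "worker_id": f"mw{w}",
                     "chosen_image_id": chosen, "correct_image_id": c.image_id,
                     "exemplar_run": 0}
                )

        drawn_ids = {d[0] for d in c.drawn_objects}
        inv = scenes[c.image_id].inventory
        for oid in inv.filtered_object_ids:
            truly = oid in drawn_ids
            p_yes = noise.presence_sensitivity if truly else 1 - noise.presence_specificity
            votes = rng.random(counts["presence"]) < p_yes
            for w, v in enumerate(votes):
                presence_rows.append(
                    {"drawing_id": c.drawing_id, "object_id": oid,
                     "worker_id": f"pw{w}", "vote": bool(v)}
                )

        for w in range(counts["extras"]):
            names = [
                n for n in c.extra_objects if rng.random() < noise.extra_sensitivity
            ]
            if rng.random() < noise.spurious_extra_rate:
                names.append(
                    EXTRA_NAME_POOL[int(rng.integers(len(EXTRA_NAME_POOL)))]
                )
            extra_rows.append(
                {"drawing_id": c.drawing_id, "worker_id": f"ew{w}",
                 "names": names or ["none"]}
            )

        for oid, (cx, cy), w_, h_ in c.drawn_objects:
            for w in range(counts["ellipses"]):
                jcx = cx + rng.normal(0, noise.ellipse_center_sd) if noise.ellipse_center_sd else cx
                jcy = cy + rng.normal(0, noise.ellipse_center_sd) if noise.ellipse_center_sd else cy
                jw = max(w_ + (rng.normal(0, noise.ellipse_size_sd) if noise.ellipse_size_sd else 0.0), 1e-3)
                jh = max(h_ + (rng.normal(0, noise.ellipse_size_sd) if noise.ellipse_size_sd else 0.0), 1e-3)
                ellipse_rows.append(
                    {"drawing_id": c.drawing_id, "object_id": oid,
                     "worker_id": f"lw{w}",
                     "cx": fx0 + jcx * fw, "cy": fy0 + jcy * fh,
                     "w": jw * fw, "h": jh * fh,
                     "frame_x0": fx0, "frame_y0": fy0,
                     "frame_w": fw, "frame_h": fh}
                )

        latent_be = rng.normal(0.2, 0.4)
        for w in range(counts["boundary"]):
            if rng.random() < noise.cant_tell_rate:
                rating = "cant_tell"
            else:
                rating = int(np.clip(round(latent_be + rng.normal(0, noise.rating_sd)), -2, 2))
            boundary_rows.append(
                {"drawing_id": c.drawing_id, "worker_id": f"bw{w}", "rating": rating}
            )

    typ_rows = []
    for image_id, scene in sorted(scenes.items()):
        if scene.inventory.image.role == "medium_foil":
            continue
        latent = float(np.clip(rng.normal(4.06, 0.68), 1, 5))
        for w in range(counts["typicality"]):
            r = int(np.clip(round(latent + rng.normal(0, noise.rating_sd)), 1, 5))
            typ_rows.append(
                {"image_id": image_id, "worker_id": f"tw{w}", "rating": r}
            )

    return {
        "match_trials": pd.DataFrame(match_rows),
        "presence_votes": pd.DataFrame(presence_rows),
        "extra_reports": pd.DataFrame(extra_rows),
        "ellipses": pd.DataFrame(ellipse_rows),
        "boundary_ratings": pd.DataFrame(boundary_rows),
        "typicality_ratings": pd.DataFrame(typ_rows),
    }


# ---------------------------------------------------------------------------
# Patch ratings and recognition


def simulate_patch_ratings(
    latent_field: np.ndarray,
    grid,
    rater_sd: float = 0.5,
    n_raters: int = 3,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Integer 1-6 meaningfulness ratings per circular patch.

    The latent patch value is the mean of the [0, 1] field over the patch
    disk, mapped linearly to the 1-6 scale; each rater adds Gaussian noise
    and the result is rounded and clipped to the scale.
    """
    if rng is None:
        rng = stage_rng(seed, "patch_ratings")
    h, w = latent_field.shape
    r = grid.patch_diameter / 2.0
    rows = []
    for cx, cy in grid.centers:
        x0, x1 = max(int(cx - r), 0), min(int(math.ceil(cx + r)), w)
        y0, y1 = max(int(cy - r), 0), min(int(math.ceil(cy + r)), h)
        xs = np.arange(x0, x1) + 0.5
        ys = np.arange(y0, y1) + 0.5
        disk = ((xs[None, :] - cx) ** 2 + (ys[:, None] - cy) ** 2) <= r**2
        patch = latent_field[y0:y1, x0:x1][disk]
        latent = 1.0 + 5.0 * float(patch.mean()) if patch.size else 3.5
        for k in range(n_raters):
            val = latent + (rng.normal(0, rater_sd) if rater_sd else 0.0)
            rows.append(
                {"scale": grid.scale, "cx": float(cx), "cy": float(cy),
                 "worker_id": f"rw{k}",
                 "rating": int(np.clip(round(val), 1, 6))}
            )
    return pd.DataFrame(rows)


def simulate_recognition(
    manifest: pd.DataFrame,
    n_participants: int,
    seed: int,
    ability: float = 2.36,
    memorability_effect: float = 2.2,
    fa_rate: float = 0.102,
) -> pd.DataFrame:
    """Old/new recognition trials: studied targets plus medium foils.

    Hit probability is logistic(ability + effect * (HR_image - mean HR));
    false alarms to foils occur at a constant rate. Requires medium_foil
    rows in the manifest.
    """
    foils = manifest[manifest["role"] == "medium_foil"]
    if foils.empty:
        raise ValueError("manifest contains no medium_foil images")
    rng = stage_rng(seed, "recognition")
    assignment = _study_assignment(manifest, n_participants)
    hr = manifest.set_index("image_id")["memorability_hr"]
    mean_hr = hr.loc[assignment["image_id"].unique()].mean()

    rows = []
    for pid, grp in assignment.groupby("participant_id", sort=True):
        for rec in grp.itertuples(index=False):
            p_hit = 1.0 / (1.0 + math.exp(
                -(ability + memorability_effect * (hr[rec.image_id] - mean_hr))
            ))
            old = rng.random() < p_hit
            rows.append(
                {"participant_id": pid, "image_id": rec.image_id,
                 "is_target": True, "memorability_half": rec.memorability_half,
                 "response": "old" if old else "new",
                 "confidence": "high" if rng.random() < 0.7 else "low"}
            )
        for rec in foils.itertuples(index=False):
            old = rng.random() < fa_rate
            rows.append(
                {"participant_id": pid, "image_id": rec.image_id,
                 "is_target": False, "memorability_half": None,
                 "response": "old" if old else "new",
                 "confidence": "high" if rng.random() < 0.5 else "low"}
            )
    return pd.DataFrame(rows)
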