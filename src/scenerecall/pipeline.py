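"""End-to-end orchestration: synthetic study -> crowd scoring -> analyses.

`run_synthetic_study` generates the stimuli, simulates the drawing
conditions and their crowd scoring, and runs the full downstream analysis
(matching, presence, extras, ellipses, displacement, maps, attention
correlations, recognition battery). It is what the acceptance script and
the parameter-recovery tests drive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import attention, crowd, maps, spatial, stats, synth

__all__ = ["StudyResults", "run_synthetic_study"]


@dataclass
class StudyResults:
    scenes: dict
    manifest: pd.DataFrame
    contents: dict  # condition -> list[DrawingContent]
    tables: dict  # condition -> crowd tables
    match_scores: dict  # condition -> DataFrame
    presence: dict  # condition -> DataFrame
    extras: dict
    displacement: pd.DataFrame
    summaries: dict
    recall_outcomes: pd.DataFrame  # delayed recall, per participant x image
    recognition_trials: pd.DataFrame
    recognition_summary: pd.DataFrame
    object_recall: pd.DataFrame  # per-object recall proportions (delayed)
    extras_per_participant: dict  # condition -> Series
    derived: dict = field(default_factory=dict)


def _presence_by_image(tables, scenes, condition):
    """Presence aggregation image by image (votes reference one inventory)."""
    votes = tables["presence_votes"]
    meta_ids = votes["drawing_id"].str.split(":", n=2, expand=True)
    votes = votes.assign(image_id=meta_ids[2])
    frames = []
    for image_id, grp in votes.groupby("image_id"):
        frames.append(crowd.aggregate_presence(grp, scenes[image_id].inventory))
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def run_synthetic_study(
    seed: int,
    n_categories: int = 30,
    n_participants: int = 30,
    conditions: dict | None = None,
    noise: synth.WorkerNoise | None = None,
    with_attention: bool = True,
    min_recallers: int = 5,
) -> StudyResults:
    """Simulate the study end to end and run every analysis stage."""
    conditions = conditions or synth.DEFAULT_CONDITIONS
    noise = noise or synth.WorkerNoise()
    scenes, manifest = synth.generate_study_scenes(seed, n_categories=n_categories)

    contents, tables, match_scores, presence, extras = {}, {}, {}, {}, {}
    extras_per_participant = {}
    displacement_frames = []
    # participant counts relative to the recall groups: the image-drawing
    # group is 24/30 the size, the category-drawing group half the size
    part_ratio = {"image_drawing": 0.8, "category_drawing": 0.5}
    for cond, params in conditions.items():
        n_part = max(int(round(n_participants * part_ratio.get(cond, 1.0))), 2)
        cont = synth.simulate_study(scenes, manifest, params, n_part, seed)
        contents[cond] = cont
        tabs = synth.simulate_crowd(cont, scenes, noise, seed,
                                    condition_params=conditions)
        tables[cond] = tabs
        meta = synth.contents_meta(cont)

        if cond == "category_drawing":
            match_scores[cond] = crowd.score_category_matching(
                tabs["match_trials"])
        else:
            match_scores[cond] = crowd.score_matching(tabs["match_trials"])

        presence[cond] = _presence_by_image(tabs, scenes, cond)
        extras[cond] = crowd.count_extra_objects(tabs["extra_reports"])
        ex = extras[cond].merge(meta, on="drawing_id")
        extras_per_participant[cond] = ex.groupby("participant_id")["n_extras"].sum()

        if cond != "category_drawing" and not tabs["ellipses"].empty:
            agg = crowd.aggregate_ellipses(tabs["ellipses"])
            disp = spatial.displacement_and_size(
                agg, {k: s.inventory for k, s in scenes.items()})
            disp = disp.merge(meta[["drawing_id", "image_id"]], on="drawing_id")
            disp["condition"] = cond
            displacement_frames.append(disp)

    displacement = pd.concat(displacement_frames, ignore_index=True)
    summaries = spatial.condition_summary(displacement)

    # delayed-recall outcomes per participant x studied image
    meta_d = synth.contents_meta(contents["delayed_recall"])
    ms = match_scores["delayed_recall"].merge(meta_d, on="drawing_id")
    assignment = synth._study_assignment(manifest, n_participants)
    recall_outcomes = assignment.merge(
        ms[["participant_id", "image_id", "recalled"]],
        on=["participant_id", "image_id"], how="left",
    )
    recall_outcomes["recalled"] = (
        recall_outcomes["recalled"].astype("boolean").fillna(False).astype(bool)
    )

    recognition_trials = synth.simulate_recognition(manifest, n_participants, seed)
    recognition_summary = stats.recognition_rates(recognition_trials)

    # per-object recall proportions for delayed recall (recalled drawings only)
    recalled_ids = set(ms.loc[ms["recalled"], "drawing_id"])
    frames = []
    for image_id, scene in scenes.items():
        if scene.inventory.image.role == "medium_foil":
            continue
        props = crowd.object_recall_proportions(
            presence["delayed_recall"], meta_d, scene.inventory, recalled_ids)
        frames.append(props)
    object_recall = pd.concat(frames, ignore_index=True)

    results = StudyResults(
        scenes=scenes, manifest=manifest, contents=contents, tables=tables,
        match_scores=match_scores, presence=presence, extras=extras,
        displacement=displacement, summaries=summaries,
        recall_outcomes=recall_outcomes, recognition_trials=recognition_trials,
        recognition_summary=recognition_summary, object_recall=object_recall,
        extras_per_participant=extras_per_participant,
    )

    if with_attention:
        results.derived["attention"] = _attention_analysis(
            results, seed, min_recallers=min_recallers)
    results.derived["recognition_battery"] = stats.recall_recognition_comparison(
        recall_outcomes, recognition_summary, recognition_trials,
        objects_drawn=_objects_drawn_table(results),
    )
    return results


def _objects_drawn_table(results: StudyResults) -> pd.DataFrame:
    meta = synth.contents_meta(results.contents["delayed_recall"])
    p = results.presence["delayed_recall"].merge(meta, on="drawing_id")
    return p[["participant_id", "image_id", "n_objects_drawn"]]


def _attention_analysis(results: StudyResults, seed: int,
                        min_recallers: int = 5, rater_sd: float = 0.5) -> dict:
    """Meaning maps from simulated patch ratings + latent saliency maps,
    correlated with object recall over qualifying images."""
    qualifying = (
        results.object_recall.groupby("image_id")["n_recallers"].first()
    )
    qualifying = set(qualifying[qualifying >= min_recallers].index)
    if not qualifying:
        return {"n_qualifying_images": 0, "n_objects": 0}
    rng = synth.stage_rng(seed, "attention")

    rows = []
    for image_id in sorted(qualifying):
        scene = results.scenes[image_id]
        dims = (scene.inventory.image.width, scene.inventory.image.height)
        grids = attention.default_patch_grids(dims, image_id)
        ratings = pd.concat(
            [synth.simulate_patch_ratings(scene.meaning, g, rater_sd=rater_sd,
                                          rng=rng)
             for g in grids.values()],
            ignore_index=True,
        )
        meaning_map = attention.build_meaning_map(ratings, grids, dims,
                                                  image_id=image_id)
        saliency_map = attention.load_saliency_map(scene.saliency, dims, image_id)
        m_scores = attention.object_model_scores(meaning_map, scene.inventory)
        s_scores = attention.object_model_scores(saliency_map, scene.inventory)
        merged = (
            m_scores.rename(columns={"score": "meaning"})[
                ["image_id", "object_id", "meaning"]]
            .merge(s_scores.rename(columns={"score": "saliency"})[
                ["object_id", "saliency"]], on="object_id")
        )
        rows.append(merged)
    scores = pd.concat(rows, ignore_index=True)
    pooled = scores.merge(
        results.object_recall[["object_id", "proportion"]], on="object_id")

    out = {
        "n_qualifying_images": len(qualifying),
        "n_objects": len(pooled),
        "saliency_rho": attention.recall_model_correlation(
            pooled["proportion"], pooled["saliency"]),
        "meaning_rho": attention.recall_model_correlation(
            pooled["proportion"], pooled["meaning"]),
        "saliency_semipartial_vs_meaning": attention.recall_model_correlation(
            pooled["proportion"], pooled["saliency"], pooled["meaning"],
            method="semi_partial"),
        "scores": pooled,
    }
    return out


def grand_memory_profile(results: StudyResults, profile_height: int = 700):
    """Grand-average delayed-recall memory map and its vertical profile."""
    from .inventory import object_count_map

    study = {k: s for k, s in results.scenes.items()
             if s.inventory.image.role != "medium_foil"}
    inventories = [s.inventory for s in study.values()]
    shape = (inventories[0].image.height, inventories[0].image.width)
    count_map = object_count_map(inventories, shape=shape)
    mem_maps = []
    for image_id, scene in study.items():
        props = results.object_recall[
            results.object_recall["image_id"] == image_id]
        m = maps.memory_map(scene.inventory, props)
        if m is not None:
            mem_maps.append(m)
    grand = maps.grand_average_map(mem_maps, count_map)
    profile = maps.vertical_profile(grand, profile_height)
    return grand, profile
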