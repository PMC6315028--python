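"""Statistical toolbox for the recall analyses.

Implements the tests used throughout the pipeline: the tie-corrected
Wilcoxon rank-sum Z approximation, label-shuffling permutation tests,
tied-rank Spearman correlation, paired t tests, the default (JZS) Bayes
factor for a one-sample t design, and the recognition-vs-recall
comparison battery.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, stats as sps

__all__ = [
    "TestResult",
    "CorrelationResult",
    "BayesFactorResult",
    "RecognitionSummary",
    "bonferroni_alpha",
    "wilcoxon_rank_sum",
    "permutation_test_two_sample",
    "spearman_corr",
    "paired_t",
    "jzs_bf01",
    "recognition_rates",
    "recall_recognition_comparison",
]


@dataclass
class TestResult:
    """Outcome of a hypothesis test, with method metadata."""

    statistic: float
    p_value: float
    method: str
    df: float | None = None
    n_iterations: int | None = None
    alpha_corrected: float | None = None
    flags: list[str] = field(default_factory=list)


@dataclass
class CorrelationResult:
    rho: float
    p_value: float
    n: int
    method: str = "simple"
    controlled_variables: tuple[str, ...] = ()
    flags: list[str] = field(default_factory=list)


@dataclass
class BayesFactorResult:
    """BF01: evidence for the null over a JZS (Cauchy effect-size) alternative."""

    bf01: float
    t_statistic: float
    n: int
    cauchy_scale: float

    @property
    def bf10(self) -> float:
        return 1.0 / self.bf01


@dataclass
class RecognitionSummary:
    participant_id: object
    hit_rate: float
    fa_rate: float
    n_recognized_high: int
    n_recognized_low: int


def bonferroni_alpha(alpha: float, n_comparisons: int) -> float:
    """Corrected per-comparison significance level alpha / m."""
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    return alpha / n_comparisons


def _tie_corrected_variance(pooled: np.ndarray, n_a: int, n_b: int) -> float:
    n = n_a + n_b
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1))
    return n_a * n_b / 12.0 * ((n + 1) - tie_term)


def wilcoxon_rank_sum(sample_a, sample_b, method: str = "normal") -> TestResult:
    """Two-tailed independent-samples Wilcoxon rank-sum test.

    Default: normal approximation on the rank sum of ``sample_a`` with
    average ranks for ties and tie-corrected variance; no continuity
    correction (immaterial at the sample sizes the pipeline compares, n=60
    images per condition). For tiny samples ``method="exact"`` enumerates
    every group assignment and reports
    P(|W - E[W]| >= |observed - E[W]|) exactly.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)  # average ranks for ties
    w = ranks[: a.size].sum()
    mean_w = a.size * (a.size + b.size + 1) / 2.0
    var_w = _tie_corrected_variance(pooled, a.size, b.size)
    if var_w == 0:  # all pooled values identical
        return TestResult(0.0, 1.0, f"wilcoxon_rank_sum_{method}",
                          flags=["degenerate"])
    z = (w - mean_w) / math.sqrt(var_w)
    if method == "exact":
        if math.comb(pooled.size, a.size) > 500_000:
            raise ValueError("samples too large for exact enumeration")
        obs_dev = abs(w - mean_w)
        count = total = 0
        for comb in itertools.combinations(range(pooled.size), a.size):
            total += 1
            if abs(ranks[list(comb)].sum() - mean_w) >= obs_dev - 1e-9:
                count += 1
        return TestResult(z, count / total, "wilcoxon_rank_sum_exact")
    if method != "normal":
        raise ValueError("method must be 'normal' or 'exact'")
    p = 2.0 * sps.norm.sf(abs(z))
    return TestResult(z, min(p, 1.0), "wilcoxon_rank_sum")


def permutation_test_two_sample(
    sample_a,
    sample_b,
    statistic=None,
    n_iterations: int = 100_000,
    seed=None,
    rng: np.random.Generator | None = None,
) -> TestResult:
    """Two-sample permutation test by label shuffling.

    Two-tailed p with the add-one rule:
    ``(1 + #{|stat_perm| >= |stat_obs|}) / (1 + n_iterations)``.
    Default statistic is the difference of group means.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    pooled = np.concatenate([a, b])
    n_a = a.size
    if rng is None:
        rng = np.random.default_rng(seed)

    mean_difference = statistic is None
    if mean_difference:
        statistic = lambda x, y: float(np.mean(x) - np.mean(y))  # noqa: E731

    obs = statistic(a, b)
    if np.all(pooled == pooled[0]):
        return TestResult(obs, 1.0, "permutation", n_iterations=n_iterations,
                          flags=["degenerate"])
    count = 0
    # chunked so 100k iterations stay within a modest memory footprint
    chunk = max(1, min(n_iterations, 2_000_000 // max(pooled.size, 1)))
    done = 0
    while done < n_iterations:
        m = min(chunk, n_iterations - done)
        idx = np.argsort(rng.random((m, pooled.size)), axis=1)
        perm = pooled[idx]
        if mean_difference:
            stat = perm[:, :n_a].mean(axis=1) - perm[:, n_a:].mean(axis=1)
        else:
            stat = np.array([statistic(row[:n_a], row[n_a:]) for row in perm])
        count += int(np.sum(np.abs(stat) >= abs(obs) - 1e-12))
        done += m
    p = (1 + count) / (1 + n_iterations)
    return TestResult(obs, p, "permutation", n_iterations=n_iterations)


def spearman_corr(x, y) -> CorrelationResult:
    """Spearman rank correlation with average ranks for ties.

    Pearson correlation on tied ranks; p from the t approximation with
    n - 2 degrees of freedom (scipy's default).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        return CorrelationResult(np.nan, np.nan, x.size, flags=["n<3"])
    if np.all(x == x[0]) or np.all(y == y[0]):
        return CorrelationResult(np.nan, np.nan, x.size, flags=["constant-input"])
    rho, p = sps.spearmanr(x, y)
    return CorrelationResult(float(rho), float(p), int(x.size))


def paired_t(x, y) -> TestResult:
    """Two-tailed paired-samples t test on x - y, df = n - 1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need equal-length samples with n >= 2")
    d = x - y
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            return TestResult(0.0, 1.0, "paired_t", df=x.size - 1)
        return TestResult(math.inf * np.sign(d.mean()), 0.0, "paired_t",
                          df=x.size - 1, flags=["zero-variance"])
    t, p = sps.ttest_rel(x, y)
    return TestResult(float(t), float(p), "paired_t", df=x.size - 1)


def jzs_bf01(t_statistic: float, n: int, cauchy_scale: float = 1.0) -> BayesFactorResult:
    """Default Bayes factor BF01 for a one-sample (paired-difference) t design.

    The alternative places a Cauchy(0, r) prior on the standardized effect
    size (Jeffreys-Zellner-Siow); the marginal likelihood is the integral
    over the implied g prior (inverse-chi-squared weight), computed by
    adaptive quadrature. BF01 > 1 favours the null.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if not np.isfinite(t_statistic):
        raise ValueError("t must be finite")
    t = float(t_statistic)
    r = float(cauchy_scale)
    nu = n - 1

    def integrand(g):
        return (
            (1 + n * g * r**2) ** -0.5
            * (1 + t**2 / ((1 + n * g * r**2) * nu)) ** (-(nu + 1) / 2)
            * (2 * math.pi) ** -0.5
            * g**-1.5
            * math.exp(-1.0 / (2 * g))
        )

    marginal, err = integrate.quad(integrand, 0, math.inf, epsrel=1e-8, limit=200)
    if marginal <= 0 or not np.isfinite(marginal) or err > 1e-6 * marginal:
        raise ArithmeticError(
            f"JZS quadrature failed to converge (value={marginal}, abserr={err})"
        )
    null_like = (1 + t**2 / nu) ** (-(nu + 1) / 2)
    return BayesFactorResult(null_like / marginal, t, n, r)


def recognition_rates(recognition_trials: pd.DataFrame) -> pd.DataFrame:
    """Per-participant hit and false-alarm rates from old/new trials.

    Expects columns participant_id, image_id, is_target (bool),
    response ("old"/"new") and optionally memorability_half
    ("high"/"low") for the targets. Confidence, if present, is ignored.
    An "old" response to a target counts as recognized regardless of
    confidence.
    """
    rows = []
    for pid, grp in recognition_trials.groupby("participant_id", sort=True):
        targets = grp[grp["is_target"]]
        foils = grp[~grp["is_target"]]
        if len(targets) == 0:
            raise ValueError(f"participant {pid!r} has no target trials")
        hits = targets["response"].eq("old")
        hr = hits.mean()
        fa = foils["response"].eq("old").mean() if len(foils) else np.nan
        n_high = n_low = 0
        if "memorability_half" in grp.columns:
            n_high = int(hits[targets["memorability_half"] == "high"].sum())
            n_low = int(hits[targets["memorability_half"] == "low"].sum())
        rows.append(
            {"participant_id": pid, "hit_rate": float(hr), "fa_rate": float(fa),
             "n_recognized_high": n_high, "n_recognized_low": n_low}
        )
    return pd.DataFrame(rows)


def recall_recognition_comparison(
    recall_outcomes: pd.DataFrame,
    recognition_summaries: pd.DataFrame,
    recognition_trials: pd.DataFrame,
    objects_drawn: pd.DataFrame | None = None,
) -> dict:
    """The recognition-versus-recall battery.

    Inputs
    ------
    recall_outcomes : one row per (participant_id, image_id) with a boolean
        ``recalled`` column and, for the memorability split, a
        ``memorability_half`` column.
    recognition_summaries : output of :func:`recognition_rates`.
    recognition_trials : raw trials (needed for image-level recognition counts).
    objects_drawn : optional per (participant_id, image_id) ``n_objects_drawn``.

    Returns a dict with image-level and participant-level Spearman
    correlations between recall and recognition, plus the paired t and JZS
    BF01 on high- versus low-memorability recalled and recognized counts.
    """
    out: dict[str, object] = {}

    recog_targets = recognition_trials[recognition_trials["is_target"]]
    recognized = recog_targets.assign(hit=recog_targets["response"].eq("old"))
    img_recognized = recognized.groupby("image_id")["hit"].sum()
    img_recalled = recall_outcomes.groupby("image_id")["recalled"].sum()
    common = img_recalled.index.intersection(img_recognized.index)
    out["image_recall_vs_recognition"] = spearman_corr(
        img_recalled.loc[common].to_numpy(), img_recognized.loc[common].to_numpy()
    )

    per_part_recalled = recall_outcomes.groupby("participant_id")["recalled"].sum()
    per_part_recognized = recognized.groupby("participant_id")["hit"].sum()
    common_p = per_part_recalled.index.intersection(per_part_recognized.index)
    out["participant_recall_vs_recognition"] = spearman_corr(
        per_part_recalled.loc[common_p].to_numpy(),
        per_part_recognized.loc[common_p].to_numpy(),
    )

    if objects_drawn is not None:
        img_objects = objects_drawn.groupby("image_id")["n_objects_drawn"].mean()
        img_recog_rate = recognized.groupby("image_id")["hit"].mean()
        common_o = img_objects.index.intersection(img_recog_rate.index)
        out["objects_drawn_vs_recognition"] = spearman_corr(
            img_objects.loc[common_o].to_numpy(),
            img_recog_rate.loc[common_o].to_numpy(),
        )

    # high/low memorability splits, per participant
    split = (
        recall_outcomes.groupby(["participant_id", "memorability_half"])["recalled"]
        .sum()
        .unstack("memorability_half")
    )
    rec_high = split["high"].to_numpy(dtype=float)
    rec_low = split["low"].to_numpy(dtype=float)
    t_recall = paired_t(rec_high, rec_low)
    out["recall_memorability_t"] = t_recall
    out["recall_memorability_bf01"] = jzs_bf01(t_recall.statistic, rec_high.size)

    s = recognition_summaries.set_index("participant_id").loc[
        split.index, ["n_recognized_high", "n_recognized_low"]
    ]
    t_recog = paired_t(s["n_recognized_high"].to_numpy(float),
                       s["n_recognized_low"].to_numpy(float))
    out["recognition_memorability_t"] = t_recog
    out["recognition_memorability_bf01"] = jzs_bf01(t_recog.statistic, len(s))
    return out
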