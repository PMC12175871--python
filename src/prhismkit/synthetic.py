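"""Synthetic study-shaped data: video catalog, exclusion filtering, and
multi-instrument rating sets with controllable agreement.

The generator emulates the shape of a rater-agreement study of health
videos: a catalog of videos drawn from 8 uploader source categories
(categories 1–4 being reliable sources — educational institutions, health
care facilities, nonprofit health plans, public health departments), six
physician raters in two experience strata, and for every (video, rater)
combination a full set of PRHISM, DISCERN and expert accuracy/harm
ratings.

Agreement between raters is controlled through the latent copy model of
:mod:`prhismkit.power`: each video's true overall-quality category derives
from its latent quality via fixed quantile thresholds (so the category
marginal is controllable independently of agreement), and each rater
reports the truth with a calibrated probability theta, otherwise an
independent draw from the marginal.  Item-level responses are the rater's
own overall judgment plus ordinal jitter, clipped to the instrument's
support, with an optional per-item not-applicable probability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .power import CategoryDistribution, calibrate_theta

__all__ = [
    "VideoRecord",
    "RaterProfile",
    "StudyDataset",
    "TABLE1_SOURCE_PROBS",
    "EXCLUSION_CRITERIA",
    "default_raters",
    "generate_catalog",
    "apply_exclusions",
    "generate_ratings",
    "generate_study",
    "summarize_catalog",
]

# Source-category mix observed in the motivating 60-video catalog:
# 6, 4, 9, 0, 15, 13, 12, 1 videos in categories 1..8.
TABLE1_SOURCE_PROBS = (6 / 60, 4 / 60, 9 / 60, 0.0, 15 / 60, 13 / 60, 12 / 60, 1 / 60)

SOURCE_CATEGORY_LABELS = {
    1: "health professions schools and other educational institutions",
    2: "health care facilities",
    3: "nonprofit health plans",
    4: "public health departments",
    5: "individual health care professionals",
    6: "entertainment, media, news",
    7: "personal blogs",
    8: "other",
}

# Exclusion criteria in protocol order; a record failing several is
# tallied once under the first.
EXCLUSION_CRITERIA = (
    "language other than target",
    "fewer than 3000 views",
    "shorter than 60 seconds",
    "irrelevant",
    "without audio",
    "short-form video",
    "duplicate",
    "advertisement",
)

MIN_VIEWS = 3000
MIN_LENGTH_MIN = 1.0


@dataclass(frozen=True)
class VideoRecord:
    """One video in the catalog.

    ``source_category`` is 1–8; categories 1–4 count as reliable sources.
    ``latent_quality`` in [0, 1] drives both the true quality category and
    the expert assessments.  The boolean flags mark screening criteria
    used by :func:`apply_exclusions`.
    """

    video_id: str
    source_category: int
    length_min: float
    views: int
    months_since_post: int
    latent_quality: float
    language_other: bool = False
    irrelevant: bool = False
    no_audio: bool = False
    short_form: bool = False
    duplicate: bool = False
    advertisement: bool = False

    def __post_init__(self):
        if not 1 <= self.source_category <= 8:
            raise ValueError("source_category must be 1..8")
        if self.length_min <= 0 or self.views < 0 or self.months_since_post < 0:
            raise ValueError("length must be positive; views/months nonnegative")
        if not 0.0 <= self.latent_quality <= 1.0:
            raise ValueError("latent_quality must lie in [0, 1]")

    @property
    def reliable(self) -> bool:
        return self.source_category <= 4


@dataclass(frozen=True)
class RaterProfile:
    """One rater: experience years, stratum, and response-style parameters.

    ``severity_bias`` shifts the rater's item-level judgments (negative =
    harsher); ``noise_sd`` is the SD of the ordinal jitter added to item
    responses around the rater's own overall judgment.  The stratum is
    senior iff physician_years > 10.
    """

    rater_id: str
    physician_years: int
    expert_years: int
    severity_bias: float = 0.0
    noise_sd: float = 0.7

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")

    @property
    def stratum(self) -> str:
        return "senior" if self.physician_years > 10 else "junior"


@dataclass(frozen=True)
class StudyDataset:
    """A complete synthetic study: catalog, rater panel, long-format
    ratings, and the generator parameters that produced them."""

    catalog: tuple
    raters: tuple
    ratings: pd.DataFrame
    provenance: dict


def default_raters(noise_sd: float = 0.7) -> tuple:
    """Six-rater panel: three seniors (>10 physician-years) and three
    juniors, mirroring the experience spread of a real expert panel."""
    years = [(8, 1), (9, 2), (10, 2), (16, 7), (24, 15), (37, 20)]
    return tuple(
        RaterProfile(rater_id=f"r{i+1}", physician_years=py, expert_years=ey,
                     noise_sd=noise_sd)
        for i, (py, ey) in enumerate(years)
    )


def generate_catalog(n: int, seed: int = 0,
                     source_probs: Sequence[float] = TABLE1_SOURCE_PROBS,
                     quality_shift: float = 1.0) -> tuple:
    """Draw ``n`` video records.

    Source categories are multinomial with ``source_probs``.  Length,
    views and months-since-post are log-normal with medians near the
    motivating catalog (8 min, ~30,500 views, 29 months) and spreads wide
    enough to bracket its printed ranges (1–126 min, 3921–978,676 views,
    7–123 months); the exact shapes are unknown and deliberately
    arbitrary.  Latent quality is Beta(2 + quality_shift, 2) for reliable
    sources and Beta(2, 2) otherwise, so increasing ``quality_shift``
    widens the quality gap between reliable and other sources.
    """
    probs = np.asarray(source_probs, dtype=float)
    if probs.shape != (8,) or (probs < 0).any() or not math.isclose(probs.sum(), 1.0,
                                                                    abs_tol=1e-9):
        raise ValueError("source_probs must be 8 nonnegative values summing to 1")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        cat = int(rng.choice(8, p=probs)) + 1
        length = float(max(np.exp(rng.normal(np.log(8.0), 1.1)), 0.1))
        views = int(np.exp(rng.normal(np.log(30_500.0), 1.2)))
        months = int(round(np.exp(rng.normal(np.log(29.0), 0.75))))
        if cat <= 4:
            q = float(rng.beta(2.0 + quality_shift, 2.0))
        else:
            q = float(rng.beta(2.0, 2.0))
        records.append(VideoRecord(
            video_id=f"v{i+1:03d}", source_category=cat, length_min=length,
            views=views, months_since_post=months, latent_quality=q))
    return tuple(records)


def apply_exclusions(records: Sequence[VideoRecord]):
    """Screen a candidate list, returning (kept, tally).

    A record is kept iff its language/relevance/audio/short-form/
    duplicate/advertisement flags are all clean, it has at least 3000
    views and runs at least 60 seconds.  ``tally`` counts exclusions per
    criterion in protocol order; a record failing several criteria is
    tallied once under the first that applies.
    """
    tally = {c: 0 for c in EXCLUSION_CRITERIA}
    kept = []
    for rec in records:
        checks = (
            rec.language_other,
            rec.views < MIN_VIEWS,
            rec.length_min < MIN_LENGTH_MIN,
            rec.irrelevant,
            rec.no_audio,
            rec.short_form,
            rec.duplicate,
            rec.advertisement,
        )
        for crit, failed in zip(EXCLUSION_CRITERIA, checks):
            if failed:
                tally[crit] += 1
                break
        else:
            kept.append(rec)
    return tuple(kept), tally


def _truth_categories(qualities: np.ndarray, marginal: CategoryDistribution
                      ) -> np.ndarray:
    """Map latent qualities to 0-based categories by rank quantiles.

    The videos are ranked by latent quality and sliced into contiguous
    blocks whose sizes follow the marginal, so the realised category
    distribution tracks the marginal regardless of the agreement level.
    """
    n = len(qualities)
    order = np.argsort(qualities, kind="stable")
    cum = np.round(np.cumsum(marginal.probs) * n).astype(int)
    cum[-1] = n
    truth = np.empty(n, dtype=int)
    start = 0
    for cat, stop in enumerate(cum):
        truth[order[start:stop]] = cat
        start = stop
    return truth


def generate_ratings(catalog: Sequence[VideoRecord],
                     raters: Sequence[RaterProfile],
                     agreement: float = 0.61,
                     seed: int = 0,
                     marginal: Optional[CategoryDistribution] = None,
                     na_prob_prhism: float = 0.10,
                     na_prob_discern: float = 0.0,
                     expert_noise_sd: float = 0.8) -> StudyDataset:
    """Generate the full multi-instrument rating set for a catalog.

    ``agreement`` is the target population pairwise weighted kappa for the
    overall-quality items; the copy probability theta is calibrated to it.
    PRHISM overall (0–4) and DISCERN overall (1–5) are independent copy-
    model reports of the same latent truth category.  The 13 PRHISM
    principles and 15 DISCERN items are the rater's own overall judgment
    plus Gaussian jitter (mean = the rater's severity bias, SD = the
    rater's noise), rounded and clipped to the instrument support, and
    marked NA with the given per-item probability.  Expert accuracy and
    harm are monotone maps of latent quality plus noise, stored in the
    source tool's original orientation (1 = accurate / not harmful) so the
    analysis pipeline exercises the recoding step.
    """
    if marginal is None:
        marginal = CategoryDistribution.uniform(5)
    if marginal.k != 5:
        raise ValueError("overall-quality marginal must have 5 categories")
    catalog = tuple(catalog)
    raters = tuple(raters)
    n, r = len(catalog), len(raters)
    if n == 0 or r == 0:
        raise ValueError("catalog and rater panel must be nonempty")
    theta = calibrate_theta(agreement, marginal)
    rng = np.random.default_rng(seed)
    pi = np.asarray(marginal.probs)

    quality = np.array([v.latent_quality for v in catalog])
    truth = _truth_categories(quality, marginal)

    def copy_report(size):
        copy = rng.random(size) < theta
        indep = rng.choice(5, size=size, p=pi)
        return np.where(copy, truth[:, None], indep)

    prhism_overall = copy_report((n, r))           # 0..4
    discern_overall = copy_report((n, r)) + 1      # 1..5

    bias = np.array([p.severity_bias for p in raters])
    noise = np.array([p.noise_sd for p in raters])

    def jitter_items(center, n_items, lo, hi, na_prob):
        jit = rng.normal(bias[None, :, None], noise[None, :, None],
                         size=(n, r, n_items))
        vals = np.clip(np.round(center[:, :, None] + jit), lo, hi).astype(int)
        # na_prob: scalar or per-item vector broadcast over (video, rater)
        probs = np.broadcast_to(np.asarray(na_prob, dtype=float), (n_items,))
        na = rng.random((n, r, n_items)) < probs[None, None, :]
        return vals, na

    prhism_items, prhism_na = jitter_items(prhism_overall, 13, 0, 4,
                                           na_prob_prhism)
    discern_items, discern_na = jitter_items(discern_overall, 15, 1, 5,
                                             na_prob_discern)

    # expert judgments (recoded orientation first: 5 = accurate/nonharmful);
    # the monotone map of latent quality is its rank-quantile truth category,
    # so noise-free experts are perfectly concordant with overall quality
    acc5 = np.clip(np.round(truth[:, None] + 1
                            + rng.normal(0, expert_noise_sd, (n, r))), 1, 5)
    harm5 = np.clip(np.round(truth[:, None] + 1
                             + rng.normal(0, expert_noise_sd, (n, r))), 1, 5)
    raw_acc = (6 - acc5).astype(int)   # stored in the source tool's coding
    raw_harm = (6 - harm5).astype(int)

    rows = []
    for i, video in enumerate(catalog):
        for j, rater in enumerate(raters):
            vid, rid = video.video_id, rater.rater_id
            for it in range(13):
                val = "NA" if prhism_na[i, j, it] else int(prhism_items[i, j, it])
                rows.append((vid, rid, "prhism", f"p{it+1}", val))
            rows.append((vid, rid, "prhism", "overall", int(prhism_overall[i, j])))
            for it in range(15):
                val = "NA" if discern_na[i, j, it] else int(discern_items[i, j, it])
                rows.append((vid, rid, "discern", f"d{it+1}", val))
            rows.append((vid, rid, "discern", "overall", int(discern_overall[i, j])))
            rows.append((vid, rid, "expert", "accuracy", int(raw_acc[i, j])))
            rows.append((vid, rid, "expert", "harm", int(raw_harm[i, j])))
    ratings = pd.DataFrame(rows, columns=["video_id", "rater_id", "instrument",
                                          "item", "value"])
    provenance = {
        "generator": "prhismkit.synthetic.generate_ratings",
        "seed": int(seed),
        "agreement_target": float(agreement),
        "theta": float(theta),
        "marginal": list(marginal.probs),
        "na_prob_prhism": np.asarray(na_prob_prhism, dtype=float).tolist(),
        "na_prob_discern": np.asarray(na_prob_discern, dtype=float).tolist(),
        "expert_noise_sd": float(expert_noise_sd),
        "n_videos": n,
        "n_raters": r,
    }
    return StudyDataset(catalog=catalog, raters=raters, ratings=ratings,
                        provenance=provenance)


def generate_study(n_videos: int = 60, seed: int = 0,
                   agreement: float = 0.61,
                   source_probs: Sequence[float] = TABLE1_SOURCE_PROBS,
                   quality_shift: float = 1.0,
                   marginal: Optional[CategoryDistribution] = None,
                   na_prob_prhism: float = 0.10,
                   na_prob_discern: float = 0.0,
                   rater_noise_sd: float = 0.7,
                   expert_noise_sd: float = 0.8) -> StudyDataset:
    """Catalog + default rater panel + ratings in one call.

    Defaults reproduce the motivating study's conditions: 60 videos with
    the observed source mix, 6 raters in two experience strata, and a
    target pairwise weighted kappa of 0.61 on overall quality.
    Seed-reproducible: the catalog and rating streams are derived from
    ``seed`` deterministically.
    """
    ss = np.random.SeedSequence(seed).generate_state(2) % (2 ** 31)
    catalog = generate_catalog(n_videos, seed=int(ss[0]),
                               source_probs=source_probs,
                               quality_shift=quality_shift)
    dataset = generate_ratings(catalog, default_raters(noise_sd=rater_noise_sd),
                               agreement=agreement, seed=int(ss[1]),
                               marginal=marginal,
                               na_prob_prhism=na_prob_prhism,
                               na_prob_discern=na_prob_discern,
                               expert_noise_sd=expert_noise_sd)
    dataset.provenance["top_seed"] = int(seed)
    dataset.provenance["source_probs"] = [float(p) for p in source_probs]
    dataset.provenance["quality_shift"] = float(quality_shift)
    return dataset


def summarize_catalog(catalog: Sequence[VideoRecord]) -> pd.DataFrame:
    """Catalog summary: median (range) of length/views/months and
    count (%) per source category."""
    catalog = list(catalog)
    if not catalog:
        raise ValueError("empty catalog")
    n = len(catalog)
    rows = []
    for name, vals in [
        ("video length (min)", [v.length_min for v in catalog]),
        ("views", [v.views for v in catalog]),
        ("time since posting (months)", [v.months_since_post for v in catalog]),
    ]:
        rows.append({
            "characteristic": name, "statistic": "median (range)",
            "median": float(np.median(vals)),
            "min": float(min(vals)), "max": float(max(vals)),
            "count": None, "percent": None,
        })
    for cat in range(1, 9):
        count = sum(1 for v in catalog if v.source_category == cat)
        rows.append({
            "characteristic": f"source category {cat}: "
                              f"{SOURCE_CATEGORY_LABELS[cat]}",
            "statistic": "n (%)", "median": None, "min": None, "max": None,
            "count": count, "percent": round(100.0 * count / n),
        })
    return pd.DataFrame(rows)
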