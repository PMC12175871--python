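"""Full analysis suite over a multi-instrument ratings dataset.

Given a study dataset (catalog + long-format ratings), runs:

* **Reliability** — interrater agreement (mean pairwise weighted kappa,
  90% CI) for PRHISM overall quality and DISCERN overall quality, overall
  and within subgroups (reliable vs other video sources; senior vs junior
  raters).  The primary success criterion is the lower 90% confidence
  limit exceeding a preset agreement threshold (default 0.53).
* **Validity** — per-rater intra-rater agreement (95% CI) between each
  instrument's overall quality and the recoded expert accuracy judgment,
  between the two instruments, their pooled means across raters, and the
  expert-vs-expert interrater agreement.
* **Per-item agreement** — mean pairwise kappa for each of the 13 PRHISM
  principles and 15 DISCERN items; items with NA responses fall back to
  unweighted kappa on the pairwise-complete subsets.
* **Score agreement** — agreement on the 0–100 PRHISM and modified
  DISCERN scores: weighted kappa on their 4-band classifications, ICC on
  the raw scores, and dataset-level means/SDs.

Every kappa row carries the Landis–Koch interpretation of its estimate.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import agreement as ag
from .instruments import (DiscernRating, PrhismRating, modified_discern_score,
                          prhism_category, prhism_score)
from .synthetic import StudyDataset, summarize_catalog

__all__ = [
    "AnalysisConfig",
    "ResultsRow",
    "run_reliability",
    "run_validity",
    "run_item_agreement",
    "run_score_agreement",
    "run_all",
]

PRHISM_SCALE = tuple(range(5))        # overall quality 0..4
DISCERN_SCALE = tuple(range(1, 6))    # items and overall 1..5
EXPERT_SCALE = tuple(range(1, 6))
BAND_SCALE = (1, 2, 3, 4)             # poor..excellent


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs of the analysis suite.

    90% CIs for the primary reliability analyses and 95% elsewhere; the
    primary success criterion is the lower reliability CI limit exceeding
    ``success_threshold``.
    """

    ci_level_reliability: float = 0.90
    ci_level_secondary: float = 0.95
    scheme: ag.WeightScheme = ag.WeightScheme.QUADRATIC
    success_threshold: float = 0.53
    seed: int = 0

    def __post_init__(self):
        for lv in (self.ci_level_reliability, self.ci_level_secondary):
            if not 0.0 < lv < 1.0:
                raise ValueError("CI levels must lie strictly in (0, 1)")
        object.__setattr__(self, "scheme", ag.WeightScheme(self.scheme))


@dataclass(frozen=True)
class ResultsRow:
    """One analysis estimate in the results table."""

    analysis_id: str
    subgroup: str
    instrument: str
    statistic: str            # "kappa" | "icc" | "score_mean"
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    level: float
    interpretation: str
    n_subjects: int
    n_raters_or_pairs: int
    scheme: str
    note: str = ""


RESULTS_COLUMNS = list(ResultsRow.__dataclass_fields__)


def _rows_to_frame(rows: Sequence[ResultsRow]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in rows], columns=RESULTS_COLUMNS)


# ---------------------------------------------------------------------------
# dataset -> matrices

def _pivot(ratings: pd.DataFrame, instrument: str, item: str,
           video_order: Sequence[str], rater_order: Sequence[str]) -> np.ndarray:
    """Subjects x raters object matrix for one item; NA -> None."""
    sub = ratings[(ratings["instrument"] == instrument)
                  & (ratings["item"] == item)]
    table = sub.pivot(index="video_id", columns="rater_id", values="value")
    table = table.reindex(index=list(video_order), columns=list(rater_order))
    out = np.empty(table.shape, dtype=object)
    vals = table.to_numpy()
    for idx in np.ndindex(*vals.shape):
        v = vals[idx]
        if v is None or (isinstance(v, float) and math.isnan(v)) or v == "NA":
            out[idx] = None
        else:
            out[idx] = int(v)
    return out


def _orders(dataset: StudyDataset):
    videos = [v.video_id for v in dataset.catalog]
    raters = [r.rater_id for r in dataset.raters]
    return videos, raters


def _kappa_row(analysis_id: str, subgroup: str, instrument: str,
               pa: ag.PairwiseAgreement, note: str = "") -> ResultsRow:
    return ResultsRow(
        analysis_id=analysis_id, subgroup=subgroup, instrument=instrument,
        statistic="kappa", estimate=pa.mean_kappa, se=pa.se,
        ci_low=pa.ci_low, ci_high=pa.ci_high, level=pa.ci_level,
        interpretation=ag.interpret_kappa(pa.mean_kappa),
        n_subjects=pa.n_subjects, n_raters_or_pairs=pa.n_pairs,
        scheme=pa.pair_estimates[0].scheme.value, note=note)


def _not_estimable(analysis_id: str, subgroup: str, instrument: str,
                   statistic: str, n_subjects: int, level: float,
                   scheme: str, note: str) -> ResultsRow:
    return ResultsRow(
        analysis_id=analysis_id, subgroup=subgroup, instrument=instrument,
        statistic=statistic, estimate=float("nan"), se=float("nan"),
        ci_low=float("nan"), ci_high=float("nan"), level=level,
        interpretation="not estimable", n_subjects=n_subjects,
        n_raters_or_pairs=0, scheme=scheme, note=note)


# ---------------------------------------------------------------------------
# reliability

def run_reliability(dataset: StudyDataset,
                    config: AnalysisConfig = AnalysisConfig(),
                    include_subgroups: bool = True) -> pd.DataFrame:
    """Interrater reliability of the overall-quality judgments.

    Mean pairwise weighted kappa with a jackknife CI at the reliability
    level (default 90%) for PRHISM overall and DISCERN overall, then the
    same restricted to reliable-source videos (categories 1–4) vs other
    sources, and to the senior (>10 physician-years) vs junior rater
    strata.  Each all-videos row carries a ``success`` note: whether the
    lower CI limit exceeds the success threshold.
    """
    videos, raters = _orders(dataset)
    lvl = config.ci_level_reliability
    reliable_mask = np.array([v.reliable for v in dataset.catalog])
    senior_mask = np.array([r.stratum == "senior" for r in dataset.raters])

    rows = []
    for instrument, scale in [("prhism", PRHISM_SCALE), ("discern", DISCERN_SCALE)]:
        matrix = _pivot(dataset.ratings, instrument, "overall", videos, raters)
        subsets = [("all videos, all raters", matrix)]
        if include_subgroups:
            subsets += [
                ("reliable sources (categories 1-4)", matrix[reliable_mask]),
                ("other sources (categories 5-8)", matrix[~reliable_mask]),
                ("senior raters (>10 y)", matrix[:, senior_mask]),
                ("junior raters (<=10 y)", matrix[:, ~senior_mask]),
            ]
        for subgroup, sub in subsets:
            aid = f"reliability_{instrument}_overall"
            if sub.shape[0] < 2 or sub.shape[1] < 2:
                rows.append(_not_estimable(
                    aid, subgroup, instrument, "kappa", sub.shape[0], lvl,
                    config.scheme.value, "fewer than 2 subjects or raters"))
                continue
            pa = ag.pairwise_mean_kappa(sub, config.scheme, level=lvl,
                                        categories=scale)
            note = ""
            if subgroup == "all videos, all raters":
                ok = pa.ci_low > config.success_threshold
                note = (f"success criterion (lower {lvl:.0%} CI limit > "
                        f"{config.success_threshold}): "
                        f"{'met' if ok else 'not met'}")
            rows.append(_kappa_row(aid, subgroup, instrument, pa, note))
    return _rows_to_frame(rows)


# ---------------------------------------------------------------------------
# validity

def _per_rater_kappas(mat_a: np.ndarray, mat_b: np.ndarray,
                      scale_a, scale_b, scheme, level):
    """Per-rater cross-instrument kappas for two aligned matrices."""
    out = []
    for j in range(mat_a.shape[1]):
        try:
            est = ag.cross_instrument_kappa(mat_a[:, j], mat_b[:, j],
                                            scale_a, scale_b, scheme, level)
        except (ag.DegenerateTableError, ValueError):
            est = None
        out.append(est)
    return out


def _pooled_mean_kappa(mat_a: np.ndarray, mat_b: np.ndarray,
                       scale_a, scale_b, scheme, level):
    """Mean of the per-rater cross-instrument kappas with a delete-one-
    video jackknife CI (shared videos make the per-rater kappas
    dependent)."""
    shift_a, shift_b = min(scale_a), min(scale_b)
    k = max(len(scale_a), len(scale_b))
    cats = tuple(range(k))
    w = ag.weight_matrix(k, scheme)
    a = np.array([[None if v is None else int(v) - shift_a for v in row]
                  for row in mat_a], dtype=object)
    b = np.array([[None if v is None else int(v) - shift_b for v in row]
                  for row in mat_b], dtype=object)

    def mean_over_raters(aa, bb):
        vals = []
        for j in range(aa.shape[1]):
            tab = ag._table_from_columns(aa[:, j], bb[:, j], cats)
            if tab is None:
                continue
            counts, n = tab
            p = counts / n
            r, c = p.sum(axis=1), p.sum(axis=0)
            p_o = (w * p).sum()
            p_e = r @ w @ c
            if p_e >= 1.0 - 1e-9:
                continue
            vals.append((p_o - p_e) / (1 - p_e))
        return (float(np.mean(vals)), len(vals)) if vals else (np.nan, 0)

    mean_k, n_valid = mean_over_raters(a, b)
    if n_valid == 0:
        return None
    n = a.shape[0]
    loo = []
    for i in range(n):
        m, nv = mean_over_raters(np.delete(a, i, axis=0), np.delete(b, i, axis=0))
        if nv > 0:
            loo.append(m)
    loo = np.asarray(loo)
    se = (float(np.sqrt((len(loo) - 1) / len(loo)
                        * ((loo - loo.mean()) ** 2).sum()))
          if len(loo) > 1 else 0.0)
    lo, hi = ag.kappa_ci(mean_k, se, level)
    return mean_k, se, lo, hi, n, n_valid


def run_validity(dataset: StudyDataset,
                 config: AnalysisConfig = AnalysisConfig()) -> pd.DataFrame:
    """Validity and intra-rater analyses against the expert standard.

    The expert subjective standard is the recoded accuracy judgment
    (5 = accurate); harm is analyzed as a parallel set of rows.  Per-rater
    kappas and pooled means are reported at the secondary level (default
    95%), as is the expert-vs-expert interrater agreement.
    """
    videos, raters = _orders(dataset)
    lvl = config.ci_level_secondary
    prh = _pivot(dataset.ratings, "prhism", "overall", videos, raters)
    dis = _pivot(dataset.ratings, "discern", "overall", videos, raters)
    raw_acc = _pivot(dataset.ratings, "expert", "accuracy", videos, raters)
    raw_harm = _pivot(dataset.ratings, "expert", "harm", videos, raters)
    # recode so 5 = accurate / nonharmful
    acc = np.vectorize(lambda v: None if v is None else 6 - v,
                       otypes=[object])(raw_acc)
    harm = np.vectorize(lambda v: None if v is None else 6 - v,
                        otypes=[object])(raw_harm)

    comparisons = [
        ("validity_prhism_vs_expert_accuracy", "prhism vs expert",
         prh, acc, PRHISM_SCALE, EXPERT_SCALE),
        ("validity_discern_vs_expert_accuracy", "discern vs expert",
         dis, acc, DISCERN_SCALE, EXPERT_SCALE),
        ("intra_rater_prhism_vs_discern", "prhism vs discern",
         prh, dis, PRHISM_SCALE, DISCERN_SCALE),
        ("validity_prhism_vs_expert_harm", "prhism vs expert harm",
         prh, harm, PRHISM_SCALE, EXPERT_SCALE),
        ("validity_discern_vs_expert_harm", "discern vs expert harm",
         dis, harm, DISCERN_SCALE, EXPERT_SCALE),
    ]
    rows = []
    for aid, instrument, mat_a, mat_b, sc_a, sc_b in comparisons:
        ests = _per_rater_kappas(mat_a, mat_b, sc_a, sc_b, config.scheme, lvl)
        for rater, est in zip(raters, ests):
            if est is None:
                rows.append(_not_estimable(aid, f"rater {rater}", instrument,
                                           "kappa", mat_a.shape[0], lvl,
                                           config.scheme.value,
                                           "degenerate table"))
                continue
            rows.append(ResultsRow(
                analysis_id=aid, subgroup=f"rater {rater}",
                instrument=instrument, statistic="kappa",
                estimate=est.kappa, se=est.se, ci_low=est.ci_low,
                ci_high=est.ci_high, level=lvl,
                interpretation=ag.interpret_kappa(est.kappa),
                n_subjects=est.n, n_raters_or_pairs=1,
                scheme=est.scheme.value))
        pooled = _pooled_mean_kappa(mat_a, mat_b, sc_a, sc_b, config.scheme, lvl)
        if pooled is None:
            rows.append(_not_estimable(aid, "pooled over raters", instrument,
                                       "kappa", mat_a.shape[0], lvl,
                                       config.scheme.value, "degenerate"))
        else:
            mean_k, se, lo, hi, n, n_valid = pooled
            rows.append(ResultsRow(
                analysis_id=aid, subgroup="pooled over raters",
                instrument=instrument, statistic="kappa", estimate=mean_k,
                se=se, ci_low=lo, ci_high=hi, level=lvl,
                interpretation=ag.interpret_kappa(mean_k), n_subjects=n,
                n_raters_or_pairs=n_valid, scheme=config.scheme.value,
                note="mean of per-rater kappas, delete-one-video jackknife CI"))

    pa = ag.pairwise_mean_kappa(acc, config.scheme, level=lvl,
                                categories=EXPERT_SCALE)
    rows.append(_kappa_row("expert_vs_expert_accuracy",
                           "all videos, all raters", "expert accuracy", pa))
    return _rows_to_frame(rows)


# ---------------------------------------------------------------------------
# per-item agreement

def run_item_agreement(dataset: StudyDataset,
                       config: AnalysisConfig = AnalysisConfig()) -> pd.DataFrame:
    """Mean pairwise kappa for every PRHISM principle and DISCERN item.

    Items containing NA responses are assessed with unweighted (identity)
    kappa on the pairwise-complete subsets, mirroring the treatment of
    not-applicable judgments; complete items use the configured weight
    scheme.  The scheme actually used is recorded per row.
    """
    videos, raters = _orders(dataset)
    lvl = config.ci_level_secondary
    rows = []
    specs = ([("prhism", f"p{i}", (0, 1, 2, 3, 4)) for i in range(1, 14)]
             + [("discern", f"d{i}", DISCERN_SCALE) for i in range(1, 16)])
    for instrument, item, scale in specs:
        matrix = _pivot(dataset.ratings, instrument, item, videos, raters)
        has_na = any(v is None for v in matrix.ravel())
        scheme = ag.WeightScheme.IDENTITY if has_na else config.scheme
        aid = f"item_agreement_{instrument}_{item}"
        note = "NA present: unweighted kappa on pairwise-complete subsets" \
            if has_na else ""
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pa = ag.pairwise_mean_kappa(matrix, scheme, level=lvl,
                                            categories=scale)
        except (ag.DegenerateTableError, ValueError) as exc:
            rows.append(_not_estimable(aid, "all videos", instrument, "kappa",
                                       matrix.shape[0], lvl, scheme.value,
                                       f"not estimable: {exc}"))
            continue
        rows.append(_kappa_row(aid, "all videos", instrument, pa, note))
    return _rows_to_frame(rows)


# ---------------------------------------------------------------------------
# score-level agreement

def _score_matrices(dataset: StudyDataset):
    """Per-(video, rater) PRHISM and modified DISCERN scores and bands.

    Returns (prhism_scores, discern_scores, prhism_bands, discern_bands)
    as subjects x raters arrays (NaN / None where no item was applicable).
    """
    videos, raters = _orders(dataset)
    n, r = len(videos), len(raters)
    p_items = [_pivot(dataset.ratings, "prhism", f"p{i}", videos, raters)
               for i in range(1, 14)]
    p_overall = _pivot(dataset.ratings, "prhism", "overall", videos, raters)
    d_items = [_pivot(dataset.ratings, "discern", f"d{i}", videos, raters)
               for i in range(1, 16)]
    d_overall = _pivot(dataset.ratings, "discern", "overall", videos, raters)

    p_scores = np.full((n, r), np.nan)
    d_scores = np.full((n, r), np.nan)
    p_bands = np.empty((n, r), dtype=object)
    d_bands = np.empty((n, r), dtype=object)
    for i in range(n):
        for j in range(r):
            try:
                sc = prhism_score(PrhismRating(
                    tuple(m[i, j] for m in p_items), int(p_overall[i, j])))
                p_scores[i, j] = sc.score
                p_bands[i, j] = sc.category.code
            except ValueError:
                p_bands[i, j] = None
            try:
                sc = modified_discern_score(DiscernRating(
                    tuple(m[i, j] for m in d_items), int(d_overall[i, j])))
                d_scores[i, j] = sc.score
                d_bands[i, j] = prhism_category(sc.score).code
            except ValueError:
                d_bands[i, j] = None
    return p_scores, d_scores, p_bands, d_bands


def run_score_agreement(dataset: StudyDataset,
                        config: AnalysisConfig = AnalysisConfig()) -> pd.DataFrame:
    """Agreement on the 0–100 scores.

    (a) Mean pairwise weighted kappa on the 4-band classification of the
    PRHISM score and of the modified DISCERN score — the PRHISM bands are
    reused for the modified DISCERN score (which has no published banding)
    so both kappas live on a common support; (b) ICC (two-way random,
    absolute agreement, single rater) on the raw scores; (c) dataset-level
    mean (SD) of both scores.
    """
    lvl = config.ci_level_secondary
    p_scores, d_scores, p_bands, d_bands = _score_matrices(dataset)
    rows = []
    band_note = ("modified DISCERN score classified with the PRHISM bands "
                 "(no published banding of its own)")
    for instrument, bands, scores, note in [
            ("prhism score", p_bands, p_scores, ""),
            ("modified discern score", d_bands, d_scores, band_note)]:
        aid = f"score_band_agreement_{instrument.split()[0]}"
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pa = ag.pairwise_mean_kappa(bands, config.scheme, level=lvl,
                                            categories=BAND_SCALE)
            rows.append(_kappa_row(aid, "all videos", instrument, pa, note))
        except (ag.DegenerateTableError, ValueError) as exc:
            rows.append(_not_estimable(aid, "all videos", instrument, "kappa",
                                       bands.shape[0], lvl,
                                       config.scheme.value, str(exc)))
        aid = f"score_icc_{instrument.split()[0]}"
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est = ag.icc(scores, level=lvl)
            rows.append(ResultsRow(
                analysis_id=aid, subgroup="all videos", instrument=instrument,
                statistic="icc", estimate=est.icc, se=float("nan"),
                ci_low=est.ci_low, ci_high=est.ci_high, level=lvl,
                interpretation=est.model_label, n_subjects=est.n_subjects,
                n_raters_or_pairs=est.n_raters, scheme="", note=note))
        except ValueError as exc:
            rows.append(_not_estimable(aid, "all videos", instrument, "icc",
                                       scores.shape[0], lvl, "", str(exc)))
        vals = scores[~np.isnan(scores)]
        rows.append(ResultsRow(
            analysis_id=f"score_mean_{instrument.split()[0]}",
            subgroup="all videos", instrument=instrument,
            statistic="score_mean", estimate=float(vals.mean()),
            se=float(vals.std(ddof=1)), ci_low=float("nan"),
            ci_high=float("nan"), level=float("nan"),
            interpretation="mean (se column holds SD)",
            n_subjects=scores.shape[0], n_raters_or_pairs=scores.shape[1],
            scheme="", note=note))
    return _rows_to_frame(rows)


# ---------------------------------------------------------------------------
# orchestration

def run_all(dataset: StudyDataset, config: AnalysisConfig = AnalysisConfig(),
            out_dir: Optional[str] = None) -> dict:
    """Run every analysis stage; optionally write the report bundle.

    Returns a dict with the results table, the catalog summary, the
    plain-text report and the failures of any stage.  With ``out_dir``
    set, writes ``results.csv``, ``catalog_summary.csv``, ``report.txt``
    and ``provenance.json`` (byte-identical across reruns with the same
    dataset and config).
    """
    stages = [
        ("reliability", run_reliability),
        ("validity", run_validity),
        ("item_agreement", run_item_agreement),
        ("score_agreement", run_score_agreement),
    ]
    frames, failures = [], {}
    for name, fn in stages:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                frames.append(fn(dataset, config))
        except Exception as exc:  # noqa: BLE001 - partial bundle on any failure
            failures[name] = f"{type(exc).__name__}: {exc}"
    results = (pd.concat(frames, ignore_index=True)
               if frames else _rows_to_frame([]))
    catalog_summary = summarize_catalog(dataset.catalog)
    report = _render_report(dataset, config, results, failures)
    bundle = {
        "results": results,
        "catalog_summary": catalog_summary,
        "report": report,
        "failures": failures,
        "config": config,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        results.to_csv(out / "results.csv", index=False, float_format="%.6f")
        catalog_summary.to_csv(out / "catalog_summary.csv", index=False,
                               float_format="%.6f")
        (out / "report.txt").write_text(report)
        prov = dict(dataset.provenance)
        prov["analysis_config"] = {
            "ci_level_reliability": config.ci_level_reliability,
            "ci_level_secondary": config.ci_level_secondary,
            "scheme": config.scheme.value,
            "success_threshold": config.success_threshold,
            "seed": config.seed,
        }
        (out / "provenance.json").write_text(
            json.dumps(prov, indent=2, sort_keys=True) + "\n")
    return bundle


def _render_report(dataset: StudyDataset, config: AnalysisConfig,
                   results: pd.DataFrame, failures: dict) -> str:
    lines = [
        "Rater-agreement analysis report",
        "=" * 32,
        f"videos: {len(dataset.catalog)}  raters: {len(dataset.raters)}",
        f"weight scheme: {config.scheme.value}; reliability CI "
        f"{config.ci_level_reliability:.0%}, secondary CI "
        f"{config.ci_level_secondary:.0%}",
        "rater strata: senior = more than 10 physician-years "
        "(a '10 or more' reading would shift a rater with exactly 10 years "
        "into the senior stratum)",
        "",
    ]
    for _, row in results.iterrows():
        if row["statistic"] == "kappa" and not math.isnan(row["estimate"]):
            lines.append(
                f"{row['analysis_id']} [{row['subgroup']}]: kappa="
                f"{row['estimate']:.2f} ({row['level']:.0%} CI "
                f"{row['ci_low']:.2f} to {row['ci_high']:.2f}), "
                f"indicating {row['interpretation']} agreement."
                + (f" {row['note']}" if row["note"] else ""))
        elif row["statistic"] == "icc" and not math.isnan(row["estimate"]):
            lines.append(
                f"{row['analysis_id']} [{row['subgroup']}]: ICC="
                f"{row['estimate']:.2f} ({row['level']:.0%} CI "
                f"{row['ci_low']:.2f} to {row['ci_high']:.2f}).")
        elif row["statistic"] == "score_mean":
            lines.append(
                f"{row['analysis_id']}: mean {row['estimate']:.1f} "
                f"(SD {row['se']:.1f}).")
        elif row["interpretation"] == "not estimable":
            lines.append(f"{row['analysis_id']} [{row['subgroup']}]: "
                         f"not estimable ({row['note']}).")
    if failures:
        lines.append("")
        lines.append("FAILED STAGES:")
        for name, msg in sorted(failures.items()):
            lines.append(f"  {name}: {msg}")
    return "\n".join(lines) + "\n"
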