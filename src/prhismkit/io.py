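"""Reading and writing the package's CSV dialects.

Ratings travel in long format — one row per (video, rater, instrument,
item, value) — with the literal token ``NA`` marking a not-applicable
item.  Empty cells are rejected rather than coerced: a blank value is a
data error, not a judgment that an item did not apply.
"""

from __future__ import annotations

import json
import re
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import pandas as pd

from .synthetic import RaterProfile, StudyDataset, VideoRecord

RATINGS_COLUMNS = ["video_id", "rater_id", "instrument", "item", "value"]

_VALID_ITEMS = {
    "prhism": {f"p{i}" for i in range(1, 14)} | {"overall"},
    "discern": {f"d{i}" for i in range(1, 16)} | {"overall"},
    "expert": {"accuracy", "harm"},
}

_VALUE_RANGE = {
    "prhism": (0, 4),
    "discern": (1, 5),
    "expert": (1, 5),
}


class RatingsFormatError(ValueError):
    """Raised when a ratings file violates the long-format contract."""


def read_ratings(path) -> pd.DataFrame:
    """Read and validate a long-format ratings CSV.

    Enforces the exact header, known instruments and items, integer
    values within each instrument's range, and the ``NA`` token (only on
    NA-able items — never on an overall judgment or expert item).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in RATINGS_COLUMNS if c not in df.columns]
    if missing:
        raise RatingsFormatError(
            f"ratings file {path} is missing required columns: {missing}; "
            f"expected header {RATINGS_COLUMNS}")
    extra = [c for c in df.columns if c not in RATINGS_COLUMNS]
    if extra:
        raise RatingsFormatError(f"unexpected columns in ratings file: {extra}")
    if df.empty:
        raise RatingsFormatError(f"ratings file {path} contains no rows")

    bad_instr = set(df["instrument"]) - set(_VALID_ITEMS)
    if bad_instr:
        raise RatingsFormatError(f"unknown instruments: {sorted(bad_instr)}")
    for instr, group in df.groupby("instrument"):
        bad_items = set(group["item"]) - _VALID_ITEMS[instr]
        if bad_items:
            raise RatingsFormatError(
                f"unknown {instr} items: {sorted(bad_items)}")
        lo, hi = _VALUE_RANGE[instr]
        for val, item in zip(group["value"], group["item"]):
            if val == "":
                raise RatingsFormatError(
                    "empty value cell encountered; use the literal token "
                    "'NA' for not-applicable items")
            if val == "NA":
                if item == "overall" or instr == "expert":
                    raise RatingsFormatError(
                        f"{instr} {item} may not be NA")
                continue
            if not re.fullmatch(r"-?\d+", val) or not lo <= int(val) <= hi:
                raise RatingsFormatError(
                    f"value {val!r} invalid for {instr} (allowed {lo}..{hi} or NA)")
    dup = df.duplicated(subset=["video_id", "rater_id", "instrument", "item"])
    if dup.any():
        raise RatingsFormatError(
            f"{int(dup.sum())} duplicate (video, rater, instrument, item) rows")
    return df.reset_index(drop=True)


def write_ratings(ratings: pd.DataFrame, path) -> None:
    ratings.to_csv(path, index=False, columns=RATINGS_COLUMNS)


_CATALOG_COLUMNS = [
    "video_id", "source_category", "reliable", "length_min", "views",
    "months_since_post", "latent_quality", "language_other", "irrelevant",
    "no_audio", "short_form", "duplicate", "advertisement",
]


def write_catalog(catalog: Sequence[VideoRecord], path) -> None:
    rows = []
    for v in catalog:
        d = asdict(v)
        d["reliable"] = v.reliable
        rows.append(d)
    pd.DataFrame(rows)[_CATALOG_COLUMNS].to_csv(path, index=False,
                                                float_format="%.6f")


def read_catalog(path) -> tuple:
    df = pd.read_csv(path)
    missing = [c for c in _CATALOG_COLUMNS if c not in df.columns and
               c != "reliable"]
    if missing:
        raise RatingsFormatError(
            f"catalog file {path} is missing required columns: {missing}")
    records = []
    for _, row in df.iterrows():
        records.append(VideoRecord(
            video_id=str(row["video_id"]),
            source_category=int(row["source_category"]),
            length_min=float(row["length_min"]),
            views=int(row["views"]),
            months_since_post=int(row["months_since_post"]),
            latent_quality=float(row["latent_quality"]),
            language_other=bool(row.get("language_other", False)),
            irrelevant=bool(row.get("irrelevant", False)),
            no_audio=bool(row.get("no_audio", False)),
            short_form=bool(row.get("short_form", False)),
            duplicate=bool(row.get("duplicate", False)),
            advertisement=bool(row.get("advertisement", False)),
        ))
    return tuple(records)


def write_raters(raters: Sequence[RaterProfile], path) -> None:
    rows = []
    for r in raters:
        d = asdict(r)
        d["stratum"] = r.stratum
        rows.append(d)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6f")


def write_study(dataset: StudyDataset, out_dir) -> dict:
    """Write a full fixture directory: catalog, raters, ratings and a
    provenance JSON.  Returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "catalog": out / "catalog.csv",
        "raters": out / "raters.csv",
        "ratings": out / "ratings.csv",
        "provenance": out / "provenance.json",
    }
    write_catalog(dataset.catalog, paths["catalog"])
    write_raters(dataset.raters, paths["raters"])
    write_ratings(dataset.ratings, paths["ratings"])
    paths["provenance"].write_text(
        json.dumps(dataset.provenance, indent=2, sort_keys=True) + "\n")
    return {k: str(v) for k, v in paths.items()}
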