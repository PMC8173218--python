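"""Deprivation-dataset construction rules.

Two raters independently flag images that contain faces (human or
non-human primate, artwork, cartoons, artifacts).  Dataset screening
removes every image flagged by *either* rater, then drops categories
whose remaining training images fall below a minimum count (strictly
fewer than ``min_images``).  Order matters: image removal runs first,
category pruning second; the pipeline enforces this.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ScreeningManifest",
    "ScreeningReport",
    "remove_flagged_images",
    "prune_small_categories",
    "screen",
]

MANIFEST_COLUMNS = ["image_id", "category", "rater1", "rater2", "split"]


@dataclass
class ScreeningManifest:
    """Image manifest: one row per image with per-rater face flags.

    ``frame`` columns: image_id (unique), category, rater1/rater2 (bool),
    split ("train" | "val").
    """

    frame: pd.DataFrame

    def __post_init__(self):
        df = self.frame
        missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"manifest missing columns {missing}")
        if df["image_id"].duplicated().any():
            dupes = df["image_id"][df["image_id"].duplicated()].head().tolist()
            raise ValueError(f"duplicate image_id values, e.g. {dupes}")
        bad = set(df["split"].unique()) - {"train", "val"}
        if bad:
            raise ValueError(f"split must be train/val, got {sorted(bad)}")
        self.frame = df.astype({"rater1": bool, "rater2": bool}).reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def categories(self) -> np.ndarray:
        return self.frame["category"].unique()

    def to_csv(self, path) -> None:
        out = self.frame.copy()
        out["rater1"] = out["rater1"].astype(int)
        out["rater2"] = out["rater2"].astype(int)
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ScreeningManifest":
        df = pd.read_csv(path, dtype={"image_id": str, "category": str, "split": str})
        df["rater1"] = df["rater1"].astype(int).astype(bool)
        df["rater2"] = df["rater2"].astype(int).astype(bool)
        return cls(df)


@dataclass
class ScreeningReport:
    """Outcome of one screening step: retained manifest plus bookkeeping."""

    retained: ScreeningManifest
    removed: pd.DataFrame
    removed_images_per_category: pd.Series
    removed_categories: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    @property
    def n_removed(self) -> int:
        return len(self.removed)

    def summary(self) -> dict:
        return {
            "n_input": len(self.retained) + self.n_removed,
            "n_retained": len(self.retained),
            "n_removed": self.n_removed,
            "removed_categories": list(self.removed_categories),
            "removed_images_per_category": {
                str(k): int(v) for k, v in self.removed_images_per_category.items()
            },
            **self.metadata,
        }

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.retained.to_csv(outdir / "retained.csv")
        removed = self.removed.copy()
        if len(removed):
            removed["rater1"] = removed["rater1"].astype(int)
            removed["rater2"] = removed["rater2"].astype(int)
        removed.to_csv(outdir / "removed.csv", index=False)
        with open(outdir / "screening_summary.json", "w") as f:
            json.dump(self.summary(), f, indent=2, sort_keys=True)


def remove_flagged_images(manifest: ScreeningManifest) -> ScreeningReport:
    """Remove every image judged by either rater as containing a face."""
    df = manifest.frame
    flagged = df["rater1"] | df["rater2"]
    removed = df[flagged]
    per_cat = removed.groupby("category").size()
    per_cat = per_cat.reindex(df["category"].unique(), fill_value=0)
    return ScreeningReport(
        retained=ScreeningManifest(df[~flagged].copy()),
        removed=removed.copy(),
        removed_images_per_category=per_cat,
        removed_categories=[],
        metadata={"rule": "either-rater flag", "stage": "remove_flagged_images"},
    )


def prune_small_categories(manifest: ScreeningManifest, min_images: int = 640) -> ScreeningReport:
    """Drop categories with strictly fewer than ``min_images`` training images.

    Only training-split images count toward the threshold; validation images
    of a dropped category are dropped with it.
    """
    if min_images < 1:
        raise ValueError("min_images must be >= 1")
    df = manifest.frame
    train_counts = (
        df[df["split"] == "train"].groupby("category").size()
        .reindex(df["category"].unique(), fill_value=0)
    )
    dropped = train_counts[train_counts < min_images].index.tolist()
    removed_mask = df["category"].isin(dropped)
    removed = df[removed_mask]
    per_cat = removed.groupby("category").size()
    per_cat = per_cat.reindex(df["category"].unique(), fill_value=0)
    return ScreeningReport(
        retained=ScreeningManifest(df[~removed_mask].copy()),
        removed=removed.copy(),
        removed_images_per_category=per_cat,
        removed_categories=dropped,
        metadata={
            "rule": f"train-split count < {min_images}",
            "stage": "prune_small_categories",
            "count_basis": "train-split images only",
        },
    )


def screen(manifest: ScreeningManifest, min_images: int = 640) -> tuple[ScreeningReport, ScreeningReport]:
    """Full screening: flagged-image removal, then small-category pruning."""
    step1 = remove_flagged_images(manifest)
    step2 = prune_small_categories(step1.retained, min_images=min_images)
    return step1, step2
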