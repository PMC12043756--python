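"""Cohort-level aggregation: per-level hit percentages and Einstichpunkt
statistics across many sides.

Mirrors the study design of running the single-side analysis on every side of
a cohort and summarising (a) at each horizontal level, the percentage of sides
where the cave can be hit (and hit easily), and (b) the distribution of the
simulated Härtel Einstichpunkt heights.  Sides whose foramen cannot be
traversed at all are reported explicitly, never silently dropped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .phantom import Scene
from .trajectory import (
    DEFAULT_HEIGHTS,
    DEFAULT_N_RAYS,
    DEFAULT_SLIT_THRESHOLD_MM,
    NoPatentForamenError,
    TrajectoryContext,
    build_aperture,
    hartel_axis,
    recommend_entry,
    scan_entry_line,
)


@dataclass
class CohortConfig:
    n_rays: int = DEFAULT_N_RAYS
    heights: np.ndarray = field(default_factory=lambda: DEFAULT_HEIGHTS.copy())
    slit_threshold: float = DEFAULT_SLIT_THRESHOLD_MM
    soft_tissue_offset: float = 0.0
    target_height: float = -2.0
    sample_seed: int = 0

    def to_dict(self) -> dict:
        return {
            "n_rays": self.n_rays,
            "heights_mm": [float(h) for h in self.heights],
            "slit_threshold_mm": self.slit_threshold,
            "soft_tissue_offset_mm": self.soft_tissue_offset,
            "target_height_mm": self.target_height,
            "sample_seed": self.sample_seed,
        }


@dataclass
class CohortSummary:
    n_sides: int
    per_level_hit_pct: dict[float, float]  # easy or possible
    per_level_easy_pct: dict[float, float]
    einstich_heights: list[float]
    span_table: pd.DataFrame
    level_table: pd.DataFrame = field(repr=False)
    failures: list[dict] = field(default_factory=list)
    config: CohortConfig = field(default_factory=CohortConfig)

    @property
    def einstich_mean(self) -> float:
        return float(np.mean(self.einstich_heights))

    @property
    def einstich_median(self) -> float:
        return float(np.median(self.einstich_heights))

    def hit_pct_at(self, height: float, easy_only: bool = False) -> float:
        d = self.per_level_easy_pct if easy_only else self.per_level_hit_pct
        return d[float(height)]

    def to_dict(self) -> dict:
        return {
            "n_sides": self.n_sides,
            "n_failures": len(self.failures),
            "failures": self.failures,
            "einstich_heights_mm": [float(h) for h in self.einstich_heights],
            "einstich_mean_mm": self.einstich_mean if self.einstich_heights else None,
            "einstich_median_mm": self.einstich_median if self.einstich_heights else None,
            "per_level_hit_pct": {str(k): v for k, v in self.per_level_hit_pct.items()},
            "per_level_easy_pct": {str(k): v for k, v in self.per_level_easy_pct.items()},
            "mean_extreme_span_mm": _nanmean(self.span_table["extreme_width_mm"]),
            "mean_easy_span_mm": _nanmean(self.span_table["easy_width_mm"]),
            "config": self.config.to_dict(),
        }

    def save(self, outdir, figures: bool = True) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "summary.json").write_text(json.dumps(self.to_dict(), indent=2))
        self.span_table.to_csv(out / "spans.csv", index=False)
        self.level_table.to_csv(out / "levels.csv", index=False)
        if figures:
            plot_levels(self.level_table, out / "fig_levels.png")
            plot_spans(self.span_table, out / "fig_spans.png")


def _nanmean(col: pd.Series) -> float | None:
    vals = col.dropna()
    return float(vals.mean()) if len(vals) else None


def run_cohort(scenes: Iterable[Scene], config: CohortConfig | None = None) -> CohortSummary:
    """Run aperture extraction, entry-line scanning and the Härtel axis on
    every side and aggregate.

    Deterministic given the scenes and config.  Aggregation is
    permutation-invariant over sides (per-level percentages and Einstichpunkt
    statistics do not depend on scene order).
    """
    if config is None:
        config = CohortConfig()
    heights = np.asarray(config.heights, dtype=float)
    span_rows = []
    level_records = []  # one row per (side, height)
    einstich = []
    failures = []
    n_ok = 0
    for idx, scene in enumerate(scenes):
        try:
            aperture = build_aperture(scene)
            ctx = TrajectoryContext(scene, aperture)
            span = scan_entry_line(
                scene,
                aperture,
                heights=heights,
                n_rays=config.n_rays,
                slit_threshold=config.slit_threshold,
                context=ctx,
            )
            hx = hartel_axis(scene, aperture, context=ctx)
        except NoPatentForamenError as exc:
            failures.append({"index": idx, "side": scene.side, "error": str(exc)})
            continue
        n_ok += 1
        try:
            rec = recommend_entry(
                span,
                soft_tissue_offset=config.soft_tissue_offset,
                target_height=config.target_height,
            )
            rec_height, downgraded = rec.height, rec.downgraded
        except ValueError:
            rec_height, downgraded = None, None
        einstich.append(float(hx.einstich_height))
        span_rows.append(
            {
                "index": idx,
                "side": scene.side,
                "lower_extreme_mm": span.lower_extreme,
                "upper_extreme_mm": span.upper_extreme,
                "lower_easy_mm": span.lower_easy,
                "upper_easy_mm": span.upper_easy,
                "extreme_width_mm": span.extreme_width,
                "easy_width_mm": span.easy_width,
                "einstich_height_mm": float(hx.einstich_height),
                "recommended_height_mm": rec_height,
                "recommendation_downgraded": downgraded,
            }
        )
        t = span.table.copy()
        t.insert(0, "index", idx)
        t.insert(1, "side", scene.side)
        level_records.append(t)

    span_table = pd.DataFrame(span_rows)
    per_hit: dict[float, float] = {}
    per_easy: dict[float, float] = {}
    if level_records:
        levels = pd.concat(level_records, ignore_index=True)
        for h in heights:
            rows = levels[levels["height_mm"] == h]
            if len(rows) == 0:
                continue
            per_hit[float(h)] = 100.0 * float(
                (rows["class"].isin(["easy", "possible"])).mean()
            )
            per_easy[float(h)] = 100.0 * float((rows["class"] == "easy").mean())
        level_table = (
            levels.groupby("height_mm")
            .agg(
                hit_pct=("class", lambda c: 100.0 * c.isin(["easy", "possible"]).mean()),
                easy_pct=("class", lambda c: 100.0 * (c == "easy").mean()),
                mean_fraction=("fraction", "mean"),
                mean_medial_fraction=("medial_fraction", "mean"),
                slitlike_pct=("slitlike", lambda s: 100.0 * s.mean()),
            )
            .reset_index()
        )
    else:
        level_table = pd.DataFrame(
            columns=["height_mm", "hit_pct", "easy_pct", "mean_fraction",
                     "mean_medial_fraction", "slitlike_pct"]
        )
    return CohortSummary(
        n_sides=n_ok,
        per_level_hit_pct=per_hit,
        per_level_easy_pct=per_easy,
        einstich_heights=einstich,
        span_table=span_table,
        level_table=level_table,
        failures=failures,
        config=config,
    )


def plot_levels(level_table: pd.DataFrame, path) -> None:
    """Bar chart of per-level hit percentages (possible+easy, and easy only)."""
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 4))
    h = level_table["height_mm"]
    ax.bar(h, level_table["hit_pct"], width=0.9, color="#b0c4de", label="possible or easy")
    ax.bar(h, level_table["easy_pct"], width=0.9, color="#2f5d8a", label="easy")
    ax.set_xlabel("height above horizontal plane (mm)")
    ax.set_ylabel("sides with a hit (%)")
    ax.legend(loc="upper right")
    ax.set_ylim(0, 105)
    fig.tight_layout()
    fig.savefig(path, dpi=130)
    plt.close(fig)


def plot_spans(span_table: pd.DataFrame, path) -> None:
    """Per-side span chart: extreme span (light), easy span (dark), Einstichpunkt (dot)."""
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 4))
    for i, row in span_table.reset_index(drop=True).iterrows():
        if row["lower_extreme_mm"] is not None and not pd.isna(row["lower_extreme_mm"]):
            ax.vlines(i, row["lower_extreme_mm"], row["upper_extreme_mm"],
                      color="#b0c4de", lw=6)
        if row["lower_easy_mm"] is not None and not pd.isna(row["lower_easy_mm"]):
            ax.vlines(i, row["lower_easy_mm"], row["upper_easy_mm"],
                      color="#2f5d8a", lw=6)
        ax.plot(i, row["einstich_height_mm"], "o", color="#c0392b", ms=4)
    ax.axhline(0.0, color="k", lw=0.8)
    ax.set_xlabel("side")
    ax.set_ylabel("height above horizontal plane (mm)")
    fig.tight_layout()
    fig.savefig(path, dpi=130)
    plt.close(fig)
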