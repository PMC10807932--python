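"""End-to-end patient characterization and cohort statistics.

``characterize`` runs the four geometric stages in order — centerline
extraction, tortuosity analysis, calcium detection, calcium quantification —
on aligned (image, coronary mask, aorta mask) inputs and assembles a
:class:`PatientReport` with a per-zone cross table and provenance (resolved
config, its hash, package version, per-stage wall time).  ``cohort_analysis``
reproduces the shape of the population statistics: per-condition
Mann-Whitney tables, an odds-ratio table of tortuosity incidence, a zone
ANOVA and a tortuosity-score threshold sweep of the calcium features.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calcium import CacParams, CalciumReport, analyze_calcium
from .centerline import CenterlineParams, CenterlineTree, build_tree
from .stats import ContingencyTable2x2, anova_oneway, mann_whitney, odds_ratio
from .tortuosity import TortuosityParams, TortuositySummary, summarize_tortuosity
from .volume import ImageVolume, LabelMap

__all__ = ["PatientReport", "characterize", "cohort_analysis", "resolve_config"]

logger = logging.getLogger("corochar")

ZONES = ("proximal", "medial", "distal")

REPORT_SCHEMA_VERSION = 1


def resolve_config(config: dict | None) -> dict:
    """Merge a per-module config dict into fully resolved parameter sets."""
    config = config or {}
    return {
        "centerline": dataclasses.asdict(CenterlineParams(**config.get("centerline", {}))),
        "tortuosity": dataclasses.asdict(TortuosityParams(**config.get("tortuosity", {}))),
        "calcium": dataclasses.asdict(CacParams(**config.get("calcium", {}))),
    }


def _config_hash(resolved: dict) -> str:
    return hashlib.sha256(json.dumps(resolved, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class PatientReport:
    tortuosity: TortuositySummary
    calcium: CalciumReport
    trees: list[CenterlineTree]
    zone_table: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    schema_version: int = REPORT_SCHEMA_VERSION

    def to_dict(self) -> dict:
        t, c = self.tortuosity, self.calcium
        return {
            "schema_version": self.schema_version,
            "tortuosity": {
                "ts": t.ts,
                "severity": t.severity,
                "n_branches": t.n_branches,
                "lt_p95": t.lt_p95,
                "ta_p95_deg": t.ta_p95_deg,
                "tract_tortuosity": t.tract_tortuosity,
                "lt_p95_by_zone": t.lt_p95_by_zone,
                "ta_p95_by_zone": t.ta_p95_by_zone,
                "bends": [dataclasses.asdict(b) for b in t.bends],
            },
            "calcium": {
                "theta_hu": c.theta_hu,
                "vs_total_mm3": c.vs_total_mm3,
                "vs_by_zone": c.vs_by_zone,
                "ppv_percent": c.ppv_percent,
                "shortest_distance_mm": c.shortest_distance_mm,
                "longest_distance_mm": c.longest_distance_mm,
                "lesions": [
                    {
                        "volume_mm3": l.volume_mm3,
                        "extent_mm": l.extent_mm,
                        "min_abscissa_mm": l.min_abscissa_mm,
                        "max_abscissa_mm": l.max_abscissa_mm,
                        "zone": l.zone,
                        "mean_hu": l.mean_hu,
                    }
                    for l in c.lesions
                ],
            },
            "zone_table": self.zone_table,
            "provenance": json.loads(json.dumps(self.provenance)),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def lesions_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.to_dict()["calcium"]["lesions"])

    def feature_row(self) -> dict:
        """Flat per-patient feature vector for cohort tables."""
        d = self.to_dict()
        row = {
            "ts": d["tortuosity"]["ts"],
            "lt_p95": d["tortuosity"]["lt_p95"],
            "ta_p95_deg": d["tortuosity"]["ta_p95_deg"],
            "vs_total_mm3": d["calcium"]["vs_total_mm3"],
            "ppv_percent": d["calcium"]["ppv_percent"],
        }
        lesions = d["calcium"]["lesions"]
        row["calcium_extent_mm"] = (
            float(np.mean([l["extent_mm"] for l in lesions])) if lesions else 0.0)
        for z in ZONES:
            row[f"tract_tortuosity_{z}"] = d["tortuosity"]["tract_tortuosity"][z]
            row[f"vs_{z}_mm3"] = d["calcium"]["vs_by_zone"][z]
        return row


def characterize(
    image: ImageVolume,
    coronary: LabelMap,
    aorta: LabelMap,
    config: dict | None = None,
) -> PatientReport:
    """Run centerlines -> tortuosity -> calcium detection -> calcium scoring."""
    image.check_same_grid(coronary, "image and coronary mask")
    image.check_same_grid(aorta, "image and aorta mask")
    resolved = resolve_config(config)
    timings: dict[str, float] = {}

    def _stage(name, fn):
        t0 = time.perf_counter()
        try:
            out = fn()
        except Exception as exc:  # annotate with the failing stage
            digest = hashlib.sha256(np.ascontiguousarray(image.data).tobytes()).hexdigest()[:12]
            raise RuntimeError(f"stage '{name}' failed on input {digest}: {exc}") from exc
        timings[name] = round(time.perf_counter() - t0, 3)
        logger.info("stage %s finished in %.2f s", name, timings[name])
        return out

    trees = _stage("centerline", lambda: build_tree(
        coronary, aorta, CenterlineParams(**resolved["centerline"])))
    tort = _stage("tortuosity", lambda: summarize_tortuosity(
        trees, TortuosityParams(**resolved["tortuosity"])))
    cac = _stage("calcium", lambda: analyze_calcium(
        image, coronary, aorta, trees, CacParams(**resolved["calcium"])))

    zone_table = {
        z: {
            "vs_mm3": cac.vs_by_zone[z],
            "tract_tortuosity": tort.tract_tortuosity[z],
            "lt_p95": tort.lt_p95_by_zone[z],
            "ta_p95_deg": tort.ta_p95_by_zone[z],
            "lesion_extent_mm": float(np.mean(
                [l.extent_mm for l in cac.lesions if l.zone == z]))
            if any(l.zone == z for l in cac.lesions) else 0.0,
        }
        for z in ZONES
    }
    provenance = {
        "config": resolved,
        "config_hash": _config_hash(resolved),
        "version": __version__,
        "stage_seconds": timings,
    }
    return PatientReport(tortuosity=tort, calcium=cac, trees=trees,
                         zone_table=zone_table, provenance=provenance)


# ---------------------------------------------------------------------------
# cohort statistics


_CONTINUOUS_FEATURES = (
    "tract_tortuosity_proximal",
    "tract_tortuosity_medial",
    "tract_tortuosity_distal",
    "lt_p95",
    "ta_p95_deg",
    "vs_total_mm3",
    "calcium_extent_mm",
)


def cohort_analysis(
    features: pd.DataFrame,
    covariates: pd.DataFrame,
    ts_thresholds: tuple[int, ...] = (1, 2, 3, 4),
) -> dict[str, pd.DataFrame]:
    """Population statistics over per-patient feature rows.

    ``features`` holds one row per patient (see
    :meth:`PatientReport.feature_row`); ``covariates`` holds binary condition
    columns (age_over_60, obesity, smoking, ...) aligned by index.  Returns
    Mann-Whitney per-condition tables, a chi-squared/odds-ratio table of
    tortuosity incidence (TS >= 1), a zone ANOVA and the TS-threshold sweep
    of the calcium features.
    """
    df = features.join(covariates, how="inner")
    if len(df) < 4:
        raise ValueError("cohort analysis needs at least 4 patients")
    cond_cols = list(covariates.columns)
    for c in cond_cols:
        if df[c].isna().any():
            raise ValueError(f"missing covariate values in column {c!r}")

    # per-condition U tests on continuous features
    rows = []
    for cond in cond_cols:
        g1 = df[df[cond].astype(bool)]
        g0 = df[~df[cond].astype(bool)]
        if len(g1) < 2 or len(g0) < 2:
            raise ValueError(f"condition {cond!r} does not split the cohort")
        for feat in _CONTINUOUS_FEATURES:
            if feat not in df:
                continue
            u, p = mann_whitney(g1[feat].dropna(), g0[feat].dropna())
            rows.append({"condition": cond, "feature": feat,
                         "n_with": len(g1), "n_without": len(g0),
                         "median_with": float(g1[feat].median()),
                         "median_without": float(g0[feat].median()),
                         "U": u, "p": p})
    utable = pd.DataFrame(rows)

    # odds-ratio table of tortuosity incidence
    cort = df["ts"] >= 1
    rows = []
    for cond in cond_cols:
        e = df[cond].astype(bool)
        t = ContingencyTable2x2(
            a=int((e & cort).sum()), b=int((~e & cort).sum()),
            c=int((e & ~cort).sum()), d=int((~e & ~cort).sum()))
        if min(t.a + t.b, t.c + t.d, t.a + t.c, t.b + t.d) == 0:
            rows.append({"condition": cond, "OR": float("nan"), "p": float("nan"),
                         "flag": "undefined (zero marginal)"})
            continue
        orv, p = odds_ratio(t)
        rows.append({"condition": cond, "OR": orv, "p": p, "flag": ""})
    or_table = pd.DataFrame(rows)

    # zone ANOVA on zone-resolved features
    rows = []
    for stem in ("tract_tortuosity", "vs"):
        cols = [c for c in df.columns if c.startswith(stem + "_")
                and c.split("_")[-1].rstrip("m3") in ("proximal", "medial", "distal")]
        cols = [f"{stem}_{z}" if f"{stem}_{z}" in df else f"{stem}_{z}_mm3"
                for z in ZONES]
        if not all(c in df for c in cols):
            continue
        groups = [df[c].dropna() for c in cols]
        f, p = anova_oneway(*groups)
        rows.append({"feature": stem, "F": f, "p": p,
                     **{z: float(df[c].mean()) for z, c in zip(ZONES, cols)}})
    anova_table = pd.DataFrame(rows)

    # TS threshold sweep of calcium features
    rows = []
    for thr in ts_thresholds:
        hi = df[df["ts"] >= thr]
        lo = df[df["ts"] < thr]
        if len(hi) < 2 or len(lo) < 2:
            continue
        for feat in ("calcium_extent_mm", "vs_total_mm3"):
            u, p = mann_whitney(hi[feat].dropna(), lo[feat].dropna())
            rows.append({"ts_threshold": thr, "feature": feat,
                         "n_below": len(lo), "n_at_or_above": len(hi),
                         "median_below": float(lo[feat].median()),
                         "median_at_or_above": float(hi[feat].median()),
                         "U": u, "p": p})
    sweep = pd.DataFrame(rows)

    return {"u_tests": utable, "odds_ratios": or_table,
            "zone_anova": anova_table, "ts_sweep": sweep}
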