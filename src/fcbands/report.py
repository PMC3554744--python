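"""Summaries of the selected edge features.

For the feature subset a band's classification converged on, this module
computes per-group means and standard deviations (on the Fisher-z
normalized features), two-sample t-tests with significance stars
(p < 0.05 -> "*", p < 0.01 -> "**"), the direction of change in patients
versus controls, per-region occurrence counts among the selected edges,
and a cross-band comparison table. No multiple-testing correction is
applied across the selected features; p-values are nominal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .atlas import AtlasRegistry
from .discrimination import AccuracyCurve, FeatureRanking
from .network import SampleDataset, pair_to_feature_index

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FeatureStat:
    """Group comparison for one selected edge feature (Fisher-z units)."""

    feature_index: int
    region_i: str                 # abbreviation
    region_j: str
    mean_patients: float
    sd_patients: float
    mean_controls: float
    sd_controls: float
    t_value: float                # positive = increased in patients
    p_value: float
    stars: str                    # "", "*", "**"
    direction: str                # "increased" | "decreased"


@dataclass(frozen=True)
class RegionOccurrence:
    """How many selected edges touch a region."""

    abbreviation: str
    count: int


def _stars(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def group_feature_stats(ds: SampleDataset, selected,
                        atlas: AtlasRegistry,
                        ranking: FeatureRanking | None = None,
                        welch: bool = False) -> list[FeatureStat]:
    """Per-feature group means/SDs, t-test, stars, and direction.

    The t statistic is pooled-variance Student's t with df = K - 2
    (Welch's correction behind ``welch=True``), two-tailed, signed so
    that positive means increased in patients. Rows follow the ranking
    order when a ranking is supplied, otherwise the given order.
    """
    selected = list(selected)
    if not selected:
        logger.info("empty feature selection; empty report")
        return []
    if not ds.normalized:
        raise ValueError("group statistics are defined on the normalized dataset")
    if ranking is not None:
        pos = {f: r for r, f in enumerate(ranking.order)}
        selected = sorted(selected, key=lambda f: pos[f])

    patients = ds.X[ds.y == 1]
    controls = ds.X[ds.y == -1]
    if patients.shape[0] < 2 or controls.shape[0] < 2:
        raise ValueError("need >= 2 subjects per group")

    out = []
    for f in selected:
        i, j = ds.feature_map[f]
        xp, xc = patients[:, f], controls[:, f]
        t, p = _stats.ttest_ind(xp, xc, equal_var=not welch)
        mean_p, mean_c = float(xp.mean()), float(xc.mean())
        out.append(FeatureStat(
            feature_index=int(f),
            region_i=atlas[i].abbreviation,
            region_j=atlas[j].abbreviation,
            mean_patients=mean_p, sd_patients=float(xp.std(ddof=1)),
            mean_controls=mean_c, sd_controls=float(xc.std(ddof=1)),
            t_value=float(t), p_value=float(p), stars=_stars(float(p)),
            direction="increased" if mean_p > mean_c else "decreased",
        ))
    return out


def region_occurrence(selected, feature_map, atlas: AtlasRegistry,
                      ) -> list[RegionOccurrence]:
    """Occurrence count of every region among the selected edges.

    Counts every incidence, so the counts sum to twice the number of
    selected edges; the number of distinct regions involved is the length
    of the returned list. Sorted by decreasing count, then abbreviation.
    """
    counts: dict[str, int] = {}
    for f in selected:
        try:
            i, j = feature_map[f]
        except IndexError:
            raise KeyError(f"feature index {f} not covered by the feature map")
        for idx in (i, j):
            abbr = atlas[idx].abbreviation
            counts[abbr] = counts.get(abbr, 0) + 1
    occ = [RegionOccurrence(a, c) for a, c in counts.items()]
    occ.sort(key=lambda r: (-r.count, r.abbreviation))
    return occ


def edges_to_feature_indices(edge_abbrevs, atlas: AtlasRegistry) -> list[int]:
    """Map (abbrev_i, abbrev_j) pairs to 0-based edge feature indices."""
    out = []
    n = len(atlas)
    for a, b in edge_abbrevs:
        i = atlas.by_abbreviation(a).index
        j = atlas.by_abbreviation(b).index
        if i > j:
            i, j = j, i
        out.append(pair_to_feature_index(i, j, n))
    return out


def band_comparison_report(curves: dict[str, AccuracyCurve],
                           stats: dict[str, list[FeatureStat]],
                           occurrences: dict[str, list[RegionOccurrence]],
                           ) -> pd.DataFrame:
    """Cross-band table: convergence point, selected-feature summary.

    The band(s) with the smallest convergence k are flagged ``fastest``;
    a tie flags every tied band rather than picking a winner.
    """
    if len(curves) < 2:
        raise ValueError("band comparison needs at least two bands")
    rows = []
    for band, curve in curves.items():
        st = stats.get(band, [])
        occ = occurrences.get(band, [])
        rows.append({
            "band": band,
            "convergence_k": curve.convergence_k,
            "converged_accuracy": curve.converged_accuracy,
            "n_selected_features": len(st),
            "n_distinct_regions": len(occ),
            "n_increased": sum(s.direction == "increased" for s in st),
            "n_decreased": sum(s.direction == "decreased" for s in st),
        })
    df = pd.DataFrame(rows)
    ks = df["convergence_k"].astype(float).fillna(np.inf)
    best = ks.min()
    df["fastest"] = ks == best
    if np.isinf(best):
        df["fastest"] = False
    return df


def stats_to_frame(stats: list[FeatureStat], band: str = "") -> pd.DataFrame:
    """Feature-statistics rows as a tidy table (CSV-ready)."""
    return pd.DataFrame([{
        "band": band,
        "feature_index": s.feature_index,
        "region_i": s.region_i,
        "region_j": s.region_j,
        "mean_patients": s.mean_patients,
        "sd_patients": s.sd_patients,
        "mean_controls": s.mean_controls,
        "sd_controls": s.sd_controls,
        "t_value": s.t_value,
        "p_value": s.p_value,
        "stars": s.stars,
        "direction": s.direction,
    } for s in stats])
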