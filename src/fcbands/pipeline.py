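"""End-to-end orchestration of the three-band classification study.

For each frequency band: condition every subject's regional series
(detrend -> optional nuisance regression -> ideal band-pass), build the
Fisher-z subjects-by-edges dataset, rank edges by SVM-RFE, trace the
LOOCV accuracy curve over nested top-k subsets, locate the convergence
point, run the permuted-label control on the selected subset, and
summarize the selected edges (group statistics, region occurrence).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import io as fio
from .atlas import AtlasRegistry, load_aal90
from .bands import BandSpec
from .conditioning import NuisanceSet, ROITimeSeriesSet, condition
from .config import RunConfig
from .discrimination import (AccuracyCurve, FeatureRanking, PermutationResult,
                             accuracy_curve, default_k_schedule,
                             permutation_control, rfe_rank)
from .network import SampleDataset, build_dataset
from .report import (FeatureStat, RegionOccurrence, band_comparison_report,
                     group_feature_stats, region_occurrence, stats_to_frame)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BandResult:
    """Everything one band's pipeline produced."""

    band: BandSpec
    dataset: SampleDataset
    ranking: FeatureRanking
    curve: AccuracyCurve
    selected_features: tuple[int, ...]
    permutation: PermutationResult | None
    feature_stats: list[FeatureStat]
    occurrences: list[RegionOccurrence]


def run_band(subjects: list[ROITimeSeriesSet], labels: np.ndarray,
             band: BandSpec, config: RunConfig, atlas: AtlasRegistry,
             nuisance: NuisanceSet | None = None,
             permutation_seed: int | None = None) -> BandResult:
    """Run the full single-band pipeline on an in-memory cohort."""
    logger.info("band %s: conditioning %d subjects (%d x %d)", band.name,
                len(subjects), subjects[0].n_timepoints, subjects[0].n_regions)
    conditioned = [condition(ts, band, nuisance) for ts in subjects]
    ds = build_dataset(conditioned, labels, band=band.name,
                       normalization=config.normalization)
    logger.info("band %s: sample dataset %d x %d", band.name,
                ds.n_subjects, ds.n_features)

    ranking = rfe_rank(ds, config.classifier, step=config.rfe_step,
                       chunk_until=config.rfe_chunk_until)
    ks = (list(config.k_schedule) if config.k_schedule
          else default_k_schedule(ds.n_features, config.k_dense_until,
                                  config.k_geometric_points))
    curve = accuracy_curve(
        ds, config.classifier, k_schedule=ks, mode=config.mode,
        ranking=ranking if config.mode == "paper_fidelity" else None,
        rfe_step=config.rfe_step,
        convergence_window=config.convergence_window,
        convergence_tolerance=config.convergence_tolerance,
    )
    n_sel = curve.convergence_k if curve.convergence_k is not None \
        else curve.k_values[int(np.argmax(curve.accuracy))]
    selected = ranking.top(n_sel)

    perm = None
    if config.n_permutations > 0:
        perm = permutation_control(
            ds, config.classifier, config.n_permutations,
            rng=config.seed if permutation_seed is None else permutation_seed,
            selected_features=selected, mode="fixed_subset",
            observed_accuracy=curve.converged_accuracy,
        )

    stats = group_feature_stats(ds, selected, atlas, ranking=ranking)
    occ = region_occurrence(selected, ds.feature_map, atlas)
    return BandResult(band=band, dataset=ds, ranking=ranking, curve=curve,
                      selected_features=selected, permutation=perm,
                      feature_stats=stats, occurrences=occ)


def write_band_result(result: BandResult, outdir, atlas: AtlasRegistry,
                      config: RunConfig) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fio.write_ranking_tsv(result.ranking, outdir / "ranking.tsv",
                          result.dataset.feature_map, atlas)
    fio.write_curve_csv(result.curve, outdir / "curve.csv")
    if result.permutation is not None:
        fio.write_permutation_csv(result.permutation,
                                  outdir / "permutations.csv")
    stats_to_frame(result.feature_stats, band=result.band.name).to_csv(
        outdir / "feature_stats.csv", index=False)
    import pandas as pd
    pd.DataFrame([{"abbreviation": o.abbreviation, "count": o.count}
                  for o in result.occurrences]
                 ).to_csv(outdir / "region_occurrence.tsv", sep="\t",
                          index=False)
    manifest = {
        "band": {"name": result.band.name, "low_hz": result.band.low,
                 "high_hz": result.band.high},
        "mode": result.curve.mode,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_subjects": result.dataset.n_subjects,
        "n_features": result.dataset.n_features,
        "convergence_k": result.curve.convergence_k,
        "converged_accuracy": result.curve.converged_accuracy,
        "n_selected": len(result.selected_features),
        "chance_level": (result.permutation.chance_level
                         if result.permutation else None),
    }
    fio.write_json(manifest, outdir / "run_manifest.json")


def run_study(config: RunConfig, subjects=None, labels=None,
              atlas: AtlasRegistry | None = None) -> dict[str, BandResult]:
    """Run every configured band; load the cohort from disk if not given."""
    if atlas is None:
        atlas = (AtlasRegistry.from_tsv(config.atlas_path)
                 if config.atlas_path else load_aal90())
    if subjects is None:
        subjects, labels = fio.read_cohort(config.manifest_path,
                                           config.tr_seconds, atlas)
    results = {}
    for band in config.bands:
        try:
            results[band.name] = run_band(subjects, labels, band, config, atlas)
        except Exception:
            logger.error("pipeline failed in band %s", band.name)
            raise
    return results


def comparison_table(results: dict[str, BandResult]):
    return band_comparison_report(
        {name: r.curve for name, r in results.items()},
        {name: r.feature_stats for name, r in results.items()},
        {name: r.occurrences for name, r in results.items()},
    )
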