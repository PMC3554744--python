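"""Plain-text readers and writers for every pipeline artifact.

All formats are TSV/CSV/JSON: per-subject time series (T rows x N
regions, header = atlas abbreviations), a cohort manifest, ground-truth
planted edges, connectivity matrices, the subjects-by-edges sample
dataset with its feature-map sidecar, rankings, accuracy curves,
permutation results, and a JSON run manifest that captures the
configuration hash and seeds needed to re-run bit-identically.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import AtlasRegistry
from .cohort import SyntheticGroundTruth
from .conditioning import ROITimeSeriesSet
from .discrimination import AccuracyCurve, FeatureRanking, PermutationResult
from .network import ConnectivityMatrix, SampleDataset


def write_timeseries_tsv(ts: ROITimeSeriesSet, path, atlas: AtlasRegistry) -> None:
    header = [atlas[i].abbreviation for i in ts.region_ids]
    pd.DataFrame(ts.values, columns=header).to_csv(path, sep="\t", index=False)


def read_timeseries_tsv(path, tr_seconds: float, atlas: AtlasRegistry,
                        subject_id: str | None = None) -> ROITimeSeriesSet:
    df = pd.read_csv(path, sep="\t")
    region_ids = tuple(atlas.by_abbreviation(c).index for c in df.columns)
    return ROITimeSeriesSet(
        subject_id=subject_id or Path(path).stem,
        values=df.to_numpy(dtype=float),
        tr_seconds=tr_seconds,
        region_ids=region_ids,
        provenance=("loaded",),
    )


def write_cohort(outdir, subjects: list[ROITimeSeriesSet], labels: np.ndarray,
                 truth: SyntheticGroundTruth, atlas: AtlasRegistry) -> Path:
    """Write per-subject TSVs, the manifest, and the planted ground truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for ts, label in zip(subjects, labels):
        fname = f"{ts.subject_id}.tsv"
        write_timeseries_tsv(ts, outdir / fname, atlas)
        rows.append({"subject_id": ts.subject_id, "label": int(label),
                     "path": fname})
    manifest = outdir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)

    gt_rows = []
    for e, fidx in zip(truth.design.planted_edges, truth.edge_feature_indices):
        gt_rows.append({
            "region_i": e.region_i, "region_j": e.region_j,
            "band": e.band.name, "low_hz": e.band.low, "high_hz": e.band.high,
            "coupling_patients": e.coupling_patients,
            "coupling_controls": e.coupling_controls,
            "feature_index": fidx,
        })
    pd.DataFrame(
        gt_rows, columns=["region_i", "region_j", "band", "low_hz", "high_hz",
                          "coupling_patients", "coupling_controls",
                          "feature_index"],
    ).to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)
    return manifest


def read_cohort(manifest_path, tr_seconds: float, atlas: AtlasRegistry,
                ) -> tuple[list[ROITimeSeriesSet], np.ndarray]:
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path, sep="\t")
    subjects, labels = [], []
    for _, row in df.iterrows():
        ts = read_timeseries_tsv(manifest_path.parent / row["path"],
                                 tr_seconds, atlas,
                                 subject_id=str(row["subject_id"]))
        subjects.append(ts)
        labels.append(int(row["label"]))
    return subjects, np.asarray(labels, dtype=int)


def write_connectivity_csv(cm: ConnectivityMatrix, path,
                           atlas: AtlasRegistry) -> None:
    abbrs = atlas.abbreviations[:cm.n_regions]
    pd.DataFrame(cm.values, index=abbrs, columns=abbrs).to_csv(path)


def write_dataset(ds: SampleDataset, path_csv, path_feature_map_tsv,
                  atlas: AtlasRegistry) -> None:
    cols = [f"f{k}" for k in range(ds.n_features)]
    df = pd.DataFrame(ds.X, columns=cols)
    df.insert(0, "label", ds.y)
    if ds.subject_ids:
        df.insert(0, "subject_id", list(ds.subject_ids))
    df.to_csv(path_csv, index=False)
    pd.DataFrame([
        {"feature_index": k,
         "region_i_abbrev": atlas[i].abbreviation,
         "region_j_abbrev": atlas[j].abbreviation}
        for k, (i, j) in enumerate(ds.feature_map)
    ]).to_csv(path_feature_map_tsv, sep="\t", index=False)


def write_ranking_tsv(ranking: FeatureRanking, path, feature_map,
                      atlas: AtlasRegistry) -> None:
    rows = []
    for rank, f in enumerate(ranking.order, start=1):
        i, j = feature_map[f]
        rows.append({"rank": rank, "feature_index": f,
                     "region_i": atlas[i].abbreviation,
                     "region_j": atlas[j].abbreviation})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_curve_csv(curve: AccuracyCurve, path) -> None:
    pd.DataFrame({"k": curve.k_values, "accuracy": curve.accuracy}
                 ).to_csv(path, index=False)


def read_curve_csv(path, band: str = "", mode: str = "paper_fidelity",
                   convergence_k=None, converged_accuracy=None) -> AccuracyCurve:
    df = pd.read_csv(path)
    return AccuracyCurve(band=band, k_values=tuple(int(k) for k in df["k"]),
                         accuracy=tuple(float(a) for a in df["accuracy"]),
                         mode=mode, convergence_k=convergence_k,
                         converged_accuracy=converged_accuracy)


def write_permutation_csv(result: PermutationResult, path) -> None:
    pd.DataFrame({
        "permutation": range(1, result.n_permutations + 1),
        "accuracy": result.permuted_accuracies,
    }).to_csv(path, index=False)


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())
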