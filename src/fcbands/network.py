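"""Functional-connectivity network construction and edge-feature assembly.

Each subject's conditioned regional series become an N x N Pearson
correlation matrix; its N(N-1)/2 strict-upper-triangle entries, taken in
row-major order (1,2),(1,3),...,(1,N),(2,3),..., form the subject's edge
feature vector. Stacking all subjects yields the K x P sample matrix
(39 x 4005 at the 90-region study scale) with labels +1 for patients and
-1 for controls. Features are variance-stabilized by the Fisher r-to-z
transform z = arctanh(r) = 0.5*ln((1+r)/(1-r)); negative correlations are
retained as features throughout.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .atlas import AtlasRegistry
from .conditioning import ROITimeSeriesSet

logger = logging.getLogger(__name__)


class ZeroVarianceError(ValueError):
    """A regional series is constant, so its correlations are undefined."""


class MissingRegionError(ValueError):
    """An atlas region has no voxels in the provided labelling."""


def upper_triangle_pairs(n_regions: int) -> tuple[tuple[int, int], ...]:
    """Row-major strict-upper-triangle region pairs, 1-based: (1,2),(1,3),..."""
    iu, ju = np.triu_indices(n_regions, k=1)
    return tuple((int(i) + 1, int(j) + 1) for i, j in zip(iu, ju))


def pair_to_feature_index(i: int, j: int, n_regions: int) -> int:
    """0-based feature position of the 1-based region pair (i, j), i < j."""
    if not 1 <= i < j <= n_regions:
        raise ValueError(f"need 1 <= i < j <= {n_regions}, got ({i}, {j})")
    i0, j0 = i - 1, j - 1
    return i0 * n_regions - i0 * (i0 + 1) // 2 + (j0 - i0 - 1)


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric N x N Pearson correlation matrix for one subject/band."""

    subject_id: str
    band: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("connectivity matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-10):
            raise ValueError("connectivity matrix must have unit diagonal")
        if v.min() < -1 - 1e-10 or v.max() > 1 + 1e-10:
            raise ValueError("correlations must lie in [-1, 1]")
        object.__setattr__(self, "values", v)

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class SampleDataset:
    """K x P subjects-by-edges feature matrix with +1/-1 labels.

    ``feature_map[p]`` is the 1-based region pair (i, j) behind feature
    column p; ``normalized`` flags whether Fisher z has been applied.
    """

    X: np.ndarray
    y: np.ndarray
    feature_map: tuple[tuple[int, int], ...]
    band: str
    normalized: bool = False
    subject_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y, dtype=int)
        if X.ndim != 2:
            raise ValueError("X must be K x P")
        if y.shape != (X.shape[0],):
            raise ValueError("one label per subject required")
        if not set(np.unique(y)) <= {-1, 1}:
            raise ValueError("labels must be +1 or -1")
        if len(set(np.unique(y))) < 2:
            raise ValueError("both classes must be present")
        if X.shape[1] != len(self.feature_map):
            raise ValueError("feature_map must cover every column")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


def roi_average(voxel_series: np.ndarray, voxel_labels: np.ndarray,
                atlas: AtlasRegistry, subject_id: str = "subject",
                tr_seconds: float = 2.0) -> ROITimeSeriesSet:
    """Average voxel time courses within each atlas region.

    ``voxel_labels`` assigns each of the V columns a 1-based atlas index;
    every atlas region must own at least one voxel.
    """
    voxel_series = np.asarray(voxel_series, dtype=float)
    voxel_labels = np.asarray(voxel_labels)
    if voxel_series.shape[1] != voxel_labels.shape[0]:
        raise ValueError("one label per voxel column required")
    T = voxel_series.shape[0]
    out = np.empty((T, len(atlas)))
    for region in atlas.regions:
        mask = voxel_labels == region.index
        if not mask.any():
            raise MissingRegionError(
                f"region {region.abbreviation} (index {region.index}) has no voxels"
            )
        out[:, region.index - 1] = voxel_series[:, mask].mean(axis=1)
    return ROITimeSeriesSet(
        subject_id=subject_id, values=out, tr_seconds=tr_seconds,
        region_ids=tuple(r.index for r in atlas.regions),
        provenance=("roi_average",),
    )


def correlation_matrix(ts: ROITimeSeriesSet, band: str = "",
                       strict: bool = True) -> ConnectivityMatrix:
    """Pearson correlation between every pair of regional series.

    In strict mode a zero-variance column is an error naming the region;
    in lenient mode its correlations are set to 0 with a warning.
    """
    values = ts.values
    sd = values.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size and strict:
        raise ZeroVarianceError(
            "zero-variance region(s): "
            + ", ".join(str(ts.region_ids[k]) for k in dead)
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = np.corrcoef(values, rowvar=False)
    if dead.size:
        logger.warning("lenient mode: zeroing correlations of %d constant region(s)",
                       dead.size)
        corr[dead, :] = 0.0
        corr[:, dead] = 0.0
    np.fill_diagonal(corr, 1.0)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    return ConnectivityMatrix(subject_id=ts.subject_id, band=band, values=corr)


def vectorize_upper(
    cm: ConnectivityMatrix,
) -> tuple[np.ndarray, tuple[tuple[int, int], ...]]:
    """Extract the strict upper triangle row-major; returns (vector, feature_map)."""
    n = cm.n_regions
    iu, ju = np.triu_indices(n, k=1)
    return cm.values[iu, ju].copy(), upper_triangle_pairs(n)


def devectorize(edge_vector: np.ndarray, n_regions: int) -> np.ndarray:
    """Rebuild the symmetric unit-diagonal matrix from an edge vector."""
    edge_vector = np.asarray(edge_vector, dtype=float)
    expected = n_regions * (n_regions - 1) // 2
    if edge_vector.shape != (expected,):
        raise ValueError(f"expected {expected} edges for N={n_regions}")
    out = np.eye(n_regions)
    iu, ju = np.triu_indices(n_regions, k=1)
    out[iu, ju] = edge_vector
    out[ju, iu] = edge_vector
    return out


def assemble_dataset(
    edge_vectors: list[np.ndarray],
    labels: np.ndarray,
    feature_map: tuple[tuple[int, int], ...],
    band: str = "",
    subject_ids: tuple[str, ...] = (),
) -> SampleDataset:
    """Stack per-subject edge vectors into the K x P sample matrix."""
    labels = np.asarray(labels, dtype=int)
    if len(edge_vectors) != labels.shape[0]:
        raise ValueError("one label per subject required")
    P = len(feature_map)
    for k, v in enumerate(edge_vectors):
        if np.asarray(v).shape != (P,):
            raise ValueError(
                f"subject {k}: edge vector length {np.asarray(v).shape} "
                f"inconsistent with feature map ({P})"
            )
    for lab in (+1, -1):
        if (labels == lab).sum() < 2:
            raise ValueError(f"need >= 2 subjects with label {lab:+d}")
    X = np.vstack([np.asarray(v, dtype=float) for v in edge_vectors])
    return SampleDataset(X=X, y=labels, feature_map=tuple(feature_map),
                         band=band, subject_ids=tuple(subject_ids))


def fisher_z(ds: SampleDataset, strict: bool = True) -> SampleDataset:
    """Apply the Fisher r-to-z transform z = arctanh(r) elementwise.

    Requires |r| < 1; in lenient mode entries at +-1 are clipped to
    +-(1 - 1e-7) and the clip count logged.
    """
    if ds.normalized:
        raise ValueError("dataset is already normalized")
    X = ds.X
    at_limit = np.abs(X) >= 1.0
    if at_limit.any():
        if strict:
            raise ValueError(
                f"{int(at_limit.sum())} entries have |r| >= 1; Fisher z undefined"
            )
        logger.warning("clipping %d entries with |r| >= 1", int(at_limit.sum()))
        X = np.clip(X, -(1 - 1e-7), 1 - 1e-7)
    return replace(ds, X=np.arctanh(X), normalized=True)


def feature_zscore(ds: SampleDataset) -> SampleDataset:
    """Per-feature standardization across subjects (sensitivity alternative)."""
    if ds.normalized:
        raise ValueError("dataset is already normalized")
    mu = ds.X.mean(axis=0)
    sd = ds.X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return replace(ds, X=(ds.X - mu) / sd, normalized=True)


def build_dataset(subjects: list[ROITimeSeriesSet], labels: np.ndarray,
                  band: str = "", normalization: str = "fisher_z") -> SampleDataset:
    """Correlate, vectorize, stack and normalize a cohort in one call."""
    vectors, fmap = [], None
    for ts in subjects:
        vec, m = vectorize_upper(correlation_matrix(ts, band=band))
        if fmap is None:
            fmap = m
        elif m != fmap:
            raise ValueError("inconsistent feature maps across subjects")
        vectors.append(vec)
    ds = assemble_dataset(
        vectors, labels, fmap, band=band,
        subject_ids=tuple(ts.subject_id for ts in subjects),
    )
    if normalization == "fisher_z":
        return fisher_z(ds)
    if normalization == "feature_zscore":
        return feature_zscore(ds)
    if normalization == "none":
        return ds
    raise ValueError(f"unknown normalization {normalization!r}")
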