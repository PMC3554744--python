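"""Synthetic multi-subject cohorts with planted band-limited connectivity.

The generator emulates the structure of a two-group resting-state study:
``n_patients + n_controls`` subjects, each a T x N matrix of regional
BOLD-like series sampled at TR seconds, with group labels +1 (patients)
and -1 (controls). Ground-truth inter-regional coupling is planted on
chosen region pairs, confined to a chosen frequency band, and set to a
group-dependent target correlation, so that every downstream stage -
filtering, network construction, feature ranking, classification - can be
validated against a known answer.

Signal model: region r of a subject is a sum of band-limited latent
components, one per planted edge incident to r, plus independent white
Gaussian noise of standard deviation ``noise_sd``. The latent of an edge
is shared by its two regions and weighted so that, within the edge's
band, the population Pearson correlation equals the group's coupling
target: with white-noise variance ``noise_sd**2`` and in-band noise power
fraction p, the weight w solves r = w**2 / (w**2 + noise_sd**2 * p),
giving w**2 = |r| * noise_sd**2 * p / (1 - |r|); a negative target flips
the sign of the latent in the second region. Outside the planted band the
latent carries no power, so couplings are invisible to other bands.
When several planted edges share a region (and overlapping bands) their
latents add, which pulls realized correlations slightly below target;
keep planted edges region-disjoint where exact targets matter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bands import BandSpec, InvalidDesignError
from .conditioning import ROITimeSeriesSet, band_bin_mask, band_power_fraction, bandpass_ideal


@dataclass(frozen=True)
class PlantedEdge:
    """Ground-truth coupling between two atlas regions in one band."""

    region_i: int                 # 1-based atlas index, < region_j
    region_j: int
    band: BandSpec
    coupling_patients: float      # target Pearson r in (-1, 1)
    coupling_controls: float

    def __post_init__(self) -> None:
        if self.region_i == self.region_j:
            raise InvalidDesignError("planted edge must join two distinct regions")
        if self.region_i > self.region_j:
            raise InvalidDesignError(
                f"planted edge regions must satisfy i < j, got "
                f"({self.region_i}, {self.region_j})"
            )
        for c in (self.coupling_patients, self.coupling_controls):
            if not -1.0 < c < 1.0:
                raise InvalidDesignError(
                    f"coupling target {c} outside the open interval (-1, 1)"
                )


@dataclass(frozen=True)
class CohortDesign:
    """Study design: group sizes, matrix geometry, and planted truth.

    Defaults mirror a 19-patient / 20-control design with 90 regions and
    170 retained volumes at TR = 2 s (180 acquired minus 10 discarded).
    """

    n_patients: int = 19
    n_controls: int = 20
    n_regions: int = 90
    n_timepoints: int = 170
    tr_seconds: float = 2.0
    planted_edges: tuple[PlantedEdge, ...] = field(default=())
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_patients", "n_controls", "n_regions", "n_timepoints"):
            if getattr(self, name) <= 0:
                raise InvalidDesignError(f"{name} must be positive")
        if self.tr_seconds <= 0:
            raise InvalidDesignError("tr_seconds must be positive")
        if self.noise_sd <= 0:
            raise InvalidDesignError("noise_sd must be positive")
        if self.n_timepoints < 8:
            raise InvalidDesignError("need at least 8 time points")
        object.__setattr__(self, "planted_edges", tuple(self.planted_edges))
        for e in self.planted_edges:
            if not 1 <= e.region_i <= self.n_regions or not 1 <= e.region_j <= self.n_regions:
                raise InvalidDesignError(
                    f"planted edge ({e.region_i}, {e.region_j}) outside atlas "
                    f"1..{self.n_regions}"
                )
            e.band.validate_nyquist(self.tr_seconds)

    @property
    def n_subjects(self) -> int:
        return self.n_patients + self.n_controls


@dataclass(frozen=True)
class SyntheticGroundTruth:
    """What was planted, keyed to the edge-feature vectorization order."""

    design: CohortDesign
    edge_feature_indices: tuple[int, ...]   # 0-based positions in the edge vector
    realized_correlations: np.ndarray       # (n_subjects, n_planted) in-band Pearson r


def band_limited_component(n_timepoints: int, tr_seconds: float, band: BandSpec,
                           rng: np.random.Generator | int) -> np.ndarray:
    """A zero-mean, unit-variance series with all spectral power in ``band``.

    Synthesized by masking the Fourier coefficients of white Gaussian
    noise outside [low, high] and inverse-transforming, then
    standardizing. Exactly matches the ideal band-pass filter used in
    conditioning, so filtering a component with its own band is (up to
    the removed mean) the identity.
    """
    if n_timepoints < 8:
        raise InvalidDesignError("band-limited synthesis needs T >= 8")
    band.validate_nyquist(tr_seconds)
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    keep = band_bin_mask(n_timepoints, tr_seconds, band)
    if not keep.any() or (keep.sum() == 1 and keep[0]):
        raise InvalidDesignError(
            f"band {band.name!r} [{band.low}, {band.high}] Hz holds no "
            f"oscillatory DFT bin at T={n_timepoints}, TR={tr_seconds}s"
        )
    white = rng.standard_normal(n_timepoints)
    coeffs = np.fft.rfft(white)
    coeffs[~keep] = 0.0
    series = np.fft.irfft(coeffs, n=n_timepoints)
    series -= series.mean()
    sd = series.std()
    if sd == 0:
        raise InvalidDesignError("degenerate band produced a constant series")
    return series / sd


def _edge_weight(target_r: float, noise_sd: float, in_band_fraction: float) -> float:
    """Latent weight hitting a target in-band correlation (see module docs)."""
    a = abs(target_r)
    return float(np.sqrt(a * noise_sd**2 * in_band_fraction / (1.0 - a)))


def generate_cohort(
    design: CohortDesign,
) -> tuple[list[ROITimeSeriesSet], np.ndarray, SyntheticGroundTruth]:
    """Simulate all subjects of a two-group cohort.

    Returns the per-subject time-series sets (patients first), the +1/-1
    label vector, and the ground truth with per-subject realized in-band
    correlations for every planted edge. Bitwise reproducible from
    ``design.seed``.
    """
    rng = np.random.default_rng(design.seed)
    T, N = design.n_timepoints, design.n_regions
    fractions = {
        e: band_power_fraction(T, design.tr_seconds, e.band)
        for e in design.planted_edges
    }

    subjects: list[ROITimeSeriesSet] = []
    labels = np.concatenate([
        np.ones(design.n_patients), -np.ones(design.n_controls)
    ]).astype(int)
    realized = np.zeros((design.n_subjects, len(design.planted_edges)))

    for s in range(design.n_subjects):
        is_patient = s < design.n_patients
        sid = (f"patient{s + 1:02d}" if is_patient
               else f"control{s - design.n_patients + 1:02d}")
        values = design.noise_sd * rng.standard_normal((T, N))
        for e in design.planted_edges:
            target = e.coupling_patients if is_patient else e.coupling_controls
            latent = band_limited_component(T, design.tr_seconds, e.band, rng)
            w = _edge_weight(target, design.noise_sd, fractions[e])
            values[:, e.region_i - 1] += w * latent
            values[:, e.region_j - 1] += np.sign(target) * w * latent
        ts = ROITimeSeriesSet(
            subject_id=sid, values=values, tr_seconds=design.tr_seconds,
            region_ids=tuple(range(1, N + 1)), provenance=("synthetic",),
        )
        subjects.append(ts)
        for k, e in enumerate(design.planted_edges):
            filtered = bandpass_ideal(ts, e.band).values
            x = filtered[:, e.region_i - 1]
            y = filtered[:, e.region_j - 1]
            realized[s, k] = np.corrcoef(x, y)[0, 1]

    # feature indices in row-major strict-upper-triangle order over 1..N
    def feat_index(i: int, j: int) -> int:
        i0, j0 = i - 1, j - 1
        return i0 * N - i0 * (i0 + 1) // 2 + (j0 - i0 - 1)

    truth = SyntheticGroundTruth(
        design=design,
        edge_feature_indices=tuple(
            feat_index(e.region_i, e.region_j) for e in design.planted_edges
        ),
        realized_correlations=realized,
    )
    return subjects, labels, truth


def design_from_dict(d: dict) -> CohortDesign:
    """Build a CohortDesign from a plain config mapping (YAML/JSON block)."""
    d = dict(d)
    edges = []
    for e in d.pop("planted_edges", []) or []:
        band = BandSpec(e["band"], float(e["low_hz"]), float(e["high_hz"]))
        edges.append(PlantedEdge(
            region_i=int(e["region_i"]), region_j=int(e["region_j"]),
            band=band,
            coupling_patients=float(e["coupling_patients"]),
            coupling_controls=float(e["coupling_controls"]),
        ))
    return CohortDesign(planted_edges=tuple(edges), **d)


def expand_to_voxels(
    ts: ROITimeSeriesSet, voxels_per_region: int, voxel_noise_sd: float,
    rng: np.random.Generator | int,
) -> tuple[np.ndarray, np.ndarray]:
    """Replicate each regional series into noisy pseudo-voxels.

    Returns a T x (N * voxels_per_region) matrix and the per-voxel atlas
    labels; averaging the voxels of each region recovers the regional
    series up to the added noise. Exists solely to exercise ROI
    averaging - no spatial structure is modelled.
    """
    if voxels_per_region < 1:
        raise InvalidDesignError("voxels_per_region must be >= 1")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    T, N = ts.values.shape
    V = N * voxels_per_region
    voxels = np.repeat(ts.values, voxels_per_region, axis=1)
    voxels = voxels + voxel_noise_sd * rng.standard_normal((T, V))
    labels = np.repeat(np.asarray(ts.region_ids), voxels_per_region)
    return voxels, labels
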