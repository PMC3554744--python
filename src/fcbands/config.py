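"""Run configuration: bands, classifier, schedules, seeds, paths.

A ``RunConfig`` is loadable from YAML/JSON and hashes to a stable
hexadecimal digest recorded in every output manifest, so two runs with
equal hashes are re-runs of the same analysis.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .bands import DEFAULT_BANDS, BandSpec
from .discrimination import ClassifierSpec


@dataclass(frozen=True)
class RunConfig:
    bands: tuple[BandSpec, ...] = DEFAULT_BANDS
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    mode: str = "paper_fidelity"          # or "nested"
    normalization: str = "fisher_z"       # or "feature_zscore"
    tr_seconds: float = 2.0
    rfe_step: float = 0.1                 # fraction eliminated per RFE iteration
    rfe_chunk_until: int = 200
    k_dense_until: int = 200
    k_geometric_points: int = 12
    k_schedule: tuple[int, ...] | None = None   # explicit override
    convergence_window: int = 10
    convergence_tolerance: float = 0.0
    n_permutations: int = 100
    seed: int = 0
    manifest_path: str = "cohort/manifest.tsv"
    atlas_path: str | None = None         # None -> shipped AAL-90
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if self.mode not in ("paper_fidelity", "nested"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.normalization not in ("fisher_z", "feature_zscore", "none"):
            raise ValueError(f"unknown normalization {self.normalization!r}")

    def to_dict(self) -> dict:
        return {
            "bands": [{"name": b.name, "low_hz": b.low, "high_hz": b.high}
                      for b in self.bands],
            "classifier": {"kernel": self.classifier.kernel,
                           "C": self.classifier.C,
                           "rbf_gamma": self.classifier.rbf_gamma},
            "mode": self.mode,
            "normalization": self.normalization,
            "tr_seconds": self.tr_seconds,
            "rfe_step": self.rfe_step,
            "rfe_chunk_until": self.rfe_chunk_until,
            "k_dense_until": self.k_dense_until,
            "k_geometric_points": self.k_geometric_points,
            "k_schedule": list(self.k_schedule) if self.k_schedule else None,
            "convergence_window": self.convergence_window,
            "convergence_tolerance": self.convergence_tolerance,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "manifest_path": self.manifest_path,
            "atlas_path": self.atlas_path,
            "output_dir": self.output_dir,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "bands" in d:
            d["bands"] = tuple(
                BandSpec(b["name"], float(b["low_hz"]), float(b["high_hz"]))
                for b in d["bands"]
            )
        if "classifier" in d:
            c = d["classifier"]
            d["classifier"] = ClassifierSpec(
                kernel=c.get("kernel", "linear"), C=float(c.get("C", 1.0)),
                rbf_gamma=c.get("rbf_gamma", "1/num_features"),
            )
        if d.get("k_schedule"):
            d["k_schedule"] = tuple(int(k) for k in d["k_schedule"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f) or {})

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
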