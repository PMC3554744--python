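"""The 90-region AAL cerebral parcellation registry.

Region indices are 1-based as printed in atlas tables; odd indices are
left-hemisphere, even are right, and homotopic pairs share an abbreviation
stem (PreCG.L / PreCG.R). The registry names the nodes of every
connectivity matrix and the endpoints of every edge feature.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd


@dataclass(frozen=True)
class AtlasRegion:
    index: int          # 1-based atlas index
    abbreviation: str   # e.g. "PreCG.L"
    name: str
    hemisphere: str     # "L" or "R"


class AtlasRegistry:
    """Ordered catalogue of atlas regions with index/abbreviation lookup."""

    def __init__(self, regions: list[AtlasRegion]):
        if not regions:
            raise ValueError("empty atlas")
        abbrs = [r.abbreviation for r in regions]
        if len(set(abbrs)) != len(abbrs):
            raise ValueError("atlas abbreviations must be unique")
        if [r.index for r in regions] != list(range(1, len(regions) + 1)):
            raise ValueError("atlas indices must be contiguous from 1")
        self.regions = list(regions)
        self._by_abbr = {r.abbreviation: r for r in regions}

    def __len__(self) -> int:
        return len(self.regions)

    def __getitem__(self, index: int) -> AtlasRegion:
        """Look up by 1-based atlas index."""
        if not 1 <= index <= len(self.regions):
            raise KeyError(f"atlas index {index} out of range 1..{len(self.regions)}")
        return self.regions[index - 1]

    def by_abbreviation(self, abbr: str) -> AtlasRegion:
        try:
            return self._by_abbr[abbr]
        except KeyError:
            raise KeyError(f"unknown region abbreviation {abbr!r}") from None

    @property
    def abbreviations(self) -> list[str]:
        return [r.abbreviation for r in self.regions]

    @classmethod
    def from_tsv(cls, path) -> "AtlasRegistry":
        df = pd.read_csv(path, sep="\t")
        regions = [
            AtlasRegion(int(row["index"]), str(row["abbreviation"]),
                        str(row["name"]), str(row["hemisphere"]))
            for _, row in df.iterrows()
        ]
        return cls(regions)

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            [(r.index, r.abbreviation, r.name, r.hemisphere) for r in self.regions],
            columns=["index", "abbreviation", "name", "hemisphere"],
        )
        df.to_csv(path, sep="\t", index=False)


def load_aal90() -> AtlasRegistry:
    """Load the shipped 90-region AAL registry (45 homotopic pairs)."""
    ref = resources.files("fcbands.data") / "aal90.tsv"
    with resources.as_file(ref) as path:
        return AtlasRegistry.from_tsv(path)


def synthetic_atlas(n_regions: int) -> AtlasRegistry:
    """A generic numbered atlas (R001, R002, ...) for reduced-scale runs."""
    regions = [
        AtlasRegion(i, f"R{i:03d}", f"synthetic region {i}", "L" if i % 2 else "R")
        for i in range(1, n_regions + 1)
    ]
    return AtlasRegistry(regions)
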