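"""Elements x markers feature matrix of average coverages.

Each classifier feature is the mean coverage of one marker over a genomic
element, optionally extended by a symmetric flank (clipped at chromosome
ends; the mean uses the clipped width, avoiding zero-padding bias). Flank
defaults to 0: the feature is the element-body mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import Interval
from .track_io import CoverageTrack


@dataclass
class FeatureMatrix:
    """Rectangular elements x markers table of mean RPM coverages."""

    ids: list[str]
    markers: tuple[str, ...]
    values: np.ndarray  # shape (n_elements, n_markers)
    elements: list[Interval]
    flank: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.ids), len(self.markers)):
            raise ValueError("feature matrix shape mismatch")
        if len(self.elements) != len(self.ids):
            raise ValueError("element list length mismatch")

    def __len__(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.markers))
        df.insert(0, "element", self.ids)
        df.insert(1, "chrom", [iv.chrom for iv in self.elements])
        df.insert(2, "start", [iv.start for iv in self.elements])
        df.insert(3, "end", [iv.end for iv in self.elements])
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def subset(self, row_idx: Sequence[int]) -> "FeatureMatrix":
        row_idx = list(row_idx)
        return FeatureMatrix(
            [self.ids[i] for i in row_idx],
            self.markers,
            self.values[row_idx],
            [self.elements[i] for i in row_idx],
            self.flank,
        )


def extract_features(
    elements: Sequence[Interval],
    tracks: Mapping[str, CoverageTrack],
    flank: int = 0,
    ids: Sequence[str] | None = None,
) -> FeatureMatrix:
    """Mean coverage of every marker over every (flank-extended) element.

    ``tracks`` is an ordered marker → track mapping; its key order fixes the
    column order of the matrix. Rows follow the input element order.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    markers = tuple(tracks.keys())
    if not markers:
        raise ValueError("no coverage tracks supplied")
    if ids is None:
        ids = [f"e{i}" for i in range(len(elements))]
    genome = next(iter(tracks.values())).genome
    regions = [iv.expanded(flank, genome) if flank else iv for iv in elements]
    values = np.empty((len(elements), len(markers)), dtype=np.float64)
    for j, marker in enumerate(markers):
        values[:, j] = tracks[marker].means(regions)
    return FeatureMatrix(list(ids), markers, values, list(elements), flank)
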