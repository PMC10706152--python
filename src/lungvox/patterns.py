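"""CALIPER-style parenchymal pattern label maps.

Quantitative CT texture analysis labels every parenchymal voxel with one of
seven patterns: normal, mild/moderate/severe lower-attenuation areas (LAA),
ground-glass opacity, reticular change, and honeycombing.  For comparison
with gas diffusion MRI these are consolidated to five: normal and mild LAA
merge into "non-involved" (mild LAA occurs in healthy lungs after deep
inhalation), while moderate and severe LAA merge into "hyperlucent"
(emphysema-like lung).  Ground-glass, reticular and honeycomb are kept.

The texture classification itself is upstream of this package; label maps
are inputs (or phantom-generated).  Integer codes are fixed here so NIfTI
label files round-trip portably.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .grids import Grid, Volume

# Raw 7-class scheme
RAW7 = {
    0: "background",
    1: "normal",
    2: "LAA_mild",
    3: "LAA_moderate",
    4: "LAA_severe",
    5: "ground_glass",
    6: "reticular",
    7: "honeycomb",
}

# Consolidated 5-class scheme
CONSOLIDATED5 = {
    0: "background",
    1: "non_involved",
    2: "ground_glass",
    3: "reticular",
    4: "hyperlucent",
    5: "honeycomb",
}

#: raw code -> consolidated code
_CONSOLIDATION = {0: 0, 1: 1, 2: 1, 3: 4, 4: 4, 5: 2, 6: 3, 7: 5}

#: consolidated pattern names counted as interstitial lung disease when
#: computing CT-abnormal percentages (hyperlucent/emphysema is excluded).
ILD_PATTERNS = ("ground_glass", "reticular", "honeycomb")


@dataclass
class CaliperLabelMap:
    """Integer pattern map on a grid, in the raw7 or consolidated5 scheme."""

    labels: np.ndarray
    grid: Grid
    scheme: str = "raw7"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label map must have an integer dtype")
        if self.scheme not in ("raw7", "consolidated5"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.labels.shape != tuple(self.grid.shape):
            raise ValueError("label shape does not match grid")

    @property
    def legend(self) -> dict[int, str]:
        return dict(RAW7 if self.scheme == "raw7" else CONSOLIDATED5)

    def as_volume(self) -> Volume:
        return Volume(self.labels, self.grid)

    def legend_json(self) -> str:
        return json.dumps({str(k): v for k, v in self.legend.items()}, indent=2)


def consolidate_patterns(raw: CaliperLabelMap) -> CaliperLabelMap:
    """Merge the 7-class map to the 5-pattern scheme.

    normal + mild LAA -> non_involved; moderate + severe LAA -> hyperlucent;
    ground-glass, reticular, honeycomb and background map through unchanged.
    The total number of nonzero (parenchymal) voxels is conserved exactly.
    """
    if raw.scheme != "raw7":
        raise ValueError("consolidate_patterns expects a raw7 map; refusing to re-map")
    codes = np.unique(raw.labels)
    unknown = [int(c) for c in codes if int(c) not in _CONSOLIDATION]
    if unknown:
        raise ValueError(f"unknown raw7 label code(s): {unknown}")
    lut = np.zeros(max(_CONSOLIDATION) + 1, dtype=raw.labels.dtype)
    for k, v in _CONSOLIDATION.items():
        lut[k] = v
    return CaliperLabelMap(lut[raw.labels], raw.grid, scheme="consolidated5")


def pattern_percentages(label_map: CaliperLabelMap, mask: np.ndarray | None = None) -> dict[str, float]:
    """Percentage of parenchymal voxels per consolidated pattern.

    Parenchyma means nonzero labels; an optional mask further restricts the
    counted region.  Percentages sum to 100 over the nonzero patterns.
    """
    if label_map.scheme != "consolidated5":
        raise ValueError("pattern_percentages expects a consolidated5 map")
    labels = label_map.labels
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != labels.shape:
            raise ValueError("mask shape mismatch")
        if not mask.any():
            raise ValueError("empty mask")
        labels = np.where(mask, labels, 0)
    parenchyma = labels > 0
    total = int(parenchyma.sum())
    if total == 0:
        raise ValueError("no parenchymal voxels under the mask")
    out = {}
    for code, name in CONSOLIDATED5.items():
        if code == 0:
            continue
        out[name] = 100.0 * float((labels == code).sum()) / total
    return out
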