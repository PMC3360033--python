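"""Domain containers shared across the package.

These are deliberately lightweight dataclasses: the heavy lifting
(distance matrices, ordinations, clustering) is done on numpy/pandas
structures, and profiles/spectra are converted to those on demand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

CONDITIONS = ("C1", "C2", "C3")
CST_LABELS = ("I", "II", "III", "IV")

#: Taxa counted as Lactobacillus species when deciding whether a community
#: is Lactobacillus-dominated.
LACTOBACILLUS_TAXA = ("L. iners", "L. crispatus", "L. gasseri", "L. jensenii")


@dataclass
class TaxonProfile:
    """One sample's phylotype proportion vector plus metadata.

    ``proportions`` maps taxon name to its relative abundance; after the
    "Other" remainder taxon is appended the vector is a proper composition
    (non-negative, summing to one).
    """

    sample_id: str
    subject_id: str
    condition: str
    total_reads: int
    proportions: Mapping[str, float]
    cst: Optional[str] = None
    nugent: Optional[int] = None

    def __post_init__(self) -> None:
        if self.total_reads <= 0:
            raise ValueError(f"total_reads must be positive, got {self.total_reads}")
        vals = np.asarray(list(self.proportions.values()), dtype=float)
        if vals.size and (vals < -1e-12).any():
            raise ValueError(f"negative proportion in sample {self.sample_id}")
        s = vals.sum()
        if vals.size and not (0 < s <= 1 + 1e-9):
            raise ValueError(
                f"proportions of {self.sample_id} sum to {s:.6f}, expected (0, 1]"
            )

    def vector(self, taxa: Sequence[str]) -> np.ndarray:
        """Proportion vector over ``taxa`` (zero-filled for absent taxa)."""
        return np.array([self.proportions.get(t, 0.0) for t in taxa], dtype=float)


@dataclass
class MetaboliteRecord:
    """Relative abundance (percent) of the three major vaginal metabolites."""

    sample_id: str
    subject_id: str
    condition: str
    lactic_pct: float
    acetic_pct: float
    succinic_pct: float
    cst: Optional[str] = None

    def __post_init__(self) -> None:
        for name in ("lactic_pct", "acetic_pct", "succinic_pct"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0 or v > 100:
                raise ValueError(f"{name}={v} outside [0, 100] for {self.sample_id}")


@dataclass
class NMRSpectrum:
    """A 1D proton spectrum on an ascending ppm grid."""

    sample_id: str
    subject_id: str
    condition: str
    ppm: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.shape != self.intensity.shape or self.ppm.ndim != 1:
            raise ValueError("ppm and intensity must be 1-D arrays of equal length")
        if not np.all(np.diff(self.ppm) > 0):
            raise ValueError("ppm grid must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")


@dataclass
class EquivalenceResult:
    """KS comparison of between-condition distances against the replicate null."""

    metric: str
    condition_pair: tuple
    ks_statistic: float
    p_value: float
    n_test: int
    n_null: int


@dataclass
class CSTAssignment:
    """Cluster-derived community state type for one sample."""

    sample_id: str
    cst_label: str
    cluster_index: int
    dominant_taxon: str
    dominant_fraction: float


@dataclass
class BucketTestResult:
    """Per-bucket paired Wilcoxon result for one condition pair."""

    bucket: tuple
    condition_pair: tuple
    statistic: float
    p_value: float
    q_value: float = field(default=float("nan"))
    degenerate: bool = False


def profiles_to_frame(profiles: Sequence[TaxonProfile]) -> pd.DataFrame:
    """Samples x taxa proportion table over the union of observed taxa.

    Taxon order: order of first appearance across profiles; absent taxa
    are zero-filled, so all rows live in one common composition space.
    """
    taxa: list[str] = []
    seen = set()
    for p in profiles:
        for t in p.proportions:
            if t not in seen:
                seen.add(t)
                taxa.append(t)
    data = np.array([p.vector(taxa) for p in profiles])
    return pd.DataFrame(data, index=[p.sample_id for p in profiles], columns=taxa)
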