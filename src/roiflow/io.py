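"""Count-matrix container and the TSV dialects used throughout the pipeline.

Counts travel as genes x ROIs TSV (first column the gene id); per-ROI
metadata as a TSV keyed by ``roi_id``; unwanted-variation factors as a TSV
of ``roi_id`` plus one column per factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from roiflow.errors import ConfigurationError

METADATA_COLUMNS = ["slide_id", "group", "compartment", "area", "nuclei"]

GROUPS = ("PD", "control")
COMPARTMENTS = ("plexus", "epithelium")


@dataclass
class RoiCountMatrix:
    """Genes x ROIs expression matrix with per-ROI metadata.

    ``counts`` rows are genes, columns are ROI ids; values are non-negative
    (integer for raw data, real-valued after normalization). ``metadata``
    is indexed by ROI id and aligned with the count columns.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ConfigurationError("duplicate gene ids in count matrix")
        if self.counts.columns.has_duplicates:
            raise ConfigurationError("duplicate ROI ids in count matrix")
        if (self.counts.to_numpy() < 0).any():
            raise ConfigurationError("negative values in count matrix")
        if self.metadata is None:
            self.metadata = pd.DataFrame(index=self.counts.columns)
        else:
            missing = set(self.counts.columns) - set(self.metadata.index)
            if missing:
                raise ConfigurationError(
                    f"ROIs missing from metadata: {sorted(missing)[:5]}"
                )
            self.metadata = self.metadata.loc[self.counts.columns]

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def rois(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def subset_rois(self, rois: list[str]) -> "RoiCountMatrix":
        return RoiCountMatrix(self.counts[rois].copy(), self.metadata.loc[rois].copy())

    def subset_compartment(self, compartment: str) -> "RoiCountMatrix":
        if compartment not in COMPARTMENTS:
            raise ConfigurationError(f"unknown compartment {compartment!r}")
        keep = self.metadata.index[self.metadata["compartment"] == compartment]
        return self.subset_rois(list(keep))


def write_counts(m: RoiCountMatrix, path: str | Path) -> None:
    m.counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts(path: str | Path, metadata: str | Path | None = None) -> RoiCountMatrix:
    counts = pd.read_csv(path, sep="\t", index_col=0)
    meta = read_metadata(metadata) if metadata is not None else None
    return RoiCountMatrix(counts, meta)


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index_label="roi_id")


def read_metadata(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="roi_id")


def write_factors(factors: pd.DataFrame, path: str | Path) -> None:
    factors.to_csv(path, sep="\t", index_label="roi_id")


def read_factors(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="roi_id")


def write_mtx(m: RoiCountMatrix, path: str | Path) -> None:
    """Write counts in MatrixMarket coordinate format (genes x ROIs)."""
    from scipy.io import mmwrite
    from scipy.sparse import coo_matrix

    mmwrite(str(path), coo_matrix(m.counts.to_numpy()))


def write_edge_list(edges: list[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b in edges:
            fh.write(f"{a}\t{b}\n")


def geometric_mean(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    return float(np.exp(np.mean(np.log(x))))
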