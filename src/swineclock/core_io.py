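"""Data model and delimited-text IO for methylation matrices and metadata.

The in-memory container is :class:`MethylationDataset`: a probes x samples
beta-value matrix (methylation fractions in [0, 1], NaN = missing) aligned
with a sample sheet and a probe annotation table, both pandas DataFrames.

All on-disk formats are comma-separated text with a header row; probe ids
occupy the first column of the matrix and annotation, sample ids the first
column of the sample sheet. Clock coefficient files carry a '#'-prefixed
header block (intercept, transform spec) followed by probe_id,coefficient
rows; see :mod:`swineclock.clock`.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MethylationDataset",
    "SAMPLE_COLUMNS",
    "PROBE_COLUMNS",
    "read_methylation_dataset",
    "write_methylation_dataset",
    "filter_mappable",
    "write_clock",
    "read_clock",
]

SAMPLE_COLUMNS = ("species", "breed", "tissue", "sex", "age_years")
PROBE_COLUMNS = ("chrom", "pos", "nearest_gene", "dist_to_tss", "island", "mappable")

_BETA_TOL = 1e-9


@dataclass
class MethylationDataset:
    """Beta matrix plus aligned sample metadata and probe annotation.

    Parameters
    ----------
    betas
        DataFrame of methylation fractions, rows indexed by probe_id,
        columns by sample_id. Values in [0, 1]; NaN marks missing.
    samples
        Sample sheet indexed by sample_id with at least the columns
        ``species, breed, tissue, sex, age_years``.
    probes
        Probe annotation indexed by probe_id with at least the columns
        ``chrom, pos, nearest_gene, dist_to_tss, island, mappable``.
    """

    betas: pd.DataFrame
    samples: pd.DataFrame
    probes: pd.DataFrame

    def __post_init__(self) -> None:
        self.betas = self.betas.astype(float)
        if self.betas.index.has_duplicates:
            raise ValueError("duplicated probe ids in beta matrix")
        if self.betas.columns.has_duplicates:
            raise ValueError("duplicated sample ids in beta matrix")
        if self.samples.index.has_duplicates:
            raise ValueError("duplicated sample ids in sample sheet")
        if self.probes.index.has_duplicates:
            raise ValueError("duplicated probe ids in annotation")
        missing_samples = self.betas.columns.difference(self.samples.index)
        if len(missing_samples):
            raise ValueError(
                f"samples absent from sample sheet: {list(missing_samples[:5])}"
            )
        missing_probes = self.betas.index.difference(self.probes.index)
        if len(missing_probes):
            raise ValueError(
                f"probes absent from annotation: {list(missing_probes[:5])}"
            )
        for col in SAMPLE_COLUMNS:
            if col not in self.samples.columns:
                raise ValueError(f"sample sheet missing column {col!r}")
        for col in PROBE_COLUMNS:
            if col not in self.probes.columns:
                raise ValueError(f"annotation missing column {col!r}")
        ages = self.samples["age_years"].to_numpy(float)
        if np.any(ages < 0):
            raise ValueError("age_years must be non-negative")
        vals = self.betas.to_numpy(float)
        with np.errstate(invalid="ignore"):
            if np.any(vals < -_BETA_TOL) or np.any(vals > 1 + _BETA_TOL):
                bad = vals[(vals < -_BETA_TOL) | (vals > 1 + _BETA_TOL)]
                raise ValueError(f"beta out of range [0,1]: e.g. {bad.flat[0]!r}")
        # align metadata to matrix order
        self.samples = self.samples.loc[self.betas.columns]
        self.probes = self.probes.loc[self.betas.index]

    # -- convenience --------------------------------------------------------------
    @property
    def n_probes(self) -> int:
        return self.betas.shape[0]

    @property
    def n_samples(self) -> int:
        return self.betas.shape[1]

    def subset_samples(self, sample_ids) -> "MethylationDataset":
        ids = pd.Index(sample_ids)
        return MethylationDataset(
            self.betas.loc[:, ids], self.samples.loc[ids].copy(), self.probes.copy()
        )

    def subset_probes(self, probe_ids) -> "MethylationDataset":
        ids = pd.Index(probe_ids)
        return MethylationDataset(
            self.betas.loc[ids], self.samples.copy(), self.probes.loc[ids].copy()
        )


def read_methylation_dataset(
    matrix_path, samples_path, annotation_path
) -> MethylationDataset:
    """Read a beta matrix, sample sheet, and probe annotation into one dataset.

    Raises on missing files, non-numeric betas, values outside [0, 1], and
    samples/probes present in the matrix but absent from the metadata.
    """
    betas = pd.read_csv(matrix_path, index_col=0)
    try:
        betas = betas.astype(float)
    except ValueError as e:
        raise ValueError(f"non-numeric beta value in {matrix_path}: {e}") from None
    samples = pd.read_csv(samples_path, index_col=0)
    probes = pd.read_csv(annotation_path, index_col=0)
    for col in ("island", "mappable"):
        if col in probes.columns:
            probes[col] = probes[col].astype(bool)
    return MethylationDataset(betas, samples, probes)


def write_methylation_dataset(ds: MethylationDataset, out_dir) -> dict[str, Path]:
    """Write matrix.csv, samples.csv, annotation.csv under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out / "matrix.csv",
        "samples": out / "samples.csv",
        "annotation": out / "annotation.csv",
    }
    ds.betas.to_csv(paths["matrix"], index_label="probe_id", float_format="%.17g")
    ds.samples.to_csv(paths["samples"], index_label="sample_id")
    ds.probes.to_csv(paths["annotation"], index_label="probe_id")
    return paths


def filter_mappable(ds: MethylationDataset) -> MethylationDataset:
    """Retain exactly the probes that uniquely map to the swine genome.

    Idempotent; the sample set is unchanged. An empty result is allowed
    (with a warning) rather than an error.
    """
    keep = ds.probes.index[ds.probes["mappable"].astype(bool)]
    if len(keep) == 0:
        warnings.warn("no mappable probes remain after filtering", stacklevel=2)
    return ds.subset_probes(keep)


def write_clock(model, path) -> Path:
    """Serialize a ClockModel to a CSV coefficient file (see swineclock.clock)."""
    from .clock import write_clock as _write

    return _write(model, path)


def read_clock(path):
    """Read a ClockModel from a coefficient file written by :func:`write_clock`."""
    from .clock import read_clock as _read

    return _read(path)
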