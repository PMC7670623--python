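"""Core in-memory containers and TSV I/O.

The pipeline's central object is a probe x sample matrix of beta values
(methylation fractions in [0, 1]) with an optional companion matrix of
detection p-values, plus a probe manifest (genomic coordinates, QC flags,
gene annotation) and a per-sample phenotype table.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

MANIFEST_COLUMNS = ["chrom", "pos", "cross_reactive", "snp", "genes"]

PHENOTYPE_COLUMNS = [
    "sample_id",
    "subject_id",
    "timepoint",
    "sex",
    "age",
    "arm",
    "weight",
    "bmi",
    "weight_T0",
    "weight_T6",
    "weight_T18",
]


class ConsistencyError(ValueError):
    """Raised when matrix / manifest / phenotype sample or probe sets disagree."""


@dataclasses.dataclass
class MethylationMatrix:
    """Probe x sample beta values with an optional detection-p companion.

    ``beta`` is a DataFrame indexed by probe id with sample-id columns; all
    values must lie in [0, 1]. ``detection_p``, when present, has the same
    shape, index and columns.
    """

    beta: pd.DataFrame
    detection_p: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.beta.index.has_duplicates:
            raise ConsistencyError("duplicated probe ids in beta matrix")
        if self.beta.columns.has_duplicates:
            raise ConsistencyError("duplicated sample ids in beta matrix")
        vals = self.beta.to_numpy()
        if vals.size and (np.nanmin(vals) < 0 or np.nanmax(vals) > 1):
            raise ConsistencyError("beta values outside [0, 1]")
        if self.detection_p is not None:
            if self.detection_p.shape != self.beta.shape:
                raise ConsistencyError("detection_p shape differs from beta")
            if not self.detection_p.index.equals(self.beta.index) or not (
                self.detection_p.columns.equals(self.beta.columns)
            ):
                raise ConsistencyError("detection_p index/columns differ from beta")

    @property
    def probe_ids(self) -> pd.Index:
        return self.beta.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.beta.columns

    @property
    def n_probes(self) -> int:
        return self.beta.shape[0]

    @property
    def n_samples(self) -> int:
        return self.beta.shape[1]

    def subset_probes(self, probe_ids) -> "MethylationMatrix":
        det = None if self.detection_p is None else self.detection_p.loc[probe_ids]
        return MethylationMatrix(self.beta.loc[probe_ids], det)

    def subset_samples(self, sample_ids) -> "MethylationMatrix":
        det = None if self.detection_p is None else self.detection_p[list(sample_ids)]
        return MethylationMatrix(self.beta[list(sample_ids)], det)


def validate_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    """Check a probe manifest and return it sorted by (chrom, pos).

    Expected: index = probe id; columns chrom, pos (1-based), cross_reactive,
    snp (0/1 flags) and genes (semicolon-joined symbols, '' for none).
    """
    missing = [c for c in ("chrom", "pos") if c not in manifest.columns]
    if missing:
        raise ConsistencyError(f"manifest missing columns: {missing}")
    if manifest.index.has_duplicates:
        raise ConsistencyError("duplicated probe ids in manifest")
    if (manifest["pos"] < 1).any():
        raise ConsistencyError("manifest positions must be >= 1")
    dup = manifest.duplicated(subset=["chrom", "pos"])
    if dup.any():
        raise ConsistencyError("duplicated (chrom, pos) in manifest")
    out = manifest.copy()
    for col, default in (("cross_reactive", 0), ("snp", 0), ("genes", "")):
        if col not in out.columns:
            out[col] = default
    out["genes"] = out["genes"].fillna("")
    return out.sort_values(["chrom", "pos"], kind="stable")


def validate_phenotypes(pheno: pd.DataFrame) -> pd.DataFrame:
    required = {"sample_id", "subject_id", "timepoint"}
    missing = required - set(pheno.columns)
    if missing:
        raise ConsistencyError(f"phenotype table missing columns: {sorted(missing)}")
    if pheno["sample_id"].duplicated().any():
        raise ConsistencyError("duplicated sample ids in phenotype table")
    bad_tp = set(pheno["timepoint"]) - {"T0", "T6", "T18"}
    if bad_tp:
        raise ConsistencyError(f"unknown timepoints: {sorted(bad_tp)}")
    return pheno.reset_index(drop=True)


# ---------------------------------------------------------------------------
# TSV round-tripping


def read_matrix(beta_path: str | Path, detection_path: str | Path | None = None) -> MethylationMatrix:
    beta = pd.read_csv(beta_path, sep="\t", index_col=0)
    det = None
    if detection_path is not None:
        det = pd.read_csv(detection_path, sep="\t", index_col=0)
    return MethylationMatrix(beta, det)


def write_matrix(m: MethylationMatrix, beta_path: str | Path, detection_path: str | Path | None = None) -> None:
    m.beta.to_csv(beta_path, sep="\t", index_label="probe_id")
    if detection_path is not None and m.detection_p is not None:
        m.detection_p.to_csv(detection_path, sep="\t", index_label="probe_id")


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={"genes": str}, keep_default_na=False)
    df["pos"] = df["pos"].astype(int)
    return validate_manifest(df)


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    manifest.to_csv(path, sep="\t", index_label="probe_id")


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    return validate_phenotypes(pd.read_csv(path, sep="\t"))


def write_phenotypes(pheno: pd.DataFrame, path: str | Path) -> None:
    pheno.to_csv(path, sep="\t", index=False)
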