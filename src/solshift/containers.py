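"""Core in-memory containers for two-fraction quantitative proteomics.

The package moves data around as two light objects: a :class:`QuantMatrix`
(features x samples abundance table with explicit missingness and a scale
tag) and a :class:`SampleMeta` (per-sample case / disease / fraction /
covariate records).  Both wrap :class:`pandas.DataFrame` so that the full
pandas API stays available through ``.values_df`` / ``.table``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_SCALES = ("raw", "log2", "modz")

REQUIRED_META_COLUMNS = ("sample_id", "case_id", "disease", "fraction")
VALID_FRACTIONS = ("soluble", "insoluble")


class SolshiftError(ValueError):
    """Base class for domain errors raised by this package."""


@dataclass
class QuantMatrix:
    """Features x samples abundance matrix with explicit missingness.

    Parameters
    ----------
    values_df
        DataFrame indexed by feature id with one column per sample.
        Missing observations are ``NaN``.
    scale
        One of ``"raw"`` (linear LFQ intensities), ``"log2"``, or
        ``"modz"`` (modified z-scores).
    """

    values_df: pd.DataFrame
    scale: str = "raw"

    def __post_init__(self) -> None:
        if self.scale not in VALID_SCALES:
            raise SolshiftError(
                f"scale must be one of {VALID_SCALES}, got {self.scale!r}"
            )
        idx = self.values_df.index
        if idx.has_duplicates:
            dups = sorted(idx[idx.duplicated()].unique().tolist())
            raise SolshiftError(f"duplicate feature IDs: {dups}")
        cols = self.values_df.columns
        if cols.has_duplicates:
            dups = sorted(cols[cols.duplicated()].unique().tolist())
            raise SolshiftError(f"duplicate sample IDs: {dups}")
        self.values_df = self.values_df.astype(float)
        if self.scale == "raw":
            vals = self.values_df.to_numpy()
            observed = ~np.isnan(vals)
            if np.any(vals[observed] <= 0):
                raise SolshiftError(
                    "raw-scale matrix contains non-positive observed values; "
                    "map them to missing on read"
                )

    # -- basic views ----------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.values_df.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values_df.columns)

    @property
    def n_features(self) -> int:
        return self.values_df.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values_df.shape[1]

    def observed_mask(self) -> pd.DataFrame:
        """Boolean DataFrame, True where a value was observed."""
        return self.values_df.notna()

    def is_complete(self) -> bool:
        return bool(self.values_df.notna().all().all())

    def log2(self) -> "QuantMatrix":
        """Return a log2-transformed copy (raw scale only)."""
        if self.scale != "raw":
            raise SolshiftError(f"log2 transform requires raw scale, got {self.scale}")
        return QuantMatrix(np.log2(self.values_df), scale="log2")

    def subset_samples(self, sample_ids) -> "QuantMatrix":
        return QuantMatrix(self.values_df.loc[:, list(sample_ids)], scale=self.scale)

    def subset_features(self, feature_ids) -> "QuantMatrix":
        return QuantMatrix(self.values_df.loc[list(feature_ids)], scale=self.scale)

    def copy(self) -> "QuantMatrix":
        return QuantMatrix(self.values_df.copy(), scale=self.scale)


@dataclass
class SampleMeta:
    """Per-sample metadata: case, disease group, fraction, covariates."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_META_COLUMNS if c not in self.table.columns]
        if missing:
            raise SolshiftError(f"metadata missing required columns: {missing}")
        t = self.table
        if t["sample_id"].duplicated().any():
            dups = sorted(t.loc[t["sample_id"].duplicated(), "sample_id"].tolist())
            raise SolshiftError(f"duplicate sample_id in metadata: {dups}")
        bad = set(t["fraction"]) - set(VALID_FRACTIONS)
        if bad:
            raise SolshiftError(
                f"fraction must be one of {VALID_FRACTIONS}, got {sorted(bad)}"
            )
        # within a disease a case contributes at most one sample per fraction
        dup_pairs = t.duplicated(subset=["disease", "case_id", "fraction"])
        if dup_pairs.any():
            rows = t.loc[dup_pairs, ["disease", "case_id", "fraction"]]
            raise SolshiftError(
                f"duplicate (case_id, fraction) within disease: {rows.to_dict('records')}"
            )
        self.table = t.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def diseases(self) -> list[str]:
        return sorted(self.table["disease"].unique())

    @property
    def fractions(self) -> list[str]:
        return sorted(self.table["fraction"].unique())

    def group_labels(self) -> pd.Series:
        """disease:fraction label per sample, indexed by sample_id."""
        t = self.table
        labels = t["disease"].astype(str) + ":" + t["fraction"].astype(str)
        return pd.Series(labels.to_numpy(), index=t["sample_id"].to_numpy(), name="group")

    def groups(self) -> dict[str, list[str]]:
        """Mapping disease:fraction -> sample ids (sorted group order)."""
        lab = self.group_labels()
        out: dict[str, list[str]] = {}
        for g in sorted(lab.unique()):
            out[g] = list(lab.index[lab == g])
        return out

    def check_matches(self, matrix: QuantMatrix) -> None:
        meta_ids = set(self.sample_ids)
        mat_ids = set(matrix.sample_ids)
        if meta_ids != mat_ids:
            only_meta = sorted(meta_ids - mat_ids)
            only_mat = sorted(mat_ids - meta_ids)
            raise SolshiftError(
                "sample mismatch between matrix and metadata: "
                f"only in metadata {only_meta}, only in matrix {only_mat}"
            )

    def aligned_to(self, matrix: QuantMatrix) -> "SampleMeta":
        """Return a copy with rows ordered like the matrix columns."""
        self.check_matches(matrix)
        t = self.table.set_index("sample_id").loc[matrix.sample_ids].reset_index()
        return SampleMeta(t)
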