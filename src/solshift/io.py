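"""Readers and writers for quant tables, sample metadata, GMT gene sets and
FASTA references.

Quant tables are wide delimited text: one feature-id column plus one column
per sample (``orientation="features_in_rows"``) or the transpose.  Missing
observations may be encoded as empty cells, ``NA``-like strings, or — for
raw linear LFQ exports — zeros / non-positive values; all are mapped to an
explicit absent value on read.
"""

from __future__ import annotations

import importlib.resources

import numpy as np
import pandas as pd
from Bio import SeqIO

from .containers import QuantMatrix, SampleMeta, SolshiftError

DEFAULT_NA = ("", "NA", "NaN", "nan", "N/A", "Filtered")


def _sep_for(path: str, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "," if str(path).endswith(".csv") else "\t"


def read_quant_table(
    path,
    orientation: str = "features_in_rows",
    scale: str = "raw",
    missing_codes=DEFAULT_NA,
    nonpositive_missing: bool | None = None,
    sep: str | None = None,
) -> QuantMatrix:
    """Read a wide quant table into a :class:`QuantMatrix`.

    Parameters
    ----------
    orientation
        ``"features_in_rows"`` (default) or ``"samples_in_rows"``.
    scale
        Scale tag for the resulting matrix (``raw``/``log2``/``modz``).
    missing_codes
        Strings mapped to missing.
    nonpositive_missing
        Map observed values <= 0 to missing.  Defaults to True for raw
        scale (zero means "not detected" in LFQ exports), False otherwise.
    """
    df = pd.read_csv(
        path,
        sep=_sep_for(path, sep),
        index_col=0,
        na_values=list(missing_codes),
        keep_default_na=False,
    )
    if orientation == "samples_in_rows":
        df = df.T
    elif orientation != "features_in_rows":
        raise SolshiftError(f"unknown orientation {orientation!r}")

    if df.shape[1] < 1:
        raise SolshiftError(f"{path}: no sample columns found")

    bad = df.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    newly_bad = bad.isna() & df.notna()
    if newly_bad.any().any():
        r, c = np.argwhere(newly_bad.to_numpy())[0]
        raise SolshiftError(
            f"{path}: non-numeric cell at feature {df.index[r]!r}, "
            f"sample {df.columns[c]!r}: {df.iloc[r, c]!r}"
        )
    df = bad

    if nonpositive_missing is None:
        nonpositive_missing = scale == "raw"
    if nonpositive_missing:
        df = df.mask(df <= 0)

    if df.index.has_duplicates:
        dups = sorted(df.index[df.index.duplicated()].unique().tolist())
        raise SolshiftError(f"{path}: duplicate feature IDs: {dups}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return QuantMatrix(df, scale=scale)


def write_quant_table(matrix: QuantMatrix, path, sep: str | None = None) -> None:
    """Write a QuantMatrix as a wide delimited table (missing as empty)."""
    matrix.values_df.to_csv(path, sep=_sep_for(path, sep), na_rep="")


def read_sample_meta(path, sep: str | None = None) -> SampleMeta:
    """Read a sample metadata table (sample_id, case_id, disease, fraction,
    optional age / sex / pmd)."""
    df = pd.read_csv(path, sep=_sep_for(path, sep), dtype={"sample_id": str, "case_id": str})
    return SampleMeta(df)


def write_sample_meta(meta: SampleMeta, path, sep: str | None = None) -> None:
    meta.table.to_csv(path, sep=_sep_for(path, sep), index=False)


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT gene-set file: name <tab> description <tab> members..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise SolshiftError(f"{path}: malformed GMT line: {line[:80]!r}")
            name, members = parts[0], [m for m in parts[2:] if m]
            if name in sets:
                raise SolshiftError(f"{path}: duplicate gene-set name {name!r}")
            sets[name] = members
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


def read_fasta_single(path) -> str:
    """Read a FASTA expected to hold exactly one protein sequence."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise SolshiftError(f"{path}: expected exactly 1 sequence, found {len(records)}")
    return str(records[0].seq)


def load_tau_2n4r() -> str:
    """Packaged 2N4R tau reference (441 aa; UniProt P10636-8)."""
    ref = importlib.resources.files("solshift") / "data" / "tau_2n4r.fasta"
    with importlib.resources.as_file(ref) as p:
        return read_fasta_single(p)


def read_peptide_table(path, sep: str | None = None) -> pd.DataFrame:
    """Read a long peptide detection table: sequence, sample_id, abundance."""
    df = pd.read_csv(path, sep=_sep_for(path, sep), dtype={"sequence": str, "sample_id": str})
    required = {"sequence", "sample_id", "abundance"}
    missing = required - set(df.columns)
    if missing:
        raise SolshiftError(f"{path}: peptide table missing columns {sorted(missing)}")
    return df
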