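"""Cohort-level QC: PCA of the quant matrix and covariate checks.

PCA is run on complete-case features after dropping the lowest-variance
fraction of features (default 30%, they contribute little to the leading
components), on centered, unit-scaled log2 abundances.  Each known
covariate is then correlated against the top components to flag technical
structure (e.g., post mortem delay) worth modelling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

from .containers import QuantMatrix, SampleMeta, SolshiftError

COVARIATE_CANDIDATES = ("disease", "fraction", "age", "sex", "pmd")


@dataclass
class PcaQcReport:
    scores: pd.DataFrame  # samples x components
    variance_explained: np.ndarray
    covariate_correlations: pd.DataFrame  # (covariate, component) -> r, p
    dropped_feature_count: int
    loadings: pd.DataFrame  # features x components


def _encode_covariate(values: pd.Series) -> np.ndarray:
    if pd.api.types.is_numeric_dtype(values):
        return values.to_numpy(dtype=float)
    return values.astype("category").cat.codes.to_numpy(dtype=float)


def pca_qc(
    matrix: QuantMatrix,
    meta: SampleMeta,
    drop_low_variance_fraction: float = 0.3,
    n_components: int = 10,
    covariates=None,
) -> PcaQcReport:
    """PCA of samples with covariate-component correlations.

    Parameters
    ----------
    matrix
        Quant matrix; raw scale is log2-transformed first.
    drop_low_variance_fraction
        Fraction of lowest-variance features removed before PCA.
    n_components
        Number of leading components retained (capped by rank).
    covariates
        Metadata columns to correlate; defaults to every known covariate
        present in the metadata.
    """
    if not (0 <= drop_low_variance_fraction < 1):
        raise SolshiftError("drop_low_variance_fraction must be in [0, 1)")
    if matrix.n_samples < 3:
        raise SolshiftError("PCA requires at least 3 samples")
    meta = meta.aligned_to(matrix)

    df = np.log2(matrix.values_df) if matrix.scale == "raw" else matrix.values_df
    df = df.dropna(axis=0)  # complete cases only
    variances = df.var(axis=1, ddof=1)
    if (variances == 0).all():
        raise SolshiftError("all features constant; PCA undefined")
    n_drop = int(np.floor(drop_low_variance_fraction * len(df)))
    keep = variances.sort_values(kind="stable").index[n_drop:]
    df = df.loc[df.index.intersection(keep, sort=False)]
    dropped = int(len(variances) - len(df))

    # drop zero-variance leftovers: unit scaling is undefined for them
    df = df.loc[df.var(axis=1, ddof=1) > 0]

    X = StandardScaler().fit_transform(df.to_numpy().T)  # samples x features
    k = min(n_components, min(X.shape) - 1) or 1
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    comp_names = [f"PC{i + 1}" for i in range(k)]
    scores_df = pd.DataFrame(scores, index=matrix.sample_ids, columns=comp_names)
    loadings = pd.DataFrame(pca.components_.T, index=df.index, columns=comp_names)

    if covariates is None:
        covariates = [c for c in COVARIATE_CANDIDATES if c in meta.table.columns]
    rows = []
    for cov in covariates:
        v = _encode_covariate(meta.table[cov])
        if np.nanstd(v) == 0:
            warnings.warn(f"covariate {cov!r} is constant; correlations undefined")
            continue
        for comp in comp_names:
            r, p = stats.pearsonr(v, scores_df[comp].to_numpy())
            rows.append({"covariate": cov, "component": comp, "r": r, "p": p})
    corr = pd.DataFrame(rows, columns=["covariate", "component", "r", "p"])

    return PcaQcReport(
        scores=scores_df,
        variance_explained=pca.explained_variance_ratio_,
        covariate_correlations=corr,
        dropped_feature_count=dropped,
        loadings=loadings,
    )


def covariate_group_anova(meta: SampleMeta, covariate: str) -> float:
    """One-way ANOVA p-value of a per-case covariate across disease groups.

    Each case contributes one record (fractions collapsed).  A constant
    covariate yields p = 1.0 with a warning.
    """
    t = meta.table.drop_duplicates(subset=["disease", "case_id"])
    if covariate not in t.columns:
        raise SolshiftError(f"unknown covariate {covariate!r}")
    groups = [
        _encode_covariate(sub[covariate].dropna())
        for _, sub in t.groupby("disease")
    ]
    groups = [g for g in groups if len(g) >= 2]
    if len(groups) < 2:
        raise SolshiftError("ANOVA needs >= 2 disease groups with >= 2 cases")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        warnings.warn(f"covariate {covariate!r} constant across all cases; p set to 1")
        return 1.0
    _, p = stats.f_oneway(*groups)
    return float(p)
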