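"""Normalization, filtering, imputation and presence/absence calls.

The normalization is a per-sample modified z-score

    z = 0.6745 * (x - median_sample) / MAD_sample

with the median and MAD (median absolute deviation, unscaled) computed over
the observed values of each sample only.  The 0.6745 factor makes z
comparable to an ordinary z-score under normality, so no 1.4826 consistency
factor is applied to the MAD.  Detection filtering, kNN imputation and
per-group presence calls follow standard label-free proteomics practice:
features must be seen in at least half of all measurements, remaining gaps
are filled from the k nearest feature neighbors, and a protein is called
missing in a group when detected in at most one of its samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer

from .containers import QuantMatrix, SampleMeta, SolshiftError

MODZ_FACTOR = 0.6745


@dataclass
class NormalizedMatrix(QuantMatrix):
    """QuantMatrix on the modz scale, retaining per-sample location/scale."""

    sample_medians: pd.Series | None = None
    sample_mads: pd.Series | None = None

    def __post_init__(self) -> None:
        self.scale = "modz"
        super().__post_init__()


def modified_zscore(matrix: QuantMatrix) -> NormalizedMatrix:
    """Per-sample modified z-score normalization of a log2 matrix.

    Raises
    ------
    SolshiftError
        If the input is not on the log2 scale, a sample has fewer than 3
        observed values, or a sample MAD is zero.
    """
    if matrix.scale != "log2":
        raise SolshiftError(
            f"modified_zscore expects a log2-scale matrix, got {matrix.scale!r}"
        )
    df = matrix.values_df
    n_obs = df.notna().sum(axis=0)
    thin = n_obs[n_obs < 3]
    if len(thin):
        raise SolshiftError(
            f"samples with <3 observed values: {sorted(thin.index.tolist())}"
        )
    medians = df.median(axis=0, skipna=True)
    mads = (df - medians).abs().median(axis=0, skipna=True)
    zero = mads[mads == 0]
    if len(zero):
        raise SolshiftError(f"zero MAD for samples: {sorted(zero.index.tolist())}")
    z = MODZ_FACTOR * (df - medians) / mads
    return NormalizedMatrix(z, sample_medians=medians, sample_mads=mads)


def filter_by_detection(
    matrix: QuantMatrix, min_detect_fraction: float = 0.5
) -> tuple[QuantMatrix, list[str]]:
    """Keep features observed in at least ``min_detect_fraction`` of all
    samples; return (filtered matrix, excluded feature ids)."""
    if not (0 < min_detect_fraction <= 1):
        raise SolshiftError("min_detect_fraction must be in (0, 1]")
    frac = matrix.values_df.notna().mean(axis=1)
    keep = frac >= min_detect_fraction
    excluded = matrix.values_df.index[~keep].tolist()
    out = type(matrix)(matrix.values_df.loc[keep].copy(), scale=matrix.scale)
    return out, excluded


def _like(matrix: QuantMatrix, values: pd.DataFrame) -> QuantMatrix:
    if isinstance(matrix, NormalizedMatrix):
        return NormalizedMatrix(
            values,
            sample_medians=matrix.sample_medians,
            sample_mads=matrix.sample_mads,
        )
    return QuantMatrix(values, scale=matrix.scale)


def impute_knn(matrix: QuantMatrix, k: int = 10) -> QuantMatrix:
    """Fill missing cells from the k nearest feature neighbors.

    Neighbor distance between two features is Euclidean over their jointly
    observed samples, scaled up by the proportion of shared observations
    (the NaN-aware Euclidean distance); a missing cell becomes the mean of
    the k nearest features observed in that sample.  A feature sharing no
    observations with any other falls back to its own mean, with a warning.
    """
    if matrix.scale == "raw":
        raise SolshiftError("impute on a log2 or normalized matrix, not raw")
    df = matrix.values_df
    if df.notna().all().all():
        return _like(matrix, df.copy())
    X = df.to_numpy(dtype=float)
    obs = ~np.isnan(X)

    # features with no overlap with any other feature cannot be imputed
    # from neighbors; fill with the feature mean up front
    shared = obs.astype(int) @ obs.astype(int).T
    np.fill_diagonal(shared, 0)
    isolated = shared.max(axis=1) == 0
    if isolated.any():
        ids = df.index[isolated].tolist()
        warnings.warn(
            f"features with no shared observations, falling back to feature mean: {ids}",
            stacklevel=2,
        )
        for i in np.where(isolated)[0]:
            X[i, ~obs[i]] = np.nanmean(X[i])

    imputer = KNNImputer(n_neighbors=k, weights="uniform", metric="nan_euclidean")
    filled = imputer.fit_transform(X)
    if filled.shape != X.shape:  # KNNImputer drops all-missing columns
        raise SolshiftError("imputation dropped columns; input has all-missing samples")
    out = pd.DataFrame(filled, index=df.index, columns=df.columns)
    # observed cells must pass through untouched
    out = out.where(~df.notna(), df)
    return _like(matrix, out)


@dataclass
class PresenceCalls:
    """Per protein x (disease, fraction) detection counts and calls."""

    detection_counts: pd.DataFrame  # features x groups, int
    group_sizes: pd.Series  # per group
    calls: pd.DataFrame  # features x groups in {present, sparse, missing}
    group_specific: pd.DataFrame  # proteins missing somewhere, majority elsewhere
    disease_specific: pd.Series  # protein -> disease, for fully exclusive cases


def call_presence(
    matrix: QuantMatrix, meta: SampleMeta, missing_max: int = 1
) -> PresenceCalls:
    """Detection counts and presence calls per protein x (disease, fraction).

    A protein is *missing* in a group when detected in at most
    ``missing_max`` of its samples, *present* when detected in a majority
    (> half), and *sparse* in between.  Proteins missing in at least one
    group but present in the majority of cases of at least one other group
    are flagged group-specific; a protein present in every group of exactly
    one disease and missing in all groups of the others is additionally
    flagged disease-specific.
    """
    meta = meta.aligned_to(matrix)
    labels = meta.group_labels()
    obs = matrix.observed_mask()
    counts = {}
    sizes = {}
    for g, samples in meta.groups().items():
        counts[g] = obs[samples].sum(axis=1)
        sizes[g] = len(samples)
    counts_df = pd.DataFrame(counts)
    sizes_s = pd.Series(sizes)

    calls = pd.DataFrame("sparse", index=counts_df.index, columns=counts_df.columns)
    for g in counts_df.columns:
        calls.loc[counts_df[g] <= missing_max, g] = "missing"
        calls.loc[counts_df[g] > sizes_s[g] / 2, g] = "present"

    is_missing = calls == "missing"
    is_present = calls == "present"
    flagged = is_missing.any(axis=1) & is_present.any(axis=1)
    group_specific = pd.DataFrame(
        {
            "missing_groups": calls.apply(
                lambda r: ",".join(sorted(r.index[r == "missing"])), axis=1
            ),
            "present_groups": calls.apply(
                lambda r: ",".join(sorted(r.index[r == "present"])), axis=1
            ),
        }
    ).loc[flagged]

    disease_of = {g: g.split(":", 1)[0] for g in counts_df.columns}
    disease_groups: dict[str, list[str]] = {}
    for g, d in disease_of.items():
        disease_groups.setdefault(d, []).append(g)
    specific = {}
    for protein in counts_df.index[flagged]:
        hits = [
            d
            for d, gs in disease_groups.items()
            if is_present.loc[protein, gs].all()
        ]
        others_missing = (
            len(hits) == 1
            and is_missing.loc[
                protein, [g for g in counts_df.columns if disease_of[g] != hits[0]]
            ].all().item()
        )
        if others_missing:
            specific[protein] = hits[0]
    disease_specific = pd.Series(specific, dtype=object, name="disease")

    return PresenceCalls(
        detection_counts=counts_df,
        group_sizes=sizes_s,
        calls=calls,
        group_specific=group_specific,
        disease_specific=disease_specific,
    )


def sparse_abundance_summary(
    matrix: QuantMatrix, sparse_features
) -> dict[str, float | None]:
    """Mean log2 abundance of a sparse feature set versus all features.

    Means are taken over observed values only.  Raw-scale input is log2
    transformed first; an empty sparse set yields a missing sparse mean.
    """
    if matrix.scale == "raw":
        df = np.log2(matrix.values_df)
    elif matrix.scale == "log2":
        df = matrix.values_df
    else:
        raise SolshiftError("sparse_abundance_summary expects raw or log2 scale")
    sparse_features = [f for f in sparse_features if f in df.index]
    all_mean = float(np.nanmean(df.to_numpy()))
    if not sparse_features:
        return {"sparse_mean_log2": None, "all_mean_log2": all_mean}
    sparse_mean = float(np.nanmean(df.loc[sparse_features].to_numpy()))
    return {"sparse_mean_log2": sparse_mean, "all_mean_log2": all_mean}
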