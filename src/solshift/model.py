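"""Per-protein linear models over disease x fraction groups with
empirical-Bayes variance moderation.

The model is a cell-means linear model fitted protein-wise: each sample
belongs to exactly one (disease, fraction) group, the coefficients are the
group means of the normalized log-scale abundances, and inference on any
contrast c (a zero-sum weight vector over groups) uses a moderated
t-statistic.  Per-protein residual variances s_g^2 (d residual degrees of
freedom each) are shrunk toward a cohort prior by empirical Bayes: the
marginal distribution of s_g^2 under the hierarchical model is a scaled F,
so the prior degrees of freedom d0 and prior variance s0^2 are estimated by
matching the mean and variance of log s_g^2 through digamma/trigamma
identities.  The posterior variance

    s_tilde^2 = (d0 * s0^2 + d * s_g^2) / (d0 + d)

replaces s_g^2 in the t-statistic, which then has d0 + d degrees of
freedom.  Significance per contrast combines a Benjamini-Hochberg FDR
threshold with an absolute log2 fold-change threshold (default 0.585,
i.e. fold change 1.5).

Usage follows the Model / Results convention::

    model = SolubilityLM(normalized_matrix, meta)
    fit = model.fit()
    res = fit.contrast("CBD:insoluble - PSP:insoluble")
    shift = fit.solubility_shift("CBD", "PSP")
    print(fit.summary())
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

from .containers import QuantMatrix, SampleMeta, SolshiftError

LFC_THRESHOLD = 0.585  # |log2 FC| > 0.585 <=> FC > 1.5 or < 0.66
FDR_THRESHOLD = 0.05
D0_CAP = 1e6  # effectively infinite shrinkage


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

@dataclass
class DesignMatrix:
    """Cell-means design: one indicator column per disease:fraction group."""

    matrix: pd.DataFrame  # samples x groups, 0/1
    group_labels: list[str]

    @property
    def n_groups(self) -> int:
        return len(self.group_labels)

    def group_sizes(self) -> pd.Series:
        return self.matrix.sum(axis=0).astype(int)


def build_design(meta: SampleMeta) -> DesignMatrix:
    """Indicator design with one column per (disease, fraction) group.

    Raises if any group has fewer than 2 samples (residual variance would
    be inestimable) or a sample lacks disease/fraction.
    """
    t = meta.table
    if t["disease"].isna().any() or t["fraction"].isna().any():
        bad = t.loc[t["disease"].isna() | t["fraction"].isna(), "sample_id"].tolist()
        raise SolshiftError(f"samples with unknown disease/fraction: {bad}")
    labels = meta.group_labels()
    X = pd.get_dummies(labels).astype(float)
    X = X[sorted(X.columns)]
    sizes = X.sum(axis=0)
    small = sizes[sizes < 2]
    if len(small):
        raise SolshiftError(
            f"groups with <2 samples (variance inestimable): {sorted(small.index)}"
        )
    return DesignMatrix(matrix=X, group_labels=list(X.columns))


def contrast_vector(design: DesignMatrix, spec) -> np.ndarray:
    """Build a zero-sum contrast weight vector over design groups.

    ``spec`` may be a mapping {group: weight}, an array of weights in
    design-column order, or a string expression like
    ``"CBD:insoluble - PSP:insoluble"``.
    """
    groups = design.group_labels
    if isinstance(spec, str):
        weights = dict.fromkeys(groups, 0.0)
        for sign, name in re.findall(r"([+-]?)\s*([A-Za-z0-9_.]+:[A-Za-z0-9_.]+)", spec):
            if name not in weights:
                raise SolshiftError(f"unknown group {name!r}; groups are {groups}")
            weights[name] += -1.0 if sign == "-" else 1.0
        c = np.array([weights[g] for g in groups])
    elif isinstance(spec, dict):
        unknown = set(spec) - set(groups)
        if unknown:
            raise SolshiftError(f"unknown groups in contrast: {sorted(unknown)}")
        c = np.array([float(spec.get(g, 0.0)) for g in groups])
    else:
        c = np.asarray(spec, dtype=float)
        if c.shape != (len(groups),):
            raise SolshiftError(f"contrast must have {len(groups)} weights")
    if abs(c.sum()) > 1e-9:
        raise SolshiftError(f"contrast weights must sum to 0, got {c.sum()}")
    if not np.any(c):
        raise SolshiftError("contrast is identically zero")
    return c


# ---------------------------------------------------------------------------
# empirical-Bayes hyperparameters
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on the inverse scale)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x += dif
        if -dif / x < 1e-8:
            break
    return float(x)


def estimate_eb_hyperparameters(s2: np.ndarray, d: float) -> tuple[float, float]:
    """Estimate prior df d0 and prior variance s0^2 from sample variances.

    Matches the first two moments of log s^2 against its theoretical
    scaled-F log distribution: with z = log s^2,

        var(z) = trigamma(d/2) + trigamma(d0/2)
        mean(z) = log s0^2 + digamma(d/2) - log(d/2)
                  - digamma(d0/2) + log(d0/2)

    When the empirical variance of z does not exceed trigamma(d/2) the data
    are consistent with a single common variance and d0 is capped at 1e6
    (effectively infinite shrinkage).
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if len(s2) < 10:
        raise SolshiftError(
            f"need >=10 positive variances to estimate the prior, got {len(s2)}"
        )
    if d < 1:
        raise SolshiftError("residual df must be >= 1")
    z = np.log(s2)
    e_mean = z.mean()
    e_var = z.var(ddof=1)
    excess = e_var - polygamma(1, d / 2)
    if excess <= 0:
        d0 = D0_CAP
    else:
        d0 = min(2.0 * _trigamma_inverse(float(excess)), D0_CAP)
    log_s0 = (
        e_mean
        - digamma(d / 2)
        + np.log(d / 2)
        + digamma(d0 / 2)
        - np.log(d0 / 2)
    )
    return float(d0), float(np.exp(log_s0))


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (one contrast family)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise SolshiftError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class SolubilityLM:
    """Protein-wise cell-means linear model for a two-fraction cohort.

    Parameters
    ----------
    matrix
        Complete (imputed) normalized matrix, features x samples, on a log
        or modified z-score scale.
    meta
        Sample metadata; every matrix sample must have one record.
    """

    def __init__(self, matrix: QuantMatrix, meta: SampleMeta):
        if matrix.scale == "raw":
            raise SolshiftError("fit the model on log2 or modz scale, not raw")
        if not matrix.is_complete():
            raise SolshiftError("model requires a complete (imputed) matrix")
        self.matrix = matrix
        self.meta = meta.aligned_to(matrix)
        self.design = build_design(self.meta)

    @classmethod
    def from_dataframes(cls, values: pd.DataFrame, meta: pd.DataFrame, scale: str = "modz"):
        return cls(QuantMatrix(values, scale=scale), SampleMeta(meta))

    def fit(self, moderate: bool = True) -> "SolubilityLMResults":
        """OLS per protein, then empirical-Bayes variance moderation."""
        X = self.design.matrix.loc[self.matrix.sample_ids].to_numpy()
        Y = self.matrix.values_df.to_numpy()  # proteins x samples
        n, g = X.shape
        xtx = X.T @ X
        xtx_inv = np.linalg.inv(xtx)
        beta = Y @ X @ xtx_inv.T  # proteins x groups
        resid = Y - beta @ X.T
        d = n - g
        if d < 1:
            raise SolshiftError("no residual degrees of freedom")
        s2 = (resid**2).sum(axis=1) / d
        if moderate:
            d0, s0_2 = estimate_eb_hyperparameters(s2, d)
        else:
            d0, s0_2 = 0.0, float(np.median(s2[s2 > 0])) if np.any(s2 > 0) else 0.0
        return SolubilityLMResults(
            model=self,
            coefficients=pd.DataFrame(
                beta, index=self.matrix.feature_ids, columns=self.design.group_labels
            ),
            s2=pd.Series(s2, index=self.matrix.feature_ids, name="s2"),
            df_residual=float(d),
            d0=d0,
            s0_2=s0_2,
            xtx_inv=xtx_inv,
        )


@dataclass
class SolubilityLMResults:
    """Fitted group means with moderated-t inference on contrasts."""

    model: SolubilityLM
    coefficients: pd.DataFrame  # proteins x groups
    s2: pd.Series
    df_residual: float
    d0: float
    s0_2: float
    xtx_inv: np.ndarray
    _contrast_cache: dict = field(default_factory=dict, repr=False)

    # -- variance moderation -------------------------------------------
    @property
    def posterior_s2(self) -> pd.Series:
        d, d0 = self.df_residual, self.d0
        if np.isinf(d0) or d0 >= D0_CAP:
            post = np.full(len(self.s2), self.s0_2)
        else:
            post = (d0 * self.s0_2 + d * self.s2.to_numpy()) / (d0 + d)
        return pd.Series(post, index=self.s2.index, name="posterior_s2")

    @property
    def df_total(self) -> float:
        return min(self.d0 + self.df_residual, 1e300)

    # -- inference ------------------------------------------------------
    def contrast(
        self,
        spec,
        lfc_threshold: float = LFC_THRESHOLD,
        fdr_threshold: float = FDR_THRESHOLD,
    ) -> pd.DataFrame:
        """Moderated t-test of one contrast, BH-adjusted within this family.

        Returns a DataFrame indexed by protein with columns log2FC, t, p,
        fdr, significant.
        """
        c = contrast_vector(self.model.design, spec)
        est = self.coefficients.to_numpy() @ c
        var_c = float(c @ self.xtx_inv @ c)
        if var_c <= 0:
            raise SolshiftError("non-estimable contrast")
        se = np.sqrt(self.posterior_s2.to_numpy() * var_c)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, est / se, 0.0)
        df = self.df_total
        p = 2.0 * stats.t.sf(np.abs(t), df)
        fdr = bh_adjust(p)
        out = pd.DataFrame(
            {
                "log2FC": est,
                "t": t,
                "p": p,
                "fdr": fdr,
                "significant": (fdr < fdr_threshold) & (np.abs(est) > lfc_threshold),
            },
            index=self.coefficients.index,
        )
        out.index.name = "protein"
        return out

    def fraction_contrast(self, disease_a: str, disease_b: str, fraction: str, **kw):
        """Disease A vs B within one fraction (A minus B)."""
        return self.contrast(f"{disease_a}:{fraction} - {disease_b}:{fraction}", **kw)

    def solubility_shift(self, disease_a: str, disease_b: str, **kw) -> pd.DataFrame:
        """Difference-of-differences solubility contrast between diseases:

            [A insoluble - A soluble] - [B insoluble - B soluble]

        Positive estimates mean the protein is comparatively more insoluble
        in disease A.  Returns the contrast table with a ``direction``
        column naming the disease the protein is more insoluble in.
        """
        groups = set(self.model.design.group_labels)
        needed = {
            f"{d}:{f}" for d in (disease_a, disease_b) for f in ("insoluble", "soluble")
        }
        missing = sorted(needed - groups)
        if missing:
            raise SolshiftError(f"missing groups for solubility shift: {missing}")
        spec = {
            f"{disease_a}:insoluble": 1.0,
            f"{disease_a}:soluble": -1.0,
            f"{disease_b}:insoluble": -1.0,
            f"{disease_b}:soluble": 1.0,
        }
        out = self.contrast(spec, **kw)
        out["direction"] = np.where(
            out["log2FC"] >= 0,
            f"more insoluble in {disease_a}",
            f"more insoluble in {disease_b}",
        )
        return out

    def all_pairwise(self, kind: str = "insoluble", **kw) -> dict[tuple[str, str], pd.DataFrame]:
        """Every disease pair for one family: a fraction name or 'shift'."""
        diseases = self.model.meta.diseases
        out = {}
        for i, a in enumerate(diseases):
            for b in diseases[i + 1:]:
                if kind == "shift":
                    out[(a, b)] = self.solubility_shift(a, b, **kw)
                else:
                    out[(a, b)] = self.fraction_contrast(a, b, kind, **kw)
        return out

    def summary(self) -> str:
        """Human-readable summary of the fit and hyperparameters."""
        sizes = self.model.design.group_sizes()
        lines = [
            "Protein-wise cell-means linear model (empirical-Bayes moderated)",
            "=" * 64,
            f"proteins: {len(self.coefficients)}    samples: {int(sizes.sum())}",
            "groups: "
            + ", ".join(f"{g} (n={int(sizes[g])})" for g in self.model.design.group_labels),
            f"residual df per protein: {self.df_residual:.0f}",
            f"prior df d0: {self.d0:.4g}    prior variance s0^2: {self.s0_2:.4g}",
            f"total df for moderated t: {self.df_total:.4g}",
            f"median residual s^2: {float(self.s2.median()):.4g}    "
            f"median posterior s^2: {float(self.posterior_s2.median()):.4g}",
        ]
        return "\n".join(lines)


def classify_significant(
    result: pd.DataFrame,
    lfc_threshold: float = LFC_THRESHOLD,
    fdr_threshold: float = FDR_THRESHOLD,
) -> pd.DataFrame:
    """(Re)apply significance thresholds and add volcano columns.

    Adds/overwrites ``significant`` (fdr < threshold and |log2FC| above the
    fold-change cut) and ``neg_log10_p`` for volcano plotting.
    """
    out = result.copy()
    out["significant"] = (out["fdr"] < fdr_threshold) & (
        out["log2FC"].abs() > lfc_threshold
    )
    with np.errstate(divide="ignore"):
        out["neg_log10_p"] = -np.log10(out["p"])
    return out


def significant_summary(results: dict) -> pd.DataFrame:
    """Count significant proteins per contrast from a {name: table} dict."""
    rows = [
        {"contrast": str(k), "n_significant": int(v["significant"].sum()), "n_tested": len(v)}
        for k, v in results.items()
    ]
    return pd.DataFrame(rows)
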