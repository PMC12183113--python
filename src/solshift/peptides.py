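"""Peptide-level solubility analysis against a reference protein isoform.

Tau is expressed as 3R or 4R isoforms depending on whether the second
microtubule-binding repeat (exon 10; residues 275-305 of the 441-aa 2N4R
reference) is spliced in.  A tryptic peptide lying in that repeat is
therefore 4R-defining, while peptides elsewhere are constitutive.  Peptide
abundances are summed over all mass detections of the same sequence
(charge states, modified forms) and tested between disease groups per
fraction with a normality-gated test: one-way ANOVA with Tukey pairwise
adjustment when every group passes Shapiro-Wilk, otherwise Kruskal-Wallis
with Dunn pairwise comparisons (BH-adjusted).  No normalization or
imputation is applied at the peptide level.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import SolshiftError

# second microtubule-binding repeat of 2N4R tau (exon 10)
R2_START, R2_END = 275, 305


def sum_peptide_detections(detections: pd.DataFrame) -> pd.DataFrame:
    """Sum abundances over all detections of the same peptide sequence.

    Input is long format (sequence, sample_id, abundance, one row per mass
    detection); output is wide (sequence x sample), with NaN where a
    sequence was never detected in a sample.
    """
    required = {"sequence", "sample_id", "abundance"}
    missing = required - set(detections.columns)
    if missing:
        raise SolshiftError(f"peptide table missing columns {sorted(missing)}")
    wide = detections.pivot_table(
        index="sequence", columns="sample_id", values="abundance", aggfunc="sum"
    )
    wide.index.name = "sequence"
    return wide


def map_peptides_to_isoform(sequences, reference: str) -> pd.DataFrame:
    """Locate peptides on a reference isoform and flag splice specificity.

    Exact substring search; coordinates are 1-based inclusive.  A mapped
    peptide overlapping the R2 repeat (275-305) is 4R-defining, any other
    mapped peptide constitutive, and peptides absent from the reference are
    unmapped.  Multiple occurrences map to the first with a warning.
    """
    rows = []
    for seq in sequences:
        if not seq:
            raise SolshiftError("empty peptide sequence")
        pos = reference.find(seq)
        if pos < 0:
            rows.append(
                {"sequence": seq, "start": pd.NA, "end": pd.NA,
                 "isoform_specificity": "unmapped"}
            )
            continue
        if reference.find(seq, pos + 1) >= 0:
            warnings.warn(
                f"peptide {seq!r} occurs multiple times in reference; "
                "using first occurrence"
            )
        start, end = pos + 1, pos + len(seq)
        overlaps_r2 = start <= R2_END and end >= R2_START
        rows.append(
            {
                "sequence": seq,
                "start": start,
                "end": end,
                "isoform_specificity": "4R-defining" if overlaps_r2 else "constitutive",
            }
        )
    out = pd.DataFrame(rows).set_index("sequence")
    out["start"] = out["start"].astype("Int64")
    out["end"] = out["end"].astype("Int64")
    return out


def _dunn_pairwise(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's z-tests on pooled ranks with tie correction, BH-adjusted."""
    names = list(groups)
    pooled = np.concatenate([groups[g] for g in names])
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    offsets = np.cumsum([0] + [len(groups[g]) for g in names])
    mean_ranks = {
        g: ranks[offsets[i]:offsets[i + 1]].mean() for i, g in enumerate(names)
    }
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n - 1))
    rows = []
    for a, b in itertools.combinations(names, 2):
        na, nb = len(groups[a]), len(groups[b])
        se = np.sqrt((n * (n + 1) / 12.0 - tie_term) * (1.0 / na + 1.0 / nb))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "statistic": z, "p": p})
    out = pd.DataFrame(rows)
    from .model import bh_adjust

    out["p_adjusted"] = np.maximum(bh_adjust(out["p"].to_numpy()), out["p"].to_numpy())
    return out


def _tukey_pairwise(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    names = list(groups)
    res = stats.tukey_hsd(*[groups[g] for g in names])
    rows = []
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            rows.append(
                {
                    "group_a": a,
                    "group_b": names[j],
                    "statistic": float(res.statistic[i, j]),
                    "p": float(res.pvalue[i, j]),
                    "p_adjusted": float(res.pvalue[i, j]),  # Tukey is family-adjusted
                }
            )
    return pd.DataFrame(rows)


@dataclass
class PeptideTestResult:
    """Normality-gated group comparison for one peptide in one fraction."""

    test_used: str  # "anova_tukey" or "kruskal_dunn"
    normality_p: dict[str, float]
    omnibus_p: float
    pairwise: pd.DataFrame  # group_a, group_b, statistic, p, p_adjusted


def peptide_group_test(
    values_by_group: dict[str, np.ndarray],
    normality_alpha: float = 0.05,
) -> PeptideTestResult:
    """Compare one peptide's abundances across disease groups.

    All groups normal by Shapiro-Wilk (p > alpha) -> one-way ANOVA with
    Tukey HSD pairwise p-values; otherwise Kruskal-Wallis with Dunn
    pairwise tests (BH-adjusted).  Missing values are dropped per group;
    every group needs >= 3 observations.  Values constant within every
    group and across groups yield omnibus p = 1.
    """
    groups = {g: np.asarray(v, dtype=float) for g, v in values_by_group.items()}
    groups = {g: v[~np.isnan(v)] for g, v in groups.items()}
    thin = [g for g, v in groups.items() if len(v) < 3]
    if thin or len(groups) < 2:
        raise SolshiftError(f"need >=2 groups with >=3 values; too few in {thin}")

    pooled = np.concatenate(list(groups.values()))
    if np.all(pooled == pooled[0]):
        names = list(groups)
        pairwise = pd.DataFrame(
            [
                {"group_a": a, "group_b": b, "statistic": 0.0, "p": 1.0, "p_adjusted": 1.0}
                for a, b in itertools.combinations(names, 2)
            ]
        )
        return PeptideTestResult(
            test_used="anova_tukey",
            normality_p={g: 1.0 for g in groups},
            omnibus_p=1.0,
            pairwise=pairwise,
        )

    normality = {}
    for g, v in groups.items():
        if np.all(v == v[0]):
            normality[g] = 0.0  # constant group: not plausibly normal
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                normality[g] = float(stats.shapiro(v).pvalue)

    if all(p > normality_alpha for p in normality.values()):
        _, omnibus = stats.f_oneway(*groups.values())
        pairwise = _tukey_pairwise(groups)
        test_used = "anova_tukey"
    else:
        _, omnibus = stats.kruskal(*groups.values())
        pairwise = _dunn_pairwise(groups)
        test_used = "kruskal_dunn"
    return PeptideTestResult(
        test_used=test_used,
        normality_p=normality,
        omnibus_p=float(omnibus),
        pairwise=pairwise,
    )


def test_peptides_by_fraction(
    abundances: pd.DataFrame, meta, min_per_group: int = 3
) -> pd.DataFrame:
    """Run the normality-gated group test for every peptide and fraction.

    ``abundances`` is the summed wide table (sequence x sample).  Returns a
    long DataFrame with one row per peptide x fraction x disease pair.
    """
    meta_t = meta.table.set_index("sample_id")
    rows = []
    for fraction in sorted(meta_t["fraction"].unique()):
        frac_samples = meta_t.index[meta_t["fraction"] == fraction]
        frac_samples = [s for s in frac_samples if s in abundances.columns]
        disease_of = meta_t.loc[frac_samples, "disease"]
        for seq, vals in abundances[frac_samples].iterrows():
            groups = {}
            for disease in sorted(disease_of.unique()):
                v = vals[disease_of.index[disease_of == disease]].dropna().to_numpy()
                if len(v) >= min_per_group:
                    groups[disease] = v
            if len(groups) < 2:
                continue
            res = peptide_group_test(groups)
            for _, pr in res.pairwise.iterrows():
                rows.append(
                    {
                        "sequence": seq,
                        "fraction": fraction,
                        "test_used": res.test_used,
                        "omnibus_p": res.omnibus_p,
                        "group_a": pr["group_a"],
                        "group_b": pr["group_b"],
                        "p": pr["p"],
                        "p_adjusted": pr["p_adjusted"],
                    }
                )
    return pd.DataFrame(rows)
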