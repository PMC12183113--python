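"""Seeded synthetic cohorts with the structure the analysis assumes.

The generator emulates a two-fraction label-free proteomics cohort of three
tauopathy-like disease groups with five cases each (30 samples): per
protein, log2 intensity is

    baseline_p + fraction_effect_p * [insoluble]
    + delta_{p,disease} * [insoluble] + case_effect_case + noise

so a planted delta is exactly the disease-specific solubility shift the
difference-of-differences contrast estimates.  Case effects are shared
between a case's soluble and insoluble samples (realistic pairing, which
the independent-samples model deliberately ignores).  A correlated block
ties a group of proteins to an anchor through a shared latent factor at a
chosen latent correlation.  Missingness is MNAR: an observation is dropped
with probability 1 / (1 + exp(slope * (x - tau))), so low-abundance
features are sparser, mirroring real LFQ dropout.  Everything is a pure
function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import QuantMatrix, SampleMeta, SolshiftError

DEFAULT_DISEASES = ("CBD", "PiD", "PSP")


@dataclass
class CohortConfig:
    """Stated world for one synthetic cohort."""

    n_proteins: int = 2000
    diseases: tuple[str, ...] = DEFAULT_DISEASES
    cases_per_group: int = 5
    baseline_mean: float = 18.0  # log2 LFQ
    baseline_sd: float = 2.0
    residual_sd: float = 0.5
    case_effect_sd: float = 0.3
    fraction_effect_sd: float = 1.5  # per-protein soluble->insoluble offset
    # protein -> disease -> extra insoluble-minus-soluble shift (log2)
    effects: dict[str, dict[str, float]] = field(default_factory=dict)
    # correlated block: proteins co-generated with an anchor
    block_size: int = 0
    block_latent_r: float = 0.9
    block_anchor: str | None = None
    # MNAR dropout: P(drop | x) = 1 / (1 + exp(slope * (x - tau)))
    dropout_tau: float = 14.0
    dropout_slope: float = 1.0
    seed: int = 0

    def validate(self, protein_ids: list[str]) -> None:
        for sd in (self.baseline_sd, self.residual_sd):
            if sd <= 0:
                raise SolshiftError("all standard deviations must be > 0")
        known = set(protein_ids)
        unknown = set(self.effects) - known
        if unknown:
            raise SolshiftError(f"effects reference unknown proteins: {sorted(unknown)}")
        if self.block_anchor is not None and self.block_anchor not in known:
            raise SolshiftError(f"block anchor {self.block_anchor!r} not a protein")


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a cohort."""

    group_means: pd.DataFrame  # proteins x disease:fraction, log2
    shifts: pd.DataFrame  # proteins x diseases: planted delta
    block_members: list[str]
    detection_prob: pd.DataFrame  # proteins x groups, at the group mean
    config: CohortConfig

    def shifted_proteins(self, disease_a: str, disease_b: str, tol: float = 1e-12):
        """Proteins whose planted shift differs between two diseases."""
        diff = self.shifts[disease_a] - self.shifts[disease_b]
        return list(diff.index[diff.abs() > tol]), diff

    def null_proteins(self, disease_a: str, disease_b: str, tol: float = 1e-12):
        shifted, _ = self.shifted_proteins(disease_a, disease_b, tol)
        return [p for p in self.shifts.index if p not in set(shifted)]


def _protein_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"PROT{i:0{width}d}" for i in range(1, n + 1)]


def generate_cohort(config: CohortConfig):
    """Generate (raw QuantMatrix, SampleMeta, SyntheticTruth) for a config.

    The returned matrix is on the raw linear LFQ scale (2**log2) with MNAR
    missingness already applied.  Byte-identical for equal seeds.
    """
    ids = _protein_ids(config.n_proteins)
    config.validate(ids)
    rng = np.random.default_rng(config.seed)
    diseases = list(config.diseases)
    n_cases = config.cases_per_group
    fractions = ["soluble", "insoluble"]

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, config.n_proteins)
    frac_effect = rng.normal(0.0, config.fraction_effect_sd, config.n_proteins)

    block_members: list[str] = []
    block_idx = np.zeros(config.n_proteins, dtype=bool)
    if config.block_size > 0:
        anchor = config.block_anchor
        pool = [i for i, pid in enumerate(ids) if pid != anchor]
        chosen = list(rng.choice(len(pool), size=config.block_size, replace=False))
        members = [pool[i] for i in chosen]
        if anchor is not None:
            members.append(ids.index(anchor))
        block_idx[members] = True
        # block proteins share the fraction response so their combined
        # soluble+insoluble profiles co-vary cleanly with the anchor
        frac_effect[block_idx] = frac_effect[members[-1]]
        block_members = [ids[i] for i in np.where(block_idx)[0]]

    delta = pd.DataFrame(0.0, index=ids, columns=diseases)
    for pid, per_disease in config.effects.items():
        for disease, value in per_disease.items():
            if disease not in delta.columns:
                raise SolshiftError(f"effect for unknown disease {disease!r}")
            delta.loc[pid, disease] = value

    sample_rows = []
    columns = {}
    group_mean = {}
    for disease in diseases:
        case_effects = rng.normal(0.0, config.case_effect_sd, n_cases)
        for fraction in fractions:
            is_ins = fraction == "insoluble"
            mu = (
                baseline
                + (frac_effect + delta[disease].to_numpy()) * is_ins
            )
            group_mean[f"{disease}:{fraction}"] = mu.copy()
            for case in range(n_cases):
                sid = f"{disease}_{case + 1:02d}_{fraction}"
                sample_rows.append(
                    {
                        "sample_id": sid,
                        "case_id": f"{disease}_{case + 1:02d}",
                        "disease": disease,
                        "fraction": fraction,
                    }
                )
                noise = rng.normal(0.0, 1.0, config.n_proteins)
                if block_idx.any():
                    latent = rng.normal()
                    r = config.block_latent_r
                    noise[block_idx] = (
                        np.sqrt(r) * latent + np.sqrt(1.0 - r) * noise[block_idx]
                    )
                x = mu + case_effects[case] + config.residual_sd * noise
                drop_p = 1.0 / (1.0 + np.exp(config.dropout_slope * (x - config.dropout_tau)))
                observed = rng.random(config.n_proteins) >= drop_p
                col = np.where(observed, 2.0**x, np.nan)
                columns[sid] = col

    values = pd.DataFrame(columns, index=ids)
    matrix = QuantMatrix(values, scale="raw")
    meta_t = pd.DataFrame(sample_rows)
    # benign covariates for QC exercises
    cases = meta_t["case_id"].unique()
    cov_rng = np.random.default_rng(config.seed + 1)
    age = {c: float(cov_rng.normal(72, 6)) for c in cases}
    pmd = {c: float(np.abs(cov_rng.normal(20, 8))) for c in cases}
    sex = {c: ("F" if cov_rng.random() < 0.5 else "M") for c in cases}
    meta_t["age"] = meta_t["case_id"].map(age)
    meta_t["pmd"] = meta_t["case_id"].map(pmd)
    meta_t["sex"] = meta_t["case_id"].map(sex)
    meta = SampleMeta(meta_t)

    gm = pd.DataFrame(group_mean, index=ids)
    detect_p = 1.0 - 1.0 / (
        1.0 + np.exp(config.dropout_slope * (gm - config.dropout_tau))
    )
    truth = SyntheticTruth(
        group_means=gm,
        shifts=delta,
        block_members=block_members,
        detection_prob=detect_p,
        config=config,
    )
    return matrix, meta, truth


# ---------------------------------------------------------------------------
# peptide-level generator
# ---------------------------------------------------------------------------

def generate_peptides(
    parent_abundance: pd.Series,
    peptides: pd.DataFrame,
    four_r_share,
    noise_sd: float = 0.1,
    max_detections: int = 3,
    seed: int = 0,
):
    """Emit a long peptide detection table from a parent protein profile.

    Parameters
    ----------
    parent_abundance
        Linear-scale parent protein abundance per sample (index sample_id).
    peptides
        DataFrame with columns ``sequence`` and ``isoform_specificity``
        ('constitutive' or '4R-defining'), e.g. from
        :func:`solshift.peptides.map_peptides_to_isoform`.
    four_r_share
        Scalar or per-sample Series in [0, 1]: fraction of the parent pool
        carrying the second repeat.  4R-defining peptides are drawn from
        that sub-pool only; a share of 0 makes them structurally absent.
    noise_sd
        SD of multiplicative log2-normal measurement noise.
    max_detections
        Detections per (sequence, sample) are drawn uniformly from
        1..max_detections to exercise summation.

    Returns (detections DataFrame, truth DataFrame of per-sample totals).
    """
    rng = np.random.default_rng(seed)
    samples = list(parent_abundance.index)
    if np.isscalar(four_r_share):
        share = pd.Series(float(four_r_share), index=samples)
    else:
        share = pd.Series(four_r_share).reindex(samples)
    if ((share < 0) | (share > 1)).any():
        raise SolshiftError("four_r_share must lie in [0, 1]")

    ion = {
        seq: float(2.0 ** rng.normal(-3.0, 1.0))
        for seq in peptides["sequence"]
    }
    det_rows = []
    truth_rows = []
    for _, prow in peptides.iterrows():
        seq = prow["sequence"]
        is_4r = prow["isoform_specificity"] == "4R-defining"
        for sid in samples:
            pool = parent_abundance[sid] * (share[sid] if is_4r else 1.0)
            if pool <= 0:
                continue
            total = pool * ion[seq] * 2.0 ** rng.normal(0.0, noise_sd)
            m = int(rng.integers(1, max_detections + 1))
            splits = rng.dirichlet(np.ones(m)) * total if m > 1 else [total]
            for part in splits:
                det_rows.append(
                    {"sequence": seq, "sample_id": sid, "abundance": float(part)}
                )
            truth_rows.append(
                {"sequence": seq, "sample_id": sid, "total": float(total), "n_detections": m}
            )
    return pd.DataFrame(det_rows), pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# recovery scoring
# ---------------------------------------------------------------------------

@dataclass
class RecoveryReport:
    power: float | None  # None when no true effects exist
    fdp: float
    bias: float | None
    n_true: int
    n_flagged: int


def evaluate_recovery(
    result: pd.DataFrame,
    truth: SyntheticTruth,
    disease_a: str,
    disease_b: str,
) -> RecoveryReport:
    """Score a solubility-shift contrast table against planted truth.

    power: fraction of truly shifted proteins flagged significant;
    FDP: fraction of flagged proteins with no planted shift;
    bias: mean(estimate - true delta difference) over true positives.

    Results may cover a subset of the truth universe (detection-filtered
    proteins count as not flagged); proteins outside the universe error.
    """
    if not set(result.index) <= set(truth.shifts.index):
        raise SolshiftError("results and truth must share the protein universe")
    shifted, true_diff = truth.shifted_proteins(disease_a, disease_b)
    flagged = set(result.index[result["significant"]])
    n_true = len(shifted)
    power = len(flagged & set(shifted)) / n_true if n_true else None
    fdp = (
        len(flagged - set(shifted)) / len(flagged) if flagged else 0.0
    )
    tp = sorted(flagged & set(shifted))
    bias = (
        float((result.loc[tp, "log2FC"] - true_diff.loc[tp]).mean()) if tp else None
    )
    return RecoveryReport(
        power=power, fdp=fdp, bias=bias, n_true=n_true, n_flagged=len(flagged)
    )
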