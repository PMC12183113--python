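"""Solubility-shift contrasts and rank-shift summaries.

The difference-of-differences contrast itself lives on
:meth:`solshift.model.SolubilityLMResults.solubility_shift`; this module
adds the functional wrapper plus rank tables: within each (disease,
fraction) group proteins are ranked 1..P by descending mean abundance, and
the soluble-minus-insoluble rank difference summarizes how far a protein
moves up the abundance ladder when it partitions into the insoluble pellet.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import QuantMatrix, SampleMeta, SolshiftError
from .model import SolubilityLMResults


def solubility_shift_contrast(
    fit: SolubilityLMResults, disease_a: str, disease_b: str, **kw
) -> pd.DataFrame:
    """[A insoluble - A soluble] - [B insoluble - B soluble] per protein."""
    return fit.solubility_shift(disease_a, disease_b, **kw)


@dataclass
class RankTable:
    """Per-group protein ranks by average abundance plus rank shifts."""

    ranks: pd.DataFrame  # proteins x groups, 1 = most abundant
    means: pd.DataFrame  # proteins x groups
    shifts: pd.DataFrame  # proteins x diseases: soluble rank - insoluble rank


def rank_shift(matrix: QuantMatrix, meta: SampleMeta) -> RankTable:
    """Rank proteins by average abundance per (disease, fraction) group.

    Requires a complete (imputed) matrix.  Rank 1 is the most abundant
    protein; ties are broken by protein id so the ranking is deterministic.
    The shift for a disease is soluble rank minus insoluble rank: a large
    positive shift marks a protein far more prominent in the insoluble
    fraction.
    """
    if not matrix.is_complete():
        raise SolshiftError("rank_shift requires a complete (imputed) matrix")
    meta = meta.aligned_to(matrix)
    groups = meta.groups()
    means = pd.DataFrame(
        {g: matrix.values_df[samples].mean(axis=1) for g, samples in groups.items()}
    )
    ranks = {}
    for g in means.columns:
        order = means[g].to_frame("m")
        order["pid"] = order.index
        order = order.sort_values(["m", "pid"], ascending=[False, True], kind="stable")
        r = pd.Series(np.arange(1, len(order) + 1), index=order.index)
        ranks[g] = r.reindex(means.index)
    ranks_df = pd.DataFrame(ranks).astype(int)

    shifts = {}
    for disease in meta.diseases:
        sol, ins = f"{disease}:soluble", f"{disease}:insoluble"
        if sol in ranks_df.columns and ins in ranks_df.columns:
            shifts[disease] = ranks_df[sol] - ranks_df[ins]
    return RankTable(ranks=ranks_df, means=means, shifts=pd.DataFrame(shifts))
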