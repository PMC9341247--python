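"""Shared/private partition and mutational concordance of matched pairs.

Mutations of a matched primary / lymph-node pair are keyed by
(chrom, pos, ref, alt) and partitioned into shared (present in both samples)
and private (present in one). Concordance is the shared fraction of the
pair's mutation union (Jaccard index); a per-gene binary-profile Pearson
correlation is available as a secondary, clearly distinct similarity metric.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import PatientPair

logger = logging.getLogger(__name__)

__all__ = [
    "PairConcordance",
    "partition_shared_private",
    "pair_concordance",
    "cohort_concordance_summary",
    "gene_profile_correlation",
]

Key = tuple[str, int, str, str]


@dataclass(frozen=True, slots=True)
class PairConcordance:
    patient_id: str
    shared: int
    private_p: int
    private_ln: int

    @property
    def union(self) -> int:
        return self.shared + self.private_p + self.private_ln

    @property
    def concordance(self) -> float:
        return self.shared / self.union

    @property
    def concordance_pct(self) -> float:
        """Concordance as a percentage rounded to one decimal (report scale)."""
        return round(100.0 * self.concordance, 1)


def partition_shared_private(
    pair: PatientPair,
) -> tuple[set[Key], set[Key], set[Key]]:
    """Split a pair's mutation keys into (shared, private_primary, private_ln).

    The three sets are disjoint and their union covers every distinct key in
    the pair.
    """
    p_keys = pair.primary.mutation_keys()
    ln_keys = pair.lymph_node.mutation_keys()
    return (p_keys & ln_keys, p_keys - ln_keys, ln_keys - p_keys)


def pair_concordance(pair: PatientPair) -> PairConcordance | None:
    """Concordance of one pair; None (with a warning) if the union is empty."""
    shared, priv_p, priv_ln = partition_shared_private(pair)
    if not (shared or priv_p or priv_ln):
        logger.warning(
            "patient %s: no mutations in either sample; excluded from concordance",
            pair.patient_id,
        )
        return None
    return PairConcordance(
        patient_id=pair.patient_id,
        shared=len(shared),
        private_p=len(priv_p),
        private_ln=len(priv_ln),
    )


def cohort_concordance_summary(
    pairs: Sequence[PatientPair],
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-pair concordance table plus cohort mean/SD/min/max (percent).

    SD uses the sample (n-1) convention. A single valid pair reports SD 0.0
    with ``sd_defined=False`` in the summary.
    """
    rows = []
    for pair in pairs:
        pc = pair_concordance(pair)
        if pc is None:
            continue
        rows.append(
            {
                "patient_id": pc.patient_id,
                "shared": pc.shared,
                "private_p": pc.private_p,
                "private_ln": pc.private_ln,
                "union": pc.union,
                "concordance_pct": pc.concordance_pct,
            }
        )
    if not rows:
        raise ValueError("no pair with a non-empty mutation union")
    table = pd.DataFrame(rows)
    vals = table["concordance_pct"].to_numpy(dtype=float)
    sd_defined = len(vals) > 1
    summary = {
        "n_pairs": float(len(vals)),
        "mean_pct": float(np.mean(vals)),
        "sd_pct": float(np.std(vals, ddof=1)) if sd_defined else 0.0,
        "min_pct": float(np.min(vals)),
        "max_pct": float(np.max(vals)),
        "sd_defined": float(sd_defined),
    }
    return table, summary


def gene_profile_correlation(pair: PatientPair) -> float:
    """Secondary metric: Pearson r between the pair's binary gene profiles.

    Genes mutated anywhere in the pair form the profile support; r is NaN for
    degenerate (constant) profiles.
    """
    genes = sorted(
        {m.gene for m in pair.primary.mutations} | {m.gene for m in pair.lymph_node.mutations}
    )
    if not genes:
        return math.nan
    p_genes = {m.gene for m in pair.primary.mutations}
    ln_genes = {m.gene for m in pair.lymph_node.mutations}
    x = np.array([g in p_genes for g in genes], dtype=float)
    y = np.array([g in ln_genes for g in genes], dtype=float)
    if x.std() == 0.0 or y.std() == 0.0:
        return math.nan
    return float(np.corrcoef(x, y)[0, 1])
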