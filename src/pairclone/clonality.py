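"""Cancer cell fraction (CCF) estimation and clonal/subclonal classification.

The CCF of a somatic mutation is the fraction of tumor cells that carry it,
estimated from the variant allele fraction (VAF) corrected for tumor purity
and local copy number. With tumor local total copy number ``c`` (default 2,
heterozygous diploid), mutation multiplicity ``m`` and purity ``p``::

    ccf = vaf * (p*c + (1-p)*2) / (p * m)

``m`` is estimated as ``max(1, round(vaf * (p*c + (1-p)*2) / p))`` and the
CCF is clamped to [0, 1]. Mutations with CCF strictly greater than 0.6 are
labelled clonal, otherwise subclonal; a CCF of exactly 0.6 is subclonal.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .cohort import MutationRecord, PatientPair, TumorSample

__all__ = [
    "CLONAL_CCF_THRESHOLD",
    "ClonalityCall",
    "estimate_ccf",
    "classify_clonality",
    "call_sample",
    "call_pairs",
    "clonality_table",
]

#: CCF above which a mutation is called clonal (strict inequality).
CLONAL_CCF_THRESHOLD = 0.6


@dataclass(frozen=True, slots=True)
class ClonalityCall:
    """CCF estimate and clonal/subclonal label for one mutation in one sample."""

    sample_id: str
    key: tuple[str, int, str, str]
    gene: str
    vaf: float
    ccf: float
    label: str  # "clonal" | "subclonal"


def estimate_ccf(
    record: MutationRecord,
    purity: float,
    total_cn: int | None = None,
    multiplicity: int | None = None,
) -> float:
    """Estimate the cancer cell fraction of one mutation.

    ``total_cn`` overrides the record's copy-number field; absent both, a
    diploid locus (c = 2) is assumed. ``multiplicity`` may be forced;
    otherwise it is estimated from the VAF (integer, at least 1).
    """
    if record.depth <= 0:
        raise ValueError("depth must be > 0 to estimate CCF")
    if not (0.0 < purity <= 1.0):
        raise ValueError(f"purity must be in (0, 1] (got {purity})")
    c = total_cn if total_cn is not None else (record.total_cn or 2)
    vaf = record.vaf
    denom_cn = purity * c + (1.0 - purity) * 2.0
    if multiplicity is None:
        multiplicity = max(1, round(vaf * denom_cn / purity))
    ccf = vaf * denom_cn / (purity * multiplicity)
    return min(max(ccf, 0.0), 1.0)


def classify_clonality(
    ccfs: Iterable[float], threshold: float = CLONAL_CCF_THRESHOLD
) -> list[str]:
    """Label each CCF ``clonal`` iff strictly above ``threshold``."""
    return ["clonal" if c > threshold else "subclonal" for c in ccfs]


def call_sample(
    sample: TumorSample, threshold: float = CLONAL_CCF_THRESHOLD
) -> list[ClonalityCall]:
    """Compute a :class:`ClonalityCall` for every mutation in a sample."""
    calls = []
    for rec in sample.mutations:
        ccf = estimate_ccf(rec, sample.purity)
        calls.append(
            ClonalityCall(
                sample_id=sample.sample_id,
                key=rec.key,
                gene=rec.gene,
                vaf=rec.vaf,
                ccf=ccf,
                label="clonal" if ccf > threshold else "subclonal",
            )
        )
    return calls


def call_pairs(
    pairs: Sequence[PatientPair], threshold: float = CLONAL_CCF_THRESHOLD
) -> dict[tuple[str, tuple], ClonalityCall]:
    """Clonality calls for every mutation in every pair, keyed by
    (sample_id, mutation key)."""
    out: dict[tuple[str, tuple], ClonalityCall] = {}
    for pair in pairs:
        for sample in pair.samples:
            for call in call_sample(sample, threshold):
                out[(call.sample_id, call.key)] = call
    return out


def clonality_table(calls: Iterable[ClonalityCall]) -> pd.DataFrame:
    rows = [
        {
            "sample_id": c.sample_id,
            "chrom": c.key[0],
            "pos": c.key[1],
            "ref": c.key[2],
            "alt": c.key[3],
            "gene": c.gene,
            "vaf": c.vaf,
            "ccf": c.ccf,
            "label": c.label,
        }
        for c in calls
    ]
    return pd.DataFrame(
        rows,
        columns=["sample_id", "chrom", "pos", "ref", "alt", "gene", "vaf", "ccf", "label"],
    )


def write_clonality_table(calls: Iterable[ClonalityCall], path: str | Path) -> Path:
    path = Path(path)
    clonality_table(calls).to_csv(path, sep="\t", index=False)
    return path
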