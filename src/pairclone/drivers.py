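"""Metastasis-related driver screen from paired clonality plus unpaired validation.

Candidate events are mutations that either first occur in the lymph-node
metastasis (absent from the matched primary) or shift from subclonal in the
primary to clonal in the node — both compatible with a role in seeding the
metastasis. Candidates are optionally narrowed by a gene-function allowlist,
then each candidate gene is tested for enrichment in lymph-node samples of
an unpaired validation cohort with a one-sided Fisher exact test
(alternative: greater prevalence in LN), with Benjamini-Hochberg q-values
reported alongside the raw-p decision flag.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from statsmodels.stats.multitest import multipletests

from .clonality import ClonalityCall
from .cohort import NONSILENT_CLASSES, PatientPair, Site, ValidationCohort
from .concordance import partition_shared_private

logger = logging.getLogger(__name__)

__all__ = [
    "CandidateEvent",
    "EnrichmentResult",
    "select_candidate_events",
    "candidate_gene_table",
    "filter_by_gene_function",
    "fisher_exact_test",
    "fisher_enrichment",
]


@dataclass(frozen=True, slots=True)
class CandidateEvent:
    patient_id: str
    key: tuple[str, int, str, str]
    gene: str
    category: str  # "ln_private" | "subclonal_to_clonal"


@dataclass(frozen=True, slots=True)
class EnrichmentResult:
    """2x2 sample-level enrichment of one gene: LN (a mutated / b not) vs
    primary (c mutated / d not)."""

    gene: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p: float
    q: float
    flag: bool


def select_candidate_events(
    pairs: Sequence[PatientPair],
    clonality_calls: dict[tuple[str, tuple], ClonalityCall],
) -> list[CandidateEvent]:
    """Candidate metastasis-related events from every pair.

    A mutation qualifies if it is LN-private (its key is absent from the
    matched primary's record set) or if it is shared but subclonal in the
    primary and clonal in the node. A mutation shared and clonal in both
    sites never qualifies. Output order is deterministic (patient, then
    genomic key) regardless of input mutation order.
    """
    events: list[CandidateEvent] = []
    for pair in sorted(pairs, key=lambda p: p.patient_id):
        shared, _, priv_ln = partition_shared_private(pair)
        gene_of = {m.key: m.gene for m in pair.lymph_node.mutations}
        for key in sorted(priv_ln):
            events.append(
                CandidateEvent(
                    patient_id=pair.patient_id,
                    key=key,
                    gene=gene_of[key],
                    category="ln_private",
                )
            )
        for key in sorted(shared):
            call_p = clonality_calls[(pair.primary.sample_id, key)]
            call_ln = clonality_calls[(pair.lymph_node.sample_id, key)]
            if call_p.label == "subclonal" and call_ln.label == "clonal":
                events.append(
                    CandidateEvent(
                        patient_id=pair.patient_id,
                        key=key,
                        gene=gene_of[key],
                        category="subclonal_to_clonal",
                    )
                )
    return events


def candidate_gene_table(events: Iterable[CandidateEvent]) -> pd.DataFrame:
    """Gene-level view of candidate events, deduplicated per patient-gene."""
    seen = {}
    for e in events:
        seen.setdefault((e.patient_id, e.gene), set()).add(e.category)
    rows: dict[str, dict] = {}
    for (pid, gene), cats in seen.items():
        row = rows.setdefault(gene, {"gene": gene, "n_patients": 0, "categories": set()})
        row["n_patients"] += 1
        row["categories"] |= cats
    out = pd.DataFrame(
        [
            {
                "gene": r["gene"],
                "n_patients": r["n_patients"],
                "categories": ",".join(sorted(r["categories"])),
            }
            for r in rows.values()
        ],
        columns=["gene", "n_patients", "categories"],
    )
    return out.sort_values(["n_patients", "gene"], ascending=[False, True]).reset_index(
        drop=True
    )


def filter_by_gene_function(
    events: Sequence[CandidateEvent], allowlist: Iterable[str]
) -> list[CandidateEvent]:
    """Keep events whose gene is on the function allowlist.

    The allowlist stands in for manual curation of metastasis-relevant gene
    function; an empty allowlist would nullify the screen and raises.
    """
    allowed = set(allowlist)
    if not allowed:
        raise ValueError("gene-function allowlist is empty")
    kept = [e for e in events if e.gene in allowed]
    logger.info(
        "gene-function filter: retained %d / %d candidate events", len(kept), len(events)
    )
    if events and not kept:
        logger.warning("gene-function filter removed every candidate event")
    return kept


def _log_pmf(x: int, K: int, N: int, n: int) -> float:
    return (
        math.lgamma(K + 1) - math.lgamma(x + 1) - math.lgamma(K - x + 1)
        + math.lgamma(N - K + 1) - math.lgamma(n - x + 1) - math.lgamma(N - K - n + x + 1)
        - (math.lgamma(N + 1) - math.lgamma(n + 1) - math.lgamma(N - n + 1))
    )


def fisher_exact_test(
    a: int, b: int, c: int, d: int, alternative: str = "greater"
) -> float:
    """Fisher exact p for the 2x2 table [[a, b], [c, d]].

    ``greater`` is the upper hypergeometric tail P(X >= a) with X the top-left
    cell under fixed margins; ``two_sided`` uses the point-probability rule
    (sum of outcomes no more likely than the observed table). Small tables
    (N <= 200) are evaluated in exact integer arithmetic; larger tables use
    a numerically stable log-gamma evaluation.
    """
    if alternative not in ("greater", "two_sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    cells = []
    for name, v in (("a", a), ("b", b), ("c", c), ("d", d)):
        iv = int(v)
        if iv != v or iv < 0:
            raise ValueError(f"cell {name} must be a non-negative integer (got {v!r})")
        cells.append(iv)
    a, b, c, d = cells
    if a + b == 0 or c + d == 0:
        raise ValueError("both row margins must be positive")
    N, K, n = a + b + c + d, a + c, a + b
    lo, hi = max(0, n - (N - K)), min(n, K)

    if N <= 200:
        num = {x: math.comb(K, x) * math.comb(N - K, n - x) for x in range(lo, hi + 1)}
        total = math.comb(N, n)
        if alternative == "greater":
            return sum(num[x] for x in range(a, hi + 1)) / total
        obs = num[a]
        return sum(v for v in num.values() if v <= obs) / total

    logs = {x: _log_pmf(x, K, N, n) for x in range(lo, hi + 1)}
    if alternative == "greater":
        sel = [logs[x] for x in range(a, hi + 1)]
    else:
        cutoff = logs[a] + 1e-9
        sel = [lp for lp in logs.values() if lp <= cutoff]
    m = max(sel)
    return min(1.0, math.exp(m) * sum(math.exp(lp - m) for lp in sel))


def _odds_ratio(a: int, b: int, c: int, d: int) -> float:
    if 0 in (a, b, c, d):
        a2, b2, c2, d2 = a + 0.5, b + 0.5, c + 0.5, d + 0.5  # Haldane correction
        return (a2 * d2) / (b2 * c2)
    return (a * d) / (b * c)


def fisher_enrichment(
    candidate_genes: Iterable[str],
    validation: ValidationCohort,
    alternative: str = "greater",
    alpha: float = 0.05,
    eligible_classes=NONSILENT_CLASSES,
) -> list[EnrichmentResult]:
    """Per-gene LN-vs-primary enrichment in an unpaired validation cohort.

    For each candidate gene, samples are scored mutated if they carry at
    least one eligible (nonsynonymous, by default) mutation in the gene. The
    one-sided test asks whether prevalence is greater in lymph-node samples.
    Genes absent from the whole cohort are excluded with a note. Results are
    BH-adjusted across the tested genes, sorted by p, and flagged at raw
    p <= alpha (q reported alongside).
    """
    ln_samples = validation.by_site(Site.LYMPH_NODE)
    p_samples = validation.by_site(Site.PRIMARY)
    mutated: dict[str, set[str]] = {}
    for s in validation.samples:
        genes = {m.gene for m in s.mutations if m.variant_class in eligible_classes}
        for g in genes:
            mutated.setdefault(g, set()).add(s.sample_id)
    n_ln, n_p = len(ln_samples), len(p_samples)
    ln_ids = {s.sample_id for s in ln_samples}
    p_ids = {s.sample_id for s in p_samples}

    tested: list[tuple[str, int, int, int, int, float]] = []
    for gene in sorted(set(candidate_genes)):
        hit = mutated.get(gene, set())
        a, c = len(hit & ln_ids), len(hit & p_ids)
        if a + c == 0:
            logger.info("gene %s absent from the validation cohort; excluded", gene)
            continue
        b, d = n_ln - a, n_p - c
        p = fisher_exact_test(a, b, c, d, alternative=alternative)
        tested.append((gene, a, b, c, d, p))
    if not tested:
        return []
    pvals = [t[5] for t in tested]
    qvals = multipletests(pvals, method="fdr_bh")[1]
    results = [
        EnrichmentResult(
            gene=g, a=a, b=b, c=c, d=d,
            odds_ratio=_odds_ratio(a, b, c, d),
            p=p, q=float(q), flag=p <= alpha,
        )
        for (g, a, b, c, d, p), q in zip(tested, qvals)
    ]
    return sorted(results, key=lambda r: (r.p, r.gene))


def enrichment_table(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": r.gene, "a_ln_mut": r.a, "b_ln_wt": r.b,
                "c_p_mut": r.c, "d_p_wt": r.d,
                "odds_ratio": r.odds_ratio, "p": r.p, "q": r.q, "flag": r.flag,
            }
            for r in results
        ],
        columns=[
            "gene", "a_ln_mut", "b_ln_wt", "c_p_mut", "d_p_wt",
            "odds_ratio", "p", "q", "flag",
        ],
    )
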