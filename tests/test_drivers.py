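"""Candidate selection, gene-function filter, Fisher test and enrichment."""

import math
import random
from fractions import Fraction

import numpy as np
import pytest
from scipy import stats

from pairclone.clonality import call_pairs
from pairclone.cohort import Site, TumorSample, ValidationCohort
from pairclone.drivers import (
    CandidateEvent,
    candidate_gene_table,
    filter_by_gene_function,
    fisher_enrichment,
    fisher_exact_test,
    select_candidate_events,
)
from pairclone.simulate import SimulationConfig, simulate_validation_cohort
from conftest import make_pair, make_record


def pair_with_vafs(p_muts, ln_muts, patient_id="CN_01"):
    """p_muts/ln_muts: {locus: alt_count} at depth 100, purity 1."""

    def sample(muts, sid, site):
        recs = [
            make_record(sample_id=sid, chrom="chr1", pos=1000 + k, alt_count=ac, depth=100)
            for k, ac in muts.items()
        ]
        return TumorSample(
            sample_id=sid, patient_id=patient_id, site=site, purity=1.0, mutations=recs
        )

    from pairclone.cohort import PatientPair

    return PatientPair(
        patient_id=patient_id,
        primary=sample(p_muts, f"{patient_id}_P", Site.PRIMARY),
        lymph_node=sample(ln_muts, f"{patient_id}_LN", Site.LYMPH_NODE),
    )


# at purity 1 and depth 100: alt_count 50 -> CCF 1.0 (clonal), 20 -> 0.4 (subclonal)
def test_candidate_selection_rules():
    pair = pair_with_vafs(
        {1: 50, 2: 20, 3: 50},  # locus 2 subclonal in P; 1,3 clonal
        {1: 50, 2: 45, 4: 50},  # locus 2 clonal in LN (0.9); 4 LN-only
    )
    calls = call_pairs([pair])
    events = select_candidate_events([pair], calls)
    by_locus = {e.key[1] - 1000: e.category for e in events}
    assert by_locus == {4: "ln_private", 2: "subclonal_to_clonal"}
    # shared-and-clonal-in-both (loci 1) never qualifies
    assert 1 not in by_locus and 3 not in by_locus


def test_candidate_selection_stable_under_input_permutation():
    pair = pair_with_vafs({1: 50, 2: 20, 5: 10}, {1: 50, 2: 45, 4: 50, 6: 50})
    calls = call_pairs([pair])
    ref = select_candidate_events([pair], calls)
    rng = random.Random(3)
    for _ in range(3):
        rng.shuffle(pair.primary.mutations)
        rng.shuffle(pair.lymph_node.mutations)
        assert select_candidate_events([pair], call_pairs([pair])) == ref


def test_gene_table_deduplicates_per_patient_gene():
    events = [
        CandidateEvent("P1", ("chr1", 1, "C", "T"), "ATR", "ln_private"),
        CandidateEvent("P1", ("chr1", 2, "C", "T"), "ATR", "subclonal_to_clonal"),
        CandidateEvent("P2", ("chr1", 3, "C", "T"), "ATR", "ln_private"),
        CandidateEvent("P2", ("chr1", 4, "C", "T"), "TET2", "ln_private"),
    ]
    table = candidate_gene_table(events)
    assert table.loc[table["gene"] == "ATR", "n_patients"].item() == 2
    assert table.loc[table["gene"] == "TET2", "n_patients"].item() == 1


def test_function_filter_identity_empty_and_error(caplog):
    events = [CandidateEvent("P1", ("chr1", 1, "C", "T"), "ATR", "ln_private")]
    assert filter_by_gene_function(events, {"ATR", "TET2"}) == events
    with caplog.at_level("WARNING"):
        assert filter_by_gene_function(events, {"KRAS"}) == []
    assert "removed every" in caplog.text
    with pytest.raises(ValueError, match="empty"):
        filter_by_gene_function(events, set())


def fisher_oracle(a, b, c, d, alt):
    """Exhaustive enumeration over tables with the observed margins, exact
    rational arithmetic via the four-factorial probability formula."""
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    N = r1 + r2
    const = Fraction(
        math.factorial(r1) * math.factorial(r2) * math.factorial(c1) * math.factorial(c2),
        math.factorial(N),
    )
    lo, hi = max(0, r1 - c2), min(r1, c1)
    probs = {
        x: const
        / Fraction(
            math.factorial(x)
            * math.factorial(r1 - x)
            * math.factorial(c1 - x)
            * math.factorial(c2 - r1 + x)
        )
        for x in range(lo, hi + 1)
    }
    if alt == "greater":
        return float(sum(p for x, p in probs.items() if x >= a))
    obs = probs[a]
    return float(sum(p for p in probs.values() if p <= obs))


@pytest.mark.parametrize("alt", ["greater", "two_sided"])
def test_fisher_matches_enumeration_on_sampled_tables(alt):
    rng = np.random.default_rng(0)
    for _ in range(300):
        a, b, c, d = rng.integers(0, 25, size=4)
        if a + b == 0 or c + d == 0:
            continue
        assert fisher_exact_test(int(a), int(b), int(c), int(d), alt) == pytest.approx(
            fisher_oracle(int(a), int(b), int(c), int(d), alt), abs=1e-12
        )


def test_fisher_balanced_table():
    p = fisher_exact_test(5, 5, 5, 5, "greater")
    assert p == pytest.approx(fisher_oracle(5, 5, 5, 5, "greater"), abs=1e-14)
    assert fisher_exact_test(4, 4, 4, 4, "two_sided") == pytest.approx(1.0)


def test_fisher_zero_top_left_upper_tail_is_one():
    assert fisher_exact_test(0, 10, 5, 5, "greater") == pytest.approx(1.0)


def test_fisher_agrees_with_scipy_cross_check():
    for table in [(12, 88, 3, 97), (1, 9, 8, 2), (20, 5, 5, 20)]:
        a, b, c, d = table
        ours = fisher_exact_test(a, b, c, d, "greater")
        ref = stats.fisher_exact([[a, b], [c, d]], alternative="greater").pvalue
        assert ours == pytest.approx(ref, rel=1e-9)


def test_fisher_large_table_loggamma_path():
    a, b, c, d = 160, 1840, 60, 1940  # N > 200 exercises the log-gamma branch
    ours = fisher_exact_test(a, b, c, d, "greater")
    ref = stats.fisher_exact([[a, b], [c, d]], alternative="greater").pvalue
    assert ours == pytest.approx(ref, rel=1e-9)


def test_fisher_invalid_inputs():
    with pytest.raises(ValueError, match="margin"):
        fisher_exact_test(0, 0, 1, 1)
    with pytest.raises(ValueError, match="non-negative"):
        fisher_exact_test(-1, 2, 3, 4)
    with pytest.raises(ValueError, match="alternative"):
        fisher_exact_test(1, 2, 3, 4, alternative="less")


def _cohort(ln_mutated, ln_total, p_mutated, p_total, gene="ATR"):
    samples = []
    for i in range(ln_total):
        muts = [make_record(sample_id=f"L{i}", gene=gene)] if i < ln_mutated else []
        samples.append(
            TumorSample(sample_id=f"L{i}", patient_id=f"L{i}", site=Site.LYMPH_NODE, mutations=muts)
        )
    for i in range(p_total):
        muts = [make_record(sample_id=f"P{i}", gene=gene)] if i < p_mutated else []
        samples.append(
            TumorSample(sample_id=f"P{i}", patient_id=f"P{i}", site=Site.PRIMARY, mutations=muts)
        )
    return ValidationCohort(samples=samples)


def test_enrichment_flags_clear_ln_excess():
    cohort = _cohort(40, 500, 15, 500)  # 8% LN vs 3% P
    (res,) = fisher_enrichment(["ATR"], cohort)
    assert res.flag and res.p <= 0.05
    assert (res.a, res.c) == (40, 15)
    assert res.odds_ratio == pytest.approx((40 * 485) / (460 * 15))


def test_enrichment_equal_prevalence_not_flagged():
    cohort = _cohort(15, 500, 15, 500)
    (res,) = fisher_enrichment(["ATR"], cohort)
    assert not res.flag


def test_enrichment_excludes_absent_gene():
    cohort = _cohort(5, 50, 5, 50)
    res = fisher_enrichment(["ATR", "NOSUCHGENE"], cohort)
    assert [r.gene for r in res] == ["ATR"]


def test_enrichment_bh_adjustment_matches_hand_formula():
    cohort_samples = _cohort(30, 200, 5, 200, gene="ATR").samples
    # add a null gene present at equal prevalence
    for i, s in enumerate(cohort_samples):
        if i % 10 == 0:
            s.mutations.append(make_record(sample_id=s.sample_id, gene="KRAS", pos=5))
    res = fisher_enrichment(["ATR", "KRAS"], ValidationCohort(samples=cohort_samples))
    ps = sorted(r.p for r in res)
    m = len(ps)
    expected_q = [min(1.0, p * m / (i + 1)) for i, p in enumerate(ps)]
    # enforce monotonicity as BH does
    for i in range(m - 2, -1, -1):
        expected_q[i] = min(expected_q[i], expected_q[i + 1])
    assert sorted(r.q for r in res) == pytest.approx(expected_q)


def test_planted_driver_attains_smallest_p():
    cfg = SimulationConfig(driver_genes={"ATR": 4.0}, seed=30)
    cohort, _ = simulate_validation_cohort(cfg, 2000, 2000, baseline_rate=0.03)
    genes = ["ATR", "KRAS", "TP53", "EGFR", "BRAF", "TET2"]
    res = fisher_enrichment(genes, cohort)
    assert res[0].gene == "ATR"
    assert res[0].flag
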