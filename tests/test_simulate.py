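"""Synthetic cohort generator: determinism, limits, planted structure."""

import filecmp

import numpy as np
import pytest
from scipy import stats

from pairclone.clonality import call_pairs
from pairclone.cohort import Site, assemble_pairs, read_mutation_table, read_sample_sheet
from pairclone.concordance import cohort_concordance_summary
from pairclone.simulate import (
    SimulationConfig,
    expected_concordance,
    ln_rate_from_odds,
    simulate_paired_cohort,
    simulate_validation_cohort,
    write_fixture,
)


def test_degenerate_config_rejected():
    with pytest.raises(ValueError, match="degenerate"):
        SimulationConfig(n_truncal=0, n_primary_private=0, n_ln_private=0)


def test_identical_config_and_seed_give_byte_identical_fixtures(tmp_path):
    cfg = SimulationConfig(n_patients=4, seed=123)
    for d in ("a", "b"):
        pairs, truth = simulate_paired_cohort(cfg)
        write_fixture(pairs, truth, tmp_path / d, config=cfg)
    for fname in ("mutations.tsv", "samples.tsv", "truth.tsv", "config.yaml"):
        assert filecmp.cmp(tmp_path / "a" / fname, tmp_path / "b" / fname, shallow=False)


def test_noiseless_limit_recovers_true_ccf():
    """purity 1 and huge depth: truncal VAF ~ 0.5 and estimated CCF ~ 1."""
    cfg = SimulationConfig(
        n_patients=1,
        n_truncal=5,
        n_primary_private=0,
        n_ln_private=0,
        shift_fraction=0.0,
        truncal_overdispersion=0.0,
        purity_range=(1.0, 1.0),
        mean_depth=1e5,
        driver_genes={},
        seed=3,
    )
    pairs, truth = simulate_paired_cohort(cfg)
    (pair,) = pairs
    assert pair.primary.mutation_keys() == pair.lymph_node.mutation_keys()
    assert (truth.mutations["category"] == "truncal").all()
    for call in call_pairs(pairs).values():
        assert call.vaf == pytest.approx(0.5, abs=0.02)
        assert call.ccf == pytest.approx(1.0, abs=0.04)


def test_without_shifts_or_ln_private_every_ln_mutation_is_shared():
    cfg = SimulationConfig(
        n_patients=10, n_ln_private=0, shift_fraction=0.0, driver_genes={}, seed=5
    )
    pairs, _ = simulate_paired_cohort(cfg)
    for pair in pairs:
        assert pair.lymph_node.mutation_keys() <= pair.primary.mutation_keys()


def test_truth_covers_every_emitted_mutation_exactly_once():
    cfg = SimulationConfig(n_patients=10, seed=9)
    pairs, truth = simulate_paired_cohort(cfg)
    truth_keys = set(
        zip(truth.mutations["patient_id"], truth.mutations["chrom"], truth.mutations["pos"])
    )
    assert len(truth_keys) == len(truth.mutations)
    emitted = {
        (pair.patient_id, m.chrom, m.pos)
        for pair in pairs
        for s in pair.samples
        for m in s.mutations
    }
    assert emitted == truth_keys


def test_private_count_distributions_follow_poisson_means():
    """χ² goodness of fit of per-patient private counts at 200 patients."""
    cfg = SimulationConfig(n_patients=200, driver_genes={}, seed=2)
    _, truth = simulate_paired_cohort(cfg)
    counts = truth.mutations.groupby(["patient_id", "category"]).size().unstack(fill_value=0)
    for category, lam in (
        ("primary_private", cfg.n_primary_private * (1 - cfg.shift_fraction)),
        ("ln_private", cfg.n_ln_private),
    ):
        obs = counts.get(category, 0)
        values = np.arange(0, int(stats.poisson(lam).ppf(0.999)) + 1)
        observed = np.array([(obs == v).sum() for v in values], dtype=float)
        observed = np.append(observed, (obs > values[-1]).sum())
        expected = stats.poisson(lam).pmf(values) * cfg.n_patients
        expected = np.append(expected, cfg.n_patients - expected.sum())
        keep = expected > 1.0
        chi2 = ((observed[keep] - expected[keep]) ** 2 / expected[keep]).sum()
        p = stats.chi2.sf(chi2, keep.sum() - 1)
        assert p > 0.01, f"{category}: chi2 GOF rejected (p={p:.4f})"


def test_empirical_concordance_within_three_se_of_closed_form():
    cfg = SimulationConfig(n_patients=200, driver_genes={}, seed=8)
    pairs, _ = simulate_paired_cohort(cfg)
    _, summary = cohort_concordance_summary(pairs)
    mean, sd = expected_concordance(cfg)
    se = 100.0 * sd / np.sqrt(summary["n_pairs"])
    assert abs(summary["mean_pct"] - 100.0 * mean) < 3 * se


def test_driver_genes_planted_as_ln_private_events():
    cfg = SimulationConfig(n_patients=15, n_driver_carriers=3, seed=4)
    _, truth = simulate_paired_cohort(cfg)
    for gene in cfg.driver_genes:
        planted = truth.mutations[
            (truth.mutations["gene"] == gene)
            & (truth.mutations["category"] == "ln_private")
        ]
        assert len(planted) >= 3


def test_fixture_roundtrip_preserves_cohort(tmp_path):
    cfg = SimulationConfig(n_patients=6, seed=11)
    pairs, truth = simulate_paired_cohort(cfg)
    out = write_fixture(pairs, truth, tmp_path / "fix", config=cfg)
    records = read_mutation_table(out / "mutations.tsv", on_invalid="raise")
    sheet = read_sample_sheet(out / "samples.tsv")
    back = assemble_pairs(records, sheet)
    assert len(back) == len(pairs)
    total = sum(len(s.mutations) for p in pairs for s in p.samples)
    total_back = sum(len(s.mutations) for p in back for s in p.samples)
    assert total_back == total
    for orig, rt in zip(pairs, back):
        assert rt.primary.purity == pytest.approx(orig.primary.purity)
        assert rt.smoking == orig.smoking


def test_fixture_refuses_nonempty_directory(tmp_path):
    cfg = SimulationConfig(n_patients=2, seed=1)
    pairs, truth = simulate_paired_cohort(cfg)
    d = tmp_path / "fix"
    write_fixture(pairs, truth, d)
    with pytest.raises(FileExistsError):
        write_fixture(pairs, truth, d)
    write_fixture(pairs, truth, d, overwrite=True)


def test_validation_cohort_sizes_and_errors():
    cfg = SimulationConfig(seed=6)
    with pytest.raises(ValueError, match="n_primary and n_ln"):
        simulate_validation_cohort(cfg, 100, 0)
    cohort, truth = simulate_validation_cohort(cfg, 50, 40)
    assert len(cohort.by_site(Site.PRIMARY)) == 50
    assert len(cohort.by_site(Site.LYMPH_NODE)) == 40
    assert truth.gene_odds == cfg.driver_genes


def test_validation_impossible_rate_rejected():
    """Odds ratios always imply a probability below 1; direct per-gene rate
    overrides are where an impossible (>= 1) probability can be requested."""
    cfg = SimulationConfig(seed=1)
    with pytest.raises(ValueError, match="rates"):
        simulate_validation_cohort(cfg, 10, 10, gene_rates={"ATR": (0.03, 1.0)})


def test_null_odds_give_equal_site_rates():
    cfg = SimulationConfig(driver_genes={}, seed=13)
    cohort, _ = simulate_validation_cohort(cfg, 1500, 1500, baseline_rate=0.03)
    rates = {}
    for site in Site:
        samples = cohort.by_site(site)
        rates[site] = np.mean([len(s.mutations) for s in samples])
    assert rates[Site.LYMPH_NODE] / rates[Site.PRIMARY] == pytest.approx(1.0, abs=0.05)


def test_planted_odds_ratio_recovered_within_ci():
    cfg = SimulationConfig(driver_genes={"ATR": 4.0}, seed=21)
    cohort, _ = simulate_validation_cohort(cfg, 2000, 2000, baseline_rate=0.03)
    a = sum(
        any(m.gene == "ATR" for m in s.mutations) for s in cohort.by_site(Site.LYMPH_NODE)
    )
    c = sum(
        any(m.gene == "ATR" for m in s.mutations) for s in cohort.by_site(Site.PRIMARY)
    )
    b, d = 2000 - a, 2000 - c
    log_or = np.log(a * d / (b * c))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    assert log_or - 1.96 * se < np.log(4.0) < log_or + 1.96 * se


def test_ln_rate_from_odds_identity():
    assert ln_rate_from_odds(0.03, 1.0) == pytest.approx(0.03)
    # odds 4 at 3% baseline: odds_ln = 4 * 0.03/0.97
    odds = 4 * 0.03 / 0.97
    assert ln_rate_from_odds(0.03, 4.0) == pytest.approx(odds / (1 + odds))


def test_sample_contexts_follow_signature_mixture():
    """Pooled spectra of samples generated from one signature resemble it."""
    from pairclone.resources import load_cosmic_signatures
    from pairclone.signatures import build_context_matrix

    cfg = SimulationConfig(
        n_patients=6,
        n_truncal=150,
        n_primary_private=0,
        n_ln_private=0,
        truncal_overdispersion=0.0,
        signature_mixtures=({1: 1.0},),
        signature_concentration=1e6,
        driver_genes={},
        seed=17,
    )
    pairs, _ = simulate_paired_cohort(cfg)
    ctx = build_context_matrix([s for p in pairs for s in p.samples])
    pooled = ctx.sum(axis=1).to_numpy()
    pooled = pooled / pooled.sum()
    ref = load_cosmic_signatures()["Signature 1"].to_numpy()
    cos = pooled @ ref / (np.linalg.norm(pooled) * np.linalg.norm(ref))
    assert cos > 0.97
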