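"""Synthetic paired primary / lymph-node cohorts under linear-progression seeding.

The generator emulates a two-site linear-progression model of nodal
metastasis: the metastatic lineage branches late from the primary's dominant
clone, so both samples share a truncal clonal backbone, the primary carries
private subclones, the node carries private clonal mutations acquired after
seeding, and a fraction of primary subclones arrives in the node as founders
and appears clonal there (the subclonal-to-clonal shift). Read counts are
binomial at a sampled sequencing depth, trinucleotide contexts are drawn
from per-sample mixtures over the packaged signature catalog, and an
unpaired validation cohort can be generated with planted gene-level
lymph-node enrichment. Every emitted mutation is recorded in a ground-truth
table, so downstream estimators can be scored exactly.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .cohort import (
    MutationRecord,
    PatientPair,
    Site,
    TumorSample,
    ValidationCohort,
    VariantClass,
    write_mutation_table,
)
from .resources import load_cosmic_signatures, load_panel_genes
from .signatures import CONTEXTS_96

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_paired_cohort",
    "simulate_validation_cohort",
    "expected_concordance",
    "write_fixture",
]

_CLASS_CHOICES = (
    (VariantClass.MISSENSE, 0.62),
    (VariantClass.NONSENSE, 0.10),
    (VariantClass.SPLICE, 0.06),
    (VariantClass.SYNONYMOUS, 0.16),
    (VariantClass.OTHER, 0.06),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic paired cohort.

    Counts are per-patient means: truncal mutations follow a
    gamma-overdispersed Poisson (patient-level factor with shape
    ``truncal_overdispersion``; marginal mean preserved) so that the truncal
    fraction — and hence pair concordance — varies between patients the way
    it does across real pairs; private counts are plain Poisson.
    ``signature_mixtures`` are alternated across patients (both samples of a
    patient share a mixture, jittered per sample by a Dirichlet with
    concentration ``signature_concentration``).
    """

    n_patients: int = 15
    n_truncal: float = 7.0
    n_primary_private: float = 4.5
    n_ln_private: float = 1.5
    shift_fraction: float = 0.1
    truncal_overdispersion: float = 0.5
    purity_range: tuple[float, float] = (0.4, 0.9)
    mean_depth: float = 800.0
    signature_mixtures: tuple[dict[int, float], ...] = (
        dataclasses.field(default_factory=lambda: ({1: 0.85, 23: 0.15}, {1: 0.15, 23: 0.85}))
    )
    signature_concentration: float = 30.0
    driver_genes: dict[str, float] = field(
        default_factory=lambda: {"ATR": 4.0, "TET2": 4.0}
    )
    n_driver_carriers: int = 2
    panel_mb: float = 1.94
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_truncal, self.n_primary_private, self.n_ln_private) < 0:
            raise ValueError("mutation count means must be >= 0")
        if self.n_truncal + self.n_primary_private + self.n_ln_private <= 0:
            raise ValueError("degenerate config: all mutation count means are 0")
        if not (0.0 <= self.shift_fraction <= 1.0):
            raise ValueError("shift_fraction must be in [0, 1]")
        lo, hi = self.purity_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("purity_range must be within (0, 1]")
        if self.panel_mb <= 0:
            raise ValueError("panel_mb must be > 0")


@dataclass(slots=True)
class GroundTruth:
    """Exact generative state behind a synthetic cohort.

    ``mutations``: one row per distinct mutation (patient, key, gene,
    category in {truncal, primary_private, ln_private, shifted}, true CCF in
    each sample; 0 where absent). ``sample_weights``: per-sample true
    signature mixture. ``gene_odds``: per-gene planted enrichment odds
    ratios (validation cohorts).
    """

    mutations: pd.DataFrame
    sample_weights: pd.DataFrame
    gene_odds: dict[str, float] = field(default_factory=dict)


def _context_distribution(weights: dict[int, float]) -> np.ndarray:
    cosmic = load_cosmic_signatures()
    probs = np.zeros(96)
    for sig_id, w in weights.items():
        probs += w * cosmic[f"Signature {sig_id}"].to_numpy()
    total = probs.sum()
    if total <= 0:
        raise ValueError("signature mixture has zero total weight")
    return probs / total


def _parse_context_class(label: str) -> tuple[str, str, str]:
    # "A[C>T]G" -> context "ACG", ref "C", alt "T"
    five, rest = label[0], label[2:]
    ref, alt, three = rest[0], rest[2], rest[4]
    return f"{five}{ref}{three}", ref, alt


def _draw_depths(rng: np.random.Generator, n: int, mean_depth: float) -> np.ndarray:
    """Poisson depths truncated at >= 10 reads."""
    depth = rng.poisson(mean_depth, size=n)
    for _ in range(100):
        low = depth < 10
        if not low.any():
            break
        depth[low] = rng.poisson(mean_depth, size=int(low.sum()))
    return np.maximum(depth, 10)


def _draw_alt(rng: np.random.Generator, depth: np.ndarray, p: np.ndarray) -> np.ndarray:
    return rng.binomial(depth, np.clip(p, 0.0, 1.0))


def _jittered_weights(
    rng: np.random.Generator, mixture: dict[int, float], concentration: float
) -> dict[int, float]:
    ids = sorted(mixture)
    base = np.array([mixture[i] for i in ids], dtype=float)
    base = base / base.sum()
    jit = rng.dirichlet(np.maximum(concentration * base, 1e-3))
    return dict(zip(ids, jit.tolist()))


def simulate_paired_cohort(
    config: SimulationConfig,
) -> tuple[list[PatientPair], GroundTruth]:
    """Generate matched primary/LN pairs with full ground truth.

    Per patient: truncal mutations (true CCF 1.0 in both samples),
    primary-private subclones (CCF in (0, 0.6], absent in LN), LN-private
    clonal mutations (CCF in (0.6, 1], absent in P), and a
    ``shift_fraction`` subset of primary subclones present in both with CCF
    <= 0.6 in P and > 0.6 in LN. Observed alt counts are
    Binomial(depth, purity * CCF / 2) under the heterozygous diploid model,
    depth Poisson(mean_depth) truncated at >= 10. Deterministic given
    ``config.seed``. Each configured driver gene is additionally planted as
    an LN-private mutation in ``n_driver_carriers`` random patients.
    """
    rng = np.random.default_rng(config.seed)
    panel = load_panel_genes()
    mixtures = tuple(config.signature_mixtures)
    class_names, class_probs = zip(*_CLASS_CHOICES)
    class_probs = np.array(class_probs) / sum(class_probs)

    # pre-assign driver carriers: gene -> set of patient indices
    carrier_of: dict[str, np.ndarray] = {}
    for gene in sorted(config.driver_genes):
        k = min(config.n_driver_carriers, config.n_patients)
        carrier_of[gene] = rng.choice(config.n_patients, size=k, replace=False)

    pairs: list[PatientPair] = []
    truth_rows: list[dict] = []
    weight_rows: list[dict] = []

    for i in range(config.n_patients):
        pid = f"CN_{i + 1:02d}"
        purity_p, purity_ln = rng.uniform(*config.purity_range, size=2)
        gamma_factor = (
            rng.gamma(config.truncal_overdispersion, 1.0 / config.truncal_overdispersion)
            if config.truncal_overdispersion > 0
            else 1.0
        )
        n_truncal = rng.poisson(config.n_truncal * gamma_factor)
        n_pp = rng.poisson(config.n_primary_private)
        n_ln = rng.poisson(config.n_ln_private)
        n_shift = rng.binomial(n_pp, config.shift_fraction)

        planted = [g for g, who in carrier_of.items() if i in who]

        mixture = mixtures[i % len(mixtures)]
        w_p = _jittered_weights(rng, mixture, config.signature_concentration)
        w_ln = _jittered_weights(rng, mixture, config.signature_concentration)
        weight_rows.append({"sample_id": f"{pid}_P", **{f"sig_{k}": v for k, v in w_p.items()}})
        weight_rows.append({"sample_id": f"{pid}_LN", **{f"sig_{k}": v for k, v in w_ln.items()}})
        ctx_probs_p = _context_distribution(w_p)
        ctx_probs_ln = _context_distribution(w_ln)

        n_total = n_truncal + n_pp + n_ln + len(planted)
        # unique loci per patient
        keys: set[tuple[str, int]] = set()
        loci = []
        while len(loci) < n_total:
            chrom = f"chr{rng.integers(1, 23)}"
            pos = int(rng.integers(1, 200_000_000))
            if (chrom, pos) not in keys:
                keys.add((chrom, pos))
                loci.append((chrom, pos))

        categories = (
            ["truncal"] * n_truncal
            + ["shifted"] * n_shift
            + ["primary_private"] * (n_pp - n_shift)
            + ["ln_private"] * (n_ln + len(planted))
        )
        genes = list(rng.choice(panel, size=n_total - len(planted))) + planted
        vclasses = list(rng.choice(len(class_names), size=n_total, p=class_probs))

        muts_p: list[MutationRecord] = []
        muts_ln: list[MutationRecord] = []
        for (chrom, pos), category, gene, vci in zip(loci, categories, genes, vclasses):
            in_p = category in ("truncal", "shifted", "primary_private")
            in_ln = category in ("truncal", "shifted", "ln_private")
            if category == "truncal":
                ccf_p, ccf_ln = 1.0, 1.0
            elif category == "primary_private":
                ccf_p, ccf_ln = 0.6 * (1.0 - rng.random()), 0.0
            elif category == "ln_private":
                ccf_p, ccf_ln = 0.0, 0.6 + 0.4 * (1.0 - rng.random())
            else:  # shifted
                ccf_p = 0.6 * (1.0 - rng.random())
                ccf_ln = 0.6 + 0.4 * (1.0 - rng.random())
            ctx_probs = ctx_probs_p if in_p else ctx_probs_ln
            label = CONTEXTS_96[rng.choice(96, p=ctx_probs)]
            context, ref, alt = _parse_context_class(label)
            vclass = class_names[vci]
            truth_rows.append(
                {
                    "patient_id": pid,
                    "chrom": chrom,
                    "pos": pos,
                    "ref": ref,
                    "alt": alt,
                    "gene": gene,
                    "category": category,
                    "ccf_primary": ccf_p,
                    "ccf_ln": ccf_ln,
                }
            )
            for present, ccf, purity, sid, bucket in (
                (in_p, ccf_p, purity_p, f"{pid}_P", muts_p),
                (in_ln, ccf_ln, purity_ln, f"{pid}_LN", muts_ln),
            ):
                if not present:
                    continue
                depth = int(_draw_depths(rng, 1, config.mean_depth)[0])
                alt_count = int(
                    _draw_alt(rng, np.array([depth]), np.array([purity * ccf / 2.0]))[0]
                )
                bucket.append(
                    MutationRecord(
                        sample_id=sid,
                        patient_id=pid,
                        gene=gene,
                        chrom=chrom,
                        pos=pos,
                        ref=ref,
                        alt=alt,
                        variant_class=vclass,
                        alt_count=alt_count,
                        depth=depth,
                        context=context,
                    )
                )

        primary = TumorSample(
            sample_id=f"{pid}_P", patient_id=pid, site=Site.PRIMARY,
            purity=float(purity_p), mutations=muts_p,
        )
        lymph_node = TumorSample(
            sample_id=f"{pid}_LN", patient_id=pid, site=Site.LYMPH_NODE,
            purity=float(purity_ln), mutations=muts_ln,
        )
        pairs.append(
            PatientPair(
                patient_id=pid,
                primary=primary,
                lymph_node=lymph_node,
                age=int(rng.integers(47, 74)),
                sex="male" if rng.random() < 0.87 else "female",
                stage=str(rng.choice(["II", "III", "IV"], p=[0.27, 0.67, 0.06])),
                smoking=str(
                    rng.choice(
                        ["smoking", "off_smoking", "never_smoking"], p=[0.6, 0.2, 0.2]
                    )
                ),
            )
        )

    truth = GroundTruth(
        mutations=pd.DataFrame(
            truth_rows,
            columns=[
                "patient_id", "chrom", "pos", "ref", "alt", "gene",
                "category", "ccf_primary", "ccf_ln",
            ],
        ),
        sample_weights=pd.DataFrame(weight_rows),
        gene_odds=dict(config.driver_genes),
    )
    return pairs, truth


def ln_rate_from_odds(baseline_rate: float, odds_ratio: float) -> float:
    """Per-sample mutation probability in LN implied by a baseline rate and OR."""
    odds = odds_ratio * baseline_rate / (1.0 - baseline_rate)
    return odds / (1.0 + odds)


def simulate_validation_cohort(
    config: SimulationConfig,
    n_primary: int,
    n_ln: int,
    baseline_rate: float = 0.03,
    gene_rates: dict[str, tuple[float, float]] | None = None,
) -> tuple[ValidationCohort, GroundTruth]:
    """Unpaired site-labelled cohort with planted gene-level LN enrichment.

    Every panel gene is mutated in a primary sample with probability
    ``baseline_rate``; in an LN sample, driver genes use the probability
    implied by their configured odds ratio and all other genes the baseline.
    ``gene_rates`` overrides both site rates per gene directly as
    ``{gene: (p_primary, p_ln)}``. Each mutated (sample, gene) contributes
    one nonsynonymous SNV record at a gene-specific locus.
    """
    if n_primary < 1 or n_ln < 1:
        raise ValueError("n_primary and n_ln must both be >= 1")
    if not (0.0 < baseline_rate < 1.0):
        raise ValueError("baseline_rate must be in (0, 1)")
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 0x5EED]).generate_state(1)[0]
    )
    panel = load_panel_genes()
    p_pri = np.full(len(panel), baseline_rate)
    p_ln = np.full(len(panel), baseline_rate)
    for g, odds in config.driver_genes.items():
        rate = ln_rate_from_odds(baseline_rate, odds)
        if rate >= 1.0:
            raise ValueError(f"gene {g}: implied LN rate {rate} >= 1")
        if g in panel:
            p_ln[panel.index(g)] = rate
    for g, (rp, rl) in (gene_rates or {}).items():
        if not (0.0 <= rp < 1.0 and 0.0 <= rl < 1.0):
            raise ValueError(f"gene {g}: rates must be in [0, 1)")
        if g in panel:
            p_pri[panel.index(g)] = rp
            p_ln[panel.index(g)] = rl

    samples: list[TumorSample] = []
    for site, n, probs, tag in (
        (Site.PRIMARY, n_primary, p_pri, "P"),
        (Site.LYMPH_NODE, n_ln, p_ln, "LN"),
    ):
        presence = rng.random((n, len(panel))) < probs[None, :]
        depths = _draw_depths(rng, int(presence.sum()), config.mean_depth)
        alts = np.maximum(1, rng.binomial(depths, 0.25))
        idx = 0
        for s in range(n):
            sid = f"V_{tag}_{s:04d}"
            muts = []
            for gi in np.flatnonzero(presence[s]):
                muts.append(
                    MutationRecord(
                        sample_id=sid,
                        patient_id=sid,
                        gene=panel[gi],
                        chrom=f"chr{gi % 22 + 1}",
                        pos=1000 * (int(gi) + 1),
                        ref="C",
                        alt="T",
                        variant_class=VariantClass.MISSENSE,
                        alt_count=int(alts[idx]),
                        depth=int(depths[idx]),
                    )
                )
                idx += 1
            samples.append(
                TumorSample(sample_id=sid, patient_id=sid, site=site, mutations=muts)
            )
    truth = GroundTruth(
        mutations=pd.DataFrame(),
        sample_weights=pd.DataFrame(),
        gene_odds={g: float(o) for g, o in config.driver_genes.items()},
    )
    return ValidationCohort(samples=samples), truth


def expected_concordance(config: SimulationConfig, quantile: float = 1e-9) -> tuple[float, float]:
    """Closed-form mean and SD of per-pair concordance under the config.

    Integrates (t + f*p) / (t + p + l) over the generative count
    distributions: t is negative-binomial (gamma-mixed Poisson, mean
    ``n_truncal``, shape ``truncal_overdispersion``), p and l Poisson, and
    the shifted count s | p ~ Binomial(p, f) enters the numerator linearly
    (its conditional mean) for the first moment and through its conditional
    variance for the second. Pairs with an empty union are excluded, so the
    result conditions on t + p + l > 0.
    """
    k = config.truncal_overdispersion
    lam_t, lam_p, lam_l = config.n_truncal, config.n_primary_private, config.n_ln_private
    f = config.shift_fraction

    def support(dist):
        hi = int(dist.ppf(1.0 - quantile))
        xs = np.arange(hi + 1)
        return xs, dist.pmf(xs)

    t_dist = (
        stats.nbinom(k, k / (k + lam_t)) if k > 0 and lam_t > 0 else stats.poisson(lam_t)
    )
    ts, pt = support(t_dist)
    ps, pp = support(stats.poisson(lam_p))
    ls, pl = support(stats.poisson(lam_l))

    T, P, L = np.meshgrid(ts, ps, ls, indexing="ij")
    W = pt[:, None, None] * pp[None, :, None] * pl[None, None, :]
    U = T + P + L
    valid = U > 0
    W = W[valid]
    T, P, U = T[valid], P[valid], U[valid]
    W = W / W.sum()
    c1 = (T + f * P) / U
    mean = float(np.sum(W * c1))
    second = float(np.sum(W * (P * f * (1 - f) + (T + f * P) ** 2) / U**2))
    var = max(second - mean**2, 0.0)
    return mean, float(np.sqrt(var))


def write_fixture(
    pairs: list[PatientPair],
    truth: GroundTruth,
    directory: str | Path,
    config: SimulationConfig | None = None,
    overwrite: bool = False,
) -> Path:
    """Write a cohort fixture: mutations.tsv, samples.tsv, truth.tsv,
    truth_signatures.tsv and config.yaml, re-readable by the cohort reader."""
    directory = Path(directory)
    if directory.exists() and any(directory.iterdir()) and not overwrite:
        raise FileExistsError(f"{directory} is not empty (pass overwrite=True)")
    directory.mkdir(parents=True, exist_ok=True)
    records = [m for pair in pairs for s in pair.samples for m in s.mutations]
    write_mutation_table(records, directory / "mutations.tsv", dialect="minimal")
    rows = []
    for pair in pairs:
        for sample in pair.samples:
            rows.append(
                {
                    "sample_id": sample.sample_id,
                    "patient_id": sample.patient_id,
                    "site": sample.site.value,
                    "purity": sample.purity,
                    "age": pair.age,
                    "sex": pair.sex,
                    "stage": pair.stage,
                    "smoking": pair.smoking,
                }
            )
    pd.DataFrame(rows).to_csv(directory / "samples.tsv", sep="\t", index=False)
    truth.mutations.to_csv(directory / "truth.tsv", sep="\t", index=False)
    truth.sample_weights.to_csv(directory / "truth_signatures.tsv", sep="\t", index=False)
    if config is not None:
        cfg = dataclasses.asdict(config)
        cfg["purity_range"] = list(cfg["purity_range"])
        cfg["signature_mixtures"] = [
            {int(k): float(v) for k, v in m.items()} for m in cfg["signature_mixtures"]
        ]
        (directory / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
    return directory
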