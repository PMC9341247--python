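"""End-to-end pipeline: clonality -> concordance -> TMB -> signatures -> drivers.

A single YAML-configurable run over a paired cohort (and optionally an
unpaired validation cohort) that writes one TSV per stage plus a
human-readable ``report.md``. Every report number is re-read from the stage
TSVs, never recomputed, so the report is a faithful view of the emitted
artifacts.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clonality as _clonality
from . import concordance as _concordance
from . import drivers as _drivers
from . import signatures as _signatures
from . import tmb as _tmb
from .cohort import (
    Site,
    assemble_pairs,
    assemble_validation_cohort,
    read_mutation_table,
    read_sample_sheet,
)
from .resources import load_cosmic_signatures

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "render_report"]


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run; every analysis threshold is explicit."""

    mutations: str
    samples: str
    out_dir: str
    dialect: str = "minimal"
    validation_mutations: str | None = None
    validation_samples: str | None = None
    allowlist: str | None = None
    clonal_threshold: float = 0.6
    panel_mb: float = 1.94
    nmf_k: int = 2
    nmf_seed: int = 17
    nmf_restarts: int = 20
    alternative: str = "greater"
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 < self.clonal_threshold < 1.0):
            raise ValueError("clonal_threshold must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


def _read_allowlist(path: str | Path) -> list[str]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"gene-function allowlist not found: {path}")
    return [line.strip() for line in path.read_text().splitlines() if line.strip()]


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and write stage TSVs plus report.md to the output dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    logger.info("stage cohort_io: reading %s", config.mutations)
    records = read_mutation_table(config.mutations, dialect=config.dialect)
    sheet = read_sample_sheet(config.samples)
    pairs = assemble_pairs(records, sheet)
    logger.info("assembled %d patient pairs", len(pairs))

    logger.info("stage clonality")
    calls = _clonality.call_pairs(pairs, threshold=config.clonal_threshold)
    _clonality.write_clonality_table(calls.values(), out / "clonality.tsv")

    logger.info("stage concordance")
    table, summary = _concordance.cohort_concordance_summary(pairs)
    table.to_csv(out / "concordance.tsv", sep="\t", index=False)
    pd.DataFrame([summary]).to_csv(out / "concordance_summary.tsv", sep="\t", index=False)

    logger.info("stage tmb")
    site_of, smoking_of = {}, {}
    tmb_rows = []
    for pair in pairs:
        for sample in pair.samples:
            res = _tmb.compute_tmb(sample, panel_mb=config.panel_mb)
            tmb_rows.append(
                {
                    "sample_id": res.sample_id,
                    "site": sample.site.value,
                    "smoking": pair.smoking,
                    "eligible_count": res.eligible_count,
                    "tmb": res.tmb,
                }
            )
    tmb_df = pd.DataFrame(tmb_rows)
    tmb_df.to_csv(out / "tmb.tsv", sep="\t", index=False)

    logger.info("stage signatures")
    all_samples = [s for pair in pairs for s in pair.samples]
    ctx = _signatures.build_context_matrix(all_samples)
    ctx.to_csv(out / "context_matrix.tsv", sep="\t")
    model = _signatures.extract_denovo_signatures(
        ctx, k=config.nmf_k, seed=config.nmf_seed, restarts=config.nmf_restarts
    )
    _signatures.map_to_cosmic(model, load_cosmic_signatures())
    _signatures.cluster_samples_by_contribution(model)
    model.signatures.to_csv(out / "signatures.tsv", sep="\t")
    model.contributions.to_csv(out / "contributions.tsv", sep="\t")
    pd.DataFrame(
        [
            {
                "denovo": name,
                "cosmic_id": match[0],
                "pearson_r": match[1],
            }
            for name, match in model.cosmic_match.items()
        ]
    ).to_csv(out / "cosmic_match.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"sample_id": s, "cluster": c} for s, c in model.sample_cluster.items()]
    ).to_csv(out / "signature_clusters.tsv", sep="\t", index=False)
    partitions = {
        pair.patient_id: _concordance.partition_shared_private(pair) for pair in pairs
    }
    _signatures.private_mutation_spectra(pairs, partitions).to_csv(
        out / "private_spectra.tsv", sep="\t"
    )

    logger.info("stage driver_screen")
    events = _drivers.select_candidate_events(pairs, calls)
    if config.allowlist is not None:
        events = _drivers.filter_by_gene_function(events, _read_allowlist(config.allowlist))
    gene_table = _drivers.candidate_gene_table(events)
    gene_table.to_csv(out / "candidate_genes.tsv", sep="\t", index=False)

    if config.validation_mutations and config.validation_samples:
        vrecords = read_mutation_table(config.validation_mutations, dialect=config.dialect)
        vsheet = read_sample_sheet(config.validation_samples)
        cohort = assemble_validation_cohort(vrecords, vsheet)
        results = _drivers.fisher_enrichment(
            gene_table["gene"],
            cohort,
            alternative=config.alternative,
            alpha=config.alpha,
        )
        _drivers.enrichment_table(results).to_csv(
            out / "enrichment.tsv", sep="\t", index=False
        )
    else:
        logger.info("no validation cohort configured; skipping enrichment")

    render_report(out)
    return out


def _top_genes(clonality_path: Path, n: int = 10) -> pd.DataFrame:
    df = pd.read_csv(clonality_path, sep="\t")
    df["patient_id"] = df["sample_id"].str.replace(r"_(P|LN)$", "", regex=True)
    n_patients = df["patient_id"].nunique()
    per_gene = df.groupby("gene")["patient_id"].nunique().sort_values(ascending=False)
    out = per_gene.head(n).reset_index()
    out.columns = ["gene", "n_patients"]
    out["frequency_pct"] = (100.0 * out["n_patients"] / n_patients).round(1)
    return out


def render_report(out_dir: str | Path) -> Path:
    """Assemble report.md from the stage TSVs present in ``out_dir``.

    Missing stage files produce explicit gap notes rather than errors, so a
    partial run still yields a readable report.
    """
    out = Path(out_dir)
    lines = ["# Paired primary / lymph-node cohort report", ""]

    def gap(stage: str, fname: str) -> None:
        lines.append(f"*{stage}: `{fname}` not found — stage output missing.*")
        lines.append("")

    f = out / "clonality.tsv"
    lines.append("## Mutation landscape")
    if f.exists():
        top = _top_genes(f)
        if len(top):
            lines.append("")
            lines.append("Most frequently mutated genes (fraction of patients):")
            lines.append("")
            lines.append("| gene | patients | frequency |")
            lines.append("|---|---|---|")
            for _, r in top.iterrows():
                lines.append(f"| {r.gene} | {int(r.n_patients)} | {r.frequency_pct}% |")
        lines.append("")
    else:
        gap("mutation landscape", "clonality.tsv")

    lines.append("## Concordance")
    f = out / "concordance_summary.tsv"
    if f.exists():
        s = pd.read_csv(f, sep="\t").iloc[0]
        lines.append("")
        lines.append(
            f"Across {int(s.n_pairs)} pairs the mean shared-mutation concordance is "
            f"{s.mean_pct:.1f}% ± {s.sd_pct:.1f}% "
            f"(range {s.min_pct:.1f}%–{s.max_pct:.1f}%)."
        )
        lines.append("")
    else:
        gap("concordance", "concordance_summary.tsv")

    lines.append("## Tumor mutational burden")
    f = out / "tmb.tsv"
    if f.exists():
        df = pd.read_csv(f, sep="\t")
        med = df.groupby("site")["tmb"].median()
        lines.append("")
        lines.append(
            "Median TMB (mut/Mb): "
            + ", ".join(f"{site} {med[site]:.1f}" for site in sorted(med.index))
            + "."
        )
        if df["smoking"].notna().any():
            smk = df.groupby("smoking")["tmb"].median()
            lines.append(
                "By smoking status: "
                + ", ".join(f"{k} {v:.1f}" for k, v in smk.sort_index().items())
                + "."
            )
        lines.append("")
    else:
        gap("tmb", "tmb.tsv")

    lines.append("## Mutational signatures")
    fm, fc = out / "cosmic_match.tsv", out / "signature_clusters.tsv"
    if fm.exists() and fc.exists():
        match = pd.read_csv(fm, sep="\t")
        clusters = pd.read_csv(fc, sep="\t")
        lines.append("")
        for _, r in match.iterrows():
            lines.append(
                f"- {r.denovo} best matches reference signature {int(r.cosmic_id)} "
                f"(Pearson r = {r.pearson_r:.3f})"
            )
        sizes = clusters["cluster"].value_counts().sort_index()
        lines.append(
            "- sample clusters: "
            + ", ".join(f"{k}: {v} samples" for k, v in sizes.items())
        )
        lines.append("")
    else:
        gap("signatures", "cosmic_match.tsv / signature_clusters.tsv")

    lines.append("## Driver screen")
    f = out / "enrichment.tsv"
    if f.exists():
        df = pd.read_csv(f, sep="\t")
        flagged = df[df["flag"]]
        lines.append("")
        if len(flagged):
            lines.append("Genes enriched in lymph-node metastases (raw one-sided p ≤ α):")
            lines.append("")
            lines.append("| gene | LN mut | P mut | OR | p | q |")
            lines.append("|---|---|---|---|---|---|")
            for _, r in flagged.iterrows():
                ln_pct = 100.0 * r.a_ln_mut / (r.a_ln_mut + r.b_ln_wt)
                p_pct = 100.0 * r.c_p_mut / (r.c_p_mut + r.d_p_wt)
                lines.append(
                    f"| {r.gene} | {int(r.a_ln_mut)} ({ln_pct:.0f}%) | "
                    f"{int(r.c_p_mut)} ({p_pct:.0f}%) | {r.odds_ratio:.2f} | "
                    f"{r.p:.2e} | {r.q:.2e} |"
                )
        else:
            lines.append("No gene reached the enrichment flag threshold.")
        lines.append("")
    else:
        gap("driver screen", "enrichment.tsv")

    report = out / "report.md"
    report.write_text("\n".join(lines))
    return report
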