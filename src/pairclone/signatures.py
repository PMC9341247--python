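"""Mutational-signature analysis on the 96 trinucleotide substitution classes.

Single-base substitutions are strand-normalized to a pyrimidine reference
(purine-reference SNVs are reverse-complemented), giving 6 substitution types
(C>A, C>G, C>T, T>A, T>C, T>G) x 16 flanking contexts = 96 classes in the
canonical COSMIC row order. De novo signatures are extracted from the
96 x samples count matrix by non-negative matrix factorization (Frobenius
objective, multiplicative updates, best of several random restarts), mapped
to the packaged reference catalog by Pearson correlation, and samples are
grouped into two subclusters by hierarchical clustering of their signature
contribution proportions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.decomposition import NMF
from sklearn.exceptions import ConvergenceWarning

from .cohort import PatientPair, TumorSample

logger = logging.getLogger(__name__)

__all__ = [
    "SUBSTITUTION_TYPES",
    "CONTEXTS_96",
    "normalize_substitution",
    "context_class",
    "build_context_matrix",
    "SignatureModel",
    "extract_denovo_signatures",
    "map_to_cosmic",
    "cluster_samples_by_contribution",
    "private_mutation_spectra",
]

SUBSTITUTION_TYPES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = "ACGT"
#: Canonical COSMIC order: substitution-major, then 5' flank, then 3' flank.
CONTEXTS_96 = tuple(
    f"{f}[{s}]{t}" for s in SUBSTITUTION_TYPES for f in _BASES for t in _BASES
)
_CONTEXT_INDEX = {c: i for i, c in enumerate(CONTEXTS_96)}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_substitution(ref: str, alt: str) -> str:
    """Pyrimidine-normalized substitution type of an SNV (e.g. G>A -> C>T)."""
    ref, alt = ref.upper(), alt.upper()
    if ref in "AG":
        ref, alt = _revcomp(ref), _revcomp(alt)
    sub = f"{ref}>{alt}"
    if sub not in SUBSTITUTION_TYPES:
        raise ValueError(f"not a valid SNV substitution: {ref}>{alt}")
    return sub


def context_class(ref: str, alt: str, context: str) -> str:
    """96-class label of an SNV given its reference trinucleotide context.

    ``context`` is the genome 3-mer centered on the variant; purine-reference
    calls are reverse-complemented so the class always has a pyrimidine
    reference. The mapping is an involution-safe normalization: applying it
    to an already pyrimidine-represented call returns the same class.
    """
    ref, alt, context = ref.upper(), alt.upper(), context.upper()
    if len(context) != 3 or context[1] != ref:
        raise ValueError(f"context {context!r} does not center on ref {ref!r}")
    if ref in "AG":
        ref, alt, context = _revcomp(ref), _revcomp(alt), _revcomp(context)
    label = f"{context[0]}[{ref}>{alt}]{context[2]}"
    if label not in _CONTEXT_INDEX:
        raise ValueError(f"invalid substitution class {label!r}")
    return label


def _fetch_context(reference, chrom: str, pos: int) -> str | None:
    try:
        seq = reference[chrom][pos - 2 : pos + 1]
        return str(seq).upper()
    except (KeyError, IndexError):
        return None


def build_context_matrix(
    samples: list[TumorSample], reference=None
) -> pd.DataFrame:
    """96 x samples count matrix of pyrimidine-normalized SNV contexts.

    SNVs lacking a context are looked up in ``reference`` (a pyfaidx.Fasta or
    any mapping of chrom -> indexable sequence) when supplied, otherwise
    skipped; non-SNVs are always skipped. Skip counts are logged. Raises if
    no sample contributes a single usable SNV.
    """
    matrix = np.zeros((96, len(samples)), dtype=float)
    skipped = 0
    for j, sample in enumerate(samples):
        for rec in sample.mutations:
            if not rec.is_snv:
                skipped += 1
                continue
            ctx = rec.context
            if ctx is None and reference is not None:
                ctx = _fetch_context(reference, rec.chrom, rec.pos)
            if ctx is None or len(ctx) != 3 or ctx[1] != rec.ref:
                skipped += 1
                continue
            matrix[_CONTEXT_INDEX[context_class(rec.ref, rec.alt, ctx)], j] += 1
    if skipped:
        logger.info("context matrix: skipped %d non-SNV or context-less calls", skipped)
    if matrix.sum() == 0:
        raise ValueError("no usable SNV with context in any sample")
    return pd.DataFrame(
        matrix,
        index=pd.Index(CONTEXTS_96, name="context"),
        columns=[s.sample_id for s in samples],
    )


@dataclass(slots=True)
class SignatureModel:
    """De novo signatures, per-sample contributions and their annotations.

    ``signatures``: 96 x k, columns sum to 1. ``contributions``: k x samples,
    absolute scale (signatures @ contributions approximates the count
    matrix). ``cosmic_match``: de novo name -> (reference signature id,
    Pearson r). ``sample_cluster``: sample -> "S1" | "S2".
    """

    signatures: pd.DataFrame
    contributions: pd.DataFrame
    reconstruction_error: float
    cosmic_match: dict[str, tuple[int, float]] = field(default_factory=dict)
    sample_cluster: dict[str, str] = field(default_factory=dict)

    @property
    def k(self) -> int:
        return self.signatures.shape[1]


def extract_denovo_signatures(
    matrix: pd.DataFrame, k: int = 2, seed: int = 17, restarts: int = 20
) -> SignatureModel:
    """NMF decomposition of the context matrix into k de novo signatures.

    Frobenius objective with multiplicative updates; the best of ``restarts``
    random initializations (derived deterministically from ``seed``) is kept.
    Signature columns are normalized to sum 1 with the scale absorbed into
    the contributions.
    """
    n_samples = matrix.shape[1]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n_samples:
        raise ValueError(f"k={k} exceeds number of samples ({n_samples})")
    X = matrix.to_numpy(dtype=float)
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    seeds = np.random.SeedSequence(seed).generate_state(restarts)
    for s in seeds:
        model = NMF(
            n_components=k,
            init="random",
            solver="mu",
            beta_loss="frobenius",
            max_iter=200,
            tol=1e-6,
            random_state=int(s) % (2**32),
        )
        with warnings.catch_warnings():
            # restarts are compared by final error; per-restart convergence
            # chatter (and transient overflow in the multiplicative updates
            # of poorly initialized restarts) is not actionable
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            W = model.fit_transform(X)
        err = float(model.reconstruction_err_)
        if best is None or err < best[0]:
            best = (err, W, model.components_)
    err, W, H = best
    scale = W.sum(axis=0)
    scale[scale == 0] = 1.0
    W = W / scale
    H = H * scale[:, None]
    names = [f"denovo_{i + 1}" for i in range(k)]
    return SignatureModel(
        signatures=pd.DataFrame(W, index=matrix.index, columns=names),
        contributions=pd.DataFrame(H, index=names, columns=matrix.columns),
        reconstruction_error=err,
    )


def map_to_cosmic(
    model: SignatureModel, cosmic: pd.DataFrame
) -> dict[str, tuple[int, float]]:
    """Best reference-catalog match for each de novo signature by Pearson r.

    Ties are broken toward the lower signature index with a logged warning;
    constant (zero-variance) de novo vectors are flagged and excluded.
    Results are stored on the model and returned.
    """
    if model.signatures.shape[0] != cosmic.shape[0]:
        raise ValueError("signature and reference matrices must share 96 rows")
    ref = cosmic.to_numpy(dtype=float)
    ids = [int(str(c).split()[-1]) for c in cosmic.columns]
    matches: dict[str, tuple[int, float]] = {}
    for name in model.signatures.columns:
        v = model.signatures[name].to_numpy(dtype=float)
        if np.std(v) == 0.0:
            logger.warning("signature %s is constant; no reference match", name)
            continue
        rs = np.array(
            [
                np.corrcoef(v, ref[:, j])[0, 1] if np.std(ref[:, j]) > 0 else np.nan
                for j in range(ref.shape[1])
            ]
        )
        best_r = np.nanmax(rs)
        tied = [ids[j] for j in range(len(ids)) if np.isclose(rs[j], best_r, atol=1e-12)]
        if len(tied) > 1:
            logger.warning(
                "signature %s: tie between reference signatures %s; keeping %d",
                name,
                tied,
                min(tied),
            )
        matches[name] = (min(tied), float(best_r))
    model.cosmic_match = matches
    return matches


def cluster_samples_by_contribution(model: SignatureModel) -> dict[str, str]:
    """Two-group agglomerative clustering of contribution proportions.

    Euclidean distance on per-sample contribution proportions (columns
    normalized to sum 1), complete linkage, cut at 2 clusters. The cluster
    whose centroid loads higher on the de novo signature mapped to the
    lowest reference id is labelled S1. Degenerate inputs (fewer than 2
    samples, or identical proportions for all samples) collapse to a single
    S1 cluster with a warning.
    """
    H = model.contributions.to_numpy(dtype=float)
    samples = list(model.contributions.columns)
    if len(samples) < 2:
        logger.warning("fewer than 2 samples; assigning all to cluster S1")
        model.sample_cluster = {s: "S1" for s in samples}
        return model.sample_cluster
    col_sums = H.sum(axis=0)
    col_sums[col_sums == 0] = 1.0
    props = (H / col_sums).T  # samples x k
    if np.allclose(props, props[0]):
        logger.warning("identical contribution proportions; degenerate single cluster")
        model.sample_cluster = {s: "S1" for s in samples}
        return model.sample_cluster
    link = hierarchy.linkage(pdist(props, metric="euclidean"), method="complete")
    labels = hierarchy.fcluster(link, t=2, criterion="maxclust")

    # anchor signature = de novo component mapped to the lowest reference id
    if model.cosmic_match:
        anchor_name = min(model.cosmic_match, key=lambda n: model.cosmic_match[n][0])
    else:
        anchor_name = model.contributions.index[0]
    anchor_idx = list(model.contributions.index).index(anchor_name)
    centroid = {
        lab: props[labels == lab, anchor_idx].mean() for lab in np.unique(labels)
    }
    s1_label = max(centroid, key=centroid.get)
    model.sample_cluster = {
        s: ("S1" if lab == s1_label else "S2") for s, lab in zip(samples, labels)
    }
    return model.sample_cluster


def private_mutation_spectra(
    pairs: list[PatientPair],
    partitions: dict[str, tuple[set, set, set]],
) -> pd.DataFrame:
    """6-substitution-type counts pooled over primary-private vs LN-private SNVs.

    ``partitions`` maps patient_id to the (shared, private_p, private_ln) key
    sets produced by the concordance partition. Empty pools yield zero
    vectors with a logged flag.
    """
    counts = {site: dict.fromkeys(SUBSTITUTION_TYPES, 0) for site in ("primary", "lymph_node")}
    for pair in pairs:
        _, priv_p, priv_ln = partitions[pair.patient_id]
        for sample, keys, site in (
            (pair.primary, priv_p, "primary"),
            (pair.lymph_node, priv_ln, "lymph_node"),
        ):
            for rec in sample.mutations:
                if rec.key in keys and rec.is_snv:
                    counts[site][normalize_substitution(rec.ref, rec.alt)] += 1
    df = pd.DataFrame(counts, columns=["primary", "lymph_node"]).reindex(
        list(SUBSTITUTION_TYPES)
    )
    for site in df.columns:
        if df[site].sum() == 0:
            logger.warning("no private SNVs in the %s pool; zero spectrum", site)
    df.index.name = "substitution"
    return df
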