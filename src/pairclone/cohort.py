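"""Domain types and I/O for paired primary / lymph-node somatic mutation cohorts.

Mutation tables are tab-separated, one row per somatic call in one sample,
with 1-based inclusive coordinates (MAF convention). Two dialects are
supported: a ``minimal`` dialect using this package's own column names, and a
``maf`` dialect mapping the standard MAF column names
(Hugo_Symbol/Chromosome/Start_Position/...). Sample sheets are TSV with one
row per sequenced sample carrying the site label (primary vs lymph node),
patient assignment, tumor purity and patient metadata.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "VariantClass",
    "Site",
    "MutationRecord",
    "TumorSample",
    "PatientPair",
    "ValidationCohort",
    "MutationTableError",
    "CohortAssemblyError",
    "read_mutation_table",
    "write_mutation_table",
    "read_sample_sheet",
    "assemble_pairs",
    "assemble_validation_cohort",
]

_DNA = set("ACGTN-")


class VariantClass(str, Enum):
    """Coding consequence of a somatic variant."""

    MISSENSE = "missense"
    NONSENSE = "nonsense"
    SPLICE = "splice"
    FRAMESHIFT_INDEL = "frameshift_indel"
    INFRAME_INDEL = "inframe_indel"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


#: Classes counted in TMB and eligible for the driver screen. Synonymous and
#: unclassified calls are retained in the tables but excluded from both.
NONSILENT_CLASSES = frozenset(
    {
        VariantClass.MISSENSE,
        VariantClass.NONSENSE,
        VariantClass.SPLICE,
        VariantClass.FRAMESHIFT_INDEL,
        VariantClass.INFRAME_INDEL,
    }
)


class Site(str, Enum):
    PRIMARY = "primary"
    LYMPH_NODE = "lymph_node"


#: Fixed mapping from MAF Variant_Classification strings. Anything absent maps
#: to OTHER.
MAF_CLASS_MAP = {
    "Missense_Mutation": VariantClass.MISSENSE,
    "Nonsense_Mutation": VariantClass.NONSENSE,
    "Splice_Site": VariantClass.SPLICE,
    "Splice_Region": VariantClass.SPLICE,
    "Frame_Shift_Del": VariantClass.FRAMESHIFT_INDEL,
    "Frame_Shift_Ins": VariantClass.FRAMESHIFT_INDEL,
    "In_Frame_Del": VariantClass.INFRAME_INDEL,
    "In_Frame_Ins": VariantClass.INFRAME_INDEL,
    "Silent": VariantClass.SYNONYMOUS,
}
_MAF_CLASS_INVERSE = {
    VariantClass.MISSENSE: "Missense_Mutation",
    VariantClass.NONSENSE: "Nonsense_Mutation",
    VariantClass.SPLICE: "Splice_Site",
    VariantClass.FRAMESHIFT_INDEL: "Frame_Shift_Del",
    VariantClass.INFRAME_INDEL: "In_Frame_Del",
    VariantClass.SYNONYMOUS: "Silent",
    VariantClass.OTHER: "Targeted_Region",
}

MINIMAL_COLUMNS = [
    "sample_id",
    "patient_id",
    "gene",
    "chrom",
    "pos",
    "ref",
    "alt",
    "variant_class",
    "alt_count",
    "depth",
    "total_cn",
    "context",
]

MAF_COLUMN_MAP = {
    "Hugo_Symbol": "gene",
    "Chromosome": "chrom",
    "Start_Position": "pos",
    "Reference_Allele": "ref",
    "Tumor_Seq_Allele2": "alt",
    "Variant_Classification": "variant_class",
    "t_alt_count": "alt_count",
    "t_depth": "depth",
    "Tumor_Sample_Barcode": "sample_id",
}
_MAF_MANDATORY = list(MAF_COLUMN_MAP)
_MINIMAL_MANDATORY = [
    "sample_id",
    "gene",
    "chrom",
    "pos",
    "ref",
    "alt",
    "variant_class",
    "alt_count",
    "depth",
]


class MutationTableError(ValueError):
    """A mutation table violates the format contract."""


class CohortAssemblyError(ValueError):
    """Sample sheet and mutation records cannot be assembled into a cohort."""


@dataclass(frozen=True, slots=True)
class MutationRecord:
    """One somatic SNV/indel call in one sample.

    ``pos`` is 1-based inclusive. ``context`` is the reference trinucleotide
    centered on ``pos`` (as read off the genome; pyrimidine normalization
    happens downstream in signature analysis).
    """

    sample_id: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    variant_class: VariantClass
    alt_count: int
    depth: int
    patient_id: str = ""
    total_cn: int | None = None
    context: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1 (got {self.pos})")
        if not (0 <= self.alt_count <= self.depth):
            raise ValueError(
                f"alt_count must satisfy 0 <= alt_count <= depth "
                f"(got {self.alt_count}/{self.depth})"
            )
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        if self.context is not None:
            if len(self.context) != 3:
                raise ValueError(f"context must be a 3-mer (got {self.context!r})")
            if self.is_snv and self.context[1] != self.ref:
                raise ValueError(
                    f"context middle base {self.context[1]!r} != ref {self.ref!r}"
                )

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Mutation identity within a patient: (chrom, pos, ref, alt)."""
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1 and "-" not in (self.ref, self.alt)

    @property
    def vaf(self) -> float:
        if self.depth == 0:
            raise ZeroDivisionError("depth is 0")
        return self.alt_count / self.depth


@dataclass(slots=True)
class TumorSample:
    sample_id: str
    patient_id: str
    site: Site
    purity: float = 1.0
    mutations: list[MutationRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0.0 < self.purity <= 1.0):
            raise ValueError(f"purity must be in (0, 1] (got {self.purity})")

    def mutation_keys(self) -> set[tuple[str, int, str, str]]:
        return {m.key for m in self.mutations}


@dataclass(slots=True)
class PatientPair:
    """A primary tumor sample and its matched lymph-node metastasis."""

    patient_id: str
    primary: TumorSample
    lymph_node: TumorSample
    age: int | None = None
    sex: str | None = None
    stage: str | None = None
    smoking: str | None = None

    def __post_init__(self) -> None:
        if self.primary.site is not Site.PRIMARY:
            raise ValueError("primary member must have site=primary")
        if self.lymph_node.site is not Site.LYMPH_NODE:
            raise ValueError("lymph_node member must have site=lymph_node")
        if not (self.primary.patient_id == self.lymph_node.patient_id == self.patient_id):
            raise ValueError("pair members must share patient_id")

    @property
    def samples(self) -> tuple[TumorSample, TumorSample]:
        return (self.primary, self.lymph_node)


@dataclass(slots=True)
class ValidationCohort:
    """Unpaired samples with site labels, used for enrichment validation."""

    samples: list[TumorSample]

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(ids) != len(set(ids)):
            raise ValueError("sample_ids must be unique in a validation cohort")
        sites = {s.site for s in self.samples}
        if sites != {Site.PRIMARY, Site.LYMPH_NODE}:
            raise ValueError("validation cohort needs at least one sample of each site")

    def by_site(self, site: Site) -> list[TumorSample]:
        return [s for s in self.samples if s.site is site]


def _row_to_record(row: dict, dialect: str) -> MutationRecord:
    if dialect == "maf":
        vc = MAF_CLASS_MAP.get(str(row["variant_class"]), VariantClass.OTHER)
    else:
        vc = VariantClass(str(row["variant_class"]))
    total_cn = row.get("total_cn")
    context = row.get("context")
    return MutationRecord(
        sample_id=str(row["sample_id"]),
        patient_id=str(row.get("patient_id") or ""),
        gene=str(row["gene"]),
        chrom=str(row["chrom"]),
        pos=int(row["pos"]),
        ref=str(row["ref"]).upper(),
        alt=str(row["alt"]).upper(),
        variant_class=vc,
        alt_count=int(row["alt_count"]),
        depth=int(row["depth"]),
        total_cn=None if _is_missing(total_cn) else int(total_cn),
        context=None if _is_missing(context) else str(context).upper(),
    )


def _is_missing(value) -> bool:
    return value is None or (isinstance(value, float) and pd.isna(value)) or value == ""


def read_mutation_table(
    path: str | Path, dialect: str = "minimal", on_invalid: str = "warn"
) -> list[MutationRecord]:
    """Read a mutation table, validating every row.

    Rows violating record invariants (e.g. alt_count > depth) or with
    unparsable integers are rejected; with ``on_invalid="warn"`` they are
    dropped and their 0-based data-row indices logged, with ``"raise"`` a
    :class:`MutationTableError` listing the offending rows is raised.
    """
    if dialect not in ("minimal", "maf"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    mandatory = _MAF_MANDATORY if dialect == "maf" else _MINIMAL_MANDATORY
    rename = MAF_COLUMN_MAP if dialect == "maf" else {}
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise MutationTableError(
            f"{path}: missing mandatory column(s): {', '.join(missing)}"
        )
    df = df.rename(columns=rename)

    records: list[MutationRecord] = []
    bad: list[tuple[int, str]] = []
    for i, row in enumerate(df.to_dict("records")):
        try:
            records.append(_row_to_record(row, dialect))
        except (ValueError, KeyError) as exc:
            bad.append((i, str(exc)))
    if bad:
        detail = "; ".join(f"row {i}: {msg}" for i, msg in bad[:20])
        if on_invalid == "raise":
            raise MutationTableError(f"{path}: {len(bad)} invalid row(s): {detail}")
        logger.warning("%s: rejected %d invalid row(s): %s", path, len(bad), detail)
    return records


def write_mutation_table(
    records: Sequence[MutationRecord], path: str | Path, dialect: str = "minimal"
) -> Path:
    """Write records as TSV with a deterministic column order.

    ``read_mutation_table(write_mutation_table(r))`` is the identity on the
    modeled fields for both dialects.
    """
    if dialect not in ("minimal", "maf"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    rows = []
    for r in records:
        rows.append(
            {
                "sample_id": r.sample_id,
                "patient_id": r.patient_id,
                "gene": r.gene,
                "chrom": r.chrom,
                "pos": r.pos,
                "ref": r.ref,
                "alt": r.alt,
                "variant_class": r.variant_class.value,
                "alt_count": r.alt_count,
                "depth": r.depth,
                "total_cn": "" if r.total_cn is None else r.total_cn,
                "context": "" if r.context is None else r.context,
            }
        )
    df = pd.DataFrame(rows, columns=MINIMAL_COLUMNS)
    if dialect == "maf":
        df["variant_class"] = [
            _MAF_CLASS_INVERSE[r.variant_class] for r in records
        ]
        inverse = {v: k for k, v in MAF_COLUMN_MAP.items()}
        df = df.rename(columns=inverse)
    df.to_csv(path, sep="\t", index=False)
    return path


SAMPLE_SHEET_COLUMNS = [
    "sample_id",
    "patient_id",
    "site",
    "purity",
    "age",
    "sex",
    "stage",
    "smoking",
]


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read a sample sheet TSV; a missing purity column defaults to 1.0."""
    df = pd.read_csv(path, sep="\t")
    for col in ("sample_id", "patient_id", "site"):
        if col not in df.columns:
            raise MutationTableError(f"{path}: sample sheet missing column {col!r}")
    if "purity" not in df.columns:
        logger.warning("%s: no purity column; defaulting purity to 1.0", path)
        df["purity"] = 1.0
    return df


def _collapse_duplicates(
    records: list[MutationRecord], sample_id: str
) -> list[MutationRecord]:
    seen: dict[tuple, MutationRecord] = {}
    dups = 0
    for r in records:
        if r.key in seen:
            dups += 1
        else:
            seen[r.key] = r
    if dups:
        warnings.warn(
            f"sample {sample_id}: collapsed {dups} duplicate mutation record(s)",
            stacklevel=2,
        )
    return list(seen.values())


def _build_samples(
    records: Iterable[MutationRecord], sheet: pd.DataFrame
) -> dict[str, TumorSample]:
    if sheet["sample_id"].duplicated().any():
        dup = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise CohortAssemblyError(f"duplicate sample_id in sample sheet: {dup}")
    samples: dict[str, TumorSample] = {}
    for row in sheet.to_dict("records"):
        purity = row.get("purity")
        if _is_missing(purity):
            logger.warning("sample %s: missing purity, defaulting to 1.0", row["sample_id"])
            purity = 1.0
        samples[str(row["sample_id"])] = TumorSample(
            sample_id=str(row["sample_id"]),
            patient_id=str(row["patient_id"]),
            site=Site(str(row["site"])),
            purity=float(purity),
        )
    by_sample: dict[str, list[MutationRecord]] = {sid: [] for sid in samples}
    for r in records:
        if r.sample_id not in samples:
            raise CohortAssemblyError(
                f"orphan record: sample {r.sample_id!r} absent from sample sheet"
            )
        target = samples[r.sample_id]
        if r.patient_id and r.patient_id != target.patient_id:
            raise CohortAssemblyError(
                f"record patient_id {r.patient_id!r} conflicts with sheet "
                f"({target.patient_id!r}) for sample {r.sample_id}"
            )
        by_sample[r.sample_id].append(
            r if r.patient_id else replace(r, patient_id=target.patient_id)
        )
    for sid, sample in samples.items():
        sample.mutations = _collapse_duplicates(by_sample[sid], sid)
    return samples


def assemble_pairs(
    records: Iterable[MutationRecord], sample_sheet: pd.DataFrame
) -> list[PatientPair]:
    """Attach records to samples and pair each primary with its matched LN.

    The sheet must list exactly one primary and one lymph-node sample per
    patient; violations raise :class:`CohortAssemblyError` naming the patient.
    Pairs are returned sorted by patient_id.
    """
    samples = _build_samples(records, sample_sheet)
    meta_cols = [c for c in ("age", "sex", "stage", "smoking") if c in sample_sheet.columns]
    meta = (
        sample_sheet.groupby("patient_id")[meta_cols].first().to_dict("index")
        if meta_cols
        else {}
    )
    by_patient: dict[str, dict[Site, TumorSample]] = {}
    for sample in samples.values():
        slot = by_patient.setdefault(sample.patient_id, {})
        if sample.site in slot:
            raise CohortAssemblyError(
                f"patient {sample.patient_id}: more than one {sample.site.value} sample"
            )
        slot[sample.site] = sample
    pairs = []
    for pid in sorted(by_patient):
        slot = by_patient[pid]
        for site in (Site.PRIMARY, Site.LYMPH_NODE):
            if site not in slot:
                raise CohortAssemblyError(f"patient {pid}: missing {site.value} sample")
        m = meta.get(pid, {})
        pairs.append(
            PatientPair(
                patient_id=pid,
                primary=slot[Site.PRIMARY],
                lymph_node=slot[Site.LYMPH_NODE],
                age=None if _is_missing(m.get("age")) else int(m["age"]),
                sex=None if _is_missing(m.get("sex")) else str(m["sex"]),
                stage=None if _is_missing(m.get("stage")) else str(m["stage"]),
                smoking=None if _is_missing(m.get("smoking")) else str(m["smoking"]),
            )
        )
    return pairs


def assemble_validation_cohort(
    records: Iterable[MutationRecord], sample_sheet: pd.DataFrame
) -> ValidationCohort:
    """Attach records to site-labelled unpaired samples."""
    samples = _build_samples(records, sample_sheet)
    return ValidationCohort(samples=sorted(samples.values(), key=lambda s: s.sample_id))
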