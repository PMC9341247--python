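"""Tumor mutational burden (TMB) on a targeted-panel footprint.

TMB is the count of eligible somatic mutations divided by the panel's
megabase footprint. By default only nonsilent coding classes count
(missense, nonsense, splice, frameshift and in-frame indels); synonymous and
unclassified calls are excluded. The default footprint of 1.94 Mb matches a
large targeted oncology assay's TMB-callable region.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .cohort import NONSILENT_CLASSES, TumorSample, VariantClass

__all__ = ["DEFAULT_PANEL_MB", "TmbResult", "compute_tmb", "compare_tmb_groups"]

DEFAULT_PANEL_MB = 1.94


@dataclass(frozen=True, slots=True)
class TmbResult:
    sample_id: str
    eligible_count: int
    panel_mb: float

    @property
    def tmb(self) -> float:
        return self.eligible_count / self.panel_mb


def compute_tmb(
    sample: TumorSample,
    panel_mb: float = DEFAULT_PANEL_MB,
    eligible_classes: frozenset[VariantClass] | set[VariantClass] = NONSILENT_CLASSES,
) -> TmbResult:
    """Mutations per megabase for one sample."""
    if panel_mb <= 0:
        raise ValueError(f"panel_mb must be > 0 (got {panel_mb})")
    count = sum(1 for m in sample.mutations if m.variant_class in eligible_classes)
    return TmbResult(sample_id=sample.sample_id, eligible_count=count, panel_mb=panel_mb)


def compare_tmb_groups(
    group_a: Sequence[TmbResult], group_b: Sequence[TmbResult]
) -> tuple[float, float, float]:
    """Compare two TMB groups: (median_a, median_b, two-sided rank-sum p).

    Uses the Wilcoxon rank-sum (Mann-Whitney U) test, exact for small
    tie-free groups, normal approximation with tie correction otherwise.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    a = np.array([r.tmb for r in group_a], dtype=float)
    b = np.array([r.tmb for r in group_b], dtype=float)
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(np.median(a)), float(np.median(b)), float(res.pvalue)
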