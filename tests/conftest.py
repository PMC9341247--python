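import pytest

from pairclone.cohort import MutationRecord, PatientPair, Site, TumorSample, VariantClass


def make_record(
    sample_id="S1",
    gene="TP53",
    chrom="chr17",
    pos=7_577_120,
    ref="C",
    alt="T",
    variant_class=VariantClass.MISSENSE,
    alt_count=50,
    depth=100,
    **kw,
):
    return MutationRecord(
        sample_id=sample_id,
        gene=gene,
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        variant_class=variant_class,
        alt_count=alt_count,
        depth=depth,
        **kw,
    )


def make_pair(p_keys, ln_keys, patient_id="CN_01", purity=1.0, gene="TP53", **read_kw):
    """Build a pair whose samples carry mutations at the given integer loci."""

    def sample(keys, sid, site):
        muts = [
            make_record(
                sample_id=sid, gene=gene, chrom="chr1", pos=1000 + k, **read_kw
            )
            for k in keys
        ]
        return TumorSample(
            sample_id=sid, patient_id=patient_id, site=site, purity=purity, mutations=muts
        )

    return PatientPair(
        patient_id=patient_id,
        primary=sample(p_keys, f"{patient_id}_P", Site.PRIMARY),
        lymph_node=sample(ln_keys, f"{patient_id}_LN", Site.LYMPH_NODE),
    )


@pytest.fixture
def abc_bcd_pair():
    """Primary carries loci {1,2,3}, lymph node {2,3,4}: 2 shared of 4 union."""
    return make_pair([1, 2, 3], [2, 3, 4])
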