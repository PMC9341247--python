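"""Packaged reference data.

``cosmic_v2_synthetic.tsv`` is a synthetic stand-in for the COSMIC v2
signature catalog: 30 seeded, mutually distinct 96-context probability
profiles in the canonical COSMIC row order. Profile 1 carries the
CpG-deamination (C>T at NpCpG) character of COSMIC signature 1 and profile 23
is C>T-leaning with an elevated T>A component; the remaining 28 are sparse
random profiles. It serves both as the simulator's signature source and as
the mapping reference, so de novo signatures can be matched by identity the
same way a real COSMIC catalog would be used.

``panel_genes.txt`` lists 538 cancer-panel gene symbols emulating a targeted
assay footprint (one HGNC symbol per line).
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources as _ilr

import pandas as pd

__all__ = ["load_cosmic_signatures", "load_panel_genes"]


@lru_cache(maxsize=1)
def load_cosmic_signatures() -> pd.DataFrame:
    """Return the packaged 96x30 signature probability matrix.

    Rows are the 96 pyrimidine-normalized trinucleotide substitution classes
    (canonical COSMIC order, e.g. ``A[C>A]A``), columns ``Signature 1`` ..
    ``Signature 30``; each column sums to 1.
    """
    ref = _ilr.files("pairclone.data").joinpath("cosmic_v2_synthetic.tsv")
    with _ilr.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", index_col=0)
    return df


@lru_cache(maxsize=1)
def load_panel_genes() -> tuple[str, ...]:
    """Return the packaged targeted-panel gene symbols, file order."""
    ref = _ilr.files("pairclone.data").joinpath("panel_genes.txt")
    genes = tuple(
        line.strip() for line in ref.read_text().splitlines() if line.strip()
    )
    return genes
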