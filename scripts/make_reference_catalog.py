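"""Regenerate the packaged synthetic COSMIC-v2-style signature catalog.

Deterministic (fixed seed): rerunning reproduces
``src/pairclone/data/cosmic_v2_synthetic.tsv`` byte-identically.

Produces 30 distinct 96-context probability profiles. Profile 1 mimics the
spontaneous-deamination (CpG C>T) character of COSMIC signature 1; profile 23
is C>T-leaning with an elevated T>A component so the two defaults used by the
simulator are mutually distinguishable and distinctive against the other 28
seeded random profiles.
"""

from pathlib import Path

import numpy as np

SUBS = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]
BASES = "ACGT"
CONTEXTS = [f"{f}[{s}]{t}" for s in SUBS for f in BASES for t in BASES]
assert len(CONTEXTS) == 96

rng = np.random.default_rng(20220718)

profiles = np.zeros((96, 30))

# profile 1: ~70% mass on N[C>T]G, remainder diffuse
sig1 = rng.dirichlet(np.full(96, 0.15))
cpg = [i for i, c in enumerate(CONTEXTS) if "[C>T]" in c and c.endswith("G")]
sig1 *= 0.25 / sig1.sum()
sig1[cpg] += 0.75 * rng.dirichlet(np.full(len(cpg), 5.0))
profiles[:, 0] = sig1 / sig1.sum()

# profile 23: ~40% non-CpG C>T, ~35% T>A, remainder diffuse
sig23 = rng.dirichlet(np.full(96, 0.15)) * 0.25
ct_noncpg = [i for i, c in enumerate(CONTEXTS) if "[C>T]" in c and not c.endswith("G")]
ta = [i for i, c in enumerate(CONTEXTS) if "[T>A]" in c]
sig23[ct_noncpg] += 0.40 * rng.dirichlet(np.full(len(ct_noncpg), 3.0))
sig23[ta] += 0.35 * rng.dirichlet(np.full(len(ta), 3.0))
profiles[:, 22] = sig23 / sig23.sum()

# remaining profiles: sparse random, rejected if too similar to any kept one
kept = [0, 22]
for j in range(30):
    if j in kept:
        continue
    while True:
        p = rng.dirichlet(np.full(96, 0.12))
        rs = [np.corrcoef(p, profiles[:, k])[0, 1] for k in kept]
        if max(rs) < 0.5:
            break
    profiles[:, j] = p
    kept.append(j)

import pandas as pd

df = pd.DataFrame(
    profiles,
    index=pd.Index(CONTEXTS, name="context"),
    columns=[f"Signature {i}" for i in range(1, 31)],
)
df = df.round(6)
df = df.div(df.sum(axis=0), axis=1).round(6)
out = str(Path(__file__).resolve().parents[1] / "src" / "pairclone" / "data" / "cosmic_v2_synthetic.tsv")
df.to_csv(out, sep="\t", float_format="%.6f")
print("wrote", out, df.shape)
print("corr 1 vs 23:", np.corrcoef(df["Signature 1"], df["Signature 23"])[0, 1])
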