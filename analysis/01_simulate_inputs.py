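#!/usr/bin/env python
"""Generate the synthetic inputs every later analysis step consumes:
a labelled homolog family (aligned FASTA + label TSV), an RMSF profile with
the six flexible windows, and a ∆∆G candidate table.

Writes under results/inputs/. All generation is seeded; re-running
reproduces byte-identical files.
"""

from pathlib import Path

import pandas as pd

from passdesign import study
from passdesign.io import write_alignment, write_table
from passdesign.synthetic import FamilyDesign, gen_ddg, gen_family, gen_rmsf

SEED = 2024
OUT = Path(__file__).resolve().parent.parent / "results" / "inputs"
OUT.mkdir(parents=True, exist_ok=True)

# Homolog family: 50 sequences per class, preference probability 0.8 at a
# planted T-vs-E contrast (mirroring the thermophilic T preference observed
# at position 84 of the engineering target).
family = gen_family(FamilyDesign(
    length=120, n_thermo=50, n_meso=50,
    planted={84: ("T", "E"), 86: ("F", "L")},
    p=0.8, gap_rate=0.02, seed=SEED,
))
write_alignment(family.alignment, OUT / "family.aln.fasta")
write_table(
    pd.DataFrame(
        [{"id": k, "label": v} for k, v in family.labels.items()]
    ),
    OUT / "family_labels.tsv",
)
print(f"family: {len(family.alignment)} aligned sequences "
      f"({sum(v == 'thermophilic' for v in family.labels.values())} thermophilic)")

# RMSF profile with the campaign's six flexible regions planted.
profile = gen_rmsf(349, study.FLEXIBLE_REGIONS, high=0.25, low=0.10,
                   noise=0.02, seed=SEED)
write_table(
    pd.DataFrame({"position": profile.positions, "rmsf_nm": profile.rmsf_nm}),
    OUT / "rmsf.tsv",
)
print(f"rmsf: {len(profile.positions)} residues, "
      f"{len(study.FLEXIBLE_REGIONS)} planted flexible windows")

# ∆∆G table over the campaign candidate list (all predicted stabilizing).
candidates = study.WAY1_MUTATIONS + study.WAY2_MUTATIONS
ddg, truth = gen_ddg(candidates, candidates, effect=1.5, noise=0.3, seed=SEED)
write_table(
    pd.DataFrame(
        [{"mutation": str(m), "ddg": v, "planted": truth[m]} for m, v in ddg.items()]
    ),
    OUT / "ddg.tsv",
)
print(f"ddg: {len(ddg)} candidate mutations written")
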