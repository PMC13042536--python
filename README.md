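# passdesign

Computational design procedures for engineering the stereoselectivity and
thermostability of a (2R,3R)-butanediol dehydrogenase (BDH) — and, more
generally, for any enzyme campaign that triages stabilizing mutations with
evolutionary information, designs diversity-constrained screening
libraries, and walks a fitness landscape by iterative saturation
mutagenesis.

The package is organised as an analysis project: the computation lives in
the importable package under `src/passdesign/`, and the numbered scripts
under `analysis/` are thin drivers that run each stage and write tables to
`results/`.

## What it computes

* **∆PFM** — homologs of the engineering target are labelled thermophilic /
  non-thermophilic, a position frequency matrix (PFM) is built per class on
  query-mapped alignment columns, and
  ∆PFM(p, a) = f_thermo(p, a) − f_nonthermo(p, a), so positive means the
  residue is enriched among thermophilic homologs.
* **PASS triage** — candidate stabilizing mutations from ∆∆G screening are
  kept if they lie in a flexible region (RMSF > 0.2 nm, Way 1) or satisfy
  ∆∆G < 0 and ∆PFM > 0 (Way 2); the union goes to experimental
  verification, and predictions are scored against outcomes
  (tp rate = % of selected mutants confirmed improved).
* **Smart libraries** — per site, keep at most 2 of the top-9-scoring
  substitutions per amino-acid embedding cluster (k = 7); combinatorial
  libraries are fragment partitions with ∏ 2^|fragment| members, lazily
  enumerated and uniformly sampled.
* **PISM** — perfect iterative saturation mutagenesis: each round
  explicitly constructs all 19 substitutions per open site on each
  template, scores them through a fitness oracle (experimental lookup
  table or synthetic landscape) and advances the best proposal per
  objective; traces record every proposal and parent link.
* **Assay statistics** — stereoselectivity s = (SA_cis − SA_trans)/(SA_cis
  + SA_trans) and the ratio (1+s)/(1−s); deactivation kinetics
  t½ = ln 2 / k_d; Michaelis–Menten fits (k_cat, K_m, k_cat/K_m);
  enantiomeric excess and conversion yield; guarded fold changes.
* **Reactive geometry** — per-frame hydride-transfer indicators dist1,
  dist2 and the attack angle above the nicotinamide plane, with
  conformation-population clustering.
* **Synthetic data** — seeded generators for every upstream input
  (labelled families, RMSF profiles, ∆∆G tables, two-substrate fitness
  landscapes, coordinate frames), so the full pipeline runs without any
  external predictor or instrument.

## Worked example

Run the three-round saturation-mutagenesis campaign on the thermostable
scaffold 6M2 over binding-pocket sites 115/118/293, with three objectives:

```sh
python analysis/05_run_pism.py
```

```
round 1: 57 proposals
  cis_selectivity    -> T22V/Q112N/A230R/T258G/A260M/I280L/Y293S
  trans_selectivity  -> T22V/Q112N/F115L/A230R/T258G/A260M/I280L
  cis_activity       -> T22V/Q112N/F115C/A230R/T258G/A260M/I280L
round 2: 114 proposals
  ...
round 3: 57 proposals
  ...
LTF lineage: F115L -> L118T -> Y293F
```

Round 1 saturates the three sites on 6M2 (3 × 19 = 57 mutants) and picks
one template per objective: Y293S for cis selectivity, F115L for trans
selectivity, F115C for raw activity. Round 2 saturates the two remaining
sites on each template (2 × 19 × 3 = 114), round 3 the last site. The
trans-selectivity path ends at 6M2/F115L/L118T/Y293F ("LTF"), a variant
with perfect trans preference (s = −1), reached through the lineage
F115L → L118T → Y293F.

The other drivers cover the remaining stages, e.g.:

```sh
python analysis/03_pass_triage.py
# PASS: 34 candidates -> 6 Way 1 + 28 Way 2 = 34 selected (union)
# validation: 30/34 stabilizing confirmed -> true-positive rate 88.2%
python analysis/06_assay_stats.py
# wild type: SA_cis 0.15 vs SA_trans 0.043 U/mg -> s = 0.554 (cis:trans 3.5:1)
# 6M2 / cis-CHD: kcat 3.33 s^-1, Km 12.44 mM, kcat/Km 0.268 s^-1 mM^-1
```

`analysis/01_simulate_inputs.py` must run first (02 and 03 read its
output); the other drivers are independent.

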