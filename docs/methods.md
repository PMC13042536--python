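# Methods

`passdesign` re-implements, as testable code, the computational design
procedures of a dehydrogenase stereoselectivity/thermostability engineering
campaign: evolutionary triage of stabilizing mutations, diversity-constrained
library design, greedy iterative saturation mutagenesis over a fitness
oracle, the assay statistics used to score variants, and reactive-geometry
indicators of the hydride-transfer step. Everything upstream that required
external predictors or instruments (language-model scores, ∆∆G calculators,
thermostability classifiers, MD trajectories, plate readers, HPLC) enters as
*input tables*; a synthetic-data module generates inputs with the same
statistical structure so the whole pipeline runs and is tested without any
external dependency.

## ∆PFM: the evolutionary stabilization signal

Homologs of the engineering target are split into thermophilic and
non-thermophilic classes by an external labeler (any labeler can be plugged
in; the generator plants labels for tests). Per class, a position frequency
matrix (PFM) is computed on the alignment columns mapped to the query's
1-based residue numbering; columns where the query is gapped are unmapped
and a lookup there is a typed error, deliberately distinct from a ∆PFM of
zero. The statistic is

    ∆PFM(p, a) = f_thermo(p, a) − f_nonthermo(p, a) ∈ [−1, 1].

**Sign convention.** We fix positive = thermophilic-preferred, so the
selection rule "keep ∆∆G < 0 and ∆PFM > 0" always reads "energetically
stabilizing *and* enriched among thermophilic homologs". (Descriptions of
this quantity sometimes state the subtraction in the opposite order while
selecting positive values as thermophilic-preferred; the convention here is
the one consistent with the selection logic.)

**Gaps.** Frequencies are normalized over non-gap symbols only, with the
per-column gap fraction reported separately. This makes ∆PFM comparable
across columns with unequal gap load; an all-gap column yields a zero row.

**Homolog pipeline.** Redundancy removal is a greedy longest-first
clustering at 90% identity (a deterministic stand-in for cd-hit), and the
similarity window keeps sequences at 40–100% identity to the query.
Identity is matches / min(ungapped lengths) over columns where neither
sequence is gapped. The reference campaign's bookkeeping of 691 homologs
(272 thermophilic + 419 non-thermophilic) is carried as study data; one
passage of the source reports 696 after redundancy removal — we treat
691, the sum of the class sizes, as the consistent figure.

## PASS triage

Candidates arrive from ∆∆G screening (tool-native units; Rosetta/ABACUS/
FoldX exports are never mixed — one unit tag per table).

* **Way 1 (position):** keep candidates inside flexible regions — maximal
  runs of residues with RMSF strictly above 0.2 nm, discarding runs shorter
  than `min_run = 3` residues. The default run length is chosen just below
  the shortest flexible region observed in the reference campaign (4
  residues); both cutoff and run length are parameters.
* **Way 2 (source):** keep candidates with ∆∆G < 0 *and* ∆PFM > 0, both
  strict (boundary values excluded). A `negative_control` flag flips the
  ∆PFM condition to < 0 for destabilizing-control selection.

The final selection is the union, with per-way provenance and a rationale
string per selected row. Prediction scoring follows the campaign's own
convention: the "true-positive rate" is the fraction of selected mutants
experimentally confirmed improved — conventionally a precision / positive
predictive value, not the sensitivity of ROC analysis — and symmetrically
for the destabilizing controls. With the published outcome lists (34
selected, 4 decreased; 34 controls, 4 improved) both rates are 30/34 =
88.2%.

## Diversity-constrained smart libraries

Per site, an external zero-shot model scores the 19 substitutions. To avoid
spending screening capacity on chemically redundant picks, the 20 residues
are clustered in an amino-acid embedding space (deterministic agglomerative
clustering, average linkage, Euclidean distance, alphabetical tie-breaks;
k = 7 by default) and at most 2 of the top-9-scoring substitutions are kept
per cluster, never padding from outside the top 9. The per-site counts this
yields depend on how the top 9 fall across clusters
(count = Σ_cluster min(2, occupancy)); the campaign's per-site counts
(5, 6, 8, 8, 7, 7, 7, 7, 7, 7 — total 69) are reproduced through fixtures
whose top-9 occupancy realizes each count, since the underlying scores are
not public.

Combinatorial libraries are ordered partitions of single mutations into
gene fragments; any subset of each fragment is realizable, so the member
count is ∏ 2^|fragment|, including the unmutated base — 3/3/3 gives
8 × 8 × 8 = 512. Enumeration is lazy and duplicate-free; sampling is
uniform without replacement and seed-reproducible.

## Perfect iterative saturation mutagenesis (PISM)

"Perfect" means every substitution is explicitly constructed (19 per site),
not sampled through degenerate codons, so each round's proposal count is
exactly Σ_site |alphabet_site|. The engine runs a greedy adaptive walk: per
round, saturate the sites still carrying the base residue on each template,
score all proposals through the oracle, and advance one template per
objective (duplicates merged in the trace; each objective retains its own
template). Supported metrics: activity toward either substrate and the
stereoselectivity value. Tie-breaking is deterministic — metric, then
fewest mutations, then canonical genotype string — which matters in
practice: two round-3 variants of the reference campaign both reach a
stereoselectivity of exactly −1 and the string tie-break selects the
published lineage endpoint.

Greedy walks provably reach the optimum of additive landscapes (tested
exhaustively against the 20³ enumeration) and can be trapped by
reciprocal sign epistasis (tested on a planted trap); the trace retains
every proposal and parent link, so lineages and misses are reconstructable.

The experimental oracle is a lookup table keyed by canonical genotype
string; missing genotypes raise, no imputation. The shipped three-round
screen table (`study.synthetic_screen_oracle`) is a synthetic stand-in:
it carries the printed named-variant measurements verbatim and fills the
rest of the 20³ genotype space with deterministic synthetic activities
confined to |s| ≤ 0.6 and ≤ 2 U/mg, so every template choice is decided by
a printed measurement, never by filler.

## Assay statistics

* Stereoselectivity value s = (SA_cis − SA_trans)/(SA_cis + SA_trans),
  undefined (typed error, never 0) when both activities vanish; the
  equivalent cis:trans ratio is r = (1+s)/(1−s) with exact algebraic
  inverse. Printed headline values were computed from unrounded raw data,
  so recomputing from printed activities differs in the last digit (e.g.
  0.554 from 0.15/0.043 vs a printed 0.561; 28.0 vs 28.1 at s = 0.931) —
  the package recomputes rather than hard-coding printed values.
* Thermal deactivation: kd from linear regression of ln(residual activity)
  vs time (≥3 distinct points, positive fractions), t½ = ln 2 / kd; an
  apparently negative kd (activation) is reported with undefined half-life.
* Michaelis–Menten: nonlinear least squares of v = Vmax·S/(Km+S)
  (scipy `curve_fit`), initialized at Vmax = max rate and Km = concentration
  nearest half-max; requires ≥5 concentrations spanning the half-saturation
  estimate; kcat = Vmax / enzyme concentration; non-physical estimates are
  rejected, not clipped.
* ee = 100·|R − S|/(R + S) with the dominant enantiomer tagged; conversion
  yield defaults to the *convertible* substrate pool as the denominator
  (the stereoisomers the enzyme accepts) — pass the total pool to use the
  other convention.
* Fold changes guard the zero-reference case with a "gained from zero"
  sentinel rather than an infinity, for substrates the reference enzyme
  cannot convert at all.

Units are fixed throughout: activities U/mg, Km mM, kcat s⁻¹, efficiency
s⁻¹·mM⁻¹, time min, RMSF nm.

## Reactive-geometry indicators

Three per-frame indicators describe whether a bound substrate is poised for
hydride transfer: dist1 (hydroxyl H at the R stereocenter → catalytic
serine Oγ), dist2 (donating carbon C_D → accepting nicotinamide C4), and
the attack angle. "Attack angle" has no single standard definition; the
default here is the elevation of the C_D→C_A vector above the
least-squares plane of the six nicotinamide ring atoms (smallest principal
axis of the centered ring coordinates), which is well-defined without an
explicit hydride position and lies in [0°, 90°]; the C_D–H_D–C_A
convention is selectable when a hydride atom is present. Coordinates are
read in Å from minimal PDB (only chain, residue number, atom name and xyz
are consumed); indicators are reported in nm and degrees. Computation is
double-precision end-to-end (the PDB boundary is single-precision), which
is what makes the 1e-9 rigid-motion invariance tolerance attainable.

Conformation populations are split by k-means on standardized indicators
with deterministic farthest-point initialization; a low between/within
separation ratio (< 2) flags a forced split of unimodal data.

## Synthetic-data generators

Every generator is a pure function of a design object + seed. Defaults
encode the study conditions: families of 50 sequences per class with
planted-preference probability p = 0.8; RMSF profiles at 0.25 nm inside /
0.10 nm outside planted windows (cutoff 0.2 nm splits them) with 0.02–0.03
nm noise; landscape effects on log-activity scale (multiplicative on
activities, keeping them positive) with observation noise frozen per
genotype so oracles are deterministic, as the ISM engine requires. What the
generators do *not* emulate: phylogenetic correlation among homologs
(sequences are drawn independently given class), force-field-realistic
coordinates, and instrument-specific error structure — so passing tests
demonstrate correctness of the procedures, not predictive performance on
real families or trajectories.

## Problem sizes and determinism

The test suite and the acceptance script use the campaign's own sizes where
printed (57/114 proposals, 512-member library, 142-sample, 14-point
kinetics grid) and modest simulation sizes elsewhere (20–100 seeds for
recovery statistics, 100–200 frames for geometry ensembles, exhaustive 20³
enumeration for the optimality check). All randomness flows through
explicit seeds; identical seeds give byte-identical generator output and
identical traces.

## Known limitations

* Way 1 is applied to the supplied candidate list only; the implicit
  precondition that candidates already passed ∆∆G screening is encoded in
  the list, not re-checked.
* Fragment membership is a residue-level partition; codon coordinates and
  fragment boundaries in base pairs are not modelled.
* Non-canonical amino acids are representable only as opaque label tokens;
  they carry no substitution-matrix or scoring semantics.
* The per-site smart-library counts are reproduced via occupancy fixtures
  (the mechanism is exercised; the upstream scores are not public).
* Melting-temperature curve fitting, docking, MD, umbrella sampling and
  chromatogram processing are out of scope; their outputs are inputs here.
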