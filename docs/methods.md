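# Methods

## Encoding

The type-I pseudo amino acid composition represents a sequence by its
20 residue fractions plus λ sequence-order correlation factors. The
correlation functional is the mean squared difference of standardized
physicochemical indices,

    Θ(R_i, R_j) = (1/Γ) Σ_k [H_k(R_j) − H_k(R_i)]²,

averaged over all residue pairs at lag τ to give θ_τ, and the combined
vector is normalized by 1 + ω Σ θ_τ so the components sum to exactly 1.
Standardization (zero mean, unit SD over the 20 amino acids, population
SD) makes heterogeneous scales commensurable; a constant index is
rejected because it carries no contrast. Consequences used as test
oracles: every component is non-negative; the vector is invariant under
sequence reversal; homopolymers have a zero order block; λ = 0 reduces
exactly to plain composition; and as ω → 0 the tail vanishes and the
head tends to the composition.

The default index trio covers three complementary property axes —
hydropathy (Kyte–Doolittle, AAindex KYTJ820101), polarity (Grantham,
GRAR740102) and solvation free energy (Eisenberg–McLachlan,
EISD860101). The machinery is index-agnostic: any TSV of 20-value
columns can replace the registry, and model files record a hash of the
table used. Index values are data, not algorithm; correctness is
defined by the standardization and correlation machinery.

### Parameters

- λ (sequence-order tiers, default 5): number of lags; must be smaller
  than every sequence length, enforced with a fail-fast error listing
  offending records. Conventional sweep: {3, 5}.
- ω (weight, default 0.5): balance of order block vs composition.
  Conventional sweep: 0.1–0.6.
- γ (RBF width, default 0.07; sweep 0.04–0.09) and C (cost, default 32;
  the published protocol grid-searches C but never reports the winner,
  so the default grid is {1, 2, 4, ..., 128} and the chosen value is
  always echoed in outputs).

## Classifier and feature scaling

The SVM is scikit-learn's libsvm-backed `SVC` with the RBF kernel;
training is deterministic, scores are oriented so higher = more
OMP-like, and a score of exactly 0 classifies negative (conservative
tie-break). Models persist with their full encoding configuration.

Pse-AAC components are simplex-normalized and therefore small (~0.05);
at the conventional γ range the kernel on such vectors is nearly
constant, and a near-constant kernel degenerates the SVM into a
majority vote. Under leave-one-out evaluation that artifact is
pernicious: the held-out sample's own class is always one short in
training, so a majority-vote classifier scores *against* the true
class and the null auROC collapses toward 0 rather than 0.5. The
package therefore offers per-feature min–max scaling fitted strictly
inside each training fold (never on the held-out sample). The library
default is scale-off, preserving the plain protocol; all synthetic
calibration runs use scale-on as their study condition, which is also
the standard LIBSVM recommendation.

## Evaluation

Confusion counts follow the usual TP/FN/FP/TN semantics with positives
= OMPs. MCC is reported as undefined (never 0) when a marginal is
zero. Percentages are displayed with half-away-from-zero rounding to 2
decimals; fractions are kept at full precision internally. The ROC is
built by sorting scores descending with ties grouped and integrating
trapezoidally; this equals the all-pairs Mann–Whitney statistic (ties
counted half), which the tests verify on random instances.

`counts_from_rates` inverts printed Sn/Sp percentages to integer
confusion counts (nearest integer at given class sizes) and validates
by round trip. The round-trip tolerance accepts ±0.005 percentage
points *or* agreement under either rounding or truncation to 2
decimals, because published tables mix the two conventions (e.g. a
printed 84.61 where the implied count gives 84.615).

The jackknife trains exactly n models for n samples; encoding is
per-sequence and hence leakage-free by construction, while scaling is
refitted per fold. A leak test (duplicating a sample must change its
held-out score) guards the contract. Folds may run in parallel
(joblib); results are bit-identical to serial execution because each
fold is pure and the reduction order is fixed.

Grid search enumerates the full (ω, λ, γ, C) product, records failing
points rather than skipping them, and selects by overall accuracy
(default) or sensitivity — both selection rules are exposed because
either is defensible on an imbalanced set; OA is the default as the
main criterion of the published protocol. Ties break by higher auROC,
then higher MCC, then smaller λ, then smaller γ.

## Synthetic data generator

The generator emulates a two-class sequence set with independently
controllable signal axes; it calibrates the software, not the biology
(no β-barrel motifs, no transmembrane topology, no homology
structure).

- Composition signal δ_c: negatives draw i.i.d. from a uniform residue
  background; positives from the background tilted toward hydrophobic
  residues by factor (1 ± δ_c), renormalized.
- Order signal δ_o: positives follow a first-order Markov chain whose
  transition matrix interpolates between the i.i.d. baseline and a
  fixed permutation pairing residues of adjacent hydropathy rank
  (I↔V, L↔F, C↔M, A↔G, T↔S, W↔Y, P↔H, E↔Q, D↔N, K↔R). With δ_c = 0
  this matrix is doubly stochastic, so the stationary composition
  stays uniform and plain composition is uninformative by
  construction; the class signal lives only in residue neighborhoods,
  exactly what the lag correlations measure.

The canonical calibration conditions are δ_c = 0.5 (strong
compositional signal) and δ_o = 0.2 (order-only signal). The order
value is deliberately moderate: the pairing permutation is an
involution, and at large δ_o sequences develop long two-letter runs
whose per-sequence composition *fluctuations* become class-informative
even though the mean composition is matched, defeating the purpose of
the order-only condition. At 0.2 the λ=0 encoding stays at chance
while λ=5 separates clearly.

Default sizes: 50 positives vs 200 negatives (the canonical ~1:4
imbalance), lengths uniform on 50–150 residues — typical of small
bacterial protein datasets. The `paper_like` preset splits any total
at 208:879 with ratio-preserving rounding. All generation is
reproducible from a single integer seed.

What passing calibration shows: the pipeline finds signal where it was
planted, at the strength planted, and none where there is none. It
does not show that real OMPs are separable at these rates — real
benchmark performance depends on curated data the package does not
ship.

## Numerical choices

- Normalization assertion tolerance 1e−9; oracle-agreement tolerance
  1e−12 in tests.
- Population SD (ddof = 0) in index standardization.
- Score tie at exactly 0 → negative class.
- Nonstandard residues: policies `strict` (default, reject), `drop`
  (delete + warn), `map` (B→D, Z→E, U→C, else drop); the encoding is
  defined only over the 20 standard residues.
- Problem sizes in tests and the acceptance script (e.g. 100 sequences
  per class for calibration, 20 null replicates at 20+20, a 30-sample
  grid-search dataset) were chosen as the smallest sizes at which the
  stochastic contrasts are unambiguous.

## Known limitations

- No homology-aware redundancy reduction; users supplying real data
  should de-redundify upstream.
- Type-II (amphiphilic) Pse-AAC, dipeptide composition, alternative
  kernels and probability calibration are out of scope.
- The generator's hydrophobic tilt and hydropathy-pairing order signal
  are engineering constructs; they make no claim about OMP biology.
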