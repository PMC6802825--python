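# Methods

## Problem and model

Given an ensemble of candidate 3D models for a protein target, each model is
to be classified as *correct* (TM-score ≥ 0.5 against the reference, i.e.
same fold) or not, with a calibrated-ish confidence. The classifier is a
random forest over 58 features per model (3 target-level, 12 model-level,
43 ensemble-level summary statistics); its score is the fraction of trees
voting "correct", banded into confidence tiers high (> 0.5), medium
(0.3, 0.5], low (0.1, 0.3], failed (≤ 0.1), with boundary values assigned to
the lower tier. Features are deliberately not normalised; trees are
scale-free. A regression variant predicts the TM-score itself and uses
predicted TM ≥ 0.5 as its success cutoff.

Ensemble statistics (max, min, median, spread = max − median) are computed
per target across all of its models for ten of the twelve model features.
The map-alignment hit length, the contact PPV, and the absolute
satisfied-contact count contribute only their per-target maxima. The
satisfied-contact count is bookkept as an auxiliary thirteenth quantity that
never appears as a model-level column, which is what makes the arithmetic
3 + 12 + (10×4 + 3) = 58 balance.

## Geometry

**Representative atoms.** Each residue is reduced to its Cβ atom (Cα for
glycine; Cα with a logged warning when Cβ is missing). Observed contacts are
pairs of representative atoms strictly closer than 8 Å with sequence
separation ≥ 5 positions (the strict `<` also defines contact satisfaction,
so one convention is used everywhere). Contact maps live in sequential
position space 1..L, so author-numbering gaps cannot distort separations.
The separation filter is configurable; 5 is the default because shorter-range
contacts are trivially satisfied by chain connectivity.

**TM-score.** For equal-length models with a fixed residue correspondence,
TM = (1/L) Σ 1/(1 + (dᵢ/d0)²) with d0 = 1.24(L−15)^⅓ − 1.8, floored at
0.5 Å — the customary floor, without which d0 is non-positive for chains of
17 residues or fewer. The score is maximised over rigid superpositions by a
fragment-seeded search: seeds are all contiguous fragments of lengths
{L, L/2, L/4} at stride 4 (plus the chain tail); each seed alternates
least-squares (Kabsch) superposition on the current residue subset with
reselection of residues at dᵢ < d0 until a fixed point (≤ 20 iterations,
subset floor of 3 residues), and the best TM over all seeds and iterations
is kept. This is the standard heuristic and is adequate for same-topology
decoys; it is not a sequence-order-independent structure aligner.

## Contact-map alignment

Both aligners compare a model's observed (binary) map against the target's
predicted (probabilistic) map without assuming a shared indexing.

**Local aligner.** The objective of a monotone partial residue
correspondence is the sum over pairs of aligned contacts of
w = p_pred / (1 + |Δsep| / sep_tolerance) (sep_tolerance 10), minus affine
gap costs between consecutive aligned pairs (gap open −1, extend −0.1;
flanks free). This quadratic objective is optimised by iterated double
dynamic programming: a residue-pair seed similarity (contact-neighbourhood
overlap) is aligned by an affine-gap local DP, the mapping induces a refined
seed (weights of contacts whose far ends are aligned, same chain side), and
the loop repeats until the mapping stabilises (≤ 20 cycles). The search runs
from three seed matrices (overlap, degree product, flat) under three
gap-open variants, then from anchored seeds that pin one observed contact
onto one predicted contact (the 32 highest-weight pinnings, 4 cycles each);
anchoring is what lets the search escape basins where pure self-consistent
refinement stalls. The reported score is always the true objective of the
best mapping encountered. On 200+ random instances of length ≤ 8 the result
equals exhaustive search over all monotone correspondences exactly; at
production sizes optimality is not guaranteed, only determinism.

DP traceback ties prefer the diagonal (match) over gaps; silent diagonal
runs through zero-weight cells are legitimate parts of a mapping (match
weights are non-negative, so they only ever save gap cost).

**Spectral aligner.** Each map's matrix (binary or probabilistic, zero
diagonal) is decomposed symmetrically; the k = 15 leading eigenvectors
(by |eigenvalue|, clamped to the map length with a warning) are scaled by
√|eigenvalue|, and signs are fixed by making each vector's
largest-magnitude entry positive. Residue-pair similarity is
S(i,j) = Σₖ |uₖ(i)·vₖ(j)|, aligned globally with affine gaps. The absolute
value makes the score exactly invariant to the sign indeterminacy of
eigendecomposition. Reported scores are floored at 0 (an empty alignment is
always available in spirit; a forced all-gap global alignment is not a
meaningful similarity).

## Other scores

- **PPV / satisfied count**: predicted contacts with p > 0.5 (threshold
  configurable) realised in the model; an empty denominator returns PPV 0
  with a warning (the alternative, NaN, would silently knock models out of
  tree splits).
- **Contact potential**: Σ p over satisfied predicted entries, minus an
  optional penalty λ·Σ p over unsatisfied ones (λ = 0 by default, keeping
  the score monotone in the satisfied set).
- **Consensus (Pcons-style)**: each model's mean pairwise TM-score to the
  other models of its ensemble. Ranking behaviour, not the exact Pcons
  S-score superposition, is what matters downstream.
- **PcombC**: w·(ProQ3D, Pcons, PPV) with default weights (0.2, 0.5, 0.3) —
  the combination weights are not canonical; the defaults favour the
  consensus term and are fully configurable. Missing inputs propagate as
  missing.
- **Convergence baseline**: mean pairwise TM of the ten models ranked
  highest by a chosen score; a target is predicted correct strictly above
  0.65. **FPR baseline**: the smallest score threshold whose empirical
  false-positive rate does not exceed the bound (positives at score >
  threshold), i.e. maximal recall at that FPR.

## Missing data

External score columns may be absent per model or per target. Per-model
gaps are imputed with the target's ensemble median (logged); a column that
is missing for an entire target is resolved with the training-set median
stored inside the persisted model, so prediction never silently invents
zeros. Persisted models carry the frozen 58-column manifest and refuse
feature tables that do not match it.

## Synthetic benchmark

The generator emulates the raw material of a template-free modelling study:

- **Natives**: persistent random walks (3.8 Å virtual bonds) collapsed by
  iterative relaxation (bond restraint, excluded volume, compaction toward
  Rg ≈ 2.45·L^0.37) into self-avoiding globules, retried until the 8 Å
  contact density lands in the realistic 1–3 contacts/residue band.
- **Decoys**: the native displaced by smooth chain-correlated fields (3–4
  low-frequency sinusoidal modes plus 15% white noise, unit RMS scaled to
  the noise level) plus a random rigid motion, so decoys stay protein-like.
  Default noise levels 0.5–8 Å span TM ≈ 0.97 down to ≈ 0.2 at L ≈ 60.
- **Per-target difficulty**: each target draws an ease factor (spread 0.6)
  that shrinks its contact precision and external-score informativeness,
  a noise scale (0.8–1.6) and a noise floor (0–5 Å). The floor is what
  produces genuine modelling failures (targets with no correct model), so
  roughly 60–90% of targets succeed and all four confidence tiers populate,
  as in real sets.
- **Predicted contacts**: a coverage fraction of native contacts as true
  entries (p ~ U(0.60, 0.95)) plus false pairs (p ~ U(0.51, 0.75)) sized so
  PPV against the native equals the requested precision (defaults 0.7/0.7).
- **External scores**: a·z(TM) + √(1−a²)·noise + a per-target offset, so
  a = informativeness (default 0.8) is the within-target correlation with
  true quality and raw scores are incomparable between targets — precisely
  the situation that motivates the classifier.
- **B_eff**: computed from small synthetic alignments with redundancy
  clusters, via Σᵢ 1/|{j : identity(i,j) ≥ 0.8}| (identity over mutually
  ungapped columns).

**Negative control.** The `uninformative_spec` decouples labels from every
feature channel: external scores are pure noise, predicted contacts are
essentially unrelated to the native, and — the crucial part — half the
targets have *all* of their decoys mirror-reflected. Reflection preserves
every interatomic distance, hence observed contact maps, their alignments,
contact satisfaction, and pairwise model similarity, while the TM-score
(proper rotations only) collapses below 0.5. Chirality is invisible to the
entire feature set, so held-out AUC must fall to chance; this is also a
real failure mode of contact-based assessment. Earlier control designs
based on large shared smooth perturbations were rejected because distortion
leaves contact-density fingerprints that are *genuine* (if weak) quality
signal. The control uses more, smaller ensembles (24 targets × 12 models)
because its effective sample size is the number of targets, and the test
side pools three disjoint-seed benchmarks.

**What passing tests show.** Parameter recovery on this benchmark (held-out
AUC ≥ 0.9 under the informative spec at 8 targets × 50 models; tier
precisions pooled over 10 replicate benchmarks of 8 × 25 rising from failed
to high; chance AUC under the control) demonstrates that the pipeline wiring,
the feature contract, and the learner behave correctly — not that the
method attains any particular accuracy on real decoys, whose error modes
(register shifts, non-native topologies that are locally native-like,
correlated external-score biases) the generator does not emulate.

## Determinism and problem sizes

All stochastic components take explicit seeds (generator, fold assignment,
forest). Tie-breaks are fixed: model ranking by descending score then
lexicographic model id; DP traceback prefers matches; eigenvector signs are
fixed as above. The bundled study sizes (8 × 50 benchmarks, 25-model
replicates, 24 × 12 controls, protocol demos batched at 10 over 50-model
pools) keep the full suite and the acceptance run in the minutes range on
one CPU while leaving every statistical margin comfortable; all are plain
parameters and scale up freely.

## Known limitations

- No local (per-residue) quality estimates; fold-level classification only.
- The TM-score search and the local aligner are deterministic heuristics;
  global optimality is verified only against exhaustive oracles at small
  scale.
- The Pcons/PcombC/SAINT2-contact surrogates reproduce the *roles* of those
  scores (consensus, combination, contact potential), not their exact
  numerical definitions; PcombC weights are a package default, prominently
  configurable.
- Single-chain, Cβ-reduced PDB handling only: no mmCIF, insertion codes,
  hetero-atoms, or nucleic acids.
- B_eff uses simple identity clustering over ungapped columns; deep gappy
  alignments would need a more careful identity definition.
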