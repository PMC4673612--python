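# Methods

## Problem and model

Given an undirected protein–protein interaction (A, B), decide the
direction of signal flow: A→B, B→A, bidirectional, or undetermined. The
only per-protein information used is the set of Pfam domain accessions;
the working hypothesis is that regulatory directionality is carried by
combinations of domains — an upstream kinase-like domain acting on a
downstream substrate-like domain being the simplest case — and that these
combinations can be nonlinear (no single domain pair explains the
direction).

The encoding places both proteins of a pair in one vector over the training
domain vocabulary G, with component values {+1, −1, 2, 0} marking
"upstream-only", "downstream-only", "shared", "absent". Three consequences
matter:

1. **Asymmetry.** Reversing the orientation flips every ±1 and fixes 2/0,
   so the two orientations of one pair are distinct but deterministic
   mirrors of each other.
2. **Null vectors.** A pair in which either protein shares no domain with G
   carries no signal; it is removed and counted, never silently scored.
   This prunes prediction sets encoded against a foreign training
   vocabulary, and the drop count is part of every report.
3. **Presence, not multiplicity.** Domains are treated as sets; repeated
   domains in one protein do not change the encoding.

Training data consists of experimentally verified directions: each
encodable verified pair contributes its forward instance labeled +1 and its
reverse labeled −1, giving an exactly balanced two-class problem (hence
equal class weights, and the characteristic SP/SE symmetry across the two
labels in balanced reports). "Negative" means *not experimentally
verified*, not *verified absent*.

The classifier is a soft-margin SVM with RBF kernel
k(x, y) = exp(−γ‖x−y‖²), fit by libsvm (through scikit-learn's `SVC`,
tolerance 1e−3, shrinking on). Prediction re-evaluates the decision
function explicitly from the stored support vectors and dual coefficients,
which makes model files self-contained and serialization exact (round-trip
scores agree to better than 1e−9; in practice bit-exactly).

## Decision fusion and metrics

The two orientation scores are combined with a threshold ε (default 0.1,
printed by every evaluation command):

| case | rule |
|---|---|
| opposite signs | positive orientation wins |
| both ≥ 0 | gap > ε → larger score wins; else bidirectional (equal scores are bidirectional at any ε, including ε = 0) |
| both < 0 | magnitude gap > ε → smaller magnitude wins; else undetermined |

Exact zeros count as non-negative; the case split is measure-zero sensitive
only there. In the doubly-negative branch the comparison uses magnitudes
("amplitudes"): both orientations look unverified, and the less implausible
one is preferred only when the evidence gap is material.

Micro metrics treat each orientation instance independently: confusion
matrix at threshold 0, one-vs-rest SP/SE/MCC per label, trace accuracy,
binary MCC, positive-class F1, and Mann–Whitney ROC-AUC on the raw decision
values (ties count ½). Zero-denominator metrics report 0 and set a
`degenerate` flag rather than raising. The bag-level `macro_accuracy` is
the fraction of verified pairs whose fused call names *exactly* the true
orientation — bidirectional and undetermined count as wrong even when one
of their orientations is the verified one, a deliberately conservative
reading of "coincident rate". There is no theorem relating micro accuracy
and macro accuracy, but when every instance is on the correct side of zero
with margins clearing ε, macro accuracy is 1 by case analysis.

## Cross-validation design

Folds are formed over *pairs*, never instances: the pairs are shuffled with
the given seed and dealt round-robin into k folds (default k = 20), so both
orientations of a pair are always held out together. Two reasons:

* out-of-fold fusion needs both orientation scores of a pair from the same
  held-out model — splitting them makes the bag-level metric undefined;
* an instance's mirror is a deterministic transform of it, so instance-level
  splitting is leakage by construction.

Empirically, with this encoding the mirrored instances are geometrically
distant under the RBF metric (every ±1 flips), so the *measured*
instance-accuracy gap between grouped and instance-shuffled folds is small
(both designs agree to within ~0.01 on the synthetic benchmark; the
acceptance script reports both). The design argument, not the measured gap,
is why grouping is mandatory.

Hyperparameter search is nested: each outer training split runs its own
inner pair-grouped CV (default 5-fold) over the (C, γ) grid, maximizing
inner instance accuracy, ties broken toward smaller C then smaller γ. The
package-wide default grids are the coarse LIBSVM-style powers of two
C ∈ {2⁻⁵, 2⁻¹, 2³, 2⁷, 2¹¹, 2¹⁵}, γ ∈ {2⁻¹⁵, 2⁻¹¹, 2⁻⁷, 2⁻³, 2¹}.
The vocabulary is built once from the full training corpus (as when a
database release is encoded as a whole), not per fold.

## Synthetic worlds

The generator emulates the three inputs — a domain universe, proteins as
domain sets, directed training pairs — with a planted direction law, so the
pipeline can be validated end to end without external downloads.

Proteins draw a uniform background of 0–4 domains; designated signal
domains are included independently with configured probabilities. Candidate
unordered pairs are sampled without replacement (at most 10× the requested
pair count, failing loudly if the rule set cannot yield enough directed
pairs). An orientation matches a rule when the putative upstream protein
carries all required (and no forbidden) upstream domains and likewise
downstream; the highest-priority matching rule fixes the direction, with a
coin flip deciding which orientation is tested first. Candidates matching
no rule carry no direction; candidates matching in **both** orientations
are ambiguous under the law. Both kinds are discarded and counted — an
ambiguous pair given a coin-flipped label would inject irreducible label
noise into nominally noise-free conditions. Label noise is then explicit:
the recorded direction flips with probability `noise`, while the truth
table keeps the pre-noise direction.

Two presets define the benchmark conditions used by the tests and the
acceptance script:

* **single_rule_world** — one linear law (upstream carries the kinase-like
  domain, downstream the substrate-like domain), 22 domains, 250 proteins,
  2–4 background domains per protein, signal domains in 45% of proteins,
  400 pairs. Any per-domain statistic separates the directions; the
  pipeline should recover essentially all of them at zero noise.
* **nonlinear_world** — direction decided by an odd-parity combination of
  two up-regulating domains (on the upstream side) and one down-regulated
  domain (on the downstream side), expressed as four mutually exclusive
  conjunctive branches; one branch is the textbook pattern "both
  up-regulating domains upstream and the down-regulated domain
  downstream". Parity makes every single-domain marginal *exactly*
  balanced between the upstream and downstream side in population (at 400
  sampled pairs the empirical difference has sd ≈ 0.035, so tests bound it
  at 0.1 ≈ 3σ), which is what defeats per-domain-frequency classifiers.
  12 domains, 300 proteins, 0–2 background domains, signal domains in half
  the proteins, 400 pairs, 5% label noise. The background is kept sparse
  deliberately: domain annotations are sparse in reality, and the planted
  law must remain recoverable from 400 pairs for the benchmark to measure
  the classifier rather than the curse of dimensionality.

The baseline against which the nonlinear claim is made
(`single_domain_baseline`) learns per-domain upstream/downstream odds from
the training folds and fuses them by majority vote over the domains in the
pair's symmetric difference (shared domains cancel; unseen domains abstain;
add-one smoothing; ties are undetermined). On the linear world it is
clearly above chance but far from perfect — background domains cast
random-sign votes — and on the parity world it is at or below chance by
construction.

What the worlds do **not** emulate: heavy-tailed Pfam domain frequencies
(uniform background for now; a power-law option is a natural extension),
pathway topology (receptor→TF chains, feedback), cross-talk between rules,
and homology structure between proteins. Passing these benchmarks
demonstrates that the pipeline recovers planted domain-combination laws
under label noise and null filtering — not that real interactomes satisfy
those laws.

## Study conditions behind the reported numbers

All quantities in `scripts/acceptance.py` (and the heavier tests) are
computed at desk scale, chosen as the smallest sizes at which the measured
properties are stable:

* linear recovery: single_rule_world, 400 pairs, noise 0, 20-fold grouped
  CV, compact grid C ∈ {2⁻¹, 2³, 2⁷} × γ ∈ {2⁻³, 2⁻¹, 2¹};
* nonlinear recovery: nonlinear_world, 400 pairs, noise 0.05, 5-fold CV,
  same grid, baseline on identical folds;
* noise sweep: 200 pairs, noise ∈ {0, 0.1, 0.2, 0.3}, 5 worlds per level,
  fixed (C, γ) = (2³, 2⁻¹), 5-fold CV;
* grouped-vs-ungrouped comparison: 400 pairs, noise 0.2, 5 worlds × 3 fold
  assignments, fixed (C, γ) = (2³, 2⁻¹), paired design;
* determinism: identical double runs of world generation, training and
  prediction output.

## Numerical and degenerate-input conventions

* Solver tolerance 1e−3, recorded in the model file; no probability
  calibration (scores are margins, not probabilities).
* Grid-search ties: smaller C, then smaller γ.
* Instance-classification threshold fixed at 0.
* Empty vocabulary, single-class training data, zero encodable pairs,
  NaN scores, fingerprint mismatches and train/test overlap are all fatal
  errors, not warnings.
* Duplicate directed records and self-pairs are rejected at parse time with
  line numbers; duplicate protein annotation lines merge only when
  identical.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; repeated runs are byte-identical.

## Known limitations

* Domain annotations are taken as given; proteins without annotations are
  (correctly) unpredictable and are dropped as null vectors.
* A single model is trained across interaction types; type tags are carried
  through but unused.
* The overall MCC of a balanced two-label design equals each per-label MCC;
  reports therefore show three numerically close MCC values rather than
  independent evidence.
* ε is a free parameter; 0.1 gives a non-degenerate mix of call types on
  the synthetic benchmark, but real applications should sweep it against
  the fraction of bidirectional/undetermined calls they can tolerate.
* Identifier normalization (isoform collapsing, UniProt mapping) is the
  caller's responsibility.
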