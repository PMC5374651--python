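# Methods

## Interaction-profile features

A docked pose is reduced to per-contact records; a profile cell is the **sum**
of contact energies mapping to one (compound, feature) pair. Summation is the
natural aggregate for pairwise-additive docking potentials, and it makes
aggregation permutation-invariant and additive over record lists (both are
tested properties). Absent contacts are exactly 0.0 — profiles are dense
matrices with sparse nonzeros, never missing values.

Feature identifiers are canonical strings: residue-based
`RES:PART:TYPE` (part ordered M before S, types E, H, V) and atom-based
`ATOM:TYPE`. The caller supplies the residue/atom lists; the package does not
detect binding sites, so the column schema is fixed by those lists alone
(86 residues always yield 516 residue-based columns). Matrices are written as
TSV with 17 significant digits, which round-trips IEEE doubles bit-exactly
(reading uses pandas' round-trip float parser).

Zero-variance columns are retained in the matrix (the schema is part of the
model contract) but excluded from the GA's selectable pool.

## Evaluation metrics

* q² = 1 − Σ(yᵢ − ŷᵢ)²/Σ(yᵢ − ȳ)² over leave-one-out predictions; ≤ 1, can be
  negative; undefined (rejected) for constant y.
* SDEP = √(Σ(yᵢ − ŷᵢ)²/N) with the **population** N denominator, so
  q² = 1 − N·SDEP²/SS_tot holds exactly (asserted to 1e−10).
* r² on held-out data is the **squared Pearson correlation** by default; an
  SS-ratio variant (`r2_ss`) is provided because the two differ whenever the
  predictions are miscalibrated in scale or offset. Pearson² is the default
  because it is the standard test-set statistic in feature-selection QSAR.

Leave-one-out folds run in row order with no shuffling; a fold's model is
fitted strictly on the other n−1 rows (a leak-detecting stub enforces this in
the test suite).

## Regressors

**PLS** is PLS1 via NIPALS with mean centering and *no* unit-variance
scaling by default — interaction energies share units, and autoscaling would
inflate near-constant columns; scaling remains available upstream by
standardising the matrix. With univariate y each NIPALS component is a
closed-form step, so fits are deterministic to the bit. At lv = rank the fit
equals OLS (tested against `numpy.linalg.lstsq` and against scikit-learn's
PLS implementation as an independent reference). Component extraction stops
early if the residual matrix runs out of rank.

**Mahalanobis machinery.** The significance of feature i is
Mᵢ = √((vᵢ − μ)′Σ⁻¹(vᵢ − μ)) where vᵢ is the feature's column over
compounds, and μ, Σ are estimated **across the feature population**. This
reading — features as observations in compound space — is the one that
"discriminates significant features": a feature whose interaction pattern
deviates from the bulk of features scores high. The dimensional roles could
also be read per-compound; that alternative is available as
`feature_significance(..., compound_space=True)` but is not the default and
no fidelity claim is made for it. Because Σ of hundreds of features in a
small-n compound space is singular, Σ is shrunk:
Σ_reg = Σ + λI, λ = 1e−6·trace(Σ)/dim by default (λ falls back to the raw
shrinkage constant when Σ is exactly zero, which correctly yields zero
distances). As shrinkage → ∞ the Mahalanobis ordering converges to the
Euclidean ordering (tested). The selection threshold is applied to the
distance M (not M²), default 10, configurable.

**kNN** predicts the unweighted mean activity of the k nearest training
compounds under Mahalanobis distance in the selected-feature subspace, the
scorer being fitted on the training compounds of each fold. Ties at the k-th
distance break by training row order (stable sort). Unweighted averaging is
the simplest defensible choice; distance weighting is deliberately out of
scope.

## GA feature selection

A chromosome is an explicit feature-index set plus one hyperparameter (lv or
k). Explicit sets with size bounds (default 3–40) prevent the degenerate
all-features solution that bitstring encodings drift toward on small n.
Hyperparameter bounds: lv ∈ 1..min(10, |features|, n−2), k ∈ 1..min(10, n−2);
the n−2 cap keeps every LOO fold valid.

Defaults: population 50, generations 100, crossover 0.8, mutation 0.1,
elitism 1, tournament size 2. Crossover is a uniform set-crossover (shared
features kept, symmetric difference split at random, hyperparameters swapped
with probability ½, children repaired to the size bounds). Mutation fires a
binomial number of add/remove events; additions draw features with
probability ∝ max(Mᵢ, ε) restricted to above-threshold features when any are
unselected, else uniformly. The same bias applies to both GEMPLS and GEMkNN
(switchable via `biased_mutation`). Fitness (LOO q²) is memoised per
(feature set, hyperparameter); any fold failure scores −∞ so unfit
chromosomes lose selection naturally. Elitism makes the best-per-generation
trajectory non-decreasing, and a fixed config seed makes runs bit-identical.

Ensemble seed policy: run r uses base_seed + r, recorded in every model
record together with a config digest.

## Consensus rule

Counts Nᵢ are pooled over all runs of both methods (per-method pooling via
the API). μ and σ are **population** statistics computed, by default, over
the *ever-selected* features only: with hundreds of never-selected features
the all-features scope drives μ − σ below zero and the rule would keep every
feature that was ever selected anyway, defeating the intended feature
reduction. The `all_features` scope is retained for comparison; candidates
additionally require Nᵢ ≥ 1 in both scopes. Final models re-run the same GA
restricted to candidate columns; the returned feature set is asserted to be
a subset of the candidates.

## Skeleton partitioning

"Shared scaffold" is computed as the maximum common substructure (rdkit
rdFMCS): element-matched, bond-order-matched, ring bonds only matching ring
bonds, complete rings required, 60 s timeout. If no MCS of ≥ 3 atoms spans
every compound, the search retries leaving out one compound at a time and
keeps the largest result (single-outlier tolerance); a skeleton is accepted
only when ≥ 50% of compounds match it, and non-matching compounds are
labelled all-specific. MCS is an implementation choice for "compound
structure alignment" — scaffold groups drawn by a chemist may differ.

Feature attribution works on the **raw records** (aggregation erases ligand
-atom identity): a feature is `common` when every contributing ligand atom is
a scaffold atom, `specific` when none is, `mixed` otherwise. Features with no
contributing records touch no scaffold atom and are classed `specific`
(harmless: such columns are all-zero and unselectable anyway). The default
filter keeps only `specific` features — the conservative reading of
"discarding common-skeleton features" — with `keep_mixed` available.

## Synthetic data

The generator emulates the statistical shape of docking-derived profiles,
not the physics: each (compound, residue, part, type) slot receives a
contact with probability 1 − sparsity (default 0.1), energy −|N(2, 1)|;
activity is y = 7 + Σβⱼ(xⱼ − x̄ⱼ) + N(0, noise_sd²) on a pIC50-like scale,
with |βⱼ| ~ U(0.5, 1.5), over 5 informative columns by default. Default
conditions (40 compounds, 86 residues → 516 features, noise 0.3) give an
oracle OLS model on the true columns a LOO q² ≈ 0.95, recorded in the
truth sidecar at generation time. Not emulated: docking geometry, spatial
correlation between neighbouring residues, pose errors, activity cliffs —
so green tests show the machinery recovers a planted linear signal under
realistic sparsity and dimensionality, not that it models any particular
protein system.

The structure fixture is a fixed phenyl-alkyl series (benzylamine through
4-phenylbutylamine plus 2-phenylethanol) whose MCS is the benzene ring plus
the benzylic carbon; each member has exactly one ring-attached carbon so the
substructure match — and hence the recorded truth labels — is unambiguous.
The companion skeleton dataset routes substituent-atom contacts into a
dedicated subsite residue that scaffold atoms never touch, mirroring the
binding picture the partition is meant to exploit and guaranteeing the
specific-feature filter is non-empty.

## Problem sizes

Statistical conclusions in the test suite use the default planted-signal
conditions (n = 40, 516 features, 5 informative). The GA ensembles behind
them use population 20 × 15 generations and 6–30 runs per experiment —
deliberately smaller than the library defaults, since the planted signal is
strong enough that the tested properties (recovery above the null rate,
variance reduction under consensus restriction, final ≥ mean preliminary q²)
are already decisive at that scale; the full suite runs in a few minutes on
one CPU. The shipped default pipeline configuration mirrors those sizes.

## Known limitations

* Feature significance depends on the chosen reading of the quadratic form
  (see above); both readings are exposed, one is default.
* The MCS outlier fallback is leave-one-out and therefore tolerates a single
  non-matching compound class, not several.
* kNN's LOO fitness refits the covariance per fold, which is exact but makes
  GEMkNN the slower of the two methods.
* No y-scrambling or k-fold validation; LOO only.
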