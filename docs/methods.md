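# Methods

## Endpoint and class definition

The modeled endpoint is logPS, the log permeability–surface-area product
(mL·s⁻¹·g⁻¹) from in-situ rat brain perfusion. Class assignment uses two
closed cutoffs: logPS ≥ −2 → CNSp+ (strong permeant), logPS ≤ −3 → CNSp−
(weak permeant). Because logPS is continuous, the exempt band is treated
as the open interval (−3, −2); records without logPS are "unlabeled" and
excluded from learning. Classification uses only the CNSp+/CNSp− subset.

## Structure standardization

Salts are reduced to the largest organic fragment (most heavy atoms, ties
by molecular weight — the source protocol says only that counterions were
removed), then neutralized where chemically possible, with stereochemistry
preserved in the canonical SMILES. Fully inorganic records are rejected
rather than silently dropped; every unparseable row lands in a rejects
report carried by the dataset.

## Descriptors

The model descriptor set is the one the published trees actually split on.

* **aLogP** — atomic-contribution (Crippen-type) octanol/water logP. The
  original study used an early CDK implementation of the Ghose–Crippen
  scheme whose absolute values differ substantially from modern
  parameterizations; this package uses RDKit's Crippen contributions.
  Consequences: the published aLogP thresholds (−1.0028) are meaningful
  only for descriptor rows on the original scale (as in the published
  worked examples), and this package's computed aLogP values should not be
  routed through the published rules. Trees induced on self-consistent
  descriptor matrices are unaffected.
* **tPSA** — Ertl fragment-additive topological polar surface area (Å²),
  N/O contributions (S/P optional by flag).
* **fPSA3** — CPSA family: Σ(qᵢ·SAᵢ) over atoms with positive Gasteiger
  charge divided by total solvent-accessible surface area. Charges:
  Gasteiger–Marsili, 75 iterations. Surface: Shrake–Rupley with a
  deterministic golden-spiral lattice of 960 points per atom, vdW radii
  inflated by a 1.4 Å water probe. Conformer: lowest-MMFF-energy of 10
  seeded distance-geometry embeddings. The charge/surface scheme is a
  package choice (the source never states one); both worked-example
  values reproduce within a few percent, well inside the ±50 % tolerance
  appropriate for conformer-dependent quantities.
* **Rotatable bonds** — single, non-ring bonds between non-terminal heavy
  atoms; amide C–N excluded by default (toggleable).
* **H-bond acceptors** — N or O, not positively charged, excluding
  pyrrole-type aromatic N and amide N.
* **BCUTS** — eigenvalues of the Burden connectivity matrix over heavy
  atoms: atomic mass on the diagonal, 0.1 × bond order off-diagonal
  (+0.01 for terminal bonds, 0.001 for non-bonded pairs). The published
  worked-example values (11.9962 for sucrose, 11.9974 for midazolam)
  identify the descriptor as the **lowest** eigenvalue — the highest
  eigenvalue of those molecules is ≈16 and ≈35.5 — so the model
  descriptor `BCUTS` is the lowest eigenvalue; `calc_bcut_high` is also
  exposed. Disconnected inputs are handled per connected component, so
  the extreme over fragments is exact.
* **MW** — monoisotopic mass (the printed worked-example masses match
  monoisotopic, not average, masses).

Descriptor failures become missing values with per-compound reasons in a
report, never zeros; a descriptor failing on >10 % of compounds raises a
manifest warning. Rows missing a used descriptor are excluded per tree.

## Tree induction

**CART** grows binary splits: candidate thresholds are midpoints of
consecutive sorted unique values; the attribute/threshold pair maximizing
the Gini impurity decrease wins, with ties broken to the lexicographically
first attribute and then the lowest threshold. No cost-complexity pruning:
stopping is purely by the protocol parameters (depth ≤ 5, parent ≥ 10,
child ≥ 5).

**CHAID** quantile-bins each continuous attribute into ≤ 10 bins **from
the rows at the node under analysis**, then iteratively merges the
adjacent bin pair with the largest pairwise χ² p-value while that p
exceeds `alpha_merge` (0.05). Undersized groups are force-merged into
their most similar neighbour so every child has ≥ 5 instances. The split
attribute is the one with the smallest Bonferroni-adjusted p-value of the
r×2 table (multiplier C(c−1, r−1), the number of ways r contiguous groups
can arise from c ordered categories); the node splits only if the adjusted
p ≤ `alpha_split` (0.05), depth < 3, and node size ≥ 10. Node-local
binning is a deliberate choice: the protocol source does not state a
binning schedule, and re-binning at each node lets deep nodes place
boundaries (e.g. near tPSA ≈ 150 Å²) that root-level deciles of the full
mixture cannot express. Leaf ties predict CNSp− (conservative:
non-penetration).

Both inducers are deterministic functions of (X, y, params). Trees
serialize to a JSON document that round-trips byte-identically and is
validated on load (child counts must sum to the parent); DOT export is
provided for figures.

The **published rule classifier** hard-codes every threshold the source
text prints and nothing else: branches whose thresholds appear only in
figures are explicit "unspecified" leaves that raise on routing rather
than guess. The CART low/high-aLogP boundary is not printed; the one
printed aLogP threshold is reused, which cannot change the worked-example
routing (any boundary between −4.31 and 0.41 gives the same result).

## Evaluation

CCR is the balanced accuracy (TP/N₁ + TN/N₀)/2 — the standard two-class
corrected classification rate consistent with the protocol's symbol
definitions. MCC uses the usual 2×2 product form, 0 by convention when a
marginal is empty. ROC curves sweep the unique scores descending with
ties grouped; AUC is the trapezoidal area (equal to the Mann–Whitney
concordant-pair probability, verified against a pair-counting oracle);
the operating cutoff maximizes Youden's J = TPR − FPR, ties resolved to
the lower (more sensitive) threshold.

Cross-validation is 10-fold, stratified by class (the protocol says only
"randomly divided"; stratification stabilizes a 120-compound dataset — a
non-stratified mode exists). Every instance is tested exactly once.
Reported performance is the mean over fold CCR/MCC (the protocol's
"average risk" reading); pooled-count metrics are emitted alongside. A
training partition that loses a class triggers re-randomization under a
derived seed, logged in the result.

## ACO fingerprint selection

Fingerprints are the public 166-key MACCS SMARTS table (RDKit dialect;
older toolkit dialects differ in a handful of keys, so cross-dialect
similarity benchmarks carry tolerance). The subset classifier is
transparent: each selected bit gets the Haldane-corrected log-odds of its
prevalence in CNSp+ vs CNSp−; a molecule's score is the sum of weights
over its set bits; classification compares the score with the Youden
cutoff of the score ROC.

Fitness is the **cross-validated** AUC of those scores: weights are fitted
per training partition and applied to the held-out fold, and the pooled
held-out scores give the ROC. Ant construction uses the
pseudo-random-proportional rule on pheromone × heuristic desirability
(η = |full-data log-odds| + 0.1, the floor keeping every bit reachable):
with probability 0.9 the ant exploits (argmax, random tie-break),
otherwise roulette. Subset sizes are drawn uniformly in [3, 15], covering
the nine-key published solution. Pheromone evaporates by factor 0.9 per
iteration and the iteration-best subset is reinforced proportionally to
its fitness; the global best is retained, so the best-fitness trace is
monotone. Defaults: 50 ants × 100 iterations.

Because the search maximizes a CV estimate computed on the full dataset,
the best subset's own CV AUC is still optimistically biased (feature
selection outside the folds). The unbiased figure is `nested_cv_auc`,
which repeats the entire search inside each training partition and scores
only held-out rows: on label-permuted data it concentrates at 0.5, and it
is the quantity used for the no-signal control.

## Synthetic study conditions

The generator reproduces the study table's statistical structure: 153
compounds, 65 CNSp+ / 55 CNSp− / 33 exempt; descriptor marginals inside
the published ranges (MW 46–1201 Da drawn log-uniform, aLogP −4.3–2.4,
tPSA 3.2–279 Å², rotatable bonds 0–18, H-bond acceptors 1–23; fPSA3 and
BCUTS bracket typical drug values). The planted rule echoes the published
thresholds — aLogP > −1 ∧ tPSA < 150 ∧ acceptors < 4 ⇒ permeant — so
end-to-end runs produce trees readable against the published ones. CNSp+
rows draw descriptors on the permeant side, CNSp− rows on the other, each
flipped with probability ε = 0.05 (label noise); exempt rows land on
either side with equal probability. logPS is drawn inside per-class
intervals (CNSp+ [−2, 0], CNSp− [−5, −3], exempt [−2.9, −2.1]), a direct
implementation of rank-matching calibration: the −2/−3 cutoffs recover
the class counts exactly, and with ε = 0 the rule and labels agree on
every non-exempt row. The analytic CCR ceiling of the Bayes classifier is
therefore 1 − ε = 0.95.

Fingerprint data plants the nine published MACCS keys as informative bits
(set probability 0.65 in CNSp+ vs 0.25 in CNSp−, a 0.4 gap echoing the
nine-key solution); the remaining 157 bits are class-independent at 0.25,
putting mean darkness near 43, typical of drug-like MACCS fingerprints.
The Bayes-optimal AUC over the informative bits (0.961 at defaults) is
computed exactly by enumerating all 2⁹ patterns.

What the generator does **not** emulate: real chemistry (synthetic rows
have no structures, so descriptor correlations such as the MW–rotatable-
bond relationship are absent), measurement error structure in logPS, and
fingerprint bit–bit correlations from shared substructures. Passing tests
therefore demonstrate algorithmic correctness and statistical behavior
under the study's sampling conditions, not predictive performance on new
chemistry.

## Problem sizes and numerical choices

Tree benchmarks average 20 generator seeds (20 × 120 compounds × 2
paradigms × 10 folds); ACO benchmarks use full default colonies for
recovery and 20-ant × 30-iteration colonies inside the nested no-signal
control, whose estimate is unbiased regardless of search intensity.
Tolerances: exact-arithmetic quantities are checked to printed precision;
engine-dependent descriptors carry the per-descriptor tolerances stated in
their tests; conformer-dependent fPSA3 allows ±50 % relative. All
stochastic stages consume explicit integer seeds and are bit-reproducible.

## Known limitations

* aLogP absolute scale differs from the original CDK-era implementation
  (see above); published aLogP thresholds apply only to original-scale
  inputs.
* CHAID follows the published algorithm description, not any specific
  statistical package's undocumented merge/adjustment details.
* The exempt band's middle class is excluded from learning, as in the
  protocol; the package does not model three-class discrimination.
* ACO subset quality is reported both as search-internal CV fitness
  (optimistic) and nested CV (unbiased); only the latter should be quoted
  as generalization performance.
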