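# bbbperm — decision-tree models of blood-brain-barrier permeability

`bbbperm` classifies small molecules as strong (CNSp+) or weak (CNSp−)
blood-brain-barrier permeants from the in-situ brain-perfusion endpoint
logPS — the log of the permeability–surface-area product (mL·s⁻¹·g⁻¹).
Compounds with logPS ≥ −2 are labeled CNSp+, logPS ≤ −3 CNSp−, and values
strictly in between are exempt from classification learning. It is written
for cheminformaticians and DMPK modelers who want interpretable, fully
reproducible permeability models rather than black-box scores.

The package covers the whole modeling workflow:

* **Curation** — compound tables (CSV/SDF/SMILES), counterion stripping,
  stereo-preserving canonicalization, logPS class assignment.
* **Descriptors** — atomic-contribution logP (aLogP), Ertl topological
  polar surface area (tPSA), the CPSA-family ratio fPSA3 (charge-weighted
  partial positive surface area / total solvent-accessible area, from a
  seeded lowest-energy MMFF conformer and Gasteiger charges),
  rotatable-bond count, H-bond-acceptor count, the lowest eigenvalue of
  the mass-weighted Burden connectivity matrix (BCUTS), and monoisotopic
  mass.
* **Trees** — CHAID (quantile binning, adjacent-category merging by
  pairwise χ², splits by smallest Bonferroni-adjusted χ² p-value) and CART
  (binary Gini-gain splits over midpoint thresholds), grown to depth 3 and
  5 with ≥10 parent / ≥5 child instances, plus the published decision
  rules (aLogP < −1.0028 ⇒ CNSp−; <4 H-bond acceptors favoring CNSp+;
  BCUTS > 11.9 in the low-aLogP branch ⇒ CNSp−; tPSA < 150 Å² in the
  high-aLogP branch ⇒ CNSp+) as a hard-coded classifier.
* **Evaluation** — stratified 10-fold cross-validation scored by the
  corrected classification rate CCR = (TP/N₁ + TN/N₀)/2 and the Matthews
  correlation coefficient, plus ROC curves with the Youden-J cutoff.
* **Fingerprints & ACO** — 166-bit MACCS keys, Tanimoto similarity, and an
  ant-colony optimizer that selects the bit subset whose log-odds-weighted
  score best separates the classes (fitness = cross-validated AUC).
* **Synthetic data** — a calibrated generator reproducing the study
  conditions (153 compounds, 65/55/33 class split, published descriptor
  ranges, a planted descriptor rule with 5 % label noise, and nine
  informative fingerprint bits), so the full pipeline runs end-to-end
  without the original measurements.

## Worked example

```python
from bbbperm import published_rule_classifier, predict_class
from bbbperm.descriptors import calc_molecular_weight, calc_rotatable_bonds

sucrose_row = {"aLogP": -4.3105, "tPSA": 189.53, "fPSA3": 0.072136,
               "rotBonds": 5, "BCUTS": 11.9962, "hBondAcceptors": 11}
midazolam_row = {"aLogP": 0.4073, "tPSA": 27.96, "fPSA3": 0.033577,
                 "rotBonds": 1, "BCUTS": 11.9974, "hBondAcceptors": 3}

chaid = published_rule_classifier("CHAID")
print(predict_class(chaid, sucrose_row))    # 0  -> CNSp-
print(predict_class(chaid, midazolam_row))  # 1  -> CNSp+
print(round(calc_molecular_weight("OC[C@H]1O[C@@](CO)(O[C@@H]2O[C@H](CO)"
      "[C@@H](O)[C@H](O)[C@H]2O)[C@@H](O)[C@@H]1O"), 2))  # 342.12 Da
```

Sucrose, a small hydrophilic sugar, is rejected at the root (aLogP below
−1.0028); midazolam, a CNS-active benzodiazepine, passes the lipophilicity
gate and its three H-bond acceptors (< 4) classify it CNSp+. The same two
molecules route to CNSp−/CNSp+ under the CART rules.

The numbered drivers under `analysis/` run the full study on the synthetic
conditions and write their tables under `results/`:

```text
$ python analysis/02_train_trees.py
CHAID: CV CCR 90.5% (ceiling 95%), MCC 0.824
CART: CV CCR 90.2% (ceiling 95%), MCC 0.817

$ python analysis/04_aco_fingerprints.py
selected bits: [23, 36, 54, 60, 82, 115, 122, 130, 134, 139, 140, 145, 150, 156, ...]
planted bits recovered: 9/9 [23, 36, 60, 82, 122, 130, 145, 150, 156]
CV AUC 0.975 (Bayes ceiling 0.961), CCR 91.3%, MCC 0.833
label-permuted nested-CV AUC 0.430 (chance control)
```

The cross-validated CCR sits a few points under the 95 % ceiling implied by
the generator's 5 % label noise — the residual gap is the finite-sample
price of depth/size-limited trees — and the colony recovers all nine
planted MACCS keys while the permuted-label control stays at chance.

There is also a thin CLI over the same functions
(`bbbperm simulate | curate | describe | train | predict | aco`).

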