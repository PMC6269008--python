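"""Synthetic datasets with the statistical structure of the study table.

The real endpoint table (153 rats-derived logPS measurements: 65 CNSp+,
55 CNSp-, 33 exempt) is not redistributable here, so every pipeline stage
is exercised on generated data that reproduces its class proportions, the
published descriptor ranges, and a planted descriptor->class rule echoing
the published tree thresholds (aLogP > -1, tPSA < 150 A^2, fewer than four
H-bond acceptors => permeant). Fingerprint data plants a configurable set
of informative MACCS bits with class-conditional set-probabilities.

Generators are pure functions of their spec (including its seed).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset_io import PermClass
from .dti import CLASS_NEG, CLASS_POS

#: Published descriptor ranges of the classification dataset (n = 120).
DEFAULT_DESCRIPTOR_RANGES: dict[str, tuple[float, float]] = {
    "MW": (46.0, 1201.0),          # Da, drawn log-uniform
    "aLogP": (-4.3, 2.4),
    "tPSA": (3.2, 279.0),          # A^2
    "rotBonds": (0, 18),           # integer
    "hBondAcceptors": (1, 23),     # integer
    "fPSA3": (0.0, 0.30),          # ratio; range chosen to bracket typical drugs
    "BCUTS": (10.5, 16.0),         # lowest Burden eigenvalue, heavy atoms C..S
}

#: The nine MACCS keys of the published ACO solution, reused as the default
#: planted informative bits.
DEFAULT_INFORMATIVE_BITS = (23, 36, 60, 82, 122, 130, 145, 150, 156)

# logPS intervals per class; the -2/-3 cutoffs then reproduce the class
# counts exactly (rank-matching calibration).
_LOGPS_INTERVALS = {
    PermClass.CNSP_POS: (-2.0, 0.0),
    PermClass.CNSP_NEG: (-5.0, -3.0),
    PermClass.EXEMPT: (-2.9, -2.1),
}


def default_planted_rule(row: dict[str, float]) -> bool:
    """True iff the row's descriptors satisfy the permeant rule."""
    return (
        row["aLogP"] > -1.0
        and row["tPSA"] < 150.0
        and row["hBondAcceptors"] < 4
    )


@dataclass
class SyntheticSpec:
    """Study conditions for the generators.

    ``class_counts`` is (CNSp+, CNSp-, exempt); ``label_noise`` is the
    probability that a non-exempt row's descriptors contradict its class
    (the planted rule is violated for a permeant or satisfied for a
    non-permeant).
    """

    n_total: int = 153
    class_counts: tuple[int, int, int] = (65, 55, 33)
    descriptor_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_DESCRIPTOR_RANGES)
    )
    label_noise: float = 0.05
    informative_bits: tuple[int, ...] = DEFAULT_INFORMATIVE_BITS
    p_bit_pos: float = 0.65
    p_bit_neg: float = 0.25
    background_bit_prob: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.class_counts) != self.n_total:
            raise ValueError(
                f"class counts {self.class_counts} do not sum to n_total {self.n_total}"
            )
        if not 0.0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must be in [0, 0.5)")
        for name, (lo, hi) in self.descriptor_ranges.items():
            if not lo < hi:
                raise ValueError(f"empty range for descriptor {name}")
        if not all(1 <= b <= 166 for b in self.informative_bits):
            raise ValueError("informative bits must be MACCS indices 1..166")


def _draw_descriptor(rng: np.random.Generator, name: str, lo: float, hi: float) -> float:
    if name == "MW":  # spans 1.4 orders of magnitude; log-uniform is realistic
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    if name in ("rotBonds", "hBondAcceptors"):
        return int(rng.integers(int(lo), int(hi) + 1))
    return float(rng.uniform(lo, hi))


def _draw_row(rng: np.random.Generator, spec: SyntheticSpec, rule_true: bool) -> dict[str, float]:
    """One descriptor row conditioned on the planted-rule side."""
    ranges = spec.descriptor_ranges
    for _ in range(1000):
        row = {k: _draw_descriptor(rng, k, lo, hi) for k, (lo, hi) in ranges.items()}
        if rule_true:
            # restrict the rule descriptors into the permeant region
            row["aLogP"] = float(rng.uniform(max(-1.0, ranges["aLogP"][0]) + 1e-9,
                                             ranges["aLogP"][1]))
            row["tPSA"] = float(rng.uniform(ranges["tPSA"][0],
                                            min(150.0, ranges["tPSA"][1]) - 1e-9))
            row["hBondAcceptors"] = int(rng.integers(max(1, int(ranges["hBondAcceptors"][0])), 4))
            return row
        if not default_planted_rule(row):
            return row
    raise RuntimeError("could not draw a rule-violating row; widen the ranges")


def generate_descriptor_dataset(
    spec: SyntheticSpec,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """(descriptor table, logPS values, class labels) under the spec.

    Classes are assigned first (exactly the spec's counts); descriptors are
    drawn on the planted rule's permeant side for CNSp+ rows and on the
    non-permeant side for CNSp- rows, each flipped with probability
    ``label_noise``; exempt rows land on either side with equal probability.
    logPS is drawn inside each class's interval, so applying the -2/-3
    cutoffs reproduces the class counts exactly.
    """
    rng = np.random.default_rng(spec.seed)
    n_pos, n_neg, n_ex = spec.class_counts
    classes = np.array(
        [PermClass.CNSP_POS] * n_pos
        + [PermClass.CNSP_NEG] * n_neg
        + [PermClass.EXEMPT] * n_ex
    )
    rng.shuffle(classes)
    rows, logps = [], []
    for cls in classes:
        if cls is PermClass.EXEMPT:
            rule_true = bool(rng.random() < 0.5)
        else:
            rule_true = cls is PermClass.CNSP_POS
            if rng.random() < spec.label_noise:
                rule_true = not rule_true
        rows.append(_draw_row(rng, spec, rule_true))
        lo, hi = _LOGPS_INTERVALS[cls]
        logps.append(float(rng.uniform(lo, hi)))
    ids = [f"syn{i:03d}" for i in range(1, spec.n_total + 1)]
    X = pd.DataFrame(rows, index=pd.Index(ids, name="id"))
    return (
        X,
        pd.Series(logps, index=X.index, name="logps"),
        pd.Series(classes, index=X.index, name="perm_class"),
    )


def classification_arrays(
    X: pd.DataFrame, labels: pd.Series
) -> tuple[pd.DataFrame, np.ndarray]:
    """Restrict to the CNSp+/CNSp- subset and encode labels 1/0."""
    mask = labels.isin([PermClass.CNSP_POS, PermClass.CNSP_NEG]).to_numpy()
    y = np.where(
        labels.to_numpy()[mask] == PermClass.CNSP_POS, CLASS_POS, CLASS_NEG
    )
    return X.loc[mask], y


def analytic_ccr_ceiling(spec: SyntheticSpec) -> float:
    """Expected CCR of the Bayes-optimal (planted-rule) classifier.

    Each non-exempt row contradicts its class with probability
    ``label_noise``, independently per class, so sensitivity and specificity
    of the true rule are both 1 - label_noise.
    """
    return 1.0 - spec.label_noise


def generate_fingerprint_dataset(
    spec: SyntheticSpec,
) -> tuple[np.ndarray, np.ndarray]:
    """(n x 166 bit matrix, labels) for the CNSp+/CNSp- subset.

    Informative bits are Bernoulli with class-specific probabilities
    (``p_bit_pos`` vs ``p_bit_neg``); all other bits are class-independent
    with ``background_bit_prob``, putting the expected darkness near the
    40-50 typical of drug-like MACCS fingerprints.
    """
    rng = np.random.default_rng(spec.seed)
    n_pos, n_neg, _ = spec.class_counts
    n = n_pos + n_neg
    y = np.array([CLASS_POS] * n_pos + [CLASS_NEG] * n_neg)
    rng.shuffle(y)
    X = (rng.random((n, 166)) < spec.background_bit_prob).astype(np.uint8)
    for bit in spec.informative_bits:
        p = np.where(y == CLASS_POS, spec.p_bit_pos, spec.p_bit_neg)
        X[:, bit - 1] = (rng.random(n) < p).astype(np.uint8)
    return X, y


def bayes_fingerprint_auc(spec: SyntheticSpec) -> float:
    """Exact AUC of the Bayes-optimal classifier on the informative bits.

    Enumerates all 2^k informative-bit patterns, scores each by its
    log-likelihood ratio, and sums P+(a) P-(b) over pattern pairs (ties
    counted half). Background bits carry no signal and do not enter.
    """
    k = len(spec.informative_bits)
    pp, pn = spec.p_bit_pos, spec.p_bit_neg
    patterns = np.array(list(itertools.product((0, 1), repeat=k)))
    prob_pos = np.prod(np.where(patterns == 1, pp, 1 - pp), axis=1)
    prob_neg = np.prod(np.where(patterns == 1, pn, 1 - pn), axis=1)
    llr = patterns.sum(axis=1)  # monotone in LLR since pp > pn, same p each bit
    order = np.argsort(llr, kind="stable")
    llr, prob_pos, prob_neg = llr[order], prob_pos[order], prob_neg[order]
    auc = 0.0
    for i in range(len(llr)):
        greater = llr > llr[i]
        equal = llr == llr[i]
        auc += prob_neg[i] * (prob_pos[greater].sum() + 0.5 * prob_pos[equal].sum())
    return float(auc)


@dataclass(frozen=True)
class FixtureCompound:
    """A real molecule with independently established expected values."""

    name: str
    smiles: str
    expected: dict


def fixture_compounds() -> list[FixtureCompound]:
    """Small curated fixture set for descriptor and fingerprint tests.

    Sucrose and midazolam are the study's two worked examples; the rest are
    small probes whose expected values follow directly from their structure.
    Tolerances reflect engine differences for conformer- or parameter-
    dependent descriptors.
    """
    return [
        FixtureCompound(
            name="sucrose",
            smiles="OC[C@H]1O[C@@](CO)(O[C@@H]2O[C@H](CO)[C@@H](O)[C@H](O)[C@H]2O)[C@@H](O)[C@@H]1O",
            expected={
                "MW": (342.12, 0.01),
                "tPSA": (189.53, 0.5),
                "rotBonds": 5,
                "hBondAcceptors": 11,
                "BCUTS": (11.9962, 0.5),
                "fPSA3": (0.072136, 0.5 * 0.072136),  # +-50% relative
                "prediction": "CNSp-",
            },
        ),
        FixtureCompound(
            name="midazolam",
            smiles="Cc1ncc2n1-c1ccc(Cl)cc1C(c1ccccc1F)=NC2",
            expected={
                "MW": (325.08, 0.01),
                "tPSA": (27.96, 3.0),
                "rotBonds": 1,
                "hBondAcceptors": 3,
                "BCUTS": (11.9974, 0.5),
                "fPSA3": (0.033577, 0.5 * 0.033577),
                "prediction": "CNSp+",
            },
        ),
        FixtureCompound(
            name="benzene", smiles="c1ccccc1", expected={"tPSA": (0.0, 1e-9)}
        ),
        FixtureCompound(
            name="cyclohexane", smiles="C1CCCCC1", expected={"hBondAcceptors": 0}
        ),
        FixtureCompound(
            name="ethanol", smiles="CCO", expected={"rotBonds": 0}
        ),
        FixtureCompound(
            name="methane", smiles="C", expected={"MW": (16.0313, 0.0005)}
        ),
        FixtureCompound(
            name="thiophene", smiles="c1ccsc1", expected={"maccs_set": (36,)}
        ),
        FixtureCompound(
            name="dimethyl sulfoxide", smiles="CS(C)=O", expected={"maccs_set": (60,)}
        ),
        FixtureCompound(
            name="glycine",
            smiles="NCC(=O)O",
            # amino N is two bonds from the carboxyl oxygens, so the
            # N~C(~O)~O key has no embedding
            expected={"smarts_false": ("[#7]~[#6](~[#8])~[#8]",)},
        ),
        FixtureCompound(
            name="methyl carbamate",
            smiles="COC(N)=O",
            expected={"smarts_true": ("[#7]~[#6](~[#8])~[#8]",)},
        ),
    ]
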