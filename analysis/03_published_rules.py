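"""Route the two published worked examples through the published rule sets.

Sucrose (small hydrophilic sugar) should classify CNSp- and midazolam (CNS
active benzodiazepine) CNSp+ under both paradigms, from the printed
descriptor rows; the desk-computable descriptors (monoisotopic mass,
rotatable bonds, tPSA, BCUTS, fPSA3) are also recomputed from structure.
"""

import json
from pathlib import Path

from bbbperm.dataset_io import CompoundRecord, embed_3d
from bbbperm.descriptors import (
    calc_bcut_low,
    calc_fpsa3,
    calc_hbond_acceptors,
    calc_molecular_weight,
    calc_rotatable_bonds,
    calc_tpsa,
)
from bbbperm.dti import CLASS_NAMES, predict_class, published_rule_classifier

RESULTS = Path(__file__).resolve().parents[1] / "results"

STRUCTURES = {
    "sucrose": "OC[C@H]1O[C@@](CO)(O[C@@H]2O[C@H](CO)[C@@H](O)[C@H](O)[C@H]2O)[C@@H](O)[C@@H]1O",
    "midazolam": "Cc1ncc2n1-c1ccc(Cl)cc1C(c1ccccc1F)=NC2",
}
PRINTED_ROWS = {
    "sucrose": {"MW": 342.12, "aLogP": -4.3105, "tPSA": 189.53, "fPSA3": 0.072136,
                "rotBonds": 5, "BCUTS": 11.9962, "hBondAcceptors": 11},
    "midazolam": {"MW": 325.08, "aLogP": 0.4073, "tPSA": 27.96, "fPSA3": 0.033577,
                  "rotBonds": 1, "BCUTS": 11.9974, "hBondAcceptors": 3},
}


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    report = {}
    for name, smiles in STRUCTURES.items():
        mol3d = embed_3d(CompoundRecord(name, name, smiles), seed=7)
        recomputed = {
            "MW": round(calc_molecular_weight(smiles), 2),
            "tPSA": round(calc_tpsa(smiles), 2),
            "fPSA3": round(calc_fpsa3(mol3d), 6),
            "rotBonds": calc_rotatable_bonds(smiles),
            "BCUTS": round(calc_bcut_low(smiles), 4),
            "hBondAcceptors": calc_hbond_acceptors(smiles),
        }
        predictions = {
            paradigm: CLASS_NAMES[
                predict_class(published_rule_classifier(paradigm), PRINTED_ROWS[name])
            ]
            for paradigm in ("CHAID", "CART")
        }
        report[name] = {"recomputed": recomputed, "printed": PRINTED_ROWS[name],
                        "prediction": predictions}
        print(f"{name}: {predictions}  (recomputed {recomputed})")
    (RESULTS / "03_published_rules.json").write_text(json.dumps(report, indent=2))


if __name__ == "__main__":
    main()
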