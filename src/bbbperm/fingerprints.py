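"""166-bit MACCS substructure-key fingerprints and Tanimoto similarity.

Bits are indexed 1..166 as in the MDL key table; "darkness" is the number
of set bits. The SMARTS definitions are the public MACCS table shipped with
RDKit (``rdkit.Chem.MACCSkeys``), which differs in a handful of keys from
older toolkit dialects — similarity benchmarks against values computed with
those dialects therefore carry a tolerance.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import MACCSkeys

N_KEYS = 166


@dataclass(frozen=True)
class BitFingerprint:
    """Fixed-length 166-bit MACCS presence vector (index 1..166)."""

    bits: np.ndarray  # shape (166,), dtype uint8

    def __post_init__(self) -> None:
        arr = np.asarray(self.bits, dtype=np.uint8)
        if arr.shape != (N_KEYS,):
            raise ValueError(f"expected {N_KEYS} bits, got shape {arr.shape}")
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("bits must be 0/1")
        object.__setattr__(self, "bits", arr)

    @property
    def darkness(self) -> int:
        """Number of set bits."""
        return int(self.bits.sum())

    def __getitem__(self, key_index: int) -> bool:
        """Presence of MACCS key ``key_index`` (1-based)."""
        if not 1 <= key_index <= N_KEYS:
            raise IndexError(f"MACCS key index must be in 1..{N_KEYS}")
        return bool(self.bits[key_index - 1])

    def set_keys(self) -> tuple[int, ...]:
        return tuple(int(i) + 1 for i in np.flatnonzero(self.bits))


def key_smarts(key_index: int) -> tuple[str, int]:
    """(SMARTS, required match count) defining MACCS key ``key_index``."""
    if not 1 <= key_index <= N_KEYS:
        raise IndexError(f"MACCS key index must be in 1..{N_KEYS}")
    return MACCSkeys.smartsPatts[key_index]


def maccs_keys(mol: Chem.Mol | str) -> BitFingerprint:
    """MACCS 166-key fingerprint: bit i set iff SMARTS pattern i matches
    with its required count."""
    if isinstance(mol, str):
        parsed = Chem.MolFromSmiles(mol)
        if parsed is None:
            raise ValueError(f"unparseable SMILES {mol!r}")
        mol = parsed
    bv = MACCSkeys.GenMACCSKeys(mol)  # 167 bits, bit 0 unused
    bits = np.zeros(N_KEYS, dtype=np.uint8)
    for i in bv.GetOnBits():
        if 1 <= i <= N_KEYS:
            bits[i - 1] = 1
    return BitFingerprint(bits=bits)


def match_substructure_key(mol: Chem.Mol | str, smarts: str) -> bool:
    """True iff at least one embedding of ``smarts`` exists in ``mol``."""
    if isinstance(mol, str):
        parsed = Chem.MolFromSmiles(mol)
        if parsed is None:
            raise ValueError(f"unparseable SMILES {mol!r}")
        mol = parsed
    patt = Chem.MolFromSmarts(smarts)
    if patt is None:
        raise ValueError(f"invalid SMARTS {smarts!r}")
    return mol.HasSubstructMatch(patt)


def tanimoto(a: BitFingerprint, b: BitFingerprint) -> float:
    """|a AND b| / |a OR b|; two all-zero fingerprints count as identical (1.0)."""
    if a.bits.shape != b.bits.shape:
        raise ValueError("fingerprint length mismatch")
    union = int(np.bitwise_or(a.bits, b.bits).sum())
    if union == 0:
        return 1.0
    inter = int(np.bitwise_and(a.bits, b.bits).sum())
    return inter / union


def mean_pairwise_tanimoto(fps: list[BitFingerprint]) -> float:
    """Mean Tanimoto over all n(n-1)/2 unordered pairs."""
    if len(fps) < 2:
        raise ValueError("need at least two fingerprints")
    vals = [tanimoto(a, b) for a, b in itertools.combinations(fps, 2)]
    return float(np.mean(vals))


def fingerprint_matrix(fps: list[BitFingerprint]) -> np.ndarray:
    """Stack fingerprints into an (n, 166) 0/1 matrix (column j = key j+1)."""
    return np.vstack([fp.bits for fp in fps]).astype(np.uint8)


def export_fingerprint_csv(
    fps: dict[str, BitFingerprint], path: str
) -> None:
    """CSV with one row per compound id and one 0/1 column per MACCS key."""
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id"] + [f"key{i}" for i in range(1, N_KEYS + 1)])
        for ident, fp in fps.items():
            writer.writerow([ident] + fp.bits.tolist())
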