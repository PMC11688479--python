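"""Binary molecular fingerprints and the Tanimoto similarity kernel.

Five schemes are supported, matching the common RDKit repertoire used in
ligand-based screening:

``morgan``
    Circular (ECFP-like) fingerprint; parameters ``radius`` and
    ``n_bits``.  The clustering default is radius 2 / 2048 bits; the ML
    benchmark default is radius 2 / 1024 bits.
``maccs``
    The 166 MACCS structural keys.  Keys are numbered 1..166 in the
    conventional 167-slot vector, so ``n_bits`` is reported as 167 with
    slot 0 permanently unset.
``rdkit_path``
    RDKit's path-based (Daylight-like) fingerprint.
``topological_torsion``
    Hashed topological torsions.
``atom_pairs``
    Hashed atom pairs.

Similarity between two fingerprints is the Tanimoto coefficient
T = |A ∩ B| / |A ∪ B| over set bits.  The empty-vs-empty case is defined
as 0 rather than 0/0: a conservative choice that never inflates
similarity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import MACCSkeys, rdFingerprintGenerator

from .chemlib import CompoundRecord

SCHEMES = ("morgan", "maccs", "rdkit_path", "topological_torsion", "atom_pairs")

#: Defaults per scheme; hashed widths default to 2048 where the scheme
#: does not fix its own length.
DEFAULT_PARAMS: dict[str, dict[str, int]] = {
    "morgan": {"radius": 2, "n_bits": 2048},
    "maccs": {},
    "rdkit_path": {"n_bits": 2048},
    "topological_torsion": {"n_bits": 2048},
    "atom_pairs": {"n_bits": 2048},
}

CLUSTERING_MORGAN = {"radius": 2, "n_bits": 2048}
ML_MORGAN = {"radius": 2, "n_bits": 1024}


@dataclass(frozen=True)
class Fingerprint:
    """A binary fingerprint: a set of on-bit indices under a named scheme."""

    scheme: str
    n_bits: int
    bits: frozenset[int]

    def __post_init__(self) -> None:
        if self.bits and (min(self.bits) < 0 or max(self.bits) >= self.n_bits):
            raise ValueError("bit index outside [0, n_bits)")

    def to_array(self) -> np.ndarray:
        """Dense 0/1 vector of length n_bits (uint8)."""
        v = np.zeros(self.n_bits, dtype=np.uint8)
        if self.bits:
            v[sorted(self.bits)] = 1
        return v


@dataclass(frozen=True)
class SimilarityMatrix:
    ids: tuple[str, ...]
    values: np.ndarray  # square, symmetric, unit diagonal

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match ids")


def _mol_from_record(c: CompoundRecord) -> Chem.Mol:
    mol = Chem.MolFromSmiles(c.smiles)
    if mol is None:
        raise ValueError(f"compound {c.id!r}: SMILES does not parse: {c.smiles!r}")
    return mol


def compute_fingerprint(
    c: CompoundRecord, scheme: str = "morgan", params: Mapping[str, int] | None = None
) -> Fingerprint:
    """Compute one binary fingerprint; deterministic given (molecule, scheme, params)."""
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    opts = dict(DEFAULT_PARAMS[scheme])
    opts.update(params or {})
    mol = _mol_from_record(c)
    if scheme == "maccs":
        bv = MACCSkeys.GenMACCSKeys(mol)  # 167 slots, key i at bit i, slot 0 unset
        return Fingerprint("maccs", 167, frozenset(bv.GetOnBits()))
    if scheme == "morgan":
        gen = rdFingerprintGenerator.GetMorganGenerator(
            radius=int(opts["radius"]), fpSize=int(opts["n_bits"])
        )
    elif scheme == "rdkit_path":
        gen = rdFingerprintGenerator.GetRDKitFPGenerator(fpSize=int(opts["n_bits"]))
    elif scheme == "topological_torsion":
        gen = rdFingerprintGenerator.GetTopologicalTorsionGenerator(
            fpSize=int(opts["n_bits"])
        )
    else:  # atom_pairs
        gen = rdFingerprintGenerator.GetAtomPairGenerator(fpSize=int(opts["n_bits"]))
    bv = gen.GetFingerprint(mol)
    return Fingerprint(scheme, int(opts["n_bits"]), frozenset(bv.GetOnBits()))


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient |A∩B|/|A∪B|; empty-vs-empty is 0 by convention."""
    if a.scheme != b.scheme or a.n_bits != b.n_bits:
        raise ValueError(
            f"fingerprint mismatch: {a.scheme}/{a.n_bits} vs {b.scheme}/{b.n_bits}"
        )
    union = len(a.bits | b.bits)
    if union == 0:
        return 0.0
    return len(a.bits & b.bits) / union


def similarity_matrix(
    fps: Sequence[Fingerprint], ids: Sequence[str] | None = None
) -> SimilarityMatrix:
    """Pairwise Tanimoto matrix over a fingerprint list (symmetric, unit diagonal)."""
    n = len(fps)
    if ids is None:
        ids = tuple(str(i) for i in range(n))
    m = np.zeros((n, n), dtype=float)
    for i in range(n):
        m[i, i] = 1.0 if fps[i].bits else 0.0
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = tanimoto(fps[i], fps[j])
    return SimilarityMatrix(tuple(ids), m)


def fingerprint_matrix(
    records: Iterable[CompoundRecord],
    scheme: str = "morgan",
    params: Mapping[str, int] | None = None,
) -> tuple[np.ndarray, list[Fingerprint]]:
    """Stack fingerprints for a record list into an (n, n_bits) 0/1 matrix."""
    fps = [compute_fingerprint(r, scheme, params) for r in records]
    if not fps:
        return np.zeros((0, 0), dtype=np.uint8), []
    return np.stack([fp.to_array() for fp in fps]), fps


def fingerprints_to_json(
    fps: Mapping[str, Fingerprint], path: str | Path
) -> None:
    """Cache fingerprints as JSON: one {id, scheme, n_bits, bits} record each."""
    payload = [
        {"id": cid, "scheme": fp.scheme, "n_bits": fp.n_bits, "bits": sorted(fp.bits)}
        for cid, fp in fps.items()
    ]
    Path(path).write_text(json.dumps(payload, indent=0) + "\n")


def fingerprints_from_json(path: str | Path) -> dict[str, Fingerprint]:
    payload = json.loads(Path(path).read_text())
    return {
        rec["id"]: Fingerprint(rec["scheme"], int(rec["n_bits"]), frozenset(rec["bits"]))
        for rec in payload
    }
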