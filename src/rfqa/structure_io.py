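"""Reading of model coordinates and contact data; contact-map extraction; score tables.

Coordinates are reduced to one representative point per residue: the Cβ atom,
or Cα for glycine (and, with a warning, for any residue missing its Cβ).
Contact maps live in sequential residue-position space (1..length), so that
sequence separation is well defined even when author numbering has gaps.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser

logger = logging.getLogger(__name__)

_RR_KEYWORDS = {"PFRMAT", "TARGET", "AUTHOR", "METHOD", "MODEL", "END", "REMARK"}


@dataclass
class StructureModel:
    """A protein model reduced to one representative atom per residue.

    ``indices`` are the author residue numbers (1-based, strictly increasing);
    ``coords`` is an (L, 3) array of representative-atom positions in Å.
    """

    model_id: str
    target_id: str
    indices: np.ndarray
    names: tuple[str, ...]
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.indices.ndim != 1 or self.coords.shape != (len(self.indices), 3):
            raise ValueError("indices and coords shapes are inconsistent")
        if len(self.indices) < 1:
            raise ValueError("a model needs at least one residue")
        if np.any(np.diff(self.indices) <= 0):
            raise ValueError("residue indices must be strictly increasing")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite representative coordinates")
        if len(self.names) != len(self.indices):
            raise ValueError("names and indices lengths differ")

    @property
    def length(self) -> int:
        return len(self.indices)

    @property
    def residues(self):
        """Ordered (index, residue_name, rep_coord) triples."""
        return list(zip(self.indices.tolist(), self.names, self.coords))


@dataclass(frozen=True)
class ContactMap:
    """Binary residue–residue contacts of one structure.

    Pairs are unordered, stored as (i, j) with i < j in 1-based sequential
    position space, and satisfy j - i >= min_separation.
    """

    length: int
    contacts: frozenset
    min_separation: int = 5

    def __post_init__(self) -> None:
        object.__setattr__(self, "contacts", frozenset(self.contacts))
        if self.length < 1:
            raise ValueError("length must be >= 1")
        for i, j in self.contacts:
            if not (1 <= i < j <= self.length):
                raise ValueError(f"invalid contact pair ({i}, {j})")
            if j - i < self.min_separation:
                raise ValueError(
                    f"pair ({i}, {j}) violates min_separation={self.min_separation}"
                )

    def __len__(self) -> int:
        return len(self.contacts)

    def to_matrix(self) -> np.ndarray:
        """Dense symmetric 0/1 matrix with zero diagonal."""
        m = np.zeros((self.length, self.length))
        for i, j in self.contacts:
            m[i - 1, j - 1] = m[j - 1, i - 1] = 1.0
        return m


@dataclass(frozen=True)
class PredictedContactMap:
    """Probabilistic contact list from a residue-contact predictor."""

    length: int
    entries: tuple  # of (i, j, p), i < j, at most one entry per pair

    def __post_init__(self) -> None:
        seen = set()
        norm = []
        for i, j, p in self.entries:
            if not (1 <= i < j <= self.length):
                raise ValueError(f"invalid predicted pair ({i}, {j})")
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability {p} outside [0, 1]")
            if (i, j) in seen:
                raise ValueError(f"duplicate predicted pair ({i}, {j})")
            seen.add((i, j))
            norm.append((int(i), int(j), float(p)))
        object.__setattr__(self, "entries", tuple(norm))

    def __len__(self) -> int:
        return len(self.entries)

    def as_dict(self) -> dict:
        return {(i, j): p for i, j, p in self.entries}

    def pairs_above(self, threshold: float) -> set:
        """Pairs with probability strictly greater than ``threshold``."""
        return {(i, j) for i, j, p in self.entries if p > threshold}

    def to_matrix(self) -> np.ndarray:
        """Dense symmetric probability matrix with zero diagonal."""
        m = np.zeros((self.length, self.length))
        for i, j, p in self.entries:
            m[i - 1, j - 1] = m[j - 1, i - 1] = p
        return m


def _representative_atom(residue):
    """Cβ, or Cα for glycine / missing Cβ; None if neither exists."""
    name = residue.get_resname()
    atom = None
    if name != "GLY" and "CB" in residue:
        atom = residue["CB"]
    elif "CA" in residue:
        if name != "GLY":
            logger.warning(
                "residue %s %s lacks a CB atom; falling back to CA",
                name, residue.id[1],
            )
        atom = residue["CA"]
    if atom is None:
        return None
    if atom.is_disordered():
        # first-listed altloc, by serial number
        atom = min(atom.disordered_get_list(), key=lambda a: a.get_serial_number())
    return atom


def read_model(path, target_id: str, model_id: str | None = None,
               chain_id: str | None = None) -> StructureModel:
    """Read one chain of a PDB file into a :class:`StructureModel`.

    Only the first MODEL is used; ``chain_id`` selects a chain (default:
    the first). Residues with insertion codes are rejected; hetero residues
    and residues without a usable representative atom are skipped.
    """
    path = Path(path)
    if model_id is None:
        model_id = path.stem
    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure(model_id, str(path))
    except Exception as exc:  # Bio.PDB raises assorted exception types
        raise ValueError(f"unreadable PDB file {path}: {exc}") from exc
    models = list(structure)
    if not models:
        raise ValueError(f"no coordinates (ATOM records) in {path}")
    chains = list(models[0])
    if chain_id is not None:
        chains = [c for c in chains if c.id == chain_id]
        if not chains:
            raise ValueError(f"chain {chain_id!r} not found in {path}")
    if not chains:
        raise ValueError(f"no chains in {path}")
    chain = chains[0]

    indices, names, coords = [], [], []
    for residue in chain:
        hetflag, seq, icode = residue.id
        if hetflag.strip():
            continue
        if icode.strip():
            raise ValueError(
                f"residue {seq}{icode} in {path} carries an insertion code; "
                "renumber the chain before use"
            )
        atom = _representative_atom(residue)
        if atom is None:
            logger.warning("residue %s in %s has no CB/CA atom; skipped", seq, path)
            continue
        indices.append(seq)
        names.append(residue.get_resname())
        coords.append(atom.get_coord())
    if not indices:
        raise ValueError(f"no residues with representative atoms in {path}")
    return StructureModel(model_id=model_id, target_id=target_id,
                          indices=np.array(indices), names=tuple(names),
                          coords=np.array(coords, dtype=float))


def observed_contact_map(model: StructureModel, cutoff_A: float = 8.0,
                         min_separation: int = 5) -> ContactMap:
    """Contacts between representative atoms strictly closer than ``cutoff_A``.

    Positions are sequential (1..length); separation is counted in sequence
    positions, so chain breaks in author numbering do not create artefacts.
    """
    xyz = model.coords
    L = model.length
    d = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=-1)
    contacts = set()
    for i in range(L):
        for j in range(i + min_separation, L):
            if d[i, j] < cutoff_A:
                contacts.add((i + 1, j + 1))
    return ContactMap(length=L, contacts=frozenset(contacts),
                      min_separation=min_separation)


def read_predicted_contacts(path, length: int) -> PredictedContactMap:
    """Parse a CASP RR-style contact list (``i j d1 d2 p`` or ``i j p`` lines).

    Header keywords and plain sequence lines are tolerated. Duplicate pairs
    keep the highest probability; indices are normalised so i < j.
    """
    best: dict = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            first = line.split()[0].upper()
            if first in _RR_KEYWORDS:
                continue
            tokens = line.split()
            if len(tokens) == 1 and tokens[0].isalpha():
                continue  # sequence line
            if len(tokens) == 5:
                i_s, j_s, _, _, p_s = tokens
            elif len(tokens) == 3:
                i_s, j_s, p_s = tokens
            else:
                raise ValueError(f"unparseable contact line: {line!r}")
            i, j, p = int(i_s), int(j_s), float(p_s)
            if i == j:
                raise ValueError(f"self-contact ({i}, {j}) in {path}")
            if i > j:
                i, j = j, i
            if not (1 <= i < j <= length):
                raise ValueError(f"contact ({i}, {j}) outside [1, {length}]")
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability {p} outside [0, 1] in {path}")
            if p > best.get((i, j), -1.0):
                best[(i, j)] = p
    entries = tuple((i, j, p) for (i, j), p in sorted(best.items()))
    return PredictedContactMap(length=length, entries=entries)


def write_contacts(path, cmap, probability: float = 1.0) -> None:
    """Write a ContactMap or PredictedContactMap in CASP RR dialect."""
    with open(path, "w") as fh:
        if isinstance(cmap, PredictedContactMap):
            for i, j, p in cmap.entries:
                fh.write(f"{i} {j} 0 8 {p:.6f}\n")
        else:
            for i, j in sorted(cmap.contacts):
                fh.write(f"{i} {j} 0 8 {probability:.6f}\n")


def read_score_table(path) -> pd.DataFrame:
    """Read a delimited score table keyed by (target_id, model_id).

    Missing numeric cells stay missing (NaN), never zero. Duplicate keys and
    absent key columns are errors.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype={0: str})
    for col in ("target_id", "model_id"):
        if col not in df.columns:
            raise ValueError(f"score table {path} lacks required column {col!r}")
    df["target_id"] = df["target_id"].astype(str)
    df["model_id"] = df["model_id"].astype(str)
    if df.duplicated(subset=["target_id", "model_id"]).any():
        raise ValueError(f"duplicate (target_id, model_id) rows in {path}")
    return df


def write_score_table(df: pd.DataFrame, path, sep: str = "\t") -> None:
    df.to_csv(path, sep=sep, index=False)
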