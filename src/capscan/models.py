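"""Core in-memory containers for coordinate models and per-residue profiles.

Residues are identified by *author numbering* (the numbers printed in the
deposited file, which is how catalytic residues are cited in the literature,
e.g. "Lys 391"), while cross-structure comparisons run in 1-based *reference
coordinates* established by :class:`ResidueMap`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

from .errors import ValidationError

#: sentinel for reference positions with no modeled residue
UNMAPPED = None

ResidueKey = tuple[int, str]  # (author_number, insertion_code)


@dataclass
class AtomRecord:
    """A single atom: name, element, position and the B-factor/pLDDT slot."""

    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    b_or_plddt: float = 0.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValidationError(f"atom {self.name}: coordinates must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValidationError(f"atom {self.name}: occupancy {self.occupancy} outside [0,1]")


@dataclass
class Residue:
    author_number: int
    insertion_code: str = ""
    aa: str = "X"
    atoms: list[AtomRecord] = field(default_factory=list)
    is_het: bool = False

    @property
    def key(self) -> ResidueKey:
        return (self.author_number, self.insertion_code)

    def atom(self, name: str) -> Optional[AtomRecord]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> Optional[AtomRecord]:
        return self.atom("CA")

    @property
    def is_water(self) -> bool:
        return self.aa in ("HOH", "WAT", "DOD")


@dataclass
class Structure:
    """One coordinate model: polymer chains plus het groups (ligands, ions, waters).

    ``chains`` maps chain id to the ordered residue list; het residues that
    belong to a polymer chain context (dummy shells in fixtures) may also live
    there flagged ``is_het``. ``ligands`` holds free-standing het groups as
    ``(chain_id, residue)`` pairs.
    """

    id: str
    chains: dict[str, list[Residue]] = field(default_factory=dict)
    ligands: list[tuple[str, Residue]] = field(default_factory=list)
    source_format: str = "pdb"

    def __post_init__(self) -> None:
        if not self.chains:
            raise ValidationError(f"structure {self.id}: at least one chain required")

    def chain(self, chain_id: str) -> list[Residue]:
        if chain_id not in self.chains:
            raise KeyError(f"structure {self.id}: no chain {chain_id!r}")
        return self.chains[chain_id]

    def polymer_residues(self, chain_id: str) -> list[Residue]:
        return [r for r in self.chain(chain_id) if not r.is_het]

    def iter_atoms(
        self, include_waters: bool = True, include_het: bool = True
    ) -> Iterator[tuple[str, Residue, AtomRecord]]:
        for cid, residues in self.chains.items():
            for res in residues:
                if res.is_het and not include_het:
                    continue
                if res.is_water and not include_waters:
                    continue
                for atom in res.atoms:
                    yield cid, res, atom
        if include_het:
            for cid, res in self.ligands:
                if res.is_water and not include_waters:
                    continue
                for atom in res.atoms:
                    yield cid, res, atom

    def sequence(self, chain_id: str) -> str:
        """One-letter sequence of the modeled (non-het) residues, in author order."""
        return "".join(r.aa for r in self.polymer_residues(chain_id))


@dataclass
class ResidueMap:
    """Mapping from 1-based reference positions to residue keys of one chain."""

    reference_length: int
    positions: dict[int, Optional[ResidueKey]]
    alignment_identity: float
    chain_id: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.alignment_identity <= 1.0:
            raise ValidationError("alignment identity outside [0,1]")

    def residue_key(self, ref_pos: int) -> Optional[ResidueKey]:
        return self.positions.get(ref_pos, UNMAPPED)

    def mapped_positions(self) -> list[int]:
        return sorted(p for p, k in self.positions.items() if k is not None)

    def ca_coordinates(self, structure: Structure) -> np.ndarray:
        """(reference_length, 3) array of Cα coordinates, NaN where missing."""
        coords = np.full((self.reference_length, 3), np.nan)
        by_key = {r.key: r for r in structure.polymer_residues(self.chain_id)}
        for pos, key in self.positions.items():
            if key is None:
                continue
            res = by_key.get(key)
            if res is None:
                continue
            ca = res.ca
            if ca is not None:
                coords[pos - 1] = ca.coords
        return coords


@dataclass
class PLDDTProfile:
    """Per-residue AlphaFold confidence (pLDDT, 0-100) keyed by reference position."""

    values: dict[int, float]
    source: str = ""

    def __post_init__(self) -> None:
        for pos, v in self.values.items():
            if not 0.0 <= v <= 100.0:
                raise ValidationError(f"pLDDT at position {pos} is {v}, outside [0,100]")

    def as_array(self, length: Optional[int] = None) -> np.ndarray:
        """1-based profile as a 0-based array with NaN at absent positions."""
        n = length if length is not None else (max(self.values) if self.values else 0)
        arr = np.full(n, np.nan)
        for pos, v in self.values.items():
            if 1 <= pos <= n:
                arr[pos - 1] = v
        return arr
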