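"""Reading and writing coordinate models, reference sequences and pLDDT profiles.

PDB/mmCIF parsing is delegated to gemmi; sequence alignment for reference
mapping uses Biopython's PairwiseAligner (global, affine gaps).
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Optional, Union

import gemmi
import numpy as np
from Bio import Align, SeqIO

from .errors import FormatError, MappingError, ParseError, ValidationError
from .models import AtomRecord, PLDDTProfile, Residue, ResidueMap, Structure

PathLike = Union[str, os.PathLike]

# modified residues mapped onto their parent amino acid for sequence purposes
_MODIFIED_PARENT = {"MSE": "M", "SEC": "U", "PYL": "O", "SEP": "S", "TPO": "T", "PTR": "Y"}


def _one_letter(resname: str) -> str:
    if resname in _MODIFIED_PARENT:
        return _MODIFIED_PARENT[resname]
    info = gemmi.find_tabulated_residue(resname)
    if info is not None and info.is_amino_acid():
        code = info.one_letter_code.upper()
        return code if code.isalpha() else "X"
    return "X"


def _is_amino_acid(resname: str) -> bool:
    if resname in _MODIFIED_PARENT:
        return True
    info = gemmi.find_tabulated_residue(resname)
    return info is not None and info.is_amino_acid()


def _resolve_altlocs(res: gemmi.Residue) -> list[AtomRecord]:
    """Keep one conformer per atom name: highest occupancy, ties by altloc letter."""
    groups: dict[str, list[gemmi.Atom]] = {}
    for atom in res:
        groups.setdefault(atom.name, []).append(atom)
    out = []
    for name, atoms in groups.items():
        best = min(atoms, key=lambda a: (-a.occ, a.altloc or "~"))
        out.append(
            AtomRecord(
                name=name,
                element=best.element.name.upper(),
                coords=np.array([best.pos.x, best.pos.y, best.pos.z]),
                occupancy=min(max(best.occ, 0.0), 1.0),
                b_or_plddt=best.b_iso,
                altloc=best.altloc or "",
            )
        )
    return out


def read_structure(path: PathLike, format: str = "auto") -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    Alternate locations are resolved to the highest-occupancy conformer.
    Waters and ions are retained as het residues. Only the first model of a
    multi-model file is used.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    fmt_map = {
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
        "auto": gemmi.CoorFormat.Detect,
    }
    if format not in fmt_map:
        raise FormatError(f"unknown format {format!r}; expected pdb, mmcif or auto")
    try:
        st = gemmi.read_structure(str(path), format=fmt_map[format])
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise ParseError(f"{path}: no models found")
    st.setup_entities()

    source = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    chains: dict[str, list[Residue]] = {}
    ligands: list[tuple[str, Residue]] = []
    for chain in st[0]:
        for gres in chain:
            is_aa = _is_amino_acid(gres.name)
            res = Residue(
                author_number=gres.seqid.num,
                insertion_code=(gres.seqid.icode or "").strip(),
                aa=_one_letter(gres.name) if is_aa else gres.name,
                atoms=_resolve_altlocs(gres),
                is_het=not is_aa,
            )
            if is_aa:
                chains.setdefault(chain.name, []).append(res)
            else:
                ligands.append((chain.name, res))
    if not chains:
        # het-only file: keep the groups addressable through their chains
        for cid, res in ligands:
            chains.setdefault(cid, []).append(res)
        ligands = []
    return Structure(id=path.stem, chains=chains, ligands=ligands, source_format=source)


_THREE_LETTER = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL", "X": "UNK",
}


def write_structure(structure: Structure, path: PathLike) -> None:
    """Write a structure as a PDB file (via gemmi)."""
    st = gemmi.Structure()
    st.name = structure.id
    model = gemmi.Model("1")

    def _add(chain_map: dict[str, gemmi.Chain], cid: str, res: Residue) -> None:
        if cid not in chain_map:
            chain_map[cid] = gemmi.Chain(cid)
        gres = gemmi.Residue()
        gres.name = res.aa if res.is_het or len(res.aa) > 1 else _THREE_LETTER.get(res.aa, "UNK")
        gres.seqid = gemmi.SeqId(res.author_number, res.insertion_code or " ")
        gres.het_flag = "H" if res.is_het else "A"
        for atom in res.atoms:
            ga = gemmi.Atom()
            ga.name = atom.name
            ga.element = gemmi.Element(atom.element)
            ga.pos = gemmi.Position(*atom.coords)
            ga.occ = atom.occupancy
            ga.b_iso = atom.b_or_plddt
            ga.altloc = atom.altloc or "\0"
            gres.add_atom(ga)
        chain_map[cid].add_residue(gres)

    chain_map: dict[str, gemmi.Chain] = {}
    for cid, residues in structure.chains.items():
        for res in residues:
            _add(chain_map, cid, res)
    for cid, res in structure.ligands:
        _add(chain_map, cid, res)
    for chain in chain_map.values():
        model.add_chain(chain)
    st.add_model(model)
    st.write_pdb(str(path))


def read_fasta(path: PathLike) -> str:
    """First sequence of a FASTA file, upper-cased."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ParseError(f"{path}: no FASTA records")
    return str(records[0].seq).upper()


def map_to_reference(
    structure: Structure,
    chain_id: str,
    reference: str,
    min_identity: float = 0.3,
) -> ResidueMap:
    """Map a chain's modeled residues onto a reference sequence.

    Uses a Needleman-Wunsch global alignment (match +1, mismatch 0, gap open
    -5, gap extend -0.5). Reference positions with no modeled residue are left
    unmapped. Raises :class:`MappingError` when the fraction of identical
    aligned pairs falls below ``min_identity`` (wrong protein).
    """
    if not reference:
        raise ValidationError("reference sequence is empty")
    residues = structure.polymer_residues(chain_id)
    seq = "".join(r.aa for r in residues)
    if not seq:
        raise MappingError(f"chain {chain_id} has no modeled amino-acid residues")

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -0.5
    alignment = aligner.align(reference.upper(), seq)[0]

    positions: dict[int, Optional[tuple[int, str]]] = {
        i: None for i in range(1, len(reference) + 1)
    }
    matches = 0
    aligned_pairs = 0
    for (r0, r1), (q0, q1) in zip(*alignment.aligned):
        for k in range(r1 - r0):
            ref_i, chain_j = r0 + k, q0 + k
            positions[ref_i + 1] = residues[chain_j].key
            aligned_pairs += 1
            if reference[ref_i].upper() == seq[chain_j]:
                matches += 1
    identity = matches / aligned_pairs if aligned_pairs else 0.0
    if identity < min_identity:
        raise MappingError(
            f"chain {chain_id}: alignment identity {identity:.2f} below floor "
            f"{min_identity:.2f} — is this the right protein?"
        )
    return ResidueMap(
        reference_length=len(reference),
        positions=positions,
        alignment_identity=identity,
        chain_id=chain_id,
    )


def read_plddt(path: PathLike, chain_id: Optional[str] = None) -> PLDDTProfile:
    """Read a per-residue pLDDT profile.

    Accepts either an AlphaFold-style model file (pLDDT stored in the B-factor
    column; the residue's Cα value is used) or a plain two-column
    position/value table. AlphaFold models number residues 1..L, so author
    numbers are taken as reference positions directly.
    """
    path = Path(path)
    if path.suffix.lower() in (".pdb", ".cif", ".mmcif", ".ent"):
        st = read_structure(path)
        cid = chain_id or next(iter(st.chains))
        values: dict[int, float] = {}
        for res in st.polymer_residues(cid):
            atom = res.ca or (res.atoms[0] if res.atoms else None)
            if atom is not None:
                values[res.author_number] = atom.b_or_plddt
        _validate_plddt(values, path)
        return PLDDTProfile(values=values, source=str(path))

    values = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ParseError(f"{path}:{ln}: expected 'position value'")
            try:
                values[int(parts[0])] = float(parts[1])
            except ValueError as exc:
                raise ParseError(f"{path}:{ln}: {exc}") from exc
    _validate_plddt(values, path)
    return PLDDTProfile(values=values, source=str(path))


def _validate_plddt(values: dict[int, float], path: Path) -> None:
    bad = {p: v for p, v in values.items() if not 0.0 <= v <= 100.0}
    if bad:
        raise ValidationError(f"{path}: pLDDT values outside [0,100]: {bad}")
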