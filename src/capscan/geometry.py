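"""Geometric consequences of capping: superposition, displacement, distances,
pocket volume, solvent-accessible and buried surface areas.

Superposition is a least-squares (Kabsch) fit with the reflection corrected;
SASA uses the Shrake-Rupley quadrature (delegated to biotite); pocket volume
follows min/max-probe semantics: grid points with clearance above the small
probe are cavity candidates, bulk solvent is whatever a large probe can reach
from the box boundary, and one connected cavity component is reported.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .errors import DataError, DegeneracyError, SelectionError, ValidationError
from .models import AtomRecord, Residue, ResidueMap, Structure

#: van-der-Waals radii by element (Å); overridable per call
DEFAULT_RADII = {
    "C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8, "P": 1.8, "H": 1.2,
    "K": 2.75, "NA": 2.27, "MG": 1.73, "CA": 2.31, "ZN": 1.39, "CL": 1.75,
    "FE": 1.56, "MN": 1.61, "SE": 1.9,
}

AtomSelector = tuple  # (chain_id, author_number, atom_name[, insertion_code])


@dataclass
class Transform:
    """Rigid-body transform: y = R x + t."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation

    def inverse(self) -> "Transform":
        rot_inv = self.rotation.T
        return Transform(rot_inv, -rot_inv @ self.translation, self.rmsd)


@dataclass
class SiteGeometry:
    """Derived scalars describing one active site across conformational states."""

    pocket_volumes: dict[str, float] = field(default_factory=dict)  # state label -> Å³
    volume_change_pct: Optional[float] = None
    displacement_mean: Optional[float] = None  # Å
    displacement_max: Optional[float] = None
    named_distances: dict[str, float] = field(default_factory=dict)  # label -> Å
    interface_areas: dict[str, float] = field(default_factory=dict)  # "A:B" -> Å²

    def to_dict(self) -> dict:
        return {
            "pocket_volumes": self.pocket_volumes,
            "volume_change_pct": self.volume_change_pct,
            "displacement_mean": self.displacement_mean,
            "displacement_max": self.displacement_max,
            "named_distances": self.named_distances,
            "interface_areas": self.interface_areas,
        }


def volume_change_pct(baseline: float, other: float) -> float:
    """Percent volume change relative to a positive baseline volume."""
    if baseline <= 0:
        raise ValidationError("percent change undefined for non-positive baseline volume")
    return 100.0 * (other - baseline) / baseline


def superpose(mobile: np.ndarray, target: np.ndarray) -> Transform:
    """Least-squares rigid fit of ``mobile`` onto ``target`` (proper rotation).

    Both inputs are paired (n, 3) coordinate sets with n >= 3 and at least
    planar rank; the returned transform minimizes the Cα RMSD.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValidationError("superpose requires equal-length (n,3) coordinate sets")
    n = len(mobile)
    if n < 3:
        raise DegeneracyError(f"superposition needs >= 3 points, got {n}")
    m_mean, t_mean = mobile.mean(axis=0), target.mean(axis=0)
    m_c, t_c = mobile - m_mean, target - t_mean
    sv = np.linalg.svd(m_c, compute_uv=False)
    if sv[1] <= 1e-8 * max(sv[0], 1e-12):
        raise DegeneracyError("superposition input is rank-deficient (collinear points)")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy warns on near-planar input
        rot, _ = Rotation.align_vectors(t_c, m_c)
    R = rot.as_matrix()
    t = t_mean - R @ m_mean
    rmsd = float(np.sqrt(np.mean(np.sum((mobile @ R.T + t - target) ** 2, axis=1))))
    return Transform(rotation=R, translation=t, rmsd=rmsd)


def segment_displacement(
    struct_a: Structure,
    struct_b: Structure,
    map_a: ResidueMap,
    map_b: ResidueMap,
    segment: tuple[int, int],
    core: Optional[Sequence[int]] = None,
    core_margin: int = 5,
) -> tuple[Optional[float], Optional[float]]:
    """Mean and max paired Cα displacement over a segment after core superposition.

    ``struct_b`` is fitted onto ``struct_a`` using the core positions (by
    default every shared mapped position outside the segment +/- core_margin);
    the displacement is then measured over segment positions modeled in both.
    Returns (None, None) with a warning when no segment position is shared.
    """
    a, b = segment
    coords_a = map_a.ca_coordinates(struct_a)
    coords_b = map_b.ca_coordinates(struct_b)
    L = min(len(coords_a), len(coords_b))

    if core is None:
        core = [p for p in range(1, L + 1) if p < a - core_margin or p > b + core_margin]
    else:
        core = [p for p in core if p < a or p > b]  # keep core disjoint from segment
    shared_core = [
        p for p in core
        if p <= L
        and not np.isnan(coords_a[p - 1]).any()
        and not np.isnan(coords_b[p - 1]).any()
    ]
    if len(shared_core) < 3:
        raise DegeneracyError(
            f"only {len(shared_core)} shared core positions; need >= 3 for superposition"
        )
    idx = np.array(shared_core) - 1
    tr = superpose(coords_b[idx], coords_a[idx])

    seg_positions = [
        p for p in range(a, b + 1)
        if p <= L
        and not np.isnan(coords_a[p - 1]).any()
        and not np.isnan(coords_b[p - 1]).any()
    ]
    if not seg_positions:
        warnings.warn("no shared modeled positions in segment; displacement undefined", stacklevel=2)
        return None, None
    sidx = np.array(seg_positions) - 1
    moved = tr.apply(coords_b[sidx])
    d = np.linalg.norm(coords_a[sidx] - moved, axis=1)
    return float(d.mean()), float(d.max())


def _iter_matching_atoms(structure: Structure, selector: AtomSelector):
    chain_id, number, atom_name = selector[0], selector[1], selector[2]
    icode = selector[3] if len(selector) > 3 else None
    for cid, res, atom in structure.iter_atoms():
        if cid != chain_id or res.author_number != number or atom.name != atom_name:
            continue
        if icode is not None and res.insertion_code != icode:
            continue
        yield res, atom


def resolve_atom(structure: Structure, selector: AtomSelector) -> AtomRecord:
    """Resolve a (chain, author number, atom name[, icode]) selector to one atom."""
    hits = list(_iter_matching_atoms(structure, selector))
    if not hits:
        raise SelectionError(f"selector {selector} matched no atom in {structure.id}")
    if len(hits) > 1:
        raise SelectionError(f"selector {selector} is ambiguous ({len(hits)} atoms)")
    return hits[0][1]


def named_distance(structure: Structure, selector_a: AtomSelector, selector_b: AtomSelector) -> float:
    """Euclidean distance (Å) between two uniquely selected atoms."""
    atom_a = resolve_atom(structure, selector_a)
    atom_b = resolve_atom(structure, selector_b)
    return float(np.linalg.norm(atom_a.coords - atom_b.coords))


def coordination_shell(
    structure: Structure,
    ion: Union[AtomSelector, str],
    cutoff: float = 3.5,
    candidate_elements: tuple[str, ...] = ("O", "N"),
) -> list[tuple[float, str]]:
    """First-shell coordination of an ion: candidate O/N atoms within a cutoff.

    ``ion`` is either an explicit atom selector or an element symbol, in which
    case exactly one het atom of that element must exist. Returns
    (distance, label) pairs ascending by distance.
    """
    if isinstance(ion, str):
        hits = [
            (cid, res, atom)
            for cid, res, atom in structure.iter_atoms()
            if res.is_het and atom.element == ion.upper()
        ]
        if not hits:
            raise SelectionError(f"no het atom with element {ion!r}")
        if len(hits) > 1:
            raise SelectionError(
                f"{len(hits)} atoms with element {ion!r}; use an explicit selector"
            )
        ion_atom = hits[0][2]
    else:
        ion_atom = resolve_atom(structure, ion)

    shell = []
    for cid, res, atom in structure.iter_atoms():
        if atom is ion_atom or atom.element not in candidate_elements:
            continue
        d = float(np.linalg.norm(atom.coords - ion_atom.coords))
        if d <= cutoff:
            label = f"{cid}/{res.aa}{res.author_number}/{atom.name}"
            shell.append((d, label))
    return sorted(shell)


def _atom_arrays(
    structure: Structure,
    include_waters: bool,
    include_het: bool,
    radii: Optional[dict[str, float]],
    chain_ids: Optional[set[str]] = None,
) -> tuple[np.ndarray, np.ndarray, list[tuple[str, Residue, AtomRecord]]]:
    table = dict(DEFAULT_RADII)
    if radii:
        table.update({k.upper(): v for k, v in radii.items()})
    coords, rads, atoms = [], [], []
    unknown = set()
    for cid, res, atom in structure.iter_atoms(include_waters=include_waters, include_het=include_het):
        if chain_ids is not None and cid not in chain_ids:
            continue
        r = table.get(atom.element.upper())
        if r is None:
            unknown.add(atom.element)
            continue
        coords.append(atom.coords)
        rads.append(r)
        atoms.append((cid, res, atom))
    if unknown:
        raise DataError(f"no van-der-Waals radius for element(s): {sorted(unknown)}")
    return np.asarray(coords, dtype=float), np.asarray(rads, dtype=float), atoms


def _sasa_points(coords: np.ndarray, radii: np.ndarray, probe: float, n_points: int) -> np.ndarray:
    import biotite.structure as struc

    arr = struc.AtomArray(len(coords))
    arr.coord = np.asarray(coords, dtype=np.float32)
    arr.element = np.array(["C"] * len(coords))  # radii supplied explicitly
    return struc.sasa(
        arr,
        probe_radius=probe,
        vdw_radii=np.asarray(radii, dtype=float),
        point_number=n_points,
        ignore_ions=False,
    )


def sasa(
    structure: Structure,
    probe: float = 1.4,
    n_sphere_points: int = 960,
    include_waters: bool = False,
    include_het: bool = True,
    radii: Optional[dict[str, float]] = None,
) -> tuple[np.ndarray, list[tuple[str, Residue, AtomRecord]]]:
    """Per-atom Shrake-Rupley solvent-accessible surface area (Å²).

    Returns the per-atom areas and the parallel (chain, residue, atom) list.
    Waters are excluded by default since deposited models differ arbitrarily
    in water content.
    """
    coords, rads, atoms = _atom_arrays(structure, include_waters, include_het, radii)
    if len(coords) == 0:
        return np.zeros(0), []
    return _sasa_points(coords, rads, probe, n_sphere_points), atoms


def buried_surface_area(
    structure: Structure,
    chain_set_a: set[str],
    chain_set_b: set[str],
    probe: float = 1.4,
    n_sphere_points: int = 960,
    include_waters: bool = False,
    radii: Optional[dict[str, float]] = None,
) -> float:
    """Interface buried surface area: SASA(A) + SASA(B) - SASA(A∪B), in Å²."""
    chain_set_a, chain_set_b = set(chain_set_a), set(chain_set_b)
    if not chain_set_a or not chain_set_b:
        raise ValidationError("both chain sets must be non-empty")
    if chain_set_a & chain_set_b:
        raise ValidationError(f"chain sets overlap: {sorted(chain_set_a & chain_set_b)}")

    def total(chains: set[str]) -> float:
        coords, rads, _ = _atom_arrays(structure, include_waters, True, radii, chain_ids=chains)
        if len(coords) == 0:
            raise DataError(f"no atoms in chain set {sorted(chains)}")
        return float(np.nansum(_sasa_points(coords, rads, probe, n_sphere_points)))

    return total(chain_set_a) + total(chain_set_b) - total(chain_set_a | chain_set_b)


def bsa_table(
    structure: Structure,
    probe: float = 1.4,
    n_sphere_points: int = 960,
    include_waters: bool = False,
) -> dict[str, float]:
    """Buried surface area for every chain pair of a multimer."""
    chain_ids = sorted(structure.chains)
    out = {}
    for a, b in itertools.combinations(chain_ids, 2):
        out[f"{a}:{b}"] = buried_surface_area(
            structure, {a}, {b}, probe=probe, n_sphere_points=n_sphere_points,
            include_waters=include_waters,
        )
    return out


def pocket_volume(
    structure: Structure,
    seed_point: Optional[Sequence[float]] = None,
    probe_min: float = 1.4,
    probe_max: float = 3.4,
    grid_spacing: float = 0.5,
    include_waters: bool = False,
    radii: Optional[dict[str, float]] = None,
) -> float:
    """Grid-based cavity volume (Å³) with small/large probe semantics.

    Grid points whose clearance from every atom surface exceeds ``probe_min``
    are cavity candidates; candidates reachable by a ``probe_max`` sphere
    rolled in from the bounding-box boundary are bulk solvent and removed.
    Of the remaining connected components the one containing (or nearest to)
    the seed point is measured; without a seed the largest component is taken.
    """
    if probe_min > probe_max:
        raise ValidationError("probe_min must not exceed probe_max")
    if grid_spacing > 1.0:
        raise ValidationError("grid_spacing must be <= 1.0 Å")
    coords, rads, _ = _atom_arrays(structure, include_waters, True, radii)
    if len(coords) == 0:
        warnings.warn("no atoms: all space is bulk solvent", stacklevel=2)
        return 0.0

    pad = rads.max() + probe_max + 2 * grid_spacing
    lo = coords.min(axis=0) - pad
    hi = coords.max(axis=0) + pad
    axes = [np.arange(lo[k], hi[k] + grid_spacing, grid_spacing) for k in range(3)]
    shape = tuple(len(ax) for ax in axes)
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)

    clearance = np.full(len(grid), np.inf)
    for r in np.unique(rads):
        tree = cKDTree(coords[rads == r])
        d, _ = tree.query(grid, k=1)
        clearance = np.minimum(clearance, d - r)
    clearance = clearance.reshape(shape)

    if seed_point is not None:
        seed_point = np.asarray(seed_point, dtype=float)
        seed_clear = np.inf
        for r in np.unique(rads):
            d = np.linalg.norm(coords[rads == r] - seed_point, axis=1).min()
            seed_clear = min(seed_clear, d - r)
        if seed_clear <= 0:
            raise SelectionError("seed point lies inside an atom")

    conn = np.ones((3, 3, 3), dtype=int)  # 26-connectivity
    open_min = clearance > probe_min
    open_max = clearance > probe_max

    labels_max, _ = ndimage.label(open_max, structure=conn)
    boundary_labels = set()
    for axis in range(3):
        for face in (0, -1):
            sl = [slice(None)] * 3
            sl[axis] = face
            boundary_labels.update(np.unique(labels_max[tuple(sl)]))
    boundary_labels.discard(0)
    bulk_centers = np.isin(labels_max, list(boundary_labels)) if boundary_labels else np.zeros(shape, bool)

    # everything a boundary-connected large probe can touch is bulk
    dist_to_bulk = ndimage.distance_transform_edt(~bulk_centers, sampling=grid_spacing)
    cavity = open_min & ~(dist_to_bulk <= probe_max)

    if not cavity.any():
        warnings.warn("no enclosed cavity found", stacklevel=2)
        return 0.0
    labels_cav, n_comp = ndimage.label(cavity, structure=conn)

    if seed_point is None:
        counts = np.bincount(labels_cav.ravel())[1:]
        target = int(np.argmax(counts)) + 1
    else:
        voxel = np.round((seed_point - lo) / grid_spacing).astype(int)
        voxel = np.clip(voxel, 0, np.array(shape) - 1)
        target = labels_cav[tuple(voxel)]
        if target == 0:
            cav_idx = np.argwhere(cavity)
            cav_xyz = lo + cav_idx * grid_spacing
            nearest = np.argmin(np.linalg.norm(cav_xyz - seed_point, axis=1))
            target = labels_cav[tuple(cav_idx[nearest])]
    return float((labels_cav == target).sum()) * grid_spacing**3
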