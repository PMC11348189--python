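"""Cα-only secondary-structure assignment (P-SEA-style geometric criteria).

Works from Cα distances, pseudo bond angles and pseudo dihedrals alone so
that backbone-only synthetic models and fully deposited models are treated
identically. Helices are nucleated where a 5-residue window satisfies the
helical distance pattern (or the angular pattern at its center) and then
extended outward while the per-residue distance pattern persists; strands are
handled analogously with extended-geometry bounds. Codes:

    H  helix (3-10 and pi folded into H)
    E  strand
    C  coil (modeled, neither of the above)
    D  disordered / missing (unmapped reference position or no Cα)
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import ValidationError
from .models import ResidueMap, Structure


@dataclass(frozen=True)
class SSParams:
    """Geometric thresholds for Cα secondary-structure assignment (Å / degrees)."""

    helix_d2: tuple[float, float] = (5.1, 6.4)  # d(i, i+2)
    helix_d3: tuple[float, float] = (4.2, 5.5)  # d(i, i+3)
    helix_alpha: tuple[float, float] = (30.0, 80.0)  # Cα dihedral at i
    helix_tau: tuple[float, float] = (85.0, 100.0)  # Cα bond angle at i
    strand_d2: tuple[float, float] = (6.7, 7.1)
    strand_d3: tuple[float, float] = (9.9, 10.7)
    min_helix_run: int = 5
    min_strand_run: int = 3
    chain_break: float = 4.5  # Å between consecutive Cα


DEFAULT_SS_PARAMS = SSParams()


def _in(value: float, bounds: tuple[float, float]) -> bool:
    return bounds[0] <= value <= bounds[1]


def _pairwise_gaps(coords: np.ndarray, chain_break: float) -> np.ndarray:
    """Boolean per bond i -> i+1: True when the bond is intact (no break, no gap)."""
    n = len(coords)
    intact = np.zeros(max(n - 1, 0), dtype=bool)
    for i in range(n - 1):
        if np.any(np.isnan(coords[i])) or np.any(np.isnan(coords[i + 1])):
            continue
        intact[i] = np.linalg.norm(coords[i + 1] - coords[i]) <= chain_break
    return intact


def _angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    v1, v2 = a - b, c - b
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def assign_ss(
    structure: Structure,
    chain_id: str,
    residue_map: ResidueMap,
    params: SSParams = DEFAULT_SS_PARAMS,
) -> str:
    """Assign one code per reference position from Cα geometry.

    Returns a string of length ``residue_map.reference_length`` over
    {H, E, C, D}; D exactly at positions with no mapped residue or no Cα.
    """
    coords = residue_map.ca_coordinates(structure)
    return assign_ss_from_coords(coords, params)


def assign_ss_from_coords(coords: np.ndarray, params: SSParams = DEFAULT_SS_PARAMS) -> str:
    n = len(coords)
    present = ~np.isnan(coords).any(axis=1)
    intact = _pairwise_gaps(coords, params.chain_break)

    def contiguous(i: int, j: int) -> bool:
        """Residues i..j (0-based, inclusive) all present and chain unbroken."""
        if i < 0 or j >= n:
            return False
        return present[i : j + 1].all() and intact[i:j].all()

    def d(i: int, j: int) -> float:
        return float(np.linalg.norm(coords[j] - coords[i]))

    # per-residue candidate patterns, forward-looking at i
    cand_h = np.zeros(n, dtype=bool)
    cand_e = np.zeros(n, dtype=bool)
    for i in range(n - 3):
        if not contiguous(i, i + 3):
            continue
        d2, d3 = d(i, i + 2), d(i, i + 3)
        cand_h[i] = _in(d2, params.helix_d2) and _in(d3, params.helix_d3)
        cand_e[i] = _in(d2, params.strand_d2) and _in(d3, params.strand_d3)

    # angular alternative for helix, centered at i (needs i-1 .. i+2)
    ang_h = np.zeros(n, dtype=bool)
    for i in range(1, n - 2):
        if not contiguous(i - 1, i + 2):
            continue
        alpha = _dihedral(coords[i - 1], coords[i], coords[i + 1], coords[i + 2])
        tau = _angle(coords[i - 1], coords[i], coords[i + 1])
        ang_h[i] = _in(alpha, params.helix_alpha) and _in(tau, params.helix_tau)

    def nucleate(cand: np.ndarray, ang: Optional[np.ndarray]) -> np.ndarray:
        """5-residue windows centered at j whose internal distances all qualify."""
        nuc = np.zeros(n, dtype=bool)
        for j in range(2, n - 2):
            if not contiguous(j - 2, j + 2):
                continue
            dist_ok = cand[j - 2] and cand[j - 1] and (
                # the window's third d2 pair (j, j+2); cand[j] would peek past it
                _in(d(j, j + 2), params.helix_d2 if ang is not None else params.strand_d2)
            )
            nuc[j] = dist_ok or (ang is not None and ang[j])
        return nuc

    def extend(nuc: np.ndarray, cand: np.ndarray) -> np.ndarray:
        """Grow each nucleus run while the per-residue pattern persists."""
        marked = nuc.copy()
        j = 0
        while j < n:
            if not nuc[j]:
                j += 1
                continue
            k = j
            while k + 1 < n and nuc[k + 1]:
                k += 1
            s, e = j, k
            while s - 1 >= 0 and cand[s - 1]:
                s -= 1
            while e + 1 < n and e - 2 >= 0 and cand[e - 2]:
                e += 1
            marked[s : e + 1] = True
            j = k + 1
        return marked

    helix = extend(nucleate(cand_h, ang_h), cand_h)
    strand = extend(nucleate(cand_e, None), cand_e) & ~helix

    codes = np.full(n, "C", dtype="U1")
    codes[~present] = "D"
    codes[helix & present] = "H"
    codes[strand & present] = "E"

    # demote runs shorter than the minimum lengths
    _demote_short_runs(codes, "H", params.min_helix_run)
    _demote_short_runs(codes, "E", params.min_strand_run)
    return "".join(codes)


def _demote_short_runs(codes: np.ndarray, code: str, min_run: int) -> None:
    n = len(codes)
    i = 0
    while i < n:
        if codes[i] != code:
            i += 1
            continue
        j = i
        while j + 1 < n and codes[j + 1] == code:
            j += 1
        if j - i + 1 < min_run:
            codes[i : j + 1] = "C"
        i = j + 1


def segment_helicity(ss: str, segment: tuple[int, int]) -> Optional[float]:
    """Fraction of helical positions among the modeled positions of a segment.

    ``segment`` is a 1-based inclusive reference interval. Returns None
    (undefined) when every position in the segment is disordered/missing.
    """
    a, b = segment
    if a > b:
        raise ValidationError(f"empty segment [{a},{b}]")
    if a < 1 or b > len(ss):
        raise ValidationError(f"segment [{a},{b}] outside reference length {len(ss)}")
    window = ss[a - 1 : b]
    modeled = sum(1 for c in window if c != "D")
    if modeled == 0:
        return None
    return sum(1 for c in window if c == "H") / modeled
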