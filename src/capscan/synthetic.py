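"""Synthetic ensembles, pLDDT profiles and active-site fixtures with known ground truth.

The generator emulates the structural signature of active-site capping: a
contiguous segment of the chain that is α-helical "in place" in one fraction
of ensemble members (folded state), entirely unresolved in another (unfolded
state), and rigidly displaced in a third (alternative, back-folded state).
Everything is seeded and bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import GenerationError, ValidationError
from .models import AtomRecord, PLDDTProfile, Residue, Structure

STATE_FOLDED = "folded"
STATE_UNFOLDED = "unfolded"
STATE_ALTERNATIVE = "alternative"

_AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

# textbook ideal alpha-helix Cα parameters
HELIX_RADIUS = 2.3  # Å
HELIX_RISE = 1.5  # Å per residue
HELIX_TWIST = 100.0  # degrees per residue

CA_BOND = 3.8  # Å, consecutive Cα-Cα distance


@dataclass
class EnsembleSpec:
    """Scenario parameters for one synthetic capping ensemble.

    Defaults mirror the study conditions: a ~550-residue chain whose
    residues 385-400 form the capping helix, with 23% folded / 69% unfolded /
    8% alternative members, an 8 Å rigid displacement of the alternative
    helix, and the first 39 residues unresolved in every member.
    """

    n_members: int = 100
    chain_length: int = 552
    event_segment: tuple[int, int] = (385, 400)
    state_fractions: tuple[float, float, float] = (0.23, 0.69, 0.08)
    displacement: float = 8.0
    missing_prefix: int = 39
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_members < 1:
            raise ValidationError("n_members must be >= 1")
        a, b = self.event_segment
        if not (1 <= a <= b <= self.chain_length):
            raise ValidationError(
                f"event_segment [{a},{b}] not within 1..{self.chain_length}"
            )
        f = self.state_fractions
        if len(f) != 3 or any(x < 0 for x in f):
            raise ValidationError("state_fractions must be three non-negative numbers")
        if abs(sum(f) - 1.0) > 1e-9:
            raise ValidationError(f"state_fractions sum to {sum(f)}, expected 1")
        if self.missing_prefix < 0 or self.missing_prefix >= a:
            raise ValidationError("missing_prefix must be >= 0 and end before the event segment")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")


@dataclass
class PlddtSpec:
    """Parameters for a synthetic pLDDT profile with a localized dip."""

    baseline: float = 90.0
    dip_depth: float = 5.0
    dip_segment: tuple[int, int] = (385, 400)
    noise_sigma: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline > 100:
            raise ValidationError("baseline must be <= 100")
        if self.baseline - self.dip_depth < 0:
            raise ValidationError("baseline - dip_depth must be >= 0")
        if self.dip_segment[0] > self.dip_segment[1]:
            raise ValidationError("dip_segment start must not exceed end")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")


@dataclass
class EnsembleResult:
    """Generated ensemble plus the planted ground truth."""

    members: list[Structure]
    labels: list[str]
    reference_sequence: str
    spec: EnsembleSpec
    state_counts: dict[str, int] = field(default_factory=dict)


def make_helix(n: int) -> np.ndarray:
    """Cα trace of an ideal α-helix (radius 2.3 Å, rise 1.5 Å, twist 100°/residue)."""
    if n < 1:
        raise ValidationError("helix length must be >= 1")
    i = np.arange(n)
    theta = np.deg2rad(HELIX_TWIST) * i
    return np.column_stack(
        [HELIX_RADIUS * np.cos(theta), HELIX_RADIUS * np.sin(theta), HELIX_RISE * i]
    )


def make_coil(
    n: int,
    seed: int,
    bond: float = CA_BOND,
    min_separation: float = 3.0,
    max_step_retries: int = 500,
    max_restarts: int = 50,
) -> np.ndarray:
    """Self-avoiding random Cα chain with fixed bond length.

    Each step takes a uniformly random direction, rejected while any
    non-adjacent Cα pair comes closer than ``min_separation``. Reproducible
    from the seed.
    """
    if n < 1:
        raise ValidationError("coil length must be >= 1")
    rng = np.random.default_rng(seed)
    for _ in range(max_restarts):
        coords = np.zeros((n, 3))
        ok = True
        for i in range(1, n):
            placed = False
            for _ in range(max_step_retries):
                v = rng.normal(size=3)
                v /= np.linalg.norm(v)
                cand = coords[i - 1] + bond * v
                if i >= 2:
                    d = np.linalg.norm(coords[: i - 1] - cand, axis=1)
                    if d.min() < min_separation:
                        continue
                coords[i] = cand
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            return coords
    raise GenerationError(
        f"could not generate a self-avoiding coil of length {n} "
        f"(min separation {min_separation} Å)"
    )


def largest_remainder_counts(fractions: tuple[float, ...], total: int) -> list[int]:
    """Integer counts summing to ``total`` via the largest-remainder rule."""
    quotas = [f * total for f in fractions]
    counts = [math.floor(q) for q in quotas]
    short = total - sum(counts)
    order = sorted(range(len(fractions)), key=lambda i: (-(quotas[i] - counts[i]), i))
    for i in order[:short]:
        counts[i] += 1
    return counts


def _reference_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(_AA_ALPHABET), size=length))


def _ca_structure(
    struct_id: str, sequence: str, coords: dict[int, np.ndarray]
) -> Structure:
    residues = [
        Residue(
            author_number=pos,
            aa=sequence[pos - 1],
            atoms=[AtomRecord(name="CA", element="C", coords=xyz)],
        )
        for pos, xyz in sorted(coords.items())
    ]
    return Structure(id=struct_id, chains={"A": residues})


def make_ensemble(spec: EnsembleSpec) -> EnsembleResult:
    """Generate a capping ensemble with planted state labels.

    All members share one scaffold conformation outside the event segment (up
    to isotropic Gaussian noise). Folded members carry an ideal helix centered
    on the scaffold segment; unfolded members have the segment residues
    missing entirely; alternative members carry the same helix rigidly
    translated by ``spec.displacement`` Å. The first ``missing_prefix``
    residues are absent in every member, emulating an unresolved N terminus.
    """
    rng = np.random.default_rng(spec.seed)
    a, b = spec.event_segment
    L = spec.chain_length
    sequence = _reference_sequence(L, rng)

    scaffold = make_coil(L, seed=int(rng.integers(2**31)))
    seg_idx = np.arange(a - 1, b)
    helix = make_helix(b - a + 1)
    helix = helix - helix.mean(axis=0) + scaffold[seg_idx].mean(axis=0)

    # displace the alternative helix away from the scaffold body
    body = np.delete(scaffold, seg_idx, axis=0)
    direction = scaffold[seg_idx].mean(axis=0) - body.mean(axis=0)
    norm = np.linalg.norm(direction)
    direction = direction / norm if norm > 1e-9 else np.array([0.0, 0.0, 1.0])

    counts = largest_remainder_counts(spec.state_fractions, spec.n_members)
    labels = (
        [STATE_FOLDED] * counts[0]
        + [STATE_UNFOLDED] * counts[1]
        + [STATE_ALTERNATIVE] * counts[2]
    )

    members = []
    for m, label in enumerate(labels):
        coords = scaffold.copy()
        if label == STATE_FOLDED:
            coords[seg_idx] = helix
        elif label == STATE_ALTERNATIVE:
            coords[seg_idx] = helix + spec.displacement * direction
        noise = rng.normal(scale=spec.noise_sigma, size=(L, 3)) if spec.noise_sigma > 0 else 0.0
        coords = coords + noise
        present = {
            pos: coords[pos - 1]
            for pos in range(spec.missing_prefix + 1, L + 1)
            if not (label == STATE_UNFOLDED and a <= pos <= b)
        }
        members.append(_ca_structure(f"member_{m:03d}", sequence, present))

    return EnsembleResult(
        members=members,
        labels=labels,
        reference_sequence=sequence,
        spec=spec,
        state_counts={
            STATE_FOLDED: counts[0],
            STATE_UNFOLDED: counts[1],
            STATE_ALTERNATIVE: counts[2],
        },
    )


def make_plddt(spec: PlddtSpec, chain_length: int) -> PLDDTProfile:
    """Synthetic pLDDT profile: noisy baseline with a localized dip."""
    rng = np.random.default_rng(spec.seed)
    values = np.full(chain_length, spec.baseline, dtype=float)
    a, b = spec.dip_segment
    values[a - 1 : b] -= spec.dip_depth
    if spec.noise_sigma > 0:
        values = values + rng.normal(scale=spec.noise_sigma, size=chain_length)
    values = np.clip(values, 0.0, 100.0)
    return PLDDTProfile(
        values={i + 1: float(v) for i, v in enumerate(values)},
        source=f"synthetic(seed={spec.seed})",
    )


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def make_cavity_shell(
    inner_radius: float = 6.0,
    atom_radius: float = 1.7,
    spacing: float = 1.0,
    center: tuple[float, float, float] = (0.0, 0.0, 0.0),
    struct_id: str = "shell",
) -> Structure:
    """Hollow spherical shell of dummy carbon atoms enclosing a cavity.

    Atom centers sit at ``inner_radius + atom_radius`` so the cavity's inner
    van-der-Waals surface is at ``inner_radius``; packing at ``spacing`` Å is
    dense enough that no probe can leak through. The enclosed volume has the
    closed form (4/3)π(inner_radius - probe_min)³, which makes the shell the
    analytic oracle for grid-based pocket-volume estimation.
    """
    r_c = inner_radius + atom_radius
    n = max(12, int(np.ceil(4 * np.pi * r_c**2 / spacing**2)))
    pts = np.asarray(center) + r_c * _fibonacci_sphere(n)
    shell = Residue(
        author_number=1,
        aa="SHL",
        is_het=True,
        atoms=[
            AtomRecord(name=f"D{i}", element="C", coords=p) for i, p in enumerate(pts)
        ],
    )
    return Structure(id=struct_id, chains={"A": [shell]})


def make_site_fixture(
    c1_c6_separation: float = 3.4,
    coordination_distances: tuple[float, ...] = (2.4, 2.8, 3.2),
    inner_radius: float = 6.0,
    ion_element: str = "K",
) -> Structure:
    """Pseudo active site: a cavity shell enclosing substrate carbons and an ion.

    Pseudo-atoms C1 and C6 sit at the given separation (default 3.4 Å, the
    compact distance characteristic of an acyclic intermediate); an ion is
    coordinated by water oxygens at the given distances (defaults spanning
    the 2.4-3.2 Å monovalent-cation range).
    """
    st = make_cavity_shell(inner_radius=inner_radius, struct_id="site_fixture")
    half = c1_c6_separation / 2.0
    lig = Residue(
        author_number=2,
        aa="LIG",
        is_het=True,
        atoms=[
            AtomRecord(name="C1", element="C", coords=(-half, 0.0, 0.0)),
            AtomRecord(name="C6", element="C", coords=(half, 0.0, 0.0)),
        ],
    )
    ion_pos = np.array([0.0, 1.5, 0.0])
    ion = Residue(
        author_number=3,
        aa=ion_element,
        is_het=True,
        atoms=[AtomRecord(name=ion_element, element=ion_element, coords=ion_pos)],
    )
    dirs = [np.array(d, dtype=float) for d in [(1, 0, 0), (0, 0, 1), (0, 1, 0), (-1, 0, 0), (0, 0, -1)]]
    waters = []
    for k, dist in enumerate(coordination_distances):
        waters.append(
            Residue(
                author_number=10 + k,
                aa="HOH",
                is_het=True,
                atoms=[AtomRecord(name="O", element="O", coords=ion_pos + dist * dirs[k % len(dirs)])],
            )
        )
    st.ligands.extend([("L", lig), ("L", ion)] + [("W", w) for w in waters])
    return st
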