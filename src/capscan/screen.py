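"""Capping screen: order matrix, folding-event calling, state assignment, pLDDT dip test.

The screen formalizes the disorder-to-order signature of active-site capping:
a reference segment that is helical in a sufficient fraction of ensemble
members *and* missing/disordered in a sufficient fraction is called a folding
event. Members are then assigned to three conformational states — folded
(helix in place), unfolded (segment disordered) and alternative (helix
present but rigidly displaced) — and a localized dip of the AlphaFold pLDDT
profile at the event is tested against a sliding-segment permutation null.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import DataError, ValidationError
from .geometry import segment_displacement, superpose
from .models import PLDDTProfile, ResidueMap, Structure
from .ss import DEFAULT_SS_PARAMS, SSParams, assign_ss, segment_helicity
from .synthetic import STATE_ALTERNATIVE, STATE_FOLDED, STATE_UNFOLDED

logger = logging.getLogger(__name__)


@dataclass
class OrderMatrix:
    """Residue x member matrix of order states: H (helix), O (ordered), D (disordered)."""

    matrix: np.ndarray  # (reference_length, n_members), dtype U1
    member_ids: list[str]

    @property
    def reference_length(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_members(self) -> int:
        return self.matrix.shape[1]


@dataclass
class FoldingEvent:
    """A contiguous reference segment undergoing a disorder-to-order transition."""

    segment: tuple[int, int]
    helical_members: float
    disordered_members: float
    mean_dip: Optional[float] = None
    p_value: Optional[float] = None
    near_active_site: Optional[bool] = None
    active_site_distance: Optional[float] = None

    @property
    def length(self) -> int:
        return self.segment[1] - self.segment[0] + 1


@dataclass
class StateAssignment:
    """Per-member conformational labels and ensemble state fractions."""

    labels: list[str]
    fractions: tuple[float, float, float]  # folded, unfolded, alternative
    displacement_threshold: float
    reference_member: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-12:
            raise ValidationError("state fractions must sum to 1")


@dataclass
class DipResult:
    """Localized pLDDT decrease at a segment versus its flanks."""

    delta: float  # mean pLDDT(segment) - mean pLDDT(flanks)
    p_value: float  # one-sided, sliding-segment permutation null
    n_perm: int
    seed: int

    def __post_init__(self) -> None:
        if not 0.0 < self.p_value <= 1.0:
            raise ValidationError("p-value must lie in (0,1]")


@dataclass(frozen=True)
class DetectionParams:
    """Thresholds of the folding-event caller.

    A position is event-positive when the fraction of members assigning it H
    is at least ``theta_h`` times the best per-position member support and the
    fraction with it disordered is at least ``theta_d``. Maximal positive runs
    separated by at most ``merge_gap`` positions are merged; merged runs
    shorter than ``min_length`` are dropped.
    """

    theta_h: float = 0.15
    theta_d: float = 0.15
    min_length: int = 5
    merge_gap: int = 2
    min_members: int = 4
    allow_small_ensemble: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.theta_h <= 1.0 and 0.0 < self.theta_d <= 1.0):
            raise ValidationError("theta_h and theta_d must lie in (0,1]")
        if self.min_length < 1:
            raise ValidationError("min_length must be >= 1")


@dataclass(frozen=True)
class StateParams:
    """Three-state assignment: helicity floor first, displacement second."""

    displacement_threshold: float = 4.0  # Å
    helicity_floor: float = 0.3
    core_margin: int = 5  # residues excluded around the event when superposing
    reference_member: Optional[int] = None


def build_order_matrix(
    ensemble: Sequence[Structure],
    maps: Sequence[ResidueMap],
    ss_params: SSParams = DEFAULT_SS_PARAMS,
) -> OrderMatrix:
    """Classify every (reference position, member) cell as H, O or D."""
    if len(ensemble) != len(maps):
        raise ValidationError("one residue map required per ensemble member")
    if not ensemble:
        raise ValidationError("empty ensemble")
    lengths = {m.reference_length for m in maps}
    if len(lengths) != 1:
        raise DataError(f"inconsistent reference lengths across members: {sorted(lengths)}")
    L = lengths.pop()
    matrix = np.full((L, len(ensemble)), "O", dtype="U1")
    for j, (st, rmap) in enumerate(zip(ensemble, maps)):
        ss = assign_ss(st, rmap.chain_id, rmap, ss_params)
        col = np.array(list(ss), dtype="U1")
        matrix[col == "H", j] = "H"
        matrix[col == "D", j] = "D"
    return OrderMatrix(matrix=matrix, member_ids=[s.id for s in ensemble])


def detect_folding_events(
    matrix: OrderMatrix, params: DetectionParams = DetectionParams()
) -> list[FoldingEvent]:
    """Call folding events from per-position helix/disorder member fractions."""
    n = matrix.n_members
    if n < 2:
        raise ValidationError("folding-event detection requires at least 2 ensemble members")
    if n < params.min_members:
        if not params.allow_small_ensemble:
            raise ValidationError(
                f"ensemble of {n} members below the minimum of {params.min_members}; "
                "set allow_small_ensemble=True to override"
            )
        warnings.warn(
            f"ensemble of {n} members below the recommended minimum "
            f"of {params.min_members}; detection may be unreliable",
            stacklevel=2,
        )

    f_h = (matrix.matrix == "H").mean(axis=1)
    f_d = (matrix.matrix == "D").mean(axis=1)
    support = 1.0 - f_d
    max_support = support.max() if len(support) else 0.0
    positive = (f_h >= params.theta_h * max_support) & (f_d >= params.theta_d) & (f_h > 0)

    runs = _runs(positive)
    merged: list[list[int]] = []
    for a, b in runs:
        if merged and a - merged[-1][1] - 1 <= params.merge_gap:
            merged[-1][1] = b
        else:
            merged.append([a, b])

    events = []
    for a, b in merged:
        if b - a + 1 < params.min_length:
            continue
        seg = matrix.matrix[a : b + 1]
        n_pos = seg.shape[0]
        frac_d_per_member = (seg == "D").sum(axis=0) / n_pos
        disordered = frac_d_per_member > 0.5
        n_h = (seg == "H").sum(axis=0)
        n_modeled = n_pos - (seg == "D").sum(axis=0)
        with np.errstate(invalid="ignore"):
            helicity = np.where(n_modeled > 0, n_h / np.maximum(n_modeled, 1), 0.0)
        helical = (~disordered) & (helicity >= 0.5)
        events.append(
            FoldingEvent(
                segment=(a + 1, b + 1),
                helical_members=float(helical.sum()) / n,
                disordered_members=float(disordered.sum()) / n,
            )
        )
    logger.info("detected %d folding event(s)", len(events))
    return events


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as 0-based inclusive (start, end) pairs."""
    runs = []
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(mask) - 1))
    return runs


def classify_states(
    ensemble: Sequence[Structure],
    maps: Sequence[ResidueMap],
    event: FoldingEvent,
    params: StateParams = StateParams(),
    ss_params: SSParams = DEFAULT_SS_PARAMS,
) -> StateAssignment:
    """Assign each member to folded / unfolded / alternative for one event.

    A member whose event-segment helicity is undefined (all missing) or below
    the helicity floor is unfolded. Remaining members are folded when the
    segment's mean Cα displacement from the reference placement (after
    superposition on the shared core outside the event) is below the
    displacement threshold, otherwise alternative. The reference placement is
    the modal one: segment centroids of all helical members are clustered in
    a common frame and the largest cluster defines "in place".
    """
    if not ensemble:
        raise ValidationError("empty ensemble")
    a, b = event.segment
    helicities = []
    for st, rmap in zip(ensemble, maps):
        ss = assign_ss(st, rmap.chain_id, rmap, ss_params)
        helicities.append(segment_helicity(ss, (a, b)))

    helical_idx = [
        i for i, h in enumerate(helicities) if h is not None and h >= params.helicity_floor
    ]
    L = maps[0].reference_length
    core = [p for p in range(1, L + 1) if p < a - params.core_margin or p > b + params.core_margin]

    if params.reference_member is not None:
        ref = params.reference_member
        if ref not in helical_idx:
            raise ValidationError(
                f"reference member {ref} is not helical over the event segment"
            )
    elif helical_idx:
        ref = _modal_reference(ensemble, maps, helical_idx, (a, b), core, params)
    else:
        ref = None

    labels = []
    for i, h in enumerate(helicities):
        if i not in helical_idx:
            labels.append(STATE_UNFOLDED)
            continue
        mean_disp, _ = segment_displacement(
            ensemble[ref], ensemble[i], maps[ref], maps[i], (a, b), core=core
        )
        if mean_disp is None:
            labels.append(STATE_UNFOLDED)
        elif mean_disp < params.displacement_threshold:
            labels.append(STATE_FOLDED)
        else:
            labels.append(STATE_ALTERNATIVE)

    n = len(labels)
    if all(lbl == STATE_UNFOLDED for lbl in labels) and not helical_idx and n == 0:
        raise DataError("no member classifiable")
    fractions = (
        labels.count(STATE_FOLDED) / n,
        labels.count(STATE_UNFOLDED) / n,
        labels.count(STATE_ALTERNATIVE) / n,
    )
    return StateAssignment(
        labels=labels,
        fractions=fractions,
        displacement_threshold=params.displacement_threshold,
        reference_member=ref if ref is not None else -1,
    )


def _modal_reference(
    ensemble: Sequence[Structure],
    maps: Sequence[ResidueMap],
    helical_idx: list[int],
    segment: tuple[int, int],
    core: list[int],
    params: StateParams,
) -> int:
    """Pick the helical member whose segment placement is the ensemble mode."""
    a, b = segment
    frame = helical_idx[0]
    frame_coords = maps[frame].ca_coordinates(ensemble[frame])
    centroids: dict[int, np.ndarray] = {}
    for i in helical_idx:
        coords = maps[i].ca_coordinates(ensemble[i])
        shared = [
            p for p in core
            if not np.isnan(coords[p - 1]).any() and not np.isnan(frame_coords[p - 1]).any()
        ]
        if len(shared) < 3:
            continue
        idx = np.array(shared) - 1
        tr = superpose(coords[idx], frame_coords[idx])
        seg_mask = ~np.isnan(coords[a - 1 : b]).any(axis=1)
        if not seg_mask.any():
            continue
        seg = tr.apply(coords[a - 1 : b][seg_mask])
        centroids[i] = seg.mean(axis=0)

    clusters: list[list[int]] = []
    for i, c in centroids.items():
        for cluster in clusters:
            if np.linalg.norm(c - centroids[cluster[0]]) < params.displacement_threshold:
                cluster.append(i)
                break
        else:
            clusters.append([i])
    if not clusters:
        return helical_idx[0]
    clusters.sort(key=lambda cl: (-len(cl), cl[0]))
    return clusters[0][0]


def plddt_dip_test(
    profile: PLDDTProfile,
    segment: tuple[int, int],
    flank_width: int = 15,
    n_perm: int = 999,
    seed: int = 0,
) -> DipResult:
    """Permutation test for a localized pLDDT decrease at a segment.

    The statistic is mean pLDDT inside the segment minus the mean over two
    flanks of ``flank_width`` residues (truncated at chain ends). The null
    distribution slides a segment of the same length to uniformly random
    non-overlapping positions; the one-sided p-value for a *decrease* uses
    the add-one correction p = (1 + #{null <= observed}) / (n_perm + 1).
    """
    if n_perm < 99:
        raise ValidationError("n_perm must be >= 99")
    values = profile.as_array()
    L = len(values)
    a, b = segment
    length = b - a + 1
    if a < 1 or b > L:
        raise ValidationError(f"segment [{a},{b}] outside profile of length {L}")
    if length > L - 2:
        raise ValidationError("segment must leave at least two flank positions")

    finite = np.isfinite(values)
    csum = np.concatenate([[0.0], np.cumsum(np.where(finite, values, 0.0))])
    ccnt = np.concatenate([[0], np.cumsum(finite.astype(int))])

    def stat(starts: np.ndarray) -> np.ndarray:
        s0 = starts - 1  # 0-based segment start
        seg_sum = csum[s0 + length] - csum[s0]
        seg_cnt = ccnt[s0 + length] - ccnt[s0]
        lo = np.maximum(s0 - flank_width, 0)
        hi = np.minimum(s0 + length + flank_width, L)
        fl_sum = (csum[s0] - csum[lo]) + (csum[hi] - csum[s0 + length])
        fl_cnt = (ccnt[s0] - ccnt[lo]) + (ccnt[hi] - ccnt[s0 + length])
        with np.errstate(invalid="ignore", divide="ignore"):
            return seg_sum / seg_cnt - fl_sum / fl_cnt

    observed = float(stat(np.array([a]))[0])
    if not np.isfinite(observed):
        raise DataError("profile does not cover the segment and/or its flanks")

    valid = np.array(
        [s for s in range(1, L - length + 2) if s + length - 1 < a or s > b], dtype=int
    )
    if len(valid) == 0:
        raise DataError("no non-overlapping null placements available")
    rng = np.random.default_rng(seed)
    starts = rng.choice(valid, size=n_perm, replace=True)
    null = stat(starts)
    p = (1 + int(np.sum(null[np.isfinite(null)] <= observed))) / (n_perm + 1)
    return DipResult(delta=observed, p_value=p, n_perm=n_perm, seed=seed)


def flag_active_site_proximity(
    events: Sequence[FoldingEvent],
    structure: Structure,
    residue_map: ResidueMap,
    site_coords: np.ndarray,
    cutoff: float = 10.0,
) -> None:
    """Annotate events in place with the minimum Cα distance to a set of site atoms."""
    site = np.atleast_2d(np.asarray(site_coords, dtype=float))
    coords = residue_map.ca_coordinates(structure)
    for ev in events:
        a, b = ev.segment
        seg = coords[a - 1 : b]
        seg = seg[~np.isnan(seg).any(axis=1)]
        if len(seg) == 0:
            continue
        d = np.linalg.norm(seg[:, None, :] - site[None, :, :], axis=2).min()
        ev.active_site_distance = float(d)
        ev.near_active_site = bool(d <= cutoff)
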