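"""Shared test utilities."""

import copy

import numpy as np


def random_rigid_transform(seed):
    from scipy.spatial.transform import Rotation

    rng = np.random.default_rng(seed)
    R = Rotation.random(random_state=rng).as_matrix()
    t = rng.uniform(-50, 50, size=3)
    return R, t


def apply_rigid(structure, R, t):
    """Deep-copied structure with every atom rigidly transformed."""
    moved = copy.deepcopy(structure)
    for _, _, atom in moved.iter_atoms():
        atom.coords = R @ atom.coords + t
    return moved
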