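import pytest

import capscan as cs


@pytest.fixture(scope="session")
def planted():
    """Noise-free 100-member ensemble at the study conditions (23/69/8%,
    event 385-400, 8 Å displacement, 39 missing N-terminal residues)."""
    spec = cs.EnsembleSpec(seed=1)
    result = cs.make_ensemble(spec)
    maps = [cs.map_to_reference(st, "A", result.reference_sequence) for st in result.members]
    return result, maps


@pytest.fixture(scope="session")
def planted_matrix(planted):
    result, maps = planted
    return cs.build_order_matrix(result.members, maps)


@pytest.fixture(scope="session")
def small_ensemble():
    """Quick 10-member ensemble with a short chain for cheap unit tests."""
    spec = cs.EnsembleSpec(
        n_members=10,
        chain_length=80,
        event_segment=(30, 45),
        state_fractions=(0.5, 0.5, 0.0),
        displacement=8.0,
        missing_prefix=0,
        seed=4,
    )
    result = cs.make_ensemble(spec)
    maps = [cs.map_to_reference(st, "A", result.reference_sequence) for st in result.members]
    return result, maps


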