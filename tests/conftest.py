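from __future__ import annotations

import numpy as np
import pytest

from kinpocket import (
    Atom,
    AtomSelection,
    FrameSeries,
    SyntheticSpec,
    Topology,
    generate,
)

_ELEMENT_MASS = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
                 "F": 18.998, "Cl": 35.45, "S": 32.06}


def make_topology(elements, res_ids=None, res_names=None, names=None,
                  chain="X"):
    """Build a minimal topology from an element list (test scaffolding)."""
    n = len(elements)
    atoms = [
        Atom(
            name=(names[i] if names else f"{elements[i]}{i}"),
            element=elements[i],
            mass=_ELEMENT_MASS[elements[i]],
            res_name=(res_names[i] if res_names else "UNK"),
            res_id=(res_ids[i] if res_ids else i + 1),
            chain_id=chain,
        )
        for i in range(n)
    ]
    return Topology(atoms)


@pytest.fixture
def topo_factory():
    return make_topology


def selection(indices, label="sel"):
    return AtomSelection(label=label, indices=np.asarray(indices, dtype=int))


@pytest.fixture
def sel_factory():
    return selection


@pytest.fixture(scope="session")
def small_scene():
    """A 300-frame synthetic scene with all components planted."""
    spec = SyntheticSpec(n_frames=300, seed=11)
    spec.hydration.schedule = [
        (0, 80, 1001), (80, 150, 1002), (200, 260, 1003)
    ]
    topology, frames, truth = generate(spec)
    return spec, topology, frames, truth
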