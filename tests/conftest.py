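"""Shared fixtures: small phantom cases and a reusable synthetic dataset.

Everything is generated programmatically at test time; session scope is
used for the expensive artifacts (a full phantom case with reference
dose, and the training dataset shared by the end-to-end tests).
"""

from __future__ import annotations

import numpy as np
import pytest

from cyberbeam.beams import encode
from cyberbeam.grid import StructureRole, VolumeGrid
from cyberbeam.rtio import CaseBundle
from cyberbeam.synthetic import (
    DoseEngineParams,
    PhantomSpec,
    RingSpec,
    analytic_dose,
    make_dataset,
    make_phantom,
    make_plan,
    make_rings,
    random_phantom_spec,
)


@pytest.fixture()
def unit_grid() -> VolumeGrid:
    """A small 2 mm isotropic grid centered on the origin."""
    shape = (20, 20, 20)
    spacing = np.array([2.0, 2.0, 2.0])
    origin = -(np.array(shape) - 1) * spacing / 2
    return VolumeGrid(np.zeros(shape, dtype=np.float32), origin, spacing)


@pytest.fixture(scope="session")
def phantom_case() -> dict:
    """One complete synthetic case: CT, structures, rings, plan, dose, beam."""
    spec = random_phantom_spec(7, shape=(48, 48, 32), spacing=(3.5, 3.5, 3.5))
    ct, structures = make_phantom(spec)
    rings = make_rings(structures.target, ct, RingSpec())
    for name, mask in rings.items():
        structures.add(name, mask, StructureRole.RING)
    plan = make_plan(structures.target, ct, n_beams=25, seed=3, prescription=24.0)
    dose = analytic_dose(plan, ct, structures.target, DoseEngineParams())
    beam = encode(plan, ct, structures.target)
    bundle = CaseBundle(ct=ct, structures=structures, plan=plan, dose=dose)
    return {"bundle": bundle, "beam": beam, "spec": spec}


@pytest.fixture(scope="session")
def dataset_dir(tmp_path_factory):
    """The desk-scale study dataset: 8 cases split 5/1/2 at default size."""
    out = tmp_path_factory.mktemp("dataset") / "ds"
    make_dataset(out, n_cases=8, split=(5, 1, 2), seed=1)
    return out
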