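"""Shared fixtures: synthetic chains and clans built at test time."""

from __future__ import annotations

import numpy as np
import pytest

from corecluster import SyntheticSpec, generate_clan
from corecluster.structure_io import STANDARD_AA, ResidueRecord, StructureModel
from corecluster.synthetic_data import _self_avoiding_trace


def make_trace_model(
    n: int, seed: int, *, noise: float = 0.0, model_id: str = "M", sequence: str | None = None
) -> StructureModel:
    """A single self-avoiding chain with a random (or given) sequence."""
    rng = np.random.default_rng(seed)
    xyz = _self_avoiding_trace(n, rng)
    if sequence is None:
        sequence = "".join(STANDARD_AA[i] for i in rng.integers(20, size=n))
    if noise:
        xyz = xyz + rng.normal(scale=noise, size=xyz.shape)
    return StructureModel(
        model_id,
        [
            ResidueRecord("A", i + 1, "", sequence[i], tuple(xyz[i]))
            for i in range(n)
        ],
    )


def perturbed_copy(model: StructureModel, sigma: float, seed: int, model_id: str = "P") -> StructureModel:
    rng = np.random.default_rng(seed)
    xyz = model.ca_coords + rng.normal(scale=sigma, size=(len(model), 3))
    return StructureModel(
        model_id,
        [
            ResidueRecord("A", r.res_seq, r.icode, r.aa, tuple(xyz[i]))
            for i, r in enumerate(model.residues)
        ],
    )


@pytest.fixture(scope="session")
def default_clan():
    """The default synthetic clan (4 families x 4 members, core 60), seed 1."""
    return generate_clan(SyntheticSpec(seed=1))


@pytest.fixture(scope="session")
def small_clan():
    """A cheaper clan for pipeline-level tests: 2 families x 3 members."""
    spec = SyntheticSpec(
        seed=2, n_families=2, members_per_family=3, core_length=40, n_decorations=1
    )
    return generate_clan(spec)
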