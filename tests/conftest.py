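"""Shared fixtures: planted toy ensembles and constructed geometries."""

from __future__ import annotations

import numpy as np
import pytest

import pocketshaper as ps
from pocketshaper.synthetic import PlantedContact

# the six pocket residues planted persistent in both wells, plus decoys
HOTSPOT_PLAN = (
    (3, "hbond"),
    (5, "hydrophobic"),
    (8, "hbond"),
    (9, "hydrophobic"),
    (12, "hbond"),
    (21, "hydrophobic"),
)
DECOY_PLAN = ((11, "hydrophobic"), (13, "hbond"))


def planted_contacts(
    hot_freqs=(0.85, 0.75), decoy_freq=0.30
) -> list[PlantedContact]:
    out = []
    for rn, typ in HOTSPOT_PLAN:
        for basin, f in enumerate(hot_freqs):
            out.append(PlantedContact(("A", rn), typ, basin, f))
    for rn, typ in DECOY_PLAN:
        for basin in range(len(hot_freqs)):
            out.append(PlantedContact(("A", rn), typ, basin, decoy_freq))
    return out


@pytest.fixture(scope="session")
def planted_ensemble():
    """600-frame two-basin ensemble with planted hotspots, decoys and a
    30% within-basin pre-reaction-state rate."""
    spec = ps.synthetic.default_two_basin_spec(
        n_frames=600,
        occupancies=(0.7, 0.3),
        planted_contacts=planted_contacts(),
        planted_prs=(0, 0.30),
        seed=11,
    )
    return ps.synthetic.generate_two_basin_ensemble(spec)


@pytest.fixture(scope="session")
def toy_topology():
    return ps.synthetic.toy_topology()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
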