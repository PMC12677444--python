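"""Shared fixtures: phantoms are generated once per session at reduced size."""

from __future__ import annotations

import dataclasses

import pytest

from panomatch.phantom import PhantomSpec, generate_phantom
from panomatch.presets import COHORT_MATCH, COHORT_RECON, COHORT_SPEC


@pytest.fixture(scope="session")
def recon_settings():
    return COHORT_RECON


@pytest.fixture(scope="session")
def match_config():
    return COHORT_MATCH


@pytest.fixture(scope="session")
def fixture_spec():
    return dataclasses.replace(COHORT_SPEC, identity_id="fixture", rng_seed=7)


@pytest.fixture(scope="session")
def fixture_phantom(fixture_spec):
    """Untilted, no-overlap, restoration-free reference subject."""
    return generate_phantom(fixture_spec, reference_settings=COHORT_RECON)


@pytest.fixture(scope="session")
def tilted_phantom(fixture_spec):
    """The same dentition tilted 5 degrees about the left-right axis."""
    spec = dataclasses.replace(fixture_spec, head_tilt_deg=5.0)
    return generate_phantom(spec, reference_settings=COHORT_RECON)
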