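"""Shared fixtures: synthetic genomes and end-to-end scenario runs.

Expensive simulations are session-scoped so several tests can interrogate
the same run.  All randomness is seeded; the suite is deterministic.
"""

from __future__ import annotations

import dataclasses

import pytest

from ligbias.experiment import STANDARD_SCENARIOS, run_scenario
from ligbias.simgenome import generate_reference


@pytest.fixture(scope="session")
def equal_genome():
    """200 kb genome with all four bases at 25%."""
    return generate_reference(200_000, 0.5, seed=101, name="eq")


@pytest.fixture(scope="session")
def gcrich_genome():
    """200 kb genome at GC 0.508 (T fraction ~24.6%)."""
    return generate_reference(200_000, 0.508, seed=202, name="gc508")


@pytest.fixture(scope="session")
def ancient_at_report():
    """Degraded-DNA scenario under AT-overhang chemistry (truth mapping)."""
    cfg = dataclasses.replace(
        STANDARD_SCENARIOS["ancient-AT"], n_fragments=20_000, mapping="truth", seed=7
    )
    return run_scenario(cfg)


@pytest.fixture(scope="session")
def ancient_be_report():
    """Degraded-DNA scenario under blunt-end chemistry (truth mapping)."""
    cfg = dataclasses.replace(
        STANDARD_SCENARIOS["ancient-BE"], n_fragments=20_000, mapping="truth", seed=7
    )
    return run_scenario(cfg)


@pytest.fixture(scope="session")
def null_report():
    """Fresh DNA, uniform fragmentation, blunt-end chemistry: the no-bias null."""
    cfg = dataclasses.replace(
        STANDARD_SCENARIOS["fresh-BE"],
        name="null",
        cleavage="uniform",
        n_fragments=20_000,
        mapping="truth",
        seed=7,
    )
    return run_scenario(cfg)
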