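"""Shared fixtures: small simulated studies reused across test modules."""
from __future__ import annotations

import logging

import numpy as np
import pytest
from hypothesis import settings

from vnarpan import simulate as sim
from vnarpan.pools import INPUT_POOL, PoolId

logging.disable(logging.WARNING)

settings.register_profile("reproducible", deadline=None, derandomize=True)
settings.load_profile("reproducible")


ROUND3_POOLS = [PoolId(c, 3) for c in "NLSUH"]


@pytest.fixture(scope="session")
def small_scenario() -> sim.PanningScenario:
    """A reduced study scenario (150 background clones) for unit tests."""
    return sim.reference_scenario(11, n_background=150)


@pytest.fixture(scope="session")
def small_ledger(small_scenario) -> sim.GroundTruthLedger:
    ledger = sim.run_panning(small_scenario)
    sim.sequence_pools(ledger, 3000, [INPUT_POOL, *ROUND3_POOLS])
    return ledger


@pytest.fixture(scope="session")
def clean_channel_ledger() -> sim.GroundTruthLedger:
    """Small study sequenced through a lossless channel (no errors, no
    truncation): the pipeline must reproduce the ledger exactly."""
    scenario = sim.reference_scenario(12, n_background=150)
    scenario.error_rate = 0.0
    scenario.short_read_fraction = 0.0
    ledger = sim.run_panning(scenario)
    sim.sequence_pools(ledger, 3000, [INPUT_POOL, PoolId("N", 3), PoolId("L", 3)])
    return ledger


def planted_cdr3s(scenario: sim.PanningScenario) -> dict[str, str]:
    by_id = {c.clone_id: c.cdr3 for c in scenario.clones}
    return {cond: by_id[cid] for cond, cid in scenario.planted.items()}


@pytest.fixture(scope="session")
def clean_read(small_scenario) -> tuple[str, str]:
    """One error-free amplicon read (id, sequence) from the small scenario."""
    from vnarpan import _codec

    codes = small_scenario.clone_read_codes(0)
    return "clean:0", _codec.decode_codes(codes).decode("ascii")
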