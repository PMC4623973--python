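"""Shared fixtures: preset models and session-scoped pH-REMD runs.

The REMD runs are the expensive ingredient (a second or two each), so every
test that needs sampled data shares these ledgers instead of re-simulating.
"""

from __future__ import annotations

import numpy as np
import pytest

import protolink as pl

KT_LN10_300K = pl.ThermoParams().kT_ln10  # ~1.37271 kcal/mol


@pytest.fixture(scope="session")
def asp_model():
    return pl.make_preset_model("single_site(Asp)")


@pytest.fixture(scope="session")
def dyad_model():
    return pl.make_preset_model("coupled_dyad")


@pytest.fixture(scope="session")
def bace_pair():
    return pl.make_preset_pair("bace_like")


@pytest.fixture(scope="session")
def asp_remd(asp_model):
    ledger, stats = pl.run_ph_remd(asp_model, schedule=pl.MCSchedule(seed=11))
    return ledger, stats


@pytest.fixture(scope="session")
def dyad_remd(dyad_model):
    ledger, stats = pl.run_ph_remd(dyad_model, schedule=pl.MCSchedule(seed=12))
    return ledger, stats


@pytest.fixture(scope="session")
def dyad_remd_no_exchange(dyad_model):
    ledger, _ = pl.run_ph_remd(
        dyad_model, schedule=pl.MCSchedule(seed=13), exchange=False
    )
    return ledger


@pytest.fixture(scope="session")
def bace_apo_remd(bace_pair):
    apo, _ = bace_pair
    ledger, stats = pl.run_ph_remd(apo, schedule=pl.MCSchedule(seed=14))
    return ledger, stats


@pytest.fixture(scope="session")
def bace_holo_remd(bace_pair):
    _, holo = bace_pair
    ledger, stats = pl.run_ph_remd(holo, schedule=pl.MCSchedule(seed=15))
    return ledger, stats


@pytest.fixture(scope="session")
def oracle_grid():
    """Dense pH grid for exact-fraction profiles (interpolation-limited checks)."""
    return np.round(np.arange(1.0, 12.0 + 1e-9, 0.125), 6)


def exact_curves(model, grid):
    """Exact titration curves for every site of an enumerable model."""
    dists = [pl.enumerate_states(model, p) for p in grid]
    curves = []
    for sid in model.site_ids:
        s = np.array([d.site_fraction_deprotonated(sid) for d in dists])
        curves.append(pl.TitrationCurve(sid, np.asarray(grid, float), s))
    return curves
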