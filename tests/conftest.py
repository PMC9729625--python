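"""Shared fixtures: small synthetic runs and a session-scoped trained model."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from glyquant.matchnet import mine_training_pairs, train
from glyquant.model import GPSM, Run, Scan
from glyquant.synthio import SimSpec, make_replicates, random_inventory, simulate_run


@pytest.fixture(scope="session")
def small_run_bundle():
    """One noisy 10-glycopeptide run with identifications and truth."""
    rng = np.random.default_rng(101)
    inventory = random_inventory(10, rng)
    run, ids, truth = simulate_run(
        SimSpec(inventory=inventory, seed=101), run_id="small"
    )
    return run, ids, truth


@pytest.fixture(scope="session")
def trained_model_bundle():
    """A compact trained matching model plus its training runs.

    Mined from six replicate runs of a 120-glycopeptide inventory; enough to
    separate genuine evidence pairs from offset/noise pairs, small enough to
    train in seconds.
    """
    runs, ids, _ = make_replicates(130, n_runs=6, seed=77)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pairs = mine_training_pairs(runs, ids, n_pos=500, n_neg=500, seed=77)
    model = train(pairs, epochs=25, seed=77)
    return model, pairs, runs, ids


@pytest.fixture(scope="session")
def trained_model(trained_model_bundle):
    return trained_model_bundle[0]


def make_scan(mz, intensity, rt=1.0, scan_id="s1", ms_level=1):
    return Scan(
        scan_id=scan_id,
        ms_level=ms_level,
        rt=rt,
        mz=np.asarray(mz, dtype=float),
        intensity=np.asarray(intensity, dtype=float),
    )


def make_profile_run(profile, isotope_mzs, rt_step=1.0, run_id="profile"):
    """A run whose summed-isotope profile equals `profile` at each scan.

    Intensity is placed entirely on the first isotopologue m/z so the mono
    trace equals the profile.
    """
    scans = []
    for i, value in enumerate(profile):
        if value > 0:
            mz = [isotope_mzs[0]]
            inten = [float(value)]
        else:
            mz, inten = [], []
        scans.append(
            Scan(
                scan_id=f"{run_id}.{i}",
                ms_level=1,
                rt=i * rt_step,
                mz=np.asarray(mz, dtype=float),
                intensity=np.asarray(inten, dtype=float),
            )
        )
    return Run(run_id=run_id, scans=scans)


def simple_gpsm(**overrides):
    defaults = dict(
        run_id="run1",
        spectrum_ref="run1.1",
        peptide="AJSSEK",
        modifications=[],
        glycan_composition={"Hex": 5, "HexNAc": 4},
        glycosite=2,
        charge=2,
        precursor_mz=0.0,
        precursor_mass=0.0,
        rt=10.0,
        protein="P1",
    )
    defaults.update(overrides)
    if not defaults["precursor_mass"]:
        from glyquant.constants import PROTON_MASS
        from glyquant.isotope import glycopeptide_formula, monoisotopic_mass

        mass = monoisotopic_mass(
            glycopeptide_formula(
                defaults["peptide"],
                defaults["modifications"],
                defaults["glycan_composition"],
            )
        )
        defaults["precursor_mass"] = mass
        defaults["precursor_mz"] = mass / defaults["charge"] + PROTON_MASS
    return GPSM(**defaults)
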