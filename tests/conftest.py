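"""Shared fixtures: a small designed library and one simulated assay.

Session-scoped so the simulation cost is paid once; all tests that need
stall profiles reuse the same seeded run.
"""

import numpy as np
import pytest

from strstall.kinetics import build_stall_profiles
from strstall.library import LibraryEntry, design_controls
from strstall.simulate import sample_ground_truth, simulate_counts

SEED = 20_260_924 % (2**31)


def _small_library(n_random=60, n_hairpin=50, n_g4=50, n_imot=50):
    return design_controls(
        n_hairpin=n_hairpin, n_g4=n_g4, n_imot=n_imot, n_random=n_random, seed=7
    )


@pytest.fixture(scope="session")
def control_library():
    return _small_library()


@pytest.fixture(scope="session")
def assay_run(control_library):
    """Ground truth, counts and stall profiles for the small library."""
    truths = sample_ground_truth(control_library, seed=SEED)
    counts = simulate_counts(truths, depth=10_000, replicates=2, seed=SEED)
    controls = [e.entry_id for e in control_library if e.category == "RANDOM"]
    profiles = build_stall_profiles(counts, controls)
    return {
        "entries": control_library,
        "truths": {t.entry_id: t for t in truths},
        "counts": counts,
        "profiles": profiles,
    }
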