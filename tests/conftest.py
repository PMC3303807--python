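"""Shared fixtures: scaled synthetic wells and independent oracles.

Tests run on dimensionally scaled-down wells (256 x 256 px fields at
the standard 1.6 um/px, ~200-cell colonies at full-assay cell density)
so the whole suite stays fast while exercising the identical code
paths as full-size plates.
"""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import cKDTree

from emtscreen import ColonySpec, simulate_well
from emtscreen.simulate import scaled_render


def sp_bruteforce(positions):
    """Independent brute-force spreading coefficient (explicit loops)."""
    xs = [p[0] for p in positions]
    ys = [p[1] for p in positions]
    n = len(xs)
    mx = sum(xs) / n
    my = sum(ys) / n
    acc = 0.0
    for x, y in zip(xs, ys):
        acc += (x - mx) ** 2 + (y - my) ** 2
    return (acc / n) ** 0.5


def one_to_one_matches(detected_um, true_um, tol_um=8.0):
    """Greedy one-to-one nearest matching; returns the number of matches."""
    detected_um = np.asarray(detected_um, dtype=float).reshape(-1, 2)
    true_um = np.asarray(true_um, dtype=float).reshape(-1, 2)
    if len(detected_um) == 0 or len(true_um) == 0:
        return 0
    tree = cKDTree(detected_um)
    k = min(3, len(detected_um))
    d, j = tree.query(true_um, k=k)
    d = d.reshape(len(true_um), -1)
    j = j.reshape(len(true_um), -1)
    cand = sorted(
        (d[t, i], t, j[t, i])
        for t in range(len(true_um))
        for i in range(d.shape[1])
        if d[t, i] <= tol_um
    )
    used_t, used_d, n = set(), set(), 0
    for _, t, di in cand:
        if t in used_t or di in used_d:
            continue
        used_t.add(t)
        used_d.add(di)
        n += 1
    return n


@pytest.fixture(scope="session")
def render_small():
    return scaled_render()


@pytest.fixture(scope="session")
def colony_small(render_small):
    cx = render_small.montage_extent_um[0] / 2
    return ColonySpec(n_cells=200, center=(cx, cx), target_sp=110.0)


@pytest.fixture(scope="session")
def simulated_well(colony_small, render_small):
    """One dispersed (negative-control-like) well, reused across tests."""
    return simulate_well(colony_small, render_small, seed=5, well_id="B02")


@pytest.fixture(scope="session")
def mini_plate_layout():
    rows = [
        ("P1", "A01", "negative_control", "DMSO", 0.0, "EGF"),
        ("P1", "B01", "negative_control", "DMSO", 0.0, "EGF"),
        ("P1", "A02", "test", "CPD_A", 1.67e-6, "EGF"),
        ("P1", "A03", "test", "CPD_A", 6.67e-6, "EGF"),
        ("P1", "A04", "test", "CPD_B", 1.67e-6, "EGF"),
        ("P1", "A05", "test", "CPD_B", 6.67e-6, "EGF"),
        ("P1", "A12", "positive_control", "REF", 6.67e-6, "EGF"),
        ("P1", "B12", "positive_control", "REF", 6.67e-6, "EGF"),
    ]
    return pd.DataFrame(
        rows,
        columns=["plate", "well", "role", "compound_id", "concentration", "growth_factor"],
    )
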