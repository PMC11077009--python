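"""Cluster statistics against brute-force oracles; thresholding contracts."""

import numpy as np
import pytest

from stresschains.fields import ScalarField2D
from stresschains.percolation import (DegenerateFieldError, OccupancyGrid,
                                      average_cluster_size, correlation_length,
                                      label_clusters, percolation_curves,
                                      spanning_density, threshold_field)


# ------------------------------------------------------------- brute oracle

def flood_fill_labels(occ, connectivity):
    """O(n^2)-style BFS labeling oracle, independent of scipy."""
    if connectivity == "face4":
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        nbrs = [(dx, dy) for dx in (-1, 0, 1) for dy in (-1, 0, 1)
                if (dx, dy) != (0, 0)]
    nx, ny = occ.shape
    labels = np.zeros(occ.shape, dtype=int)
    nxt = 0
    for sx in range(nx):
        for sy in range(ny):
            if occ[sx, sy] and labels[sx, sy] == 0:
                nxt += 1
                stack = [(sx, sy)]
                labels[sx, sy] = nxt
                while stack:
                    x, y = stack.pop()
                    for dx, dy in nbrs:
                        u, v = x + dx, y + dy
                        if 0 <= u < nx and 0 <= v < ny and occ[u, v] \
                                and labels[u, v] == 0:
                            labels[u, v] = nxt
                            stack.append((u, v))
    return labels, nxt


def oracle_stats(occ, connectivity):
    """P, S, xi from the BFS labels by direct enumeration (pairwise xi)."""
    labels, n = flood_fill_labels(occ, connectivity)
    nx, ny = occ.shape
    sizes, spanning, coords = [], [], []
    for k in range(1, n + 1):
        pts = np.argwhere(labels == k)
        sizes.append(len(pts))
        spanning.append(
            (pts[:, 0].min() == 0 and pts[:, 0].max() == nx - 1)
            or (pts[:, 1].min() == 0 and pts[:, 1].max() == ny - 1))
        coords.append(pts)
    sizes = np.array(sizes)
    spanning = np.array(spanning, dtype=bool)
    P = sizes[spanning].sum() / occ.size if n else 0.0
    fin = ~spanning
    S = float((sizes[fin] ** 2).sum() / sizes[fin].sum()) if fin.any() else 0.0
    num = den = 0.0
    for k in np.nonzero(fin)[0]:
        pts = coords[k].astype(float)
        d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
        num += d2.sum()          # ordered pairs incl. i = j (zero)
        den += len(pts) ** 2
    xi = float(np.sqrt(num / den)) if den else float("nan")
    return P, S, xi


# ------------------------------------------------------------- thresholding

def test_threshold_extremes_and_rank_example():
    f = ScalarField2D(np.array([[1.0, 2.0], [3.0, 4.0]]))
    assert threshold_field(f, 1.0).occupied.all()
    assert not threshold_field(f, 0.0).occupied.any()
    occ = threshold_field(f, 0.5).occupied
    assert occ.tolist() == [[False, False], [True, True]]  # sites {3, 4}


def test_threshold_constant_field_degenerate():
    with pytest.raises(DegenerateFieldError):
        threshold_field(ScalarField2D(np.ones((4, 4))), 0.5)


def test_threshold_occupied_fraction_tracks_p():
    rng = np.random.default_rng(0)
    f = ScalarField2D(rng.random((64, 64)))
    for p in (0.1, 0.3, 0.5927, 0.8):
        frac = threshold_field(f, p).occupied.mean()
        assert frac == pytest.approx(p, abs=2 / 64**2 + 1e-12)


# ----------------------------------------------------------------- labeling

def test_label_trivial_grids():
    full = OccupancyGrid(np.ones((8, 8), bool), "face4")
    lab = label_clusters(full)
    assert lab.n_clusters == 1
    assert lab.sizes[0] == 64
    assert lab.spanning[0]

    checker = np.indices((8, 8)).sum(axis=0) % 2 == 0
    lab4 = label_clusters(OccupancyGrid(checker, "face4"))
    assert lab4.n_clusters == int(checker.sum())    # all singletons
    lab8 = label_clusters(OccupancyGrid(checker, "moore8"))
    assert lab8.n_clusters == 1                     # one diagonal cluster

    empty = label_clusters(OccupancyGrid(np.zeros((5, 5), bool)))
    assert empty.n_clusters == 0
    assert spanning_density(empty) == 0.0


def test_spanning_density_single_row():
    occ = np.zeros((10, 10), bool)
    occ[4, :] = True
    lab = label_clusters(OccupancyGrid(occ, "face4"))
    assert spanning_density(lab) == pytest.approx(0.1)


def test_average_cluster_size_conventions():
    occ = np.zeros((10, 10), bool)
    occ[1, 1] = True                      # size 1
    occ[5, 3:6] = True                    # size 3
    lab = label_clusters(OccupancyGrid(occ, "face4"))
    assert average_cluster_size(lab) == pytest.approx(2.5)    # (1+9)/(1+3)
    assert average_cluster_size(lab, method="mean") == pytest.approx(2.0)

    occ2 = np.zeros((8, 8), bool)
    occ2[2, 2:4] = True; occ2[3, 2:4] = True   # one 4-site blob
    lab2 = label_clusters(OccupancyGrid(occ2, "face4"))
    assert average_cluster_size(lab2) == pytest.approx(4.0)

    occ3 = np.zeros((8, 8), bool)
    occ3[:, 3] = True                          # spanning only
    lab3 = label_clusters(OccupancyGrid(occ3, "face4"))
    assert average_cluster_size(lab3) == 0.0
    assert np.isnan(correlation_length(lab3))


def test_correlation_length_hand_value():
    """Two adjacent sites: mean squared same-cluster pair distance is
    2 Rg^2 = 1/2, so xi = sqrt(1/2)."""
    occ = np.zeros((6, 6), bool)
    occ[2, 2] = occ[2, 3] = True
    lab = label_clusters(OccupancyGrid(occ, "face4"))
    assert correlation_length(lab) == pytest.approx(np.sqrt(0.5), abs=1e-12)

    occ2 = np.zeros((6, 6), bool)
    occ2[::3, ::3] = True   # isolated singletons
    lab2 = label_clusters(OccupancyGrid(occ2, "face4"))
    assert correlation_length(lab2) == 0.0


@pytest.mark.parametrize("connectivity", ["face4", "moore8"])
def test_cluster_statistics_match_bruteforce_on_random_grids(connectivity):
    """Exact agreement (xi to 1e-10) with the BFS + pairwise oracle."""
    rng = np.random.default_rng(99)
    for _ in range(30):
        occ = rng.random((16, 16)) < rng.uniform(0.3, 0.7)
        lab = label_clusters(OccupancyGrid(occ, connectivity))
        P, S, xi = oracle_stats(occ, connectivity)
        assert spanning_density(lab) == pytest.approx(P, abs=1e-12)
        assert average_cluster_size(lab) == pytest.approx(S, abs=1e-12)
        if np.isnan(xi):
            assert np.isnan(correlation_length(lab))
        else:
            assert correlation_length(lab) == pytest.approx(xi, abs=1e-10)


# -------------------------------------------------------------------- curves

def test_curves_full_grid_equals_single_observables():
    rng = np.random.default_rng(5)
    vals = rng.random((33, 33))
    p_grid = np.array([0.3, 0.6, 0.9])
    curves = percolation_curves([vals], p_grid)
    ell = 32
    for k, p in enumerate(p_grid):
        occ = threshold_field(ScalarField2D(vals), p)
        lab = label_clusters(occ)
        assert curves.P[ell][0, k] == pytest.approx(spanning_density(lab))
        assert curves.S[ell][0, k] == pytest.approx(average_cluster_size(lab))


def test_curves_occupation_is_bernoulli_and_P_monotone():
    rng = np.random.default_rng(6)
    fields = [rng.random((33, 33)) for _ in range(30)]
    p_grid = np.arange(0.35, 0.85, 0.05)
    curves = percolation_curves(fields, p_grid)
    Pm = curves.mean("P", 32)
    assert np.all(np.diff(Pm) >= -0.02)   # nondecreasing within MC error
    assert curves.P[32].shape == (30, len(p_grid))


def test_curves_subsystem_extraction_and_errors():
    rng = np.random.default_rng(7)
    vals = rng.random((65, 65))
    curves = percolation_curves([vals], np.array([0.55]), ells=[16, 32])
    assert curves.ells == [16, 32]
    with pytest.raises(ValueError, match="exceeds"):
        percolation_curves([vals], np.array([0.5]), ells=[100])


def test_spanning_probability_steepens_with_size():
    """The Pi(p) transition sharpens as the subsystem grows."""
    rng = np.random.default_rng(8)
    fields = [rng.random((65, 65)) for _ in range(60)]
    p_grid = np.arange(0.45, 0.76, 0.01)
    curves = percolation_curves(fields, p_grid, ells=[16, 64])
    def width(ell):
        pi = curves.mean("Pi", ell)
        return (curves.p[np.searchsorted(pi, 0.9, side="left").clip(0, len(pi)-1)]
                - curves.p[np.searchsorted(pi, 0.1, side="left").clip(0, len(pi)-1)])
    assert width(64) < width(16)
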