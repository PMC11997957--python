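import numpy as np
import pytest
from scipy.optimize import linprog

import megjoint as mj
from megjoint.mesh import LEFT, geodesic_distances
from megjoint.transport import _unbalanced_block, ground_metric


def exact_transport_cost(a, b, M):
    """Balanced transport cost by linear programming (equal masses)."""
    n, m = len(a), len(b)
    A_eq = []
    for i in range(n):
        row = np.zeros((n, m))
        row[i, :] = 1
        A_eq.append(row.ravel())
    for j in range(m):
        row = np.zeros((n, m))
        row[:, j] = 1
        A_eq.append(row.ravel())
    res = linprog(M.ravel(), A_eq=np.array(A_eq),
                  b_eq=np.concatenate([a, b]), bounds=(0, None))
    assert res.success
    return res.fun


def random_instance(rng):
    n = int(rng.integers(3, 11))
    pts = rng.uniform(0, 1, (n, 2))
    M = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    a = rng.uniform(0.1, 1.0, n)
    b = rng.uniform(0.1, 1.0, n)
    b *= a.sum() / b.sum()
    return a, b, M


def test_ground_metric_structure(mesh_ico1):
    metric = ground_metric(mesh_ico1)
    assert metric.eps == pytest.approx(5.0 / (3.0 * mesh_ico1.n_vertices))
    for vids, M in metric.blocks.values():
        assert np.allclose(M, M.T)
        assert np.all(np.diag(M) == 0)
        assert np.all(M >= 0)


def test_entropic_cost_matches_lp_oracle():
    """At eps -> 0+ with gamma -> inf the generalized cost reduces to
    exact (balanced) optimal transport; agreement within 1% on small
    random instances."""
    rng = np.random.default_rng(0)
    for _ in range(5):
        a, b, M = random_instance(rng)
        ref = exact_transport_cost(a, b, M)
        out = _unbalanced_block(a, b, M, eps=1e-5 * M.max(), gamma=1e6,
                                max_iter=50000, tol=1e-14)
        assert abs(out["cost"] - ref) <= 0.01 * ref


def test_point_mass_displacement_limit(metric_ico1, mesh_ico1):
    """Two equal point masses: the eps->0+, gamma->inf cost is mass
    times the squared-geodesic ground cost."""
    u, v = 5, 8
    vids, M = metric_ico1.blocks[LEFT]
    iu = list(vids).index(u)
    iv = list(vids).index(v)
    x = np.zeros(mesh_ico1.n_vertices)
    y = np.zeros(mesh_ico1.n_vertices)
    x[u] = 0.3
    y[v] = 0.3
    c = mj.unbalanced_wasserstein(x, y, metric_ico1, eps=1e-5 * M.max(),
                                  gamma=1e6, tol=1e-12)
    assert c == pytest.approx(0.3 * M[iu, iv], rel=1e-3)


def test_displacement_monotonicity(metric_ico1, mesh_ico1):
    x = np.zeros(mesh_ico1.n_vertices)
    x[5] = 1.0
    d = geodesic_distances(mesh_ico1, 5)
    far = int(np.argsort(np.where(np.isfinite(d), d, -1))[-1])
    y_far = np.zeros(mesh_ico1.n_vertices)
    y_far[far] = 1.0
    c_same = mj.unbalanced_wasserstein(x, x, metric_ico1)
    c_far = mj.unbalanced_wasserstein(x, y_far, metric_ico1)
    assert c_same < c_far


def test_sign_separation_closed_form(metric_ico1, mesh_ico1):
    """Opposite-sign vectors decompose into two one-sided problems whose
    mass is destroyed at price gamma."""
    x = np.zeros(mesh_ico1.n_vertices)
    y = np.zeros(mesh_ico1.n_vertices)
    x[3] = 0.7     # purely positive
    y[10] = -0.4   # purely negative
    gamma = 1.3
    c = mj.unbalanced_wasserstein(x, y, metric_ico1, gamma=gamma)
    assert c == pytest.approx(gamma * (0.7 + 0.4), rel=1e-12)


def test_cost_is_nonnegative_and_finite(metric_ico1, mesh_ico1):
    rng = np.random.default_rng(3)
    for _ in range(5):
        x = rng.standard_normal(mesh_ico1.n_vertices) * (rng.random(mesh_ico1.n_vertices) < 0.05)
        y = rng.standard_normal(mesh_ico1.n_vertices) * (rng.random(mesh_ico1.n_vertices) < 0.05)
        c = mj.unbalanced_wasserstein(x, y, metric_ico1)
        assert np.isfinite(c) and c >= 0


class TestBarycenter:
    def test_identical_point_masses(self, metric_ico1, mesh_ico1):
        x = np.zeros(mesh_ico1.n_vertices)
        x[5] = 1.0
        b = mj.wasserstein_barycenter([x, x, x], metric_ico1)
        assert int(np.argmax(np.abs(b))) == 5

    def test_two_masses_concentrate_near_midpoint(self, metric_ico1, mesh_ico1):
        """Brute-force oracle: the vertex minimizing the sum of the two
        transport costs is the geodesic midpoint; the barycenter mass
        must concentrate there (within one mesh edge)."""
        d = geodesic_distances(mesh_ico1, 5)
        far = int(np.argsort(np.where(np.isfinite(d), d, -1))[-1])
        xu = np.zeros(mesh_ico1.n_vertices)
        xv = np.zeros(mesh_ico1.n_vertices)
        xu[5] = 1.0
        xv[far] = 1.0
        costs = []
        for w in mesh_ico1.hemisphere_vertices(LEFT):
            yw = np.zeros(mesh_ico1.n_vertices)
            yw[w] = 1.0
            costs.append((
                mj.unbalanced_wasserstein(xu, yw, metric_ico1)
                + mj.unbalanced_wasserstein(xv, yw, metric_ico1),
                int(w),
            ))
        best = min(costs)[1]
        b = mj.wasserstein_barycenter([xu, xv], metric_ico1)
        bary_peak = int(np.argmax(np.abs(b)))
        gap = geodesic_distances(mesh_ico1, best)[bary_peak]
        assert gap <= 1.01 * mesh_ico1.edge_lengths().max()

    def test_permutation_invariance(self, metric_ico1, mesh_ico1):
        rng = np.random.default_rng(5)
        xs = []
        for _ in range(3):
            x = np.zeros(mesh_ico1.n_vertices)
            x[rng.integers(0, mesh_ico1.n_vertices, 3)] = rng.random(3)
            xs.append(x)
        b1 = mj.wasserstein_barycenter(xs, metric_ico1)
        b2 = mj.wasserstein_barycenter(xs[::-1], metric_ico1)
        assert np.allclose(b1, b2)

    def test_single_input_peaks_at_input(self, metric_ico1, mesh_ico1):
        """With one subject the barycenter is the entropically blurred
        input: its argmax stays at the input vertex."""
        x = np.zeros(mesh_ico1.n_vertices)
        x[7] = -0.8
        b = mj.wasserstein_barycenter([x], metric_ico1)
        assert int(np.argmax(np.abs(b))) == 7
        assert b[7] < 0  # sign channel preserved

    def test_empty_input_raises(self, metric_ico1):
        with pytest.raises(ValueError):
            mj.wasserstein_barycenter([], metric_ico1)


def test_degenerate_empty_marginal_cost():
    M = np.array([[0.0, 1.0], [1.0, 0.0]])
    out = _unbalanced_block(np.zeros(2), np.array([0.2, 0.3]), M,
                            eps=0.1, gamma=2.0)
    assert out["cost"] == pytest.approx(2.0 * 0.5)


def test_nonconvergence_raises():
    from megjoint.eloreta import ConvergenceError
    M = np.array([[0.0, 1.0], [1.0, 0.0]])
    a = np.array([1.0, 0.5])
    b = np.array([0.5, 1.0])
    with pytest.raises(ConvergenceError):
        _unbalanced_block(a, b, M, eps=0.5 * M.max(), gamma=1.0,
                          max_iter=3, tol=1e-14)
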