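"""Unbalanced entropic optimal transport on the cortical mesh.

Signed source amplitude vectors are compared with a generalized
Wasserstein cost: the vector is split into positive and negative
channels (``x = x+ - x-``) and each channel is transported separately
against the corresponding channel of the other vector (no cross-channel
transport).  Transport never crosses hemispheres — the ground metric is
squared geodesic distance restricted per hemisphere, so the problem
decouples into independent per-hemisphere, per-channel blocks whose
costs add.

Each block is a KL-relaxed (unbalanced) entropic transport problem

    min_P  <M, P> + eps*KL(P | K) + gamma*KL(P 1 | a) + gamma*KL(P^T 1 | b)

solved by stabilized scaling iterations in the log domain.  The
reported cost is the transport term plus the two marginal penalties at
the entropic optimum (the entropy term is dropped), so it approaches
the exact unregularized unbalanced cost as eps -> 0+.  Mass creation /
destruction is priced at ``gamma`` per unit, which makes the cost
against an empty marginal finite: ``gamma`` times the remaining mass.

Ground-metric units are m^2 (geodesic mm distances are converted), so
the default entropic strength ``eps = 5 / (3 P)`` has a sane ratio to
the cost scale at head size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .eloreta import ConvergenceError
from .mesh import LEFT, RIGHT, Mesh, geodesic_distances

__all__ = [
    "TransportGroundMetric",
    "ground_metric",
    "unbalanced_wasserstein",
    "signed_wasserstein",
    "wasserstein_barycenter",
]


@dataclass
class TransportGroundMetric:
    """Per-hemisphere squared-geodesic cost blocks (m^2).

    ``blocks[h] = (vertex_ids, M)`` with ``M`` symmetric, zero-diagonal.
    ``eps`` is the default entropic strength (``5 / (3 P)`` with P the
    total vertex count unless overridden).
    """

    blocks: dict[int, tuple[np.ndarray, np.ndarray]]
    eps: float
    n_vertices: int

    def __post_init__(self) -> None:
        for vids, M in self.blocks.values():
            if M.shape != (len(vids), len(vids)):
                raise ValueError("cost block shape mismatch")


def ground_metric(mesh: Mesh, eps: float | None = None) -> TransportGroundMetric:
    """Build the hemisphere-blocked squared-geodesic ground metric."""
    blocks = {}
    for hemi in (LEFT, RIGHT):
        vids = mesh.hemisphere_vertices(hemi)
        D = geodesic_distances(mesh, vids)[:, vids]
        M = (D * 1e-3) ** 2  # mm -> m, squared
        M = 0.5 * (M + M.T)
        np.fill_diagonal(M, 0.0)
        blocks[hemi] = (vids, M)
    P = mesh.n_vertices
    if eps is None:
        eps = 5.0 / (3.0 * P)
    return TransportGroundMetric(blocks=blocks, eps=eps, n_vertices=P)


def _log(x: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.log(x)


def logsumexp(A: np.ndarray, axis: int) -> np.ndarray:
    """Minimal fast log-sum-exp along one axis (handles -inf rows)."""
    m = np.max(A, axis=axis)
    finite = np.isfinite(m)
    out = np.full(m.shape, -np.inf)
    if np.any(finite):
        mm = np.where(finite, m, 0.0)
        s = np.sum(np.exp(A - np.expand_dims(mm, axis)), axis=axis)
        out = np.where(finite, mm + np.log(s), -np.inf)
    return out


def _unbalanced_block(
    a: np.ndarray,
    b: np.ndarray,
    M: np.ndarray,
    eps: float,
    gamma: float,
    max_iter: int = 2000,
    tol: float = 1e-3,
    want_grad: bool = False,
    state: dict | None = None,
) -> dict:
    """Solve one unbalanced entropic block on the support of a and b.

    Returns a dict with ``cost`` and optionally ``grad`` (the marginal
    derivative of the cost w.r.t. ``a`` on the full block, clipped to
    [-gamma, gamma]).  ``state`` may carry full-block dual potentials
    from a previous, nearby solve to warm-start the iterations; it is
    updated in place.  Raises :class:`ConvergenceError` if the scaling
    iterations do not settle.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ma, mb = float(a.sum()), float(b.sum())
    if ma <= 0 or mb <= 0:
        # degenerate: all mass on the non-empty side is destroyed
        cost = gamma * (ma + mb)
        out = {"cost": cost, "n_iter": 0, "converged": True}
        if want_grad:
            if ma <= 0 and mb > 0:
                # creating mass at i reroutes one unit of b from
                # destruction (gamma) to transport (nearest-cost column)
                near = M[:, np.flatnonzero(b > 0)].min(axis=1)
                out["grad"] = np.clip(near - gamma, -gamma, gamma)
            else:
                out["grad"] = np.full(len(a), gamma)
        return out

    ia = np.flatnonzero(a > 0)
    ib = np.flatnonzero(b > 0)
    la = _log(a[ia])
    lb = _log(b[ib])
    Msub = M[np.ix_(ia, ib)]
    scale = max(float(Msub.max()), eps)

    # epsilon scaling: when eps is small relative to the cost scale,
    # anneal down from a well-conditioned entropic strength with
    # warm-started dual potentials; otherwise iterate directly
    if eps >= 0.02 * scale or state is not None:
        eps_schedule = [eps]
    else:
        eps_schedule = []
        e = 0.1 * scale
        while e > eps * 1.001:
            eps_schedule.append(e)
            e *= 0.5
        eps_schedule.append(eps)

    if state is not None and "f" in state:
        f = state["f"][ia].copy()
        g = state["g"][ib].copy()
    else:
        f = np.zeros(len(ia))  # dual potentials in cost units
        g = np.zeros(len(ib))
    # potentials can reach the order of gamma (mass destruction), so the
    # stopping tolerance scales with the larger of the cost block and gamma
    tol_f = tol * max(scale, gamma)
    n_iter = 0
    converged = False
    for e_k in eps_schedule:
        phi_k = gamma / (gamma + e_k)
        logK = -Msub / e_k
        final = e_k == eps
        budget = max_iter if final else max(20, max_iter // 10)
        for _ in range(budget):
            n_iter += 1
            log_Kv = logsumexp(logK + (g / e_k)[None, :], axis=1)
            f_new = e_k * phi_k * (la - log_Kv)
            log_Ku = logsumexp(logK + (f_new / e_k)[:, None], axis=0)
            g_new = e_k * phi_k * (lb - log_Ku)
            delta = max(
                float(np.max(np.abs(f_new - f))),
                float(np.max(np.abs(g_new - g))),
            )
            f, g = f_new, g_new
            if delta < tol_f:
                converged = final
                break
        if converged:
            break
    if not converged:
        raise ConvergenceError(
            f"unbalanced scaling iterations did not converge "
            f"({n_iter} iterations, last change {delta:.3e})",
            [delta],
        )

    phi = gamma / (gamma + eps)
    logK = -Msub / eps
    log_u = f / eps
    log_v = g / eps
    logP = log_u[:, None] + logK + log_v[None, :]
    P = np.exp(logP)
    transport = float(np.sum(P * Msub))
    # at the scaling fixed point the marginals are a*e^{-f/gamma} and
    # b*e^{-g/gamma} identically; evaluating the KL penalties through
    # these identities is stable even for very large gamma, where the
    # penalty would otherwise amplify residual iteration error
    rho_a = np.exp(-f / gamma)
    rho_b = np.exp(-g / gamma)
    kl_row = float(np.sum(a[ia] * (1.0 - rho_a * (1.0 + f / gamma))))
    kl_col = float(np.sum(b[ib] * (1.0 - rho_b * (1.0 + g / gamma))))
    cost = transport + gamma * kl_row + gamma * kl_col
    if state is not None:
        f_full = np.zeros(len(a))
        g_full = np.zeros(len(b))
        f_full[ia] = f
        g_full[ib] = g
        state["f"], state["g"] = f_full, g_full
    out = {"cost": cost, "n_iter": n_iter, "converged": True}
    if want_grad:
        # f_i = eps*phi*(log a_i - log (Kv)_i); empty coords use log a = 0
        # (the potential felt by a unit mass), then g = gamma(1 - e^{-f/gamma})
        logK_full = -M[:, ib] / eps
        log_Kv_full = logsumexp(logK_full + log_v[None, :], axis=1)
        f = -eps * phi * log_Kv_full
        f[ia] += eps * phi * la
        with np.errstate(over="ignore"):
            g = gamma * (1.0 - np.exp(-f / gamma))
        out["grad"] = np.clip(g, -gamma, gamma)
    return out


def _split_channels(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    return np.clip(x, 0.0, None), np.clip(-x, 0.0, None)


def signed_wasserstein(
    x: np.ndarray,
    y: np.ndarray,
    metric: TransportGroundMetric,
    eps: float | None = None,
    gamma: float = 1.0,
    max_iter: int = 2000,
    tol: float = 1e-3,
    want_grad: bool = False,
    state: dict | None = None,
) -> tuple[float, np.ndarray | None]:
    """Generalized Wasserstein cost between signed vectors on the mesh.

    Sums the unbalanced block costs over (hemisphere x sign channel).
    With ``want_grad`` also returns the derivative w.r.t. ``x`` (the
    positive-channel gradient where ``x > 0``, minus the
    negative-channel gradient where ``x < 0``, zero on the zero set).
    On the zero set of ``x`` the returned gradient is the slope of the
    steepest profitable mass-creation direction (zero when creating
    mass in either sign channel would increase the cost), so a
    gradient-based solver can activate vertices the transport term
    pulls toward.  ``state`` (a mutable dict) warm-starts the block
    solves across repeated nearby evaluations.
    """
    if eps is None:
        eps = metric.eps
    xp, xn = _split_channels(x)
    yp, yn = _split_channels(y)
    cost = 0.0
    grad = np.zeros(metric.n_vertices) if want_grad else None
    for hemi, (vids, M) in metric.blocks.items():
        g_pos = g_neg = None
        for xa, ya, sign in ((xp, yp, 1.0), (xn, yn, -1.0)):
            block_state = None
            if state is not None:
                block_state = state.setdefault((hemi, sign), {})
            res = _unbalanced_block(
                xa[vids], ya[vids], M, eps, gamma,
                max_iter=max_iter, tol=tol, want_grad=want_grad,
                state=block_state,
            )
            cost += res["cost"]
            if want_grad:
                if sign > 0:
                    g_pos = res["grad"]
                else:
                    g_neg = res["grad"]
        if want_grad:
            xb = x[vids]
            g_block = np.zeros(len(vids))
            g_block[xb > 0] = g_pos[xb > 0]
            g_block[xb < 0] = -g_neg[xb < 0]
            zero = xb == 0
            # slope g_pos for +mass creation, g_neg for -mass creation;
            # follow whichever descends faster, stay put if neither does
            create_pos = zero & (g_pos < 0) & (g_pos <= g_neg)
            create_neg = zero & (g_neg < 0) & (g_neg < g_pos)
            g_block[create_pos] = g_pos[create_pos]
            g_block[create_neg] = -g_neg[create_neg]
            grad[vids] = g_block
    return cost, grad


def unbalanced_wasserstein(
    x: np.ndarray,
    y: np.ndarray,
    metric: TransportGroundMetric,
    eps: float | None = None,
    gamma: float = 1.0,
    max_iter: int = 2000,
    tol: float = 1e-3,
) -> float:
    """Cost-only interface to :func:`signed_wasserstein`."""
    cost, _ = signed_wasserstein(
        x, y, metric, eps=eps, gamma=gamma, max_iter=max_iter, tol=tol
    )
    return cost


def _barycenter_block(
    masses: list[np.ndarray],
    M: np.ndarray,
    eps: float,
    gamma: float,
    support: np.ndarray,
    weights: np.ndarray,
    max_iter: int = 2000,
    tol: float = 1e-3,
) -> np.ndarray:
    """Unbalanced entropic barycenter of non-negative mass vectors.

    Scaling iterations with the power-mean barycenter update

        b = ( sum_s w_s (K^T u_s)^{eps/(eps+gamma)} )^{(eps+gamma)/eps}

    which reduces to the classic iterative-Bregman geometric mean in the
    balanced limit.  The barycenter support is restricted to ``support``
    (column indices of ``M``).
    """
    active = [(s, np.flatnonzero(m > 0)) for s, m in enumerate(masses) if m.sum() > 0]
    n = M.shape[0]
    if not active:
        return np.zeros(n)
    t = eps / (eps + gamma)
    phi = gamma / (gamma + eps)
    logKs = [-M[np.ix_(ia, support)] / eps for _, ia in active]
    las = [_log(masses[s][ia]) for s, ia in active]
    lws = _log(weights[[s for s, _ in active]])
    log_vs = [np.zeros(len(support)) for _ in active]
    log_b = np.full(len(support), -np.inf)
    for _ in range(max_iter):
        log_Kus = []
        for k, (logK, la) in enumerate(zip(logKs, las)):
            log_Kv = logsumexp(logK + log_vs[k][None, :], axis=1)
            log_u = phi * (la - log_Kv)
            log_Kus.append(logsumexp(logK + log_u[:, None], axis=0))
        stacked = np.stack([lw + t * lku for lw, lku in zip(lws, log_Kus)])
        log_b_new = logsumexp(stacked, axis=0) / t
        for k in range(len(active)):
            log_vs[k] = phi * (log_b_new - log_Kus[k])
        delta = float(np.max(np.abs(
            np.where(np.isfinite(log_b_new) | np.isfinite(log_b),
                     log_b_new - log_b, 0.0)
        )))
        log_b = log_b_new
        if delta < tol:
            break
    else:
        raise ConvergenceError(
            "barycenter scaling iterations did not converge", [delta]
        )
    b = np.zeros(n)
    b[support] = np.exp(log_b)
    return b


def wasserstein_barycenter(
    estimates: list[np.ndarray],
    metric: TransportGroundMetric,
    eps: float | None = None,
    gamma: float = 1.0,
    weights: np.ndarray | None = None,
    max_iter: int = 2000,
    tol: float = 1e-3,
    support_dilation_mm: float | None = None,
    mesh: Mesh | None = None,
) -> np.ndarray:
    """Barycenter of signed source vectors under the generalized cost.

    Positive and negative channels are averaged independently per
    hemisphere and recombined.  The barycenter support defaults to the
    full hemisphere; passing ``support_dilation_mm`` together with the
    mesh restricts it to the geodesic dilation of the inputs' supports
    (a speed optimization for sparse estimates).
    """
    if not estimates:
        raise ValueError("need at least one estimate")
    if eps is None:
        eps = metric.eps
    S = len(estimates)
    w = np.full(S, 1.0 / S) if weights is None else np.asarray(weights, float)
    out = np.zeros(metric.n_vertices)
    for vids, M in metric.blocks.values():
        pos = [np.clip(np.asarray(x)[vids], 0.0, None) for x in estimates]
        neg = [np.clip(-np.asarray(x)[vids], 0.0, None) for x in estimates]
        for channel, sign in ((pos, 1.0), (neg, -1.0)):
            union = np.flatnonzero(np.sum(channel, axis=0) > 0)
            if len(union) == 0:
                continue
            if support_dilation_mm is not None and mesh is not None:
                d = geodesic_distances(mesh, vids[union])[:, vids]
                support = np.flatnonzero(np.min(d, axis=0) <= support_dilation_mm)
            else:
                support = np.arange(len(vids))
            b = _barycenter_block(
                channel, M, eps, gamma, support, w,
                max_iter=max_iter, tol=tol,
            )
            out[vids] += sign * b
    return out
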