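"""Marginal maximum likelihood (EM) calibration of 2PL/3PL models.

The latent ability distribution is a fixed standard-normal prior evaluated
on an equally spaced quadrature grid, so every form is calibrated onto its
own sample-standardized scale; reconciling those scales is the job of the
equating module.

The M-step ascends each item's expected complete-data log-likelihood with
Fisher-scoring steps under box constraints, with step-halving so the step
never decreases the objective; this makes the algorithm a generalized EM
and the marginal log-likelihood monotone nondecreasing across cycles.
Guessing parameters are estimated through a logit reparameterization
``c = c_max * expit(z)`` which keeps ``c`` inside ``(0, c_max)`` without
constrained optimizers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy.special import expit, logit, ndtri

from anchorlink.irt_core import ItemParams, ResponseMatrix

__all__ = [
    "QuadratureGrid",
    "CalibrationSettings",
    "CalibrationResult",
    "fit_irt",
    "score_eap",
]

_A_BOUNDS = (1e-2, 30.0)
_B_BOUNDS = (-10.0, 10.0)
_Z_BOUNDS = (-30.0, 30.0)
_P_FLOOR = 1e-10


@dataclass(frozen=True)
class QuadratureGrid:
    """Equally spaced ability nodes with renormalized standard-normal mass."""

    nodes: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        nodes = np.asarray(self.nodes, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "weights", weights)
        if nodes.ndim != 1 or nodes.size < 2:
            raise ValueError("grid needs at least 2 nodes")
        if not np.all(np.diff(nodes) > 0):
            raise ValueError("nodes must be strictly increasing")
        if weights.shape != nodes.shape:
            raise ValueError("weights and nodes shape mismatch")
        if np.any(weights < 0) or not np.isclose(weights.sum(), 1.0, atol=1e-12):
            raise ValueError("weights must be nonnegative and sum to 1")

    @classmethod
    def standard_normal(cls, n_nodes: int = 61, lo: float = -6.0, hi: float = 6.0) -> "QuadratureGrid":
        nodes = np.linspace(lo, hi, n_nodes)
        w = np.exp(-0.5 * nodes**2)
        return cls(nodes=nodes, weights=w / w.sum())


@dataclass(frozen=True)
class CalibrationSettings:
    n_quad: int = 61
    theta_lo: float = -6.0
    theta_hi: float = 6.0
    tol: float = 1e-4
    max_cycles: int = 500
    c_max: float = 0.5
    inner_steps: int = 2
    #: abort as non-converged when the marginal loglik has moved less than
    #: this over ``stall_window`` cycles while parameters still drift above
    #: ``tol`` (a likelihood ridge); set to None to always run out the clock
    stall_tol: Optional[float] = 1e-9
    stall_window: int = 10

    def grid(self) -> QuadratureGrid:
        return QuadratureGrid.standard_normal(self.n_quad, self.theta_lo, self.theta_hi)


@dataclass(frozen=True)
class CalibrationResult:
    """Outcome of one form's calibration.

    ``item_estimates`` covers the estimable items only; columns whose
    responses were all-0 or all-1 are listed in ``excluded_items`` with a
    reason and carry no estimates.  ``converged`` is True iff the maximum
    absolute item-parameter change fell below the tolerance within
    ``max_cycles``.
    """

    item_estimates: Tuple[ItemParams, ...]
    excluded_items: Dict[str, str]
    theta_hat: np.ndarray
    person_ids: Tuple[str, ...]
    loglik: float
    loglik_path: Tuple[float, ...]
    converged: bool
    n_cycles: int
    model: str

    def estimates_by_id(self) -> Dict[str, ItemParams]:
        return {it.item_id: it for it in self.item_estimates}


def _icc_matrix(a: np.ndarray, b: np.ndarray, c: np.ndarray, nodes: np.ndarray) -> np.ndarray:
    """P[i, k] = ICC of item i at node k."""
    q = expit(a[:, None] * (nodes[None, :] - b[:, None]))
    return c[:, None] + (1.0 - c[:, None]) * q


def _marginal_loglik(X: np.ndarray, logp: np.ndarray, log1mp: np.ndarray, logw: np.ndarray) -> Tuple[float, np.ndarray]:
    """Returns (marginal loglik, posterior matrix persons x nodes)."""
    ll = X @ (logp - log1mp) + log1mp.sum(axis=0)  # persons x nodes
    ll += logw[None, :]
    top = ll.max(axis=1)
    post = np.exp(ll - top[:, None])
    norm = post.sum(axis=1)
    post /= norm[:, None]
    return float((top + np.log(norm)).sum()), post


def _clip_p(p: np.ndarray) -> np.ndarray:
    return np.minimum(np.maximum(p, _P_FLOOR), 1 - _P_FLOOR)


def _expected_loglik(p: np.ndarray, r: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Per-item expected complete-data loglik given node-level counts."""
    p = _clip_p(p)
    return (r * np.log(p) + (n[None, :] - r) * np.log1p(-p)).sum(axis=1)


def _m_step(
    a: np.ndarray,
    b: np.ndarray,
    z: np.ndarray,
    r: np.ndarray,
    n: np.ndarray,
    nodes: np.ndarray,
    c_max: float,
    estimate_c: bool,
    inner_steps: int,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fisher-scoring ascent of each item's expected complete-data loglik.

    All items advance simultaneously (arrays I x K); step-halving per item
    guarantees the objective never decreases, which preserves the EM ascent
    property even though the maximizer is inexact.
    """
    n_par = 3 if estimate_c else 2
    theta = nodes[None, :]
    for _ in range(inner_steps):
        c = c_max * expit(z) if estimate_c else np.zeros_like(a)
        q = expit(a[:, None] * (theta - b[:, None]))
        p = np.clip(c[:, None] + (1.0 - c[:, None]) * q, _P_FLOOR, 1 - _P_FLOOR)
        f0 = _expected_loglik(p, r, n)

        gp = (r - n[None, :] * p) / (p * (1 - p))  # dL/dp at each node
        qq = q * (1 - q)
        J = np.empty((a.size, nodes.size, n_par))
        J[:, :, 0] = (1.0 - c[:, None]) * qq * (theta - b[:, None])
        J[:, :, 1] = -(1.0 - c[:, None]) * qq * a[:, None]
        if estimate_c:
            dcdz = c_max * expit(z) * (1 - expit(z))
            J[:, :, 2] = (1.0 - q) * dcdz[:, None]

        grad = np.einsum("ik,ikp->ip", gp, J)
        w = n[None, :] / (p * (1 - p))
        info = np.einsum("ik,ikp,ikq->ipq", w, J, J)
        info += 1e-6 * np.eye(n_par)[None, :, :]
        try:
            step = np.linalg.solve(info, grad[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            step = grad / np.maximum(np.einsum("ipp->ip", info), 1e-8)

        # items whose proposed step is negligible are already at their
        # optimum; keep them out of the halving loop entirely
        active = np.flatnonzero(np.abs(step).max(axis=1) > 1e-10)
        if active.size == 0:
            break
        a_new, b_new, z_new = a.copy(), b.copy(), z.copy()
        scale = 1.0
        todo = active
        for _half in range(10):
            a_try = np.clip(a[todo] + scale * step[todo, 0], *_A_BOUNDS)
            b_try = np.clip(b[todo] + scale * step[todo, 1], *_B_BOUNDS)
            if estimate_c:
                z_try = np.clip(z[todo] + scale * step[todo, 2], *_Z_BOUNDS)
                c_try = c_max * expit(z_try)
            else:
                z_try = z[todo]
                c_try = np.zeros(todo.size)
            p_try = _clip_p(
                c_try[:, None] + (1.0 - c_try[:, None]) * expit(a_try[:, None] * (theta - b_try[:, None]))
            )
            f_try = _expected_loglik(p_try, r[todo], n)
            # tiny slack absorbs rounding noise; any per-cycle loglik loss is
            # bounded by n_items * 1e-13, far below the 1e-8 ascent tolerance
            ok = f_try >= f0[todo] - 1e-13
            idx = todo[ok]
            a_new[idx] = a_try[ok]
            b_new[idx] = b_try[ok]
            if estimate_c:
                z_new[idx] = z_try[ok]
            todo = todo[~ok]
            if todo.size == 0:
                break
            scale *= 0.5
        a, b, z = a_new, b_new, z_new
    return a, b, z


def fit_irt(
    responses: ResponseMatrix,
    model: str = "2PL",
    settings: Optional[CalibrationSettings] = None,
) -> CalibrationResult:
    """Estimate item parameters by MML-EM and abilities by EAP.

    Items observed in a single response category are inestimable under MML
    with a free difficulty; they are excluded from estimation and recorded
    in ``excluded_items``.  A fit that fails to reach the parameter-change
    tolerance within ``max_cycles`` is returned with ``converged=False``
    rather than raising.
    """
    if model not in ("2PL", "3PL"):
        raise ValueError(f"model must be '2PL' or '3PL', got {model!r}")
    settings = settings or CalibrationSettings()
    X_full = responses.values.astype(float)
    if X_full.shape[0] < 2 or X_full.shape[1] < 2:
        raise ValueError("calibration requires at least 2 persons and 2 items")

    col_means = X_full.mean(axis=0)
    estimable = (col_means > 0) & (col_means < 1)
    excluded = {
        responses.item_ids[j]: ("all responses correct" if col_means[j] >= 1 else "all responses incorrect")
        for j in np.flatnonzero(~estimable)
    }
    keep = np.flatnonzero(estimable)
    X = X_full[:, keep]
    item_ids = tuple(responses.item_ids[j] for j in keep)
    grid = settings.grid()
    nodes, logw = grid.nodes, np.log(grid.weights)
    estimate_c = model == "3PL"

    if X.shape[1] == 0:
        theta = np.zeros(X.shape[0])
        return CalibrationResult(
            item_estimates=(),
            excluded_items=excluded,
            theta_hat=theta,
            person_ids=responses.person_ids,
            loglik=0.0,
            loglik_path=(),
            converged=False,
            n_cycles=0,
            model=model,
        )

    # init: a = 1, b = probit of failure rate, c = 0.1 (3PL)
    pbar = np.clip(X.mean(axis=0), 1e-3, 1 - 1e-3)
    a = np.ones(X.shape[1])
    b = np.clip(ndtri(1.0 - pbar), -3.0, 3.0)
    z = np.full(X.shape[1], logit(np.clip(0.1 / settings.c_max, 1e-6, 1 - 1e-6)))

    loglik_path = []
    converged = False
    n_cycles = 0
    n_items = X.shape[1]
    # item-level active set: items whose parameters stopped moving are
    # skipped in the M-step until a full confirmation pass re-checks them
    active = np.arange(n_items)
    for cycle in range(1, settings.max_cycles + 1):
        n_cycles = cycle
        c = settings.c_max * expit(z) if estimate_c else np.zeros_like(a)
        P = np.clip(_icc_matrix(a, b, c, nodes), _P_FLOOR, 1 - _P_FLOOR)
        ll, post = _marginal_loglik(X, np.log(P), np.log1p(-P), logw)
        loglik_path.append(ll)
        nk = post.sum(axis=0)  # expected persons per node
        rk = X[:, active].T @ post  # expected correct per active item x node
        a_act, b_act, z_act = _m_step(
            a[active], b[active], z[active], rk, nk, nodes,
            settings.c_max, estimate_c, settings.inner_steps,
        )
        c_act = settings.c_max * expit(z_act) if estimate_c else np.zeros(active.size)
        delta_i = np.maximum(np.abs(a_act - a[active]), np.abs(b_act - b[active]))
        if estimate_c:
            delta_i = np.maximum(delta_i, np.abs(c_act - settings.c_max * expit(z[active])))
        a[active], b[active], z[active] = a_act, b_act, z_act
        if delta_i.size == 0 or delta_i.max() < settings.tol:
            if active.size == n_items:
                converged = True
                break
            active = np.arange(n_items)  # confirmation pass over everything
        else:
            moving = active[delta_i >= 0.1 * settings.tol]
            active = moving if moving.size else np.arange(n_items)
        if (
            settings.stall_tol is not None
            and cycle > settings.stall_window
            and abs(loglik_path[-1] - loglik_path[-1 - settings.stall_window]) < settings.stall_tol
        ):
            break  # likelihood ridge: parameters drift, fit quality frozen

    c = settings.c_max * expit(z) if estimate_c else np.zeros_like(a)
    P = np.clip(_icc_matrix(a, b, c, nodes), _P_FLOOR, 1 - _P_FLOOR)
    ll, post = _marginal_loglik(X, np.log(P), np.log1p(-P), logw)
    loglik_path.append(ll)
    theta_hat = post @ nodes

    estimates = tuple(
        ItemParams(item_id=item_ids[j], a=float(a[j]), b=float(b[j]), c=float(c[j]) if estimate_c else 0.0)
        for j in range(len(item_ids))
    )
    return CalibrationResult(
        item_estimates=estimates,
        excluded_items=excluded,
        theta_hat=theta_hat,
        person_ids=responses.person_ids,
        loglik=ll,
        loglik_path=tuple(loglik_path),
        converged=converged,
        n_cycles=n_cycles,
        model=model,
    )


def score_eap(
    responses: ResponseMatrix,
    item_estimates: Sequence[ItemParams],
    grid: Optional[QuadratureGrid] = None,
) -> np.ndarray:
    """Expected-a-posteriori ability for each response pattern.

    The posterior combines the standard-normal grid prior with the
    likelihood of the person's responses on the supplied item estimates;
    shrinkage keeps the estimate finite for all-correct and all-incorrect
    patterns.  With no items the prior mean (0) is returned.
    """
    if responses.values.shape[0] < 1:
        raise ValueError("no response rows to score")
    grid = grid or QuadratureGrid.standard_normal()
    est = {it.item_id: it for it in item_estimates}
    cols = [j for j, iid in enumerate(responses.item_ids) if iid in est]
    if not cols:
        return np.full(responses.n_persons, float(grid.nodes @ grid.weights))
    X = responses.values[:, cols].astype(float)
    a = np.array([est[responses.item_ids[j]].a for j in cols])
    b = np.array([est[responses.item_ids[j]].b for j in cols])
    c = np.array([est[responses.item_ids[j]].c for j in cols])
    P = np.clip(_icc_matrix(a, b, c, grid.nodes), _P_FLOOR, 1 - _P_FLOOR)  # items x nodes
    _, post = _marginal_loglik(X, np.log(P), np.log1p(-P), np.log(grid.weights))
    return post @ grid.nodes
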