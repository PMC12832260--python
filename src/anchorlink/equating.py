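"""Anchor-item scale linking: five coefficient estimators plus transforms.

All methods estimate the same linear map from the source form's scale onto
the target form's scale,

    b_target = A * b_source + B,    a_target = a_source / A,

differing only in how (A, B) are extracted from the anchor items' paired
estimates: moment-based (mean-sigma, mean-mean, mean-geometric-mean) or
characteristic-curve-based (item response function / Haebara, test
response function / Stocking-Lord).  Guessing parameters are
scale-invariant and pass through untouched.

Coefficients compose along chains of adjacent links, which implements
indirect equating between forms that share no anchors.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

from anchorlink.calibration import QuadratureGrid
from anchorlink.irt_core import ItemParams

__all__ = [
    "METHODS",
    "EquatingCoefficients",
    "AnchorPairs",
    "DegenerateAnchorError",
    "ms_coefficients",
    "mm_coefficients",
    "mgm_coefficients",
    "irf_coefficients",
    "trf_coefficients",
    "compute_coefficients",
    "transform_item",
    "transform_theta",
    "chain_compose",
]

METHODS = ("MS", "MM", "MGM", "IRF", "TRF")

_A_MIN = 1e-3


class DegenerateAnchorError(ValueError):
    """Anchor set carries no usable information for the requested method."""


@dataclass(frozen=True)
class EquatingCoefficients:
    """Linear linking map ``x_target = A * x_source + B`` (for difficulties)."""

    A: float
    B: float
    method: str = "MM"
    n_anchors: int = 0
    source_form: int = 0
    target_form: int = 0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.A) and np.isfinite(self.B)):
            raise ValueError(f"coefficients must be finite, got A={self.A}, B={self.B}")
        if self.A <= 0:
            raise ValueError(f"slope A must be > 0, got {self.A}")

    def inverse(self) -> "EquatingCoefficients":
        return replace(self, A=1.0 / self.A, B=-self.B / self.A,
                       source_form=self.target_form, target_form=self.source_form)


@dataclass(frozen=True)
class AnchorPairs:
    """Paired anchor estimates on the source and target form scales."""

    item_ids: Tuple[str, ...]
    a_source: np.ndarray
    b_source: np.ndarray
    c_source: np.ndarray
    a_target: np.ndarray
    b_target: np.ndarray
    c_target: np.ndarray

    def __post_init__(self) -> None:
        arrays = {}
        for name in ("a_source", "b_source", "c_source", "a_target", "b_target", "c_target"):
            arr = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            object.__setattr__(self, name, arr)
            arrays[name] = arr
        n = len(self.item_ids)
        if n < 1:
            raise ValueError("at least one anchor pair is required")
        for name, arr in arrays.items():
            if arr.shape != (n,):
                raise ValueError(f"{name} must have length {n}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
        if np.any(self.a_source <= 0) or np.any(self.a_target <= 0):
            raise ValueError("anchor discriminations must be strictly positive")

    @property
    def n(self) -> int:
        return len(self.item_ids)

    @classmethod
    def from_estimates(
        cls,
        source: Mapping[str, ItemParams] | Iterable[ItemParams],
        target: Mapping[str, ItemParams] | Iterable[ItemParams],
        anchor_ids: Optional[Sequence[str]] = None,
    ) -> "AnchorPairs":
        """Pair up the common items of two estimate sets.

        ``anchor_ids`` restricts the pairing; by default every shared
        item_id is used, in the source's ordering.
        """
        src = source if isinstance(source, Mapping) else {it.item_id: it for it in source}
        tgt = target if isinstance(target, Mapping) else {it.item_id: it for it in target}
        if anchor_ids is None:
            anchor_ids = [iid for iid in src if iid in tgt]
        else:
            anchor_ids = [iid for iid in anchor_ids if iid in src and iid in tgt]
        if not anchor_ids:
            raise DegenerateAnchorError("no shared anchor items between the two estimate sets")
        return cls(
            item_ids=tuple(anchor_ids),
            a_source=np.array([src[i].a for i in anchor_ids]),
            b_source=np.array([src[i].b for i in anchor_ids]),
            c_source=np.array([src[i].c for i in anchor_ids]),
            a_target=np.array([tgt[i].a for i in anchor_ids]),
            b_target=np.array([tgt[i].b for i in anchor_ids]),
            c_target=np.array([tgt[i].c for i in anchor_ids]),
        )


def _with_meta(A: float, B: float, method: str, pairs: AnchorPairs,
               source_form: int, target_form: int) -> EquatingCoefficients:
    return EquatingCoefficients(A=float(A), B=float(B), method=method,
                                n_anchors=pairs.n, source_form=source_form,
                                target_form=target_form)


def ms_coefficients(pairs: AnchorPairs, source_form: int = 0, target_form: int = 0) -> EquatingCoefficients:
    """Mean-sigma: slope from the ratio of anchor-difficulty spreads.

    ``A = SD(b_target) / SD(b_source)`` so that the map agrees in direction
    with the mean-mean and mean-geometric-mean estimators.
    """
    if pairs.n < 2:
        raise DegenerateAnchorError("mean-sigma needs at least 2 anchors (an SD of 1 value is undefined)")
    sd_s = float(np.std(pairs.b_source))
    sd_t = float(np.std(pairs.b_target))
    if sd_s <= 0:
        raise DegenerateAnchorError("source anchor difficulties have zero spread")
    A = sd_t / sd_s
    B = float(np.mean(pairs.b_target) - A * np.mean(pairs.b_source))
    return _with_meta(A, B, "MS", pairs, source_form, target_form)


def mm_coefficients(pairs: AnchorPairs, source_form: int = 0, target_form: int = 0) -> EquatingCoefficients:
    """Mean-mean: ``A = sum(a_source) / sum(a_target)``; intercept from mean difficulties."""
    A = float(pairs.a_source.sum() / pairs.a_target.sum())
    B = float(np.mean(pairs.b_target) - A * np.mean(pairs.b_source))
    return _with_meta(A, B, "MM", pairs, source_form, target_form)


def mgm_coefficients(pairs: AnchorPairs, source_form: int = 0, target_form: int = 0) -> EquatingCoefficients:
    """Mean-geometric-mean: ``A`` is the geometric mean of per-anchor ratios."""
    A = float(np.exp(np.mean(np.log(pairs.a_source / pairs.a_target))))
    B = float(np.mean(pairs.b_target) - A * np.mean(pairs.b_source))
    return _with_meta(A, B, "MGM", pairs, source_form, target_form)


def _curve_loss(pairs: AnchorPairs, grid: QuadratureGrid, test_level: bool):
    nodes, weights = grid.nodes, grid.weights
    p_t = pairs.c_target[:, None] + (1 - pairs.c_target[:, None]) * expit(
        pairs.a_target[:, None] * (nodes[None, :] - pairs.b_target[:, None])
    )

    def loss(x: np.ndarray) -> float:
        A, B = x
        if A <= _A_MIN:
            return 1e12
        a_s = pairs.a_source[:, None] / A
        b_s = A * pairs.b_source[:, None] + B
        p_s = pairs.c_source[:, None] + (1 - pairs.c_source[:, None]) * expit(a_s * (nodes[None, :] - b_s))
        diff = p_t - p_s
        if test_level:
            val = 0.5 * float(weights @ diff.sum(axis=0) ** 2)
        else:
            val = 0.5 * float(weights @ (diff**2).sum(axis=0))
        if not np.isfinite(val):
            raise FloatingPointError(f"non-finite equating loss at A={A}, B={B}")
        return val

    return loss


def _curve_coefficients(
    pairs: AnchorPairs,
    grid: Optional[QuadratureGrid],
    init: Optional[EquatingCoefficients],
    test_level: bool,
    method: str,
    source_form: int,
    target_form: int,
) -> EquatingCoefficients:
    grid = grid or QuadratureGrid.standard_normal()
    if init is None:
        init = mm_coefficients(pairs)
    loss = _curve_loss(pairs, grid, test_level)
    res = minimize(loss, x0=np.array([init.A, init.B]), method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 2000})
    A, B = res.x
    # never return a point worse than the warm start
    if loss(res.x) > loss(np.array([init.A, init.B])):
        A, B = init.A, init.B
    return _with_meta(max(A, _A_MIN), B, method, pairs, source_form, target_form)


def irf_coefficients(
    pairs: AnchorPairs,
    grid: Optional[QuadratureGrid] = None,
    init: Optional[EquatingCoefficients] = None,
    source_form: int = 0,
    target_form: int = 0,
) -> EquatingCoefficients:
    """Haebara linking: minimize the weighted item-level squared ICC gap."""
    return _curve_coefficients(pairs, grid, init, False, "IRF", source_form, target_form)


def trf_coefficients(
    pairs: AnchorPairs,
    grid: Optional[QuadratureGrid] = None,
    init: Optional[EquatingCoefficients] = None,
    source_form: int = 0,
    target_form: int = 0,
) -> EquatingCoefficients:
    """Stocking-Lord linking: the square sits outside the sum over anchors."""
    return _curve_coefficients(pairs, grid, init, True, "TRF", source_form, target_form)


_DISPATCH = {
    "MS": ms_coefficients,
    "MM": mm_coefficients,
    "MGM": mgm_coefficients,
    "IRF": irf_coefficients,
    "TRF": trf_coefficients,
}


def compute_coefficients(method: str, pairs: AnchorPairs, source_form: int = 0,
                         target_form: int = 0, **kwargs) -> EquatingCoefficients:
    method = method.upper()
    if method not in _DISPATCH:
        raise ValueError(f"unknown equating method {method!r}; choose from {METHODS}")
    return _DISPATCH[method](pairs, source_form=source_form, target_form=target_form, **kwargs)


def transform_item(item: ItemParams, coef: EquatingCoefficients) -> ItemParams:
    """Map an item's parameters onto the target scale: ``b' = A b + B``, ``a' = a / A``, ``c' = c``."""
    return replace(item, a=item.a / coef.A, b=coef.A * item.b + coef.B)


def transform_theta(theta, coef: EquatingCoefficients):
    """Ability rescaling ``theta' = A theta + B`` matching the item map."""
    theta = np.asarray(theta, dtype=float)
    out = coef.A * theta + coef.B
    return out if out.ndim else float(out)


def chain_compose(link_coefs: Sequence[EquatingCoefficients]) -> EquatingCoefficients:
    """Compose adjacent links into one indirect-equating map.

    Links are applied in order; the result equals the functional
    composition of the individual linear maps.  Form indices must chain
    (target of link k is the source of link k+1) whenever they are set.
    """
    if not link_coefs:
        raise ValueError("need at least one link")
    A, B = 1.0, 0.0
    for k, coef in enumerate(link_coefs):
        if k > 0:
            prev = link_coefs[k - 1]
            if prev.target_form and coef.source_form and prev.target_form != coef.source_form:
                raise ValueError(
                    f"broken chain: link {k - 1} targets form {prev.target_form} "
                    f"but link {k} starts from form {coef.source_form}"
                )
        A, B = coef.A * A, coef.A * B + coef.B
    return EquatingCoefficients(
        A=A,
        B=B,
        method="+".join(c.method for c in link_coefs),
        n_anchors=min(c.n_anchors for c in link_coefs),
        source_form=link_coefs[0].source_form,
        target_form=link_coefs[-1].target_form,
    )
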