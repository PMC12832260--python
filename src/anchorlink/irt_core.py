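"""Core IRT primitives: parameter containers, ICCs, and response simulation.

The generating model is the three-parameter logistic ICC

    p(theta) = c + (1 - c) * logistic(a * (theta - b))

with ``a`` forced to 1 under the 1PL and ``c`` forced to 0 under the
1PL/2PL.  Item banks consist of three test forms linked by two disjoint
anchor blocks: forms 1 and 2 share the ``link12`` block, forms 2 and 3
share the ``link23`` block, and no item appears on both forms 1 and 3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Sequence, Tuple

import numpy as np
from scipy.special import expit

__all__ = [
    "ANCHOR_BLOCKS",
    "ItemParams",
    "ItemBank",
    "AbilitySample",
    "ResponseMatrix",
    "icc_probability",
    "lognormal_params_from_moments",
    "generate_item_bank",
    "generate_abilities",
    "simulate_responses",
]

ANCHOR_BLOCKS = ("none", "link12", "link23")


@dataclass(frozen=True)
class ItemParams:
    """A single item's generating or estimated parameter triple.

    Parameters
    ----------
    item_id : str
        Opaque identifier, unique within a bank.
    a : float
        Discrimination; must be strictly positive.
    b : float
        Difficulty on the logit scale; must be finite.
    c : float
        Guessing probability (lower asymptote) in ``[0, 1)``.
    anchor_block : str
        One of ``"none"``, ``"link12"`` (shared by forms 1 and 2) or
        ``"link23"`` (shared by forms 2 and 3).
    """

    item_id: str
    a: float
    b: float
    c: float = 0.0
    anchor_block: str = "none"

    def __post_init__(self) -> None:
        if not (np.isfinite(self.a) and self.a > 0):
            raise ValueError(f"item {self.item_id!r}: discrimination a must be finite and > 0, got {self.a}")
        if not np.isfinite(self.b):
            raise ValueError(f"item {self.item_id!r}: difficulty b must be finite, got {self.b}")
        if not (np.isfinite(self.c) and 0.0 <= self.c < 1.0):
            raise ValueError(f"item {self.item_id!r}: guessing c must lie in [0, 1), got {self.c}")
        if self.anchor_block not in ANCHOR_BLOCKS:
            raise ValueError(f"item {self.item_id!r}: unknown anchor_block {self.anchor_block!r}")


@dataclass(frozen=True)
class ItemBank:
    """Three test forms drawn from a common item pool.

    ``form_assignment`` maps each item_id to the frozen set of form indices
    (subset of {1, 2, 3}) on which the item appears.  Anchor items appear on
    exactly two adjacent forms; unique items on exactly one.
    """

    items: Tuple[ItemParams, ...]
    form_assignment: Dict[str, FrozenSet[int]]

    def __post_init__(self) -> None:
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate item_id in bank")
        if set(ids) != set(self.form_assignment):
            raise ValueError("form_assignment keys must match item ids exactly")
        for it in self.items:
            forms = self.form_assignment[it.item_id]
            if not forms or not forms <= {1, 2, 3}:
                raise ValueError(f"item {it.item_id!r}: invalid form set {set(forms)}")
            if len(forms) > 2:
                raise ValueError(f"item {it.item_id!r} assigned to more than two forms")
            if forms == {1, 3}:
                raise ValueError(f"item {it.item_id!r} shared between forms 1 and 3")
            if it.anchor_block == "link12" and forms != {1, 2}:
                raise ValueError(f"link12 anchor {it.item_id!r} must sit on forms 1 and 2")
            if it.anchor_block == "link23" and forms != {2, 3}:
                raise ValueError(f"link23 anchor {it.item_id!r} must sit on forms 2 and 3")
            if it.anchor_block == "none" and len(forms) != 1:
                raise ValueError(f"non-anchor item {it.item_id!r} must sit on exactly one form")

    def form_items(self, form_index: int) -> Tuple[ItemParams, ...]:
        """Items of one form, in bank order."""
        if form_index not in (1, 2, 3):
            raise ValueError(f"form_index must be 1, 2 or 3, got {form_index}")
        return tuple(it for it in self.items if form_index in self.form_assignment[it.item_id])

    def anchors(self, block: str) -> Tuple[ItemParams, ...]:
        if block not in ("link12", "link23"):
            raise ValueError(f"block must be 'link12' or 'link23', got {block!r}")
        return tuple(it for it in self.items if it.anchor_block == block)


@dataclass(frozen=True)
class AbilitySample:
    """Person abilities for one form, with the generating moments attached."""

    person_ids: Tuple[str, ...]
    theta: np.ndarray
    form_index: int
    mu: float
    sigma: float

    def __post_init__(self) -> None:
        theta = np.asarray(self.theta, dtype=float)
        object.__setattr__(self, "theta", theta)
        if theta.ndim != 1 or theta.size < 1:
            raise ValueError("theta must be a nonempty 1-D array")
        if len(self.person_ids) != theta.size:
            raise ValueError("person_ids and theta length mismatch")
        if not np.all(np.isfinite(theta)):
            raise ValueError("theta contains non-finite values")

    @property
    def n(self) -> int:
        return self.theta.size


@dataclass(frozen=True)
class ResponseMatrix:
    """Persons x items binary outcomes for a single form (no missingness)."""

    values: np.ndarray
    person_ids: Tuple[str, ...]
    item_ids: Tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.int8)
        object.__setattr__(self, "values", values)
        if values.ndim != 2:
            raise ValueError("values must be 2-D (persons x items)")
        if values.shape != (len(self.person_ids), len(self.item_ids)):
            raise ValueError(
                f"shape {values.shape} inconsistent with {len(self.person_ids)} persons "
                f"x {len(self.item_ids)} items"
            )
        if not np.isin(values, (0, 1)).all():
            raise ValueError("responses must be 0 or 1 with no missing entries within a form")

    @property
    def n_persons(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]


def icc_probability(theta, item: ItemParams, model: str = "3PL"):
    """Item characteristic curve: probability of a correct response.

    ``model`` selects the constraint set: 1PL forces ``a = 1`` and
    ``c = 0``; 2PL forces ``c = 0``; 3PL uses the item's parameters as-is.
    Accepts scalar or array ``theta``.
    """
    theta = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(theta)):
        raise ValueError("theta must be finite")
    if model not in ("1PL", "2PL", "3PL"):
        raise ValueError(f"unknown model {model!r}")
    a = 1.0 if model == "1PL" else item.a
    c = 0.0 if model in ("1PL", "2PL") else item.c
    p = c + (1.0 - c) * expit(a * (theta - item.b))
    return p if p.ndim else float(p)


def lognormal_params_from_moments(mean: float, sd: float) -> Tuple[float, float]:
    """Underlying normal (mu, sigma) of a log-normal with the given mean/SD.

    The moments refer to the log-normal variable itself:
    ``sigma^2 = ln(1 + (sd/mean)^2)`` and ``mu = ln(mean) - sigma^2 / 2``.
    A zero ``sd`` degenerates to a point mass at ``mean``.
    """
    if mean <= 0:
        raise ValueError("log-normal mean must be positive")
    if sd < 0:
        raise ValueError("log-normal sd must be nonnegative")
    if sd == 0:
        return math.log(mean), 0.0
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def generate_item_bank(
    tss: int,
    n_anchor: int,
    a_dist: Tuple[float, float] = (1.0, 0.2),
    b_dist: Tuple[float, float] = (0.0, 1.0),
    c: float = 0.0,
    rng_seed=None,
    anchor_a: float | None = None,
) -> ItemBank:
    """Generate three linked forms of ``tss`` items each.

    Discriminations are log-normal with mean/SD ``a_dist`` (moments of the
    values, not of their logs); difficulties are normal with mean/SD
    ``b_dist``; every item carries the common guessing probability ``c``.
    Forms 1 and 2 share ``n_anchor`` items, forms 2 and 3 share a disjoint
    block of ``n_anchor`` items; form 2 hosts both blocks, hence the
    requirement ``n_anchor <= floor(tss / 2)``.

    ``anchor_a`` optionally fixes the discrimination of every anchor item
    to a constant (manipulated anchor quality); unique items are unaffected.
    """
    if tss < 1:
        raise ValueError(f"tss must be a positive integer, got {tss}")
    if not 1 <= n_anchor <= tss // 2:
        raise ValueError(
            f"n_anchor must satisfy 1 <= n_anchor <= floor(tss/2) = {tss // 2} "
            f"(form 2 hosts both anchor blocks), got {n_anchor}"
        )
    if not 0.0 <= c < 1.0:
        raise ValueError(f"guessing probability must lie in [0, 1), got {c}")
    rng = np.random.default_rng(rng_seed)
    n_total = 3 * tss - 2 * n_anchor
    mu_a, sigma_a = lognormal_params_from_moments(*a_dist)
    a = np.exp(mu_a + sigma_a * rng.standard_normal(n_total))
    b = b_dist[0] + b_dist[1] * rng.standard_normal(n_total)

    # Layout: [form1 unique | link12 | form2 unique | link23 | form3 unique]
    n_unique1 = tss - n_anchor
    n_unique2 = tss - 2 * n_anchor
    n_unique3 = tss - n_anchor
    blocks: List[Tuple[str, int, FrozenSet[int]]] = [
        ("u1", n_unique1, frozenset({1})),
        ("link12", n_anchor, frozenset({1, 2})),
        ("u2", n_unique2, frozenset({2})),
        ("link23", n_anchor, frozenset({2, 3})),
        ("u3", n_unique3, frozenset({3})),
    ]
    items: List[ItemParams] = []
    assignment: Dict[str, FrozenSet[int]] = {}
    pos = 0
    for tag, count, forms in blocks:
        is_anchor = tag in ("link12", "link23")
        for k in range(count):
            item_id = f"{tag}_{k:03d}"
            a_k = anchor_a if (is_anchor and anchor_a is not None) else float(a[pos])
            items.append(
                ItemParams(
                    item_id=item_id,
                    a=a_k,
                    b=float(b[pos]),
                    c=c,
                    anchor_block=tag if is_anchor else "none",
                )
            )
            assignment[item_id] = forms
            pos += 1
    return ItemBank(items=tuple(items), form_assignment=assignment)


def generate_abilities(n: int, mu: float, sigma: float, form_index: int, rng_seed=None) -> AbilitySample:
    """Draw ``n`` abilities from Normal(mu, sigma) for one form's sample."""
    if n < 1:
        raise ValueError(f"sample size must be >= 1, got {n}")
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    rng = np.random.default_rng(rng_seed)
    theta = mu + sigma * rng.standard_normal(n)
    person_ids = tuple(f"f{form_index}_p{k:05d}" for k in range(n))
    return AbilitySample(person_ids=person_ids, theta=theta, form_index=form_index, mu=mu, sigma=sigma)


def simulate_responses(
    abilities: AbilitySample,
    form_items: Sequence[ItemParams],
    model: str = "3PL",
    rng_seed=None,
) -> ResponseMatrix:
    """Bernoulli response simulation under the generating ICC.

    Generation always honors each item's ``c``; requesting ``model="2PL"``
    for items with ``c > 0`` is rejected because the 2PL-vs-3PL distinction
    belongs to calibration, not data generation.
    """
    if model not in ("2PL", "3PL"):
        raise ValueError(f"model must be '2PL' or '3PL', got {model!r}")
    items = tuple(form_items)
    if not items:
        raise ValueError("form_items must be nonempty")
    if model == "2PL" and any(it.c > 0 for it in items):
        raise ValueError("model='2PL' requested but items carry c > 0; generation must honor c (use model='3PL')")
    a = np.array([it.a for it in items])
    b = np.array([it.b for it in items])
    c = np.array([it.c for it in items])
    p = c + (1.0 - c) * expit(a * (abilities.theta[:, None] - b))
    rng = np.random.default_rng(rng_seed)
    values = (rng.random(p.shape) < p).astype(np.int8)
    return ResponseMatrix(
        values=values,
        person_ids=abilities.person_ids,
        item_ids=tuple(it.item_id for it in items),
    )
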