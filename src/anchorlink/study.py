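"""Factorial simulation study: generate, calibrate, equate, score recovery.

A scenario fixes test-set size (tss), anchor-item proportion (aip), sample
size per form (n) and the common guessing probability (c).  One iteration
draws a fresh item bank and three ability samples — Normal(-0.5, 0.8),
Normal(0.0, 1.0) and Normal(+0.5, 1.2) for forms 1..3 — simulates
responses, calibrates each form under 2PL and 3PL, links forms 1 and 3
onto the form-2 reference scale with each equating method, and scores
parameter recovery for discriminations, difficulties and abilities against
the generating values.

Form 2 is the reference scale because its sample is standard normal: the
sample-standardized calibration scale then coincides in expectation with
the generating metric, so true parameters are comparable without
re-standardization.  The 1->3 chain is composed and recorded for
chain-consistency checks.

Within an iteration, the same item bank, abilities and response matrices
feed every model and method (common random numbers).
"""

from __future__ import annotations

import itertools
import logging
import zlib
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from anchorlink.calibration import CalibrationSettings, fit_irt
from anchorlink.equating import (
    AnchorPairs,
    DegenerateAnchorError,
    EquatingCoefficients,
    chain_compose,
    compute_coefficients,
    transform_item,
    transform_theta,
)
from anchorlink.irt_core import (
    AbilitySample,
    ResponseMatrix,
    generate_abilities,
    generate_item_bank,
    simulate_responses,
)
from anchorlink.recovery import RecoveryIndices, compute_indices

__all__ = [
    "SAMPLE_MOMENTS",
    "ScenarioSpec",
    "StudyConfig",
    "IterationRecord",
    "ConvergenceStats",
    "StudyResults",
    "n_anchor_for",
    "sampling_error_of_mean",
    "sampling_error_of_variance",
    "guessing_from_distractors",
    "build_design_grid",
    "run_iteration",
    "run_study",
    "convergence_stats",
]

logger = logging.getLogger(__name__)

#: (mean, SD) of the generating ability distribution for forms 1, 2, 3.
SAMPLE_MOMENTS = ((-0.5, 0.8), (0.0, 1.0), (0.5, 1.2))

DEFAULT_TSS = (20, 40, 60, 80)
DEFAULT_AIP = (0.05, 0.10, 0.15, 0.20, 0.25)
DEFAULT_N = (25, 50, 100, 500, 1000)
DEFAULT_C = (0.000, 0.125, 0.167, 0.250)


def n_anchor_for(aip: float, tss: int) -> int:
    """Anchor count per link: round-half-up of aip*tss, never below 1."""
    return max(1, int(np.floor(aip * tss + 0.5)))


def sampling_error_of_mean(n: int, sigma: float = 1.0) -> float:
    """Closed-form SE of the sample mean of n draws from Normal(mu, sigma)."""
    if n < 1 or sigma <= 0:
        raise ValueError("need n >= 1 and sigma > 0")
    return sigma / np.sqrt(n)


def sampling_error_of_variance(n: int, sigma: float = 1.0) -> float:
    """Closed-form SE of the unbiased sample variance of a normal sample:
    sqrt(2 sigma^4 / (n - 1))."""
    if n < 2 or sigma <= 0:
        raise ValueError("need n >= 2 and sigma > 0")
    return float(np.sqrt(2.0 * sigma**4 / (n - 1)))


def guessing_from_distractors(d: int) -> float:
    """Guessing probability of a multiple-choice item with d distractors: 1/d."""
    if d < 1:
        raise ValueError("need at least one distractor")
    return 1.0 / d


@dataclass(frozen=True)
class ScenarioSpec:
    tss: int
    aip: float
    n: int
    c: float
    scenario_id: str = ""

    def __post_init__(self) -> None:
        if self.tss < 2:
            raise ValueError(f"tss must be >= 2, got {self.tss}")
        if not 0 < self.aip <= 0.5:
            raise ValueError(f"aip must lie in (0, 0.5], got {self.aip}")
        if self.n < 2:
            raise ValueError(f"n must be >= 2, got {self.n}")
        if not 0 <= self.c < 1:
            raise ValueError(f"c must lie in [0, 1), got {self.c}")
        if not self.scenario_id:
            object.__setattr__(
                self, "scenario_id", f"tss{self.tss}_aip{self.aip:g}_n{self.n}_c{self.c:g}"
            )

    @property
    def n_anchor(self) -> int:
        return n_anchor_for(self.aip, self.tss)


@dataclass
class StudyConfig:
    tss_levels: Tuple[int, ...] = DEFAULT_TSS
    aip_levels: Tuple[float, ...] = DEFAULT_AIP
    n_levels: Tuple[int, ...] = DEFAULT_N
    c_levels: Tuple[float, ...] = DEFAULT_C
    iterations: int = 1000
    master_seed: int = 0
    models: Tuple[str, ...] = ("2PL", "3PL")
    methods: Tuple[str, ...] = ("MS", "MM", "MGM", "IRF", "TRF")
    calibration: CalibrationSettings = field(default_factory=CalibrationSettings)
    anchor_a: Optional[float] = None  # fixed anchor discrimination override

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        bad = set(m.upper() for m in self.models) - {"2PL", "3PL"}
        if bad:
            raise ValueError(f"unknown models: {sorted(bad)}")
        bad = set(m.upper() for m in self.methods) - {"MS", "MM", "MGM", "IRF", "TRF"}
        if bad:
            raise ValueError(f"unknown methods: {sorted(bad)}")
        self.models = tuple(m.upper() for m in self.models)
        self.methods = tuple(m.upper() for m in self.methods)


@dataclass(frozen=True)
class IterationRecord:
    """One iteration's recovery indices and convergence bookkeeping.

    ``indices`` maps (model, method, parameter) -> RecoveryIndices for the
    model x method combinations where all three forms converged and
    equating succeeded; ``failures`` maps (model, method) -> reason for the
    rest.  ``chain_13`` holds the composed 1->3 coefficients per
    (model, method) for chain-consistency checks.
    """

    scenario: ScenarioSpec
    iteration: int
    indices: Dict[Tuple[str, str, str], RecoveryIndices]
    failures: Dict[Tuple[str, str], str]
    m_aa: float
    converged_forms: Dict[str, int]
    chain_13: Dict[Tuple[str, str], EquatingCoefficients]

    def all_converged(self, model: str) -> bool:
        return self.converged_forms.get(model, 0) == 3


@dataclass(frozen=True)
class ConvergenceStats:
    """Per-scenario and overall convergence summaries.

    ``per_scenario`` has one row per scenario x model with columns ``cr``
    (share of iterations with all 3 forms converged) and ``mean_forms``.
    ``total_rate`` is converged form-fits / attempted form-fits pooled over
    everything; ``mean_converged_forms`` the pooled mean of per-estimation
    converged-form counts.
    """

    per_scenario: pd.DataFrame
    total_rate: float
    mean_converged_forms: float


@dataclass(frozen=True)
class StudyResults:
    records: pd.DataFrame  # long format, one row per iteration x model x method x parameter
    convergence: pd.DataFrame  # one row per scenario x iteration x model
    config: StudyConfig


def build_design_grid(config: StudyConfig) -> List[ScenarioSpec]:
    """Full factorial tss x aip x n x c, in stable declaration order."""
    for name, levels in (("tss", config.tss_levels), ("aip", config.aip_levels),
                         ("n", config.n_levels), ("c", config.c_levels)):
        if not levels:
            raise ValueError(f"empty level set for factor {name}")
    return [
        ScenarioSpec(tss=tss, aip=aip, n=n, c=c)
        for tss, aip, n, c in itertools.product(
            config.tss_levels, config.aip_levels, config.n_levels, config.c_levels
        )
    ]


def _iteration_seeds(master_seed: int, scenario: ScenarioSpec, iteration: int) -> List[np.random.SeedSequence]:
    """Deterministic child streams: bank, abilities x3, responses x3."""
    # stable across processes (unlike builtin str hash)
    scen_key = zlib.crc32(scenario.scenario_id.encode())
    root = np.random.SeedSequence(entropy=master_seed, spawn_key=(scen_key, iteration))
    return root.spawn(7)


def run_iteration(
    scenario: ScenarioSpec,
    iteration: int,
    config: StudyConfig,
) -> IterationRecord:
    """Execute one full generate -> calibrate -> equate -> score pass."""
    seeds = _iteration_seeds(config.master_seed, scenario, iteration)
    bank = generate_item_bank(
        tss=scenario.tss,
        n_anchor=scenario.n_anchor,
        c=scenario.c,
        rng_seed=seeds[0],
        anchor_a=config.anchor_a,
    )
    samples: List[AbilitySample] = []
    responses: List[ResponseMatrix] = []
    for j, (mu, sd) in enumerate(SAMPLE_MOMENTS, start=1):
        sample = generate_abilities(scenario.n, mu, sd, form_index=j, rng_seed=seeds[j])
        samples.append(sample)
        responses.append(
            simulate_responses(sample, bank.form_items(j), model="3PL", rng_seed=seeds[3 + j])
        )

    true_by_id = {it.item_id: it for it in bank.items}
    anchors = bank.anchors("link12") + bank.anchors("link23")
    m_aa = float(np.mean([it.a for it in anchors]))

    indices: Dict[Tuple[str, str, str], RecoveryIndices] = {}
    failures: Dict[Tuple[str, str], str] = {}
    converged_forms: Dict[str, int] = {}
    chain_13: Dict[Tuple[str, str], EquatingCoefficients] = {}

    for model in config.models:
        fits = [fit_irt(resp, model=model, settings=config.calibration) for resp in responses]
        n_conv = sum(f.converged for f in fits)
        converged_forms[model] = n_conv
        if n_conv < 3:
            for method in config.methods:
                failures[(model, method)] = f"{3 - n_conv} form(s) failed to converge"
            continue
        est = [f.estimates_by_id() for f in fits]
        link12_ids = [it.item_id for it in bank.anchors("link12")]
        link23_ids = [it.item_id for it in bank.anchors("link23")]
        for method in config.methods:
            try:
                pairs12 = AnchorPairs.from_estimates(est[0], est[1], link12_ids)
                pairs32 = AnchorPairs.from_estimates(est[2], est[1], link23_ids)
                coef12 = compute_coefficients(method, pairs12, source_form=1, target_form=2)
                coef32 = compute_coefficients(method, pairs32, source_form=3, target_form=2)
            except (DegenerateAnchorError, FloatingPointError) as exc:
                failures[(model, method)] = f"equating failed: {exc}"
                continue
            chain_13[(model, method)] = chain_compose([coef12, coef32.inverse()])

            # pool item estimates on the reference (form 2) scale; anchors
            # contribute one estimate per form on which they were calibrated
            true_a: List[float] = []
            true_b: List[float] = []
            est_a: List[float] = []
            est_b: List[float] = []
            for form_idx, coef in ((1, coef12), (2, None), (3, coef32)):
                for iid, it_est in est[form_idx - 1].items():
                    placed = transform_item(it_est, coef) if coef else it_est
                    true_a.append(true_by_id[iid].a)
                    true_b.append(true_by_id[iid].b)
                    est_a.append(placed.a)
                    est_b.append(placed.b)
            true_theta = np.concatenate([s.theta for s in samples])
            est_theta = np.concatenate(
                [
                    transform_theta(fits[0].theta_hat, coef12),
                    fits[1].theta_hat,
                    transform_theta(fits[2].theta_hat, coef32),
                ]
            )
            indices[(model, method, "a")] = compute_indices(true_a, est_a, "a")
            indices[(model, method, "b")] = compute_indices(true_b, est_b, "b")
            indices[(model, method, "theta")] = compute_indices(true_theta, est_theta, "theta")

    return IterationRecord(
        scenario=scenario,
        iteration=iteration,
        indices=indices,
        failures=failures,
        m_aa=m_aa,
        converged_forms=converged_forms,
        chain_13=chain_13,
    )


def _record_rows(rec: IterationRecord) -> List[dict]:
    base = {
        "scenario_id": rec.scenario.scenario_id,
        "tss": rec.scenario.tss,
        "aip": rec.scenario.aip,
        "n": rec.scenario.n,
        "c": rec.scenario.c,
        "iteration": rec.iteration,
        "m_aa": rec.m_aa,
    }
    rows = []
    for (model, method, parameter), idx in rec.indices.items():
        rows.append(
            {
                **base,
                "model": model,
                "method": method,
                "parameter": parameter,
                **idx.as_dict(),
                "n_used": idx.n_used,
                "converged_forms": rec.converged_forms[model],
            }
        )
    return rows


def run_study(
    config: StudyConfig,
    scenarios: Optional[Sequence[ScenarioSpec]] = None,
    progress: Optional[Callable[[str, int, int], None]] = None,
) -> StudyResults:
    """Run every scenario x iteration and collect long-format results.

    Results are deterministic under a fixed ``master_seed`` regardless of
    execution order because every iteration derives its own seed streams.
    Failures (non-convergence, degenerate anchors) are recorded in the
    convergence table and as absent index rows, never raised.
    """
    scenarios = list(scenarios) if scenarios is not None else build_design_grid(config)
    rows: List[dict] = []
    conv_rows: List[dict] = []
    for s_idx, scenario in enumerate(scenarios):
        for it in range(config.iterations):
            rec = run_iteration(scenario, it, config)
            rows.extend(_record_rows(rec))
            for model in config.models:
                conv_rows.append(
                    {
                        "scenario_id": scenario.scenario_id,
                        "tss": scenario.tss,
                        "aip": scenario.aip,
                        "n": scenario.n,
                        "c": scenario.c,
                        "iteration": it,
                        "model": model,
                        "converged_forms": rec.converged_forms[model],
                        "all_converged": rec.all_converged(model),
                        "n_failures": sum(1 for (m, _m2) in rec.failures if m == model),
                    }
                )
        if progress is not None:
            progress(scenario.scenario_id, s_idx + 1, len(scenarios))
        else:
            logger.info("scenario %s done (%d/%d)", scenario.scenario_id, s_idx + 1, len(scenarios))
    columns = [
        "scenario_id", "tss", "aip", "n", "c", "iteration", "m_aa", "model",
        "method", "parameter", "r", "bias", "rmse", "mae", "see", "n_used",
        "converged_forms",
    ]
    records = pd.DataFrame(rows, columns=columns) if rows else pd.DataFrame(columns=columns)
    convergence = pd.DataFrame(conv_rows)
    return StudyResults(records=records, convergence=convergence, config=config)


def convergence_stats(convergence: pd.DataFrame) -> ConvergenceStats:
    """Aggregate the per-iteration convergence table.

    ``cr`` per scenario x model is the share of iterations in which all
    three forms converged; ``total_rate`` pools individual form-fits
    (3 per iteration x model) over the whole table.
    """
    if convergence.empty:
        raise ValueError("empty convergence table")
    per = (
        convergence.groupby(["scenario_id", "model"], sort=True)
        .agg(
            cr=("all_converged", "mean"),
            mean_forms=("converged_forms", "mean"),
            n_iterations=("iteration", "count"),
        )
        .reset_index()
    )
    total_rate = float(convergence["converged_forms"].sum() / (3 * len(convergence)))
    mean_forms = float(convergence["converged_forms"].mean())
    return ConvergenceStats(per_scenario=per, total_rate=total_rate, mean_converged_forms=mean_forms)
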