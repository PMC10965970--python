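"""Self-consistency studies for the ABC engine.

These routines quantify, on fully synthetic data, how well the ABC analysis
recovers a known scenario and mutation rate. mtDNA is a single locus, so
scenario resolution is intrinsically weak; the studies report honest rates
rather than asserting success.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from bridgehead.abc_engine import (
    PriorSpec,
    ReferenceTable,
    build_reference_table,
    direct_posterior,
    estimate_parameters,
    logistic_posterior,
    simulate_summary,
)
from bridgehead.coalescent import DOUBLE, POPULATIONS, SINGLE, MutationModel, ScenarioSpec


@dataclass
class RecoveryResult:
    n_datasets: int
    n_modal_correct_direct: int
    n_modal_correct_logistic: int

    @property
    def direct_rate(self) -> float:
        return self.n_modal_correct_direct / self.n_datasets

    @property
    def logistic_rate(self) -> float:
        return self.n_modal_correct_logistic / self.n_datasets


def _observed_under(
    scenario_id: str,
    draw: dict[str, float],
    model_template: MutationModel,
    rng: np.random.Generator,
) -> np.ndarray:
    spec = ScenarioSpec(scenario_id).with_parameters(
        ne={p: draw[f"ne_{p}"] for p in POPULATIONS}
    )
    model = MutationModel(
        mu=draw["mu"],
        L=model_template.L,
        base_freqs=model_template.base_freqs,
        kappa_CT=model_template.kappa_CT,
        kappa_AG=model_template.kappa_AG,
        p_invariant=model_template.p_invariant,
        gamma_shape=model_template.gamma_shape,
        gamma_categories=model_template.gamma_categories,
    )
    return simulate_summary(spec, model, rng)


def scenario_recovery_study(
    table: ReferenceTable,
    priors: PriorSpec,
    model_template: MutationModel,
    n_per_scenario: int = 20,
    truth_prior_fraction: float = 0.5,
    n_closest: int = 500,
    closest_fraction: float = 0.01,
    seed: int = 0,
) -> RecoveryResult:
    """Modal-scenario recovery over synthetic observed datasets.

    Truth parameters are drawn from the priors restricted to their central
    `truth_prior_fraction`; each observed dataset is analysed against the
    shared reference table with both the direct and the logistic method.
    """
    rng = np.random.default_rng(seed)
    truth_priors = priors.central(truth_prior_fraction)
    n_closest = min(n_closest, table.n_rows)
    correct_direct = correct_logistic = 0
    n_total = 0
    for scenario in (SINGLE, DOUBLE):
        for _ in range(n_per_scenario):
            draw = truth_priors.draw(rng)
            observed = _observed_under(scenario, draw, model_template, rng)
            d = direct_posterior(table, observed, n_closest=n_closest, n_boot=200, rng=rng)
            g = logistic_posterior(table, observed, closest_fraction=closest_fraction)
            correct_direct += d.modal_scenario() == scenario
            correct_logistic += g.modal_scenario() == scenario
            n_total += 1
    return RecoveryResult(n_total, correct_direct, correct_logistic)


@dataclass
class CoverageResult:
    n_runs: int
    n_covered: int
    median_log10_ratio: float  # median |log10(posterior median / truth)|
    n_within_factor3: int = 0

    @property
    def coverage(self) -> float:
        return self.n_covered / self.n_runs

    @property
    def median_factor(self) -> float:
        return float(10.0**self.median_log10_ratio)

    @property
    def factor3_rate(self) -> float:
        return self.n_within_factor3 / self.n_runs


def mu_coverage_study(
    table: ReferenceTable,
    priors: PriorSpec,
    model_template: MutationModel,
    n_runs: int = 20,
    truth_prior_fraction: float = 0.5,
    closest_fraction: float = 0.01,
    seed: int = 0,
) -> CoverageResult:
    """How often the 95% HPD for mu covers the truth, plus median accuracy."""
    rng = np.random.default_rng(seed)
    truth_priors = priors.central(truth_prior_fraction)
    covered = 0
    ratios = []
    for k in range(n_runs):
        scenario = SINGLE if k % 2 == 0 else DOUBLE
        draw = truth_priors.draw(rng)
        observed = _observed_under(scenario, draw, model_template, rng)
        post = estimate_parameters(
            table, observed, closest_fraction=closest_fraction, parameters=("mu",)
        )[0]
        lo, hi = post.hpd95
        covered += lo <= draw["mu"] <= hi
        ratios.append(abs(np.log10(post.point / draw["mu"])))
    within3 = int(sum(r <= np.log10(3.0) for r in ratios))
    return CoverageResult(n_runs, covered, float(np.median(ratios)), within3)
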