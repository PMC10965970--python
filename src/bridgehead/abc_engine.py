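"""ABC scenario comparison and parameter estimation (rejection + regression).

Implements the standard DIYABC-style workflow on the serial-introduction
simulator: a reference table of prior draws and their 20 summary statistics,
scenario choice by the direct method (scenario frequency among the closest
simulations) and by logistic regression of the scenario label on statistic
deviations, and parameter estimation by local-linear regression adjustment of
the closest simulations with Epanechnikov kernel weights.

Summary statistics are standardised by their median absolute deviation over
the whole reference table before distances are computed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from bridgehead.coalescent import (
    DOUBLE,
    POPULATIONS,
    SINGLE,
    MutationModel,
    ScenarioSpec,
    evolve_sequences_codes,
    population_groups,
    sample_genealogy,
)
from bridgehead.popgen_stats import summary_from_codes, summary_stat_names

logger = logging.getLogger(__name__)

#: Parameter column order of the reference table.
PARAM_NAMES = ("mu",) + tuple(f"ne_{p}" for p in POPULATIONS)


@dataclass
class PriorSpec:
    """Flat priors: mutation rate (substitutions/site/generation) and Ne's."""

    mu_bounds: tuple[float, float] = (1.115e-8, 1.5e-5)
    ne_bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {p: (10.0, 100_000.0) for p in POPULATIONS}
    )

    def __post_init__(self) -> None:
        bounds = [self.mu_bounds, *self.ne_bounds.values()]
        if any(lo <= 0 or lo >= hi for lo, hi in bounds):
            raise ValueError("prior bounds must be positive with min < max")

    def draw(self, rng: np.random.Generator) -> dict[str, float]:
        params = {"mu": rng.uniform(*self.mu_bounds)}
        for p in POPULATIONS:
            params[f"ne_{p}"] = rng.uniform(*self.ne_bounds[p])
        return params

    def central(self, fraction: float = 0.5) -> "PriorSpec":
        """Priors restricted to the central `fraction` of each flat range."""
        def mid(lo: float, hi: float) -> tuple[float, float]:
            half = fraction / 2.0
            return lo + (0.5 - half) * (hi - lo), lo + (0.5 + half) * (hi - lo)

        return PriorSpec(
            mu_bounds=mid(*self.mu_bounds),
            ne_bounds={p: mid(*b) for p, b in self.ne_bounds.items()},
        )


@dataclass
class ReferenceTable:
    """Per-simulation scenario labels, parameters and summary statistics."""

    scenarios: np.ndarray  # (n,) str
    params: np.ndarray  # (n, len(PARAM_NAMES))
    stats: np.ndarray  # (n, 20)
    stat_names: tuple[str, ...]
    scale: np.ndarray  # (20,) MAD-based standardisation

    @property
    def n_rows(self) -> int:
        return len(self.scenarios)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.stats, columns=list(self.stat_names))
        for i, name in enumerate(PARAM_NAMES):
            df.insert(i, name, self.params[:, i])
        df.insert(0, "scenario", self.scenarios)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ReferenceTable":
        stat_names = tuple(c for c in df.columns if c not in ("scenario", *PARAM_NAMES))
        stats = df[list(stat_names)].to_numpy(float)
        return cls(
            df["scenario"].to_numpy(str),
            df[list(PARAM_NAMES)].to_numpy(float),
            stats,
            stat_names,
            _mad_scale(stats),
        )


def _mad_scale(stats: np.ndarray) -> np.ndarray:
    """Per-statistic MAD; statistics whose MAD degenerates to 0 (e.g. counts
    pinned at their maximum for most of the prior) fall back to the standard
    deviation, then to 1 for truly constant columns."""
    med = np.median(stats, axis=0)
    mad = np.median(np.abs(stats - med), axis=0)
    zero = mad == 0
    if zero.any():
        sd = stats.std(axis=0)
        mad[zero] = np.where(sd[zero] > 0, sd[zero], 1.0)
        logger.warning(
            "%d summary statistics have zero MAD; falling back to SD", zero.sum()
        )
    return mad


def simulate_summary(spec: ScenarioSpec, model: MutationModel, rng: np.random.Generator) -> np.ndarray:
    """One prior-conditional simulation reduced to its 20 summary statistics."""
    genealogy = sample_genealogy(spec, rng)
    codes = evolve_sequences_codes(genealogy, model, rng)
    return summary_from_codes(codes, population_groups(spec))


def build_reference_table(
    n_per_scenario: int,
    priors: PriorSpec,
    model_template: MutationModel,
    specs: tuple[ScenarioSpec, ScenarioSpec] | None = None,
    rng: np.random.Generator | int = 0,
) -> ReferenceTable:
    """Simulate the ABC reference table: balanced prior draws per scenario."""
    if n_per_scenario < 1:
        raise ValueError("n_per_scenario must be >= 1")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if specs is None:
        specs = (ScenarioSpec(SINGLE), ScenarioSpec(DOUBLE))
    scenarios, params, stats = [], [], []
    for spec in specs:
        for i in range(n_per_scenario):
            draw = priors.draw(rng)
            sim_spec = spec.with_parameters(
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
            try:
                vec = simulate_summary(sim_spec, model, rng)
            except Exception as exc:  # pragma: no cover - defensive
                raise RuntimeError(
                    f"simulation failed at scenario {spec.scenario_id!r} row {i}"
                ) from exc
            scenarios.append(spec.scenario_id)
            params.append([draw[name] for name in PARAM_NAMES])
            stats.append(vec)
    stats_arr = np.asarray(stats)
    if not np.isfinite(stats_arr).all():
        raise ValueError("non-finite summary statistics in reference table")
    return ReferenceTable(
        np.asarray(scenarios),
        np.asarray(params),
        stats_arr,
        summary_stat_names(list(POPULATIONS)),
        _mad_scale(stats_arr),
    )


@dataclass
class ScenarioPosterior:
    method: str
    prob: dict[str, float]
    interval: dict[str, tuple[float, float]]

    def modal_scenario(self) -> str:
        return max(self.prob, key=self.prob.get)


def _closest_indices(table: ReferenceTable, observed: np.ndarray, m: int) -> tuple[np.ndarray, np.ndarray]:
    """Indices of the m nearest rows (standardised Euclidean) and distances.

    Ties at the cutoff are broken by simulation index (stable argsort).
    """
    dev = (table.stats - observed[None, :]) / table.scale[None, :]
    dist = np.sqrt((dev**2).sum(axis=1))
    order = np.argsort(dist, kind="stable")[:m]
    return order, dist[order]


def direct_posterior(
    table: ReferenceTable,
    observed: np.ndarray,
    n_closest: int = 500,
    n_boot: int = 10_000,
    rng: np.random.Generator | int = 0,
) -> ScenarioPosterior:
    """Scenario frequency among the closest simulations, bootstrap 95% interval."""
    observed = np.asarray(observed, dtype=float)
    if n_closest > table.n_rows:
        raise ValueError("n_closest exceeds reference-table size")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    idx, _ = _closest_indices(table, observed, n_closest)
    labels = table.scenarios[idx]
    scen_names = sorted(set(table.scenarios.tolist()))
    prob = {s: float((labels == s).mean()) for s in scen_names}
    boot = rng.choice(labels, size=(n_boot, n_closest), replace=True)
    interval = {}
    for s in scen_names:
        freqs = (boot == s).mean(axis=1)
        lo, hi = np.quantile(freqs, [0.025, 0.975])
        interval[s] = (float(lo), float(hi))
    return ScenarioPosterior("direct", prob, interval)


def logistic_posterior(
    table: ReferenceTable,
    observed: np.ndarray,
    closest_fraction: float = 0.01,
) -> ScenarioPosterior:
    """Logistic regression of scenario label on standardised stat deviations.

    Fitted over the closest fraction of the table; the posterior probability
    is the fitted value at deviation zero, with a delta-method 95% interval on
    the linear predictor. Falls back to the direct estimate under complete
    separation.
    """
    observed = np.asarray(observed, dtype=float)
    m = max(2, int(round(closest_fraction * table.n_rows)))
    idx, _ = _closest_indices(table, observed, m)
    scen_names = sorted(set(table.scenarios.tolist()))
    if len(scen_names) != 2:
        raise ValueError("logistic comparison implemented for two scenarios")
    labels = table.scenarios[idx]
    if len(set(labels.tolist())) < 2:
        # one-scenario closest set: degenerate separation, use the direct rule
        warnings.warn(
            "closest set contains a single scenario; falling back to direct",
            stacklevel=2,
        )
        direct = direct_posterior(table, observed, n_closest=m)
        return ScenarioPosterior("logistic(fallback=direct)", direct.prob, direct.interval)
    y = (labels == scen_names[0]).astype(float)
    dev = (table.stats[idx] - observed[None, :]) / table.scale[None, :]
    # drop constant columns to keep the design full-rank
    keep = dev.std(axis=0) > 1e-12
    x = sm.add_constant(dev[:, keep], has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(y, x, family=sm.families.Binomial()).fit(maxiter=200)
        eta = float(fit.params[0])
        se = float(np.sqrt(fit.cov_params()[0, 0]))
        if not np.isfinite(eta) or not np.isfinite(se) or abs(eta) > 30:
            raise np.linalg.LinAlgError("separation")
    except Exception:
        warnings.warn(
            "logistic fit failed (likely complete separation); falling back to direct",
            stacklevel=2,
        )
        direct = direct_posterior(table, observed, n_closest=m)
        return ScenarioPosterior("logistic(fallback=direct)", direct.prob, direct.interval)

    from scipy.special import expit

    p0 = float(expit(eta))
    lo, hi = float(expit(eta - 1.96 * se)), float(expit(eta + 1.96 * se))
    prob = {scen_names[0]: p0, scen_names[1]: 1.0 - p0}
    interval = {scen_names[0]: (lo, hi), scen_names[1]: (1.0 - hi, 1.0 - lo)}
    return ScenarioPosterior("logistic", prob, interval)


def hpd_interval(sample, level: float = 0.95, weights=None) -> tuple[float, float]:
    """Shortest contiguous interval of the sorted sample holding >= level mass."""
    sample = np.asarray(sample, dtype=float)
    if sample.size == 0:
        raise ValueError("empty sample")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if weights is None:
        weights = np.ones_like(sample)
    weights = np.asarray(weights, dtype=float)
    order = np.argsort(sample, kind="stable")
    xs, ws = sample[order], weights[order]
    total = ws.sum()
    if total <= 0:
        raise ValueError("weights sum to zero")
    target = level * total
    cum = np.concatenate([[0.0], np.cumsum(ws)])
    best = (np.inf, xs[0], xs[-1])
    j = 0
    for i in range(len(xs)):
        while j < len(xs) and cum[j + 1] - cum[i] < target:
            j += 1
        if j >= len(xs):
            break
        width = xs[j] - xs[i]
        if width < best[0]:
            best = (width, xs[i], xs[j])
    return float(best[1]), float(best[2])


def weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values, kind="stable")
    v, w = values[order], weights[order]
    cum = np.cumsum(w)
    return float(v[np.searchsorted(cum, 0.5 * cum[-1])])


@dataclass
class ParameterPosterior:
    parameter: str
    point: float
    hpd95: tuple[float, float]
    adjusted_sample: np.ndarray
    weights: np.ndarray


def _local_linear_adjust(
    theta: np.ndarray, dev: np.ndarray, weights: np.ndarray
) -> np.ndarray:
    """Regression adjustment theta* = theta - b^T dev (weighted least squares).

    A small ridge term is added when the weighted design is singular.
    """
    x = np.column_stack([np.ones(len(dev)), dev])
    wsq = np.sqrt(weights)
    xw, yw = x * wsq[:, None], theta * wsq
    gram = xw.T @ xw
    rhs = xw.T @ yw
    try:
        beta = np.linalg.solve(gram, rhs)
    except np.linalg.LinAlgError:
        warnings.warn("singular local-linear design; ridge-regularised solve", stacklevel=2)
        beta = np.linalg.solve(gram + 1e-8 * np.eye(len(gram)) * np.trace(gram), rhs)
    return theta - dev @ beta[1:]


def estimate_parameters(
    table: ReferenceTable,
    observed: np.ndarray,
    closest_fraction: float = 0.01,
    transform: str = "log",
    scenario_weights: dict[str, float] | None = None,
    parameters: tuple[str, ...] = PARAM_NAMES,
) -> list[ParameterPosterior]:
    """Local-linear regression ABC posterior for each parameter.

    Within the closest fraction of the table, parameters (log-transformed by
    default: both mu and the Ne's span orders of magnitude) are regressed on
    standardised statistic deviations with Epanechnikov kernel weights and
    adjusted to deviation zero. When `scenario_weights` is given, per-scenario
    adjusted samples are mixed with those weights ("summarised over
    scenarios"); otherwise the closest set is used as one pool. The point
    estimate is the weighted median; the interval the weighted 95% HPD.
    Back-transformed draws are clipped to the prior support of the table
    (min/max of the sampled column) with a logged count.
    """
    observed = np.asarray(observed, dtype=float)
    m = max(20, int(round(closest_fraction * table.n_rows)))
    if m > table.n_rows:
        raise ValueError("closest set larger than the reference table")
    if transform not in ("log", "none"):
        raise ValueError("transform must be 'log' or 'none'")

    def one_pool(rows: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        idx, dist = _closest_indices(
            ReferenceTable(
                table.scenarios[rows], table.params[rows], table.stats[rows],
                table.stat_names, table.scale,
            ),
            observed,
            min(m, len(rows)),
        )
        idx = rows[idx]
        delta = dist[-1] if dist[-1] > 0 else 1.0
        w = 1.0 - (dist / delta) ** 2
        w = np.where(w <= 0, 1e-12, w)
        dev = (table.stats[idx] - observed[None, :]) / table.scale[None, :]
        return idx, dev, w

    pools: list[tuple[np.ndarray, np.ndarray, np.ndarray, float]] = []
    if scenario_weights is None:
        rows = np.arange(table.n_rows)
        pools.append((*one_pool(rows), 1.0))
    else:
        for s, wt in scenario_weights.items():
            rows = np.flatnonzero(table.scenarios == s)
            if rows.size and wt > 0:
                pools.append((*one_pool(rows), float(wt)))

    out = []
    for name in parameters:
        col = list(PARAM_NAMES).index(name)
        lo_bound = table.params[:, col].min()
        hi_bound = table.params[:, col].max()
        samples, weights = [], []
        for idx, dev, w, wt in pools:
            theta = table.params[idx, col]
            if transform == "log":
                adj = np.exp(_local_linear_adjust(np.log(theta), dev, w))
            else:
                adj = _local_linear_adjust(theta, dev, w)
            clipped = np.clip(adj, lo_bound, hi_bound)
            n_clip = int((clipped != adj).sum())
            if n_clip:
                logger.info("%s: %d adjusted draws clipped to prior support", name, n_clip)
            samples.append(clipped)
            weights.append(w / w.sum() * wt)
        sample = np.concatenate(samples)
        weight = np.concatenate(weights)
        point = weighted_median(sample, weight)
        hpd = hpd_interval(sample, 0.95, weight)
        out.append(ParameterPosterior(name, point, hpd, sample, weight))
    return out


def posterior_to_frame(posteriors: list[ParameterPosterior]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "parameter": [p.parameter for p in posteriors],
            "median": [p.point for p in posteriors],
            "hpd95_low": [p.hpd95[0] for p in posteriors],
            "hpd95_high": [p.hpd95[1] for p in posteriors],
        }
    )
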