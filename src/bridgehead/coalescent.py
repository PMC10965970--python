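"""Serial-founder coalescent for invasion scenarios + TN93+I+Gamma sequences.

The demographic model has four populations along an invasion chain: a native
source (Japan) and three invasive populations (USA, Azores, Italy) founded at
fixed times of 112, 52 and 12 generations before sampling (one generation per
year). Two scenario topologies are supported: ``single_introduction``
(Japan -> USA -> Azores -> Italy) and ``double_introduction`` (Japan -> USA,
USA -> Azores, USA -> Italy). Genealogies follow the haploid continuous-time
Kingman coalescent (pair rate k(k-1)/(2 Ne), Ne the haploid mitochondrial
effective size, constant per population from its founding); at each split
time the daughter population's surviving lineages are injected into its
source.

Sequences evolve along the genealogy under TN93 with a proportion of
invariant sites and continuous (or optionally discretised) gamma rate
heterogeneity. The generator matrix is normalised to one expected
substitution per site per unit time at stationarity, so branch "length" in
substitutions is mu x generations x site-rate multiplier; the realised
genome-wide mean rate is mu x (1 - p_invariant). Branch endpoint states are
sampled from the exact finite-time transition probabilities (spectral
decomposition of the reversible generator), which is exact in distribution
and uniformly fast across mutation rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammainc

from bridgehead.alignment_io import MitogenomeAlignment, write_alignment

POPULATIONS = ("Japan", "USA", "Azores", "Italy")
SINGLE = "single_introduction"
DOUBLE = "double_introduction"

#: Default haploid effective sizes. Chosen once so that the generator's
#: regional diversity ladder resembles field samples of a recent serial
#: invasion at the default mutation rate: a diverse native population and
#: progressively founder-reduced invasive ones (see docs/methods.md).
DEFAULT_NE = {"Japan": 30_000.0, "USA": 850.0, "Azores": 130.0, "Italy": 5.0}
DEFAULT_SAMPLE_SIZES = {"Japan": 21, "USA": 23, "Azores": 20, "Italy": 22}
DEFAULT_SPLIT_TIMES = {"USA": 112.0, "Azores": 52.0, "Italy": 12.0}

_BYTES = np.array([b"A", b"C", b"G", b"T"])


@dataclass
class ScenarioSpec:
    """One serial-introduction scenario: topology, split times, sizes."""

    scenario_id: str = SINGLE
    split_times: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SPLIT_TIMES))
    ne: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_NE))
    sample_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_SAMPLE_SIZES))
    generation_time: float = 1.0  # years per generation

    def __post_init__(self) -> None:
        if self.scenario_id not in (SINGLE, DOUBLE):
            raise ValueError(f"unknown scenario {self.scenario_id!r}")
        t = self.split_times
        if not t["Italy"] < t["Azores"] < t["USA"]:
            raise ValueError("split times must satisfy Italy < Azores < USA")
        if any(v < 1 for v in self.ne.values()):
            raise ValueError("all Ne must be >= 1")
        if any(v < 0 for v in self.sample_sizes.values()):
            raise ValueError("sample sizes must be >= 0")
        if sum(self.sample_sizes.values()) < 2:
            raise ValueError("need at least 2 sampled tips overall")

    def source_of(self, population: str) -> str:
        if population == "USA":
            return "Japan"
        if population == "Azores":
            return "USA"
        if population == "Italy":
            return "Azores" if self.scenario_id == SINGLE else "USA"
        raise KeyError(f"{population} has no source (native range)")

    def with_parameters(self, ne: dict[str, float] | None = None, **kw) -> "ScenarioSpec":
        return replace(self, ne=dict(ne) if ne is not None else dict(self.ne), **kw)


@dataclass
class MutationModel:
    """TN93 + invariant sites + gamma rate heterogeneity.

    kappa_CT and kappa_AG are the instantaneous-rate ratios of the two
    transition classes to transversions; the rate matrix is rescaled so the
    expected substitution rate at stationarity is exactly 1, then multiplied
    by mu (substitutions/site/generation) and the per-site rate multiplier.
    gamma_categories = 0 requests continuous gamma rates.
    """

    mu: float = 1.14e-6
    L: int = 16_031
    base_freqs: tuple[float, float, float, float] = (0.35, 0.15, 0.10, 0.40)
    kappa_CT: float = 25.0
    kappa_AG: float = 41.0
    p_invariant: float = 0.85
    gamma_shape: float = 1.17
    gamma_categories: int = 0

    def __post_init__(self) -> None:
        pi = np.asarray(self.base_freqs, dtype=float)
        if pi.min() <= 0 or abs(pi.sum() - 1.0) > 1e-8:
            raise ValueError("base_freqs must be positive and sum to 1")
        if not 0 <= self.p_invariant < 1:
            raise ValueError("p_invariant must be in [0, 1)")
        if self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be positive")
        self._spectral_cache = None

    def rate_matrix(self) -> np.ndarray:
        """TN93 generator, normalised to unit expected rate at stationarity."""
        pi = np.asarray(self.base_freqs)
        q = np.empty((4, 4))
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                pair = {i, j}
                if pair == {0, 2}:  # A <-> G purine transition
                    rate = self.kappa_AG
                elif pair == {1, 3}:  # C <-> T pyrimidine transition
                    rate = self.kappa_CT
                else:
                    rate = 1.0
                q[i, j] = rate * pi[j]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mean_rate = -(pi * np.diag(q)).sum()
        return q / mean_rate

    def spectral(self):
        """(eigenvalues, A) with P_ik(t) = sum_j A[i,k,j] exp(lam_j t).

        The reversible generator is symmetrised with diag(sqrt(pi)) so a
        symmetric eigendecomposition can be used.
        """
        if self._spectral_cache is None:
            pi = np.asarray(self.base_freqs)
            q = self.rate_matrix()
            d = np.sqrt(pi)
            sym = (q * d[:, None]) / d[None, :]
            lam, v = np.linalg.eigh((sym + sym.T) / 2.0)
            u = v / d[:, None]
            uinv = v.T * d[None, :]
            a = np.einsum("ij,jk->ikj", u, uinv)  # A[i,k,j]
            self._spectral_cache = (lam, np.ascontiguousarray(a))
        return self._spectral_cache

    def discrete_gamma_rates(self) -> np.ndarray:
        """Mean rates of equal-probability gamma categories (mean-1 gamma)."""
        k, a = self.gamma_categories, self.gamma_shape
        if k <= 0:
            raise ValueError("no discrete categories requested")
        from scipy.stats import gamma as gamma_dist

        bounds = gamma_dist.ppf(np.arange(k + 1) / k, a, scale=1.0 / a)
        upper = gammainc(a + 1.0, a * bounds[1:])
        lower = gammainc(a + 1.0, a * bounds[:-1])
        return k * (upper - lower)

    def site_rates(self, rng: np.random.Generator) -> np.ndarray:
        """Per-site rate multipliers: 0 with prob p_invariant, else gamma."""
        rates = np.zeros(self.L)
        variable = rng.random(self.L) >= self.p_invariant
        n_var = int(variable.sum())
        if n_var:
            if self.gamma_categories > 0:
                cats = self.discrete_gamma_rates()
                rates[variable] = cats[rng.integers(0, self.gamma_categories, n_var)]
            else:
                rates[variable] = rng.gamma(self.gamma_shape, 1.0 / self.gamma_shape, n_var)
        return rates


@dataclass
class GenealogySample:
    """A sampled genealogy: binary rooted tree with node times in generations."""

    tip_labels: list[str]
    tip_population: dict[str, str]
    times: np.ndarray  # (2n-1,), tips first at 0
    children: np.ndarray  # (2n-1, 2), -1 for tips
    node_population: list[str]  # population in which each node lives/coalesced

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def root(self) -> int:
        return len(self.times) - 1

    def tmrca(self) -> float:
        return float(self.times[self.root])

    def total_branch_length(self) -> float:
        tot = 0.0
        for u in range(len(self.times)):
            for c in self.children[u]:
                if c >= 0:
                    tot += self.times[u] - self.times[c]
        return tot

    def newick(self) -> str:
        def sub(u: int) -> str:
            c1, c2 = self.children[u]
            if c1 < 0:
                return self.tip_labels[u]
            b1 = self.times[u] - self.times[c1]
            b2 = self.times[u] - self.times[c2]
            return f"({sub(c1)}:{b1:.8g},{sub(c2)}:{b2:.8g})"

        return sub(self.root) + ";"

    def cross_population_coalescence_times(self) -> list[tuple[str, str, float]]:
        """(population set of left subtree, right subtree, time) per internal node
        where the two merged lineages subtend tips of different populations."""
        tipsets: dict[int, frozenset] = {}
        out = []
        for u in range(len(self.times)):
            c1, c2 = self.children[u]
            if c1 < 0:
                tipsets[u] = frozenset([self.tip_population[self.tip_labels[u]]])
            else:
                s1, s2 = tipsets[c1], tipsets[c2]
                tipsets[u] = s1 | s2
                if s1 != s2 or len(s1) > 1:
                    out.append(("|".join(sorted(s1)), "|".join(sorted(s2)), float(self.times[u])))
        return out


def sample_genealogy(spec: ScenarioSpec, rng: np.random.Generator) -> GenealogySample:
    """Sample one genealogy under the serial-introduction coalescent."""
    tip_labels: list[str] = []
    tip_population: dict[str, str] = {}
    active: dict[str, list[int]] = {p: [] for p in POPULATIONS}
    node = 0
    for pop in POPULATIONS:
        for i in range(spec.sample_sizes[pop]):
            label = f"{pop}_{i + 1}"
            tip_labels.append(label)
            tip_population[label] = pop
            active[pop].append(node)
            node += 1
    n_tips = node
    times = [0.0] * n_tips
    children: list[tuple[int, int]] = [(-1, -1)] * n_tips
    node_population = [tip_population[lbl] for lbl in tip_labels]

    def coalesce_in(pop: str, t_start: float, t_end: float) -> None:
        nonlocal node
        t = t_start
        lineages = active[pop]
        ne = spec.ne[pop]
        while len(lineages) >= 2:
            k = len(lineages)
            rate = k * (k - 1) / (2.0 * ne)
            t_next = t + rng.exponential(1.0 / rate)
            if t_next >= t_end:
                return
            t = t_next
            i, j = rng.choice(k, size=2, replace=False)
            if i > j:
                i, j = j, i
            a, b = lineages[i], lineages[j]
            del lineages[j], lineages[i]
            times.append(t)
            children.append((a, b))
            node_population.append(pop)
            lineages.append(node)
            node += 1

    events = sorted(spec.split_times.items(), key=lambda kv: kv[1])
    t_prev = 0.0
    for founded_pop, t_split in events:
        for pop in POPULATIONS:
            if active[pop]:
                coalesce_in(pop, t_prev, t_split)
        source = spec.source_of(founded_pop)
        active[source].extend(active[founded_pop])
        active[founded_pop] = []
        t_prev = t_split
    coalesce_in("Japan", t_prev, np.inf)
    return GenealogySample(
        tip_labels, tip_population, np.asarray(times), np.asarray(children, dtype=int), node_population
    )


def _transmit_at(
    parent_state: np.ndarray,
    cand: np.ndarray,
    x: np.ndarray,
    u: np.ndarray,
    lam: np.ndarray,
    a_tensor: np.ndarray,
    d_stay: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample child states given parent states along one branch.

    Exact thinning: the substitution probability of a site satisfies
    1 - P_ii(x) <= qmax * x (qmax the largest exit rate of the generator), so
    `cand` holds the candidate sites with u < qmax * x and the transition
    exponentials are evaluated only there; the same uniform decides acceptance
    against the exact probability.
    """
    child = parent_state.copy()
    if cand.size == 0:
        return child
    e = np.exp(x[cand, None] * lam[None, :])  # (m, 4)
    par = parent_state[cand]
    stay = np.einsum("sj,sj->s", e, d_stay[par])
    hit = u[cand] < 1.0 - stay
    idx = cand[hit]
    if idx.size:
        e, par = e[hit], par[hit]
        rows = a_tensor[par]  # (m, 4, 4) as [target, eig]
        p = np.clip(np.einsum("mkj,mj->mk", rows, e), 0.0, None)
        p[np.arange(idx.size), par] = 0.0
        bad = p.sum(axis=1) <= 0.0  # numerically-zero rows (d ~ 0): uniform over targets
        if bad.any():
            p[bad] = 1.0
            p[bad, par[bad]] = 0.0
        cdf = np.cumsum(p, axis=1)
        v = rng.random(idx.size) * cdf[:, -1]
        child[idx] = (cdf > v[:, None]).argmax(axis=1)
    return child


def evolve_sequences_codes(
    genealogy: GenealogySample, model: MutationModel, rng: np.random.Generator
) -> np.ndarray:
    """Integer-coded (A,C,G,T)=(0..3) tip sequences, shape (n_tips, L).

    The per-site uniforms and candidate substitution sites of every branch are
    drawn in one batch (see `_transmit` for the thinning argument), so the
    per-branch work scales with the expected number of substitutions rather
    than with alignment length.
    """
    pi = np.asarray(model.base_freqs)
    lam, a_tensor = model.spectral()
    d_stay = np.ascontiguousarray(a_tensor[np.arange(4), np.arange(4), :])  # A[i,i,j]
    qmax = float(-np.diag(model.rate_matrix()).min())

    rates = model.site_rates(rng)
    var_idx = np.flatnonzero(rates > 0)
    r = rates[var_idx]
    root_full = rng.choice(4, size=model.L, p=pi).astype(np.uint8)

    n_tips = genealogy.n_tips
    # branches in parent-before-child order
    branches: list[tuple[int, int]] = []
    stack = [genealogy.root]
    while stack:
        u = stack.pop()
        for c in genealogy.children[u]:
            if c >= 0:
                branches.append((u, c))
                if c >= n_tips:
                    stack.append(c)
    tips = np.repeat(root_full[None, :], n_tips, axis=0)
    if not r.size or not branches:
        return tips

    blen = np.array([genealogy.times[u] - genealogy.times[c] for u, c in branches])
    x_all = (model.mu * blen)[:, None] * r[None, :]
    u_all = rng.random(x_all.shape)
    cand_rows, cand_cols = np.nonzero(u_all < np.minimum(qmax * x_all, 1.0))
    row_start = np.searchsorted(cand_rows, np.arange(len(branches) + 1))

    states: dict[int, np.ndarray] = {genealogy.root: root_full[var_idx].astype(np.intp)}
    pending = {u: len([c for c in genealogy.children[u] if c >= 0]) for u, _ in branches}
    tips_var = np.repeat(states[genealogy.root][None, :].astype(np.uint8), n_tips, axis=0)
    for b, (u, c) in enumerate(branches):
        s_u = states[u]
        cols = cand_cols[row_start[b] : row_start[b + 1]]
        s_c = _transmit_at(
            s_u, cols, x_all[b], u_all[b], lam, a_tensor, d_stay, rng
        )
        pending[u] -= 1
        if pending[u] == 0 and u != genealogy.root:
            del states[u]
        if c < n_tips:
            tips_var[c] = s_c.astype(np.uint8)
        else:
            states[c] = s_c
    tips[:, var_idx] = tips_var
    return tips


def codes_to_alignment(
    codes: np.ndarray, tip_labels: list[str], tip_population: dict[str, str]
) -> MitogenomeAlignment:
    sites = _BYTES[codes]
    return MitogenomeAlignment(list(tip_labels), dict(tip_population), sites)


def evolve_sequences(
    genealogy: GenealogySample, model: MutationModel, rng: np.random.Generator
) -> MitogenomeAlignment:
    """Evolve sequences along the genealogy; returns a labelled alignment."""
    codes = evolve_sequences_codes(genealogy, model, rng)
    return codes_to_alignment(codes, genealogy.tip_labels, genealogy.tip_population)


@dataclass
class SimulatedDataset:
    alignment: MitogenomeAlignment
    truth: dict
    seed: int


def simulate_dataset(
    spec: ScenarioSpec, model: MutationModel, seed: int
) -> SimulatedDataset:
    """One synthetic dataset; deterministic given the seed."""
    rng = np.random.default_rng(seed)
    genealogy = sample_genealogy(spec, rng)
    aln = evolve_sequences(genealogy, model, rng)
    truth = {
        "scenario_id": spec.scenario_id,
        "mu": model.mu,
        **{f"ne_{p}": spec.ne[p] for p in POPULATIONS},
    }
    return SimulatedDataset(aln, truth, seed)


def population_groups(spec: ScenarioSpec) -> list[np.ndarray]:
    """Row-index groups of the simulated alignment, in POPULATIONS order."""
    groups, offset = [], 0
    for pop in POPULATIONS:
        n = spec.sample_sizes[pop]
        groups.append(np.arange(offset, offset + n))
        offset += n
    return groups


DEFAULT_BENCHMARK_CONFIG = {
    "scenarios": [SINGLE, DOUBLE],
    "replicates": 2,
    "seed": 20260926,
    "mu": MutationModel.mu,
    "ne": DEFAULT_NE,
    "sample_sizes": DEFAULT_SAMPLE_SIZES,
    "L": MutationModel.L,
}


def generate_benchmark_suite(config: dict | None, out_dir: str | Path) -> pd.DataFrame:
    """Write FASTA + metadata + truth tables for a grid of scenarios/replicates.

    Returns the truth table (one row per emitted dataset); also written as
    ``truth.tsv`` in `out_dir`. Dataset directories are named
    ``<scenario>_rep<k>``.
    """
    cfg = dict(DEFAULT_BENCHMARK_CONFIG)
    if config:
        cfg.update(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(int(cfg["seed"])).generate_state(
        len(cfg["scenarios"]) * int(cfg["replicates"])
    ) % (2**31)
    model = MutationModel(mu=float(cfg["mu"]), L=int(cfg["L"]))
    rows = []
    i = 0
    for scenario in cfg["scenarios"]:
        spec = ScenarioSpec(
            scenario_id=scenario,
            ne={k: float(v) for k, v in cfg["ne"].items()},
            sample_sizes={k: int(v) for k, v in cfg["sample_sizes"].items()},
        )
        for rep in range(int(cfg["replicates"])):
            seed = int(seeds[i])
            i += 1
            ds = simulate_dataset(spec, model, seed)
            d = out_dir / f"{scenario}_rep{rep + 1}"
            d.mkdir(exist_ok=True)
            write_alignment(ds.alignment, d / "alignment.fasta", d / "metadata.tsv")
            rows.append({"dataset": d.name, "seed": seed, **ds.truth})
    truth = pd.DataFrame(rows)
    truth.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    return truth
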