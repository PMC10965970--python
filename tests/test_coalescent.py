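import numpy as np
import pytest
from scipy.linalg import expm
from scipy.stats import ks_2samp

from bridgehead.coalescent import (
    DOUBLE,
    POPULATIONS,
    SINGLE,
    GenealogySample,
    MutationModel,
    ScenarioSpec,
    evolve_sequences,
    evolve_sequences_codes,
    generate_benchmark_suite,
    population_groups,
    sample_genealogy,
    simulate_dataset,
)
from bridgehead.popgen_stats import summary_from_codes


def one_population_spec(n: int, ne: float) -> ScenarioSpec:
    return ScenarioSpec(
        sample_sizes={"Japan": n, "USA": 0, "Azores": 0, "Italy": 0},
        ne={"Japan": ne, "USA": 1, "Azores": 1, "Italy": 1},
    )


def two_tip_genealogy(branch_generations: float) -> GenealogySample:
    """A fixed two-tip genealogy with both branches of the given length."""
    return GenealogySample(
        ["a", "b"],
        {"a": "Japan", "b": "Japan"},
        np.array([0.0, 0.0, branch_generations]),
        np.array([[-1, -1], [-1, -1], [0, 1]]),
        ["Japan", "Japan", "Japan"],
    )


class TestGenealogy:
    def test_pair_tmrca_mean(self):
        # haploid coalescent: E[T2] = Ne
        rng = np.random.default_rng(1)
        spec = one_population_spec(2, 1000.0)
        t = np.array([sample_genealogy(spec, rng).tmrca() for _ in range(10_000)])
        se = t.std() / np.sqrt(len(t))
        assert abs(t.mean() - 1000.0) < 3 * se

    def test_n_sample_tmrca_mean(self):
        # E[TMRCA] = 2 Ne (1 - 1/n)
        rng = np.random.default_rng(2)
        n, ne = 10, 500.0
        spec = one_population_spec(n, ne)
        t = np.array([sample_genealogy(spec, rng).tmrca() for _ in range(10_000)])
        se = t.std() / np.sqrt(len(t))
        assert abs(t.mean() - 2 * ne * (1 - 1 / n)) < 3 * se

    @pytest.mark.parametrize("scenario", [SINGLE, DOUBLE])
    def test_split_time_constraints(self, scenario):
        # a coalescence joining two populations cannot predate their common
        # ancestry: anything involving Japan > 112; Italy/Azores pairs > 52
        # except Italy-Azores under the single-introduction chain (> 12)
        rng = np.random.default_rng(3)
        spec = ScenarioSpec(
            scenario,
            sample_sizes={"Japan": 4, "USA": 4, "Azores": 4, "Italy": 4},
            ne={"Japan": 5000, "USA": 50, "Azores": 50, "Italy": 50},
        )
        for _ in range(100):
            g = sample_genealogy(spec, rng)
            for left, right, t in g.cross_population_coalescence_times():
                pops = set(left.split("|")) | set(right.split("|"))
                if "Japan" in pops:
                    assert t > 112
                elif pops == {"Italy", "Azores"}:
                    assert t > (12 if scenario == SINGLE else 52)
                elif "USA" in pops:
                    assert t > (52 if "Azores" in pops else 12)

    def test_ultrametric_and_times_ordered(self):
        rng = np.random.default_rng(4)
        g = sample_genealogy(ScenarioSpec(), rng)
        assert g.n_tips == 86
        for u in range(len(g.times)):
            for c in g.children[u]:
                if c >= 0:
                    assert g.times[u] > g.times[c] or g.times[c] == 0
        assert (g.times[: g.n_tips] == 0).all()

    def test_watterson_segregating_sites(self):
        # low-mutation limit: E[S] = theta_w * L_eff * H_{n-1}, with the
        # effective per-site rate mu (1 - p_invariant)
        rng = np.random.default_rng(5)
        n, ne, mu = 8, 400.0, 5e-7
        model = MutationModel(mu=mu, L=8_000)
        spec = one_population_spec(n, ne)
        counts = []
        for _ in range(1_500):
            g = sample_genealogy(spec, rng)
            codes = evolve_sequences_codes(g, model, rng)
            counts.append((codes != codes[0]).any(axis=0).sum())
        counts = np.array(counts, dtype=float)
        harmonic = sum(1.0 / i for i in range(1, n))
        expected = 2 * ne * mu * (1 - model.p_invariant) * model.L * harmonic
        se = counts.std() / np.sqrt(len(counts))
        assert abs(counts.mean() - expected) < 3 * se


class TestAgainstMsprime:
    @pytest.mark.parametrize("scenario", [SINGLE, DOUBLE])
    def test_tmrca_distribution_matches_msprime(self, scenario):
        """Independent oracle: the same serial-founder demography in msprime."""
        import msprime

        ne = {"Japan": 2000.0, "USA": 300.0, "Azores": 100.0, "Italy": 40.0}
        sizes = {"Japan": 6, "USA": 6, "Azores": 5, "Italy": 5}
        spec = ScenarioSpec(scenario, ne=ne, sample_sizes=sizes)

        dem = msprime.Demography()
        for pop in POPULATIONS:
            dem.add_population(name=pop, initial_size=ne[pop])
        italy_source = "Azores" if scenario == SINGLE else "USA"
        dem.add_population_split(time=12, derived=["Italy"], ancestral=italy_source)
        dem.add_population_split(time=52, derived=["Azores"], ancestral="USA")
        dem.add_population_split(time=112, derived=["USA"], ancestral="Japan")
        dem.sort_events()

        n_rep = 400
        oracle = np.array(
            [
                msprime.sim_ancestry(
                    samples=sizes, demography=dem, ploidy=1, random_seed=s
                ).max_root_time
                for s in range(1, n_rep + 1)
            ]
        )
        rng = np.random.default_rng(99)
        ours = np.array([sample_genealogy(spec, rng).tmrca() for _ in range(n_rep)])
        assert ks_2samp(ours, oracle).pvalue > 0.001
        assert abs(ours.mean() - oracle.mean()) < 4 * oracle.std() / np.sqrt(n_rep)


class TestMutationModel:
    def test_rate_matrix_normalised(self):
        m = MutationModel()
        q = m.rate_matrix()
        pi = np.asarray(m.base_freqs)
        assert q.sum(axis=1) == pytest.approx(np.zeros(4), abs=1e-12)
        assert -(pi * np.diag(q)).sum() == pytest.approx(1.0)

    def test_spectral_reconstructs_generator(self):
        m = MutationModel()
        lam, a = m.spectral()
        q = np.einsum("ikj,j->ik", a, lam)  # d/dt P(t) at t=0
        assert q == pytest.approx(m.rate_matrix(), abs=1e-10)

    def test_stationarity_of_transition_matrix(self):
        m = MutationModel()
        pi = np.asarray(m.base_freqs)
        lam, a = m.spectral()
        p = np.einsum("ikj,j->ik", a, np.exp(lam * 0.7))
        assert pi @ p == pytest.approx(pi, abs=1e-12)

    def test_discrete_gamma_rates_mean_one(self):
        m = MutationModel(gamma_categories=8)
        rates = m.discrete_gamma_rates()
        assert len(rates) == 8
        assert rates.mean() == pytest.approx(1.0, abs=1e-6)
        assert (np.diff(rates) > 0).all()

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            MutationModel(base_freqs=(0.5, 0.5, 0.2, -0.2))
        with pytest.raises(ValueError):
            MutationModel(p_invariant=1.0)


class TestSequenceEvolution:
    def test_all_invariant_sites_gives_identical_sequences(self):
        rng = np.random.default_rng(6)
        model = MutationModel(mu=1e-3, L=500, p_invariant=1 - 1e-12)
        g = sample_genealogy(one_population_spec(5, 200.0), rng)
        codes = evolve_sequences_codes(g, model, rng)
        assert (codes == codes[0]).all()

    def test_jc_limit_matches_closed_form(self):
        # kappas 1, equal frequencies, no invariant sites, a single unit-rate
        # gamma category: expected pairwise difference on total branch length
        # 2d is p = (3/4)(1 - exp(-4/3 * 2d))
        rng = np.random.default_rng(7)
        L = 20_000
        d = 0.15  # substitutions/site on each branch
        model = MutationModel(
            mu=1.0,
            L=L,
            base_freqs=(0.25, 0.25, 0.25, 0.25),
            kappa_CT=1.0,
            kappa_AG=1.0,
            p_invariant=0.0,
            gamma_categories=1,
        )
        g = two_tip_genealogy(d)
        codes = evolve_sequences_codes(g, model, rng)
        p_hat = (codes[0] != codes[1]).mean()
        p_exp = 0.75 * (1 - np.exp(-4.0 / 3.0 * 2 * d))
        se = np.sqrt(p_exp * (1 - p_exp) / L)
        assert abs(p_hat - p_exp) < 3 * se

    def test_tn93_site_patterns_match_matrix_exponential(self):
        # joint (root, tip) pattern frequencies on one branch against the
        # numerically exponentiated generator
        rng = np.random.default_rng(8)
        L = 100_000
        t = 0.3
        model = MutationModel(
            mu=1.0, L=L, p_invariant=0.0, gamma_categories=1
        )
        g = two_tip_genealogy(t)
        codes = evolve_sequences_codes(g, model, rng)
        pi = np.asarray(model.base_freqs)
        p_oracle = expm(model.rate_matrix() * 2 * t)  # tip-to-tip: both branches
        joint_oracle = pi[:, None] * p_oracle
        joint_hat = np.zeros((4, 4))
        for i in range(4):
            for j in range(4):
                joint_hat[i, j] = ((codes[0] == i) & (codes[1] == j)).mean()
        assert np.abs(joint_hat - joint_oracle).max() < 1e-2

    def test_stationary_base_composition(self):
        rng = np.random.default_rng(9)
        model = MutationModel(mu=1.0, L=50_000, p_invariant=0.0, gamma_categories=1)
        g = two_tip_genealogy(5.0)  # long branch: tip is a stationary draw
        codes = evolve_sequences_codes(g, model, rng)
        freqs = np.bincount(codes[0], minlength=4) / model.L
        pi = np.asarray(model.base_freqs)
        se = np.sqrt(pi * (1 - pi) / model.L)
        assert (np.abs(freqs - pi) < 3 * se).all()

    def test_japan_marginals_identical_across_scenarios(self):
        # the two scenario topologies only differ downstream of Japan, so
        # Japan-only statistics must share a distribution (KS, alpha = 0.01)
        def japan_mpd(scenario, seed):
            rng = np.random.default_rng(seed)
            spec = ScenarioSpec(
                scenario,
                sample_sizes={"Japan": 10, "USA": 2, "Azores": 2, "Italy": 2},
            )
            model = MutationModel(mu=2e-6, L=4_000)
            out = []
            for _ in range(300):
                g = sample_genealogy(spec, rng)
                codes = evolve_sequences_codes(g, model, rng)
                vec = summary_from_codes(codes, population_groups(spec))
                out.append(vec[1])  # mean pairwise differences within Japan
            return np.array(out)

        a = japan_mpd(SINGLE, 100)
        b = japan_mpd(DOUBLE, 200)
        assert ks_2samp(a, b).pvalue > 0.01


class TestSimulateDataset:
    def test_same_seed_identical(self):
        spec = ScenarioSpec()
        model = MutationModel(L=1_000)
        a = simulate_dataset(spec, model, 42)
        b = simulate_dataset(spec, model, 42)
        assert (a.alignment.sites == b.alignment.sites).all()
        assert a.truth == b.truth

    def test_zero_rate_is_monomorphic(self):
        ds = simulate_dataset(ScenarioSpec(), MutationModel(mu=0.0, L=800), 1)
        sites = ds.alignment.sites
        assert (sites == sites[0]).all()

    def test_sample_sizes_and_regions(self):
        ds = simulate_dataset(ScenarioSpec(), MutationModel(L=500), 2)
        counts = {}
        for sid in ds.alignment.sequence_ids:
            counts[ds.alignment.regions[sid]] = counts.get(ds.alignment.regions[sid], 0) + 1
        assert counts == {"Japan": 21, "USA": 23, "Azores": 20, "Italy": 22}


class TestBenchmarkSuite:
    def test_default_grid_layout(self, tmp_path):
        truth = generate_benchmark_suite({"replicates": 2, "L": 400}, tmp_path)
        assert len(truth) == 4  # 2 scenarios x 2 replicates
        for name in truth["dataset"]:
            assert (tmp_path / name / "alignment.fasta").exists()
            assert (tmp_path / name / "metadata.tsv").exists()
        from bridgehead.alignment_io import read_alignment

        aln = read_alignment(
            tmp_path / truth["dataset"][0] / "alignment.fasta",
            tmp_path / truth["dataset"][0] / "metadata.tsv",
        )
        assert aln.n_sequences == 86 and aln.n_columns == 400

    def test_truth_table_round_trip_and_mu_in_prior(self, tmp_path):
        import pandas as pd

        generate_benchmark_suite({"replicates": 1, "L": 300}, tmp_path)
        truth = pd.read_csv(tmp_path / "truth.tsv", sep="\t")
        assert {"dataset", "seed", "scenario_id", "mu"} <= set(truth.columns)
        assert ((truth["mu"] >= 1.115e-8) & (truth["mu"] <= 1.5e-5)).all()
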