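"""HKY proposals, Moran fixation, and the origin-fixation engine."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as stst
from scipy import stats

from foldevo.evolution import (EvolutionRun, HKYModel, combined_fitness,
                               evolve, evolve_genome, hky_rate,
                               moran_fixation_probability, propose_mutation)
from foldevo.sequences import (CodingSequence, NUCLEOTIDES,
                               random_coding_sequence, translate)
from foldevo.stability import (EnergyModel, FitnessSpec, compute_stabilities,
                               toy_hydrophobic_model)
from foldevo.structure import ContactMap
from foldevo.theory import enumerate_stationary, mutation_only_sample


class TestHKYRates:
    def test_jukes_cantor_limit(self):
        hky = HKYModel(gc=0.5, kappa=1.0)
        rates = [hky_rate(a, b, hky) for a in NUCLEOTIDES for b in NUCLEOTIDES
                 if a != b]
        assert np.allclose(rates, rates[0])

    def test_transition_transversion_ratio(self):
        hky = HKYModel(gc=0.5, kappa=4.0)
        assert hky_rate("A", "G", hky) / hky_rate("A", "C", hky) == pytest.approx(4.0)

    @pytest.mark.parametrize("gc", [0.2, 0.5, 0.8])
    @pytest.mark.parametrize("kappa", [1.0, 4.0])
    def test_detailed_balance_all_ordered_pairs(self, gc, kappa):
        hky = HKYModel(gc=gc, kappa=kappa)
        pi = hky.pi
        for a in range(4):
            for b in range(4):
                if a == b:
                    continue
                assert pi[a] * hky_rate(a, b, hky) == pytest.approx(
                    pi[b] * hky_rate(b, a, hky))

    def test_same_nucleotide_rejected(self):
        with pytest.raises(ValueError):
            hky_rate("A", "A", HKYModel())

    def test_chargaff_parity_of_stationary_frequencies(self):
        pi = HKYModel(gc=0.3).pi
        assert pi[0] == pi[3] and pi[1] == pi[2]  # A=T, C=G
        assert pi.sum() == pytest.approx(1.0)


class TestProposeMutation:
    def test_symmetric_case_is_uniform(self, rng):
        seq = CodingSequence("ACGTAC")
        hky = HKYModel(gc=0.5, kappa=1.0)
        n = 30000
        sites = np.zeros(6)
        for _ in range(n):
            site, _ = propose_mutation(seq, hky, rng)
            sites[site] += 1
        # chi-square against uniform site choice
        chi2 = ((sites - n / 6) ** 2 / (n / 6)).sum()
        assert chi2 < stats.chi2.ppf(0.997, df=5)

    def test_homopolymer_sites_equiprobable(self, rng):
        seq = CodingSequence("AAAAAA")
        hky = HKYModel(gc=0.2, kappa=4.0)
        n = 30000
        sites = np.zeros(6)
        for _ in range(n):
            site, _ = propose_mutation(seq, hky, rng)
            sites[site] += 1
        chi2 = ((sites - n / 6) ** 2 / (n / 6)).sum()
        assert chi2 < stats.chi2.ppf(0.997, df=5)

    def test_frequencies_match_analytic_law(self, rng):
        # joint (site, new nt) law: P = out(a_i)/sum_j out(a_j) * q(a_i,b)/out(a_i)
        seq = CodingSequence("ACG")
        hky = HKYModel(gc=0.3, kappa=4.0)
        out = hky.out_rates()
        nt = seq.nt_indices()
        tot = out[nt].sum()
        expected = {}
        for i, a in enumerate(nt):
            for b in range(4):
                if b == a:
                    continue
                expected[(i, NUCLEOTIDES[b])] = hky_rate(int(a), b, hky) / tot
        n = 60000
        counts = {k: 0 for k in expected}
        for _ in range(n):
            counts[propose_mutation(seq, hky, rng)] += 1
        for k, p in expected.items():
            sigma = math.sqrt(n * p * (1 - p))
            assert abs(counts[k] - n * p) < 3.5 * sigma


def _moran_absorption_oracle(r: float, N: int) -> float:
    """Fixation probability of one mutant from the explicit Moran birth-death
    chain, by linear-algebra absorption: states 0..N mutant copies."""
    P = np.zeros((N + 1, N + 1))
    P[0, 0] = P[N, N] = 1.0
    for i in range(1, N):
        w = r * i + (N - i)
        up = (r * i / w) * ((N - i) / N)
        down = ((N - i) / w) * (i / N)
        P[i, i + 1] = up
        P[i, i - 1] = down
        P[i, i] = 1.0 - up - down
    # absorption probability at N: solve (I - Q) h = b over transient states
    trans = list(range(1, N))
    Q = P[np.ix_(trans, trans)]
    b = P[np.ix_(trans, [N])].ravel()
    h = np.linalg.solve(np.eye(N - 1) - Q, b)
    return float(h[0])


class TestMoranFixation:
    def test_neutral_value(self):
        for N in (1, 2, 10, 100):
            assert moran_fixation_probability(1.0, 1.0, N) == pytest.approx(1.0 / N)

    def test_boundary_cases(self):
        assert moran_fixation_probability(1.0, 0.0, 50) == 0.0
        assert moran_fixation_probability(1.0, 0.7, 1) == 1.0
        with pytest.raises(ValueError):
            moran_fixation_probability(0.0, 1.0, 10)
        with pytest.raises(ValueError):
            moran_fixation_probability(1.0, 1.0, 0)

    def test_known_value_n10(self):
        assert moran_fixation_probability(1.0, 1.1, 10) == pytest.approx(
            _moran_absorption_oracle(1.1, 10), abs=1e-10)

    @pytest.mark.parametrize("r", [0.5, 0.9, 1.0, 1.1, 2.0])
    @pytest.mark.parametrize("N", [2, 5, 10, 20])
    def test_closed_form_equals_chain_absorption(self, r, N):
        closed = moran_fixation_probability(1.0, r, N)
        assert closed == pytest.approx(_moran_absorption_oracle(r, N), abs=1e-10)

    @settings(deadline=None, max_examples=80, derandomize=True)
    @given(r=stst.floats(min_value=1e-3, max_value=50.0),
           N=stst.integers(min_value=1, max_value=10000))
    def test_probability_bounds_and_reversal_identity(self, r, N):
        p = moran_fixation_probability(1.0, r, N)
        assert 0.0 <= p <= 1.0
        q = moran_fixation_probability(r, 1.0, N)  # reciprocal fitness ratio
        if q > 1e-280 and N <= 1000:
            assert p / q == pytest.approx(r ** (N - 1), rel=1e-8)

    def test_extreme_ratios_do_not_overflow(self):
        assert moran_fixation_probability(1.0, 1e-8, 10000) == 0.0
        assert moran_fixation_probability(1e-8, 1.0, 10000) == pytest.approx(1.0, abs=1e-6)


class TestCombinedFitness:
    def test_trivial_combinations(self):
        assert combined_fitness([1, 1, 1], "min") == 1
        assert combined_fitness([1, 1, 1], "product") == 1
        assert combined_fitness([0.5, 0.8], "min") == pytest.approx(0.5)
        assert combined_fitness([0.5, 0.8], "product") == pytest.approx(0.4)

    def test_every_protein_is_essential(self):
        for mode in ("min", "product"):
            assert combined_fitness([1.0, 0.0, 0.9], mode) == 0.0

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            combined_fitness([], "min")


def _permissive_dimer():
    """2-codon toy where every sense sequence is viable (for neutral tests)."""
    cmap = ContactMap(L=2, pairs=np.array([[0, 1]]), min_separation=1,
                      source="toy:dimer")
    model = toy_hydrophobic_model(s_conf=0.05)  # all dG > 0
    fs = FitnessSpec(beta=0.0, c_dG=0.9, dG_ref=0.2, use_gap=False,
                     form="power_clipped")
    return CodingSequence("TTTTGG"), cmap, model, fs


class TestEvolve:
    def test_neutral_acceptance_scales_as_one_over_n(self):
        # with beta=0 and every sense sequence viable the acceptance
        # probability is 1/N per non-stop proposal; calibrate the stop
        # fraction with an N=1 run, then check N=10
        gene, cmap, model, fs = _permissive_dimer()
        r1 = evolve(gene, cmap, model,
                    EvolutionRun(N=1, fitness_spec=fs, n_accept_total=4000,
                                 burn_in=10, replicas=1, seed=5))
        rate1 = 4000 / r1.trajectory["proposal"].max()   # = 1 - p_stop
        r10 = evolve(gene, cmap, model,
                     EvolutionRun(N=10, fitness_spec=fs, n_accept_total=4000,
                                  burn_in=10, replicas=1, seed=6))
        rate10 = 4000 / r10.trajectory["proposal"].max()
        expected = rate1 / 10
        sigma = math.sqrt(expected * (1 - expected) / r10.trajectory["proposal"].max())
        assert abs(rate10 - expected) < 4 * sigma
        assert (r1.trajectory["fitness"] == 1.0).all()

    def test_rejects_nonviable_start(self, study):
        bad = CodingSequence("AAA" * study.cmap.L)  # poly-K: lethal
        run = EvolutionRun(N=5, fitness_spec=study.fitness_spec,
                           n_accept_total=10, burn_in=1, replicas=1, seed=0)
        with pytest.raises(ValueError, match="nonviable"):
            evolve(bad, study.cmap, study.model, run)

    def test_accepted_states_are_stop_free_and_consistent(self, study):
        run = EvolutionRun(N=20, fitness_spec=study.fitness_spec,
                           n_accept_total=150, burn_in=30, replicas=2, seed=9)
        res = evolve(study.gene, study.cmap, study.model, run)
        tr = res.trajectory
        assert len(tr) == 2 * 150
        assert (tr["fitness"] > 0).all()
        assert np.allclose(tr["log_fitness"], np.log(tr["fitness"]))
        # replay replica 0 and verify the final recorded stabilities
        nt = list(study.gene.nucleotides)
        for _, row in tr[tr.replica == 0].iterrows():
            nt[int(row.site)] = NUCLEOTIDES[int(row.new_nt)]
        prot = translate(CodingSequence("".join(nt)))
        sp = compute_stabilities(prot, study.cmap, study.model)
        last = tr[tr.replica == 0].iloc[-1]
        assert sp.dG_unf == pytest.approx(last.dG_unf, abs=1e-9)
        assert sp.alpha_gap == pytest.approx(last.alpha_gap, abs=1e-9)

    def test_n1_stationary_matches_mutation_only(self, study):
        # N=1 accepts every viable proposal; restricted to the viable set the
        # stationary law is the mutation-only measure conditioned on
        # viability, so compare against the conditioned i.i.d. sample
        run = EvolutionRun(N=1, fitness_spec=study.fitness_spec,
                           n_accept_total=4000, burn_in=400, replicas=4, seed=3)
        res = evolve(study.gene, study.cmap, study.model, run)
        # residence-weighted (occupancy) means per replica
        means = []
        for _, grp in res.trajectory.groupby("replica"):
            grp = grp[grp.accept_idx >= 400]
            props = grp["proposal"].to_numpy()
            w = np.diff(props, append=props[-1] + max(int(np.mean(np.diff(props))), 1))
            means.append((np.average(grp["x"], weights=w),
                          np.average(grp["y"], weights=w)))
        mx, my = np.mean(means, axis=0)
        sx, sy = np.std(means, axis=0, ddof=1) / 2  # 4 replicas
        s = mutation_only_sample(study.gene, study.cmap, study.model,
                                 HKYModel(gc=0.5), 200000, seed=8,
                                 fitness_spec=study.fitness_spec)
        viable = (s[:, 0] > 0) & (s[:, 1] > 0)
        assert abs(mx - s[viable, 0].mean()) < 5 * sx
        assert abs(my - s[viable, 1].mean()) < 5 * sy

    def test_summary_reports_replica_level_sem(self, study):
        run = EvolutionRun(N=10, fitness_spec=study.fitness_spec,
                           n_accept_total=120, burn_in=30, replicas=3, seed=1)
        res = evolve(study.gene, study.cmap, study.model, run)
        reps = res.summary["x"]["replica_means"]
        assert len(reps) == 3
        assert res.sem("x") == pytest.approx(np.std(reps, ddof=1) / math.sqrt(3))

    def test_burn_in_must_precede_collection_end(self):
        with pytest.raises(ValueError, match="burn_in"):
            EvolutionRun(N=5, n_accept_total=100, burn_in=100)


class TestToyChainAgainstExactOracle:
    def test_occupancy_matches_enumerated_stationary(self, toy_dimer):
        # gc = 0.5: the per-proposal chain and the rate chain share their
        # stationary law, so residence-weighted occupancy of the simulation
        # must match the exact enumerated vector (replica-level 3 sigma)
        gene, cmap, model, fs = toy_dimer
        hky = HKYModel(gc=0.5, kappa=4.0)
        N = 5
        exact = enumerate_stationary(gene, cmap, model, hky, fs, N)
        lookup = {s: k for k, s in enumerate(exact.sequences)}
        n_rep, burn = 4, 800
        run = EvolutionRun(N=N, hky=hky, fitness_spec=fs, n_accept_total=12000,
                           burn_in=burn, replicas=n_rep, seed=17)
        res = evolve(gene, cmap, model, run)
        top = np.argsort(exact.exact)[::-1][:8]
        freqs = np.zeros((n_rep, len(exact.sequences)))
        for rep, grp in res.trajectory.groupby("replica"):
            nt = list(gene.nucleotides)
            # rebuild occupancy: state after each acceptance, weighted by
            # residence time in proposals; burn-in rows update the state
            # but contribute no weight
            props = grp["proposal"].to_numpy()
            res_t = np.diff(props, append=props[-1] + max(int(np.mean(np.diff(props))), 1))
            for (_, row), w in zip(grp.iterrows(), res_t):
                nt[int(row.site)] = NUCLEOTIDES[int(row.new_nt)]
                if row.accept_idx >= burn:
                    freqs[rep, lookup["".join(nt)]] += w
        freqs /= freqs.sum(axis=1, keepdims=True)
        emp = freqs.mean(axis=0)
        assert 0.5 * np.abs(emp - exact.exact).sum() < 0.05  # global TV
        for k in top:
            sem = freqs[:, k].std(ddof=1) / math.sqrt(n_rep)
            assert abs(emp[k] - exact.exact[k]) < 4 * sem + 5e-4


class TestEvolveGenome:
    def test_single_gene_reduces_to_evolve(self, study):
        run = EvolutionRun(N=10, fitness_spec=study.fitness_spec,
                           n_accept_total=80, burn_in=20, replicas=1, seed=2)
        a = evolve(study.gene, study.cmap, study.model, run)
        b = evolve_genome([(study.gene, study.cmap)], study.model, run,
                          mode="product")
        pd.testing.assert_frame_equal(a.trajectory, b.trajectory)

    def test_identical_genes_substitute_at_equal_rates(self):
        gene, cmap, model, fs = _permissive_dimer()
        run = EvolutionRun(N=4, fitness_spec=fs, n_accept_total=4000,
                           burn_in=100, replicas=1, seed=4)
        res = evolve_genome([(gene, cmap), (gene, cmap)], model, run,
                            mode="product")
        counts = res.trajectory["gene"].value_counts()
        n = counts.sum()
        assert abs(counts[0] - n / 2) < 3.5 * math.sqrt(n * 0.25)

    def test_proposals_target_genes_by_length(self):
        # second gene twice as long: under neutrality accepted substitutions
        # land on it twice as often
        gene1, cmap1, model, fs = _permissive_dimer()
        cmap2 = ContactMap(L=4, pairs=np.array([[0, 3]]), min_separation=3)
        rng = np.random.default_rng(0)
        gene2 = CodingSequence("TTTTGGTTCTGG")
        run = EvolutionRun(N=1, fitness_spec=fs, n_accept_total=6000,
                           burn_in=100, replicas=1, seed=12)
        res = evolve_genome([(gene1, cmap1), (gene2, cmap2)], model, run,
                            mode="min")
        counts = res.trajectory["gene"].value_counts()
        n = counts.sum()
        p = 2 / 3  # length share of gene2
        assert abs(counts[1] - n * p) < 3.5 * math.sqrt(n * p * (1 - p))

    def test_one_nonviable_protein_zeroes_the_genome(self):
        # an unfoldable protein (dG < 0 for every sequence) is lethal for
        # the whole genome, whatever the other proteins do
        gene, cmap, model, fs = _permissive_dimer()
        unfoldable = toy_hydrophobic_model(s_conf=5.0)  # dG always < 0
        run = EvolutionRun(N=5, fitness_spec=fs, n_accept_total=10,
                           burn_in=1, replicas=1, seed=0)
        with pytest.raises(ValueError, match="nonviable"):
            evolve_genome([(gene, cmap), (gene, cmap)], unfoldable, run)
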