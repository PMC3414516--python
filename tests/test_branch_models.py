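"""GY94 construction, pruning correctness, fits and LRT machinery."""

import numpy as np
import pytest

from tpsevol import (
    CodonAlignment,
    CodonFrequencies,
    PhyloTree,
    SimulationSpec,
    build_codon_freqs,
    fit_branch_model,
    gy94_rate_matrix,
    likelihood_ratio_test,
    pruning_loglik,
    simulate_codon_alignment,
    transition_matrix,
)
from tpsevol._codons import CODON_INDEX, N_SENSE, SENSE_CODONS
from tpsevol.branch_models import SpectralQ
from tpsevol.errors import NotNestedError, TpsEvolError

EQUAL = CodonFrequencies("equal", np.full(N_SENSE, 1.0 / N_SENSE))


class TestCodonFreqs:
    def test_equal_model(self):
        ca = CodonAlignment(ids=["a"], rows=[["ATG"]])
        f = build_codon_freqs(ca, "equal")
        assert np.allclose(f.pi, 1.0 / N_SENSE)

    def test_single_codon_alignment_concentrates(self):
        ca = CodonAlignment(ids=["a", "b"], rows=[["ATG"], ["ATG"]])
        f = build_codon_freqs(ca, "F3x4")
        assert f.pi[CODON_INDEX["ATG"]] > 0.99

    def test_f3x4_hand_product(self):
        ca = CodonAlignment(
            ids=["a", "b"], rows=[["ATG", "TTC"], ["ATG", "TTT"]]
        )
        f = build_codon_freqs(ca, "F3x4", floor=0.0)
        # position freqs: pos1 A=T=1/2; pos2 T=1; pos3 G=1/2, C=1/4, T=1/4
        raw_atg = 0.5 * 1.0 * 0.5
        raw_ttt = 0.5 * 1.0 * 0.25
        ratio = f.pi[CODON_INDEX["ATG"]] / f.pi[CODON_INDEX["TTT"]]
        assert ratio == pytest.approx(raw_atg / raw_ttt, rel=1e-9)


class TestRateMatrix:
    def test_detailed_balance_and_normalization(self):
        rng = np.random.default_rng(0)
        pi = rng.dirichlet(np.ones(N_SENSE))
        freqs = CodonFrequencies("empirical_codon", pi)
        rm = gy94_rate_matrix(3.0, 0.4, freqs)
        flux = rm.pi[:, None] * rm.Q
        assert np.allclose(flux, flux.T, atol=1e-14)
        assert -rm.pi @ np.diag(rm.Q) == pytest.approx(1.0, abs=1e-12)
        off = rm.Q.copy()
        np.fill_diagonal(off, 0.0)
        assert np.all(off >= 0)
        assert np.allclose(rm.Q.sum(axis=1), 0.0, atol=1e-12)

    def test_symmetric_rates_at_neutral_parameters(self):
        rm = gy94_rate_matrix(1.0, 1.0, EQUAL)
        off = rm.Q[rm.Q > 0]
        assert np.allclose(off, off[0])

    def test_multi_hit_rates_zero(self):
        rm = gy94_rate_matrix(2.0, 0.5, EQUAL)
        i, j = CODON_INDEX["ATG"], CODON_INDEX["TTC"]  # 3 differences
        assert rm.Q[i, j] == 0.0


class TestTransitionMatrix:
    def test_identity_at_zero(self):
        rm = gy94_rate_matrix(2.0, 0.5, EQUAL)
        assert np.allclose(transition_matrix(rm, 0.0), np.eye(N_SENSE))

    def test_rows_stochastic(self):
        rm = gy94_rate_matrix(2.0, 0.5, EQUAL)
        P = transition_matrix(rm, 0.7)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)
        assert P.min() >= 0

    def test_long_time_limit_is_pi(self):
        rng = np.random.default_rng(1)
        pi = rng.dirichlet(np.ones(N_SENSE) * 5)
        rm = gy94_rate_matrix(2.0, 0.5, CodonFrequencies("empirical_codon", pi))
        P = transition_matrix(rm, 100.0)
        assert np.allclose(P, np.tile(rm.pi, (N_SENSE, 1)), atol=1e-6)

    def test_semigroup(self):
        rm = gy94_rate_matrix(2.0, 0.5, EQUAL)
        sq = SpectralQ(rm)
        assert np.allclose(
            sq.P(0.1) @ sq.P(0.2), sq.P(0.3), atol=1e-8
        )

    def test_negative_time_rejected(self):
        rm = gy94_rate_matrix(2.0, 0.5, EQUAL)
        with pytest.raises(TpsEvolError):
            transition_matrix(rm, -0.1)


class TestPruning:
    def test_three_leaves_zero_lengths_identical_codon(self):
        tree = PhyloTree.from_newick("(a:0,b:0,c:0);")
        ca = CodonAlignment(
            ids=list("abc"), rows=[["ATG"], ["ATG"], ["ATG"]]
        )
        lnl = pruning_loglik(tree, ca, 2.0, 0.5, EQUAL)
        assert lnl == pytest.approx(np.log(1.0 / N_SENSE), abs=1e-12)

    def test_matches_exhaustive_summation(
        self, quartet_tree, quartet_alignment
    ):
        """Pruning equals brute-force summation over both internal nodes
        of the derooted quartet (61^2 assignments per column)."""
        kappa, omega = 2.0, 0.2
        lnl = pruning_loglik(
            quartet_tree, quartet_alignment, kappa, omega, EQUAL
        )
        sq = SpectralQ(gy94_rate_matrix(kappa, omega, EQUAL))
        # derooted topology: root children a(0.1), b(0.2), X(0.20); X -> c,d
        Pa, Pb, Px = sq.P(0.1), sq.P(0.2), sq.P(0.2)
        Pc, Pd = sq.P(0.12), sq.P(0.3)
        pi = EQUAL.pi
        total = 0.0
        for col in range(quartet_alignment.ncol):
            s = {
                x: CODON_INDEX[quartet_alignment.row(x)[col]]
                for x in "abcd"
            }
            site = 0.0
            for r in range(N_SENSE):
                inner = 0.0
                for x in range(N_SENSE):
                    inner += (
                        Px[r, x] * Pc[x, s["c"]] * Pd[x, s["d"]]
                    )
                site += pi[r] * Pa[r, s["a"]] * Pb[r, s["b"]] * inner
            total += np.log(site)
        assert lnl == pytest.approx(total, abs=1e-10)

    def test_invariant_to_virtual_root(self, quartet_alignment):
        reps = [
            "((a:0.1,b:0.2):0.15,(c:0.12,d:0.3):0.05);",
            "((c:0.12,d:0.3):0.2,a:0.1,b:0.2);",
            "(a:0.1,b:0.2,(c:0.12,d:0.3):0.2);",
        ]
        vals = [
            pruning_loglik(
                PhyloTree.from_newick(nwk), quartet_alignment, 2.0, 0.2, EQUAL
            )
            for nwk in reps
        ]
        assert np.allclose(vals, vals[0], atol=1e-10)

    def test_gradient_matches_finite_differences(self, tree8):
        from tpsevol.branch_models import PruningEngine

        ca, _ = simulate_codon_alignment(
            SimulationSpec(
                tree=tree8, kappa=2.0,
                omega_by_class={"background": 0.2},
                n_codons=60, seed=4,
            )
        )
        eng = PruningEngine(tree8, ca)
        freqs = build_codon_freqs(ca, "F3x4")
        spectra = [SpectralQ(gy94_rate_matrix(2.0, 0.2, freqs))]
        ec = np.zeros(eng.index.n_nodes, dtype=int)
        t = eng.index.edge_length.copy()
        v, g = eng.loglik(freqs.pi, spectra, ec, t, grad_t=True)
        for e in eng.index.edges:
            h = 1e-6
            t2 = t.copy()
            t2[e] += h
            fd = (eng.loglik(freqs.pi, spectra, ec, t2) - v) / h
            assert g[e] == pytest.approx(fd, rel=1e-3, abs=1e-4)


@pytest.fixture(scope="module")
def fitted_pair(tree8, foreground8, one_ratio_alignment):
    ca, _ = one_ratio_alignment
    fit0 = fit_branch_model(
        tree8, ca, model="one_ratio", n_starts=1, seed=0
    )
    fit1 = fit_branch_model(
        tree8, ca, model="two_ratio", foreground=foreground8,
        n_starts=1, seed=0,
        init={
            "kappa": fit0.kappa,
            "omegas": [fit0.omega_by_class["all"]] * 2,
            "t": {
                frozenset(k): v
                for k, v in fit0.branch_lengths.items()
            },
        },
    )
    return fit0, fit1


class TestFitsAndLRT:

    def test_one_ratio_recovers_parameters(self, fitted_pair):
        fit0, _ = fitted_pair
        assert fit0.converged
        assert 0.07 <= fit0.omega_by_class["all"] <= 0.13
        assert 1.5 <= fit0.kappa <= 2.6

    def test_nesting_loglik_ordering(self, fitted_pair):
        fit0, fit1 = fitted_pair
        assert fit1.loglik >= fit0.loglik - 1e-6
        assert fit1.n_free_params == fit0.n_free_params + 1

    def test_lrt_on_null_data_is_modest(self, fitted_pair):
        lrt = likelihood_ratio_test(*fitted_pair)
        assert lrt.df == 1
        assert 0.0 <= lrt.statistic < 15.0
        assert 0.0 <= lrt.p_value <= 1.0

    def test_lrt_chi2_quantile(self, fitted_pair):
        """2dl = 3.841 with df = 1 sits exactly at the 5% point."""
        fit0, fit1 = fitted_pair
        clone = type(fit1)(**{**fit1.__dict__})
        clone.loglik = fit0.loglik + 3.841458820694124 / 2.0
        lrt = likelihood_ratio_test(fit0, clone)
        assert lrt.p_value == pytest.approx(0.05, abs=1e-6)

    def test_equal_logliks_give_p_one(self, fitted_pair):
        fit0, fit1 = fitted_pair
        clone = type(fit1)(**{**fit1.__dict__})
        clone.loglik = fit0.loglik
        lrt = likelihood_ratio_test(fit0, clone)
        assert lrt.statistic == 0.0 and lrt.p_value == 1.0

    def test_statistic_clipped_at_zero(self, fitted_pair):
        fit0, fit1 = fitted_pair
        clone = type(fit1)(**{**fit1.__dict__})
        clone.loglik = fit0.loglik - 1e-6  # optimizer noise below null
        lrt = likelihood_ratio_test(fit0, clone)
        assert lrt.statistic == 0.0

    def test_different_data_rejected(
        self, tree8, foreground8, fitted_pair
    ):
        fit0, _ = fitted_pair
        ca2, _ = simulate_codon_alignment(
            SimulationSpec(
                tree=tree8, kappa=2.0,
                omega_by_class={"background": 0.1},
                n_codons=50, seed=999,
            )
        )
        other = fit_branch_model(
            tree8, ca2, model="two_ratio", foreground=foreground8,
            n_starts=1, seed=0, maxiter=20,
        )
        with pytest.raises(NotNestedError):
            likelihood_ratio_test(fit0, other)

    def test_two_ratio_needs_foreground(self, tree8, one_ratio_alignment):
        with pytest.raises(TpsEvolError):
            fit_branch_model(
                tree8, one_ratio_alignment[0], model="two_ratio"
            )


class TestTableSuite:
    def test_relaxed_clade_flagged_across_regions(self):
        """A clade simulated under relaxed omega must come out significant
        in the summary table, with the report embedding its settings."""
        from tpsevol import DomainBlock, balanced_tree
        from tpsevol.branch_models import run_table1_suite

        tree = balanced_tree(6, depth=0.5)
        fg = frozenset(["t1", "t2", "t3"])
        ca, truth = simulate_codon_alignment(
            SimulationSpec(
                tree=tree, kappa=2.0,
                omega_by_class={"background": 0.08, "foreground": 0.5},
                n_codons=240, seed=6, foreground=fg,
                domain_blocks=[
                    DomainBlock(
                        "TPS", 160, {"background": 0.08, "foreground": 0.5}
                    ),
                    DomainBlock(
                        "TPP", 80, {"background": 0.12, "foreground": 0.5}
                    ),
                ],
            )
        )
        df = run_table1_suite(
            ca,
            [{"name": "tree1", "tree": tree, "foreground": fg}],
            partition=truth["partition"],
            regions=("full_length", "TPS"),
            seed=0,
        )
        assert list(df["region"].unique()) == ["full_length", "TPS"]
        assert set(df["model"]) == {"one_ratio", "two_ratio"}
        assert (df["freq_model"] == "F3x4").all()
        two = df[df["model"] == "two_ratio"]
        full = two[two["region"] == "full_length"].iloc[0]
        assert full["p"] < 0.01
        assert "omega_fg" in full["parameters"]
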