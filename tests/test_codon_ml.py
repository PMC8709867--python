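"""MG94xHKY rate matrices, pruning likelihood, and omega estimation."""

import numpy as np
import pytest
from scipy.linalg import expm

from genedecay.codon_ml import (
    CODON_INDEX,
    IS_SYNONYMOUS,
    N_CODONS,
    SINGLE_STEP,
    CodonAlignment,
    CodonModelParams,
    build_rate_matrix,
    empirical_pi,
    fit,
    log_likelihood,
    lrt_relaxation,
    branch_omegas_for_dating,
    _raw_rate_matrix,
)
from genedecay.event_inference import StatusTree
from genedecay.synthetic_data import SimulationSpec, simulate_alignment

EQUAL_PI = np.full(N_CODONS, 1.0 / N_CODONS)


def _params(kappa=2.0, omega=0.3, pi=None, lengths=None):
    return CodonModelParams(
        kappa=kappa,
        omega_by_category={"x": omega},
        pi=EQUAL_PI if pi is None else pi,
        branch_lengths=lengths or {},
    )


class TestRateMatrix:
    def test_neutral_symmetric_case(self):
        # kappa=1, omega=1, equal pi: all single-step rates equal
        q = build_rate_matrix(_params(kappa=1.0, omega=1.0), "x")
        off = q[SINGLE_STEP]
        assert np.allclose(off, off[0])
        assert np.allclose(q[~SINGLE_STEP & ~np.eye(N_CODONS, dtype=bool)], 0.0)
        assert np.allclose(q.sum(axis=1), 0.0, atol=1e-12)

    def test_normalization_and_detailed_balance_random_draws(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            pi = rng.dirichlet(np.ones(N_CODONS) * 5)
            params = _params(
                kappa=float(rng.uniform(0.5, 8)), omega=float(rng.uniform(0.05, 3)),
                pi=pi,
            )
            q = build_rate_matrix(params, "x")
            # unit expected rate
            assert abs(-(pi @ np.diag(q)) - 1.0) < 1e-10
            # reversibility
            flux = pi[:, None] * q
            assert np.abs(flux - flux.T).max() < 1e-12

    def test_synonymous_transition_entry(self):
        # AAA -> AAG is a synonymous transition: q = kappa * pi_AAG / norm
        params = _params(kappa=2.0, omega=0.2)
        q = build_rate_matrix(params, "x")
        raw = _raw_rate_matrix(EQUAL_PI, 2.0, 0.2)
        norm = float(EQUAL_PI @ -np.diag(raw))
        i, j = CODON_INDEX["AAA"], CODON_INDEX["AAG"]
        assert q[i, j] == pytest.approx(2.0 * EQUAL_PI[j] / norm)

    def test_omega_monotone_in_nonsyn_fraction(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            pi = rng.dirichlet(np.ones(N_CODONS) * 10)
            kappa = float(rng.uniform(0.5, 6))
            fractions = []
            for omega in (0.1, 0.5, 1.0, 2.0):
                q = _raw_rate_matrix(pi, kappa, omega)
                nonsyn = np.where(SINGLE_STEP & ~IS_SYNONYMOUS, q, 0.0)
                fractions.append(
                    float(pi @ nonsyn.sum(axis=1)) / float(pi @ -np.diag(q))
                )
            assert np.all(np.diff(fractions) > 0)

    def test_invalid_pi_rejected(self):
        bad = np.full(N_CODONS, 1.0 / N_CODONS)
        bad[0] = 0.0
        bad[1] += 1.0 / N_CODONS
        with pytest.raises(ValueError, match="positive"):
            _params(pi=bad)


class TestLogLikelihood:
    def test_two_taxon_closed_form(self):
        tree = StatusTree.from_newick("(A:1,B:1);")
        aln = CodonAlignment.from_sequences({"A": "ATG", "B": "ACG"})
        lengths = {frozenset({"A"}): 0.07, frozenset({"B"}): 0.13}
        params = _params(lengths=lengths)
        q = build_rate_matrix(params, "x")
        pa = expm(q * 0.07)
        pb = expm(q * 0.13)
        i, j = CODON_INDEX["ATG"], CODON_INDEX["ACG"]
        expected = np.log(sum(EQUAL_PI[k] * pa[k, i] * pb[k, j] for k in range(N_CODONS)))
        got = log_likelihood(tree, aln, params)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_zero_length_identical_sequences(self):
        tree = StatusTree.from_newick("(A:1,B:1);")
        aln = CodonAlignment.from_sequences({"A": "ATGGCA", "B": "ATGGCA"})
        lengths = {frozenset({"A"}): 0.0, frozenset({"B"}): 0.0}
        got = log_likelihood(tree, aln, _params(lengths=lengths))
        assert got == pytest.approx(2 * np.log(1.0 / N_CODONS), abs=1e-10)

    def test_leaf_relabeling_invariance(self):
        tree = StatusTree.from_newick("((A:1,B:1):1,(C:1.5,D:1.5):0.5);")
        seqs = {"A": "ATGAAA", "B": "ATGAAG", "C": "ACGAAA", "D": "ATGCAA"}
        lengths = {k: 0.02 * len(k) for k in tree.labels}
        lnl = log_likelihood(
            tree, CodonAlignment.from_sequences(seqs), _params(lengths=lengths)
        )
        # swap the labels of A and B together with their data
        tree2 = StatusTree.from_newick("((B:1,A:1):1,(C:1.5,D:1.5):0.5);")
        lnl2 = log_likelihood(
            tree2, CodonAlignment.from_sequences(seqs), _params(lengths=lengths)
        )
        assert lnl == pytest.approx(lnl2, abs=1e-10)

    def test_gap_is_uninformative(self):
        tree = StatusTree.from_newick("(A:1,B:1);")
        lengths = {frozenset({"A"}): 0.05, frozenset({"B"}): 0.05}
        one = log_likelihood(
            tree,
            CodonAlignment.from_sequences({"A": "ATG", "B": "---"}),
            _params(lengths=lengths),
        )
        # marginalizing B leaves the stationary probability of A's codon
        assert one == pytest.approx(np.log(1.0 / N_CODONS), abs=1e-10)

    def test_stop_in_functional_row_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            CodonAlignment.from_sequences({"A": "TAA"})

    def test_stop_recoded_for_pseudogenic_row(self):
        aln = CodonAlignment.from_sequences({"A": "TAA"}, pseudogenic={"A"})
        assert aln.codes[0, 0] == -1


class TestEmpiricalPi:
    def test_modes_sum_to_one(self):
        aln = CodonAlignment.from_sequences({"A": "ATGGCAACC", "B": "ATGGCGACA"})
        for mode in ("equal", "f1x4", "f3x4"):
            pi = empirical_pi(aln, mode)
            assert pi.shape == (N_CODONS,)
            assert pi.sum() == pytest.approx(1.0)
            assert (pi > 0).all()

    def test_unknown_mode_rejected(self):
        aln = CodonAlignment.from_sequences({"A": "ATG"})
        with pytest.raises(ValueError, match="pi mode"):
            empirical_pi(aln, "f61")


NEWICK6 = "(((A:10,B:10):15,(C:12,D:12):13):15,(E:20,F:20):20);"


class TestFit:
    def test_omega_recovery(self):
        """omega-hat lands in [0.1, 0.35] for data simulated at omega 0.2."""
        hits = 0
        for seed in range(20):
            spec = SimulationSpec(
                newick=NEWICK6, sites=150, omega_functional=0.2, seed=seed
            )
            sim = simulate_alignment(spec)
            cmap = {k: "all" for k in sim.tree.labels}
            result = fit(sim.tree, sim.alignment, cmap)
            if 0.1 <= result.params.omega_by_category["all"] <= 0.35:
                hits += 1
        assert hits >= 18

    def test_identical_sequences_drive_rate_to_lower_bound(self):
        tree = StatusTree.from_newick("((A:1,B:1):1,C:2);")
        aln = CodonAlignment.from_sequences(
            {"A": "ATGGCAACC" * 5, "B": "ATGGCAACC" * 5, "C": "ATGGCAACC" * 5}
        )
        cmap = {k: "all" for k in tree.labels}
        result = fit(tree, aln, cmap)
        assert max(result.params.branch_lengths.values()) < 1e-4

    def test_category_constraint_equivalence(self):
        """A two-category model with both omegas pinned to the one-category
        optimum reproduces the one-category likelihood."""
        spec = SimulationSpec(newick=NEWICK6, sites=100, omega_functional=0.3, seed=1)
        sim = simulate_alignment(spec)
        one = fit(sim.tree, sim.alignment, {k: "all" for k in sim.tree.labels})
        omega = one.params.omega_by_category["all"]
        two_map = {
            k: ("fg" if k == frozenset({"E"}) else "bg") for k in sim.tree.labels
        }
        params = CodonModelParams(
            kappa=one.params.kappa,
            omega_by_category={"fg": omega, "bg": omega},
            pi=one.params.pi,
            branch_lengths=one.params.branch_lengths,
        )
        lnl = log_likelihood(sim.tree, sim.alignment, params, two_map)
        assert lnl == pytest.approx(one.lnl, abs=1e-6)


class TestLRT:
    def test_statistic_nonnegative_and_df(self):
        spec = SimulationSpec(newick=NEWICK6, sites=100, omega_functional=0.2, seed=3)
        sim = simulate_alignment(spec)
        res = lrt_relaxation(sim.tree, sim.alignment, [frozenset({"E"})])
        assert res.statistic >= 0
        assert res.df == 1
        assert 0 <= res.pvalue <= 1
        assert res.aux_statistic is not None

    def test_power_against_neutral_foreground(self):
        """A fully neutral foreground branch against omega 0.1 background is
        detected: median p < 0.05 over a handful of simulations."""
        pvals = []
        for seed in range(6):
            spec = SimulationSpec(
                newick=NEWICK6,
                sites=500,
                omega_functional=0.1,
                loss_events=((("E",), 19.99),),  # neutral for ~the whole branch
                indel_rate=0.0,
                seed=seed,
            )
            sim = simulate_alignment(spec)
            res = lrt_relaxation(sim.tree, sim.alignment, [frozenset({"E"})])
            pvals.append(res.pvalue)
        assert np.median(pvals) < 0.05

    def test_foreground_validation(self):
        spec = SimulationSpec(newick=NEWICK6, sites=30, seed=0)
        sim = simulate_alignment(spec)
        with pytest.raises(ValueError, match="non-empty"):
            lrt_relaxation(sim.tree, sim.alignment, [])
        with pytest.raises(ValueError, match="proper subset"):
            lrt_relaxation(sim.tree, sim.alignment, list(sim.tree.labels))


class TestBranchOmegas:
    def test_neutral_branch_omega_exceeds_functional(self):
        """A branch that was neutral for most of its length gets a higher
        category omega than the pooled functional branches."""
        wins = 0
        for seed in range(8):
            spec = SimulationSpec(
                newick=NEWICK6,
                sites=300,
                omega_functional=0.1,
                loss_events=((("E",), 19.5),),
                indel_rate=0.0,
                seed=seed,
            )
            sim = simulate_alignment(spec)
            table = branch_omegas_for_dating(sim.tree, sim.alignment)
            if table.omega_mixed[frozenset({"E"})] > table.omega_functional:
                wins += 1
        assert wins >= 7

    def test_requires_functional_branches(self):
        spec = SimulationSpec(newick="(A:1,B:1);", sites=30, seed=0)
        sim = simulate_alignment(spec)
        labels = {k: "pseudogenic" for k in sim.tree.labels}
        with pytest.raises(ValueError, match="functional"):
            branch_omegas_for_dating(sim.tree, sim.alignment, labels)
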