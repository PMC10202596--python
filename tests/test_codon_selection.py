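import numpy as np
import pytest
from scipy.linalg import expm
from scipy.stats import chi2

import relict
from relict.codon_selection import (
    BranchPartition,
    CodonModel,
    ModelFit,
    _class_tms,
    _encode,
    _pruning,
    build_codon_rate_matrix,
    codon_log_likelihood,
    estimate_codon_freqs,
    fit_branch_model,
    likelihood_ratio_test,
)
from relict.genetics import CODON_AA, SENSE_CODONS, SINGLE_DIFF
from relict.synthetic_data import SimConfig, simulate_codon_alignment
from relict.trees import Phylogeny


@pytest.fixture(scope="module")
def model(uniform_freqs):
    return CodonModel(kappa=2.5, omega_by_class={"bg": 0.4}, codon_freqs=uniform_freqs)


@pytest.fixture(scope="module")
def uniform_freqs():
    return np.full(61, 1.0 / 61.0)


class TestRateMatrix:
    def test_rows_sum_to_zero(self, model):
        Q = build_codon_rate_matrix(model, "bg")
        assert np.abs(Q.sum(axis=1)).max() < 1e-12

    def test_detailed_balance(self):
        rng = np.random.default_rng(1)
        pi = rng.dirichlet(np.ones(61))
        m = CodonModel(3.0, {"bg": 0.7}, pi)
        Q = build_codon_rate_matrix(m, "bg")
        flux = pi[:, None] * Q
        assert np.abs(flux - flux.T).max() < 1e-12

    def test_multi_nucleotide_changes_forbidden(self, model):
        Q = build_codon_rate_matrix(model, "bg")
        off = ~np.eye(61, dtype=bool)
        assert np.all(Q[off & ~SINGLE_DIFF] == 0)

    def test_mean_rate_is_one(self, model):
        Q = build_codon_rate_matrix(model, "bg")
        assert -float(model.codon_freqs @ np.diag(Q)) == pytest.approx(1.0)

    def test_omega_zero_blocks_nonsynonymous_flux(self, uniform_freqs):
        m = CodonModel(2.0, {"bg": 0.0}, uniform_freqs)
        Q = build_codon_rate_matrix(m, "bg")
        aa = np.array(list(CODON_AA))
        nonsyn = aa[:, None] != aa[None, :]
        assert np.all(Q[nonsyn & SINGLE_DIFF] == 0)


class TestLikelihood:
    def test_two_tips_one_site_matches_direct_sum(self, model, uniform_freqs):
        t1, t2 = 0.12, 0.3
        tree = Phylogeny.from_newick(f"(A:{t1},B:{t2});")
        aln = relict.CodonAlignment({"A": "ATG", "B": "ACG"}, ref_species="A")
        Q = build_codon_rate_matrix(model, "bg")
        P1, P2 = expm(Q * t1), expm(Q * t2)
        j = SENSE_CODONS.index("ATG")
        k = SENSE_CODONS.index("ACG")
        direct = np.log(np.sum(uniform_freqs * P1[:, j] * P2[:, k]))
        ll = codon_log_likelihood(aln, tree, model=model)
        assert ll == pytest.approx(direct, abs=1e-10)

    def test_zero_branches_identical_sequences(self, model, uniform_freqs):
        tree = Phylogeny.from_newick("(A:0,B:0);")
        aln = relict.CodonAlignment({"A": "ATGACG", "B": "ATGACG"}, ref_species="A")
        ll = codon_log_likelihood(aln, tree, model=model)
        assert ll == pytest.approx(2 * np.log(1 / 61), abs=1e-9)

    def test_reroot_invariance(self, model):
        tree = Phylogeny.from_newick("((A:0.1,B:0.3):0.15,(C:0.2,D:0.05):0.25);")
        cfg = SimConfig(seed=3, n_codons=40, kappa=2.5, omega_by_class={"bg": 0.4})
        aln = simulate_codon_alignment(tree, cfg)
        ll = codon_log_likelihood(aln, tree, model=model)
        for edge in [v for v in range(tree.n_nodes) if v != tree.root][:4]:
            rerooted = tree.reroot_at_edge(edge, 0.3)
            ll2 = codon_log_likelihood(aln, rerooted, model=model)
            assert ll2 == pytest.approx(ll, abs=1e-8)

    def test_species_mismatch_is_input_error(self, model):
        tree = Phylogeny.from_newick("(A:0.1,B:0.1);")
        aln = relict.CodonAlignment({"A": "ATG", "X": "ATG"})
        with pytest.raises(ValueError, match="mismatch"):
            codon_log_likelihood(aln, tree, model=model)

    def test_gradient_matches_finite_differences(self, model, uniform_freqs):
        tree = Phylogeny.from_newick("((A:0.1,B:0.3):0.15,(C:0.2,D:0.05):0.25);")
        cfg = SimConfig(seed=3, n_codons=30, kappa=2.5, omega_by_class={"bg": 0.4})
        aln = simulate_codon_alignment(tree, cfg)
        codes, counts, _ = _encode(aln, tree)
        tms = _class_tms(model, tree.classes, tree)
        lengths = tree.lengths.copy()
        ll0, grad = _pruning(tree, codes, counts, tms, lengths, uniform_freqs, want_grad=True)
        h = 1e-6
        for v in range(tree.n_nodes):
            if v == tree.root:
                continue
            lp, lm = lengths.copy(), lengths.copy()
            lp[v] += h
            lm[v] -= h
            fd = (
                _pruning(tree, codes, counts, tms, lp, uniform_freqs)[0]
                - _pruning(tree, codes, counts, tms, lm, uniform_freqs)[0]
            ) / (2 * h)
            assert grad[v] == pytest.approx(fd, rel=1e-4, abs=1e-6)


class TestFrequencyEstimation:
    def test_f61_matches_empirical(self):
        aln = relict.CodonAlignment({"A": "ATGATG", "B": "ATGACG"}, ref_species="A")
        freqs = estimate_codon_freqs(aln, "f61")
        assert freqs.sum() == pytest.approx(1.0)
        assert freqs[SENSE_CODONS.index("ATG")] > freqs[SENSE_CODONS.index("TTT")]

    @pytest.mark.parametrize("method", ["f3x4", "f1x4", "f61", "equal"])
    def test_valid_distributions(self, method):
        cfg = SimConfig(seed=2, n_codons=60)
        tree = relict.generate_yule_tree(4, seed=2).with_height(0.3)
        aln = simulate_codon_alignment(tree, cfg)
        freqs = estimate_codon_freqs(aln, method)
        assert freqs.shape == (61,)
        assert freqs.sum() == pytest.approx(1.0)
        assert (freqs > 0).all()


class TestFitting:
    def test_constrained_equal_matches_single_class(self, two_class_dataset):
        tree, aln = two_class_dataset
        tied = BranchPartition(constraints={"fg": ("tied", "bg")})
        fit_tied = fit_branch_model(aln, tree, tied, n_starts=1)
        fit_single = fit_branch_model(aln, tree, BranchPartition.single("all"), n_starts=1)
        assert fit_tied.logL == pytest.approx(fit_single.logL, abs=1e-6)
        assert fit_tied.model.omega_by_class["fg"] == fit_tied.model.omega_by_class["bg"]

    def test_fixed_constraint_honored(self, two_class_dataset):
        tree, aln = two_class_dataset
        part = BranchPartition(constraints={"bg": ("fixed", 0.25)})
        fit = fit_branch_model(aln, tree, part, n_starts=1)
        assert fit.model.omega_by_class["bg"] == 0.25
        # fixing one class frees one fewer parameter
        free_fit = fit_branch_model(aln, tree, BranchPartition(), n_starts=1)
        assert free_fit.n_params == fit.n_params + 1
        assert free_fit.logL >= fit.logL - 1e-6

    def test_recovery_of_generating_omegas(self, two_class_dataset):
        tree, aln = two_class_dataset
        fit = fit_branch_model(aln, tree, BranchPartition(), n_starts=1)
        assert fit.converged
        assert fit.model.omega_by_class["bg"] == pytest.approx(0.2, abs=0.2)
        assert fit.model.omega_by_class["fg"] == pytest.approx(0.8, abs=0.35)

    def test_adding_parameters_never_hurts(self, two_class_dataset):
        tree, aln = two_class_dataset
        null = fit_branch_model(aln, tree, BranchPartition.single("all"), n_starts=1)
        alt = fit_branch_model(aln, tree, BranchPartition(), n_starts=1, init=null)
        assert alt.logL >= null.logL - 1e-6


class TestLRT:
    def _fit(self, logL, n_params):
        model = CodonModel(2.0, {"a": 0.5}, np.full(61, 1 / 61))
        return ModelFit(model, np.zeros(1), logL, n_params, True, BranchPartition())

    def test_equal_likelihoods_give_p_one(self):
        stat, p = likelihood_ratio_test(self._fit(-100.0, 3), self._fit(-100.0, 2))
        assert stat == 0.0
        assert p == 1.0

    def test_chi_square_critical_value(self):
        stat, p = likelihood_ratio_test(
            self._fit(-100.0, 3), self._fit(-100.0 - 3.841 / 2, 2), df=1
        )
        assert stat == pytest.approx(3.841)
        assert p == pytest.approx(0.05, abs=5e-4)

    def test_nesting_violation_raises(self):
        with pytest.raises(ValueError, match="nesting"):
            likelihood_ratio_test(self._fit(-105.0, 3), self._fit(-100.0, 2))

    def test_df_defaults_to_parameter_difference(self):
        stat, p = likelihood_ratio_test(self._fit(-98.0, 4), self._fit(-100.0, 2))
        assert p == pytest.approx(chi2.sf(4.0, 2))
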