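"""Model fitting, likelihood-ratio tests, and AIC model selection."""

import numpy as np
import pytest

from omegascan import (
    CodonAlignment,
    CodonModelSpec,
    ModelFamily,
    fit_branch_site,
    fit_free_ratio,
    fit_model,
    likelihood_ratio_test,
    select_frequency_model,
)
from omegascan.selection import FitResult, LRTResult, ModelSpecError, NestingError
from omegascan.trees import PhyloTree


def _fit(result_lnl, k):
    return FitResult(
        spec=CodonModelSpec(), lnL=result_lnl, kappa_hat=2.0, omega_hat={0: 0.4},
        branch_lengths_hat={}, site_class_props=None, n_free_params=k,
        converged=True, n_restarts_used=1,
    )


class TestLRT:
    def test_chi2_critical_value(self):
        lrt = likelihood_ratio_test(_fit(-100.0, 2), _fit(-100.0 + 3.841 / 2, 3))
        assert lrt.stat == pytest.approx(3.841)
        assert lrt.df == 1
        assert lrt.p_value == pytest.approx(0.0500, abs=5e-4)

    def test_equal_likelihoods_give_p_one(self):
        lrt = likelihood_ratio_test(_fit(-50.0, 2), _fit(-50.0, 4))
        assert lrt.stat == 0.0 and lrt.p_value == 1.0
        assert lrt.df == 2  # defaults to the free-parameter difference

    def test_alt_worse_than_null_rejected(self):
        with pytest.raises(NestingError):
            likelihood_ratio_test(_fit(-50.0, 2), _fit(-51.0, 3))

    def test_not_nested_by_params_rejected(self):
        with pytest.raises(NestingError):
            likelihood_ratio_test(_fit(-50.0, 3), _fit(-49.0, 3))

    def test_mixture_reference_halves_tail(self):
        plain = likelihood_ratio_test(_fit(-100.0, 2), _fit(-98.0, 3))
        mixed = likelihood_ratio_test(_fit(-100.0, 2), _fit(-98.0, 3), mixture=True)
        assert mixed.p_value == pytest.approx(plain.p_value / 2)


class TestAIC:
    def test_aic_arithmetic_exact(self):
        f = _fit(-100.0, 2)
        assert f.aic == 204.0

    def test_fit_aic_consistent(self, small_sim):
        spec = CodonModelSpec(
            family=ModelFamily.one_ratio, estimate_branch_lengths=False, n_restarts=1
        )
        fit = fit_model(small_sim["codon_aln"], small_sim["tree"], spec, seed=0)
        assert fit.aic == 2 * fit.n_free_params - 2 * fit.lnL


class TestFitModel:
    def test_one_ratio_recovers_background_omega(self, small_sim):
        # data carry a relaxed foreground, so the pooled estimate sits
        # between 0.4 and 2.0 but close to the dominant background
        spec = CodonModelSpec(
            family=ModelFamily.one_ratio, estimate_branch_lengths=False, n_restarts=1
        )
        fit = fit_model(small_sim["codon_aln"], small_sim["tree"], spec, seed=0)
        assert 0.3 < fit.omega_hat[0] < 1.2
        assert fit.converged

    def test_branch_model_separates_categories(self, small_sim):
        spec = CodonModelSpec(
            family=ModelFamily.branch, estimate_branch_lengths=False, n_restarts=1
        )
        fit = fit_model(small_sim["codon_aln"], small_sim["tree"], spec, seed=0)
        assert fit.omega_hat[1] > fit.omega_hat[0]
        assert 0.25 < fit.omega_hat[0] < 0.6  # truth 0.4

    def test_synonymous_only_divergence_drives_omega_to_floor(self, code):
        # 60 sites differing only by the synonymous AAA<->AAG change
        rows = ["AAA" * 30 + "AAG" * 30, "AAG" * 30 + "AAA" * 30]
        aln = CodonAlignment(taxa=["x", "y"], codon_rows=rows)
        tree = PhyloTree.from_newick("(x:0.5,y:0.5);")
        spec = CodonModelSpec(
            family=ModelFamily.one_ratio, estimate_branch_lengths=False, n_restarts=1
        )
        fit = fit_model(aln, tree, spec, seed=0)
        assert fit.omega_hat[0] == pytest.approx(spec.omega_bounds[0], rel=1e-3)

    def test_foreground_without_synonymous_change_reports_999(self, code):
        # the foreground taxon differs from its sister by purely
        # nonsynonymous substitutions: dS = 0 on that branch, so the
        # category omega is unbounded and reports as the 999 sentinel
        import numpy as np

        rng = np.random.default_rng(0)
        base = [code.sense_codons[s] for s in rng.integers(0, 61, size=100)]
        B, C, F = list(base), list(base), list(base)
        for i in range(0, 30, 3):  # background divergence, partly synonymous
            if C[i] == "AAA":
                C[i] = "AAG"
            elif C[i].startswith("CT"):
                C[i] = "CTC"
        for i in range(1, 20, 5):
            if C[i][0] in "AG":
                C[i] = "AAC"
        F[5] = "AAC" if F[5] != "AAC" else "AAA"   # Lys/Asn-type changes
        F[15] = "GAT" if F[15] != "GAT" else "GAA"
        F[25] = "TGG" if F[25] != "TGG" else "TGT"
        aln = CodonAlignment(
            taxa=["F", "B", "C"],
            codon_rows=["".join(F), "".join(B), "".join(C)],
        )
        tree = PhyloTree.from_newick("((F#1:0.05,B:0.05):0.05,C:0.1);")
        spec = CodonModelSpec(
            family=ModelFamily.branch, estimate_branch_lengths=True, n_restarts=2
        )
        fit = fit_model(aln, tree, spec, seed=0)
        assert fit.omega_report()[1] == 999.0
        assert fit.omega_report()[0] < 2.0

    def test_nesting_monotonicity(self, small_sim):
        aln, tree = small_sim["codon_aln"], small_sim["tree"]
        fits = {}
        for fam in (ModelFamily.one_ratio, ModelFamily.branch, ModelFamily.free_ratio):
            spec = CodonModelSpec(
                family=fam, estimate_branch_lengths=False, n_restarts=1
            )
            fits[fam] = fit_model(aln, tree, spec, seed=0)
        tol = 1e-4
        assert fits[ModelFamily.branch].lnL >= fits[ModelFamily.one_ratio].lnL - tol
        assert fits[ModelFamily.free_ratio].lnL >= fits[ModelFamily.branch].lnL - tol

    def test_missing_category_rejected(self, small_sim):
        tree = small_sim["tree"].copy()
        for n in tree.branches:
            if n.category == 1:
                n.category = 2  # leaves category 1 empty
        spec = CodonModelSpec(family=ModelFamily.branch, estimate_branch_lengths=False)
        with pytest.raises(ModelSpecError):
            fit_model(small_sim["codon_aln"], tree, spec, seed=0)


class TestFreeRatio:
    def test_elevated_branch_has_max_omega_and_flag(self, small_sim):
        fit = fit_free_ratio(
            small_sim["codon_aln"], small_sim["tree"], seed=0,
            estimate_branch_lengths=False, n_restarts=1,
        )
        report = fit.omega_report()
        fg_terminal = tuple(sorted(small_sim["foreground"]))
        elevated = {b for b, w in report.items() if w > 0.8}
        assert fit.flagged_branches == sorted(elevated, key=lambda b: list(report).index(b))
        # the relaxed foreground clade contributes flagged branches
        assert any(set(b) <= set(small_sim["foreground"]) for b in elevated)


class TestBranchSite:
    def test_null_has_one_fewer_parameter_and_is_nested(self, small_sim):
        aln, tree = small_sim["codon_aln"], small_sim["tree"]
        null = fit_branch_site(aln, tree, alternative=False, seed=0,
                               estimate_branch_lengths=False, n_restarts=1)
        alt = fit_branch_site(aln, tree, alternative=True, seed=0,
                              estimate_branch_lengths=False, n_restarts=1)
        assert alt.n_free_params == null.n_free_params + 1
        assert alt.lnL >= null.lnL - 1e-4
        p0, p1 = alt.site_class_props
        assert 0 <= p0 <= 1 and 0 <= p1 <= 1 and p0 + p1 <= 1 + 1e-9
        assert alt.omega_hat["omega2"] >= 1.0
        assert null.omega_hat["omega2"] == 1.0

    def test_requires_single_foreground_category(self, small_sim):
        tree = small_sim["tree"].copy()
        tree.set_categories(reset=True)  # no foreground at all
        with pytest.raises(ModelSpecError):
            fit_branch_site(small_sim["codon_aln"], tree, alternative=True, seed=0,
                            estimate_branch_lengths=False)


class TestFrequencySelection:
    def test_ranked_ascending_by_aic(self, small_sim):
        ranked = select_frequency_model(
            small_sim["codon_aln"], small_sim["tree"], seed=0,
            estimate_branch_lengths=False, n_restarts=1,
        )
        aics = [f.aic for f in ranked]
        assert aics == sorted(aics)
        assert len(ranked) == 4

    def test_needs_two_schemes(self, small_sim):
        with pytest.raises(ModelSpecError):
            select_frequency_model(
                small_sim["codon_aln"], small_sim["tree"], schemes=["CF0"], seed=0
            )
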