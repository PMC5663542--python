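import math

import numpy as np
import pytest

from icinma.data import ContrastObservation, EvidenceNetwork, NetworkError, Treatment, TrialArm
from icinma.model import (
    McmcConfig,
    ModelSpec,
    PosteriorDraws,
    build_design,
    compute_dic,
    league_table,
    log_posterior,
    sample_posterior,
)

from conftest import QUICK, two_node_network


def triangle_network():
    t = {x: Treatment(x, x) for x in ("A", "B", "C")}
    arms = [
        TrialArm("t1", "A", 50), TrialArm("t1", "B", 50),
        TrialArm("t2", "B", 50), TrialArm("t2", "C", 50),
        TrialArm("t3", "A", 50), TrialArm("t3", "C", 50),
    ]
    contrasts = [
        ContrastObservation("t1", "A", "B", "PFS", -0.4, 0.2),
        ContrastObservation("t2", "B", "C", "PFS", -0.3, 0.2),
        ContrastObservation("t3", "A", "C", "PFS", -0.6, 0.2),
    ]
    return EvidenceNetwork(t, arms, contrasts).validate()


class TestBuildDesign:
    def test_melanoma_pfs_parameter_count(self, melanoma_net):
        design = build_design(melanoma_net, ModelSpec())
        assert len(design.nodes) == 10  # incl. the gp100 auxiliary
        assert len(design.basic) == 9
        assert design.nodes[0] == "CHE"
        assert "GP100" in design.basic
        assert len(design.reportable) == 9  # CHE + 8 others, GP100 excluded

    def test_two_node_design(self):
        design = build_design(two_node_network(), ModelSpec(reference="A"))
        assert design.basic == ["B"]
        assert list(design.consistency_map.values()) == ["d[B] - d[A]"]

    def test_triangle_maps_offbaseline_contrast(self):
        design = build_design(triangle_network(), ModelSpec(reference="A"))
        assert design.consistency_map[("t3", "A", "C")] == "d[C] - d[A]"
        assert design.consistency_map[("t2", "B", "C")] == "d[C] - d[B]"
        # design row of t2: +1 on C, -1 on B
        row = design.X[1]
        b, c = design.basic.index("B"), design.basic.index("C")
        assert row[c] == 1.0 and row[b] == -1.0

    def test_disconnected_network_rejected(self):
        t = {x: Treatment(x, x) for x in ("A", "B", "C", "D")}
        arms = [
            TrialArm("t1", "A", 10), TrialArm("t1", "B", 10),
            TrialArm("t2", "C", 10), TrialArm("t2", "D", 10),
        ]
        contrasts = [
            ContrastObservation("t1", "A", "B", "PFS", 0.0, 0.5),
            ContrastObservation("t2", "C", "D", "PFS", 0.0, 0.5),
        ]
        net = EvidenceNetwork(t, arms, contrasts).validate()
        with pytest.raises(NetworkError, match="components"):
            build_design(net, ModelSpec(reference="A"))


class TestLogPosterior:
    def test_single_contrast_closed_form(self):
        net = two_node_network(y=0.0, se=1.0)
        spec = ModelSpec(reference="A", prior_sd_d=15.0)
        lp0 = log_posterior(np.array([0.0]), net, spec)
        # likelihood fully normalized, N(0;0,1) at its mode; the vague prior
        # enters as an unnormalized kernel, zero at d = 0
        assert lp0 == pytest.approx(-0.5 * math.log(2 * math.pi), abs=1e-9)
        # moving d by 1 unit changes the likelihood kernel by -0.5 plus prior
        lp1 = log_posterior(np.array([1.0]), net, spec)
        assert lp0 - lp1 == pytest.approx(0.5 + 0.5 / 15.0**2, abs=1e-9)

    def test_random_model_tau_to_zero_matches_fixed_likelihood(self):
        net = triangle_network()
        spec_f = ModelSpec(reference="A", effect_model="fixed")
        spec_r = ModelSpec(reference="A", effect_model="random")
        design_f = build_design(net, spec_f)
        design_r = build_design(net, spec_r)
        from icinma.model import _Model

        d = np.array([-0.4, -0.65])
        m_f = _Model(design_f)
        ll_fixed = m_f.loglik(d[None, :])[0]
        # random state with deltas pinned at the consistency values
        delta = design_r.X @ d
        state = np.concatenate([d, delta, [1e-6]])
        m_r = _Model(design_r)
        ll_random = m_r.loglik(state[None, :])[0]
        assert ll_random == pytest.approx(ll_fixed, abs=1e-9)

    def test_tau_outside_prior_support_is_minus_inf(self):
        net = triangle_network()
        spec = ModelSpec(reference="A", effect_model="random", prior_tau_upper=2.0)
        design = build_design(net, spec)
        state = np.zeros(design.n_params)
        state[-1] = 2.5
        assert log_posterior(state, net, spec) == -np.inf
        state[-1] = -0.1
        assert log_posterior(state, net, spec) == -np.inf


class TestSamplePosterior:
    def test_two_node_conjugate_oracle(self):
        # with a vague prior the posterior of d is ~ N(y, se^2)
        y, se = math.log(0.5), 0.2
        net = two_node_network(y=y, se=se)
        spec = ModelSpec(reference="A")
        draws, diag = sample_posterior(
            net, spec, McmcConfig(seed=11, n_chains=2, burn_in=2000, keep=2000, thin=5)
        )
        x = draws.draws_of("d[B]")
        assert np.median(x) == pytest.approx(y, abs=0.01)
        assert x.std() == pytest.approx(se, rel=0.1)
        assert diag.converged

    def test_same_seed_reproduces_draws(self):
        net = two_node_network()
        spec = ModelSpec(reference="A")
        cfg = McmcConfig(seed=5, **QUICK)
        d1, _ = sample_posterior(net, spec, cfg)
        d2, _ = sample_posterior(net, spec, cfg)
        assert np.array_equal(d1.samples, d2.samples)

    def test_paper_schedule_fit_converges(self, paper_fixed_fit):
        _, diag = paper_fixed_fit
        assert diag.max_psrf < 1.05
        assert diag.converged


class TestDic:
    def test_degenerate_posterior_has_zero_pd(self, melanoma_net):
        spec = ModelSpec()
        design = build_design(melanoma_net, spec)
        theta = np.tile(0.1 * np.arange(design.n_params), (100, 2, 1))
        draws = PosteriorDraws(
            samples=theta,
            param_names=design.param_names,
            design=design,
            config=McmcConfig(seed=0, n_chains=2, burn_in=1, keep=500, thin=1),
        )
        diag = compute_dic(draws, melanoma_net, spec)
        assert diag.pd == pytest.approx(0.0, abs=1e-9)
        assert diag.dic == pytest.approx(diag.dbar, abs=1e-9)

    def test_random_model_has_more_effective_parameters(self, melanoma_net):
        cfg = McmcConfig(seed=2, **QUICK)
        _, diag_f = sample_posterior(melanoma_net, ModelSpec(), cfg)
        _, diag_r = sample_posterior(
            melanoma_net, ModelSpec(effect_model="random"), cfg
        )
        assert diag_r.pd > diag_f.pd

    def test_dic_parts_are_consistent(self, paper_fixed_fit):
        _, diag = paper_fixed_fit
        assert diag.dic == pytest.approx(diag.dbar + diag.pd, abs=1e-9)


class TestLeagueTable:
    def test_diagonal_and_antisymmetry(self, paper_fixed_fit):
        draws, _ = paper_fixed_fit
        lt = league_table(draws)
        for a in lt.treatments:
            assert lt.entry(a, a) == (1.0, 1.0, 1.0)
            for b in lt.treatments:
                if a == b:
                    continue
                m_ab, lo_ab, hi_ab = lt.entry(a, b)
                m_ba, lo_ba, hi_ba = lt.entry(b, a)
                assert m_ab * m_ba == pytest.approx(1.0, rel=1e-12)
                assert lo_ab * hi_ba == pytest.approx(1.0, rel=1e-12)
                assert hi_ab * lo_ba == pytest.approx(1.0, rel=1e-12)

    def test_consistency_identity_is_exact_drawwise(self, paper_fixed_fit):
        draws, _ = paper_fixed_fit
        names, mat = draws.basic_draws()
        a, b, c = (names.index(t) for t in ("IPI", "NIV", "PEM"))
        d_ab = mat[:, b] - mat[:, a]
        d_bc = mat[:, c] - mat[:, b]
        d_ac = mat[:, c] - mat[:, a]
        assert np.max(np.abs(d_ab + d_bc - d_ac)) < 1e-12

    def test_median_multiplicativity_approximate(self, paper_fixed_fit):
        draws, _ = paper_fixed_fit
        lt = league_table(draws)
        m_ab = lt.entry("NIV", "IPI")[0]
        m_bc = lt.entry("PEM", "NIV")[0]
        m_ac = lt.entry("PEM", "IPI")[0]
        assert m_ab * m_bc == pytest.approx(m_ac, rel=0.02)

    def test_aux_node_excluded_by_default(self, paper_fixed_fit):
        draws, _ = paper_fixed_fit
        lt = league_table(draws)
        assert "GP100" not in lt.treatments
        full = league_table(draws, include=draws.design.nodes)
        assert "GP100" in full.treatments

    def test_prior_dominance_vanishes(self, melanoma_net):
        # widening the vague prior tenfold leaves the medians unchanged
        cfg = McmcConfig(seed=8, n_chains=2, burn_in=3000, keep=5000, thin=10)
        d1, _ = sample_posterior(melanoma_net, ModelSpec(prior_sd_d=15.0), cfg)
        d2, _ = sample_posterior(melanoma_net, ModelSpec(prior_sd_d=150.0), cfg)
        lt1, lt2 = league_table(d1), league_table(d2)
        for a in lt1.treatments:
            for b in lt1.treatments:
                if a == b:
                    continue
                delta = abs(
                    math.log(lt1.entry(a, b)[0]) - math.log(lt2.entry(a, b)[0])
                )
                assert delta < 0.01
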