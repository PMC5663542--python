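import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from icinma.data import (
    ContrastObservation,
    EvidenceNetwork,
    NetworkError,
    RiskFlags,
    Treatment,
    TrialArm,
    filter_low_risk,
    load_trial_table,
    merge_dose_arms,
    resolve_auxiliary_nodes,
    se_from_ci,
    write_trial_table,
)
from icinma.datasets import (
    load_melanoma_network,
    load_melanoma_risk_flags,
    trial_table_path,
)

Z95 = norm.ppf(0.975)


class TestSeFromCI:
    @pytest.mark.parametrize(
        "lo, hi, expected",
        [
            (0.45, 0.73, 0.1235),  # pembrolizumab 2 mg/kg arm
            (0.31, 0.57, 0.1553),  # ipilimumab+nivolumab arm
            (0.43, 0.76, 0.1453),  # nivolumab arm
        ],
    )
    def test_reported_ci_widths(self, lo, hi, expected):
        assert se_from_ci(lo, hi) == pytest.approx(expected, abs=2e-4)

    def test_unit_se_construction(self):
        # upper = lower * e^(2z) makes the log-width exactly 2z, so se = 1
        for x in (0.01, 0.7, 3.0):
            assert se_from_ci(x, x * math.exp(2 * Z95)) == pytest.approx(1.0)

    @given(
        lo=st.floats(0.01, 10.0),
        width=st.floats(1.01, 20.0),
        k=st.floats(1e-3, 1e3),
    )
    @settings(max_examples=100, deadline=None)
    def test_scale_invariance(self, lo, width, k):
        hi = lo * width
        assert se_from_ci(k * lo, k * hi) == pytest.approx(
            se_from_ci(lo, hi), rel=1e-9
        )

    def test_coverage_level_uses_normal_quantile(self):
        # halving coverage widens se according to the quantile ratio
        ratio = se_from_ci(0.5, 2.0, level=0.5) / se_from_ci(0.5, 2.0, level=0.95)
        assert ratio == pytest.approx(Z95 / norm.ppf(0.75))

    @pytest.mark.parametrize("lo, hi", [(0.5, 0.5), (0.7, 0.4), (-1.0, 2.0), (0.0, 1.0)])
    def test_rejects_bad_bounds(self, lo, hi):
        with pytest.raises(ValueError):
            se_from_ci(lo, hi)


class TestLoadTrialTable:
    def test_melanoma_fixture_shape(self):
        net = load_trial_table(trial_table_path())
        assert len(net.trial_ids) == 12
        # ten trials report usable PFS hazard ratios
        trials_with_hr = {c.trial_id for c in net.contrasts_for("PFS")}
        assert len(trials_with_hr) == 10
        assert {"hersh2011", "weber2009"}.isdisjoint(trials_with_hr)
        # the PFS comparison graph has 10 nodes incl. the gp100 auxiliary
        assert len(net.nodes_for("PFS")) == 10
        assert "GP100" in net.nodes_for("PFS")
        assert "IPI_BUD" not in net.nodes_for("PFS")
        assert len(net.reportable_ids()) == 10
        assert len(net.contrasts_for("PFS")) == 14  # raw, before dose pooling

    def test_ci_roundtrip_reconstructs_printed_bounds(self):
        # exp(y -/+ z*se) reproduces every transcribed CI to 3 decimals
        import pandas as pd

        raw = pd.read_csv(trial_table_path(), dtype=str, comment="#")
        printed = {}
        for _, row in raw.iterrows():
            hr = str(row["hr"]).strip()
            if hr not in ("ref", "nan", ""):
                printed[(row["trial_id"], row["treatment"], row["dose_label"])] = (
                    float(row["ci_low"]),
                    float(row["ci_high"]),
                )
        net = load_trial_table(trial_table_path())
        assert printed
        for c in net.contrasts:
            lo, hi = printed[(c.trial_id, c.comparator, c.dose_label)]
            # centre on the CI's geometric midpoint: the printed point HR is
            # rounded to 2 decimals and need not sit exactly mid-interval
            mid = math.log(math.sqrt(lo * hi))
            assert math.exp(mid - Z95 * c.se) == pytest.approx(lo, abs=5e-4)
            assert math.exp(mid + Z95 * c.se) == pytest.approx(hi, abs=5e-4)
            # the stored point estimate sits near mid-interval (the source
            # prints rounded values; a few rows are mildly asymmetric)
            assert math.exp(c.y) == pytest.approx(math.exp(mid), abs=0.03)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("trial_id,treatment,n,hr,ci_low,ci_high\n")
        with pytest.raises(NetworkError, match="no trials"):
            load_trial_table(p)

    def test_minimal_two_arm_trial(self, tmp_path):
        p = tmp_path / "mini.csv"
        p.write_text(
            "trial_id,treatment,n,hr,ci_low,ci_high\n"
            "t1,NIV,50,0.5,0.3,0.8\n"
            "t1,CHE,50,ref,,\n"
        )
        net = load_trial_table(p)
        assert len(net.trial_ids) == 1
        assert len(net.nodes_for("PFS")) == 2
        assert len(net.contrasts) == 1
        assert net.contrasts[0].y == pytest.approx(math.log(0.5))

    def test_malformed_ci_names_row(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(
            "trial_id,treatment,n,hr,ci_low,ci_high\n"
            "t1,NIV,50,0.5,0.9,0.8\n"
            "t1,CHE,50,ref,,\n"
        )
        with pytest.raises(NetworkError, match="row 2"):
            load_trial_table(p)

    def test_unknown_treatment_code(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(
            "trial_id,treatment,n,hr,ci_low,ci_high\n"
            "t1,XYZ,50,0.5,0.3,0.8\n"
        )
        with pytest.raises(NetworkError, match="XYZ"):
            load_trial_table(p)

    def test_duplicate_contrast_rejected(self, tmp_path):
        p = tmp_path / "dup.csv"
        p.write_text(
            "trial_id,treatment,n,hr,ci_low,ci_high\n"
            "t1,NIV,50,0.5,0.3,0.8\n"
            "t1,NIV,50,0.5,0.3,0.8\n"
            "t1,CHE,50,ref,,\n"
        )
        with pytest.raises(NetworkError, match="duplicate"):
            load_trial_table(p)

    def test_serialization_roundtrip_lossless(self, tmp_path):
        net = load_melanoma_network()
        path = tmp_path / "net.yaml"
        net.save(path)
        again = EvidenceNetwork.load(path)
        assert again.to_dict() == net.to_dict()

    def test_table_write_read_roundtrip(self, tmp_path):
        net = load_melanoma_network()
        path = tmp_path / "table.csv"
        write_trial_table(net, path)
        again = load_trial_table(path)
        assert sorted(again.trial_ids) == sorted(net.trial_ids)
        by_key = {
            (c.trial_id, c.comparator): c for c in again.contrasts_for("PFS")
        }
        for c in net.contrasts_for("PFS"):
            c2 = by_key[(c.trial_id, c.comparator)]
            assert c2.y == pytest.approx(c.y, abs=1e-9)
            assert c2.se == pytest.approx(c.se, abs=1e-9)


class TestMergeDoseArms:
    def test_pembrolizumab_doses_pool_to_single_contrast(self):
        net = load_trial_table(trial_table_path())
        merged = merge_dose_arms(net, policy="pool")
        ribas = [c for c in merged.contrasts if c.trial_id == "ribas2015"]
        assert len(ribas) == 1
        assert math.exp(ribas[0].y) == pytest.approx(0.53, abs=0.005)
        arm = [
            a
            for a in merged.arms
            if a.trial_id == "ribas2015" and a.treatment_id == "PEM"
        ]
        assert len(arm) == 1 and arm[0].n_enrolled == 180 + 181
        assert "pooled" in arm[0].dose_label

    def test_equal_contrasts_pool_to_se_over_sqrt2(self):
        t = {x: Treatment(x, x) for x in ("A", "B")}
        arms = [
            TrialArm("t1", "A", 50),
            TrialArm("t1", "B", 50, dose_label="low"),
            TrialArm("t1", "B", 50, dose_label="high"),
        ]
        contrasts = [
            ContrastObservation("t1", "A", "B", "PFS", -0.5, 0.2, dose_label="low"),
            ContrastObservation("t1", "A", "B", "PFS", -0.5, 0.2, dose_label="high"),
        ]
        net = EvidenceNetwork(t, arms, contrasts).validate()
        merged = merge_dose_arms(net, "pool")
        (c,) = merged.contrasts
        assert c.y == pytest.approx(-0.5)
        assert c.se == pytest.approx(0.2 / math.sqrt(2))

    def test_pooled_se_never_exceeds_smaller_input(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            y1, y2 = rng.normal(size=2)
            s1, s2 = rng.uniform(0.05, 1.0, size=2)
            t = {x: Treatment(x, x) for x in ("A", "B")}
            arms = [
                TrialArm("t1", "A", 50),
                TrialArm("t1", "B", 50, dose_label="d1"),
                TrialArm("t1", "B", 50, dose_label="d2"),
            ]
            contrasts = [
                ContrastObservation("t1", "A", "B", "PFS", y1, s1, "d1"),
                ContrastObservation("t1", "A", "B", "PFS", y2, s2, "d2"),
            ]
            merged = merge_dose_arms(
                EvidenceNetwork(t, arms, contrasts).validate(), "pool"
            )
            assert merged.contrasts[0].se <= min(s1, s2) + 1e-12

    def test_keep_first_retains_first_listed_dose(self):
        net = load_trial_table(trial_table_path())
        kept = merge_dose_arms(net, policy="keep_first")
        ribas = [c for c in kept.contrasts if c.trial_id == "ribas2015"]
        assert len(ribas) == 1
        assert math.exp(ribas[0].y) == pytest.approx(0.57, abs=1e-9)

    def test_keep_all_is_identity(self):
        net = load_trial_table(trial_table_path())
        assert merge_dose_arms(net, "keep_all_as_distinct") is net


class TestResolveAuxiliary:
    def test_rebase_independent_differences_hodi_contrasts(self):
        net = load_melanoma_network(aux_policy="rebase_independent")
        hodi = [c for c in net.contrasts if c.trial_id == "hodi2010"]
        assert len(hodi) == 1
        (c,) = hodi
        assert c.baseline == "IPI" and c.comparator == "IPI_GP100"
        assert math.exp(c.y) == pytest.approx(0.81 / 0.64, abs=1e-9)
        se1 = se_from_ci(0.74, 0.92)
        se2 = se_from_ci(0.56, 0.78)
        assert c.se == pytest.approx(math.hypot(se1, se2))
        assert "GP100" not in net.treatments

    def test_network_without_auxiliaries_unchanged(self):
        t = {x: Treatment(x, x) for x in ("A", "B")}
        arms = [TrialArm("t1", "A", 10), TrialArm("t1", "B", 10)]
        contrasts = [ContrastObservation("t1", "A", "B", "PFS", 0.1, 0.2)]
        net = EvidenceNetwork(t, arms, contrasts).validate()
        assert resolve_auxiliary_nodes(net, "rebase_independent") is net

    def test_aux_node_keeps_gp100_nonreportable(self):
        net = load_melanoma_network(aux_policy="aux_node")
        assert len(net.treatments) == 11
        assert len(net.reportable_ids()) == 10
        assert not net.treatments["GP100"].reportable


class TestFilterLowRisk:
    def test_all_low_risk_is_identity_in_content(self, tmp_path):
        net = load_melanoma_network()
        flags = RiskFlags({t: True for t in net.trial_ids})
        out = filter_low_risk(net, flags)
        assert sorted(out.trial_ids) == sorted(net.trial_ids)

    def test_masking_bias_flags_leave_nine_trials(self):
        net = load_melanoma_network()
        out = filter_low_risk(net, load_melanoma_risk_flags())
        assert len(out.trial_ids) == 9

    def test_disconnection_is_reported_not_fitted(self):
        net = load_melanoma_network()
        # keep only two trials whose comparisons share no treatment
        flags = {t: t in ("weber2015", "robert2015a") for t in net.trial_ids}
        with pytest.raises(NetworkError, match="disconnected"):
            filter_low_risk(net, RiskFlags(flags))

    def test_missing_coverage_rejected(self):
        net = load_melanoma_network()
        with pytest.raises(NetworkError, match="missing"):
            filter_low_risk(net, RiskFlags({"weber2015": True}))
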