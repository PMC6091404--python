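"""Experiment generator: design invariants, sampling, behavior, I/O."""

import io

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

import blastdm as b
from blastdm.ddm import DDMParams
from blastdm.synthetic import _cue_counts


class TestConfig:
    def test_defaults_valid(self):
        b.ExperimentConfig().validate()

    @pytest.mark.parametrize("kw", [
        {"trials_per_block": 102}, {"cue_validity": 1.2},
        {"cue_fraction": 0.0}, {"deadline_speed_s": -1.0},
    ])
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            b.ExperimentConfig(**kw).validate()


class TestDesign:
    def test_block_structure(self):
        d = b.build_design(b.ExperimentConfig(rng_seed=4))
        assert len(d) == 600
        per_cond = d.groupby("condition")["block_index"].nunique()
        assert per_cond.to_dict() == {"accuracy": 2, "bias": 2, "speed": 2}
        # positions 4-6 repeat the order of positions 1-3
        order = list(d.groupby("block_index")["condition"].first().sort_index())
        assert order[3:6] == order[0:3]

    def test_cell_balance_every_block(self):
        d = b.build_design(b.ExperimentConfig(rng_seed=5))
        counts = d.groupby(["block_index", "stimulus", "difficulty"]).size()
        assert set(counts) == {25}

    def test_cue_only_in_bias_blocks(self):
        d = b.build_design(b.ExperimentConfig(rng_seed=6))
        assert (d.loc[d.condition != "bias", "cue"] == "none").all()
        assert (d.loc[d.condition == "bias", "cue"] != "none").all()

    def test_cue_fraction_and_validity(self):
        d = b.build_design(b.ExperimentConfig(rng_seed=7))
        bias = d[d.condition == "bias"]
        cued = bias[bias.cue == "present"]
        assert len(cued) == 100  # exactly half the 200 bias trials
        # two-block total is exactly 65% blast (33 + 32 of 100)
        assert (cued.stimulus == "blast").sum() == 65

    def test_cued_blast_fraction_over_many_designs(self):
        # >= 10,000 cued trials pooled across participants' designs
        rng = np.random.default_rng(8)
        cfg = b.ExperimentConfig()
        frac = []
        for _ in range(100):
            d = b.build_design(cfg, rng)
            cued = d[(d.condition == "bias") & (d.cue == "present")]
            frac.append((cued.stimulus == "blast").to_numpy())
        x = np.concatenate(frac)
        se = np.sqrt(0.65 * 0.35 / len(x))
        assert len(x) >= 10000
        assert abs(x.mean() - 0.65) < 3 * se + 0.01

    def test_cumulative_rounding_rounds_toward_cue_first(self):
        cfg = b.ExperimentConfig()
        assert _cue_counts(cfg, 0) == (50, 33)
        assert _cue_counts(cfg, 1) == (50, 32)

    def test_determinism(self):
        cfg = b.ExperimentConfig(rng_seed=9)
        pd.testing.assert_frame_equal(b.build_design(cfg), b.build_design(cfg))


class TestSampleParticipants:
    def test_zero_scale_degenerates_to_locations(self, novice_hyper):
        hyper = b.CohortHyper("novice", {
            c: {k: (loc, 0.0) for k, (loc, s) in blk.items()}
            for c, blk in novice_hyper.per_condition.items()})
        profs = b.sample_participants(hyper, 3, seed=1)
        for p in profs:
            assert p.ddm["accuracy"].a == pytest.approx(0.14)
            assert p.ddm["accuracy"].z == pytest.approx(0.07)

    def test_determinism(self, novice_hyper):
        p1 = b.sample_participants(novice_hyper, 5, seed=2)
        p2 = b.sample_participants(novice_hyper, 5, seed=2)
        for a, c in zip(p1, p2):
            assert a.ddm["speed"] == c.ddm["speed"]

    def test_threshold_mean_matches_truncated_normal_moment(self):
        hyper = b.CohortHyper("novice", {"accuracy": {
            "d_be": (0.18, 0.0), "d_bh": (0.1, 0.0), "d_nbe": (-0.2, 0.0),
            "d_nbh": (-0.07, 0.0), "s_d": (0.08, 0.0), "a": (0.13, 0.02),
            "z_rel": (0.5, 0.0), "s_z": (0.02, 0.0), "t_nd": (0.35, 0.0)}})
        profs = b.sample_participants(hyper, 10000, seed=3)
        a_vals = np.array([p.ddm["accuracy"].a for p in profs])
        # oracle: truncated-normal mean by numeric integration
        lo, hi = 1e-4, np.inf
        f = lambda x: x * stats.norm.pdf(x, 0.13, 0.02)
        mass = 1 - stats.norm.cdf(lo, 0.13, 0.02)
        expect = integrate.quad(f, lo, 1.0)[0] / mass
        se = a_vals.std() / 100
        assert a_vals.mean() == pytest.approx(expect, abs=3 * se)

    def test_warns_when_location_outside_support(self):
        hyper = b.CohortHyper("novice", {"accuracy": {
            "d_be": (0.18, 0.0), "d_bh": (0.1, 0.0), "d_nbe": (-0.2, 0.0),
            "d_nbh": (-0.07, 0.0), "s_d": (0.08, 0.0), "a": (-0.1, 0.02),
            "z_rel": (0.5, 0.0), "s_z": (0.02, 0.0), "t_nd": (0.35, 0.0)}})
        with pytest.warns(UserWarning, match="support"):
            b.sample_participants(hyper, 2, seed=4)


def _uniform_profiles(n=1, **overrides):
    base = dict(d_be=0.18, d_bh=0.10, d_nbe=-0.22, d_nbh=-0.07,
                s_d=0.05, a=0.12, z=0.06, s_z=0.02, t_nd=0.3)
    base.update(overrides)
    bias = dict(base, z_cue=base.get("z_cue", base["z"]))
    return [b.ParticipantProfile(
        participant_id=f"n{i:03d}", population="novice",
        ddm={"accuracy": DDMParams(**base), "speed": DDMParams(**base),
             "bias": DDMParams(**bias)})
        for i in range(n)]


class TestSimulateDataset:
    def test_huge_drift_gives_ceiling_accuracy_no_timeouts(self):
        profs = _uniform_profiles(d_be=50.0, d_bh=50.0, d_nbe=-50.0,
                                  d_nbh=-50.0, s_d=0.0)
        tr = b.simulate_dataset(profs, b.ExperimentConfig(rng_seed=1), seed=2)
        assert (tr.choice == "timeout").sum() == 0
        assert (tr.choice == tr.stimulus).mean() > 0.999

    def test_zero_drift_is_unbiased(self):
        profs = _uniform_profiles(d_be=0.0, d_bh=0.0, d_nbe=0.0, d_nbh=0.0,
                                  s_d=0.0)
        cfg = b.ExperimentConfig(rng_seed=2)
        tr = pd.concat([b.simulate_dataset(profs, cfg, seed=s)
                        for s in range(15)])
        acc = tr[(tr.condition == "accuracy") & (tr.choice != "timeout")]
        p = (acc.choice == "blast").mean()
        assert p == pytest.approx(0.5, abs=3 * np.sqrt(0.25 / len(acc)))

    def test_cue_raises_blast_rate(self):
        profs = _uniform_profiles(z_cue=0.085)
        cfg = b.ExperimentConfig(rng_seed=3)
        tr = pd.concat([b.simulate_dataset(profs, cfg, seed=100 + s)
                        for s in range(60)])
        biasb = tr[(tr.condition == "bias") & (tr.choice != "timeout")]
        cued = biasb[biasb.cue == "present"]
        uncued = biasb[biasb.cue == "absent"]
        assert len(cued) >= 5000
        n_c = (cued.choice == "blast").sum()
        n_u = (uncued.choice == "blast").sum()
        res = stats.binomtest(
            n_c, len(cued), p=(uncued.choice == "blast").mean(),
            alternative="greater")
        assert res.pvalue < 1e-6

    def test_deadline_consistency(self, small_cohort_trials):
        tr = small_cohort_trials
        for cond, dl in (("speed", 1.0), ("accuracy", 5.0), ("bias", 5.0)):
            sub = tr[(tr.condition == cond) & (tr.choice != "timeout")]
            assert (sub.rt_s <= dl).all()
            t_out = tr[(tr.condition == cond) & (tr.choice == "timeout")]
            assert ((t_out.rt_s > dl) | t_out.rt_s.isna()).all()

    def test_seed_determinism_byte_identical(self, novice_hyper):
        profs = b.sample_participants(novice_hyper, 2, seed=5)
        cfg = b.ExperimentConfig(rng_seed=5)
        t1 = b.simulate_dataset(profs, cfg, seed=6)
        t2 = b.simulate_dataset(profs, cfg, seed=6)
        s1, s2 = io.StringIO(), io.StringIO()
        b.write_trials(t1, s1)
        b.write_trials(t2, s2)
        assert s1.getvalue() == s2.getvalue()

    def test_sdt_mode_rates(self):
        profs = b.sample_sdt_participants("experienced", 5, seed=7)
        cfg = b.ExperimentConfig(rng_seed=7)
        tr = b.simulate_dataset(profs, cfg, model="sdt", seed=8)
        assert tr.rt_s.isna().all()
        acc = (tr.choice == tr.stimulus).mean()
        assert 0.75 < acc < 0.95  # d' around 2.5

    def test_missing_condition_params_named_error(self):
        prof = _uniform_profiles(1)[0]
        del prof.ddm["speed"]
        with pytest.raises(ValueError, match="speed"):
            b.simulate_dataset([prof], b.ExperimentConfig(), seed=1)


class TestTrialIO:
    def test_roundtrip(self, small_cohort_trials):
        buf = io.StringIO()
        b.write_trials(small_cohort_trials, buf)
        buf.seek(0)
        back = b.read_trials(buf)
        pd.testing.assert_frame_equal(
            small_cohort_trials.reset_index(drop=True), back)

    def test_case_mismatch_names_row(self, small_cohort_trials):
        buf = io.StringIO()
        bad = small_cohort_trials.copy()
        bad.loc[bad.index[7], "choice"] = "Blast"
        b.write_trials(bad, buf)
        buf.seek(0)
        with pytest.raises(ValueError, match="row 7"):
            b.read_trials(buf)

    def test_negative_rt_rejected(self, small_cohort_trials):
        buf = io.StringIO()
        bad = small_cohort_trials.copy()
        bad.loc[bad.index[3], "rt_s"] = -0.2
        b.write_trials(bad, buf)
        buf.seek(0)
        with pytest.raises(ValueError, match="row 3"):
            b.read_trials(buf)

    def test_missing_column(self):
        buf = io.StringIO("participant_id,choice\nx,blast\n")
        with pytest.raises(ValueError, match="missing column"):
            b.read_trials(buf)

    def test_header_only_is_empty_table(self):
        buf = io.StringIO(",".join(b.synthetic.TRIAL_COLUMNS) + "\n")
        out = b.read_trials(buf)
        assert len(out) == 0
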