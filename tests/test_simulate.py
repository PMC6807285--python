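import numpy as np
import pytest

from aacsim.config import ApproachPolicy, CohortSpec, ConfigurationError, \
    ExposurePolicy, PatientSpec, TaskConfig
from aacsim.extract import (reconstruct_decisions,
                            token_availability_durations)
from aacsim.simulate import (balanced_threat_sequence, simulate_cohort,
                             simulate_memory_ratings, simulate_task1_block,
                             simulate_task1_epoch, simulate_task2_block,
                             simulate_task2_epoch)

NEVER_APPROACH = ApproachPolicy(approach_intercept=-50.0)
ALWAYS_APPROACH = ApproachPolicy(approach_intercept=50.0,
                                 approach_coef_threat=0.0,
                                 approach_coef_loss=0.0,
                                 al_base=200.0, latency_noise_sd=0.0)


def kinds(events):
    return [ev.kind for ev in events]


class TestTask1Epoch:
    def test_never_approach_agent_stays_safe(self, config):
        rng = np.random.default_rng(0)
        for _ in range(20):
            events = simulate_task1_epoch(config, NEVER_APPROACH, "high", rng)
            ks = kinds(events)
            assert "leave_safe" not in ks
            assert "caught" not in ks
            assert "token_collected" not in ks
            assert ks.count("token_on") == 6

    def test_catch_probability_matches_per_step_survival_product(self, config):
        """Agent held outside for 1000 ms at hazard 0.3/100 ms: the catch
        probability per excursion is 1 - 0.7**10 (closed form)."""
        policy = ALWAYS_APPROACH.replace(rl_base=1000.0, rl_coef_threat=0.0,
                                         rl_coef_loss=0.0)
        expected = 1.0 - 0.7 ** 10
        rng = np.random.default_rng(42)
        excursions = catches = 0
        for _ in range(900):
            for ev in simulate_task1_epoch(config, policy, "high", rng):
                if ev.kind == "leave_safe":
                    excursions += 1
                elif ev.kind == "caught":
                    catches += 1
        p_hat = catches / excursions
        se = np.sqrt(expected * (1 - expected) / excursions)
        assert abs(p_hat - expected) < 3 * se

    def test_token_availability_mean(self, config):
        """Sampled availability durations average 1.25 s."""
        rng = np.random.default_rng(7)
        logs = []
        for i in range(1800):
            events = simulate_task1_epoch(config, NEVER_APPROACH, "low", rng)
            logs.append(type("L", (), {"events": events})())
        durs = token_availability_durations(logs)
        assert durs.size >= 10_000
        se = durs.std(ddof=1) / np.sqrt(durs.size)
        assert abs(durs.mean() - 1250.0) < 3 * se

    def test_inter_token_wait_mean(self, config):
        """Waits between token cycles average availability_mean + 500 ms."""
        rng = np.random.default_rng(11)
        waits = []
        for _ in range(800):
            events = simulate_task1_epoch(config, NEVER_APPROACH, "low", rng)
            offs = {ev.payload["token_index"]: ev.t for ev in events
                    if ev.kind == "token_off"}
            ons = {ev.payload["token_index"]: ev.t for ev in events
                   if ev.kind == "token_on"}
            for i in range(1, 6):
                waits.append(ons[i + 1] - offs[i])
        waits = np.asarray(waits)
        se = waits.std(ddof=1) / np.sqrt(waits.size)
        assert abs(waits.mean() - 1750.0) < 3 * se

    def test_catch_ends_collection_and_token_conservation(self, config):
        rng = np.random.default_rng(3)
        policy = ALWAYS_APPROACH.replace(rl_base=600.0)
        seen_catch = False
        for _ in range(150):
            events = simulate_task1_epoch(config, policy, "high", rng)
            collected = sum(ev.kind == "token_collected" for ev in events)
            end = events[-1]
            assert end.kind == "epoch_end"
            assert end.payload["collected"] == collected
            caught_t = [ev.t for ev in events if ev.kind == "caught"]
            if caught_t:
                seen_catch = True
                assert end.payload["retained"] == 0
                # no collections after the catch
                assert all(ev.t <= caught_t[0] for ev in events
                           if ev.kind == "token_collected")
                # a catch only happens outside the safe place
                outside = [ev.t for ev in events if ev.kind == "leave_safe"]
                assert outside and caught_t[0] >= outside[0]
            else:
                assert end.payload["retained"] == collected >= 0
        assert seen_catch

    def test_non_finite_policy_rejected(self, config):
        with pytest.raises(ConfigurationError):
            simulate_task1_epoch(config, NEVER_APPROACH, "extreme", 0)


class TestTask1Block:
    def test_default_block_shape(self, task1_block):
        assert len(task1_block.epoch_ids) == 45
        threats = [events[0].threat_level
                   for events in task1_block.epochs().values()]
        assert {t: threats.count(t) for t in set(threats)} == \
            {"low": 15, "med": 15, "high": 15}

    def test_three_epoch_block_has_one_per_level(self, control_policy):
        cfg = TaskConfig(epochs_per_block=3)
        log = simulate_task1_block(cfg, control_policy, 5)
        threats = sorted(ev.threat_level for ev in log.events
                         if ev.kind == "epoch_start")
        assert threats == ["high", "low", "med"]

    def test_indivisible_epoch_count_warns_and_nearly_balances(self):
        with pytest.warns(UserWarning, match="near-balanced"):
            seq = balanced_threat_sequence(44, np.random.default_rng(0))
        counts = sorted(seq.count(t) for t in ("low", "med", "high"))
        assert counts == [14, 15, 15]

    def test_same_seed_reproduces_identical_log(self, config, control_policy):
        a = simulate_task1_block(config, control_policy, 99)
        b = simulate_task1_block(config, control_policy, 99)
        assert [ev.to_json() for ev in a] == [ev.to_json() for ev in b]

    def test_events_time_ordered_within_epochs(self, task1_block):
        for events in task1_block.epochs().values():
            ts = [ev.t for ev in events]
            assert ts == sorted(ts)


class TestTask2:
    def test_attempts_capped_at_six(self, config):
        flood = ExposurePolicy(w=1.0, presses_per_epoch_mean=30.0)
        rng = np.random.default_rng(0)
        saw_cap = False
        for _ in range(60):
            events = simulate_task2_epoch(config, flood, "low", rng)
            n_up = sum(ev.kind == "key_up" for ev in events)
            assert n_up <= 6
            attempts = [ev.payload["attempt"] for ev in events
                        if ev.kind == "key_up"]
            assert attempts == list(range(1, n_up + 1))
            if n_up == 6:
                saw_cap = True
        assert saw_cap

    def test_exposure_success_fraction_matches_wakeup_probability(self, config):
        """Over many attempts at medium threat, about 20% succeed."""
        flood = ExposurePolicy(w=1.0, presses_per_epoch_mean=12.0)
        rng = np.random.default_rng(1)
        succ = attempts = 0
        while attempts < 10_500:
            for ev in simulate_task2_epoch(config, flood, "med", rng):
                if ev.kind == "expose_success":
                    succ += 1
                    attempts += 1
                elif ev.kind == "expose_fail":
                    attempts += 1
        p_hat = succ / attempts
        se = np.sqrt(0.2 * 0.8 / attempts)
        assert abs(p_hat - 0.2) < 3 * se

    def test_success_ends_epoch(self, config):
        rng = np.random.default_rng(2)
        for _ in range(50):
            events = simulate_task2_epoch(config, ExposurePolicy(
                w=1.0, presses_per_epoch_mean=10.0), "high", rng)
            succ = [ev.t for ev in events if ev.kind == "expose_success"]
            if succ:
                assert events[-1].kind == "epoch_end"
                assert events[-1].t == succ[0]

    def test_invalid_weight_rejected(self, config):
        with pytest.raises(ConfigurationError):
            ExposurePolicy(w=1.2)

    def test_block_shape_and_determinism(self, config):
        a = simulate_task2_block(config, ExposurePolicy(), 17)
        b = simulate_task2_block(config, ExposurePolicy(), 17)
        assert len(a.epoch_ids) == config.exposure_epochs_per_block
        assert [ev.to_json() for ev in a] == [ev.to_json() for ev in b]


class TestCohort:
    def test_controls_only(self, config):
        cfg = TaskConfig(epochs_per_block=6, n_blocks_task1=1,
                         exposure_epochs_per_block=6, n_blocks_task2=1)
        logs, manifest = simulate_cohort(CohortSpec(n_controls=3,
                                                    master_seed=5), cfg)
        assert set(manifest.group) == {"control"}
        assert manifest.subject_id.nunique() == 3

    def test_identical_master_seed_reproduces_cohort(self, config):
        cfg = TaskConfig(epochs_per_block=6, n_blocks_task1=1,
                         n_blocks_task2=1, exposure_epochs_per_block=6)
        spec = CohortSpec(n_controls=2, master_seed=9,
                          patients=(PatientSpec(label="P1"),))
        logs_a, man_a = simulate_cohort(spec, cfg)
        logs_b, man_b = simulate_cohort(spec, cfg)
        assert man_a.equals(man_b)
        assert all([e.to_json() for e in la] == [e.to_json() for e in lb]
                   for la, lb in zip(logs_a, logs_b))

    def test_zero_loss_slope_patient_recovered_downstream(self, config):
        """A lesion agent with no loss sensitivity yields a near-zero
        fitted loss slope after extraction and per-subject summary.

        The cumulative scoring rule makes each loss cell the survival
        probability of the per-token policy chain, so even a flat policy
        has a small structural slope: the closed-form oracle is the slope
        of ``p_threat**(loss+1)`` averaged over threat levels.
        """
        from aacsim.config import THREAT_CODES
        from aacsim.effects import subject_summary
        from aacsim.extract import condition_means
        import pandas as pd
        cfg = TaskConfig(n_blocks_task1=4)
        flat = ApproachPolicy(approach_coef_loss=0.0)
        cells = np.mean([[flat.approach_probability(lv, 0) ** (l + 1)
                          for l in range(6)] for lv in THREAT_CODES], axis=0)
        oracle_slope = np.polyfit(np.arange(6), cells, 1)[0]

        spec = CohortSpec(
            n_controls=2, master_seed=21,
            patients=(PatientSpec(
                label="FLAT",
                approach_overrides={"approach_coef_loss": 0.0}),))
        logs, _ = simulate_cohort(spec, cfg, tasks=("task1",))
        dec = pd.concat([reconstruct_decisions(lg) for lg in logs
                         if lg.subject_id == "FLAT"], ignore_index=True)
        slope = subject_summary(condition_means(dec),
                                "loss_linear_coefficient").value.iloc[0]
        assert abs(slope) < 0.06
        assert slope == pytest.approx(oracle_slope, abs=0.03)


class TestMemoryRatings:
    def test_identity_when_unbiased(self):
        spec = CohortSpec(rating_slope=1.0, rating_bias=0.0,
                          rating_noise_sd=0.0)
        rates = {"low": 10.0, "med": 25.0, "high": 40.0}
        assert simulate_memory_ratings(rates, spec) == rates

    def test_paper_default_bias_arithmetic(self):
        """slope 0.99, bias 36.3, true rate 20 -> 56.1."""
        spec = CohortSpec(rating_slope=0.99, rating_bias=36.3,
                          rating_noise_sd=0.0)
        out = simulate_memory_ratings({"med": 20.0}, spec)
        assert out["med"] == pytest.approx(56.1)

    def test_clipping_at_scale_ends(self):
        spec = CohortSpec(rating_noise_sd=0.0)
        out = simulate_memory_ratings({"high": 100.0}, spec)
        assert out["high"] == 100.0
        with pytest.raises(ValueError):
            simulate_memory_ratings({"low": -5.0}, spec)
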