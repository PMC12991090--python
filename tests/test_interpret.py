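"""Perturbation engine: schedule, loss terms, clustering statistic, concordance."""

import numpy as np
import pytest

from rocit_lite import nn
from rocit_lite.features import FeatureSet
from rocit_lite.interpret import (
    ConcordanceTally,
    PerturbationConfig,
    PerturbationResult,
    best_by_read,
    cell_type_concordance,
    clustering_coefficient,
    perturb_batch,
    perturbation_loss,
    schedule,
    select_confident,
    summarize_perturbations,
)


class TestSchedule:
    CFG = PerturbationConfig(lambda_max=10.0)

    def test_start_endpoint(self):
        assert schedule(0, self.CFG) == (0.5, 0.0)
        assert schedule(self.CFG.t0, self.CFG) == (0.5, 0.0)

    def test_end_endpoint(self):
        eps, lam = schedule(self.CFG.warmup_steps, self.CFG)
        assert eps == pytest.approx(0.01) and lam == pytest.approx(10.0)
        eps, lam = schedule(self.CFG.warmup_steps + 100, self.CFG)
        assert eps == pytest.approx(0.01) and lam == pytest.approx(10.0)

    def test_midpoint_linear(self):
        t = self.CFG.t0 + (self.CFG.warmup_steps - self.CFG.t0) // 2
        eps, lam = schedule(t, self.CFG)
        assert eps == pytest.approx(0.255)
        assert lam == pytest.approx(5.0)

    def test_total_steps(self):
        assert self.CFG.n_steps == 1000


class TestLossTerms:
    def _inputs(self, delta, x, t, lam=10.0):
        cfg = PerturbationConfig(lambda_max=lam)
        x = np.asarray(x, np.float64)[None, :]
        delta = np.asarray(delta, np.float64)[None, :]
        n = x.shape[1]
        valid = np.ones((1, n))
        return cfg, x, delta, valid, np.full(1, float(n))

    def test_zero_delta_in_range_is_pure_class_bce(self):
        cfg, x, delta, valid, n_att = self._inputs([0.0, 0.0], [0.3, 0.7], t=0)
        logits = np.array([0.4])
        y = np.array([1.0])
        loss, dlogits, ddelta = perturbation_loss(logits, x, delta, y, 0, cfg, n_att, valid)
        expected = -np.log(1 / (1 + np.exp(-0.4)))
        assert loss == pytest.approx(expected)
        assert np.allclose(ddelta, 0.0)

    def test_clip_penalty_value(self):
        cfg, x, delta, valid, n_att = self._inputs([0.0, 0.0], [1.3, 0.5], t=0)
        loss, _, _ = perturbation_loss(np.array([0.0]), x, delta, np.array([1.0]), 0, cfg, n_att, valid)
        base = -np.log(0.5)
        assert loss == pytest.approx(base + cfg.gamma * 0.3 / 2)

    def test_l0_saturates_at_lambda_over_n(self):
        cfg, x, delta, valid, n_att = self._inputs([5.0, 0.0], [0.5, 0.5], t=2000, lam=10.0)
        t = cfg.n_steps  # schedule fully annealed: eps = 0.01, lam = 10
        loss, _, _ = perturbation_loss(np.array([0.0]), x, delta, np.array([1.0]), t, cfg, n_att, valid)
        base = -np.log(0.5)
        assert loss == pytest.approx(base + 10.0 / 2, rel=1e-4)

    def test_l0_inactive_before_t0(self):
        cfg, x, delta, valid, n_att = self._inputs([5.0, 0.0], [0.5, 0.5], t=0)
        loss, _, _ = perturbation_loss(np.array([0.0]), x, delta, np.array([1.0]), 0, cfg, n_att, valid)
        assert loss == pytest.approx(-np.log(0.5))


class TestSelectConfident:
    def test_mid_probability_reads_excluded(self, tiny_feature_sets):
        sets = tiny_feature_sets[:4]
        probs = np.array([0.1, 0.5, 0.85, 0.79])
        kept, kp = select_confident(sets, probs)
        assert [fs.read_id for fs in kept] == [sets[0].read_id, sets[2].read_id]
        assert kp.tolist() == [0.1, 0.85]


class TestClusteringCoefficient:
    def test_all_perturbed_is_exactly_zero(self):
        assert clustering_coefficient(np.ones(30, bool)) == 0.0

    def test_fewer_than_two_undefined(self):
        mask = np.zeros(30, bool)
        mask[4] = True
        assert clustering_coefficient(mask) is None

    def test_adjacent_pair_clustered(self):
        mask = np.zeros(100, bool)
        mask[50:52] = True
        c = clustering_coefficient(mask, n_perm=500, seed=0)
        assert c is not None and c > 0.5

    def test_spread_out_set_dispersed(self):
        mask = np.zeros(100, bool)
        mask[[0, 33, 66, 99]] = True
        c = clustering_coefficient(mask, n_perm=500, seed=0)
        assert c < 0.0  # evenly spaced: farther apart than random

    def test_random_sets_centred_at_zero(self):
        rng = np.random.default_rng(11)
        cs = []
        for _ in range(150):
            mask = np.zeros(120, bool)
            mask[rng.choice(120, 12, replace=False)] = True
            cs.append(clustering_coefficient(mask, n_perm=400, seed=int(rng.integers(2**31))))
        assert abs(np.mean(cs)) < 0.05


def fake_result(read_id, delta, p_before, p_after, lam=5.0):
    return PerturbationResult(
        read_id=read_id, delta=np.asarray(delta, float),
        p_before=p_before, p_after=p_after,
        success=bool((p_before <= 0.2 and p_after >= 0.8) or (p_before >= 0.8 and p_after <= 0.2)),
        lambda_max=lam,
    )


class TestResultBookkeeping:
    def test_threshold_defines_perturbed_mask(self):
        r = fake_result("a", [0.05, -0.3, 0.15, 0.0], 0.9, 0.1)
        assert r.perturbed_mask.tolist() == [False, True, True, False]
        assert r.n_perturbed == 2

    def test_direction(self):
        assert fake_result("a", [0.2], 0.9, 0.1).direction == "tumor_to_non_tumor"
        assert fake_result("a", [0.2], 0.1, 0.9).direction == "non_tumor_to_tumor"

    def test_best_by_read_prefers_sparser_conversion(self):
        a = fake_result("r", [0.3, 0.3, 0.3], 0.9, 0.1, lam=5.0)
        b = fake_result("r", [0.3, 0.0, 0.0], 0.9, 0.1, lam=15.0)
        c = fake_result("r", [0.3], 0.9, 0.5, lam=10.0)  # not successful
        best = best_by_read([a, b, c])
        assert best["r"].lambda_max == 15.0

    def test_summary_partitions_by_direction(self, tiny_feature_sets):
        sets = tiny_feature_sets[:2]
        n0, n1 = sets[0].n_cpg, sets[1].n_cpg
        res = [
            fake_result(sets[0].read_id, np.r_[0.3, 0.3, np.zeros(n0 - 2)], 0.9, 0.1),
            fake_result(sets[1].read_id, np.r_[-0.3, np.zeros(n1 - 1)], 0.1, 0.9),
        ]
        summ = summarize_perturbations(res, sets, n_perm=100)
        assert summ.n_converted == 2
        assert summ.fraction_converted == 1.0
        assert summ.fraction_increased == pytest.approx(2 / 3)
        n_cs = sum(len(v) for v in summ.clustering_by_direction.values())
        assert n_cs == 1  # the single-site perturbation has no defined C

    def test_empty_results_summary(self):
        summ = summarize_perturbations([], [], n_perm=10)
        assert summ.n_converted == 0 and summ.mean_fraction_perturbed is None


class TestConcordance:
    def _fs(self, meth, marker_col_value):
        n = len(meth)
        atlas = np.full((n, 84), 0.3, np.float32)
        atlas[:, 0] = marker_col_value  # cell type 0 deviates from the mean
        return FeatureSet(
            read_id="r0", chromosome="chr1",
            meth=np.asarray(meth, np.float32),
            pos_norm=np.zeros(n, np.float32),
            site_percentiles=np.zeros((n, 19), np.float32),
            atlas=atlas, atlas_missing=np.zeros((n, 84), bool),
        )

    def test_shift_toward_marker_on_p_increase_is_tumor_like(self):
        fs = self._fs([0.1, 0.1], marker_col_value=0.95)
        res = fake_result("r0", [0.5, 0.0], 0.1, 0.9)  # p increased, moved toward 0.95
        tallies = cell_type_concordance([res], [fs], [f"c{i}" for i in range(84)], min_markers=1)
        assert tallies["c0"].tumor_like == 1 and tallies["c0"].non_tumor_like == 0

    def test_sign_inverts_for_p_decreasing_perturbations(self):
        fs = self._fs([0.1, 0.1], marker_col_value=0.95)
        res = fake_result("r0", [0.5, 0.0], 0.9, 0.1)  # p decreased, moved toward 0.95
        tallies = cell_type_concordance([res], [fs], [f"c{i}" for i in range(84)], min_markers=1)
        assert tallies["c0"].non_tumor_like == 1 and tallies["c0"].tumor_like == 0

    def test_small_deviation_is_not_a_marker(self):
        fs = self._fs([0.1], marker_col_value=0.65)  # |0.65 - mean| < 0.5
        res = fake_result("r0", [0.5], 0.1, 0.9)
        tallies = cell_type_concordance([res], [fs], [f"c{i}" for i in range(84)], min_markers=1)
        assert "c0" not in tallies

    def test_marker_floor_excludes_cell_type(self):
        fs = self._fs([0.1] * 5, marker_col_value=0.95)  # 5 marker CpGs < 20
        res = fake_result("r0", [0.5] * 5, 0.1, 0.9)
        tallies = cell_type_concordance([res], [fs], [f"c{i}" for i in range(84)], min_markers=20)
        assert "c0" not in tallies


class TestPerturbBatchMechanics:
    """Cheap engine checks on a tiny model; conversion rates are covered by
    the acceptance suite."""

    @pytest.fixture(scope="class")
    def setup(self, tiny_feature_sets, pert_model):
        model, _ = pert_model
        from rocit_lite.classifier import predict

        probs = predict(model, tiny_feature_sets, seed=0)
        confident, _ = select_confident(tiny_feature_sets, probs)
        return model, confident[:8]

    def test_model_weights_frozen_and_results_well_formed(self, setup):
        model, sets = setup
        before = model.weight_hash()
        cfg = PerturbationConfig(lambda_max=5.0, t0=2, warmup_steps=18)  # 20-step smoke run
        results = perturb_batch(model, sets, cfg, seed=0)
        assert model.weight_hash() == before
        assert len(results) == len(sets)
        for r in results:
            assert 0 <= r.p_before <= 1 and 0 <= r.p_after <= 1
            assert np.all((np.abs(r.delta) >= cfg.delta_threshold) | (r.delta == 0))
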