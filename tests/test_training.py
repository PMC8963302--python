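import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import cdrloop as cl
from cdrloop.autodiff import Tensor
from cdrloop.egnn import forward_ensemble
from cdrloop.training import (
    BondedPairSchema,
    TrainingConfig,
    _prepare,
    bonded_l1_loss,
    evaluate_ensemble_rmsd,
    per_network_rmsd_loss,
    total_loss,
    train,
)


@pytest.fixture(scope="module")
def prepared(ref_loops, small_cfg):
    return _prepare(ref_loops, TrainingConfig(), small_cfg)


def brute_force_bonded_l1(avg: np.ndarray, truth: np.ndarray,
                          pairs) -> float:
    """Independent enumeration of every pair instance."""
    ia, ib, _ = pairs
    vals = []
    for a, b in zip(ia, ib):
        dp = np.sqrt(((avg[a] - avg[b]) ** 2).sum())
        dt = np.sqrt(((truth[a] - truth[b]) ** 2).sum())
        vals.append(abs(dp - dt))
    return float(np.mean(vals))


class TestPerNetworkRmsdLoss:
    def test_zero_when_all_members_match_truth(self, prepared):
        truth = prepared.truth
        preds = np.broadcast_to(truth, (5,) + truth.shape).copy()
        loss = per_network_rmsd_loss(preds, truth, prepared.interior_idx)
        assert loss.data.item() == pytest.approx(0.0, abs=1e-12)

    def test_one_member_off_by_one_angstrom_gives_one_fifth(self, prepared):
        truth = prepared.truth
        preds = np.broadcast_to(truth, (5,) + truth.shape).copy()
        preds[2, prepared.interior_idx] += np.array([0.0, 1.0, 0.0])
        loss = per_network_rmsd_loss(preds, truth, prepared.interior_idx)
        assert loss.data.item() == pytest.approx(0.2, abs=1e-12)

    def test_no_superposition_semantics(self, prepared):
        """Moving the truth alone changes the loss — nothing is re-fit."""
        truth = prepared.truth
        preds = np.broadcast_to(truth, (5,) + truth.shape).copy()
        moved_truth = truth + np.array([0.5, 0.0, 0.0])
        loss = per_network_rmsd_loss(preds, moved_truth, prepared.interior_idx)
        assert loss.data.item() == pytest.approx(0.5, abs=1e-12)


class TestBondedL1Loss:
    def test_zero_when_averaged_equals_truth(self, prepared):
        loss = bonded_l1_loss(prepared.truth, prepared.truth, prepared.pairs)
        assert loss.data.item() == 0.0

    def test_matches_brute_force_enumeration_on_random_loops(self, small_cfg, rand_seq):
        rng = np.random.default_rng(12)
        for trial in range(6):
            n = int(rng.integers(2, 9))
            rec = cl.make_idealized_loop(
                n, seed=300 + trial, sequence=rand_seq(rng, n)
            )
            prep = _prepare([rec], TrainingConfig(), small_cfg)
            avg = prep.truth + rng.normal(scale=0.5, size=prep.truth.shape)
            loss = bonded_l1_loss(avg, prep.truth, prep.pairs).data.item()
            assert loss == pytest.approx(
                brute_force_bonded_l1(avg, prep.truth, prep.pairs), abs=1e-10
            )

    def test_displaced_ca_contribution_pattern(self, small_cfg):
        rec = cl.make_idealized_loop(2, seed=9, sequence="AA")
        prep = _prepare([rec], TrainingConfig(), small_cfg)
        avg = prep.truth.copy()
        ca0, ca1 = prep.pairs[0][0], prep.pairs[1][0]  # first pair instance is Ca-Ca
        axis = avg[ca1] - avg[ca0]
        avg[ca0] += 0.3 * axis / np.linalg.norm(axis)
        loss = bonded_l1_loss(avg, prep.truth, prep.pairs).data.item()
        assert loss == pytest.approx(
            brute_force_bonded_l1(avg, prep.truth, prep.pairs), abs=1e-6
        )

    def test_invariant_under_joint_rigid_motion(self, prepared):
        rng = np.random.default_rng(13)
        avg = prepared.truth + rng.normal(scale=0.3, size=prepared.truth.shape)
        base = bonded_l1_loss(avg, prepared.truth, prepared.pairs).data.item()
        rot = Rotation.random(random_state=3).as_matrix()
        shift = np.array([2.0, -7.0, 1.0])
        moved = bonded_l1_loss(
            avg @ rot.T + shift, prepared.truth @ rot.T + shift, prepared.pairs
        ).data.item()
        assert moved == pytest.approx(base, abs=1e-9)


class TestTotalLoss:
    def test_phase_one_perfect_prediction_is_zero(self, prepared):
        preds = np.broadcast_to(prepared.truth, (5,) + prepared.truth.shape).copy()
        loss = total_loss(preds, prepared.truth, 1, prepared.interior_idx, prepared.pairs)
        assert loss.data.item() == 0.0

    def test_phase_two_is_sum_of_published_terms(self, prepared):
        rng = np.random.default_rng(14)
        preds = np.stack(
            [prepared.truth + rng.normal(scale=0.4, size=prepared.truth.shape)
             for _ in range(5)]
        )
        rmsd = per_network_rmsd_loss(preds, prepared.truth, prepared.interior_idx)
        l1 = bonded_l1_loss(preds.mean(axis=0), prepared.truth, prepared.pairs)
        total = total_loss(preds, prepared.truth, 2, prepared.interior_idx,
                           prepared.pairs, l1_weight=1.0)
        assert total.data.item() == pytest.approx(
            rmsd.data.item() + 1.0 * l1.data.item(), abs=1e-10
        )

    def test_phase_two_at_least_phase_one(self, prepared):
        rng = np.random.default_rng(15)
        preds = np.stack(
            [prepared.truth + rng.normal(scale=0.4, size=prepared.truth.shape)
             for _ in range(5)]
        )
        p1 = total_loss(preds, prepared.truth, 1, prepared.interior_idx, prepared.pairs)
        p2 = total_loss(preds, prepared.truth, 2, prepared.interior_idx, prepared.pairs)
        assert p2.data.item() >= p1.data.item()

    def test_unknown_phase_rejected(self, prepared):
        with pytest.raises(ValueError):
            total_loss(prepared.truth[None], prepared.truth, 3,
                       prepared.interior_idx, prepared.pairs)


class TestBondedPairSchema:
    def test_five_classes(self):
        assert len(BondedPairSchema().classes) == 5

    def test_single_residue_loop_has_no_cross_residue_instances(self):
        schema = BondedPairSchema()
        slices = {"H3": slice(0, 4 * 5)}  # 1 interior residue + 4 anchors
        interior = np.zeros(20, dtype=bool)
        interior[8:12] = True
        ia, ib, names = schema.pair_indices(slices, interior)
        assert set(names) == {"CA-CB", "CA-N", "CA-C"}
        assert len(names) == 3

    def test_instance_counts_for_known_loop(self, prepared):
        ia, ib, names = prepared.pairs
        total_res = 47  # fixture loop lengths 7+5+8+11+7+9
        # 3 intra classes per residue + 2 cross classes per consecutive pair
        assert len(names) == 3 * total_res + 2 * (total_res - 6)


class TestGradientFlow:
    def test_every_interior_coordinate_receives_gradient(self, small_cfg, ref_loops):
        """Perturbing any predicted atom must change the loss: the loss
        gradient with respect to the initial coordinates is dense over the
        loop interiors."""
        h3 = [next(r for r in ref_loops if r.loop_id == "H3")]
        prep = _prepare(h3, TrainingConfig(), small_cfg)
        ens = cl.init_ensemble(small_cfg)
        x0 = Tensor(np.broadcast_to(prep.init, (5,) + prep.init.shape).copy(),
                    requires_grad=True)
        pred = forward_ensemble(prep.fm, x0, ens, small_cfg, prep.edges)
        loss = total_loss(pred, prep.truth, 2, prep.interior_idx, prep.pairs)
        loss.backward()
        interior_grads = np.abs(x0.grad[:, prep.interior_idx]).max(axis=(0, 2))
        assert np.all(interior_grads > 0)


@pytest.fixture(scope="module")
def tiny_run(small_cfg, rand_seq):
    rng = np.random.default_rng(21)
    loops = [
        cl.make_idealized_loop(3, seed=400 + i, loop_id="H3",
                               sequence=rand_seq(rng, 3))
        for i in range(4)
    ]
    cfg = TrainingConfig(max_epochs_phase1=8, max_epochs_phase2=4,
                         patience=50, seed=5)
    ensemble, history = train([[r] for r in loops], cfg, small_cfg,
                              validation=[[loops[0]]])
    return loops, cfg, ensemble, history


class TestTrain:

    def test_history_is_finite_and_descends_in_phase_one(self, tiny_run):
        _, _, _, history = tiny_run
        p1 = [h for h in history if h["phase"] == 1]
        assert all(np.isfinite(h["train_loss"]) for h in history)
        assert p1[-1]["train_loss"] <= p1[0]["train_loss"]

    def test_same_seed_reproduces_history(self, tiny_run, small_cfg):
        loops, cfg, _, history = tiny_run
        _, again = train([[r] for r in loops], cfg, small_cfg,
                         validation=[[loops[0]]])
        assert again == history

    def test_phases_appear_in_order(self, tiny_run):
        _, _, _, history = tiny_run
        phases = [h["phase"] for h in history]
        assert phases == sorted(phases)

    def test_empty_dataset_rejected(self, small_cfg):
        with pytest.raises(ValueError):
            train([], TrainingConfig(), small_cfg)

    def test_evaluate_ensemble_rmsd_matches_history_scale(self, tiny_run, small_cfg):
        loops, cfg, ensemble, _ = tiny_run
        val = evaluate_ensemble_rmsd(ensemble, [[loops[0]]], cfg, small_cfg)
        assert np.isfinite(val) and val >= 0
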