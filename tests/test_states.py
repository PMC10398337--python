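import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist

from dalff.states import (
    cluster_states,
    compare_group_metrics,
    compute_state_metrics,
    metrics_table,
    select_k,
)


def make_stacks(rng, centers, n_subjects=4, windows_per_subject=20, noise=0.1):
    """Windows drawn around the given centers; returns stacks + true labels."""
    k, v = centers.shape
    stacks, labels = {}, {}
    for i in range(n_subjects):
        lab = rng.integers(0, k, windows_per_subject)
        stacks[f"s{i}"] = centers[lab] + rng.normal(0, noise, (windows_per_subject, v))
        labels[f"s{i}"] = lab + 1
    return stacks, labels


class TestClusterStates:
    def test_k1_closed_form_median(self, rng):
        stacks = {"a": rng.normal(size=(10, 5)), "b": rng.normal(size=(7, 5))}
        model = cluster_states(stacks, k=1, n_init=1)
        pooled = np.vstack(list(stacks.values()))
        assert np.allclose(model.centroids[0], np.median(pooled, axis=0))

    def test_perfect_recovery_separated(self, rng):
        # oracle: ground-truth labels used at generation
        centers = np.array([[0.0] * 6, [10.0] * 6, [20.0] * 6])
        stacks, truth = make_stacks(rng, centers, noise=0.0)
        model = cluster_states(stacks, k=3, n_init=3, seed=1)
        from sklearn.metrics import adjusted_rand_score

        true = np.concatenate(list(truth.values()))
        pred = np.concatenate([model.assignments[s] for s in stacks])
        assert adjusted_rand_score(true, pred) == 1.0

    def test_duplication_invariance(self, rng):
        centers = np.array([[0.0] * 4, [5.0] * 4])
        # unbalanced occupancies so the modal-state relabeling is unambiguous
        stacks = {
            f"s{i}": centers[(rng.random(20) > 0.3).astype(int)]
            + rng.normal(0, 0.1, (20, 4))
            for i in range(2)
        }
        doubled = {**stacks, **{f"{k}_copy": v.copy() for k, v in stacks.items()}}
        m1 = cluster_states(stacks, k=2, n_init=3, seed=0)
        m2 = cluster_states(doubled, k=2, n_init=3, seed=0)
        # same centroid set (occupancy-ordered) and identical assignments
        assert np.allclose(np.sort(m1.centroids, axis=0), np.sort(m2.centroids, axis=0))
        for sid in stacks:
            assert np.array_equal(m1.assignments[sid], m2.assignments[sid])

    def test_cost_non_increasing(self, rng):
        stacks, _ = make_stacks(rng, np.array([[0.0] * 5, [3.0] * 5]), noise=1.0)
        model = cluster_states(stacks, k=2, n_init=1, seed=0)
        costs = np.asarray(model.cost_history)
        assert np.all(np.diff(costs) <= 1e-9)

    def test_centroids_are_medians_at_convergence(self, rng):
        stacks, _ = make_stacks(rng, np.array([[0.0] * 5, [8.0] * 5]), noise=0.5)
        model = cluster_states(stacks, k=2, n_init=2, seed=0)
        pooled = np.vstack([stacks[s] for s in stacks])
        labels = np.concatenate([model.assignments[s] for s in stacks])
        for j in range(2):
            members = pooled[labels == j + 1]
            assert np.allclose(model.centroids[j], np.median(members, axis=0), atol=1e-8)

    def test_assignment_is_nearest_l1_centroid(self, rng):
        stacks, _ = make_stacks(rng, np.array([[0.0] * 5, [4.0] * 5]), noise=1.0)
        model = cluster_states(stacks, k=2, n_init=2, seed=0)
        pooled = np.vstack([stacks[s] for s in stacks])
        labels = np.concatenate([model.assignments[s] for s in stacks]) - 1
        d = cdist(pooled, model.centroids, metric="cityblock")
        assert np.array_equal(d.argmin(axis=1), labels)

    def test_subject_order_invariance(self, rng):
        centers = np.array([[0.0] * 5, [6.0] * 5, [12.0] * 5])
        stacks, _ = make_stacks(rng, centers, n_subjects=5)
        m1 = cluster_states(stacks, k=3, n_init=5, seed=0)
        reordered = {k: stacks[k] for k in reversed(list(stacks))}
        m2 = cluster_states(reordered, k=3, n_init=5, seed=0)
        # occupancy ordering makes labels comparable; match centroids by L1
        d = cdist(m1.centroids, m2.centroids, metric="cityblock")
        assert np.allclose(np.sort(d.min(axis=1)), 0, atol=1e-6)

    def test_mismatched_voxels_rejected(self, rng):
        with pytest.raises(ValueError, match="voxel count"):
            cluster_states({"a": rng.normal(size=(5, 4)), "b": rng.normal(size=(5, 3))}, k=2)

    def test_state1_is_modal(self, rng):
        centers = np.array([[0.0] * 4, [9.0] * 4])
        stacks = {"a": np.vstack([centers[0] + rng.normal(0, 0.1, (15, 4)),
                                  centers[1] + rng.normal(0, 0.1, (5, 4))])}
        model = cluster_states(stacks, k=2, n_init=3, seed=0)
        counts = np.bincount(np.concatenate(list(model.assignments.values())) - 1)
        assert counts[0] >= counts[1]


class TestSelectK:
    def test_recovers_planted_k3(self, rng):
        centers = np.array([[0.0] * 8, [10.0] * 8, [20.0] * 8])
        stacks, _ = make_stacks(rng, centers, n_subjects=5, noise=0.3)
        out = select_k(stacks, (2, 3, 4, 5), n_init=3, seed=0)
        assert out["chosen_k"] == 3

    def test_pure_noise_warns(self, rng):
        stacks = {"a": rng.normal(size=(40, 6)), "b": rng.normal(size=(40, 6))}
        out = select_k(stacks, (2, 3, 4), n_init=2, seed=0)
        assert out["warning"] is None or "flat" in out["warning"]
        assert len(out["costs"]) == 3

    def test_singleton_range(self, rng):
        stacks = {"a": rng.normal(size=(20, 4))}
        out = select_k(stacks, (2,), n_init=2, seed=0)
        assert out["chosen_k"] == 2

    def test_out_of_range_k_rejected(self, rng):
        with pytest.raises(ValueError):
            select_k({"a": rng.normal(size=(20, 4))}, (1, 2))


class TestStateMetrics:
    def test_hand_example(self):
        m = compute_state_metrics(np.array([1, 1, 2, 2, 2, 1]), k=2, tr=2.0, step=1)
        assert m.n_transitions == 2
        assert np.allclose(m.occupancy, [0.5, 0.5])
        assert m.mean_dwell_windows[0] == pytest.approx(1.5)
        assert m.mean_dwell_windows[1] == pytest.approx(3.0)
        assert m.mean_dwell_seconds[1] == pytest.approx(6.0)

    def test_constant_sequence(self):
        m = compute_state_metrics(np.full(17, 2), k=2, tr=2.0, step=1)
        assert m.n_transitions == 0
        assert m.mean_dwell_windows[1] == 17
        assert np.isnan(m.mean_dwell_windows[0])
        assert np.all(np.isnan(m.transition_matrix[0]))

    def test_alternating_sequence(self):
        labels = np.tile([1, 2], 5)
        m = compute_state_metrics(labels, k=2, tr=2.0, step=1)
        assert m.n_transitions == 9
        assert np.allclose(m.mean_dwell_windows, 1.0)

    def test_occupancy_sums_to_one(self, rng):
        labels = rng.integers(1, 4, 50)
        m = compute_state_metrics(labels, k=3)
        assert m.occupancy.sum() == pytest.approx(1.0)
        assert m.n_transitions <= 49

    def test_transition_matrix_rows_stochastic(self, rng):
        labels = rng.integers(1, 4, 100)
        m = compute_state_metrics(labels, k=3)
        visited = ~np.isnan(m.transition_matrix).all(axis=1)
        assert np.allclose(m.transition_matrix[visited].sum(axis=1), 1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compute_state_metrics(np.array([]), k=2)


class TestGroupComparison:
    def make_table(self, rng, shift=0.0):
        rows = []
        for g, n, delta in (("patient", 10, shift), ("control", 10, 0.0)):
            for i in range(n):
                rows.append(
                    {
                        "subject_id": f"{g}{i}",
                        "group": g,
                        "n_transitions": rng.poisson(5) + delta,
                        "occupancy_state1": np.clip(rng.normal(0.5 + delta / 50, 0.1), 0, 1),
                    }
                )
        return pd.DataFrame(rows)

    def test_identical_groups_near_null(self, rng):
        ps = []
        for rep in range(30):
            table = self.make_table(np.random.default_rng(rep))
            out = compare_group_metrics(table)
            ps.extend(out["p_value"].tolist())
        assert np.mean(np.asarray(ps) < 0.05) < 0.2

    def test_planted_shift_detected(self, rng):
        table = self.make_table(rng, shift=6.0)
        out = compare_group_metrics(table)
        row = out[out.metric == "n_transitions"].iloc[0]
        assert row.p_value < 0.01
        assert row.difference > 0

    def test_single_subject_group_rejected(self, rng):
        table = self.make_table(rng).iloc[[0, 10, 11, 12]]
        with pytest.raises(ValueError):
            compare_group_metrics(table)

    def test_zero_variance_flagged(self):
        table = pd.DataFrame(
            {
                "subject_id": list("abcdef"),
                "group": ["patient"] * 3 + ["control"] * 3,
                "n_transitions": [2, 2, 2, 2, 2, 2],
            }
        )
        out = compare_group_metrics(table)
        assert out.iloc[0].zero_variance


def test_metrics_table_shape(rng, small_covariates):
    centers = np.array([[0.0] * 4, [8.0] * 4])
    stacks = {
        sid: centers[rng.integers(0, 2, 10)] + rng.normal(0, 0.1, (10, 4))
        for sid in small_covariates["subject_id"]
    }
    model = cluster_states(stacks, k=2, n_init=2, seed=0)
    table = metrics_table(model, small_covariates, tr=2.0, step=1)
    assert len(table) == 12
    assert {"n_transitions", "occupancy_state1", "dwell_state2"} <= set(table.columns)
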