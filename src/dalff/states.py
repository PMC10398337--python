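"""Recurring-state analysis of windowed ALFF maps.

All subjects' windows are pooled and clustered with L1 (Manhattan) k-means:
assignment by cityblock distance, centroid update by the component-wise
median (the true L1 minimizer).  States are relabeled by descending overall
occupancy, so state 1 is always the modal state.  Per-subject temporal
metrics — fractional occupancy, mean dwell time, number of transitions and
the transition probability matrix — are computed from the window-level
state sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy import stats

__all__ = [
    "StateModel",
    "StateMetrics",
    "cluster_states",
    "select_k",
    "compute_state_metrics",
    "metrics_table",
    "compare_group_metrics",
]


@dataclass
class StateModel:
    k: int
    centroids: np.ndarray  # (k, V)
    assignments: dict[str, np.ndarray]  # subject id -> window labels in 1..k
    inertia: float  # total within-cluster L1 cost
    n_iter: int
    seed: int
    n_init: int
    cost_history: list[float] = field(default_factory=list)


@dataclass
class StateMetrics:
    """Temporal state properties for one subject."""

    occupancy: np.ndarray  # (k,) fractions summing to 1
    mean_dwell_windows: np.ndarray  # (k,) NaN for unvisited states
    mean_dwell_seconds: np.ndarray
    n_transitions: int
    transition_matrix: np.ndarray  # (k, k); unvisited-state rows are NaN
    visits_per_minute: np.ndarray  # (k,) state entries per minute of scan


def _l1_cost(windows: np.ndarray, centroids: np.ndarray, labels: np.ndarray) -> float:
    return float(np.abs(windows - centroids[labels]).sum())


def _weighted_seed(windows: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """L1 analogue of careful seeding: new seeds drawn with prob ~ min distance."""
    n = windows.shape[0]
    centers = [windows[rng.integers(n)]]
    for _ in range(1, k):
        d = cdist(windows, np.asarray(centers), metric="cityblock").min(axis=1)
        total = d.sum()
        if total == 0:
            centers.append(windows[rng.integers(n)])
            continue
        centers.append(windows[rng.choice(n, p=d / total)])
    return np.asarray(centers)


def _lloyd_l1(
    windows: np.ndarray, centroids: np.ndarray, max_iter: int
) -> tuple[np.ndarray, np.ndarray, float, int, list[float]]:
    k = centroids.shape[0]
    labels = np.full(windows.shape[0], -1)
    history: list[float] = []
    for it in range(max_iter):
        dist = cdist(windows, centroids, metric="cityblock")
        new_labels = dist.argmin(axis=1)
        cost = float(dist[np.arange(len(new_labels)), new_labels].sum())
        history.append(cost)
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for j in range(k):
            members = windows[labels == j]
            if members.size == 0:
                # re-seed an emptied centroid from the farthest window
                far = dist.min(axis=1).argmax()
                centroids[j] = windows[far]
            else:
                centroids[j] = np.median(members, axis=0)
    final_cost = _l1_cost(windows, centroids, labels)
    return labels, centroids, final_cost, it + 1, history


def cluster_states(
    stacks: dict[str, np.ndarray],
    k: int,
    n_init: int = 10,
    max_iter: int = 300,
    seed: int = 0,
) -> StateModel:
    """Pool all subjects' windows and run L1 k-means; best of ``n_init`` starts.

    Parameters
    ----------
    stacks : mapping of subject id -> (W, V) window-by-voxel matrix.  All
        subjects must share the same voxel set.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    ids = list(stacks)
    sizes = {stacks[i].shape[1] for i in ids}
    if len(sizes) != 1:
        raise ValueError(f"subjects disagree on voxel count: {sorted(sizes)}")
    windows = np.vstack([stacks[i] for i in ids]).astype(np.float64)
    if windows.shape[0] < k:
        raise ValueError(f"only {windows.shape[0]} windows for k={k}")

    best: tuple[float, np.ndarray, np.ndarray, int, list[float]] | None = None
    root = np.random.SeedSequence(seed)
    for child in root.spawn(n_init):
        rng = np.random.default_rng(child)
        init = _weighted_seed(windows, k, rng) if k > 1 else np.median(windows, axis=0)[None]
        labels, centroids, cost, n_iter, history = _lloyd_l1(windows, init.copy(), max_iter)
        if best is None or cost < best[0]:
            best = (cost, labels, centroids, n_iter, history)
    assert best is not None
    cost, labels, centroids, n_iter, history = best

    # relabel states by descending overall occupancy: state 1 = modal state
    counts = np.bincount(labels, minlength=k)
    order = np.argsort(-counts, kind="stable")
    remap = np.empty(k, dtype=np.int64)
    remap[order] = np.arange(k)
    labels = remap[labels]
    centroids = centroids[order]

    assignments = {}
    start = 0
    for i in ids:
        w = stacks[i].shape[0]
        assignments[i] = labels[start : start + w] + 1
        start += w
    return StateModel(
        k=k,
        centroids=centroids,
        assignments=assignments,
        inertia=cost,
        n_iter=n_iter,
        seed=seed,
        n_init=n_init,
        cost_history=history,
    )


def select_k(
    stacks: dict[str, np.ndarray],
    k_range: tuple[int, ...] = (2, 3, 4, 5, 6),
    n_init: int = 5,
    seed: int = 0,
    silhouette_sample: int = 500,
) -> dict:
    """Cost and silhouette diagnostics per k; elbow by max second difference.

    Always returns the full curves so the choice can be overridden.  A flat
    (structureless) cost curve sets ``warning``.
    """
    ks = sorted(k_range)
    if not all(2 <= k <= 10 for k in ks):
        raise ValueError("k_range must lie within [2, 10]")
    from sklearn.metrics import silhouette_score

    windows = np.vstack(list(stacks.values()))
    costs, silhouettes, models = [], [], {}
    rng = np.random.default_rng(seed)
    sample = (
        rng.choice(windows.shape[0], size=silhouette_sample, replace=False)
        if windows.shape[0] > silhouette_sample
        else np.arange(windows.shape[0])
    )
    for k in ks:
        model = cluster_states(stacks, k, n_init=n_init, seed=seed)
        models[k] = model
        costs.append(model.inertia)
        pooled = np.concatenate([model.assignments[i] for i in stacks])
        lab = pooled[sample]
        if len(np.unique(lab)) < 2:
            silhouettes.append(float("nan"))
        else:
            silhouettes.append(float(silhouette_score(windows[sample], lab, metric="cityblock")))
    costs_arr = np.asarray(costs)
    warning = None
    if costs_arr[0] <= 0 or (costs_arr[0] - costs_arr[-1]) / max(costs_arr[0], 1e-300) < 0.05:
        warning = "cost curve is nearly flat; no clear cluster structure"
        chosen = ks[0]
    elif len(ks) >= 3:
        second_diff = costs_arr[:-2] - 2 * costs_arr[1:-1] + costs_arr[2:]
        chosen = ks[1 + int(np.argmax(second_diff))]
    else:
        chosen = ks[0]
    return {
        "chosen_k": int(chosen),
        "k_values": ks,
        "costs": costs,
        "silhouettes": silhouettes,
        "warning": warning,
        "models": models,
    }


def _runs(labels: np.ndarray) -> list[tuple[int, int]]:
    """Maximal constant segments as (state, length) pairs."""
    runs = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            runs.append((int(labels[start]), i - start))
            start = i
    return runs


def compute_state_metrics(
    labels: np.ndarray, k: int, tr: float = 2.0, step: int = 1
) -> StateMetrics:
    """Occupancy, dwell times, transition count and transition matrix.

    Dwell time in seconds uses the window stride: one window = tr * step s.
    """
    labels = np.asarray(labels, dtype=np.int64)
    if labels.size == 0:
        raise ValueError("empty label sequence")
    if labels.min() < 1 or labels.max() > k:
        raise ValueError(f"labels must lie in 1..{k}")
    w = labels.size
    occupancy = np.bincount(labels - 1, minlength=k) / w
    runs = _runs(labels)
    dwell = np.full(k, np.nan)
    visits = np.zeros(k)
    for state in range(1, k + 1):
        lengths = [ln for s, ln in runs if s == state]
        if lengths:
            dwell[state - 1] = float(np.mean(lengths))
            visits[state - 1] = len(lengths)
    n_transitions = int(np.sum(labels[1:] != labels[:-1]))
    tm = np.zeros((k, k))
    for a, b in zip(labels[:-1], labels[1:]):
        tm[a - 1, b - 1] += 1
    row_sums = tm.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        tm = np.where(row_sums > 0, tm / row_sums, np.nan)
    scan_minutes = w * tr * step / 60.0
    return StateMetrics(
        occupancy=occupancy,
        mean_dwell_windows=dwell,
        mean_dwell_seconds=dwell * tr * step,
        n_transitions=n_transitions,
        transition_matrix=tm,
        visits_per_minute=visits / scan_minutes,
    )


def metrics_table(
    model: StateModel, covariates: pd.DataFrame, tr: float, step: int
) -> pd.DataFrame:
    """Long-format per-subject state metrics joined with group labels."""
    rows = []
    group_of = dict(zip(covariates["subject_id"], covariates["group"]))
    for sid, labels in model.assignments.items():
        m = compute_state_metrics(labels, model.k, tr, step)
        row = {"subject_id": sid, "group": group_of.get(sid, ""), "n_transitions": m.n_transitions}
        for j in range(model.k):
            row[f"occupancy_state{j + 1}"] = m.occupancy[j]
            row[f"dwell_state{j + 1}"] = m.mean_dwell_windows[j]
        rows.append(row)
    return pd.DataFrame(rows)


def _route_two_sample(x: np.ndarray, y: np.ndarray, alpha_normality: float = 0.05):
    """Shapiro-routed two-sample test: t when both groups look normal, else rank."""
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        return "degenerate", 0.0, 1.0
    normal = all(
        stats.shapiro(v).pvalue >= alpha_normality if len(np.unique(v)) > 2 else False
        for v in (x, y)
    )
    if normal:
        res = stats.ttest_ind(x, y)
        return "t", float(res.statistic), float(res.pvalue)
    res = stats.mannwhitneyu(x, y, alternative="two-sided")
    return "ranksum", float(res.statistic), float(res.pvalue)


def compare_group_metrics(
    table: pd.DataFrame, patient_label: str = "patient", alpha_normality: float = 0.05
) -> pd.DataFrame:
    """Group comparison of every state metric column in a metrics table."""
    groups = sorted(table["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, found {groups}")
    other = [g for g in groups if g != patient_label][0]
    sizes = table["group"].value_counts()
    if sizes.min() < 2:
        raise ValueError(f"need >= 2 subjects per group, got {sizes.to_dict()}")
    rows = []
    metric_cols = [c for c in table.columns if c not in ("subject_id", "group")]
    for col in metric_cols:
        x = table.loc[table["group"] == patient_label, col].dropna().to_numpy(float)
        y = table.loc[table["group"] == other, col].dropna().to_numpy(float)
        if len(x) < 2 or len(y) < 2:
            # e.g. a dwell time for a state most subjects never visit
            rows.append(
                {
                    "metric": col,
                    "mean_patient": x.mean() if len(x) else np.nan,
                    "mean_control": y.mean() if len(y) else np.nan,
                    "difference": np.nan,
                    "method": "insufficient",
                    "statistic": np.nan,
                    "p_value": np.nan,
                    "zero_variance": False,
                }
            )
            continue
        flagged = x.std(ddof=1) == 0 and y.std(ddof=1) == 0
        method, statistic, p = _route_two_sample(x, y, alpha_normality)
        rows.append(
            {
                "metric": col,
                "mean_patient": x.mean(),
                "mean_control": y.mean(),
                "difference": x.mean() - y.mean(),
                "method": method,
                "statistic": statistic,
                "p_value": p,
                "zero_variance": flagged,
            }
        )
    return pd.DataFrame(rows)
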