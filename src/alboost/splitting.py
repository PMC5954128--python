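"""Representativeness-driven train/test selection by simulated annealing.

The test set should cover the parent collection's feature space rather
than being an arbitrary random sample. The coverage objective is the mean,
over all parent compounds, of the Euclidean distance to the nearest
selected compound (0 when everything is selected; lower is better). A
swap-move simulated annealing search minimizes it, run independently
within each class so both classes contribute their stated proportion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .data_io import FeatureTable, apply_normalizer, fit_normalizer

__all__ = [
    "AnnealSchedule",
    "SplitResult",
    "representativeness_score",
    "sa_select",
    "stratified_split",
]


@dataclass
class AnnealSchedule:
    """Geometric-cooling parameters.

    `t_initial=None` auto-calibrates the start temperature so that roughly
    `accept_target` of early uphill moves are accepted.
    """

    t_initial: float | None = None
    cooling: float = 0.95
    moves_per_temp: int = 200
    t_min: float = 1e-4
    max_moves: int = 50_000
    accept_target: float = 0.8


@dataclass
class SplitResult:
    train_indices: np.ndarray
    test_indices: np.ndarray
    test_counts: dict[str, int]
    score: float                 # summed per-class representativeness of the test set
    seed: int


def representativeness_score(
    subset: np.ndarray | list[int], table: FeatureTable
) -> float:
    """Mean distance from each parent compound to its nearest subset member.

    Distances are Euclidean in the table's feature space as given; callers
    wanting scale-free coverage normalize the table first.
    """
    idx = np.asarray(subset, dtype=int)
    if idx.size == 0:
        raise ValueError("subset must be non-empty")
    if idx.min() < 0 or idx.max() >= table.n:
        raise ValueError("subset index out of range")
    d = cdist(table.matrix, table.matrix[idx])
    return float(d.min(axis=1).mean())


def _subset_score(dist: np.ndarray, members: np.ndarray) -> float:
    return float(dist[:, members].min(axis=1).mean())


def sa_select(
    table: FeatureTable,
    subset_size: int,
    seed: int = 0,
    schedule: AnnealSchedule | None = None,
) -> np.ndarray:
    """Select a maximally representative subset by simulated annealing.

    Swap moves exchange one selected compound for one unselected compound;
    worse moves are accepted with probability exp(-delta/T) under geometric
    cooling. The best subset ever visited is returned, sorted by index.
    Deterministic given `seed`.
    """
    if not 1 <= subset_size <= table.n:
        raise ValueError(f"subset_size must be in 1..{table.n}")
    if subset_size == table.n:
        return np.arange(table.n)
    schedule = schedule or AnnealSchedule()
    rng = np.random.default_rng(seed)

    dist = cdist(table.matrix, table.matrix)
    members = rng.choice(table.n, size=subset_size, replace=False)
    in_subset = np.zeros(table.n, dtype=bool)
    in_subset[members] = True
    score = _subset_score(dist, members)
    best_members, best_score = members.copy(), score

    t = schedule.t_initial
    if t is None:
        # probe uphill deltas from the start state to set the temperature
        deltas = []
        for _ in range(64):
            i = rng.integers(subset_size)
            j = rng.choice(np.flatnonzero(~in_subset))
            trial = members.copy()
            trial[i] = j
            delta = _subset_score(dist, trial) - score
            if delta > 0:
                deltas.append(delta)
        t = -np.mean(deltas) / np.log(schedule.accept_target) if deltas else 1.0

    moves = 0
    while t > schedule.t_min and moves < schedule.max_moves:
        for _ in range(schedule.moves_per_temp):
            moves += 1
            i = rng.integers(subset_size)
            j = rng.choice(np.flatnonzero(~in_subset))
            trial = members.copy()
            trial[i] = j
            trial_score = _subset_score(dist, trial)
            delta = trial_score - score
            if delta <= 0 or rng.random() < np.exp(-delta / t):
                in_subset[members[i]] = False
                in_subset[j] = True
                members, score = trial, trial_score
                if score < best_score:
                    best_members, best_score = members.copy(), score
            if moves >= schedule.max_moves:
                break
        t *= schedule.cooling
    return np.sort(best_members)


def stratified_split(
    table: FeatureTable,
    test_fraction: float = 0.2,
    seed: int = 0,
    schedule: AnnealSchedule | None = None,
    strategy: str = "sa",
) -> SplitResult:
    """Per-class representative test selection.

    Within each class, floor(test_fraction * class size) compounds are
    selected — by annealing on the z-scored feature space (`strategy="sa"`)
    or uniformly at random (`strategy="random"`) — to form the test set;
    the remainder is the training set.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    if strategy not in ("sa", "random"):
        raise ValueError("strategy must be 'sa' or 'random'")
    counts = table.class_counts()
    if min(counts.values()) == 0:
        raise ValueError(f"both classes must be present; got {counts}")

    normed = apply_normalizer(table, fit_normalizer(table))
    seeds = np.random.SeedSequence(seed).generate_state(len(table.class_names))
    test_parts: list[np.ndarray] = []
    test_counts: dict[str, int] = {}
    total_score = 0.0
    for class_seed, cls in zip(seeds, table.class_names):
        cls_idx = np.flatnonzero(table.labels == cls)
        size = int(np.floor(test_fraction * cls_idx.size))
        if size == 0:
            raise ValueError(
                f"class {cls!r} has {cls_idx.size} compounds; "
                f"floor({test_fraction} * {cls_idx.size}) = 0 test compounds"
            )
        sub = normed.select(cls_idx)
        if strategy == "sa":
            local = sa_select(sub, size, seed=int(class_seed % 2**31), schedule=schedule)
        else:
            local = np.sort(
                np.random.default_rng(int(class_seed % 2**31)).choice(
                    cls_idx.size, size=size, replace=False
                )
            )
        total_score += representativeness_score(local, sub)
        test_parts.append(cls_idx[local])
        test_counts[cls] = size

    test_indices = np.sort(np.concatenate(test_parts))
    mask = np.zeros(table.n, dtype=bool)
    mask[test_indices] = True
    return SplitResult(
        train_indices=np.flatnonzero(~mask),
        test_indices=test_indices,
        test_counts=test_counts,
        score=total_score,
        seed=seed,
    )
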