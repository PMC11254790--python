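"""Per-subject sample balancing: SMOTE up-sampling plus random down-sampling.

Minority classes are grown by the original SMOTE rule — each synthetic beat
is ``x + λ (x_nn − x)`` for a class member ``x``, one of its k nearest
same-class neighbours ``x_nn`` (Euclidean distance, k = 5) and
``λ ~ U[0, 1]`` — and majority classes are randomly down-sampled, until
every subject has exactly the target count (the mean or the maximum of the
original distribution).  Every synthetic row carries provenance (seed row,
neighbour row, λ) so the interpolation can be replayed and audited.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .records import BeatDataset


@dataclass(frozen=True)
class BalanceConfig:
    policy: str = "max"  # or "mean"
    k_neighbors: int = 5
    seed: int = 0
    scope: str = "train_only"  # or "whole_dataset"

    def __post_init__(self) -> None:
        if self.policy not in ("mean", "max"):
            raise ValueError("policy must be 'mean' or 'max'")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.scope not in ("train_only", "whole_dataset"):
            raise ValueError("scope must be 'train_only' or 'whole_dataset'")


@dataclass
class SyntheticProvenance:
    """Audit trail of SMOTE interpolation, one entry per synthetic row."""

    seed_rows: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    neighbor_rows: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    lambdas: np.ndarray = field(default_factory=lambda: np.array([], dtype=float))

    def __len__(self) -> int:
        return int(self.seed_rows.size)


def target_count(counts: dict[str, int], policy: str) -> int:
    """Balanced per-class count: rounded mean or maximum of the originals."""
    if not counts:
        raise ValueError("counts must be non-empty")
    vals = list(counts.values())
    if policy == "max":
        return int(max(vals))
    if policy == "mean":
        # round half away from zero (counts are positive)
        return int(np.floor(np.mean(vals) + 0.5))
    raise ValueError(f"unknown policy {policy!r}")


def smote_oversample(
    X: np.ndarray, n_new: int, k: int = 5, seed: int = 0
) -> tuple[np.ndarray, SyntheticProvenance]:
    """Generate ``n_new`` synthetic rows inside one class.

    Each row is ``x + λ (x_nn − x)`` with ``x`` a uniformly chosen class
    member, ``x_nn`` one of its ``min(k, n−1)`` nearest same-class
    neighbours, and ``λ ~ U[0, 1]``.  Deterministic per seed.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D matrix of class rows")
    n = X.shape[0]
    if n_new < 0:
        raise ValueError("n_new must be non-negative")
    if n_new == 0:
        return np.empty((0, X.shape[1])), SyntheticProvenance()
    if n < 2:
        raise ValueError(
            "SMOTE needs at least 2 rows in the class to interpolate; "
            f"got {n} — cannot up-sample a singleton class"
        )
    k_eff = min(k, n - 1)
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(X)
    # column 0 is the row itself; columns 1..k_eff are the neighbours
    neigh = nn.kneighbors(X, return_distance=False)[:, 1:]
    rng = np.random.default_rng(seed)
    seed_rows = rng.integers(0, n, size=n_new)
    neigh_choice = rng.integers(0, k_eff, size=n_new)
    lambdas = rng.uniform(0.0, 1.0, size=n_new)
    neighbor_rows = neigh[seed_rows, neigh_choice]
    synth = X[seed_rows] + lambdas[:, None] * (X[neighbor_rows] - X[seed_rows])
    return synth, SyntheticProvenance(
        seed_rows=seed_rows.astype(int),
        neighbor_rows=neighbor_rows.astype(int),
        lambdas=lambdas,
    )


def downsample(X: np.ndarray, n: int, seed: int = 0) -> np.ndarray:
    """Uniform random subset of ``n`` rows without replacement."""
    X = np.asarray(X)
    if n > X.shape[0]:
        raise ValueError(f"cannot down-sample {X.shape[0]} rows to {n}")
    if n == X.shape[0]:
        return X.copy()
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(X.shape[0], size=n, replace=False))
    return X[idx]


def balance(
    ds: BeatDataset, cfg: BalanceConfig | None = None
) -> tuple[BeatDataset, dict[str, SyntheticProvenance]]:
    """Equalize every subject's beat count to the policy target.

    Minority classes reach the target via SMOTE (all original rows are
    retained); majority classes are randomly down-sampled.  Returns the
    balanced dataset and, per up-sampled class, the synthetic provenance
    (row indices refer to that class's original row block, in dataset
    order).
    """
    cfg = cfg or BalanceConfig()
    counts = ds.class_counts()
    tgt = target_count(counts, cfg.policy)
    ss = np.random.SeedSequence(cfg.seed)
    class_seeds = {
        lab: int(s.generate_state(1)[0] % (2**31 - 1))
        for lab, s in zip(sorted(counts), ss.spawn(len(counts)))
    }
    parts: list[BeatDataset] = []
    provenance: dict[str, SyntheticProvenance] = {}
    for lab in sorted(counts):
        mask = np.array([str(x) == lab for x in ds.labels])
        sub = ds.subset(np.flatnonzero(mask))
        n = len(sub)
        if n == tgt:
            parts.append(sub)
        elif n > tgt:
            rng = np.random.default_rng(class_seeds[lab])
            idx = np.sort(rng.choice(n, size=tgt, replace=False))
            parts.append(sub.subset(idx))
        else:
            synth, prov = smote_oversample(
                sub.beats, tgt - n, k=cfg.k_neighbors, seed=class_seeds[lab]
            )
            provenance[lab] = prov
            synth_ds = BeatDataset(
                synth,
                np.array([lab] * synth.shape[0], dtype=object),
                np.array(["smote"] * synth.shape[0], dtype=object),
            )
            parts.append(BeatDataset.concat([sub, synth_ds]))
    return BeatDataset.concat(parts), provenance


def replay_check(
    X: np.ndarray, synth: np.ndarray, prov: SyntheticProvenance
) -> float:
    """Max replay error ‖s − (x + λ(x_nn − x))‖∞ over all synthetic rows."""
    if len(prov) == 0:
        return 0.0
    expected = X[prov.seed_rows] + prov.lambdas[:, None] * (
        X[prov.neighbor_rows] - X[prov.seed_rows]
    )
    return float(np.max(np.abs(synth - expected)))
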