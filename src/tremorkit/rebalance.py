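"""Class rebalancing: random undersampling + SMOTE oversampling.

Clinician-scored tremor datasets are heavily skewed toward "no tremor"
(~91.5% of windows). Rebalancing brings every severity class to the same
target count (default 300): classes above the target are randomly
undersampled — the removed real rows are retained as a *discarded pool*
used later as an out-of-sample test set — and classes below it are
oversampled with SMOTE: each synthetic row is

    x_new = x_i + u * (x_nn - x_i),   u ~ Uniform(0, 1),

with ``x_nn`` drawn among the k nearest same-class neighbours of ``x_i``
(k = 5, capped at class size - 1). Neighbours are searched in z-scored
selected-feature space; the interpolation itself is done on the raw
coordinates, so every synthetic row lies exactly on the segment between
its two parents. Parent pairs are recorded so synthetic rows can be
excluded from any audit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .features import LABEL_COLUMN

DEFAULT_TARGET = 300
DEFAULT_SMOTE_K = 5


@dataclass
class ResampledDataset:
    """Balanced feature matrix plus bookkeeping for out-of-sample evaluation.

    ``X``/``y`` hold the balanced rows; ``synthetic`` flags SMOTE rows;
    ``provenance`` maps each balanced row to either its source row index in
    the input matrix or, for synthetic rows, its parent index pair.
    ``discarded_X``/``discarded_y`` hold the real rows removed by
    undersampling.
    """

    X: pd.DataFrame
    y: np.ndarray
    synthetic: np.ndarray
    discarded_X: pd.DataFrame
    discarded_y: np.ndarray
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (len(self.X) == len(self.y) == len(self.synthetic) == len(self.provenance)):
            raise ValueError("inconsistent balanced-row bookkeeping")
        if len(self.discarded_X) != len(self.discarded_y):
            raise ValueError("inconsistent discarded-pool bookkeeping")

    def to_frame(self) -> pd.DataFrame:
        """Single exportable frame with ``label``, ``synthetic`` and ``split`` columns."""
        bal = self.X.copy()
        bal[LABEL_COLUMN] = self.y
        bal["synthetic"] = self.synthetic
        bal["split"] = "balanced"
        pool = self.discarded_X.copy()
        pool[LABEL_COLUMN] = self.discarded_y
        pool["synthetic"] = False
        pool["split"] = "discarded"
        return pd.concat([bal, pool], ignore_index=True)


def random_undersample(
    rows: np.ndarray, target: int, seed: int | np.random.Generator = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform random target-sized subset of one class; complement is discarded.

    Returns ``(kept_idx, discarded_idx)`` as positions into ``rows``' first
    axis. Raises if the class is smaller than the target.
    """
    n = len(rows)
    if n < target:
        raise ValueError(f"cannot undersample {n} rows to {target}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    kept = np.sort(rng.choice(n, size=target, replace=False))
    discarded = np.setdiff1d(np.arange(n), kept)
    return kept, discarded


def smote_oversample(
    rows: np.ndarray,
    target: int,
    k: int = DEFAULT_SMOTE_K,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray, list]:
    """Grow one class to ``target`` rows with SMOTE interpolation.

    Returns ``(all_rows, synthetic_flags, provenance)`` where the first
    ``len(rows)`` entries are the real rows (flag False, provenance = own
    index) followed by ``target - len(rows)`` synthetic rows (flag True,
    provenance = (i, j) parent index pair). ``k`` is capped at class
    size - 1; a single-row class cannot be oversampled.
    """
    rows = np.asarray(rows, dtype=float)
    n = len(rows)
    if n < 2:
        raise ValueError("SMOTE needs at least 2 rows (no neighbours otherwise)")
    if n >= target:
        raise ValueError(f"class of {n} rows already at/above target {target}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k = min(k, n - 1)

    # neighbour search in z-scored space; interpolation on raw coordinates
    mu = rows.mean(axis=0)
    sd = rows.std(axis=0)
    sd[sd == 0] = 1.0
    z = (rows - mu) / sd
    nn = NearestNeighbors(n_neighbors=k + 1).fit(z)
    neigh = nn.kneighbors(z, return_distance=False)[:, 1:]  # drop self

    n_new = target - n
    base = rng.integers(0, n, size=n_new)
    pick = rng.integers(0, k, size=n_new)
    u = rng.uniform(0.0, 1.0, size=n_new)
    parents = neigh[base, pick]
    new_rows = rows[base] + u[:, None] * (rows[parents] - rows[base])

    all_rows = np.vstack([rows, new_rows])
    flags = np.concatenate([np.zeros(n, bool), np.ones(n_new, bool)])
    provenance: list = list(range(n)) + [
        (int(b), int(p)) for b, p in zip(base, parents)
    ]
    return all_rows, flags, provenance


def rebalance_dataset(
    fm: pd.DataFrame,
    target: int = DEFAULT_TARGET,
    k: int = DEFAULT_SMOTE_K,
    seed: int = 0,
) -> ResampledDataset:
    """Balance all three severity classes to ``target`` rows each.

    ``fm`` is a selected-feature matrix with a ``label`` column. Classes
    above the target are undersampled (complement goes to the discarded
    pool); classes below it are SMOTE-oversampled; classes exactly at the
    target pass through. Real rows are exactly partitioned between the
    balanced set and the discarded pool.
    """
    if LABEL_COLUMN not in fm.columns:
        raise ValueError(f"feature matrix must carry a '{LABEL_COLUMN}' column")
    y = fm[LABEL_COLUMN].to_numpy()
    classes = np.unique(y)
    if set(classes) != {0, 1, 2}:
        raise ValueError(f"expected the 3 severity classes, found {classes}")
    X = fm.drop(columns=[LABEL_COLUMN])
    cols = X.columns
    rng = np.random.default_rng(seed)

    bal_parts, bal_labels, bal_flags, provenance = [], [], [], []
    pool_parts, pool_labels = [], []
    for c in (0, 1, 2):
        idx = np.flatnonzero(y == c)
        rows = X.iloc[idx].to_numpy(dtype=float)
        if len(idx) > target:
            kept, discarded = random_undersample(rows, target, rng)
            bal_parts.append(rows[kept])
            bal_flags.append(np.zeros(target, bool))
            provenance += [int(idx[i]) for i in kept]
            pool_parts.append(rows[discarded])
            pool_labels.append(np.full(len(discarded), c))
            bal_labels.append(np.full(target, c))
        elif len(idx) == target:
            bal_parts.append(rows)
            bal_flags.append(np.zeros(target, bool))
            provenance += [int(i) for i in idx]
            bal_labels.append(np.full(target, c))
        else:
            all_rows, flags, prov = smote_oversample(rows, target, k, rng)
            bal_parts.append(all_rows)
            bal_flags.append(flags)
            provenance += [
                int(idx[p]) if isinstance(p, int) else (int(idx[p[0]]), int(idx[p[1]]))
                for p in prov
            ]
            bal_labels.append(np.full(target, c))

    X_bal = pd.DataFrame(np.vstack(bal_parts), columns=cols)
    if pool_parts:
        X_pool = pd.DataFrame(np.vstack(pool_parts), columns=cols)
        y_pool = np.concatenate(pool_labels)
    else:
        X_pool = pd.DataFrame(np.empty((0, len(cols))), columns=cols)
        y_pool = np.empty(0, dtype=int)
    return ResampledDataset(
        X=X_bal,
        y=np.concatenate(bal_labels).astype(int),
        synthetic=np.concatenate(bal_flags),
        discarded_X=X_pool,
        discarded_y=y_pool.astype(int),
        provenance=provenance,
    )
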