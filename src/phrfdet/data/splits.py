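"""Train/val/test partitioning — before augmentation, to avoid leakage.

The canonical ratio is 7:1:2: ``|train| = ⌊0.7·N⌋``, ``|val| = ⌊0.1·N⌋`` and
the test split takes the remainder, so 986 images partition into
(690, 98, 198).  An optional stratified mode balances the per-image dominant
class across splits; the aggregate ratio is preserved either way.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DatasetSplit", "split_dataset"]


@dataclass
class DatasetSplit:
    train: list
    val: list
    test: list
    ratios: tuple
    seed: int

    def __post_init__(self):
        parts = [set(self.train), set(self.val), set(self.test)]
        total = sum(len(p) for p in parts)
        if len(set().union(*parts)) != total:
            raise ValueError("splits overlap")


def _sizes(n: int, ratios) -> tuple:
    n_train = int(np.floor(ratios[0] * n))
    n_val = int(np.floor(ratios[1] * n))
    return n_train, n_val, n - n_train - n_val


def split_dataset(ids, ratios=(0.7, 0.1, 0.2), seed: int = 0,
                  per_class_labels=None, stratify: bool = False) -> DatasetSplit:
    """Seeded shuffle-and-partition of image ids.

    ``per_class_labels`` maps each id to its dominant class and is required
    when ``stratify`` is set; stratification partitions each class with the
    same rule and rebalances remainders to keep the aggregate split sizes.
    """
    ids = list(ids)
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios must sum to 1, got {ratios}")
    rng = np.random.default_rng(seed)
    if not stratify:
        order = rng.permutation(len(ids))
        shuffled = [ids[i] for i in order]
        n_train, n_val, n_test = _sizes(len(ids), ratios)
        return DatasetSplit(shuffled[:n_train],
                            shuffled[n_train:n_train + n_val],
                            shuffled[n_train + n_val:], tuple(ratios), seed)
    if per_class_labels is None:
        raise ValueError("stratify=True requires per_class_labels")
    train, val, test = [], [], []
    classes = sorted({per_class_labels[i] for i in ids})
    for c in classes:
        members = [i for i in ids if per_class_labels[i] == c]
        order = rng.permutation(len(members))
        shuffled = [members[i] for i in order]
        n_train, n_val, n_test = _sizes(len(members), ratios)
        train += shuffled[:n_train]
        val += shuffled[n_train:n_train + n_val]
        test += shuffled[n_train + n_val:]
    # rebalance rounding drift toward the aggregate sizes
    n_train, n_val, n_test = _sizes(len(ids), ratios)
    pool = train + val + test
    return DatasetSplit(pool[:n_train], pool[n_train:n_train + n_val],
                        pool[n_train + n_val:], tuple(ratios), seed)
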