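"""Train/test partitioning strategies for curated datasets.

The default is 80/20 stratified sampling on the dependent variable
(pACTIVITY), binned in equal-width 1.0 log-unit bins; random, Murcko-scaffold
and diversity (max-min Tanimoto) splits are provided as alternatives.
All strategies are deterministic under a seed and always emit a disjoint,
exhaustive partition of the dataset indices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold

from .featurization import similarity_matrix_from_smiles

__all__ = ["SplitSpec", "split_dataset"]

STRATEGIES = ("stratified", "random", "diversity", "scaffold")


@dataclass(frozen=True)
class SplitSpec:
    strategy: str = "stratified"
    train_fraction: float = 0.8
    seed: int = 0
    bin_width: float = 1.0  # stratification bin width in log units

    def __post_init__(self):
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")


def _train_size(n: int, fraction: float) -> int:
    k = int(round(n * fraction))
    return min(max(k, 1), n - 1)  # both partitions non-empty


def _stratified(y: np.ndarray, spec: SplitSpec, rng) -> np.ndarray:
    """Equal-width binning with largest-remainder train allocation.

    Bins with fewer than 2 members are merged into their nearest non-empty
    neighbour so every stratum can contribute to both partitions; the total
    train size is exactly round(n * fraction) and each bin's train share is
    within one compound of the target fraction.
    """
    n = len(y)
    lo = float(np.min(y))
    bins = np.floor((y - lo) / spec.bin_width).astype(int)
    # merge undersized bins into nearest (by bin id) bin with >= 2 members
    labels = np.unique(bins)
    counts = {b: int(np.sum(bins == b)) for b in labels}
    big = [b for b in labels if counts[b] >= 2]
    if big:
        for b in labels:
            if counts[b] < 2:
                nearest = min(big, key=lambda g: (abs(g - b), g))
                bins[bins == b] = nearest
    else:  # every bin tiny: single stratum
        bins[:] = 0

    total_train = _train_size(n, spec.train_fraction)
    labels = np.unique(bins)
    quota = {b: spec.train_fraction * np.sum(bins == b) for b in labels}
    base = {b: int(np.floor(quota[b])) for b in labels}
    short = total_train - sum(base.values())
    # distribute the remainder to the bins with largest fractional part
    order = sorted(labels, key=lambda b: (-(quota[b] - base[b]), b))
    for b in order[: max(short, 0)]:
        base[b] += 1

    train = []
    for b in labels:
        members = np.flatnonzero(bins == b)
        members = rng.permutation(members)
        k = min(base[b], len(members))
        train.extend(members[:k])
    train = np.sort(np.array(train, dtype=int))
    return train


def _scaffold_key(smiles: str) -> str:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return smiles
    return MurckoScaffold.MurckoScaffoldSmiles(mol=mol) or "<acyclic>"


def _scaffold(smiles: list[str], spec: SplitSpec, rng) -> np.ndarray:
    """Whole Murcko-scaffold groups go to one side only."""
    groups: dict[str, list[int]] = {}
    for i, smi in enumerate(smiles):
        groups.setdefault(_scaffold_key(smi), []).append(i)
    keys = sorted(groups)
    keys = [keys[i] for i in rng.permutation(len(keys))]
    target = _train_size(len(smiles), spec.train_fraction)
    train: list[int] = []
    for k in keys:
        if len(train) >= target:
            break
        if len(train) + len(groups[k]) <= len(smiles) - 1:  # keep test non-empty
            train.extend(groups[k])
    if not train:  # single giant scaffold: fall back to its first group
        train = groups[keys[0]][: target]
    return np.sort(np.array(train, dtype=int))


def _diversity(smiles: list[str], spec: SplitSpec, rng) -> np.ndarray:
    """Max-min Tanimoto picking: the test set is chosen first, greedily
    maximising the minimum fingerprint distance to already-picked members."""
    n = len(smiles)
    fps = similarity_matrix_from_smiles(smiles).astype(float)
    inter = fps @ fps.T
    sums = fps.sum(axis=1)
    union = sums[:, None] + sums[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / union, 1.0)
    dist = 1.0 - sim
    n_test = n - _train_size(n, spec.train_fraction)
    picked = [int(rng.integers(n))]
    min_d = dist[picked[0]].copy()
    while len(picked) < n_test:
        min_d[picked] = -1.0
        nxt = int(np.argmax(min_d))
        picked.append(nxt)
        min_d = np.minimum(min_d, dist[nxt])
    test = set(picked)
    return np.array([i for i in range(n) if i not in test], dtype=int)


def split_dataset(dataset, spec: SplitSpec = SplitSpec()) -> tuple[np.ndarray, np.ndarray]:
    """Partition a curated dataset into (train_indices, test_indices).

    ``dataset`` is a :class:`~liabprof.curation.CuratedDataset` or any object
    with ``pactivity`` and ``smiles`` attributes. The same spec (including
    seed) always reproduces the same partition.
    """
    y = np.asarray(dataset.pactivity, dtype=float)
    n = len(y)
    if n < 5:
        raise ValueError("dataset too small to split (need >= 5 compounds)")
    rng = np.random.default_rng(spec.seed)
    if spec.strategy == "stratified":
        train = _stratified(y, spec, rng)
    elif spec.strategy == "random":
        perm = rng.permutation(n)
        train = np.sort(perm[: _train_size(n, spec.train_fraction)])
    elif spec.strategy == "scaffold":
        train = _scaffold(list(dataset.smiles), spec, rng)
    else:
        train = _diversity(list(dataset.smiles), spec, rng)
    mask = np.zeros(n, dtype=bool)
    mask[train] = True
    test = np.flatnonzero(~mask)
    return train, test
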