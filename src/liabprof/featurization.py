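"""Compound featurization: 11 physicochemical descriptors plus two folded
circular fingerprints (2059 features total).

Each compound is encoded as:

* 11 physicochemical descriptors (molecular weight, cLogP, TPSA, H-bond
  donors/acceptors, rotatable bonds, aromatic and aliphatic ring counts,
  stereocenters, fraction of sp3 carbons, heavy atoms);
* a 1024-bit extended-connectivity (Morgan, radius 6) fingerprint;
* a 1024-bit feature-invariant (pharmacophoric Morgan, radius 6) fingerprint.

The 2048-bit concatenation of the two fingerprints (EC first) is the
similarity vector used for Tanimoto-based applicability-domain checks and
diversity splitting. A descriptor filter (low variance, high pairwise
correlation) is provided for use ahead of PCA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors, rdMolDescriptors, rdFingerprintGenerator
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "PHYSCHEM_NAMES",
    "FeatureBlock",
    "compute_physchem",
    "compute_fingerprints",
    "featurize",
    "build_feature_matrix",
    "feature_names",
    "similarity_matrix_from_smiles",
    "filter_descriptors",
    "FeatureEncoder",
    "DescriptorFilter",
    "tanimoto",
]

N_PHYSCHEM = 11
N_BITS = 1024
N_FEATURES = N_PHYSCHEM + 2 * N_BITS  # 2059
FP_RADIUS = 6

PHYSCHEM_NAMES = (
    "MolWt",
    "LogP",
    "TPSA",
    "NumHDonors",
    "NumHAcceptors",
    "NumRotatableBonds",
    "NumAromaticRings",
    "NumAliphaticRings",
    "NumStereoCenters",
    "FractionCSP3",
    "HeavyAtomCount",
)

_ec_gen = rdFingerprintGenerator.GetMorganGenerator(radius=FP_RADIUS, fpSize=N_BITS)
_fc_gen = rdFingerprintGenerator.GetMorganGenerator(
    radius=FP_RADIUS,
    fpSize=N_BITS,
    atomInvariantsGenerator=rdFingerprintGenerator.GetMorganFeatureAtomInvGen(),
)


class FeaturizationError(ValueError):
    pass


@dataclass(frozen=True)
class FeatureBlock:
    """Per-compound feature vectors; ``vector`` is the full 2059-length row."""

    physchem: np.ndarray  # (11,)
    ec_bits: np.ndarray  # (1024,) uint8
    fc_bits: np.ndarray  # (1024,) uint8

    @property
    def similarity_bits(self) -> np.ndarray:
        """2048-bit EC||FC concatenation used for Tanimoto similarity."""
        return np.concatenate([self.ec_bits, self.fc_bits])

    @property
    def vector(self) -> np.ndarray:
        return np.concatenate([self.physchem, self.ec_bits, self.fc_bits])


def _mol(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FeaturizationError(f"unparsable SMILES: {smiles!r}")
    return mol


def compute_physchem(smiles: str) -> np.ndarray:
    """11 physicochemical descriptors in the fixed ``PHYSCHEM_NAMES`` order."""
    mol = _mol(smiles)
    return np.array(
        [
            Descriptors.MolWt(mol),
            Descriptors.MolLogP(mol),
            Descriptors.TPSA(mol),
            rdMolDescriptors.CalcNumHBD(mol),
            rdMolDescriptors.CalcNumHBA(mol),
            rdMolDescriptors.CalcNumRotatableBonds(mol),
            rdMolDescriptors.CalcNumAromaticRings(mol),
            rdMolDescriptors.CalcNumAliphaticRings(mol),
            len(Chem.FindMolChiralCenters(mol, includeUnassigned=True, useLegacyImplementation=False)),
            rdMolDescriptors.CalcFractionCSP3(mol),
            mol.GetNumHeavyAtoms(),
        ],
        dtype=float,
    )


def compute_fingerprints(smiles: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (ec_bits, fc_bits, similarity_bits) for a standardized SMILES."""
    mol = _mol(smiles)
    ec = np.frombuffer(_ec_gen.GetFingerprint(mol).ToBitString().encode(), "u1") - ord("0")
    fc = np.frombuffer(_fc_gen.GetFingerprint(mol).ToBitString().encode(), "u1") - ord("0")
    return ec, fc, np.concatenate([ec, fc])


def featurize(smiles: str) -> FeatureBlock:
    ec, fc, _ = compute_fingerprints(smiles)
    return FeatureBlock(compute_physchem(smiles), ec, fc)


def feature_names() -> list[str]:
    return (
        list(PHYSCHEM_NAMES)
        + [f"EC{i}" for i in range(N_BITS)]
        + [f"FC{i}" for i in range(N_BITS)]
    )


def build_feature_matrix(dataset) -> tuple[np.ndarray, list[str]]:
    """Encode a curated dataset (or SMILES iterable) as an (n, 2059) matrix.

    Row order follows the dataset order; columns are physchem, EC bits, FC
    bits. Any unparsable compound aborts with its identity in the error.
    """
    smiles = list(dataset.smiles) if hasattr(dataset, "smiles") else list(dataset)
    if len(smiles) == 0:
        raise FeaturizationError("empty dataset")
    rows, bad = [], []
    for smi in smiles:
        try:
            rows.append(featurize(smi).vector)
        except FeaturizationError:
            bad.append(smi)
    if bad:
        raise FeaturizationError(f"unparsable compounds: {bad}")
    return np.vstack(rows), feature_names()


def similarity_matrix_from_smiles(smiles) -> np.ndarray:
    """(n, 2048) uint8 matrix of similarity bits for a SMILES iterable."""
    return np.vstack([compute_fingerprints(s)[2] for s in smiles]).astype(np.uint8)


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto coefficient |a&b| / |a|b| between two binary bit vectors."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0  # two empty fingerprints are indistinguishable
    return float(np.logical_and(a, b).sum() / union)


def filter_descriptors(
    X: np.ndarray,
    sd_min: float = 0.01,
    r_max: float = 0.95,
    columns: list[str] | None = None,
) -> tuple[np.ndarray, list[int], list]:
    """Drop low-variance and highly correlated columns, deterministically.

    Columns are scanned in their given order: a column is dropped when its
    sample SD is below ``sd_min`` or when its absolute Pearson correlation
    with an already-retained column exceeds ``r_max`` (the later column of an
    offending pair is always the one dropped). Idempotent.

    Returns (reduced matrix, kept column indices, dropped column labels).
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    sd = X.std(axis=0, ddof=1) if n > 1 else np.zeros(p)
    kept: list[int] = []
    dropped: list[int] = []
    candidates = [j for j in range(p) if sd[j] >= sd_min]
    dropped.extend(j for j in range(p) if sd[j] < sd_min)
    if candidates:
        sub = X[:, candidates]
        corr = np.atleast_2d(np.corrcoef(sub, rowvar=False))
        kept_local: list[int] = []
        for local_j, j in enumerate(candidates):
            if kept_local and np.any(np.abs(corr[local_j, kept_local]) > r_max):
                dropped.append(j)
            else:
                kept_local.append(local_j)
                kept.append(j)
    if not kept:
        raise FeaturizationError("all columns dropped by descriptor filter")
    dropped_labels = (
        [columns[j] for j in sorted(dropped)] if columns is not None else sorted(dropped)
    )
    return X[:, kept], kept, dropped_labels


class FeatureEncoder(TransformerMixin, BaseEstimator):
    """Stateless sklearn transformer: SMILES sequence -> (n, 2059) matrix."""

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> np.ndarray:
        return build_feature_matrix(X)[0]

    def get_feature_names_out(self, input_features=None):
        return np.array(feature_names())


class DescriptorFilter(TransformerMixin, BaseEstimator):
    """Sklearn transformer wrapping :func:`filter_descriptors`.

    Parameters
    ----------
    sd_min : float
        Minimum sample standard deviation for a column to be retained.
    r_max : float
        Maximum |Pearson R| tolerated between two retained columns.
    """

    def __init__(self, sd_min: float = 0.01, r_max: float = 0.95):
        self.sd_min = sd_min
        self.r_max = r_max

    def fit(self, X, y=None):
        _, self.kept_idx_, self.dropped_ = filter_descriptors(
            X, self.sd_min, self.r_max
        )
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        return np.asarray(X, dtype=float)[:, self.kept_idx_]
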