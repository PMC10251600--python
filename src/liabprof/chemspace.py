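"""Chemical-space analysis: basic-framework scaffolds, scaffold-grouped PCA
and pairwise dataset comparison matrices.

A *basic framework* abstracts a molecule one level beyond its Murcko
scaffold (rings plus linkers, side chains removed): every atom is converted
to carbon while branching, double/triple bonds and aromaticity are kept, so
e.g. pyridine and benzene collapse to the same framework. Frameworks group
the chemical space; per-framework averaged descriptors are autoscaled and
projected by PCA for 2-D maps. Dataset panels are compared pairwise by the
Kolmogorov-Smirnov statistic on their pACTIVITY distributions and by the
mean cross-set fingerprint Tanimoto similarity.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold
from scipy.stats import ks_2samp
from sklearn.decomposition import PCA

from .featurization import (
    PHYSCHEM_NAMES,
    compute_physchem,
    filter_descriptors,
    similarity_matrix_from_smiles,
)

__all__ = [
    "basic_framework",
    "scaffold_table",
    "pca_project",
    "dataset_distance_matrices",
]


class FrameworkError(ValueError):
    pass


def basic_framework(smiles: str) -> str:
    """Carbon-skeleton framework of a molecule's Murcko scaffold.

    Returns the canonical SMILES of the scaffold with every atom replaced by
    carbon (bond orders and aromaticity preserved; charges, isotopes and
    stereo dropped), or the empty string for acyclic molecules, which have
    no scaffold. Idempotent and invariant to input atom ordering. Rings that
    cannot re-aromatise after abstraction fall back to their single-bond
    skeleton with a warning.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FrameworkError(f"unparsable SMILES: {smiles!r}")
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    if scaffold is None or scaffold.GetNumAtoms() == 0:
        return ""
    rw = Chem.RWMol(scaffold)
    for atom in rw.GetAtoms():
        atom.SetAtomicNum(6)
        atom.SetFormalCharge(0)
        atom.SetIsotope(0)
        atom.SetNoImplicit(False)
        atom.SetNumExplicitHs(0)
        atom.SetChiralTag(Chem.ChiralType.CHI_UNSPECIFIED)
    for bond in rw.GetBonds():
        bond.SetStereo(Chem.BondStereo.STEREONONE)
    frame = rw.GetMol()
    try:
        Chem.SanitizeMol(frame)
    except Exception:
        warnings.warn(
            f"framework of {smiles!r} failed aromatic perception; "
            "falling back to a single-bond skeleton"
        )
        for atom in frame.GetAtoms():
            atom.SetIsAromatic(False)
        for bond in frame.GetBonds():
            bond.SetIsAromatic(False)
            bond.SetBondType(Chem.BondType.SINGLE)
        Chem.SanitizeMol(frame)
    return Chem.MolToSmiles(frame)


def scaffold_table(
    datasets: dict[str, object],
    autoscale: bool = True,
) -> pd.DataFrame:
    """Group a panel of curated datasets by basic framework.

    One row per unique framework, carrying: member count, per-dataset
    occurrence (number of datasets containing it), mean and SD of member
    pACTIVITY, and the 11 physicochemical descriptors averaged over members
    (column-wise autoscaled to mean 0 / SD 1 when ``autoscale``). Acyclic
    compounds, which have no framework, are counted in the ``<acyclic>``
    row's member count but excluded from the feature table.
    """
    rows: dict[str, dict] = {}
    n_acyclic = 0
    for name, ds in datasets.items():
        for smi, p in zip(ds.smiles, np.asarray(ds.pactivity, float)):
            fw = basic_framework(smi)
            if not fw:
                n_acyclic += 1
                continue
            entry = rows.setdefault(
                fw, {"pact": [], "feats": [], "targets": set()}
            )
            entry["pact"].append(p)
            entry["feats"].append(compute_physchem(smi))
            entry["targets"].add(name)
    if not rows:
        raise FrameworkError("no ring-containing compounds in the panel")
    frameworks = sorted(rows)
    feats = np.vstack([np.mean(rows[fw]["feats"], axis=0) for fw in frameworks])
    if autoscale and len(frameworks) > 1:
        sd = feats.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        feats = (feats - feats.mean(axis=0)) / sd
    table = pd.DataFrame(feats, columns=list(PHYSCHEM_NAMES))
    table.insert(0, "framework", frameworks)
    table.insert(1, "member_count", [len(rows[fw]["pact"]) for fw in frameworks])
    table.insert(2, "target_occurrence", [len(rows[fw]["targets"]) for fw in frameworks])
    table.insert(3, "pACTIVITY_mean", [float(np.mean(rows[fw]["pact"])) for fw in frameworks])
    table.insert(
        4,
        "pACTIVITY_sd",
        [float(np.std(rows[fw]["pact"], ddof=1)) if len(rows[fw]["pact"]) > 1 else 0.0
         for fw in frameworks],
    )
    table.attrs["n_acyclic"] = n_acyclic
    return table


def pca_project(
    X,
    n_components: int = 2,
    sd_min: float = 0.01,
    r_max: float = 0.95,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCA of a (framework x descriptor) matrix after descriptor filtering.

    Low-variance (SD < ``sd_min``) and highly correlated (|R| > ``r_max``)
    columns are removed first. Returns (scores, loadings, explained-variance
    fractions); fractions are non-increasing and sum to <= 1.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least two rows")
    Xf, kept, _ = filter_descriptors(X, sd_min=sd_min, r_max=r_max)
    if Xf.shape[1] < 2:
        raise ValueError("fewer than two descriptors survive filtering")
    if n_components > min(Xf.shape):
        raise ValueError("more components requested than available")
    pca = PCA(n_components=n_components, svd_solver="full").fit(Xf)
    return pca.transform(Xf), pca.components_.T, pca.explained_variance_ratio_


def _mean_cross_tanimoto(fa: np.ndarray, fb: np.ndarray, within: bool) -> float:
    a = fa.astype(np.float64)
    b = fb.astype(np.float64)
    inter = a @ b.T
    union = a.sum(axis=1)[:, None] + b.sum(axis=1)[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / union, 1.0)
    if within:
        iu = np.triu_indices(len(a), k=1)
        return float(sim[iu].mean()) if len(iu[0]) else 1.0
    return float(sim.mean())


def dataset_distance_matrices(
    datasets: dict[str, object],
    max_compounds: int = 200,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise dataset comparison matrices over a panel.

    Returns three symmetric DataFrames indexed by dataset name:

    * Kolmogorov-Smirnov statistic between pACTIVITY distributions
      (sup ECDF difference, 0 on the diagonal);
    * the corresponding KS p-values (1 on the diagonal);
    * mean fingerprint Tanimoto similarity over cross-set compound pairs
      (within-set mean pairwise similarity on the diagonal). Sets larger
      than ``max_compounds`` are subsampled with the given seed.
    """
    names = list(datasets)
    rng = np.random.default_rng(seed)
    pacts, fps = {}, {}
    for name in names:
        ds = datasets[name]
        y = np.asarray(ds.pactivity, dtype=float)
        smiles = list(ds.smiles)
        if len(smiles) < 2:
            raise ValueError(f"dataset {name!r} needs at least 2 compounds")
        pacts[name] = y
        if len(smiles) > max_compounds:
            idx = rng.choice(len(smiles), size=max_compounds, replace=False)
            smiles = [smiles[i] for i in sorted(idx)]
        fps[name] = similarity_matrix_from_smiles(smiles)
    k = len(names)
    ks_stat = np.zeros((k, k))
    ks_p = np.ones((k, k))
    tani = np.zeros((k, k))
    for i, a in enumerate(names):
        tani[i, i] = _mean_cross_tanimoto(fps[a], fps[a], within=True)
        for j in range(i + 1, k):
            b = names[j]
            res = ks_2samp(pacts[a], pacts[b])
            ks_stat[i, j] = ks_stat[j, i] = res.statistic
            ks_p[i, j] = ks_p[j, i] = res.pvalue
            tani[i, j] = tani[j, i] = _mean_cross_tanimoto(fps[a], fps[b], within=False)
    mk = lambda m: pd.DataFrame(m, index=names, columns=names)
    return mk(ks_stat), mk(ks_p), mk(tani)
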