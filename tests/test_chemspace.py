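"""Chemical space: basic frameworks, scaffold grouping, PCA, matrices."""

import numpy as np
import pytest
from rdkit import Chem

from liabprof.chemspace import (
    basic_framework,
    dataset_distance_matrices,
    pca_project,
    scaffold_table,
)
from liabprof.curation import CuratedCompound, CuratedDataset
from liabprof.featurization import PHYSCHEM_NAMES


class TestBasicFramework:
    @pytest.mark.parametrize(
        "smiles,expected",
        [
            ("c1ccccc1", "c1ccccc1"),  # fixed point
            ("c1ccncc1", "c1ccccc1"),  # heteroatom -> carbon
            ("Cc1ccccc1", "c1ccccc1"),  # side chain removed
            ("C1CCNCC1", "C1CCCCC1"),
            ("O=C1CCCCC1", "C=C1CCCCC1"),  # exocyclic double bond is kept
        ],
    )
    def test_examples(self, smiles, expected):
        assert basic_framework(smiles) == Chem.CanonSmiles(expected)

    @pytest.mark.parametrize("smiles", ["CCO", "CC(C)CO", "C"])
    def test_acyclic_has_no_framework(self, smiles):
        assert basic_framework(smiles) == ""

    def test_idempotent(self, library100):
        for smi in library100[:20]:
            fw = basic_framework(smi)
            if fw:
                assert basic_framework(fw) == fw

    def test_atom_order_invariance(self, library100):
        for smi in library100[:10]:
            mol = Chem.MolFromSmiles(smi)
            renumbered = Chem.MolToSmiles(mol, canonical=False, doRandom=False,
                                          rootedAtAtom=mol.GetNumAtoms() // 2)
            assert basic_framework(renumbered) == basic_framework(smi)


def _panel(library100, panel100):
    clean, _ = panel100
    return {
        t: CuratedDataset(
            t, [CuratedCompound(s, float(p)) for s, p in zip(df["smiles"], df["pACTIVITY"])]
        )
        for t, df in clean.items()
    }


class TestScaffoldTable:
    def test_autoscaled_columns(self, library100, panel100):
        table = scaffold_table(_panel(library100, panel100))
        for name in PHYSCHEM_NAMES:
            col = table[name].to_numpy()
            if col.std(ddof=1) > 0:
                assert abs(col.mean()) < 1e-9
                assert col.std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_grouping_conserves_members(self, library100, panel100):
        panel = _panel(library100, panel100)
        table = scaffold_table(panel)
        total = sum(len(ds) for ds in panel.values())
        assert table["member_count"].sum() + table.attrs["n_acyclic"] == total

    def test_two_member_average(self):
        # benzene and pyridine share the benzene framework; MolWt averages
        ds = CuratedDataset("T", [
            CuratedCompound("c1ccccc1", 6.0),
            CuratedCompound("c1ccncc1", 7.0),
            CuratedCompound("C1CCCC1", 5.0),
        ])
        table = scaffold_table({"T": ds}, autoscale=False)
        row = table[table.framework == "c1ccccc1"].iloc[0]
        assert row.member_count == 2
        assert row.pACTIVITY_mean == pytest.approx(6.5)
        from liabprof.featurization import compute_physchem
        mw = (compute_physchem("c1ccccc1")[0] + compute_physchem("c1ccncc1")[0]) / 2
        assert row.MolWt == pytest.approx(mw)


class TestPCA:
    def test_explained_variance_sorted_and_bounded(self, library100, panel100):
        table = scaffold_table(_panel(library100, panel100))
        scores, loadings, evr = pca_project(table[list(PHYSCHEM_NAMES)].to_numpy())
        assert np.all(np.diff(evr) <= 1e-12)
        assert np.all((evr >= 0) & (evr <= 1)) and evr.sum() <= 1 + 1e-9
        assert scores.shape[1] == 2

    def test_two_column_closed_form(self, rng):
        # known covariance: eigenvalues computable by hand from the 2x2 matrix
        n = 4000
        X = rng.multivariate_normal([0, 0], [[4.0, 1.0], [1.0, 1.0]], size=n)
        _, _, evr = pca_project(X, n_components=2, sd_min=1e-12, r_max=0.999)
        S = np.cov(X, rowvar=False)
        tr, det = S[0, 0] + S[1, 1], S[0, 0] * S[1, 1] - S[0, 1] ** 2
        lam1 = (tr + np.sqrt(tr**2 - 4 * det)) / 2
        assert evr[0] == pytest.approx(lam1 / tr, rel=1e-6)

    def test_mean_row_projects_to_origin(self, rng):
        X = rng.normal(size=(30, 4))
        from sklearn.decomposition import PCA

        scores, loadings, _ = pca_project(X, n_components=2, sd_min=1e-9, r_max=0.999)
        mean_scores = (X.mean(axis=0) - X.mean(axis=0)) @ loadings
        assert np.allclose(mean_scores, 0.0)
        assert np.allclose(scores.mean(axis=0), 0.0, atol=1e-9)

    def test_too_many_components_rejected(self, rng):
        with pytest.raises(ValueError):
            pca_project(rng.normal(size=(10, 3)), n_components=5, sd_min=1e-9)


class TestDistanceMatrices:
    def test_matrix_contracts(self, library100, panel100):
        ks, ksp, tani = dataset_distance_matrices(_panel(library100, panel100), seed=1)
        assert np.allclose(ks.values, ks.values.T)
        assert np.allclose(tani.values, tani.values.T)
        assert np.all(np.diag(ks.values) == 0)
        assert np.all((tani.values >= 0) & (tani.values <= 1))
        assert np.all((ks.values >= 0) & (ks.values <= 1))

    def test_disjoint_ranges_ks_is_one(self):
        a = CuratedDataset("A", [CuratedCompound("CCO", 5.0), CuratedCompound("CCC", 5.2)])
        b = CuratedDataset("B", [CuratedCompound("CCN", 8.0), CuratedCompound("CCCl", 8.4)])
        ks, _, _ = dataset_distance_matrices({"A": a, "B": b})
        assert ks.loc["A", "B"] == 1.0

    def test_ks_matches_exhaustive_ecdf_oracle(self, rng):
        x = rng.normal(6, 1, size=5)
        y = rng.normal(6.5, 1, size=5)
        a = CuratedDataset("A", [CuratedCompound(f"C{'C'*i}O", v) for i, v in enumerate(x)])
        b = CuratedDataset("B", [CuratedCompound(f"C{'C'*i}N", v) for i, v in enumerate(y)])
        ks, _, _ = dataset_distance_matrices({"A": a, "B": b})
        # brute-force sup over all ECDF breakpoints
        sup = max(
            abs(np.mean(x <= t) - np.mean(y <= t)) for t in np.concatenate([x, y])
        )
        assert ks.loc["A", "B"] == pytest.approx(sup)
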