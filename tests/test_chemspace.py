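import itertools

import numpy as np
import pandas as pd
import pytest

from lodie.chemspace import (
    filter_suspects,
    fit_pca,
    monoisotopic_mass,
    project,
    select_representatives,
)
from lodie.errors import ValidationError

# hand-computed from standard atomic masses (C 12, H 1.0078250319,
# N 14.0030740052, O 15.9949146221)
GLYCINE_MASS = 75.03203
CAFFEINE_MASS = 194.08038


class TestSuspectFilter:
    TOY = pd.DataFrame(
        {
            "compound_id": [
                "water", "glycine", "caffeine", "benzene", "ethanol",
                "urea", "atrazine", "nacl", "ibuprofen", "badformula",
            ],
            "formula": [
                "H2O", "C2H5NO2", "C8H10N4O2", "C6H6", "C2H6O",
                "CH4N2O", "C8H14ClN5", "NaCl", "C13H18O2", "Xx9Qq",
            ],
        }
    )
    # hand enumeration: water lacks C; benzene lacks N/O; nacl lacks C;
    # glycine, ethanol, urea are < 100 Da; badformula unparseable;
    # caffeine, atrazine, ibuprofen retained
    EXPECTED_KEPT = {"caffeine", "atrazine", "ibuprofen"}

    def test_matches_hand_enumeration(self):
        kept, rejected = filter_suspects(self.TOY)
        assert set(kept["compound_id"]) == self.EXPECTED_KEPT
        assert set(rejected["compound_id"]) == set(self.TOY["compound_id"]) - self.EXPECTED_KEPT

    def test_rejection_reasons(self):
        _, rejected = filter_suspects(self.TOY)
        reasons = dict(zip(rejected["compound_id"], rejected["reason"]))
        assert reasons["water"] == "no-carbon"
        assert reasons["benzene"] == "no-nitrogen-or-oxygen"
        assert reasons["glycine"].startswith("mass-below")
        assert reasons["badformula"].startswith("unparseable")

    def test_monoisotopic_masses(self):
        assert monoisotopic_mass("C2H5NO2") == pytest.approx(GLYCINE_MASS, abs=1e-4)
        assert monoisotopic_mass("C8H10N4O2") == pytest.approx(CAFFEINE_MASS, abs=1e-4)

    def test_idempotent_and_order_independent(self):
        kept1, _ = filter_suspects(self.TOY)
        again = self.TOY.rename(columns={}).iloc[::-1].reset_index(drop=True)
        kept2, _ = filter_suspects(again)
        assert set(kept1["compound_id"]) == set(kept2["compound_id"])
        kept3, rej3 = filter_suspects(
            pd.concat([kept1[["compound_id"]], kept1[["compound_id"]]]).assign(
                formula=list(kept1["formula"]) * 2
            )
        )
        assert len(rej3) == 0


def _cloud(n=30, p=4, seed=0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(rng.normal(size=(n, p)), columns=[f"d{i}" for i in range(p)])
    df.insert(0, "compound_id", [f"c{i:03d}" for i in range(n)])
    return df


class TestPCA:
    def test_collinear_points_put_everything_on_pc1(self):
        t = np.linspace(-1, 1, 10)
        df = pd.DataFrame({"compound_id": [f"c{i}" for i in range(10)],
                           "d0": 2 * t, "d1": -3 * t})
        model, _ = fit_pca(df, n_components=1)
        assert model.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_isotropic_cloud_has_comparable_ratios(self):
        rng = np.random.default_rng(42)
        df = pd.DataFrame(rng.normal(size=(4000, 2)), columns=["d0", "d1"])
        df.insert(0, "compound_id", [f"c{i}" for i in range(4000)])
        model, _ = fit_pca(df, 2)
        r1, r2 = model.explained_variance_ratio
        assert r1 / r2 < 1.2

    def test_sign_convention_deterministic(self):
        df = _cloud()
        m1, s1 = fit_pca(df, 2)
        m2, s2 = fit_pca(df, 2)
        pd.testing.assert_frame_equal(m1.loadings, m2.loadings)
        for col in ("pc1", "pc2"):
            j = m1.loadings[col].abs().idxmax()
            assert m1.loadings.loc[j, col] > 0

    def test_matches_sklearn(self):
        sk = pytest.importorskip("sklearn.decomposition")
        df = _cloud(40, 6, seed=3)
        model, scores = fit_pca(df, 3)
        X = df.drop(columns="compound_id")
        Z = ((X - X.mean()) / X.std(ddof=1)).to_numpy()
        ref = sk.PCA(n_components=3).fit(Z)
        np.testing.assert_allclose(
            model.explained_variance_ratio, ref.explained_variance_ratio_, rtol=1e-9
        )
        np.testing.assert_allclose(
            np.abs(model.loadings.to_numpy().T), np.abs(ref.components_), atol=1e-9
        )

    def test_scores_zero_mean_and_variance_matches_eigenvalues(self):
        df = _cloud(25, 5, seed=9)
        model, scores = fit_pca(df, 2)
        vals = scores[["pc1", "pc2"]].to_numpy()
        np.testing.assert_allclose(vals.mean(axis=0), 0.0, atol=1e-10)
        total = np.var(vals, axis=0, ddof=1).sum()
        X = df.drop(columns="compound_id")
        Z = ((X - X.mean()) / X.std(ddof=1)).to_numpy()
        eig = np.linalg.svd(Z, compute_uv=False) ** 2 / (len(df) - 1)
        assert total == pytest.approx(eig[:2].sum(), rel=1e-9)

    def test_components_beyond_rank_rejected(self):
        df = _cloud(4, 6)
        with pytest.raises(ValidationError):
            fit_pca(df, 5)

    def test_constant_column_dropped(self):
        df = _cloud(10, 3)
        df["const"] = 7.0
        model, _ = fit_pca(df, 2)
        assert model.dropped == ["const"]
        assert "const" not in model.loadings.index


class TestProject:
    def test_training_scores_reproduced_bitwise(self):
        df = _cloud(20, 4, seed=5)
        model, scores = fit_pca(df, 2)
        again = project(model, df)
        assert (again[["pc1", "pc2"]].to_numpy() == scores[["pc1", "pc2"]].to_numpy()).all()

    def test_column_order_irrelevant(self):
        df = _cloud(20, 4, seed=6)
        model, scores = fit_pca(df, 2)
        shuffled = df[["compound_id", "d2", "d0", "d3", "d1"]]
        again = project(model, shuffled)
        assert (again[["pc1", "pc2"]].to_numpy() == scores[["pc1", "pc2"]].to_numpy()).all()

    def test_all_zero_row_finite(self):
        df = _cloud(20, 4, seed=7)
        model, _ = fit_pca(df, 2)
        new = pd.DataFrame([{"compound_id": "z", "d0": 0.0, "d1": 0.0, "d2": 0.0, "d3": 0.0}])
        out = project(model, new)
        assert np.isfinite(out[["pc1", "pc2"]].to_numpy()).all()

    def test_missing_descriptor_named(self):
        df = _cloud(20, 4, seed=8)
        model, _ = fit_pca(df, 2)
        with pytest.raises(ValidationError, match="d3"):
            project(model, df.drop(columns=["d3"]))


def _min_pairwise(pts):
    return min(
        np.linalg.norm(a - b) for a, b in itertools.combinations(pts, 2)
    )


class TestSelectRepresentatives:
    SQUARE = pd.DataFrame(
        {
            "compound_id": ["center", "ne", "nw", "se", "sw"],
            "pc1": [0.0, 1.0, -1.0, 1.0, -1.0],
            "pc2": [0.0, 1.0, 1.0, -1.0, -1.0],
        }
    )

    def test_square_plus_center_returns_corners(self):
        chosen = select_representatives(self.SQUARE, 4)
        assert sorted(chosen) == ["ne", "nw", "se", "sw"]
        # exhaustive oracle: the corners are the unique maximin 4-subset
        pts = {r.compound_id: np.array([r.pc1, r.pc2]) for r in self.SQUARE.itertuples()}
        best = max(
            itertools.combinations(pts, 4),
            key=lambda ids: _min_pairwise([pts[i] for i in ids]),
        )
        assert sorted(best) == sorted(chosen)

    def test_n_equals_population_returns_all(self):
        chosen = select_representatives(self.SQUARE, 5)
        assert sorted(chosen) == sorted(self.SQUARE["compound_id"])

    def test_n_one_returns_farthest_from_centroid(self):
        df = pd.DataFrame(
            {"compound_id": ["a", "b", "c"], "pc1": [0.0, 1.0, 10.0], "pc2": [0.0, 0.0, 0.0]}
        )
        assert select_representatives(df, 1) == ["c"]

    def test_n_exceeding_population_rejected(self):
        with pytest.raises(ValidationError):
            select_representatives(self.SQUARE, 6)

    def test_beats_random_subsets_on_min_pairwise_distance(self):
        rng = np.random.default_rng(12)
        df = pd.DataFrame(
            {
                "compound_id": [f"c{i:03d}" for i in range(60)],
                "pc1": rng.normal(size=60),
                "pc2": rng.normal(size=60),
            }
        )
        chosen = select_representatives(df, 8)
        pts = df.set_index("compound_id")[["pc1", "pc2"]]
        ours = _min_pairwise(pts.loc[chosen].to_numpy())
        for _ in range(100):
            sub = rng.choice(df["compound_id"], size=8, replace=False)
            assert ours >= _min_pairwise(pts.loc[sub].to_numpy())
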