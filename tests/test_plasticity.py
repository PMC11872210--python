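"""Euclidean-distance plasticity indices (MVPi, trait variation)."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import cdist
from scipy.stats import ortho_group

from traitscape import (euclidean_distance, fit_trait_scape, mvpi,
                        plasticity_by_contrast, trait_variation_index)
from traitscape.synth import FUNCTIONAL_TRAITS

# hand enumeration: ambient {(0,0),(0,2)} vs treatment {(3,0),(3,2)}
# pairs: 3, sqrt(13), sqrt(13), 3 -> mean (6 + 2*sqrt(13))/4
HAND_MVPI = (6 + 2 * np.sqrt(13)) / 4


class TestEuclideanDistance:
    def test_zero_for_identical(self):
        assert euclidean_distance([1, 2, 3], [1, 2, 3]) == 0.0

    def test_3_4_5_triangle(self):
        assert euclidean_distance((0, 0), (3, 4)) == 5.0

    def test_matches_elementwise_sum(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            x, y = rng.normal(size=(2, 6))
            oracle = np.sqrt(sum((xi - yi) ** 2 for xi, yi in zip(x, y)))
            assert euclidean_distance(x, y) == pytest.approx(oracle, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            euclidean_distance([1, 2], [1, 2, 3])


class TestMVPi:
    def test_identical_environments_zero(self):
        rows = np.ones((3, 6))
        assert mvpi(rows, rows) == 0.0

    def test_hand_enumerated_four_pairs(self):
        amb = np.array([[0.0, 0], [0, 2]])
        trt = np.array([[3.0, 0], [3, 2]])
        assert mvpi(amb, trt) == pytest.approx(HAND_MVPI, abs=1e-12)

    def test_single_pair_reduces_to_distance(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=(2, 6))
        assert mvpi(x[None], y[None]) == pytest.approx(
            euclidean_distance(x, y), abs=1e-12)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            mvpi(np.empty((0, 3)), np.ones((2, 3)))

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_isometry_invariance(self, seed):
        """MVPi is unchanged by rotating the score space and by adding a
        constant vector to all scores."""
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(rng.integers(1, 5), 6))
        B = rng.normal(size=(rng.integers(1, 5), 6))
        Q = ortho_group.rvs(6, random_state=rng)
        c = rng.normal(size=6)
        base = mvpi(A, B)
        assert mvpi(A @ Q + c, B @ Q + c) == pytest.approx(base, abs=1e-9)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_bounded_below_by_centroid_distance(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(rng.integers(1, 6), 4))
        B = rng.normal(size=(rng.integers(1, 6), 4))
        centroid_gap = np.linalg.norm(A.mean(axis=0) - B.mean(axis=0))
        assert mvpi(A, B) >= centroid_gap - 1e-12

    def test_score_space_equals_trait_space(self):
        """MVPi in full score space equals MVPi computed directly on
        centered/scaled trait values (rotation isometry)."""
        rng = np.random.default_rng(3)
        X = rng.normal(loc=10, scale=3, size=(20, 6))
        scape = fit_trait_scape(X)
        S = np.asarray(scape.scores_)
        Z = (X - scape.mean_) / scape.scale_
        assert mvpi(S[:8], S[8:]) == pytest.approx(mvpi(Z[:8], Z[8:]), abs=1e-9)


class TestTraitVariation:
    def test_replicate_at_centroid_scores_zero(self):
        out = trait_variation_index({"H1": np.array([[1.0, 1.0]]),
                                     "A1": np.array([[1.0, 1.0]])})
        assert out["H1"] == 0.0

    def test_unit_circle_index_one(self):
        rows = np.array([[1.0, 0], [-1, 0], [0, 1], [0, -1]])
        out = trait_variation_index({"H1": rows})
        assert out["H1"] == pytest.approx(1.0, abs=1e-12)

    def test_matches_direct_averaging(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=(3, 4)), rng.normal(size=(5, 4))
        out = trait_variation_index({"A": a, "B": b})
        centroid = np.vstack([a, b]).mean(axis=0)
        assert out["A"] == pytest.approx(
            np.linalg.norm(a - centroid, axis=1).mean(), abs=1e-12)
        assert out["B"] == pytest.approx(
            np.linalg.norm(b - centroid, axis=1).mean(), abs=1e-12)

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError):
            trait_variation_index({})


def _records_from_matrix(X, individuals, cytotypes, waters, co2s):
    df = pd.DataFrame(X, columns=list(FUNCTIONAL_TRAITS))
    df.insert(0, "pot_id", [f"p{i}" for i in range(len(X))])
    df["individual"] = individuals
    df["cytotype"] = cytotypes
    df["water"] = waters
    df["co2"] = co2s
    df["survived"] = True
    return df


class TestPlasticityByContrast:
    def _toy(self, seed=0, shift=0.0):
        """2 individuals x 4 cells x 3 replicates; optional treatment shift."""
        rng = np.random.default_rng(seed)
        rows, ind, cyto, wat, co2 = [], [], [], [], []
        for i, (name, ct) in enumerate([("H1", "hybrid"), ("A1", "allopolyploid")]):
            for w in ("well-watered", "drought"):
                for c in ("ambient", "elevated"):
                    for _ in range(3):
                        x = rng.normal(loc=5, size=6)
                        if not (w == "well-watered" and c == "ambient"):
                            x = x + shift
                        rows.append(x)
                        ind.append(name)
                        cyto.append(ct)
                        wat.append(w)
                        co2.append(c)
        return _records_from_matrix(np.array(rows), ind, cyto, wat, co2)

    def test_identical_cells_give_zero_mvpi(self):
        rec = self._toy(seed=1)
        X = rec[list(FUNCTIONAL_TRAITS)].to_numpy()
        # make every cell identical per individual: constant rows
        X[:] = np.tile(np.arange(6.0), (len(X), 1))
        X += np.repeat(np.arange(len(X) // 12), 12)[:, None]  # vary by individual
        rec[list(FUNCTIONAL_TRAITS)] = X
        scape = fit_trait_scape(rec[list(FUNCTIONAL_TRAITS)])
        res = plasticity_by_contrast(scape, rec, group_by="individual")
        assert np.allclose(res.indices["mvpi"], 0.0)

    def test_cardinality_per_contrast(self, greenhouse):
        from traitscape import impute_missing
        surv = greenhouse[greenhouse["survived"]].reset_index(drop=True)
        X = impute_missing(surv[list(FUNCTIONAL_TRAITS)])
        scape = fit_trait_scape(X)
        full = pd.concat([surv.drop(columns=list(FUNCTIONAL_TRAITS)), X], axis=1)
        res = plasticity_by_contrast(scape, full, group_by="individual")
        per_contrast = res.indices.groupby("contrast")["group"].count()
        assert (per_contrast == 6).all()

    def test_mvpi_equals_mean_of_its_pairs(self):
        rec = self._toy(seed=2, shift=1.0)
        scape = fit_trait_scape(rec[list(FUNCTIONAL_TRAITS)])
        res = plasticity_by_contrast(scape, rec, group_by="individual")
        for _, row in res.indices.dropna(subset=["mvpi"]).iterrows():
            pairs = res.ed_pairs[(res.ed_pairs["group"] == row["group"])
                                 & (res.ed_pairs["contrast"] == row["contrast"])]
            assert len(pairs) == row["n"] * row["m"]
            assert row["mvpi"] == pytest.approx(pairs["ed"].mean(), abs=1e-12)

    def test_group_without_ambient_reported_missing(self):
        rec = self._toy(seed=3)
        rec = rec[~((rec["individual"] == "H1") & (rec["water"] == "well-watered")
                    & (rec["co2"] == "ambient"))].reset_index(drop=True)
        scape = fit_trait_scape(rec[list(FUNCTIONAL_TRAITS)])
        res = plasticity_by_contrast(scape, rec, group_by="individual")
        h1 = res.indices[res.indices["group"] == "H1"].set_index("contrast")
        # contrasts referencing the removed ambient cell are missing, not zero
        assert h1.loc["DR-aCO2 vs WW-aCO2", "mvpi"] != h1.loc["DR-aCO2 vs WW-aCO2", "mvpi"]
        assert np.isnan(h1.loc["WW-eCO2 vs WW-aCO2", "mvpi"])
        assert np.isnan(h1.loc["DR-eCO2 vs WW-aCO2", "mvpi"])
        # the drought-internal CO2 contrast still has its reference cell
        assert np.isfinite(h1.loc["DR-eCO2 vs DR-aCO2", "mvpi"])
        assert not res.indices[res.indices["group"] == "A1"]["mvpi"].isna().any()

    def test_interaction_effect_raises_allopolyploid_mvpi(self):
        """A cytotype x CO2 interaction in the generator shows up as
        higher allopolyploid plasticity under the CO2 contrast."""
        from traitscape import DesignSpec, generate_greenhouse
        from conftest import interaction_model
        rec = generate_greenhouse(DesignSpec(seed=42), interaction_model())
        surv = rec[rec["survived"]].reset_index(drop=True)
        scape = fit_trait_scape(surv[list(FUNCTIONAL_TRAITS)])
        res = plasticity_by_contrast(scape, surv, group_by="cytotype")
        co2_contrast = res.indices[res.indices["contrast"]
                                   == "DR-eCO2 vs DR-aCO2"].set_index("group")
        assert co2_contrast.loc["allopolyploid", "mvpi"] > \
            co2_contrast.loc["hybrid", "mvpi"]
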