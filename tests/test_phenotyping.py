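"""Marker gating, cell classification, phenotype matrices and heatmaps."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from hypothesis.extra.numpy import arrays

from spatialimmune.errors import DegenerateDataError, ValidationError
from spatialimmune.phenotyping import (
    DEFAULT_CLASS_RULES,
    ClassRule,
    MarkerGater,
    Phenotype,
    build_phenotype_matrix,
    class_sets,
    classify_cell_types,
    cluster_profiles,
    contexture_medians,
    correlate_it_pt,
    gate_cells,
    normalize_for_heatmap,
    phenotype_proportion,
)


class TestMarkerGater:
    def test_boundary_intensity_is_positive(self):
        X = pd.DataFrame({"CD3": [2.0, 1.999]})
        pos = gate_cells(X, thresholds={"CD3": 2.0}, markers=["CD3"])
        assert pos["CD3"].tolist() == [True, False]

    def test_zero_intensities_all_negative(self):
        X = pd.DataFrame({"CD3": np.zeros(5)})
        pos = gate_cells(X, thresholds={"CD3": 1.0}, markers=["CD3"])
        assert not pos["CD3"].any()

    def test_missing_marker_raises(self):
        X = pd.DataFrame({"CD3": [1.0, 2.0]})
        with pytest.raises(ValidationError, match="CD8"):
            gate_cells(X, markers=["CD8"])

    def test_auto_threshold_recovers_truth(self, mihc_cohort, gated):
        cells, _, _, truth = mihc_cohort
        positivity, _ = gated
        for marker in ("CD3", "CD8", "PD1", "CD45RO"):
            agree = (
                positivity[marker].to_numpy()
                == truth.cells[f"pos_{marker}"].to_numpy()
            ).mean()
            assert agree >= 0.99

    def test_unimodal_warns_and_uses_range_midpoint(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"M": np.exp(rng.normal(0, 0.3, size=500))})
        with pytest.warns(UserWarning, match="unimodal"):
            gater = MarkerGater(markers=["M"]).fit(X)
        lo, hi = X["M"].min(), X["M"].max()
        assert gater.thresholds_["M"] == pytest.approx((lo + hi) / 2)

    def test_sklearn_get_set_params(self):
        g = MarkerGater(thresholds={"CD3": 1.0})
        assert g.get_params()["thresholds"] == {"CD3": 1.0}
        g.set_params(markers=["CD3"])
        assert g.markers == ["CD3"]


class TestClassification:
    @staticmethod
    def _pos(**kwargs):
        base = {m: [False] for m in ("CD3", "CD4", "CD8", "CD2", "CD16")}
        base.update({k: [v] for k, v in kwargs.items()})
        return pd.DataFrame(base)

    def test_cytotoxic_t_is_also_t(self):
        sets = class_sets(classify_cell_types(self._pos(CD3=True, CD8=True)))
        assert sets.iloc[0] == frozenset({"T", "Tc"})

    def test_nk_rule(self):
        sets = class_sets(classify_cell_types(self._pos(CD2=True)))
        assert sets.iloc[0] == frozenset({"NK"})

    def test_no_positive_markers_empty_set(self):
        sets = class_sets(classify_cell_types(self._pos()))
        assert sets.iloc[0] == frozenset()

    def test_unknown_marker_in_rule(self):
        with pytest.raises(ValidationError, match="FOXP3"):
            classify_cell_types(self._pos(), rules=[ClassRule("Treg", {"FOXP3": True})])

    def test_subset_consistency_on_cohort(self, mihc_cohort, gated):
        cells = mihc_cohort[0]
        _, classes = gated
        counts = classes.groupby(
            [cells["patient_id"], cells["region"]]
        ).sum()
        assert (counts["Tc"] <= counts["T"]).all()
        assert (counts["Th"] <= counts["T"]).all()


class TestPhenotypeProportion:
    @staticmethod
    def _frame():
        n = 50
        classes = pd.DataFrame({"Tc": [True] * 5 + [False] * 45})
        positivity = pd.DataFrame(
            {"PD1": [True, True, False, False, False] + [False] * 45,
             "LAG3": [True, True, True, False, False] + [False] * 45}
        )
        return classes, positivity

    def test_proportion_of_all_cells(self):
        classes, positivity = self._frame()
        p = phenotype_proportion(classes, positivity, Phenotype(cls="Tc"))
        assert p == pytest.approx(0.10)

    def test_parent_class_mode(self):
        classes, positivity = self._frame()
        p = phenotype_proportion(
            classes, positivity,
            Phenotype(cls="Tc", markers=("PD1", "LAG3"), denominator="parent_class"),
            min_cells=5,
        )
        assert p == pytest.approx(0.40)

    def test_small_denominator_missing(self):
        classes, positivity = self._frame()
        p = phenotype_proportion(
            classes, positivity,
            Phenotype(cls="Tc", markers=("PD1",), denominator="parent_class"),
            min_cells=10,
        )
        assert np.isnan(p)

    def test_empty_denominator_missing(self):
        classes = pd.DataFrame({"Tc": [False] * 3})
        positivity = pd.DataFrame({"PD1": [False] * 3})
        p = phenotype_proportion(
            classes, positivity,
            Phenotype(cls="Tc", markers=("PD1",), denominator="parent_class"),
        )
        assert np.isnan(p)


class TestPhenotypeMatrix:
    def test_matrix_matches_independent_recount(self, mihc_cohort, gated):
        cells = mihc_cohort[0]
        positivity, classes = gated
        matrix = build_phenotype_matrix(cells, classes, positivity)
        patient, region = matrix.index[0]
        mask = (
            (cells["patient_id"] == patient) & (cells["region"] == region)
        ).to_numpy()
        # direct recount of the Tc proportion of all cells
        expected = (
            classes.loc[mask, "Tc"].to_numpy().sum() / mask.sum()
        )
        assert matrix.loc[(patient, region), "Tc"] == pytest.approx(expected)

    def test_proportions_bounded(self, mihc_cohort, gated):
        cells = mihc_cohort[0]
        positivity, classes = gated
        matrix = build_phenotype_matrix(cells, classes, positivity)
        vals = matrix.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        assert ((finite >= 0) & (finite <= 1)).all()

    def test_contexture_median(self):
        idx = pd.MultiIndex.from_tuples(
            [("P1", "IT"), ("P2", "IT"), ("P3", "IT")], names=["patient_id", "region"]
        )
        m = pd.DataFrame({"T": [0.1, 0.2, 0.3]}, index=idx)
        assert contexture_medians(m).loc["IT", "T"] == pytest.approx(0.2)


class TestHeatmapNormalization:
    def test_forced_example(self):
        m = pd.DataFrame({"f": [1.0, 2.0, 4.0]})
        out = normalize_for_heatmap(m)
        assert out["f"].tolist() == pytest.approx([-0.5, 0.0, 1.0])

    def test_constant_column_zeros(self):
        out = normalize_for_heatmap(pd.DataFrame({"f": [3.0, 3.0, 3.0]}))
        assert (out["f"] == 0).all()

    @given(
        arrays(
            float,
            st.tuples(st.integers(3, 12), st.integers(1, 5)),
            elements=st.floats(-100, 100, allow_nan=False),
        )
    )
    def test_output_bounded_by_one(self, arr):
        out = normalize_for_heatmap(pd.DataFrame(arr))
        assert np.nanmax(np.abs(out.to_numpy()), initial=0.0) <= 1.0 + 1e-12


class TestClusterProfiles:
    def test_identical_rows_merge_first(self):
        m = pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0], [4.0, 1.0, 3.0, 2.0]],
            index=["a", "b", "c"],
        )
        res = cluster_profiles(m)
        first_merge = res.linkage[0]
        assert {int(first_merge[0]), int(first_merge[1])} == {0, 1}
        assert first_merge[2] == pytest.approx(0.0)

    def test_negated_row_merges_last(self):
        m = pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0], [1.1, 2.2, 2.9, 4.2], [4.0, 3.0, 2.0, 1.0]],
            index=["a", "b", "neg"],
        )
        res = cluster_profiles(m)
        # last merge joins the negated profile at the largest height
        assert res.order.index("neg") in (0, 2)
        assert res.linkage[-1, 2] == res.linkage[:, 2].max()

    def test_merge_heights_monotone(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame(rng.normal(size=(8, 5)))
        res = cluster_profiles(m)
        heights = res.linkage[:, 2]
        assert (np.diff(heights) >= -1e-12).all()

    def test_constant_rows_appended_last(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.normal(size=(4, 5)))
        m.loc[4] = 1.0  # constant profile
        res = cluster_profiles(m)
        assert res.order[-1] == 4
        assert res.unclustered == [4]

    def test_too_few_clusterable_rows(self):
        m = pd.DataFrame([[1.0, 2.0], [1.0, 1.0], [2.0, 2.0]])
        with pytest.raises(DegenerateDataError):
            cluster_profiles(m)


class TestItPtCorrelation:
    @staticmethod
    def _matrix(pt_values):
        rows = {}
        for i, (it_v, pt_v) in enumerate(zip(range(1, 9), pt_values)):
            rows[(f"P{i}", "IT")] = {"f": float(it_v)}
            rows[(f"P{i}", "PT")] = {"f": float(pt_v)}
        m = pd.DataFrame.from_dict(rows, orient="index")
        m.index = pd.MultiIndex.from_tuples(m.index, names=["patient_id", "region"])
        return m

    def test_identical_vectors(self):
        out, medians = correlate_it_pt(self._matrix(list(range(1, 9))))
        assert out.loc[0, "r"] == pytest.approx(1.0)
        assert medians.loc["all"] == pytest.approx(1.0)

    def test_reversed_ranks(self):
        out, _ = correlate_it_pt(self._matrix(list(range(8, 0, -1))))
        assert out.loc[0, "r"] == pytest.approx(-1.0)

    def test_insufficient_pairs_missing(self):
        m = self._matrix(list(range(1, 9))).iloc[:6]  # 3 complete pairs < 5
        out, _ = correlate_it_pt(m)
        assert np.isnan(out.loc[0, "r"])

    def test_generator_cross_region_dependence_sign(self, mihc_cohort, gated):
        # hot patients are high in both regions, cold low in both: the T-cell
        # proportion must correlate positively between IT and PT
        cells = mihc_cohort[0]
        positivity, classes = gated
        matrix = build_phenotype_matrix(cells, classes, positivity)
        out, _ = correlate_it_pt(matrix)
        r = out.set_index("phenotype").loc["T", "r"]
        assert r > 0
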