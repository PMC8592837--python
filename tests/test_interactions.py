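"""Interaction equations: distances, pair counts, the normalized index,
per-cell flags and interaction-conditioned fold-changes."""

import numpy as np
import pandas as pd
import pytest

from spatialimmune.errors import ValidationError
from spatialimmune.interactions import (
    InteractionConfig,
    digital_stain,
    flag_interacting_cells,
    interaction_frequency,
    interaction_index,
    interaction_matrix,
    interaction_phenotype_fc,
    is_interacting,
    pair_distance,
)
from spatialimmune.phenotyping import Phenotype

from _oracles import brute_force_pair_count


def _frame(xy, ids=None, region="IT", patient="P1"):
    xy = np.asarray(xy, dtype=float)
    n = len(xy)
    return pd.DataFrame(
        {
            "cell_id": ids if ids is not None else [f"c{i}" for i in range(n)],
            "patient_id": [patient] * n,
            "core_id": [f"{patient}-c1"] * n,
            "region": [region] * n,
            "x_px": xy[:, 0],
            "y_px": xy[:, 1],
        }
    )


class TestPairDistance:
    def test_three_four_five(self):
        assert pair_distance((0, 0), (3, 4)) == pytest.approx(5.0)

    def test_identical_points(self):
        assert pair_distance((1, 1), (1, 1)) == 0.0

    def test_boundary_distance(self):
        assert pair_distance((0, 0), (60, 80)) == pytest.approx(100.0)

    def test_nonfinite_raises(self):
        with pytest.raises(ValidationError):
            pair_distance((np.nan, 0), (0, 0))


class TestIsInteracting:
    @pytest.mark.parametrize(
        "d, expected", [(100.0, 1), (100.001, 0), (0.0, 1), (22.0, 1)]
    )
    def test_threshold_inclusive(self, d, expected):
        assert is_interacting(d) == expected

    def test_negative_distance_raises(self):
        with pytest.raises(ValidationError):
            is_interacting(-1.0)


class TestInteractionFrequency:
    def test_one_pair_inside_one_outside(self):
        a = _frame([(0, 0)], ids=["a1"])
        b = _frame([(60, 80), (200, 200)], ids=["b1", "b2"])
        assert interaction_frequency(a, b) == 1

    def test_collinear_self_pairs(self):
        c = _frame([(0, 0), (90, 0), (180, 0)])
        assert interaction_frequency(c, c) == 2

    def test_empty_input(self):
        a = _frame(np.empty((0, 2)))
        b = _frame([(0, 0)], ids=["b1"])
        assert interaction_frequency(a, b) == 0

    def test_mixed_regions_raise(self):
        a = _frame([(0, 0)], region="IT")
        b = _frame([(10, 0)], ids=["b1"], region="PT")
        with pytest.raises(ValidationError, match="regions"):
            interaction_frequency(a, b)

    def test_shared_cell_excluded_by_id(self):
        # one physical cell under both type labels: no self-pair
        a = _frame([(0, 0)], ids=["x"])
        b = _frame([(0, 0)], ids=["x"])
        # identical id sets -> same-type mode, single cell, no pairs
        assert interaction_frequency(a, b) == 0
        b2 = _frame([(0, 0), (50, 0)], ids=["x", "y"])
        assert interaction_frequency(a, b2) == 1

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            pts = rng.uniform(0, 500, size=(200, 2))
            ids = np.array([f"c{i}" for i in range(200)], dtype=object)
            ia = rng.choice(200, size=20, replace=False)
            ib = rng.choice(200, size=30, replace=False)
            a = _frame(pts[ia], ids=list(ids[ia]))
            b = _frame(pts[ib], ids=list(ids[ib]))
            expected = brute_force_pair_count(pts[ia], ids[ia], pts[ib], ids[ib], 100.0)
            assert interaction_frequency(a, b) == expected

    def test_invariances(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 400, size=(80, 2))
        a = _frame(pts[:30], ids=[f"a{i}" for i in range(30)])
        b = _frame(pts[30:], ids=[f"b{i}" for i in range(50)])
        base = interaction_frequency(a, b)
        # translation
        at, bt = a.copy(), b.copy()
        for f in (at, bt):
            f["x_px"] += 123.4
            f["y_px"] -= 55.0
        assert interaction_frequency(at, bt) == base
        # rotation about origin
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        ar, br = a.copy(), b.copy()
        for f in (ar, br):
            xy = f[["x_px", "y_px"]].to_numpy() @ R.T
            f["x_px"], f["y_px"] = xy[:, 0], xy[:, 1]
        assert interaction_frequency(ar, br) == base
        # scaling with scaled threshold
        s = 3.5
        as_, bs = a.copy(), b.copy()
        for f in (as_, bs):
            f["x_px"] *= s
            f["y_px"] *= s
        cfg = InteractionConfig(threshold_px=100.0 * s)
        assert interaction_frequency(as_, bs, cfg) == base

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(0, 300, size=(60, 2))
        a = _frame(pts[:25], ids=[f"a{i}" for i in range(25)])
        b = _frame(pts[25:], ids=[f"b{i}" for i in range(35)])
        counts = [
            interaction_frequency(a, b, InteractionConfig(threshold_px=t))
            for t in (10, 50, 100, 200, 500)
        ]
        assert counts == sorted(counts)

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 300, size=(40, 2))
        a = _frame(pts[:15], ids=[f"a{i}" for i in range(15)])
        b = _frame(pts[15:], ids=[f"b{i}" for i in range(25)])
        iab = interaction_frequency(a, b)
        iba = interaction_frequency(b, a)
        assert iab == iba
        assert iab <= 15 * 25
        iaa = interaction_frequency(a, a)
        assert iaa <= 15 * 14 // 2


class TestInteractionIndex:
    def test_zero_count(self):
        assert interaction_index(0, 5, 7, 100) == 0.0

    def test_formula_value(self):
        assert interaction_index(4, 2, 3, 50) == pytest.approx(4 * 50 / np.sqrt(6))

    def test_linear_in_total_count(self):
        assert interaction_index(3, 4, 5, 200) == pytest.approx(
            2 * interaction_index(3, 4, 5, 100)
        )

    def test_empty_type_missing(self):
        with pytest.warns(UserWarning, match="empty"):
            assert np.isnan(interaction_index(0, 0, 5, 10))

    def test_sum_variant(self):
        assert interaction_index(4, 2, 3, 50, variant="sum") == pytest.approx(
            4 * 50 / np.sqrt(5)
        )


class TestInteractionMatrix:
    def test_single_type_cohort(self):
        cells = _frame([(0, 0), (50, 0), (400, 0)])
        classes = pd.DataFrame(
            {"T": [True, True, True], "NK": [False, False, False]},
            index=cells.index,
        )
        cfg = InteractionConfig(types=("T", "NK"))
        out = interaction_matrix(cells, classes, cfg).set_index(["type_a", "type_b"])
        assert out.loc[("T", "T"), "i_ab"] == 1
        assert np.isnan(out.loc[("T", "NK"), "I_ab"])
        assert np.isnan(out.loc[("NK", "NK"), "I_ab"])

    def test_clustered_vs_uniform_index(self):
        from spatialimmune.phenotyping import classify_cell_types, gate_cells
        from spatialimmune.synthetic import CohortConfig, SpatialProcess, generate_cohort

        medians = {}
        for kind in ("uniform", "clustered"):
            cells, _, _, _ = generate_cohort(
                CohortConfig(
                    n_patients=6, seed=13, spatial_process=SpatialProcess(kind=kind)
                )
            )
            pos = gate_cells(cells)
            cls = classify_cell_types(pos)
            m = interaction_matrix(cells, cls)
            medians[kind] = np.nanmedian(m["I_ab"])
        assert medians["clustered"] > medians["uniform"]

    def test_multi_core_aggregation_sums_counts(self):
        cells1 = _frame([(0, 0), (50, 0)])
        cells2 = _frame([(0, 0), (30, 0)])
        cells2["core_id"] = "P1-c2"
        cells2["cell_id"] = ["d0", "d1"]
        cells = pd.concat([cells1, cells2], ignore_index=True)
        classes = pd.DataFrame({"T": [True] * 4}, index=cells.index)
        out = interaction_matrix(cells, classes, InteractionConfig(types=("T",)))
        rec = out.iloc[0]
        assert rec["i_ab"] == 2 and rec["m"] == 4 and rec["c"] == 4


class TestFlagInteractingCells:
    def test_lone_focal_cell(self):
        cells = _frame([(0, 0)])
        classes = pd.DataFrame({"T": [True], "NK": [False]}, index=cells.index)
        flags = flag_interacting_cells(cells, classes, "T", "NK")
        assert flags.tolist() == [False]

    def test_self_excluded_when_focal_is_also_partner(self):
        cells = _frame([(0, 0)])
        classes = pd.DataFrame({"T": [True], "NK": [True]}, index=cells.index)
        flags = flag_interacting_cells(cells, classes, "T", "NK")
        assert flags.tolist() == [False]

    def test_matches_brute_force(self):
        rng = np.random.default_rng(4)
        pts = rng.uniform(0, 400, size=(120, 2))
        cells = _frame(pts)
        is_t = rng.random(120) < 0.4
        is_nk = rng.random(120) < 0.3
        classes = pd.DataFrame({"T": is_t, "NK": is_nk}, index=cells.index)
        flags = flag_interacting_cells(cells, classes, "T", "NK")
        for idx in np.flatnonzero(is_t):
            expected = False
            for jdx in np.flatnonzero(is_nk):
                if jdx == idx:
                    continue
                if np.hypot(*(pts[idx] - pts[jdx])) <= 100.0:
                    expected = True
                    break
            assert flags.loc[f"c{idx}"] == expected


class TestInteractionPhenotypeFC:
    @staticmethod
    def _cohort(p_int, p_non, n_int=10, n_non=50, n_patients=6):
        """Patients with an interacting focal block (near one NK cell) and a
        far non-interacting block, with exact positivity fractions."""
        frames, pos_rows, cls_rows = [], [], []
        for p in range(n_patients):
            pid = f"P{p}"
            xy = [(0.0, 0.0)]  # the NK partner
            kinds = [("NK", False)]
            for i in range(n_int):
                xy.append((10.0 + i * 0.01, 0.0))
                kinds.append(("T", i < round(p_int * n_int)))
            for i in range(n_non):
                xy.append((5000.0 + i * 0.01, 0.0))
                kinds.append(("T", i < round(p_non * n_non)))
            f = _frame(xy, ids=[f"{pid}-c{i}" for i in range(len(xy))], patient=pid)
            frames.append(f)
            for kind, mpos in kinds:
                cls_rows.append({"T": kind == "T", "NK": kind == "NK"})
                pos_rows.append({"CD45RO": bool(mpos)})
        cells = pd.concat(frames, ignore_index=True)
        classes = pd.DataFrame(cls_rows, index=cells.index)
        positivity = pd.DataFrame(pos_rows, index=cells.index)
        return cells, classes, positivity

    def test_equal_proportions_zero_fc(self):
        cells, classes, positivity = self._cohort(0.2, 0.2)
        out = interaction_phenotype_fc(
            cells, classes, positivity, pairs=[("T", "NK")], markers=["CD45RO"]
        )
        assert out.loc[0, "fc_log10"] == pytest.approx(0.0)
        assert out.loc[0, "p_value"] == pytest.approx(1.0)

    def test_tenfold_enrichment_gives_unit_fc(self):
        cells, classes, positivity = self._cohort(0.2, 0.02)
        out = interaction_phenotype_fc(
            cells, classes, positivity, pairs=[("T", "NK")], markers=["CD45RO"]
        )
        assert out.loc[0, "fc_log10"] == pytest.approx(1.0)
        assert out.loc[0, "p_value"] < 0.05

    def test_min_cell_rule_reports_missing(self):
        cells, classes, positivity = self._cohort(0.2, 0.02, n_int=4)
        out = interaction_phenotype_fc(
            cells, classes, positivity, pairs=[("T", "NK")], markers=["CD45RO"],
            min_cells=10,
        )
        assert np.isnan(out.loc[0, "fc_log10"])
        assert out.loc[0, "n_patients"] == 0


class TestDigitalStain:
    def test_writes_file_with_matching_counts(self, tmp_path, mihc_cohort, gated):
        cells = mihc_cohort[0].iloc[:5000].reset_index(drop=True)
        positivity, classes = gated
        positivity = positivity.iloc[:5000].reset_index(drop=True)
        classes = classes.iloc[:5000].reset_index(drop=True)
        out = tmp_path / "stain.png"
        meta = digital_stain(
            cells, classes, positivity,
            Phenotype(cls="T", markers=("TIM3",)), out,
        )
        assert out.exists() and out.stat().st_size > 0
        total = sum(f["n_points"] for f in meta["facets"].values())
        assert total == len(cells)

    def test_unknown_phenotype_raises(self, tmp_path, mihc_cohort, gated):
        cells = mihc_cohort[0].iloc[:100].reset_index(drop=True)
        positivity, classes = gated
        with pytest.raises(ValidationError, match="unknown"):
            digital_stain(
                cells,
                classes.iloc[:100].reset_index(drop=True),
                positivity.iloc[:100].reset_index(drop=True),
                Phenotype(cls="Treg"),
                tmp_path / "x.png",
            )
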