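"""Inter-regional statistics, CB distances, stage correlations, PCA."""

import itertools

import numpy as np
import pandas as pd
import pytest

from protatlas.regional import (
    cb_distance,
    inter_regional_curve,
    inter_regional_difference,
    pca_scores,
    stage_correlation,
)
from protatlas.simulate import SimConfig, simulate_atlas

from conftest import build_matrix


class TestInterRegional:
    def test_identical_samples_give_zero(self):
        m = build_matrix({"P1": [4.0, 4.0], "P2": [8.0, 8.0]},
                         [("F50", "PFC"), ("F50", "V1")])
        assert inter_regional_difference(m, "F50", "CTX").value == 0.0

    def test_hand_worked_toy(self):
        # log2 profiles (1,3) and (2,5): mean(|1-2|, |3-5|) = 1.5
        m = build_matrix({"P1": [2.0**1, 2.0**2], "P2": [2.0**3, 2.0**5]},
                         [("F50", "PFC"), ("F50", "V1")])
        r = inter_regional_difference(m, "F50", "CTX")
        assert r.value == pytest.approx(1.5)
        assert r.n_pairs == 1

    def test_same_region_pairs_excluded_by_default(self):
        m = build_matrix({"P1": [2.0, 4.0, 16.0]},
                         [("F50", "PFC"), ("F50", "PFC"), ("F50", "V1")])
        r = inter_regional_difference(m, "F50", "CTX")
        # pairs: (PFC1,V1): |1-4|=3; (PFC2,V1): |2-4|=2 -> 2.5; replicate pair skipped
        assert r.n_pairs == 2
        assert r.value == pytest.approx(2.5)
        r_all = inter_regional_difference(m, "F50", "CTX", include_same_region=True)
        assert r_all.n_pairs == 3

    def test_single_region_group_falls_back_with_warning(self):
        m = build_matrix({"P1": [2.0, 8.0]}, [("F50", "CB"), ("F50", "CB")])
        with pytest.warns(UserWarning, match="one region"):
            r = inter_regional_difference(m, "F50", "CB")
        assert r.value == pytest.approx(2.0)

    def test_invariant_to_sample_order(self):
        m = build_matrix({"P1": [2.0, 4.0, 8.0], "P2": [16.0, 2.0, 4.0]},
                         [("F50", "PFC"), ("F50", "V1"), ("F50", "TL")])
        v1 = inter_regional_difference(m, "F50", "CTX").value
        perm = list(m.sample_ids)[::-1]
        v2 = inter_regional_difference(m.subset(perm), "F50", "CTX").value
        assert v1 == pytest.approx(v2, abs=1e-12)

    def test_v_shaped_region_schedule_recovers_minimum_stage(self):
        cfg = SimConfig(n_proteins=200, region_effect_sd=0.8,
                        region_scale_by_stage={"F50": 2.0, "F90": 1.0,
                                               "F120": 0.25, "P3": 1.5},
                        n_stage_markers=0, n_macro_markers=0,
                        n_emergent_per_transition=0, dropout=0.0, seed=21)
        m = simulate_atlas(cfg).matrix
        curve = inter_regional_curve(m)
        ctx = curve[curve["group"] == "CTX"].set_index("stage")["value"]
        assert ctx.idxmin() == "F120"


class TestCbDistance:
    def test_identical_region_distance_zero(self):
        m = build_matrix({"P1": [4.0, 4.0], "P2": [8.0, 8.0]},
                         [("F50", "CB"), ("F50", "PFC")])
        assert cb_distance(m, "F50").iloc[0]["distance"] == 0.0

    def test_pythagorean_toy(self):
        # log2 differences (3, 4) -> distance 5
        m = build_matrix({"P1": [2.0**5, 2.0**2], "P2": [2.0**6, 2.0**2]},
                         [("F50", "CB"), ("F50", "PFC")])
        assert cb_distance(m, "F50").iloc[0]["distance"] == pytest.approx(5.0)

    def test_growing_cb_shift_gives_monotone_distances(self):
        rng = np.random.default_rng(2)
        shifts = {"F50": 0.5, "F90": 1.0, "F120": 2.0, "P3": 4.0}
        specs = [(s, r) for s in shifts for r in ("CB", "PFC") for _ in range(2)]
        rows = {}
        for i in range(20):
            base = rng.normal(20, 0.2, len(specs))
            vals = [b + (shifts[s] if r == "CB" else 0.0)
                    for b, (s, r) in zip(base, specs)]
            rows[f"P{i}"] = (2.0 ** np.array(vals)).tolist()
        m = build_matrix(rows, specs)
        d = {s: cb_distance(m, s).iloc[0]["distance"] for s in shifts}
        assert d["F50"] < d["F90"] < d["F120"] < d["P3"]

    def test_triangle_inequality_on_mean_profiles(self, planted_atlas):
        m = planted_atlas.matrix
        d = cb_distance(m, "F120").set_index("region")["distance"]
        # distance CB->A <= CB->B + B->A for profiles on a shared protein set:
        # verify with explicit complete-case profiles
        sub = m.subset(m.samples(stage="F120"))
        log2 = sub.log2.dropna()
        prof = {r: log2.loc[:, sub.samples(region=r)].mean(axis=1)
                for r in ("CB", "STr", "V1")}
        dab = np.linalg.norm(prof["CB"] - prof["STr"])
        dbc = np.linalg.norm(prof["STr"] - prof["V1"])
        dac = np.linalg.norm(prof["CB"] - prof["V1"])
        assert dac <= dab + dbc + 1e-9


class TestStageCorrelation:
    def test_self_correlation_is_one(self, planted_atlas):
        corr = stage_correlation(planted_atlas.matrix)
        diag = corr[corr["stage_a"] == corr["stage_b"]]
        assert (diag["r"] == 1.0).all()

    def test_anticorrelated_profiles(self):
        specs = [("F50", "PFC"), ("F90", "PFC")]
        m = build_matrix({"P1": [2.0**1, 2.0**3], "P2": [2.0**2, 2.0**2],
                          "P3": [2.0**3, 2.0**1]}, specs)
        corr = stage_correlation(m).set_index(["stage_a", "stage_b"])
        assert corr.loc[("F50", "F90"), "r"] == pytest.approx(-1.0)

    def test_random_walk_stages_make_adjacent_exceed_distant(self):
        rng = np.random.default_rng(4)
        stages = ["F50", "F90", "F120", "P3"]
        specs = [(s, "PFC") for s in stages for _ in range(2)]
        walk = np.cumsum(rng.normal(0, 1.0, size=(100, 4)), axis=1)
        rows = {f"P{i}": (2.0 ** (20 + np.repeat(walk[i], 2))).tolist()
                for i in range(100)}
        m = build_matrix(rows, specs)
        corr = stage_correlation(m).set_index(["stage_a", "stage_b"])["r"]
        adjacent = np.mean([corr[("F50", "F90")], corr[("F90", "F120")],
                            corr[("F120", "P3")]])
        assert adjacent > corr[("F50", "P3")]


class TestPca:
    def test_duplicate_samples_identical_scores(self):
        m = build_matrix({"P1": [2.0, 2.0, 8.0], "P2": [4.0, 4.0, 2.0],
                          "P3": [8.0, 8.0, 4.0]},
                         [("F50", "PFC"), ("F50", "PFC"), ("F50", "V1")])
        scores, _ = pca_scores(m, n_components=2)
        np.testing.assert_allclose(scores.iloc[0], scores.iloc[1], atol=1e-9)

    def test_variance_fractions_valid(self, planted_atlas):
        _, frac = pca_scores(planted_atlas.matrix, n_components=2)
        assert frac.sum() <= 1.0 + 1e-9
        assert frac[0] >= frac[1] >= 0

    def test_dominant_axis_recovered(self):
        rng = np.random.default_rng(6)
        t = rng.normal(0, 3, size=20)  # dominant 1-D structure over samples
        specs = [("F50", "PFC")] * 20
        rows = {}
        direction = rng.normal(0, 1, size=10)
        for i in range(10):
            rows[f"P{i}"] = (2.0 ** (20 + direction[i] * t + rng.normal(0, 0.01, 20))).tolist()
        m = build_matrix(rows, specs)
        scores, frac = pca_scores(m, n_components=2)
        cos = np.corrcoef(scores["PC1"], t)[0, 1]
        assert abs(cos) > 0.99
        assert frac[0] > 0.95

    def test_too_few_complete_proteins_is_error(self):
        m = build_matrix({"P1": [0.0, 2.0], "P2": [1.0, 0.0]},
                         [("F50", "PFC"), ("F50", "V1")])
        with pytest.raises(ValueError, match="complete-case"):
            pca_scores(m, n_components=2)
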