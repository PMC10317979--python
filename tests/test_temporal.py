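"""Emergence calls, rates of change, set trajectories, fuzzy c-means."""

import numpy as np
import pandas as pd
import pytest

from protatlas.core import AnnotationTable, GeneSetCollection
from protatlas.temporal import (
    call_new_proteins,
    fuzzy_cmeans,
    fuzzy_cmeans_trends,
    rate_of_change,
    set_trajectory,
)

from conftest import build_matrix


def _two_stage_matrix(early_vals, late_vals, extra=None):
    n_e, n_l = len(early_vals), len(late_vals)
    specs = [("F120", "V1")] * n_e + [("P3", "V1")] * n_l
    rows = {"P1": list(early_vals) + list(late_vals)}
    if extra:
        rows.update(extra)
    return build_matrix(rows, specs)


class TestNewProteins:
    def test_zero_then_positive_is_new(self):
        m = _two_stage_matrix([0, 0, 0], [64.0, 80.0, 96.0],
                              extra={"P2": [4, 5, 6, 4, 5, 6]})
        calls = call_new_proteins(m, ("F120", "P3")).set_index("protein_id")
        assert calls.loc["P1", "status"] == "new"
        assert calls.loc["P1", "p"] < 0.05 and calls.loc["P1", "fold_change"] > 1

    def test_detected_both_stages_is_continuing(self):
        m = _two_stage_matrix([4, 5, 6], [5, 6, 7])
        calls = call_new_proteins(m, ("F120", "P3")).set_index("protein_id")
        assert calls.loc["P1", "status"] == "continuing"

    def test_never_detected_is_absent(self):
        m = _two_stage_matrix([0, 0, 0], [0, 0, 0], extra={"P2": [1, 2, 3, 1, 2, 3]})
        calls = call_new_proteins(m, ("F120", "P3")).set_index("protein_id")
        assert calls.loc["P1", "status"] == "absent"

    def test_non_adjacent_transition_rejected(self):
        m = _two_stage_matrix([1, 2], [3, 4])
        with pytest.raises(ValueError, match="not adjacent"):
            call_new_proteins(m, ("F50", "P3"))

    def test_calls_anti_monotone_in_alpha(self, planted_atlas):
        m = planted_atlas.matrix
        strict = call_new_proteins(m, ("F120", "P3"), macro_region="CTX", alpha=0.001)
        loose = call_new_proteins(m, ("F120", "P3"), macro_region="CTX", alpha=0.05)
        new_strict = set(strict.loc[strict["status"] == "new", "protein_id"])
        new_loose = set(loose.loc[loose["status"] == "new", "protein_id"])
        assert new_strict <= new_loose

    def test_planted_emergent_recovered(self, planted_atlas):
        m = planted_atlas.matrix
        ledger = planted_atlas.ledger
        planted = set(ledger.loc[(ledger["role"] == "emergent")
                                 & (ledger["class_label"] == "F90->F120"), "protein_id"])
        calls = call_new_proteins(m, ("F90", "F120"), macro_region="CTX")
        new = set(calls.loc[calls["status"] == "new", "protein_id"])
        assert len(planted & new) / len(planted) >= 0.95


class TestRateOfChange:
    def test_equal_means_rate_zero(self):
        m = _two_stage_matrix([4, 8], [8, 4])
        r = rate_of_change(m, ("F120", "P3")).iloc[0]
        assert r["rate_per_day"] == pytest.approx(0.0)

    def test_four_log2_over_forty_days(self):
        specs = [("F50", "PFC")] * 2 + [("F90", "PFC")] * 2
        m = build_matrix({"P1": [2.0**10, 2.0**10, 2.0**14, 2.0**14]}, specs)
        r = rate_of_change(m, ("F50", "F90")).iloc[0]
        assert r["rate_per_day"] == pytest.approx(0.1)

    def test_telescoping_additivity(self, planted_atlas):
        m = planted_atlas.matrix
        deltas = [rate_of_change(m, t, macro_region="CTX").set_index("protein_id")["delta_log2"]
                  for t in (("F50", "F90"), ("F90", "F120"), ("F120", "P3"))]
        total = deltas[0] + deltas[1] + deltas[2]
        log2 = m.log2
        first = np.nanmean(log2.loc[:, m.samples(stage="F50", macro_region="CTX")], axis=1)
        last = np.nanmean(log2.loc[:, m.samples(stage="P3", macro_region="CTX")], axis=1)
        direct = pd.Series(last - first, index=m.proteins)
        ok = total.notna() & direct.notna()
        np.testing.assert_allclose(total[ok], direct[ok], atol=1e-9)


class TestSetTrajectory:
    def _matrix(self):
        rng = np.random.default_rng(9)
        stages = ["F50", "F90", "F120", "P3"]
        specs = [(s, r) for s in stages for r in ("PFC", "V1") for _ in range(3)]
        rows = {}
        for i in range(6):
            vals = []
            for s_i, (s, r) in enumerate(specs):
                up = 1.0 * stages.index(s) if (r == "PFC" and i < 3) else 0.0
                vals.append(2.0 ** (10 + up + rng.normal(0, 0.1)))
            rows[f"P{i}"] = vals
        return build_matrix(rows, specs)

    def _ann_sets(self):
        ann = AnnotationTable(gene_symbol={f"P{i}": f"G{i}" for i in range(6)})
        sets = GeneSetCollection({"UPSET": frozenset({"G0", "G1", "G2"}),
                                  "ONE": frozenset({"G4"})})
        return ann, sets

    def test_single_protein_set_equals_its_stage_means(self):
        m = self._matrix()
        ann, sets = self._ann_sets()
        traj, _ = set_trajectory(m, sets, ann, region="V1")
        one = traj[traj["set_name"] == "ONE"].set_index("stage")["mean_abundance"]
        for s in one.index:
            expected = m.lfq.loc["P4", m.samples(stage=s, region="V1")].mean()
            assert one[s] == pytest.approx(expected)

    def test_planted_regional_increase_significant_only_there(self):
        m = self._matrix()
        ann, sets = self._ann_sets()
        _, seg_pfc = set_trajectory(m, sets, ann, region="PFC")
        _, seg_v1 = set_trajectory(m, sets, ann, region="V1")
        up_pfc = seg_pfc[seg_pfc["set_name"] == "UPSET"]
        up_v1 = seg_v1[seg_v1["set_name"] == "UPSET"]
        assert up_pfc["significant"].any()
        assert not up_v1["significant"].any()

    def test_unmapped_set_skipped_with_warning(self):
        m = self._matrix()
        ann = AnnotationTable(gene_symbol={"P0": "G0"})
        sets = GeneSetCollection({"GHOST": frozenset({"NOPE"})})
        with pytest.warns(UserWarning, match="GHOST"):
            traj, _ = set_trajectory(m, sets, ann)
        assert traj.empty


class TestFuzzyCMeans:
    @staticmethod
    def _archetype_data(n_per=40, noise=0.15, seed=0):
        rng = np.random.default_rng(seed)
        arch = np.array([[-1.2, -0.4, 0.4, 1.2],    # up
                         [1.2, 0.4, -0.4, -1.2],    # down
                         [-1.0, 1.0, 1.0, -1.0],    # up-down
                         [1.0, -1.0, -1.0, 1.0]])   # down-up
        x, labels = [], []
        for k in range(4):
            x.append(arch[k] + rng.normal(0, noise, size=(n_per, 4)))
            labels += [k] * n_per
        return np.vstack(x), np.array(labels)

    def test_memberships_sum_to_one(self):
        x, _ = self._archetype_data()
        _, u, _ = fuzzy_cmeans(x, c=4, seed=1)
        np.testing.assert_allclose(u.sum(axis=1), 1.0, atol=1e-12)

    def test_archetype_recovery_above_90_percent(self):
        x, labels = self._archetype_data()
        _, u, _ = fuzzy_cmeans(x, c=4, seed=1)
        hard = u.argmax(axis=1)
        # best cluster->archetype agreement
        agree = sum((hard[labels == k] == np.bincount(hard[labels == k]).argmax()).sum()
                    for k in range(4))
        assert agree / len(labels) >= 0.9

    def test_objective_monotone_nonincreasing(self):
        x, _ = self._archetype_data(noise=0.4)
        _, _, history = fuzzy_cmeans(x, c=4, seed=2)
        assert all(b <= a + 1e-9 for a, b in zip(history, history[1:]))

    def test_fixed_seed_identical_result(self):
        x, _ = self._archetype_data()
        v1, u1, _ = fuzzy_cmeans(x, c=4, seed=3)
        v2, u2, _ = fuzzy_cmeans(x, c=4, seed=3)
        np.testing.assert_array_equal(u1, u2)

    def test_low_fuzzifier_approaches_kmeans(self):
        # in the m -> 1 limit the update rule hardens to k-means; start both
        # algorithms from the same centroids so the limits are comparable
        from sklearn.cluster import KMeans

        x, _ = self._archetype_data(noise=0.1, seed=4)
        init = x[[0, 40, 80, 120]]
        _, u, _ = fuzzy_cmeans(x, c=4, fuzzifier=1.05, init=init)
        hard = u.argmax(axis=1)
        km = KMeans(n_clusters=4, init=init, n_init=1).fit_predict(x)
        # compare partitions up to label permutation via pairwise co-assignment
        co_f = hard[:, None] == hard[None, :]
        co_k = km[:, None] == km[None, :]
        assert (co_f == co_k).mean() >= 0.98

    def test_trends_on_matrix(self, planted_atlas):
        memb, centroids, history = fuzzy_cmeans_trends(planted_atlas.matrix, seed=0)
        assert centroids.shape[0] == 4
        np.testing.assert_allclose(
            memb[[c for c in memb.columns if c.startswith("cluster_")]].sum(axis=1),
            1.0, atol=1e-9)
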