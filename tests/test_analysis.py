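"""Dissimilarity measures and repeated-measures statistics vs. independent
textbook/brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

import whorfnet as w
from whorfnet import analysis
from whorfnet.analysis import RDM, centrality_rollup, dissim_summary
from whorfnet.protocol import ResponseMatrix


def _response_matrix(omega: np.ndarray, concept_of) -> ResponseMatrix:
    return ResponseMatrix(
        omega=omega, concept_of=np.asarray(concept_of),
        semantic_type="concrete", label="label", subject_seed=0,
    )


def _toy_rdm(matrix: np.ndarray) -> RDM:
    return RDM(matrix=matrix, area="all", meta={})


class TestRDM:
    def test_hand_computed_distances(self):
        omega = np.zeros((3, 12, 625))
        omega[1, 0, 0], omega[1, 0, 1] = 3.0, 4.0  # 3-4-5 triangle vs zeros
        rdm = w.compute_rdm(_response_matrix(omega, [0, 0, 1]), "*A1")
        assert rdm.matrix[0, 1] == pytest.approx(5.0)
        assert rdm.matrix[0, 2] == 0.0  # identical responses
        assert np.allclose(rdm.matrix, rdm.matrix.T)
        assert np.all(np.diag(rdm.matrix) == 0)

    def test_all_areas_concatenation(self):
        omega = np.zeros((2, 12, 625))
        omega[0, 3, 7] = 2.0   # differences in different areas both count
        omega[1, 9, 11] = 1.0
        rdm = w.compute_rdm(_response_matrix(omega, [0, 1]), "all")
        assert rdm.matrix[0, 1] == pytest.approx(np.sqrt(5.0))

    def test_common_cell_permutation_invariance(self, rng):
        omega = rng.random((4, 12, 625))
        perm = rng.permutation(625)
        a = w.compute_rdm(_response_matrix(omega, [0, 0, 1, 1]), "*V1").matrix
        b = w.compute_rdm(
            _response_matrix(omega[:, :, perm], [0, 0, 1, 1]), "*V1"
        ).matrix
        assert np.allclose(a, b)

    def test_unknown_area_rejected(self):
        with pytest.raises(ValueError, match="unknown area"):
            w.compute_rdm(_response_matrix(np.zeros((2, 12, 625)), [0, 1]), "*XX")


class TestDissimSummary:
    def test_toy_two_concept_rdm(self):
        """All within distances 1 and between distances 2 → (1, 2, 1)."""
        m = np.full((6, 6), 2.0)
        for c in (0, 1):
            for i, j in itertools.product(range(3), range(3)):
                m[3 * c + i, 3 * c + j] = 0.0 if i == j else 1.0
        s = dissim_summary(_toy_rdm(m), [0, 0, 0, 1, 1, 1])
        assert (s.dissim_w, s.dissim_b, s.dissim_diff) == (1.0, 2.0, 1.0)

    def test_constant_rdm_has_zero_diff(self):
        m = np.full((6, 6), 3.0)
        np.fill_diagonal(m, 0.0)
        s = dissim_summary(_toy_rdm(m), [0, 0, 0, 1, 1, 1])
        assert s.dissim_diff == 0.0

    def test_pair_counts_for_full_design(self):
        """10 concepts × 3 instances: 30 within pairs and 405 between."""
        concept_of = np.repeat(np.arange(10), 3)
        iu, same = analysis._pair_masks(concept_of)
        assert int(same.sum()) == 30
        assert int((~same).sum()) == 405

    def test_brute_force_equivalence(self, rng):
        """Means equal a per-pair python loop on a random symmetric matrix."""
        m = rng.random((30, 30))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        concept_of = np.repeat(np.arange(10), 3)
        s = dissim_summary(_toy_rdm(m), concept_of)
        within, between = [], []
        for i in range(30):
            for j in range(i + 1, 30):
                (within if concept_of[i] == concept_of[j] else between).append(m[i, j])
        assert s.dissim_w == pytest.approx(np.mean(within))
        assert s.dissim_b == pytest.approx(np.mean(between))

    def test_invariant_under_concept_relabeling(self, rng):
        m = rng.random((12, 12))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        base = dissim_summary(_toy_rdm(m), [0, 0, 0, 1, 1, 1, 2, 2, 2, 3, 3, 3])
        relab = dissim_summary(_toy_rdm(m), [3, 3, 3, 0, 0, 0, 2, 2, 2, 1, 1, 1])
        assert base == relab

    def test_permutation_null_centres_on_zero(self, rng):
        m = rng.random((12, 12))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        null = analysis.dissim_diff_permutation_null(
            _toy_rdm(m), np.repeat(np.arange(4), 3), n_perm=600, rng=rng
        )
        # null DissimDiff values average to ~0 relative to their spread
        assert abs(null.mean()) < 3 * null.std() / np.sqrt(null.size)

    def test_malformed_map_rejected(self):
        with pytest.raises(ValueError, match="concept_map"):
            dissim_summary(_toy_rdm(np.zeros((6, 6))), [0, 0, 1])


def _summary_frame() -> pd.DataFrame:
    """Fabricated two-subject summary with a known label effect."""
    rows = []
    for subj in (0, 1):
        for sem in ("concrete", "abstract"):
            for area in ("*V1", "*M1_L", "*AT", "*PF_L"):
                base = 2.0 + subj
                rows.append((subj, sem, "no-label", area, 1.0, base, base - 1.0))
                rows.append((subj, sem, "label", area, 0.5, 1.5 * base, 1.5 * base - 0.5))
    return pd.DataFrame(
        rows, columns=["subject", "semantic_type", "label", "area",
                       "dissim_w", "dissim_b", "dissim_diff"],
    )


class TestLabelEffect:
    def test_percentage_change_arithmetic(self):
        eff = analysis.label_effect(_summary_frame(), "dissim_b")
        assert np.allclose(eff["effect_pct"], 50.0)  # 1.5× baseline → +50%
        eff_w = analysis.label_effect(_summary_frame(), "dissim_w")
        assert np.allclose(eff_w["effect_pct"], -50.0)

    def test_equal_conditions_give_zero(self):
        df = _summary_frame()
        df["dissim_b"] = 1.0
        eff = analysis.label_effect(df, "dissim_b")
        assert np.allclose(eff["effect_pct"], 0.0)

    def test_zero_baseline_excluded_with_warning(self, caplog):
        df = _summary_frame()
        df.loc[(df.subject == 0) & (df.label == "no-label"), "dissim_b"] = 0.0
        with caplog.at_level("WARNING"):
            eff = analysis.label_effect(df, "dissim_b")
        assert 0 not in set(eff["subject"])
        assert "zero no-label baseline" in caplog.text

    def test_aggregate_mean_and_ci(self):
        eff = analysis.label_effect(_summary_frame(), "dissim_b")
        agg = analysis.aggregate_label_effect(eff)
        assert np.allclose(agg["mean_pct"], 50.0)
        assert np.all(agg["ci95_lo"] <= agg["mean_pct"])


def _rm_anova_oracle_2x2(table: pd.DataFrame) -> dict[str, tuple[float, float]]:
    """Textbook within-subject 2×2 ANOVA from marginal means (independent of
    the pipeline implementation)."""
    wide = table.pivot_table(index="subject", columns=["A", "B"], values="value")
    n = wide.shape[0]
    out = {}
    a_diff = wide.xs("a1", axis=1, level="A").mean(axis=1) - wide.xs(
        "a2", axis=1, level="A"
    ).mean(axis=1)
    b_diff = wide.xs("b1", axis=1, level="B").mean(axis=1) - wide.xs(
        "b2", axis=1, level="B"
    ).mean(axis=1)
    inter = (
        wide[("a1", "b1")] - wide[("a1", "b2")] - wide[("a2", "b1")] + wide[("a2", "b2")]
    )
    # for a two-level within factor, F = t² of the paired contrast
    for name, d in (("A", a_diff), ("B", b_diff), ("A:B", inter / 2)):
        t = d.mean() / (d.std(ddof=1) / np.sqrt(n))
        out[name] = t**2
    return out


class TestRmAnova:
    def _table(self, rng) -> pd.DataFrame:
        rows = []
        for subj in range(4):
            for a in ("a1", "a2"):
                for b in ("b1", "b2"):
                    rows.append((subj, a, b, rng.normal(loc=(a == "a1") * 1.5)))
        return pd.DataFrame(rows, columns=["subject", "A", "B", "value"])

    def test_matches_textbook_oracle(self, rng):
        table = self._table(rng)
        got = w.rm_anova(table, ["A", "B"])
        expected = _rm_anova_oracle_2x2(table)
        for effect, f_expected in expected.items():
            f_got = float(got.loc[got.effect == effect, "F"].iloc[0])
            assert f_got == pytest.approx(f_expected, rel=1e-8)
        assert (got["df_num"] == 1).all()
        assert (got["df_den"] == 3).all()

    def test_shift_and_subject_relabel_invariance(self, rng):
        table = self._table(rng)
        base = w.rm_anova(table, ["A", "B"])["F"].to_numpy()
        shifted = table.assign(value=table.value + 11.0)
        assert np.allclose(w.rm_anova(shifted, ["A", "B"])["F"], base)
        relabeled = table.assign(subject=table.subject.map({0: 3, 1: 2, 2: 1, 3: 0}))
        assert np.allclose(w.rm_anova(relabeled, ["A", "B"])["F"], base)

    def test_three_factor_design_runs(self, rng):
        rows = []
        for subj in range(4):
            for a in "xy":
                for b in "xy":
                    for d in "xy":
                        rows.append((subj, a, b, d, rng.normal()))
        table = pd.DataFrame(rows, columns=["subject", "A", "B", "D", "value"])
        got = w.rm_anova(table, ["A", "B", "D"])
        assert len(got) == 7  # 3 mains + 3 two-way + 1 three-way
        assert (got["F"] >= 0).all()

    def test_missing_cells_rejected(self, rng):
        table = self._table(rng).iloc[:-1]
        with pytest.raises(ValueError, match="unbalanced|missing"):
            w.rm_anova(table, ["A", "B"])


class TestPosthoc:
    def test_identical_samples(self):
        out = w.posthoc_paired_tests({"same": (np.ones(5), np.ones(5))})
        row = out.iloc[0]
        assert row.t == 0.0 and row.p_raw == 1.0 and row.p_bonferroni == 1.0

    def test_hand_computed_t_and_bonferroni(self):
        a = np.array([2.0, 3.0, 4.0, 5.0])
        b = np.array([1.0, 1.5, 2.0, 2.5])
        d = a - b
        t_expected = d.mean() / (d.std(ddof=1) / 2.0)
        out = w.posthoc_paired_tests({"c1": (a, b), "c2": (a, a + 1)})
        row = out.set_index("contrast").loc["c1"]
        assert row.t == pytest.approx(t_expected)
        assert row.p_bonferroni == pytest.approx(min(1.0, row.p_raw * 2))

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="paired samples"):
            w.posthoc_paired_tests({"bad": (np.array([1.0]), np.array([2.0]))})


class TestCentralityRollup:
    def test_means_over_the_documented_areas(self):
        df = _summary_frame()
        df.loc[df.area == "*V1", "dissim_diff"] = 1.0
        df.loc[df.area == "*M1_L", "dissim_diff"] = 3.0
        df.loc[df.area == "*AT", "dissim_diff"] = 5.0
        df.loc[df.area == "*PF_L", "dissim_diff"] = 7.0
        roll = centrality_rollup(df)
        prim = roll[roll.centrality == "primary"]["dissim_diff"]
        cent = roll[roll.centrality == "central"]["dissim_diff"]
        assert np.allclose(prim, 2.0)  # mean of *V1 and *M1_L only
        assert np.allclose(cent, 6.0)

    def test_swapping_central_areas_is_invariant(self):
        df = _summary_frame()
        swapped = df.copy()
        swapped.loc[df.area == "*AT", "area"] = "*tmp"
        swapped.loc[df.area == "*PF_L", "area"] = "*AT"
        swapped.loc[swapped.area == "*tmp", "area"] = "*PF_L"
        a = centrality_rollup(df).sort_values(
            ["subject", "semantic_type", "label", "centrality"]
        )
        b = centrality_rollup(swapped).sort_values(
            ["subject", "semantic_type", "label", "centrality"]
        )
        assert np.allclose(a["dissim_diff"], b["dissim_diff"])

    def test_missing_area_rejected(self):
        df = _summary_frame()
        with pytest.raises(ValueError, match="missing areas"):
            centrality_rollup(df[df.area != "*AT"])


class TestCollapse:
    def test_collapsed_diff_equals_mean_of_per_area_diffs(self):
        df = _summary_frame()
        coll = analysis.collapse_areas(df)
        for _, row in coll.iterrows():
            sub = df[
                (df.subject == row.subject)
                & (df.semantic_type == row.semantic_type)
                & (df.label == row.label)
            ]
            assert row.dissim_diff == pytest.approx(sub.dissim_diff.mean())
            assert row.dissim_diff == pytest.approx(row.dissim_b - row.dissim_w)
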