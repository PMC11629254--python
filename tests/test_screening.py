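"""Volcano statistics, VIP intersection, marker panel and null behaviour."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lipidauth import synthetic_data as sd
from lipidauth.screening import (
    ScreeningResult,
    ScreeningThresholds,
    fold_change,
    intersect_panel,
    screen_part,
    t_test,
    volcano_select,
)
from tests.conftest import make_table, two_group_table


class TestTTest:
    def test_identical_groups_p_one(self):
        table = make_table(np.ones((8, 2)), ["NX"] * 4 + ["GS"] * 4, ["LT"] * 8)
        p = t_test(table)
        assert (p == 1.0).all()

    def test_separated_groups_tiny_p(self):
        rng = np.random.default_rng(0)
        table = two_group_table(rng, n_nx=6, n_non=6, n_lipids=1, shift=[10.0])
        assert t_test(table)["L1"] < 1e-6

    def test_matches_exhaustive_permutation_oracle(self):
        """Welch p on a 4-vs-4 toy agrees with the exact permutation p of the
        t statistic within the resolution of 70 permutations."""
        a = np.array([3.1, 4.2, 2.8, 3.9])
        b = np.array([5.0, 6.1, 5.7, 4.9])
        table = make_table(
            np.r_[a, b][:, None], ["NX"] * 4 + ["GS"] * 4, ["LT"] * 8
        )
        p_welch = t_test(table)["L1"]

        def welch_t(x, y):
            vx, vy = x.var(ddof=1), y.var(ddof=1)
            return (x.mean() - y.mean()) / np.sqrt(vx / 4 + vy / 4)

        pooled = np.r_[a, b]
        t_obs = abs(welch_t(a, b))
        count = 0
        combos = list(itertools.combinations(range(8), 4))
        for idx in combos:
            mask = np.zeros(8, bool)
            mask[list(idx)] = True
            count += abs(welch_t(pooled[mask], pooled[~mask])) >= t_obs - 1e-12
        p_perm = count / len(combos)
        assert abs(p_welch - p_perm) < 0.05

    def test_zero_variance_different_means(self):
        values = np.r_[np.full(4, 1.0), np.full(4, 2.0)][:, None]
        table = make_table(values, ["NX"] * 4 + ["GS"] * 4, ["LT"] * 8)
        assert t_test(table)["L1"] < 1e-12 or t_test(table)["L1"] == np.finfo(float).tiny


class TestFoldChange:
    def test_published_car1_arithmetic(self):
        """Pooled non-NX over NX mean for the leading carnitine: 0.193,
        below the down-regulation cut of 0.25."""
        values = np.r_[np.full(6, 7.51e5), np.full(12, 1.45e5)][:, None]
        table = make_table(values, ["NX"] * 6 + ["GS"] * 6 + ["IM"] * 6, ["LT"] * 18, ["CAR1"])
        fc = fold_change(table)["CAR1"]
        assert fc == pytest.approx(1.45e5 / 7.51e5, rel=1e-12)
        assert fc == pytest.approx(0.193, abs=5e-4)
        assert fc < 0.25

    def test_equal_means_unity(self):
        table = make_table(np.ones((8, 3)), ["NX"] * 4 + ["IM"] * 4, ["KM"] * 8)
        assert (fold_change(table) == 1.0).all()

    def test_reciprocity_under_contrast_swap(self):
        rng = np.random.default_rng(2)
        table = two_group_table(rng, n_lipids=4, shift=[1.0, 0.0, -1.0, 2.0])
        fc = fold_change(table)
        swapped = make_table(
            table.values(),
            ["GS" if r == "NX" else "NX" for r in table.region],
            list(table.part),
            table.lipid_ids,
        )
        # swapping which group is NX inverts the ratio
        np.testing.assert_allclose(fold_change(swapped) * fc, 1.0, rtol=0.3)

    def test_zero_nx_mean_rejected(self):
        values = np.r_[np.zeros(4), np.ones(4)][:, None]
        table = make_table(values, ["NX"] * 4 + ["GS"] * 4, ["LT"] * 8)
        with pytest.raises(ValueError, match="NX group mean"):
            fold_change(table)


def _result_from(p, fc, vip, part="LT"):
    idx = [f"L{i}" for i in range(len(p))]
    thresholds = ScreeningThresholds()
    df = pd.DataFrame({"p_value": p, "fold_change": fc, "vip": vip}, index=idx)
    direction = pd.Series("none", index=idx)
    direction[(df.fold_change > 4) & (df.p_value < 0.05)] = "up"
    direction[(df.fold_change < 0.25) & (df.p_value < 0.05)] = "down"
    df["direction"] = direction
    df["passes_volcano"] = direction.ne("none")
    df["passes_vip"] = df.vip > 1.6
    df["selected"] = df.passes_volcano & df.passes_vip
    return ScreeningResult(part, df, thresholds)


class TestVolcanoAndPanel:
    def test_rule_application(self):
        res = _result_from(p=[0.04, 0.04, 0.2, 0.01], fc=[5.0, 3.0, 6.0, 0.1], vip=[2, 2, 2, 2])
        up, down = volcano_select(res)
        assert up == {"L0"}  # p=0.04, FC=5
        assert down == {"L3"}
        assert "L1" not in up | down  # FC=3 inside the band
        assert "L2" not in up | down  # p too large

    @settings(max_examples=50, derandomize=True)
    @given(
        p_max=st.floats(0.01, 0.2),
        fc_up=st.floats(1.5, 8.0),
        tighten=st.floats(1.0, 2.0),
    )
    def test_threshold_monotonicity(self, p_max, fc_up, tighten):
        """Relaxing any threshold never shrinks the selected volcano sets."""
        rng = np.random.default_rng(7)
        df = pd.DataFrame(
            {
                "p_value": rng.uniform(0, 1, 60),
                "fold_change": np.exp(rng.normal(0, 2, 60)),
                "vip": rng.uniform(0, 3, 60),
            },
            index=[f"L{i}" for i in range(60)],
        )
        loose = ScreeningThresholds(p_max=p_max, fc_up=fc_up)
        tight = ScreeningThresholds(p_max=p_max / tighten, fc_up=fc_up * tighten)
        up_t, down_t = volcano_select(df, tight)
        up_l, down_l = volcano_select(df, loose)
        assert up_t <= up_l and down_t <= down_l

    def test_intersection_basic(self):
        lt = _result_from([0.01] * 4, [5, 5, 0.1, 5], [2] * 4, part="LT")
        km = _result_from([0.01, 0.5, 0.01, 0.01], [5, 5, 0.1, 5], [2] * 4, part="KM")
        panel = intersect_panel(lt, km)
        assert set(panel.markers) == {"L0", "L2", "L3"}
        assert panel.intersection <= lt.selected and panel.intersection <= km.selected
        assert panel.direction["L2"] == "down"

    def test_direction_conflict_dropped(self):
        lt = _result_from([0.01], [5.0], [2.0], part="LT")
        km = _result_from([0.01], [0.1], [2.0], part="KM")
        with pytest.warns(UserWarning, match="direction conflict"):
            panel = intersect_panel(lt, km)
        assert len(panel) == 0

    def test_disjoint_sets_empty_panel(self):
        lt = _result_from([0.01, 0.9], [5.0, 1.0], [2.0, 0.1], part="LT")
        km = _result_from([0.9, 0.01], [1.0, 5.0], [0.1, 2.0], part="KM")
        assert len(intersect_panel(lt, km)) == 0

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            ScreeningThresholds(p_max=0.0)
        assert ScreeningThresholds(fc_up=4.0).fc_down == 0.25


class TestFullScreen:
    def test_recovers_planted_design(self, screen_lt, screen_km, marker_panel):
        assert len(screen_lt.selected) == 13
        assert len(screen_km.selected) == 28
        assert len(marker_panel) == 11
        assert set(marker_panel.markers) == {f"CAR{i}" for i in range(1, 12)}
        assert all(d == "down" for d in marker_panel.direction.values())

    def test_permuted_labels_yield_nominal_false_rate(self, default_spec):
        """Under label permutation the t-test false-positive fraction stays
        near p_max and the full selection (needing FC > 4 too) is empty or
        nearly so."""
        spec = sd.default_spec(n_background=300, n_qc=0, seed=0)
        table = sd.generate(spec, seed=99)
        sub = table.subset(part="LT", biological_only=True)
        rng = np.random.default_rng(123)
        fracs, n_selected = [], []
        regions = sub.region.to_numpy()
        for _ in range(200):
            perm = make_table(
                sub.values(), rng.permutation(regions), list(sub.part), sub.lipid_ids
            )
            p = t_test(perm)
            fracs.append((p < 0.05).mean())
            fc = fold_change(perm)
            n_selected.append(int(((p < 0.05) & ((fc > 4) | (fc < 0.25))).sum()))
        assert 0.03 <= np.mean(fracs) <= 0.07
        assert np.mean(n_selected) < 1.0

    def test_screen_part_requires_samples(self, default_table):
        with pytest.raises(ValueError):
            screen_part(default_table, "XX")
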