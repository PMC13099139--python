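"""Hit-calling pipeline: aggregation, robust Z stages, replicate
combination, exclusions, phenotypes, concordance and group statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from centroscreen import screen, synth

# fixtures hold non-tested features constant, which legitimately trips the
# zero-spread fallback for those features
pytestmark = pytest.mark.filterwarnings("ignore:.*zero spread.*:UserWarning")


def make_cells(rows):
    """Cell table from (plate, well, replicate, score) tuples; other
    features filled with constants."""
    df = pd.DataFrame(rows, columns=["plate", "well", "replicate", "clustering_score"])
    df["spot_count"] = 46
    df["radial_distance"] = 0.66
    df["nuclear_area"] = 110.0
    df["qc_pass"] = True
    return df


def simple_layout(wells, role="library"):
    return pd.DataFrame(
        {
            "plate": [1] * len(wells),
            "well": wells,
            "role": role,
            "gene": [f"G{i}" for i in range(len(wells))],
        }
    )


class TestAggregateWells:
    def test_arithmetic_mean(self):
        cells = make_cells([(1, "A01", 1, 1.0), (1, "A01", 1, 2.0), (1, "A01", 1, 3.0)])
        layout = simple_layout(["A01"])
        out = screen.aggregate_wells(cells, layout, min_cells=1)
        assert out.loc[0, "mean_clustering_score"] == pytest.approx(2.0)
        assert out.loc[0, "n_cells_pass_qc"] == 3

    def test_no_passing_cells_flagged_unusable(self):
        cells = make_cells([(1, "A01", 1, 1.0)])
        cells["qc_pass"] = False
        out = screen.aggregate_wells(cells, simple_layout(["A01"]))
        assert not out.loc[0, "usable"]
        assert np.isnan(out.loc[0, "mean_clustering_score"])

    def test_qc_failing_cells_do_not_affect_summary(self):
        good = make_cells([(1, "A01", 1, v) for v in (1.0, 2.0, 3.0)])
        bad = make_cells([(1, "A01", 1, 99.0)] * 4)
        bad["qc_pass"] = False
        both = pd.concat([good, bad], ignore_index=True)
        layout = simple_layout(["A01"])
        a = screen.aggregate_wells(good, layout, min_cells=1)
        b = screen.aggregate_wells(both, layout, min_cells=1)
        assert a.loc[0, "mean_clustering_score"] == b.loc[0, "mean_clustering_score"]
        assert a.loc[0, "n_cells_pass_qc"] == b.loc[0, "n_cells_pass_qc"]

    def test_unknown_well_rejected(self):
        cells = make_cells([(1, "Z99", 1, 1.0)])
        with pytest.raises(ValueError, match="Z99"):
            screen.aggregate_wells(cells, simple_layout(["A01"]))


def wells_frame(values, roles=None, plate=1, replicate=1):
    n = len(values)
    roles = roles or ["library"] * n
    return pd.DataFrame(
        {
            "plate": plate,
            "well": [f"A{i + 1:02d}" for i in range(n)],
            "replicate": replicate,
            "role": roles,
            "gene": [f"G{i}" for i in range(n)],
            "n_cells_pass_qc": 100,
            "qc_fail_fraction": 0.05,
            "usable": True,
            "mean_clustering_score": values,
            "mean_spot_count": 46.0,
            "mean_radial_distance": 0.66,
            "mean_nuclear_area": 110.0,
        }
    )


class TestNormalizePlate:
    def test_hand_computed_robust_z(self):
        """Library {1..9}: median 5, MAD 2 -> the well at 9 scores
        (9-5)/(1.4826*2) = 1.349."""
        wells = wells_frame(list(range(1, 10)))
        z = screen.normalize_plate(wells, "clustering")
        assert z.iloc[-1] == pytest.approx((9 - 5) / (1.4826 * 2), abs=1e-3)

    def test_all_equal_falls_back_to_zero(self):
        wells = wells_frame([5.0] * 9)
        with pytest.warns(UserWarning, match="zero spread"):
            z = screen.normalize_plate(wells, "clustering")
        assert (z == 0).all()

    def test_extreme_controls_do_not_shift_library_z(self):
        lib = wells_frame(list(range(1, 10)))
        ctrl = wells_frame([1000.0, -1000.0], roles=["PLK1", "NCAPH2"])
        ctrl["well"] = ["B01", "B02"]
        both = pd.concat([lib, ctrl], ignore_index=True)
        z_alone = screen.normalize_plate(lib, "clustering")
        z_both = screen.normalize_plate(both, "clustering")
        np.testing.assert_allclose(z_both.iloc[:9], z_alone, atol=1e-12)

    def test_too_few_library_wells_rejected(self):
        wells = wells_frame([1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="library wells"):
            screen.normalize_plate(wells, "clustering")


class TestStandardizeReplicate:
    def test_idempotent_on_standardized_single_plate(self):
        rng = np.random.default_rng(0)
        wells = wells_frame(rng.normal(0, 1, 40))
        z1 = screen.normalize_plate(wells, "clustering")
        z2 = screen.standardize_replicate(z1, wells)
        np.testing.assert_allclose(z2, z1, atol=0.15)

    def test_pooled_library_median_is_zero(self):
        rng = np.random.default_rng(1)
        p1 = wells_frame(rng.normal(0, 1, 20), plate=1)
        p2 = wells_frame(rng.normal(3, 1, 20), plate=2)
        wells = pd.concat([p1, p2], ignore_index=True)
        z1 = screen.normalize_plate(wells, "clustering")
        z2 = screen.standardize_replicate(z1, wells)
        assert np.median(z2[wells["role"] == "library"]) == pytest.approx(0.0, abs=1e-12)

    def test_matches_bruteforce_two_stage(self):
        """Straight-line recomputation with literal loops reproduces the
        two-stage Z on a 3-plate replicate."""
        rng = np.random.default_rng(2)
        frames = [wells_frame(rng.normal(i, 1 + i, 30), plate=i + 1) for i in range(3)]
        wells = pd.concat(frames, ignore_index=True)
        z1 = screen.normalize_plate(wells, "clustering")
        z2 = screen.standardize_replicate(z1, wells)

        # independent oracle
        expected = np.empty(len(wells))
        stage1 = np.empty(len(wells))
        for plate in (1, 2, 3):
            idx = wells.index[wells["plate"] == plate]
            vals = wells.loc[idx, "mean_clustering_score"].to_numpy()
            med = np.median(vals)
            mad = np.median(np.abs(vals - med))
            stage1[idx] = (vals - med) / (1.4826 * mad)
        med = np.median(stage1)
        mad = np.median(np.abs(stage1 - med))
        expected = (stage1 - med) / (1.4826 * mad)
        np.testing.assert_allclose(z2.to_numpy(), expected, atol=1e-12)


class TestCombineAndCall:
    def _two_rep_wells(self, z_by_rep):
        frames = []
        for rep, vals in z_by_rep.items():
            f = wells_frame(vals, replicate=rep)
            frames.append(f)
        return pd.concat(frames, ignore_index=True)

    def test_mean_and_sd_arithmetic(self):
        rng = np.random.default_rng(3)
        wells = self._two_rep_wells({1: rng.normal(0, 1, 10), 2: rng.normal(0, 1, 10)})
        wells.loc[(wells["replicate"] == 1) & (wells["well"] == "A01"), "mean_clustering_score"] = 2.0
        wells.loc[(wells["replicate"] == 2) & (wells["well"] == "A01"), "mean_clustering_score"] = 4.0
        wz = wells.copy()
        for feat in ("clustering", "count", "cellnumber", "area"):
            wz[f"z_{feat}"] = 0.0
        wz.loc[(wz["replicate"] == 1) & (wz["well"] == "A01"), "z_clustering"] = 2.0
        wz.loc[(wz["replicate"] == 2) & (wz["well"] == "A01"), "z_clustering"] = 4.0
        out = screen.combine_replicates(wz).set_index("well")
        assert out.loc["A01", "mean_z_clustering"] == pytest.approx(3.0)
        assert out.loc["A01", "sd_z_clustering"] == pytest.approx(np.sqrt(2.0))

    def test_combine_matches_per_gene_loop(self):
        rng = np.random.default_rng(4)
        wells = self._two_rep_wells({1: rng.normal(0, 1, 50), 2: rng.normal(0, 1, 50)})
        wz = screen.compute_well_z(wells)
        out = screen.combine_replicates(wz).set_index("well")
        for well in wz["well"].unique():
            vals = wz.loc[wz["well"] == well, "z_clustering"].to_numpy()
            assert out.loc[well, "mean_z_clustering"] == pytest.approx(vals.mean(), abs=1e-12)
            assert out.loc[well, "sd_z_clustering"] == pytest.approx(vals.std(ddof=1), abs=1e-12)

    def _gene_row(self, **over):
        base = dict(
            plate=1, well="A01", role="library", gene="G1",
            mean_z_clustering=0.0, sd_z_clustering=0.5,
            mean_z_count=0.0, sd_z_count=0.5,
            mean_z_cellnumber=0.0, sd_z_cellnumber=0.5,
            mean_z_area=0.0, sd_z_area=0.5,
            qc_fail_fraction=0.05, incomplete=False,
        )
        base.update(over)
        return pd.DataFrame([base])

    def test_clear_hit_with_direction(self):
        out = screen.call_hits(self._gene_row(mean_z_clustering=3.0))
        assert out.loc[0, "hit"]
        assert out.loc[0, "clustering_direction"] == "clustered"
        assert out.loc[0, "excluded_reason"] == "none"

    def test_cytotoxic_exclusion_beats_hit(self):
        out = screen.call_hits(self._gene_row(mean_z_clustering=-3.0, mean_z_cellnumber=-2.6))
        assert not out.loc[0, "hit"]
        assert out.loc[0, "excluded_reason"] == "cytotoxic"

    def test_cytotoxic_boundary_not_excluded(self):
        out = screen.call_hits(self._gene_row(mean_z_clustering=3.0, mean_z_cellnumber=-2.5))
        assert out.loc[0, "hit"]  # strict inequality: -2.5 does not trigger

    def test_inconsistent_replicates_excluded(self):
        out = screen.call_hits(self._gene_row(mean_z_count=2.6, sd_z_count=3.0))
        assert not out.loc[0, "hit"]
        assert out.loc[0, "excluded_reason"] == "inconsistent"

    def test_threshold_is_strict(self):
        out = screen.call_hits(self._gene_row(mean_z_clustering=2.5))
        assert not out.loc[0, "hit"]

    def test_dysmorphic_excluded_first(self):
        out = screen.call_hits(
            self._gene_row(mean_z_clustering=5.0, mean_z_cellnumber=-5.0, qc_fail_fraction=0.8)
        )
        assert out.loc[0, "excluded_reason"] == "dysmorphic"

    def test_every_gene_exactly_one_reason(self):
        rng = np.random.default_rng(5)
        rows = pd.concat(
            [
                self._gene_row(
                    gene=f"G{i}",
                    well=f"A{i:02d}",
                    mean_z_clustering=rng.normal(0, 3),
                    mean_z_count=rng.normal(0, 3),
                    mean_z_cellnumber=rng.normal(0, 2),
                    sd_z_clustering=abs(rng.normal(0, 2)),
                    sd_z_count=abs(rng.normal(0, 2)),
                    qc_fail_fraction=rng.uniform(0, 1),
                )
                for i in range(60)
            ],
            ignore_index=True,
        )
        out = screen.call_hits(rows)
        assert out["excluded_reason"].isin(
            ["none", "dysmorphic", "cytotoxic", "inconsistent", "incomplete"]
        ).all()
        assert (~out["hit"] | (out["excluded_reason"] == "none")).all()


class TestPhenotype:
    @pytest.mark.parametrize(
        "cd,nd,expected",
        [
            ("clustered", "lower", "higher clustering"),
            ("unclustered", "higher", "dispersion"),
            ("unclustered", "lower", "fewer larger clusters"),
            ("clustered", "none", "clustering-only (clustered)"),
            ("none", "higher", "count-only (higher)"),
        ],
    )
    def test_categories(self, cd, nd, expected):
        call = {"hit": True, "clustering_direction": cd, "count_direction": nd}
        assert screen.classify_phenotype(call) == expected

    def test_non_hit_rejected(self):
        with pytest.raises(ValueError):
            screen.classify_phenotype({"hit": False})


def calls_frame(z_values, hits=None):
    n = len(z_values)
    hits = hits if hits is not None else [False] * n
    return pd.DataFrame(
        {
            "gene": [f"G{i}" for i in range(n)],
            "role": "library",
            "mean_z_clustering": z_values,
            "mean_z_count": 0.0,
            "excluded_reason": "none",
            "hit": hits,
            "clustering_direction": ["clustered" if h else "none" for h in hits],
            "count_direction": "none",
        }
    )


class TestConcordance:
    def test_identical_screens_perfect_correlation(self, rng):
        a = calls_frame(rng.normal(0, 1, 30), hits=[True] * 5 + [False] * 25)
        rep = screen.compare_cell_lines(a, a.copy())
        assert rep.pearson_r == pytest.approx(1.0)
        assert len(rep.common_hits) == 5
        assert (rep.direction_agreement["clustering_agreement"] == "same").all()

    def test_hand_computed_pearson(self):
        za = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        zb = [2.0, 1.0, 4.0, 3.0, 6.0, 5.0]
        a = calls_frame(za)
        b = calls_frame(zb)
        expected = np.corrcoef(za, zb)[0, 1]
        rep = screen.compare_cell_lines(a, b)
        assert rep.pearson_r == pytest.approx(expected)

    def test_independent_null_screens_uncorrelated(self, rng):
        a = calls_frame(rng.normal(0, 1, 1000))
        b = calls_frame(rng.normal(0, 1, 1000))
        rep = screen.compare_cell_lines(a, b)
        assert abs(rep.pearson_r) < 0.1

    def test_disjoint_gene_sets_rejected(self, rng):
        a = calls_frame(rng.normal(0, 1, 5))
        b = calls_frame(rng.normal(0, 1, 5))
        b["gene"] = [f"H{i}" for i in range(5)]
        with pytest.raises(ValueError):
            screen.compare_cell_lines(a, b)


class TestCompareGroups:
    def test_identical_groups_not_significant(self, rng):
        v = rng.normal(0, 1, 100)
        values = np.concatenate([v, v])
        labels = ["a"] * 100 + ["b"] * 100
        for method in ("anova_tukey", "pairwise_t_bonferroni"):
            out = screen.compare_groups(values, labels, method)
            assert out.loc[0, "p_adj"] > 0.9
            assert out.loc[0, "stars"] == ""

    def test_bonferroni_multiplies_raw_p(self, rng):
        values = np.concatenate([rng.normal(i * 0.1, 1, 30) for i in range(4)])
        labels = np.repeat(list("abcd"), 30)
        out = screen.compare_groups(values, labels, "pairwise_t_bonferroni")
        k = 6  # C(4,2) comparisons
        from scipy import stats as ss

        x = values[labels == "a"]
        y = values[labels == "b"]
        _, raw = ss.ttest_ind(x, y, equal_var=False)
        row = out[(out["group1"] == "a") & (out["group2"] == "b")].iloc[0]
        assert row["p_adj"] == pytest.approx(min(1.0, raw * k))

    def test_large_effect_four_stars(self, rng):
        values = np.concatenate([rng.normal(0, 1, 200), rng.normal(2, 1, 200)])
        labels = ["a"] * 200 + ["b"] * 200
        out = screen.compare_groups(values, labels, "pairwise_t_bonferroni")
        assert out.loc[0, "stars"] == "****"

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            screen.compare_groups([1.0, 2.0, 3.0], ["a", "a", "b"])


@settings(derandomize=True, max_examples=15, deadline=None)
@given(st.integers(min_value=0, max_value=10_000))
def test_well_order_invariance(seed):
    """Permuting well rows within a plate changes no Z value or call."""
    rng = np.random.default_rng(seed)
    frames = []
    for rep in (1, 2):
        f = wells_frame(rng.normal(0, 1, 25), replicate=rep)
        frames.append(f)
    wells = pd.concat(frames, ignore_index=True)
    shuffled = wells.sample(frac=1.0, random_state=seed).reset_index(drop=True)
    a = screen.combine_replicates(screen.compute_well_z(wells)).set_index("well").sort_index()
    b = screen.combine_replicates(screen.compute_well_z(shuffled)).set_index("well").sort_index()
    np.testing.assert_allclose(
        a["mean_z_clustering"].to_numpy(), b["mean_z_clustering"].to_numpy(), atol=1e-12
    )
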