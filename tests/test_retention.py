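"""Gene retention rates, pattern filter, R_bw categories, correlations."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import panretain as pr
from panretain.retention import RbwCategory, rbw_table, family_size_table
from panretain.io import HogRecord, PresenceAbsenceMatrix


def make_pav(species, calls):
    calls = np.asarray(calls, dtype=bool)
    return PresenceAbsenceMatrix(
        species=species,
        line_ids=[f"{species}{i}" for i in range(calls.shape[0])],
        gene_ids=[f"{species}_g{j}" for j in range(calls.shape[1])],
        calls=calls,
    )


class TestGrr:
    @pytest.mark.parametrize(
        "present,total,expected",
        [(13, 20, 65.0), (16, 16, 100.0), (2, 16, 12.5), (8, 20, 40.0)],
    )
    def test_worked_examples(self, present, total, expected):
        col = np.array([True] * present + [False] * (total - present))
        assert pr.grr(col) == expected

    def test_empty_column_rejected(self):
        with pytest.raises(ValueError):
            pr.grr(np.array([], dtype=bool))

    @given(st.lists(st.booleans(), min_size=1, max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_scale_free(self, calls):
        """Duplicating every line (present and absent alike) leaves GRR
        unchanged."""
        col = np.array(calls)
        assert pr.grr(np.concatenate([col, col])) == pytest.approx(pr.grr(col))

    def test_exclude_nodata_changes_denominator(self):
        presence = np.array([True, False, False, False])
        nodata = np.array([False, False, True, True])
        assert pr.grr(presence) == 25.0
        assert pr.grr(presence, nodata, exclude_nodata=True) == 50.0

    def test_all_nodata_is_nan(self):
        presence = np.array([False, False])
        nodata = np.array([True, True])
        assert math.isnan(pr.grr(presence, nodata, exclude_nodata=True))


def _random_retention(rng, n_hogs=200, species=("barley", "emmer", "wheat")):
    hogs = [
        HogRecord(f"H{i}", f"O{i % 40}", {sp: [f"{sp}_g{i}"] for sp in species})
        for i in range(n_hogs)
    ]
    pavs = {
        sp: PresenceAbsenceMatrix(
            species=sp,
            line_ids=[f"{sp}{k}" for k in range(20)],
            gene_ids=[f"{sp}_g{i}" for i in range(n_hogs)],
            calls=rng.random((20, n_hogs)) < rng.random(n_hogs)[None, :],
        )
        for sp in species
    }
    return hogs, pavs


class TestPatternFilter:
    def _table_from_grrs(self, rows):
        """rows: hog_id -> (grr per species)."""
        species = ["barley", "emmer", "wheat"]
        data = {}
        for hid, vals in rows.items():
            data[hid] = {
                (sp, "grr"): v for sp, v in zip(species, vals)
            } | {(sp, "n_present"): 0 for sp in species} | {
                (sp, "n_lines"): 20 for sp in species
            }
        frame = pd.DataFrame.from_dict(data, orient="index")
        frame.columns = pd.MultiIndex.from_tuples(frame.columns)
        return pr.RetentionTable(frame, species)

    def test_decreasing_chain_passes(self):
        table = self._table_from_grrs({"H1": (65.0, 40.0, 12.5)})
        out = pr.pattern_filter(table, ["barley", "emmer", "wheat"])
        assert out.hog_ids == ["H1"]

    def test_tie_fails_strict(self):
        table = self._table_from_grrs({"H1": (65.0, 65.0, 12.5)})
        assert pr.pattern_filter(table, ["barley", "emmer", "wheat"]).hog_ids == []

    def test_tie_passes_relaxed(self):
        table = self._table_from_grrs({"H1": (65.0, 65.0, 12.5), "H2": (50.0,) * 3})
        out = pr.pattern_filter(table, ["barley", "emmer", "wheat"], strict=False)
        assert out.hog_ids == ["H1"]

    def test_missing_grr_skipped_and_counted(self):
        table = self._table_from_grrs({"H1": (65.0, math.nan, 12.5)})
        out = pr.pattern_filter(table, ["barley", "emmer", "wheat"])
        assert out.hog_ids == [] and out.n_skipped_missing == 1

    def test_matches_brute_force_on_random_table(self):
        rng = np.random.default_rng(11)
        hogs, pavs = _random_retention(rng)
        table = pr.retention_table(hogs, pavs)
        out = pr.pattern_filter(table, ["barley", "emmer", "wheat"], hogs=hogs)
        # independent brute-force scan over the GRR frame
        g = table.grr_frame()
        expected = [
            hid
            for hid, row in g.iterrows()
            if row["barley"] > row["emmer"] > row["wheat"]
        ]
        assert sorted(out.hog_ids) == sorted(expected)

    def test_invariant_under_row_permutation(self):
        rng = np.random.default_rng(5)
        hogs, pavs = _random_retention(rng, n_hogs=60)
        table = pr.retention_table(hogs, pavs)
        base = set(pr.pattern_filter(table, ["barley", "emmer", "wheat"]).hog_ids)
        shuffled = pr.RetentionTable(
            table.data.sample(frac=1.0, random_state=3), table.species
        )
        assert set(pr.pattern_filter(shuffled, ["barley", "emmer", "wheat"]).hog_ids) == base


class TestRbw:
    @pytest.mark.parametrize(
        "a,b,category,ratio",
        [
            (65.0, 12.5, RbwCategory.BARLEY_PREFERENTIAL, 5.2),
            (50.0, 50.0, RbwCategory.NEUTRAL, 1.0),
            (42.5, 50.0, RbwCategory.UNASSIGNED, 0.85),  # cutoff gap
            (55.0, 50.0, RbwCategory.UNASSIGNED, 1.1),   # other gap
            (40.0, 50.0, RbwCategory.WHEAT_PREFERENTIAL, 0.8),
            (60.0, 50.0, RbwCategory.BARLEY_PREFERENTIAL, 1.2),
        ],
    )
    def test_category_boundaries(self, a, b, category, ratio):
        rec = pr.rbw_categorize(a, b)
        assert rec.category is category
        assert rec.r_bw == pytest.approx(ratio)

    def test_lost_in_wheat_is_extreme_barley_preference(self):
        rec = pr.rbw_categorize(30.0, 0.0)
        assert rec.category is RbwCategory.BARLEY_PREFERENTIAL
        assert math.isinf(rec.r_bw)

    def test_both_zero_undefined(self):
        assert pr.rbw_categorize(0.0, 0.0).category is RbwCategory.UNDEFINED

    def test_negative_grr_rejected(self):
        with pytest.raises(ValueError):
            pr.rbw_categorize(-1.0, 5.0)

    def test_categories_partition_defined_hogs(self):
        rng = np.random.default_rng(2)
        hogs, pavs = _random_retention(rng, n_hogs=150)
        table = pr.retention_table(hogs, pavs)
        rbw = rbw_table(table, "barley", "wheat")
        g = table.grr_frame()
        n_defined = int((g["barley"].notna() & g["wheat"].notna()).sum())
        assert len(rbw) == n_defined
        assert rbw["category"].isin([c.value for c in RbwCategory]).all()


class TestPearsonAndFamilySize:
    def test_retention_copy_number_example(self):
        assert pr.pearson([1, 2, 3], [0.65, 0.40, 0.125]) == pytest.approx(
            -0.9996, abs=5e-5
        )

    def test_perfect_anticorrelation(self):
        x = np.arange(5.0)
        assert pr.pearson(x, -x) == pytest.approx(-1.0)

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(size=100), rng.normal(size=100)
        manual = ((x - x.mean()) * (y - y.mean())).sum() / (
            np.sqrt(((x - x.mean()) ** 2).sum()) * np.sqrt(((y - y.mean()) ** 2).sum())
        )
        assert pr.pearson(x, y) == pytest.approx(manual, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            pr.pearson([1, 1, 1], [1, 2, 3])

    def test_linear_mean_grr_gives_minus_one(self):
        hogs = []
        pavs_calls = []
        # family sizes 1..4, mean GRR exactly linear decreasing: 80,70,60,50
        species = "barley"
        gene_ids, cols = [], []
        for og, (size, grr_val) in enumerate(zip([1, 2, 3, 4], [16, 14, 12, 10])):
            for h in range(size):
                hid = f"O{og}.H{h}"
                gid = f"g_{og}_{h}"
                hogs.append(HogRecord(hid, f"O{og}", {species: [gid]}))
                gene_ids.append(gid)
                cols.append([True] * grr_val + [False] * (20 - grr_val))
        pav = PresenceAbsenceMatrix(
            species=species,
            line_ids=[f"L{i}" for i in range(20)],
            gene_ids=gene_ids,
            calls=np.array(cols).T,
        )
        table = pr.retention_table(hogs, {species: pav})
        res = pr.family_size_correlation(table, hogs, species)
        assert res.correlation == pytest.approx(-1.0)
        assert res.slope == pytest.approx(-10.0)  # GRR drops 10 points per HOG

    def test_single_og_errors(self):
        hogs = [HogRecord("H1", "O1", {"barley": ["g1"]})]
        pav = make_pav("barley", np.ones((4, 1)))
        pav.gene_ids = ["g1"]
        table = pr.retention_table(hogs, {"barley": pav})
        with pytest.raises(ValueError):
            pr.family_size_correlation(table, hogs, "barley")

    def test_matches_brute_force_on_synthetic_dosage_panel(self):
        hogs, pavs, _ = pr.gen_pangenome(n_ogs=150, seed=21)
        table = pr.retention_table(hogs, pavs)
        res = pr.family_size_correlation(table, hogs, "wheat")
        per_og = family_size_table(table, hogs, "wheat")
        x = per_og["family_size"].to_numpy(float)
        y = per_og["mean_grr"].to_numpy(float)
        manual = ((x - x.mean()) * (y - y.mean())).sum() / (
            np.sqrt(((x - x.mean()) ** 2).sum()) * np.sqrt(((y - y.mean()) ** 2).sum())
        )
        assert res.correlation == pytest.approx(manual, abs=1e-12)
        assert res.correlation < 0


class TestTpmTransform:
    @pytest.mark.parametrize("tpm,expected", [(0.99, 0.0), (99.99, 2.0), (0.0, -2.0)])
    def test_log10_offset(self, tpm, expected):
        assert pr.tpm_log_transform([tpm])[0] == pytest.approx(expected)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            pr.tpm_log_transform([-0.1])
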