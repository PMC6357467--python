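"""Fisher region enrichment, BH, co-occurrence, gene sets, promoter screen."""

from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

from dmrkit.enrichment import (
    celltype_promoter_screen,
    enrichment_panel,
    fisher_region_enrichment,
    gene_set_overlap,
    tf_cooccurrence,
)
from dmrkit.io import MethylationMatrix
from dmrkit.regions import RegionSet


def _tiles(n, start=0, spacing=1000, width=500, chrom="chr1", name=""):
    rows = [(chrom, start + i * spacing, start + i * spacing + width) for i in range(n)]
    return RegionSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]), name=name)


def _fisher_two_sided_oracle(a, b, c, d):
    """Exhaustive hypergeometric enumeration of all tables with the observed
    margins; two-sided p sums probabilities <= that of the observed table."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    probs = {}
    for x in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        probs[x] = comb(col1, x) * comb(n - col1, row1 - x) / comb(n, row1)
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9))


class TestFisherRegionEnrichment:
    def test_odds_ratio_arithmetic(self):
        # a=8, b=2 / c=10, d=40 -> OR 16
        query = _tiles(10)
        ann_rows = query.df.iloc[:8]
        background = _tiles(50, start=100_000)
        ann = RegionSet(
            pd.concat([ann_rows, background.df.iloc[:10]]), name="ann"
        )
        res = fisher_region_enrichment(query, background, ann)
        assert (res.a, res.b, res.c, res.d) == (8, 2, 10, 40)
        assert res.odds_ratio == pytest.approx(16.0)
        assert res.fraction_query_overlapping == pytest.approx(0.8)

    def test_matched_overlap_rates_are_null(self):
        query = _tiles(20)
        background = _tiles(20, start=200_000)
        ann = RegionSet(pd.concat([query.df.iloc[:10], background.df.iloc[:10]]), name="ann")
        res = fisher_region_enrichment(query, background, ann)
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p >= 0.5

    def test_empty_universe_rejected(self):
        q = _tiles(3)
        with pytest.raises(ValueError, match="non-empty"):
            fisher_region_enrichment(q, RegionSet(pd.DataFrame(columns=["chrom", "start", "end"])), q)

    def test_shared_regions_rejected(self):
        q = _tiles(5)
        with pytest.raises(ValueError, match="disjoint"):
            fisher_region_enrichment(q, q, q)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 25), st.integers(0, 25), st.integers(0, 60), st.integers(0, 60))
    def test_p_matches_enumeration_oracle(self, a, b, c, d):
        if a + b == 0 or c + d == 0:
            return
        query = _tiles(a + b)
        background = _tiles(c + d, start=10_000_000)
        ann = RegionSet(
            pd.concat([query.df.iloc[:a], background.df.iloc[:c]])
            if a + c
            else pd.DataFrame({"chrom": ["chr9"], "start": [0], "end": [1]}),
            name="ann",
        )
        res = fisher_region_enrichment(query, background, ann)
        assert (res.a, res.c) == (a, c)
        assert res.p == pytest.approx(_fisher_two_sided_oracle(a, b, c, d), abs=1e-9)


def _bh_oracle(ps):
    """Step-up BH from its definition."""
    m = len(ps)
    order = np.argsort(ps, kind="mergesort")
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, ps[i] * m / rank)
        q[i] = prev
    return q


class TestPanelAndBH:
    def test_four_equal_spaced_ps(self):
        np.testing.assert_allclose(
            multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1], [0.04] * 4
        )

    def test_single_annotation_q_equals_p(self):
        query = _tiles(10)
        background = _tiles(30, start=500_000)
        ann = {"only": RegionSet(query.df.iloc[:6], name="only")}
        panel = enrichment_panel(query, background, ann)
        assert panel.iloc[0]["q"] == pytest.approx(panel.iloc[0]["p"])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40))
    def test_bh_matches_step_up_oracle(self, ps):
        got = multipletests(ps, method="fdr_bh")[1]
        np.testing.assert_allclose(got, _bh_oracle(np.asarray(ps)), atol=1e-12)

    def test_panel_q_monotone_in_sorted_p(self):
        rng = np.random.default_rng(0)
        query = _tiles(30)
        background = _tiles(60, start=1_000_000)
        coll = {}
        for k in range(6):
            pick = rng.random(30) < rng.uniform(0.1, 0.9)
            rows = pd.concat([query.df[pick], background.df[rng.random(60) < 0.3]])
            if rows.empty:
                rows = pd.DataFrame({"chrom": ["chr9"], "start": [0], "end": [1]})
            coll[f"ann{k}"] = RegionSet(rows, name=f"ann{k}")
        panel = enrichment_panel(query, background, coll).sort_values("p")
        assert panel["q"].is_monotonic_increasing


class TestCooccurrence:
    def test_region_overlapping_both_sets_counts_once(self):
        query = _tiles(3)
        peaks = {
            "A": RegionSet(query.df.iloc[[0]], name="A"),
            "B": RegionSet(query.df.iloc[[0, 1]], name="B"),
        }
        member, all_count, pairwise = tf_cooccurrence(query, peaks)
        assert all_count == 1
        assert member["A"].tolist() == [True, False, False]
        assert pairwise.iloc[0]["both"] == 1

    def test_disjoint_peak_sets_give_zero_all_factor_count(self):
        query = _tiles(4)
        peaks = {
            "A": RegionSet(query.df.iloc[[0]], name="A"),
            "B": RegionSet(query.df.iloc[[1]], name="B"),
        }
        _, all_count, _ = tf_cooccurrence(query, peaks)
        assert all_count == 0

    def test_counts_sum_to_query_size(self):
        rng = np.random.default_rng(1)
        query = _tiles(20)
        peaks = {
            f"f{k}": RegionSet(query.df[rng.random(20) < 0.5].reset_index(drop=True)
                               if (rng.random(20) < 0.5).any()
                               else pd.DataFrame({"chrom": ["chr9"], "start": [0], "end": [1]}),
                               name=f"f{k}")
            for k in range(4)
        }
        member, _, _ = tf_cooccurrence(query, peaks)
        combos = member.value_counts()
        assert combos.sum() == len(query)


class TestGeneSetOverlap:
    def test_total_overlap_closed_form(self):
        universe = {f"g{i}" for i in range(10)}
        genes = {f"g{i}" for i in range(5)}
        x, p = gene_set_overlap(genes, genes, universe)
        assert x == 5
        assert p == pytest.approx(1 / comb(10, 5))

    def test_zero_overlap_has_unit_p(self):
        universe = {f"g{i}" for i in range(10)}
        x, p = gene_set_overlap({"g0", "g1"}, {"g8", "g9"}, universe)
        assert x == 0 and p == pytest.approx(1.0)

    def test_subset_requirement(self):
        with pytest.raises(ValueError):
            gene_set_overlap({"zz"}, {"g1"}, {"g1", "g2"})

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(2, 30), st.data())
    def test_matches_enumeration_oracle(self, n_universe, data):
        ka = data.draw(st.integers(0, n_universe))
        kb = data.draw(st.integers(0, n_universe))
        universe = [f"g{i}" for i in range(n_universe)]
        rng = np.random.default_rng(ka * 31 + kb)
        genes_a = set(rng.choice(universe, size=ka, replace=False))
        genes_b = set(rng.choice(universe, size=kb, replace=False))
        x, p = gene_set_overlap(genes_a, genes_b, set(universe))
        # enumeration: P(X >= x) over all B draws of size kb
        total = comb(n_universe, kb)
        expect = sum(
            comb(ka, y) * comb(n_universe - ka, kb - y)
            for y in range(x, min(ka, kb) + 1)
        ) / total if total else 1.0
        assert p == pytest.approx(min(1.0, expect), abs=1e-9)


class TestCelltypePromoterScreen:
    @staticmethod
    def _matrix_with_groups(rng, n_cpg=60, shift=0.0):
        pos = np.arange(n_cpg) * 400
        total = rng.integers(8, 20, size=(n_cpg, 8))
        base = rng.uniform(0.3, 0.7, size=n_cpg)
        probs = np.tile(base[:, None], (1, 8)).astype(float)
        probs[:, :4] = np.clip(probs[:, :4] + shift, 0.01, 0.99)
        meth = rng.binomial(total, probs)
        samples = [f"WD{i}" for i in range(4)] + [f"HC{i}" for i in range(4)]
        m = MethylationMatrix(
            chrom=np.array(["chr1"] * n_cpg, dtype=object), pos=pos,
            meth=meth, total=total, samples=samples,
        )
        sheet = pd.DataFrame({"sample": samples, "group": ["WD"] * 4 + ["HC"] * 4})
        return m, sheet

    def test_disjoint_promoters_overlap_fraction_zero(self):
        rng = np.random.default_rng(2)
        m, sheet = self._matrix_with_groups(rng)
        dmrs = RegionSet(pd.DataFrame({"chrom": ["chr2"], "start": [0], "end": [100]}))
        proms = {"HEP": _tiles(5, name="HEP")}
        overlap, _ = celltype_promoter_screen(m, dmrs, proms, sheet, "WD", "HC")
        assert overlap.iloc[0]["dmr_overlap_fraction"] == 0.0

    def test_welch_statistic_matches_closed_form(self):
        rng = np.random.default_rng(3)
        m, sheet = self._matrix_with_groups(rng)
        proms = {"HEP": _tiles(2, width=900, spacing=8000, name="HEP")}
        _, tests = celltype_promoter_screen(m, proms["HEP"], proms, sheet, "WD", "HC")
        from dmrkit.calling import region_sample_methylation
        from scipy import stats as sps

        table = region_sample_methylation(m, proms["HEP"])
        for i, (_, row) in enumerate(tests.iterrows()):
            ya = table.iloc[i, :4].to_numpy()
            yb = table.iloc[i, 4:].to_numpy()
            t, p = sps.ttest_ind(ya, yb, equal_var=False)
            assert row["t"] == pytest.approx(t) and row["p"] == pytest.approx(p)

    def test_identical_groups_near_nominal_rate(self):
        rng = np.random.default_rng(4)
        rates = []
        for rep in range(8):
            m, sheet = self._matrix_with_groups(rng, n_cpg=200)
            proms = {"HEP": _tiles(40, width=300, spacing=2000, name="HEP")}
            overlap, _ = celltype_promoter_screen(
                m, proms["HEP"], proms, sheet, "WD", "HC"
            )
            rates.append(overlap.iloc[0]["fraction_nominal_p05"])
        assert np.mean(rates) < 0.15  # ~5% type-I target, generous MC margin
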