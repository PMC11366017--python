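import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import epiage as ea
from epiage.selection import rank_associations

from conftest import make_bulk


def hand_spearman(x, y):
    """Textbook formula 1 - 6*sum(d^2)/(n(n^2-1)); valid without ties."""
    rx = np.argsort(np.argsort(x)) + 1
    ry = np.argsort(np.argsort(y)) + 1
    d = rx - ry
    n = len(x)
    return 1 - 6 * np.sum(d**2) / (n * (n**2 - 1))


class TestSpearman:
    def test_perfect_monotone(self):
        assert ea.spearman_age_correlation([1, 2, 3], [0.1, 0.2, 0.3]) == pytest.approx(1.0)

    def test_hand_formula_example(self):
        rho = ea.spearman_age_correlation([1, 2, 3, 4], [0.4, 0.1, 0.3, 0.2])
        assert rho == pytest.approx(-0.4)

    def test_constant_methylation_is_missing(self):
        assert np.isnan(ea.spearman_age_correlation([1, 2, 3], [0.5, 0.5, 0.5]))

    def test_constant_age_is_missing(self):
        assert np.isnan(ea.spearman_age_correlation([2, 2, 2], [0.1, 0.5, 0.9]))

    def test_fewer_than_three_pairs_is_missing(self):
        assert np.isnan(ea.spearman_age_correlation([1, 2], [0.1, 0.2]))
        assert np.isnan(
            ea.spearman_age_correlation([1, 2, 3], [0.1, np.nan, 0.2]))

    def test_matches_hand_rank_formula_on_random_vectors(self):
        rng = np.random.default_rng(123)
        for _ in range(1000):
            n = rng.integers(3, 13)
            x = rng.permutation(n).astype(float)
            y = rng.standard_normal(n)  # continuous: no ties a.s.
            assert ea.spearman_age_correlation(x, y) == pytest.approx(
                hand_spearman(x, y), abs=1e-12)


class TestCombineAssociations:
    def test_same_sign_mean(self):
        mean_rho, ok = ea.combine_associations({"A": 0.5, "B": 0.3})
        assert ok and mean_rho == pytest.approx(0.4)

    def test_inconsistent_signs_flagged(self):
        _, ok = ea.combine_associations({"A": 0.5, "B": -0.2})
        assert not ok

    def test_missing_dataset_ignored(self):
        mean_rho, ok = ea.combine_associations({"A": 0.5, "B": float("nan")})
        assert ok and mean_rho == pytest.approx(0.5)

    def test_zero_is_sign_neutral(self):
        _, ok = ea.combine_associations({"A": 0.5, "B": 0.0})
        assert ok

    def test_advisory_dataset_filters_sign_but_not_mean(self):
        mean_rho, ok = ea.combine_associations({"A": 0.5, "PB": -0.2},
                                               advisory_ids=("PB",))
        assert not ok
        mean_rho, ok = ea.combine_associations({"A": 0.5, "PB": 0.9},
                                               advisory_ids=("PB",))
        assert ok and mean_rho == pytest.approx(0.5)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(min_value=-1, max_value=1), min_size=1, max_size=6))
    def test_permutation_invariant(self, rhos):
        d1 = {f"D{i}": r for i, r in enumerate(rhos)}
        d2 = dict(reversed(list(d1.items())))
        m1, s1 = ea.combine_associations(d1)
        m2, s2 = ea.combine_associations(d2)
        assert s1 == s2 and m1 == pytest.approx(m2, abs=1e-12)


def ranked_frame(entries):
    """entries: list of (chrom, pos, mean_rho)."""
    idx = pd.MultiIndex.from_tuples([(c, p) for c, p, _ in entries],
                                    names=("chrom", "pos"))
    df = pd.DataFrame({"mean_rho": [r for _, _, r in entries],
                       "sign_consistent": True}, index=idx)
    return rank_associations(df)


class TestPruneSites:
    def test_nearby_similar_site_becomes_backup(self):
        ranked = ranked_frame([("chr1", 100, 0.80), ("chr1", 3000, 0.75),
                               ("chr1", 10000, 0.70)])
        sel = ea.prune_sites(ranked)
        assert sel.main_sites == [("chr1", 100), ("chr1", 10000)]
        assert sel.backups[("chr1", 100)] == [("chr1", 3000)]

    def test_outside_window_both_main(self):
        ranked = ranked_frame([("chr1", 100, 0.80), ("chr1", 6100, 0.79)])
        sel = ea.prune_sites(ranked)
        assert len(sel.main_sites) == 2

    def test_large_rho_delta_both_main(self):
        ranked = ranked_frame([("chr1", 100, 0.80), ("chr1", 1100, 0.60)])
        sel = ea.prune_sites(ranked)
        assert len(sel.main_sites) == 2

    def test_different_chromosomes_never_pruned(self):
        ranked = ranked_frame([("chr1", 100, 0.8), ("chr2", 100, 0.79)])
        sel = ea.prune_sites(ranked)
        assert len(sel.main_sites) == 2

    def test_against_brute_force_oracle(self):
        # no pair of retained mains may violate the pruning rule, and the
        # mains must be a subsequence of the ranked input
        rng = np.random.default_rng(99)
        for rep in range(200):
            n = int(rng.integers(2, 201))
            entries = []
            seen = set()
            while len(entries) < n:
                c = f"chr{rng.integers(1, 4)}"
                p = int(rng.integers(1, 20001))
                if (c, p) in seen:
                    continue
                seen.add((c, p))
                entries.append((c, p, float(rng.uniform(-1, 1))))
            ranked = ranked_frame(entries)
            sel = ea.prune_sites(ranked)
            mains = sel.main_sites
            rho = ranked["mean_rho"].abs()
            for i in range(len(mains)):
                for j in range(i + 1, len(mains)):
                    (c1, p1), (c2, p2) = mains[i], mains[j]
                    if c1 == c2 and abs(p1 - p2) <= 5000:
                        assert abs(rho[mains[i]] - rho[mains[j]]) >= 0.1
            order = {s: k for k, s in enumerate(ranked.index)}
            assert [order[s] for s in mains] == sorted(order[s] for s in mains)
            # every backup maps to exactly one main and satisfies the rule
            for m, bl in sel.backups.items():
                for b in bl:
                    assert b[0] == m[0] and abs(b[1] - m[1]) <= 5000
                    assert abs(rho[b] - rho[m]) < 0.1
            all_backups = sel.backup_sites()
            assert len(all_backups) == len(set(all_backups))
            assert len(mains) + len(all_backups) == n


class TestSelectTop:
    def test_keeps_rank_order(self):
        ranked = ranked_frame([("chr1", 100 + 10000 * i, 0.9 - 0.01 * i)
                               for i in range(10)])
        sel = ea.prune_sites(ranked)
        top = ea.select_top(sel, 5)
        assert top.main_sites == sel.main_sites[:5]

    def test_identity_when_n_equals_total(self):
        ranked = ranked_frame([("chr1", 100, 0.9), ("chr2", 100, 0.8)])
        sel = ea.prune_sites(ranked)
        assert ea.select_top(sel, 2).main_sites == sel.main_sites

    def test_single_best_site(self):
        ranked = ranked_frame([("chr1", 100, 0.7), ("chr2", 100, 0.9)])
        sel = ea.prune_sites(ranked)
        assert ea.select_top(sel, 1).main_sites == [("chr2", 100)]

    def test_shortfall_is_error(self):
        ranked = ranked_frame([("chr1", 100, 0.9)])
        sel = ea.prune_sites(ranked)
        with pytest.raises(ValueError, match="short by 2"):
            ea.select_top(sel, 3)


class TestFilterCandidateSites:
    def _cohort(self):
        # 3 datasets x 4 samples, 4 sites with crafted coverage patterns
        sites = [("chr1", 100), ("chr1", 200), ("chr1", 300), ("chr1", 400)]
        ds = []
        cover = {
            "D1": [True, True, True, True],
            "D2": [False, True, True, True],
            "D3": [False, False, True, True],
        }
        for d, cov in cover.items():
            meth = np.ones((4, 4))
            total = np.full((4, 4), 10.0)
            for j, c in enumerate(cov):
                if not c:
                    meth[:, j] = np.nan
                    total[:, j] = np.nan
            ds.append(make_bulk(meth, total, ages=[1, 2, 3, 4],
                                dataset_id=d, sites=sites))
        return ds, sites

    def test_min_studies_rule(self):
        ds, sites = self._cohort()
        # site 0 covered only in D1 -> excluded even with zero missingness there
        keep = ea.filter_candidate_sites(ds, max_overall_missing=1.0)
        assert sites[0] not in keep
        assert sites[2] in keep

    def test_per_dataset_missingness_rule(self):
        ds, sites = self._cohort()
        # site 3: knock out 2/4 samples in D3 (50% > 25%)
        ds[2].meth.iloc[:2, 3] = np.nan
        ds[2].total.iloc[:2, 3] = np.nan
        keep = ea.filter_candidate_sites(ds, max_overall_missing=1.0)
        assert sites[3] not in keep
        assert sites[2] in keep

    def test_overall_missingness_rule(self):
        ds, sites = self._cohort()
        # site 1 missing in D3 entirely: overall missingness 4/12 = 33.3% > 33%
        keep = ea.filter_candidate_sites(ds, max_overall_missing=0.33)
        assert sites[1] not in keep
        keep = ea.filter_candidate_sites(ds, max_overall_missing=0.34)
        assert sites[1] in keep

    def test_requires_two_datasets(self):
        ds, _ = self._cohort()
        with pytest.raises(ValueError, match="at least 2"):
            ea.filter_candidate_sites(ds[:1])


def test_selection_table_lists_roles(small_cohort):
    datasets, _ = small_cohort
    sites = ea.filter_candidate_sites(datasets)
    assoc = ea.site_associations(datasets, sites)
    sel = ea.prune_sites(rank_associations(assoc))
    tab = ea.selection_table(sel)
    assert set(tab["role"]) <= {"main", "backup"}
    assert (tab.loc[tab["role"] == "backup", "main_partner"] != "").all()
    assert tab["mean_rho"].notna().all()
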