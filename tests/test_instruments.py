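"""Instrument selection filters, LD clumping and strength diagnostics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from protmr.instruments import (
    GeneAnnotation,
    LDMatrix,
    cis_filter,
    clump,
    f_statistic,
    mhc_exclude,
    select_instruments,
    significance_filter,
    variance_explained,
    variance_explained_eaf,
)

GENE = GeneAnnotation("P1", "G1", "2", 10_000_000, 10_050_000)


class TestFilters:
    @pytest.mark.parametrize(
        "pos,chrom,kept",
        [
            (10_000_000 - 999_999, "2", True),
            (10_000_000 - 1_000_000, "2", True),
            (10_000_000 - 1_000_001, "2", False),
            (10_050_000 + 1_000_000, "2", True),
            (10_050_000 + 1_000_001, "2", False),
            (10_000_000, "3", False),
        ],
    )
    def test_cis_window_boundaries(self, make_sumstats, pos, chrom, kept):
        ss = make_sumstats([{"pos": pos, "chrom": chrom}])
        assert cis_filter(ss, GENE).n_records == (1 if kept else 0)

    @pytest.mark.parametrize(
        "pval,kept", [(4.9e-8, True), (5e-8, False), (0.5, False)]
    )
    def test_significance_strictly_below_alpha(self, make_sumstats, pval, kept):
        ss = make_sumstats([{"pval": pval}])
        assert significance_filter(ss).n_records == (1 if kept else 0)

    def test_significance_mixed_counts(self, make_sumstats):
        pvals = [1e-9, 1e-10, 4e-8, 0.5, 0.1, 5e-8, 6e-8, 0.9, 0.2, 0.3]
        ss = make_sumstats([{"pval": p} for p in pvals])
        assert significance_filter(ss).n_records == 3

    @pytest.mark.parametrize(
        "chrom,pos,kept",
        [
            ("6", 30_000_000, False),
            ("6", 25_999_999, True),
            ("6", 26_000_000, False),
            ("6", 34_000_000, False),
            ("6", 34_000_001, True),
            ("7", 30_000_000, True),
        ],
    )
    def test_mhc_zone_inclusive_bounds(self, make_sumstats, chrom, pos, kept):
        ss = make_sumstats([{"chrom": chrom, "pos": pos}])
        assert mhc_exclude(ss).n_records == (1 if kept else 0)

    def test_filters_commute(self, make_sumstats):
        rows = [
            {"chrom": "2", "pos": 10_000_000, "pval": 1e-9},
            {"chrom": "2", "pos": 12_000_000, "pval": 1e-10},
            {"chrom": "6", "pos": 30_000_000, "pval": 1e-12},
            {"chrom": "2", "pos": 10_020_000, "pval": 0.5},
            {"chrom": "3", "pos": 10_000_000, "pval": 1e-9},
        ]
        ss = make_sumstats(rows)
        ops = [
            lambda s: cis_filter(s, GENE),
            significance_filter,
            mhc_exclude,
        ]
        results = []
        for perm in itertools.permutations(ops):
            out = ss
            for op in perm:
                out = op(out)
            results.append(tuple(out.df["snp_id"]))
        assert len(set(results)) == 1
        assert results[0] == ("rs1",)


def ld_from_pairs(snp_ids, pairs):
    n = len(snp_ids)
    r2 = np.eye(n)
    idx = {s: i for i, s in enumerate(snp_ids)}
    for a, b, v in pairs:
        r2[idx[a], idx[b]] = r2[idx[b], idx[a]] = v
    return LDMatrix(snp_ids=list(snp_ids), r2=r2)


def greedy_oracle(records, ld, threshold):
    """Characterization of the greedy clump output: the unique subset that is
    pairwise independent and whose every excluded record tags (r^2 >= t) some
    kept record ranked ahead of it (smaller p, then smaller position)."""
    ranked = sorted(records, key=lambda r: (r["pval"], r["pos"]))
    ids = [r["snp_id"] for r in ranked]
    solutions = []
    for size in range(len(ids) + 1):
        for subset in itertools.combinations(ids, size):
            chosen = set(subset)
            ok = all(
                ld.r2_between(a, b) < threshold
                for a, b in itertools.combinations(subset, 2)
            )
            if not ok:
                continue
            rank = {s: i for i, s in enumerate(ids)}
            for r in ids:
                if r in chosen:
                    continue
                if not any(
                    ld.r2_between(r, c) >= threshold and rank[c] < rank[r]
                    for c in chosen
                ):
                    ok = False
                    break
            if ok:
                solutions.append(chosen)
    assert len(solutions) == 1
    return solutions[0]


class TestClump:
    def test_hand_traced_example(self, make_sumstats):
        ss = make_sumstats(
            [
                {"snp_id": "A", "pval": 1e-10},
                {"snp_id": "B", "pval": 1e-9},
                {"snp_id": "C", "pval": 1e-8},
            ]
        )
        ss.df["snp_id"] = ["A", "B", "C"]
        ld = ld_from_pairs(
            ["A", "B", "C"], [("A", "B", 0.5), ("A", "C", 0.0005), ("B", "C", 0.3)]
        )
        out = clump(ss, ld, 0.001)
        assert sorted(out.df["snp_id"]) == ["A", "C"]

    def test_identity_ld_keeps_all(self, make_sumstats):
        ss = make_sumstats([{"pval": p} for p in (1e-9, 1e-10, 1e-11)])
        ld = ld_from_pairs(list(ss.df["snp_id"]), [])
        assert clump(ss, ld).n_records == 3

    def test_fully_correlated_keeps_smallest_p(self, make_sumstats):
        ss = make_sumstats([{"pval": 1e-8}, {"pval": 1e-12}, {"pval": 1e-10}])
        ids = list(ss.df["snp_id"])
        ld = ld_from_pairs(ids, [(a, b, 1.0) for a, b in itertools.combinations(ids, 2)])
        out = clump(ss, ld)
        assert list(out.df["snp_id"]) == ["rs2"]

    def test_missing_snp_treated_independent(self, make_sumstats):
        ss = make_sumstats([{"pval": 1e-9}, {"pval": 1e-10}])
        ld = LDMatrix(snp_ids=["other"], r2=np.array([[1.0]]))
        assert clump(ss, ld).n_records == 2

    def test_equal_p_tie_breaks_by_position(self, make_sumstats):
        ss = make_sumstats([{"pval": 1e-9, "pos": 2_000_000}, {"pval": 1e-9, "pos": 1_000_000}])
        ids = list(ss.df["snp_id"])
        ld = ld_from_pairs(ids, [(ids[0], ids[1], 0.9)])
        out = clump(ss, ld)
        assert out.df["pos"].tolist() == [1_000_000]

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_bruteforce_oracle(self, data):
        from conftest import build_sumstats as make_sumstats

        n = data.draw(st.integers(min_value=2, max_value=8))
        pvals = data.draw(
            st.lists(
                st.floats(min_value=1e-12, max_value=0.99, allow_nan=False),
                min_size=n,
                max_size=n,
            )
        )
        ss = make_sumstats([{"pval": p} for p in pvals])
        ids = list(ss.df["snp_id"])
        pairs = []
        for a, b in itertools.combinations(ids, 2):
            if data.draw(st.booleans()):
                pairs.append((a, b, data.draw(st.sampled_from([0.0, 0.0005, 0.01, 0.5, 1.0]))))
        ld = ld_from_pairs(ids, pairs)
        records = ss.df.to_dict("records")
        expected = greedy_oracle(records, ld, 0.001)
        got = set(clump(ss, ld, 0.001).df["snp_id"])
        assert got == expected


class TestStrength:
    def test_zero_beta_gives_zero_r2(self):
        assert variance_explained(0.0, 0.1, 1000) == 0.0

    def test_known_value(self):
        # Z = 10, n = 1000 -> 100/1098
        assert variance_explained(1.0, 0.1, 1000) == pytest.approx(100 / 1098)

    def test_monotone_in_z(self):
        r2s = [variance_explained(b, 0.1, 1000) for b in (0.1, 0.5, 1.0, 2.0)]
        assert r2s == sorted(r2s)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            variance_explained(0.1, 0.1, 3)

    def test_eaf_based_alternative(self):
        assert variance_explained_eaf(0.2, 0.5) == pytest.approx(2 * 0.25 * 0.04)
        with pytest.raises(ValueError):
            variance_explained_eaf(0.2, 0.0)

    def test_f_statistic_zero_r2(self):
        assert f_statistic(0.0, 100) == 0.0

    def test_f_statistic_domain(self):
        with pytest.raises(ValueError):
            f_statistic(1.0, 100)
        with pytest.raises(ValueError):
            f_statistic(0.5, 2)


class TestSelectInstruments:
    def _ld(self, ids, pairs=()):
        return ld_from_pairs(ids, list(pairs))

    def test_two_independent_significant_cis_snps(self, make_sumstats):
        ss = make_sumstats(
            [
                {"chrom": "2", "pos": 10_000_000, "pval": 1e-9},
                {"chrom": "2", "pos": 10_040_000, "pval": 1e-10},
                {"chrom": "2", "pos": 10_020_000, "pval": 0.5},
            ]
        )
        inst = select_instruments(ss, GENE, self._ld(list(ss.df["snp_id"])))
        assert inst.n_snps == 2
        assert (inst.f_stat > 10).all()
        assert (inst.r2_explained > 0).all()

    def test_mhc_only_protein_yields_empty_set(self, make_sumstats):
        gene = GeneAnnotation("P2", "G2", "6", 29_000_000, 29_050_000)
        ss = make_sumstats([{"chrom": "6", "pos": 29_000_000, "pval": 1e-9}])
        inst = select_instruments(ss, gene, self._ld(["rs1"]))
        assert inst.n_snps == 0

    def test_correlated_pair_clumps_to_lowest_p(self, make_sumstats):
        ss = make_sumstats(
            [
                {"chrom": "2", "pos": 10_000_000, "pval": 1e-9},
                {"chrom": "2", "pos": 10_001_000, "pval": 1e-12},
            ]
        )
        ld = self._ld(["rs1", "rs2"], [("rs1", "rs2", 0.9)])
        inst = select_instruments(ss, GENE, ld)
        assert inst.n_snps == 1
        assert inst.records["snp_id"].iloc[0] == "rs2"
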