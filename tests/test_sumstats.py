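"""Summary-statistic I/O, validation and allele harmonization."""

import pandas as pd
import pytest

from protmr.sumstats import (
    AssocRecord,
    ConfigurationError,
    EmptyInputError,
    SumStats,
    TraitMeta,
    harmonize,
    kept_pairs,
    read_sumstats,
    read_trait_meta,
    write_sumstats,
    write_trait_meta,
)


class TestAssocRecord:
    @pytest.mark.parametrize(
        "field,value",
        [
            ("se", 0.0),
            ("se", -1.0),
            ("pval", 0.0),
            ("pval", 1.5),
            ("eaf", -0.1),
            ("effect_allele", "AT"),
            ("effect_allele", "G"),  # identical to other_allele
            ("pos", 0),
        ],
    )
    def test_invariant_violations_rejected(self, field, value):
        kwargs = dict(
            snp_id="rs1",
            chrom="1",
            pos=100,
            effect_allele="A",
            other_allele="G",
            beta=0.1,
            se=0.02,
            pval=1e-5,
        )
        kwargs[field] = value
        with pytest.raises(ValueError):
            AssocRecord(**kwargs)

    def test_palindromic_detection(self):
        base = dict(snp_id="rs1", chrom="1", pos=100, beta=0.1, se=0.02, pval=0.5)
        assert AssocRecord(effect_allele="A", other_allele="T", **base).is_palindromic()
        assert AssocRecord(effect_allele="C", other_allele="G", **base).is_palindromic()
        assert not AssocRecord(effect_allele="A", other_allele="G", **base).is_palindromic()


class TestReadWrite:
    def test_roundtrip_preserves_records(self, make_sumstats, tmp_path):
        ss = make_sumstats([{"beta": 0.11}, {"beta": -0.2, "eaf": 0.5}, {"se": 0.5}])
        path = tmp_path / "x.tsv"
        write_sumstats(ss, path)
        back = read_sumstats(path, ss.meta)
        pd.testing.assert_frame_equal(
            back.df[ss.df.columns].astype(ss.df.dtypes.to_dict()), ss.df
        )

    def test_invalid_rows_dropped_and_tallied(self, make_sumstats):
        df = make_sumstats(
            [{}, {"se": 0.0}, {"pval": 0.0}, {"effect_allele": "A", "other_allele": "A"}]
        ).df
        # bypass the constructor check by rebuilding through from_frame
        ss = SumStats.from_frame(df, TraitMeta("t", "continuous", 100))
        assert ss.n_records == 1
        assert ss.qc_tally["invalid_se"] == 1
        assert ss.qc_tally["invalid_pval"] == 1
        assert ss.qc_tally["identical_alleles"] == 1

    def test_duplicate_snp_ids_deduplicated(self, make_sumstats):
        df = make_sumstats([{}, {}]).df
        df.loc[1, "snp_id"] = "rs1"
        ss = SumStats.from_frame(df, TraitMeta("t", "continuous", 100))
        assert ss.n_records == 1
        assert ss.qc_tally["duplicate_snp"] == 1

    def test_missing_mandatory_column_is_config_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("SNP\tCHR\tPOS\nrs1\t1\t100\n")
        with pytest.raises(ConfigurationError):
            read_sumstats(path, TraitMeta("t", "continuous", 100))

    def test_zero_valid_rows_is_empty_input_error(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("SNP\tCHR\tPOS\tEA\tOA\tBETA\tSE\tP\nrs1\t1\t100\tA\tG\t0.1\t0\t0.5\n")
        with pytest.raises(EmptyInputError):
            read_sumstats(path, TraitMeta("t", "continuous", 100))

    def test_column_map_resolves_dialects(self, make_sumstats, tmp_path):
        ss = make_sumstats([{}])
        path = tmp_path / "dialect.tsv"
        write_sumstats(ss, path)
        renamed = pd.read_csv(path, sep="\t").rename(
            columns={"SNP": "rsid", "BETA": "effect", "P": "pvalue"}
        )
        renamed.to_csv(path, sep="\t", index=False)
        back = read_sumstats(
            path, ss.meta, column_map={"rsid": "SNP", "effect": "BETA", "pvalue": "P"}
        )
        assert back.n_records == 1

    def test_trait_meta_sidecar_roundtrip(self, tmp_path):
        meta = TraitMeta("BCC", "binary", 275_911, 16_328, "outcome GWAS")
        write_trait_meta(meta, tmp_path / "m.json")
        assert read_trait_meta(tmp_path / "m.json") == meta

    def test_binary_meta_requires_cases(self):
        with pytest.raises(ValueError):
            TraitMeta("t", "binary", 100)
        with pytest.raises(ValueError):
            TraitMeta("t", "binary", 100, n_cases=200)


class TestHarmonize:
    def _pair(self, exp_row, out_row, window=0.08):
        exp = pd.DataFrame([dict(snp_id="rs1", chrom="1", pos=100, **exp_row)])
        out = pd.DataFrame([dict(snp_id="rs1", chrom="1", pos=100, **out_row)])
        e = SumStats(meta=TraitMeta("e", "continuous", 1000), df=exp)
        o = SumStats(meta=TraitMeta("o", "continuous", 1000), df=out)
        return harmonize(e, o, eaf_window=window).iloc[0]

    @staticmethod
    def _row(ea, oa, beta, eaf=0.3):
        return dict(
            effect_allele=ea, other_allele=oa, beta=beta, se=0.05, pval=1e-4, eaf=eaf
        )

    def test_swapped_alleles_flip_sign(self):
        r = self._pair(self._row("A", "G", 0.10), self._row("G", "A", 0.05, eaf=0.7))
        assert r["dropped_reason"] == "none"
        assert r["flipped"]
        assert r["beta_out"] == pytest.approx(-0.05)

    def test_matching_alleles_kept_unchanged(self):
        r = self._pair(self._row("A", "G", 0.10), self._row("A", "G", 0.05))
        assert r["dropped_reason"] == "none"
        assert not r["flipped"]
        assert r["beta_out"] == pytest.approx(0.05)

    def test_palindromic_within_window_dropped(self):
        r = self._pair(
            self._row("A", "T", 0.10, eaf=0.3), self._row("A", "T", 0.05, eaf=0.51)
        )
        assert r["dropped_reason"] == "palindromic_ambiguous"

    def test_palindromic_missing_eaf_dropped(self):
        r = self._pair(
            self._row("A", "T", 0.10, eaf=None), self._row("A", "T", 0.05, eaf=0.2)
        )
        assert r["dropped_reason"] == "palindromic_ambiguous"

    def test_palindromic_outside_window_frequency_aligned(self):
        concordant = self._pair(
            self._row("A", "T", 0.10, eaf=0.2), self._row("A", "T", 0.05, eaf=0.25)
        )
        assert concordant["dropped_reason"] == "none"
        assert not concordant["flipped"]
        discordant = self._pair(
            self._row("A", "T", 0.10, eaf=0.2), self._row("A", "T", 0.05, eaf=0.8)
        )
        assert discordant["dropped_reason"] == "none"
        assert discordant["flipped"]
        assert discordant["beta_out"] == pytest.approx(-0.05)

    def test_incompatible_alleles_dropped(self):
        r = self._pair(self._row("A", "G", 0.10), self._row("C", "T", 0.05))
        assert r["dropped_reason"] == "allele_mismatch"

    def test_no_shared_snps_gives_empty_result(self, make_sumstats):
        e = make_sumstats([{}])
        o = make_sumstats([{}])
        o.df["snp_id"] = "rsX"
        assert len(harmonize(e, o)) == 0

    def test_idempotent_on_aligned_pairs(self, make_sumstats):
        e = make_sumstats([{"beta": 0.1, "eaf": 0.2}, {"beta": -0.3, "eaf": 0.7}])
        o = make_sumstats([{"beta": 0.05, "eaf": 0.21}, {"beta": 0.02, "eaf": 0.69}])
        first = kept_pairs(harmonize(e, o))
        # rebuild an outcome already expressed on the exposure's alleles
        o2 = make_sumstats(
            [
                {"beta": b, "eaf": f}
                for b, f in zip(first["beta_out"], [0.21, 0.69])
            ]
        )
        second = kept_pairs(harmonize(e, o2))
        assert not second["flipped"].any()
        assert second["beta_out"].tolist() == first["beta_out"].tolist()

    def test_sign_consistency_under_label_flip(self, make_sumstats):
        e = make_sumstats([{"beta": 0.1, "eaf": 0.2}, {"beta": -0.3, "eaf": 0.7}])
        o = make_sumstats([{"beta": 0.05, "eaf": 0.25}, {"beta": 0.02, "eaf": 0.65}])
        flipped = o.df.copy()
        flipped[["effect_allele", "other_allele"]] = flipped[
            ["other_allele", "effect_allele"]
        ].to_numpy()
        flipped["beta"] = -flipped["beta"]
        flipped["eaf"] = 1 - flipped["eaf"]
        o_flipped = SumStats(meta=o.meta, df=flipped)
        a = kept_pairs(harmonize(e, o))
        b = kept_pairs(harmonize(e, o_flipped))
        assert a["beta_out"].tolist() == pytest.approx(b["beta_out"].tolist())
        assert a["eaf_exp"].tolist() == b["eaf_exp"].tolist()
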