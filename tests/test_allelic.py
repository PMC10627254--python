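import numpy as np
import pandas as pd
import pytest

from matecall.allelic import (
    classify_gene,
    classify_library,
    cross_organ_update,
    load_allele_depths,
    site_presence,
    summarize_calls,
)
from matecall.genotypes import Thresholds, find_distinguishing_sites, score_detectability
from matecall.synthetic_data import simulate_library


def brute_force_classify(site_data, length, thr):
    """Independent re-statement of the classification rules.

    ``site_data``: list of (transcript_pos, depth_male, depth_female,
    depth_other). Enumerates the sites directly from the stated rules:
    a site participates with total depth >= 3; an allele is present with
    >= 3 reads; a sex qualifies with >= 5 present sites, total depth over
    them >= 15, and span >= 75% of the transcript.
    """
    verdicts = {}
    for sex, col in (("male", 1), ("female", 2)):
        present = []
        for tpos, dm, df, do in site_data:
            total = dm + df + do
            if total < thr.min_site_cov:
                continue
            if (dm, df, do)[col - 1] >= thr.min_allele_calls:
                present.append((tpos, total))
        ok = len(present) >= thr.min_snps
        ok = ok and sum(t for _, t in present) >= thr.min_sum_cov
        if len(present) >= 2:
            tps = [p for p, _ in present]
            ok = ok and (max(tps) - min(tps)) / length >= thr.min_span
        else:
            ok = False
        verdicts[sex] = ok
    if verdicts["male"] and verdicts["female"]:
        return "both"
    if verdicts["male"]:
        return "male"
    if verdicts["female"]:
        return "female"
    return "undetermined"


def make_records(site_data, library_id="L1"):
    cols = ["library_id", "chrom", "pos", "depth_male_allele",
            "depth_female_allele", "depth_other"]
    if not site_data:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(
        [
            dict(
                library_id=library_id,
                chrom="2L",
                pos=1000 + i,
                depth_male_allele=dm,
                depth_female_allele=df,
                depth_other=do,
            )
            for i, (_, dm, df, do) in enumerate(site_data)
        ]
    )


def make_sites(site_data, gene_id="gX"):
    return pd.DataFrame(
        [
            dict(
                chrom="2L",
                pos=1000 + i,
                gene_id=gene_id,
                transcript_pos=tpos,
                male_allele="A",
                female_allele="G",
                strand="+",
            )
            for i, (tpos, *_rest) in enumerate(site_data)
        ]
    )


class TestSitePresence:
    @pytest.mark.parametrize(
        "dm,df,do,expected",
        [
            (3, 0, 0, (True, False)),  # threshold boundary
            (2, 2, 0, (False, False)),  # covered but each allele below 3
            (3, 3, 0, (True, True)),
            (0, 0, 2, (False, False)),  # below site coverage entirely
            (2, 0, 1, (False, False)),  # participates, neither allele at 3
            (0, 3, 5, (False, True)),
        ],
    )
    def test_presence_rules(self, dm, df, do, expected, thresholds):
        assert site_presence(dm, df, do, thresholds) == expected


class TestClassifyGene:
    def test_six_male_sites_spanning_80pct(self, thresholds):
        data = [(100 + i * 160, 3, 0, 0) for i in range(6)]  # span 800/1000
        call = classify_gene("gX", make_records(data), make_sites(data), 1000, thresholds)
        assert call.call == "male"
        assert call.n_sites_male == 6
        assert call.sum_cov_male == 18
        assert call.span_male == pytest.approx(0.80)

    def test_four_present_sites_undetermined(self, thresholds):
        data = [(100, 3, 0, 0), (400, 3, 0, 0), (700, 3, 0, 0), (900, 3, 0, 0)]
        call = classify_gene("gX", make_records(data), make_sites(data), 1000, thresholds)
        assert call.call == "undetermined"

    def test_summed_coverage_14_undetermined(self, thresholds):
        # 5 male-present sites spanning 80%, one site only 2 reads total
        data = [(100, 3, 0, 0), (300, 3, 0, 0), (500, 3, 0, 0), (700, 3, 0, 0), (900, 2, 0, 0)]
        call = classify_gene("gX", make_records(data), make_sites(data), 1000, thresholds)
        assert call.call == "undetermined"
        assert call.n_sites_male == 4  # the 2-read site does not participate

    def test_both_sexes_meeting_criteria(self, thresholds):
        data = [(100 + i * 160, 4, 4, 0) for i in range(6)]
        call = classify_gene("gX", make_records(data), make_sites(data), 1000, thresholds)
        assert call.call == "both"

    def test_no_depth_records_is_undetermined(self, thresholds):
        data = [(100, 3, 0, 0)]
        call = classify_gene(
            "gX", make_records([]), make_sites(data), 1000, thresholds
        )
        assert call.call == "undetermined"
        assert call.sum_cov == 0

    def test_allele_specific_sum_switch(self):
        # male allele sum 18 < 30 but total depth 78 >= 30: the two sum
        # conventions diverge only when min_sum_cov exceeds
        # min_snps * min_allele_calls
        data = [(100 + i * 160, 3, 10, 0) for i in range(6)]
        default = classify_gene(
            "gX", make_records(data), make_sites(data), 1000, Thresholds(min_sum_cov=30)
        )
        strict = classify_gene(
            "gX", make_records(data), make_sites(data), 1000,
            Thresholds(min_sum_cov=30, sum_allele_specific=True),
        )
        assert default.call == "both"
        assert strict.call == "female"

    def test_matches_brute_force_on_random_instances(self, thresholds):
        rng = np.random.default_rng(42)
        for _ in range(200):
            length = int(rng.integers(200, 2000))
            n_sites = int(rng.integers(1, 15))
            tpos = sorted(rng.choice(np.arange(1, length + 1), n_sites, replace=False))
            data = [
                (
                    int(tp),
                    int(rng.choice([0, 1, 2, 3, 4, 10])),
                    int(rng.choice([0, 1, 2, 3, 4, 10])),
                    int(rng.choice([0, 0, 0, 1, 2])),
                )
                for tp in tpos
            ]
            got = classify_gene(
                "gX", make_records(data), make_sites(data), length, thresholds
            ).call
            assert got == brute_force_classify(data, length, thresholds)

    def test_adding_reads_never_undetermines(self, thresholds):
        """Monotonicity: extra depth on any allele cannot demote a call."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            length = 1000
            tpos = sorted(rng.choice(np.arange(1, 1001), 8, replace=False))
            data = [
                (int(tp), int(rng.integers(0, 6)), int(rng.integers(0, 6)), 0)
                for tp in tpos
            ]
            before = classify_gene(
                "gX", make_records(data), make_sites(data), length, thresholds
            ).call
            if before == "undetermined":
                continue
            i = int(rng.integers(len(data)))
            allele = int(rng.integers(2))
            boosted = list(data)
            tp, dm, df, do = boosted[i]
            boosted[i] = (tp, dm + 5, df, do) if allele == 0 else (tp, dm, df + 5, do)
            after = classify_gene(
                "gX", make_records(boosted), make_sites(boosted), length, thresholds
            ).call
            assert after != "undetermined"

    def test_label_symmetry(self, thresholds):
        """Swapping allele depth columns swaps male<->female in the call."""
        rng = np.random.default_rng(3)
        swap = {"male": "female", "female": "male", "both": "both", "undetermined": "undetermined"}
        for _ in range(50):
            tpos = sorted(rng.choice(np.arange(1, 1001), 7, replace=False))
            data = [
                (int(tp), int(rng.integers(0, 8)), int(rng.integers(0, 8)), 0)
                for tp in tpos
            ]
            flipped = [(tp, df, dm, do) for tp, dm, df, do in data]
            a = classify_gene("gX", make_records(data), make_sites(data), 1000, thresholds).call
            b = classify_gene("gX", make_records(flipped), make_sites(flipped), 1000, thresholds).call
            assert b == swap[a]


class TestLoadAlleleDepths:
    def test_vcf_ad_orientation(self, tmp_path):
        # ref C is the female allele, alt T the male allele
        vcf = tmp_path / "d.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n'
            "##contig=<ID=2L>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tL1\n"
            "2L\t1000\t.\tC\tT\t.\tPASS\t.\tAD\t7,4\n"
            "2L\t2000\t.\tA\tG\t.\tPASS\t.\tAD\t5,1\n"
        )
        sites = pd.DataFrame(
            [
                dict(chrom="2L", pos=1000, gene_id="g1", transcript_pos=10,
                     male_allele="T", female_allele="C"),
            ]
        )
        depths = load_allele_depths(str(vcf), sites, library_id="L1")
        assert len(depths) == 1  # 2L:2000 is not a distinguishing site
        row = depths.iloc[0]
        assert row["depth_female_allele"] == 7
        assert row["depth_male_allele"] == 4
        assert row["depth_other"] == 0

    def test_tsv_ref_alt_orientation_and_other_allele(self, tmp_path):
        tsv = tmp_path / "d.tsv"
        tsv.write_text(
            "library_id\tchrom\tpos\tref\talt\tref_depth\talt_depth\n"
            "L1\t2L\t1000\tC\tT\t7\t4\n"
            "L1\t2L\t3000\tC\tA\t6\t2\n"  # alt A matches neither parent
        )
        sites = pd.DataFrame(
            [
                dict(chrom="2L", pos=1000, gene_id="g1", transcript_pos=10,
                     male_allele="T", female_allele="C"),
                dict(chrom="2L", pos=3000, gene_id="g1", transcript_pos=50,
                     male_allele="G", female_allele="C"),
            ]
        )
        depths = load_allele_depths(str(tsv), sites)
        assert depths.iloc[0]["depth_male_allele"] == 4
        row = depths.iloc[1]
        assert (row["depth_male_allele"], row["depth_female_allele"]) == (0, 6)
        assert row["depth_other"] == 2

    def test_simulator_round_trip(self, small_genomes, tmp_path):
        depths = simulate_library(small_genomes, small_genomes.config, "L1")
        path = tmp_path / "sim.tsv"
        depths.to_csv(path, sep="\t", index=False)
        loaded = load_allele_depths(str(path), small_genomes.site_truth)
        pd.testing.assert_frame_equal(loaded, depths, check_dtype=False)


def toy_calls():
    rows = []
    for lib, cross, organ, call in [
        ("L1", "c1", "parovaria", "male"),
        ("L2", "c1", "spermatheca", "undetermined"),
        ("L3", "c1", "seminal_receptacle", "female"),
        ("L4", "c2", "parovaria", "undetermined"),
    ]:
        rows.append(
            dict(
                gene_id="g1", library_id=lib, cross_id=cross, organ=organ,
                n_sites_male=6 if call in ("male", "both") else 0,
                n_sites_female=6 if call in ("female", "both") else 0,
                sum_cov=20, sum_cov_male=20, sum_cov_female=0,
                span_male=0.8, span_female=0.0, call=call, evidence_source="snp",
            )
        )
    return pd.DataFrame(rows)


class TestCrossOrganUpdate:
    def test_update_adds_male_call_above_span(self, thresholds):
        calls = toy_calls()
        cov = pd.DataFrame(
            [dict(gene_id="g1", library_id="L2", parent="male", covered_span_fraction=0.80)]
        )
        out = cross_organ_update(calls, cov, thresholds)
        row = out[out["library_id"] == "L2"].iloc[0]
        assert row["call"] == "male"
        assert row["evidence_source"] == "parent_specific_update"

    def test_below_span_no_update(self, thresholds):
        calls = toy_calls()
        cov = pd.DataFrame(
            [dict(gene_id="g1", library_id="L2", parent="male", covered_span_fraction=0.70)]
        )
        out = cross_organ_update(calls, cov, thresholds)
        assert out[out["library_id"] == "L2"].iloc[0]["call"] == "undetermined"

    def test_no_seed_call_in_cross_no_update(self, thresholds):
        calls = toy_calls()
        cov = pd.DataFrame(
            [dict(gene_id="g1", library_id="L4", parent="male", covered_span_fraction=0.99)]
        )
        out = cross_organ_update(calls, cov, thresholds)
        # cross c2 has no SNP-derived male call, so nothing propagates
        assert out[out["library_id"] == "L4"].iloc[0]["call"] == "undetermined"

    def test_female_call_gains_male_becomes_both(self, thresholds):
        calls = toy_calls()
        cov = pd.DataFrame(
            [dict(gene_id="g1", library_id="L3", parent="male", covered_span_fraction=0.90)]
        )
        out = cross_organ_update(calls, cov, thresholds)
        assert out[out["library_id"] == "L3"].iloc[0]["call"] == "both"

    def test_snp_calls_never_downgraded(self, thresholds):
        calls = toy_calls()
        cov = pd.DataFrame(
            [
                dict(gene_id="g1", library_id=lib, parent=parent, covered_span_fraction=0.9)
                for lib in ("L1", "L2", "L3")
                for parent in ("male", "female")
            ]
        )
        out = cross_organ_update(calls, cov, thresholds)
        snp_before = calls[calls["evidence_source"] == "snp"]
        for _, row in snp_before.iterrows():
            after = out[out["library_id"] == row["library_id"]].iloc[0]
            if row["call"] in ("male", "both"):
                assert after["call"] in ("male", "both")
            if row["call"] in ("female", "both"):
                assert after["call"] in ("female", "both")

    def test_unknown_library_rejected(self, thresholds):
        cov = pd.DataFrame(
            [dict(gene_id="g1", library_id="L99", parent="male", covered_span_fraction=0.9)]
        )
        with pytest.raises(ValueError, match="L99"):
            cross_organ_update(toy_calls(), cov, thresholds)


class TestSummarizeCalls:
    def test_counts_by_gene(self):
        summary, mean_libs = summarize_calls(toy_calls())
        row = summary.iloc[0]
        assert row["libraries_male"] == 1
        assert row["libraries_female"] == 1
        assert row["organs"] == 2
        assert row["crosses"] == 1
        assert mean_libs == 1.0

    def test_empty_calls_give_empty_summary(self):
        summary, mean_libs = summarize_calls(pd.DataFrame(columns=["gene_id", "call"]))
        assert summary.empty
        assert np.isnan(mean_libs)

    def test_summary_matches_brute_recount(self, small_genomes, thresholds):
        genomes = small_genomes
        sites = find_distinguishing_sites(genomes.genotypes, "sire", "dam", genomes.models)
        det = score_detectability(sites, genomes.models, thresholds)
        calls = []
        for lib, cross, organ in [
            ("L1", "c1", "parovaria"), ("L2", "c1", "spermatheca"),
            ("L3", "c2", "parovaria"), ("L4", "c2", "spermatheca"),
        ]:
            depths = simulate_library(genomes, genomes.config, lib)
            calls.append(
                classify_library(depths, sites, det, genomes.models, thresholds,
                                 library_id=lib, cross_id=cross, organ=organ)
            )
        calls = pd.concat(calls, ignore_index=True)
        summary, _ = summarize_calls(calls)
        for _, row in summary.iterrows():
            sub = calls[calls["gene_id"] == row["gene_id"]]
            assert row["libraries_male"] == sum(c in ("male", "both") for c in sub["call"])
            assert row["libraries_female"] == sum(c in ("female", "both") for c in sub["call"])
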