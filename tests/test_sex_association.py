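"""Segregation filter: exhaustive oracle, published worked example, recovery."""

import itertools

import numpy as np
import pandas as pd
import pytest

from dioica import sex_association as sa
from dioica.design import SampleDesign
from dioica.errors import ConfigurationError, InputError
from dioica.simulate import (
    SimulationConfig,
    simulate_unigenes,
    simulate_variants,
    write_vcf,
)


def _design():
    return SampleDesign.from_lists(["M1", "M2", "M3"], ["F1", "F2", "F3"])


def _calls_from_alleles(alleles, design, depth=10, gene="g", pos=1):
    rows = [
        (gene, pos, s, design.sex[s], a, depth)
        for s, a in zip(design.samples, alleles)
    ]
    return pd.DataFrame(rows, columns=sa.CALL_COLUMNS)


class TestPublishedWorkedExample:
    """The nine-position genotype table of the motivating study."""

    def test_all_five_genes_and_nine_sites_recovered(
        self, published_genotype_table, published_design
    ):
        calls = sa.load_genotype_table(published_genotype_table, published_design)
        assert len(calls) == 9 * 6
        sites, report = sa.run_filter(calls, published_design, min_depth=5)
        assert len(sites) == 9
        assert len(report) == 5
        assert report["n_sites"].sum() == 9

    def test_printed_allele_assignments_reproduced(
        self, published_genotype_table, published_design
    ):
        calls = sa.load_genotype_table(published_genotype_table, published_design)
        sites, _ = sa.run_filter(calls, published_design)
        site = sites[(sites["gene"] == "Cluster-47702.80936") & (sites["pos"] == 1101)]
        assert len(site) == 1
        assert site.iloc[0]["female_allele"] == "C"
        assert site.iloc[0]["male_allele"] == "G"
        # two positions in one gene count as one putative gene
        two = sites[sites["gene"] == "Cluster-47702.80197"]
        assert sorted(two["pos"]) == [360, 460]

    def test_blank_continuation_rows_forward_filled(
        self, published_genotype_table, published_design, tmp_path
    ):
        tab = published_genotype_table.copy().astype(object)
        prev = None
        for i in tab.index:
            if tab.loc[i, "Gene_ID"] == prev:
                tab.loc[i, "Gene_ID"] = ""
            else:
                prev = tab.loc[i, "Gene_ID"]
        path = tmp_path / "tab.tsv"
        tab.to_csv(path, sep="\t", index=False)
        calls = sa.load_genotype_table(path, published_design)
        _, report = sa.run_filter(calls, published_design)
        assert len(report) == 5


class TestExhaustiveOracle:
    def test_matches_brute_force_on_all_biallelic_assignments(self):
        """All 2^6 allele assignments over {A, C}: filter == definition."""
        design = _design()
        for assignment in itertools.product("AC", repeat=6):
            calls = _calls_from_alleles(assignment, design)
            sites = sa.find_sex_segregating_sites(calls, design)
            females = {a for s, a in zip(design.samples, assignment) if design.sex[s] == "F"}
            males = {a for s, a in zip(design.samples, assignment) if design.sex[s] == "M"}
            expected = len(females) == 1 and len(males) == 1 and females != males
            assert len(sites) == (1 if expected else 0), assignment

    def test_non_uniform_males_rejected(self):
        design = _design()
        calls = _calls_from_alleles(["G", "G", "C", "C", "C", "C"], design)
        # samples order is M1 M2 M3 F1 F2 F3 -> males G,G,C not uniform
        assert sa.find_sex_segregating_sites(calls, design).empty

    def test_sex_swap_swaps_alleles_but_keeps_sites(self):
        design = _design()
        calls = _calls_from_alleles(["G", "G", "G", "C", "C", "C"], design)
        sites = sa.find_sex_segregating_sites(calls, design)
        swapped_design = design.swapped()
        calls_sw = calls.assign(
            sex=[swapped_design.sex[s] for s in calls["individual"]]
        )
        sites_sw = sa.find_sex_segregating_sites(calls_sw, swapped_design)
        assert len(sites) == len(sites_sw) == 1
        assert sites.iloc[0]["female_allele"] == sites_sw.iloc[0]["male_allele"]
        assert sites.iloc[0]["male_allele"] == sites_sw.iloc[0]["female_allele"]


class TestDepthFilter:
    def test_boundary_depth_is_inclusive(self):
        design = _design()
        calls = _calls_from_alleles("GGGCCC", design, depth=5)
        assert len(sa.apply_depth_filter(calls, design, min_depth=5)) == 6

    def test_single_shallow_individual_drops_position(self):
        design = _design()
        calls = _calls_from_alleles("GGGCCC", design, depth=5)
        calls.loc[2, "depth"] = 4
        assert sa.apply_depth_filter(calls, design, min_depth=5).empty

    def test_missing_individual_drops_position(self):
        design = _design()
        calls = _calls_from_alleles("GGGCCC", design).iloc[:5]
        assert sa.apply_depth_filter(calls, design).empty

    def test_empty_input(self):
        assert sa.apply_depth_filter(pd.DataFrame(columns=sa.CALL_COLUMNS), _design()).empty

    def test_raising_min_depth_never_adds_sites(self, default_ds, tmp_path):
        path = tmp_path / "v.vcf"
        write_vcf(default_ds.variants, default_ds.unigenes, default_ds.design, path)
        calls = sa.load_genotypes(path, default_ds.design)
        previous = None
        for depth in (1, 3, 5, 8, 12, 20):
            sites, _ = sa.run_filter(calls, default_ds.design, min_depth=depth)
            found = set(zip(sites["gene"], sites["pos"]))
            if previous is not None:
                assert found <= previous
            previous = found


class TestVcfLoading:
    def test_round_trip_against_generator_records(self, default_ds, tmp_path):
        path = tmp_path / "v.vcf"
        write_vcf(default_ds.variants, default_ds.unigenes, default_ds.design, path)
        calls = sa.load_genotypes(path, default_ds.design)
        n_sites = default_ds.config.n_snp_sites
        assert len(calls) == n_sites * 6
        rec = default_ds.variants.iloc[0]
        sub = calls[(calls["gene"] == rec["gene"]) & (calls["pos"] == rec["pos"])]
        for s in default_ds.design.samples:
            row = sub[sub["individual"] == s].iloc[0]
            assert row["allele"] == rec[f"GT:{s}"]
            assert row["depth"] == rec[f"DP:{s}"]

    def test_het_and_missing_become_nocalls(self, tmp_path, published_design):
        vcf = tmp_path / "h.vcf"
        column_order = [
            "EUCO_F1", "EUCO_F2", "EUCO_F3", "EUCO_M1", "EUCO_M2", "EUCO_M3",
        ]
        samples = "\t".join(column_order)
        gts = ["0/1:9", "./.:0", "0/0:9", "1/1:9", "1/1:9", "1/1:9"]
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=g1,length=100>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n'
            f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n"
            "g1\t10\t.\tC\tG\t.\tPASS\t.\tGT:DP\t" + "\t".join(gts) + "\n"
        )
        calls = sa.load_genotypes(vcf, published_design)
        by_ind = calls.set_index("individual")["allele"]
        assert pd.isna(by_ind["EUCO_F1"])  # heterozygous
        assert pd.isna(by_ind["EUCO_F2"])  # missing
        assert by_ind["EUCO_F3"] == "C"
        assert by_ind["EUCO_M1"] == "G"
        # the no-calls make the position ineligible
        assert sa.find_sex_segregating_sites(calls, published_design).empty

    def test_unknown_sample_rejected(self, tmp_path, published_design):
        vcf = tmp_path / "u.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSTRANGER\n"
            "g1\t10\t.\tC\tG\t.\tPASS\t.\tGT\t0/0\n"
        )
        with pytest.raises(InputError, match="STRANGER"):
            sa.load_genotypes(vcf, published_design)


class TestSyntheticRecovery:
    def test_planted_sites_recovered_no_decoys_over_20_seeds(self, tmp_path):
        """Across 20 replicates the filter recovers exactly the planted set."""
        for seed in range(20):
            cfg = SimulationConfig(
                seed=seed, n_genes=40, gene_length_range=(300, 900),
                n_male_biased=0, n_female_biased=0,
                n_male_specific=0, n_female_specific=0,
                n_snp_sites=30, n_sex_segregating=6,
            )
            uni = simulate_unigenes(cfg)
            records, manifest = simulate_variants(cfg, uni)
            path = tmp_path / f"v{seed}.vcf"
            write_vcf(records, uni, cfg.design(), path)
            calls = sa.load_genotypes(path, cfg.design())
            sites, _ = sa.run_filter(calls, cfg.design(), min_depth=5)
            found = set(zip(sites["gene"], sites["pos"]))
            planted = set(
                zip(manifest.seg_sites["gene"], manifest.seg_sites["pos"])
            )
            assert found == planted, f"seed {seed}"


class TestSummaries:
    def test_empty_site_set_reports_zero_genes(self):
        report = sa.summarize_by_gene(
            pd.DataFrame(columns=["gene", "pos", "female_allele", "male_allele"])
        )
        assert len(report) == 0

    @pytest.mark.parametrize(
        "n_males,n_females,expected",
        [(3, 3, 2 / 62), (1, 1, 1.0), (2, 2, 2 / 14), (5, 1, 2 / 62)],
    )
    def test_null_rate_matches_enumeration(self, n_males, n_females, expected):
        rate = sa.segregation_null_rate(n_males, n_females)
        assert rate == pytest.approx(expected)
        # independent enumeration over all 2^n assignments
        n = n_males + n_females
        hits = polymorphic = 0
        for bits in itertools.product((0, 1), repeat=n):
            if len(set(bits)) == 1:
                continue
            polymorphic += 1
            males, females = set(bits[:n_males]), set(bits[n_males:])
            if len(males) == 1 and len(females) == 1 and males != females:
                hits += 1
        assert rate == pytest.approx(hits / polymorphic)

    def test_null_rate_requires_both_sexes(self):
        with pytest.raises(ConfigurationError):
            sa.segregation_null_rate(0, 3)
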