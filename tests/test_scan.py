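"""Fixed-difference scan, region merging, nearest-gene and LD checks."""

import numpy as np
import pandas as pd
import pytest

from pomepan import (
    CultivarPanel,
    GeneModel,
    GenoSimSpec,
    Region,
    ScanConfig,
    default_scan_panel,
    locus_is_differentiated,
    merge_regions,
    nearest_gene,
    region_r2_check,
    scan_genome,
    simulate_genotypes,
)
from pomepan.core import HET, HOM_ALT, HOM_REF, MISSING

from conftest import make_genotype_matrix


def panel_20_19():
    return default_scan_panel(20, 19)


def calls_for(n_soft, n_hard, soft_fill, hard_fill, overrides=()):
    calls = np.array([soft_fill] * n_soft + [hard_fill] * n_hard, dtype=np.int8)
    for idx, val in overrides:
        calls[idx] = val
    return calls


class TestLocusRule:
    def test_exact_fixed_difference(self):
        panel = panel_20_19()
        ok, orient = locus_is_differentiated(
            calls_for(20, 19, HOM_REF, HOM_ALT), panel
        )
        assert ok and orient == "ref_fixed_in_soft"

    def test_opposite_orientation(self):
        panel = panel_20_19()
        ok, orient = locus_is_differentiated(
            calls_for(20, 19, HOM_ALT, HOM_REF), panel
        )
        assert ok and orient == "ref_fixed_in_hard"

    def test_one_het_tolerated_per_subpopulation(self):
        panel = panel_20_19()
        calls = calls_for(20, 19, HOM_REF, HOM_ALT, overrides=[(0, HET), (20, HET)])
        ok, _ = locus_is_differentiated(calls, panel)
        assert ok

    def test_two_hets_rejected(self):
        panel = panel_20_19()
        calls = calls_for(20, 19, HOM_REF, HOM_ALT, overrides=[(0, HET), (1, HET)])
        ok, _ = locus_is_differentiated(calls, panel)
        assert not ok

    def test_opposite_homozygote_rejected(self):
        panel = panel_20_19()
        calls = calls_for(20, 19, HOM_REF, HOM_ALT, overrides=[(0, HOM_ALT)])
        ok, _ = locus_is_differentiated(calls, panel)
        assert not ok

    def test_missing_excludes_locus_by_default(self):
        panel = panel_20_19()
        calls = calls_for(20, 19, HOM_REF, HOM_ALT, overrides=[(0, MISSING)])
        assert not locus_is_differentiated(calls, panel)[0]

    def test_ignore_missing_policy_with_called_fraction(self):
        panel = panel_20_19()
        cfg = ScanConfig(missing_policy="ignore_missing", min_called_fraction=0.8)
        calls = calls_for(20, 19, HOM_REF, HOM_ALT, overrides=[(0, MISSING)])
        assert locus_is_differentiated(calls, panel, cfg)[0]
        # below the called fraction the locus becomes ineligible
        many_missing = [(i, MISSING) for i in range(5)]
        calls = calls_for(20, 19, HOM_REF, HOM_ALT, overrides=many_missing)
        assert not locus_is_differentiated(calls, panel, cfg)[0]

    def test_all_missing_side_ineligible(self):
        panel = panel_20_19()
        cfg = ScanConfig(missing_policy="ignore_missing", min_called_fraction=0.0)
        calls = calls_for(20, 19, MISSING, HOM_ALT)
        assert not locus_is_differentiated(calls, panel, cfg)[0]

    def test_monomorphic_not_selected(self):
        panel = panel_20_19()
        assert not locus_is_differentiated(
            calls_for(20, 19, HOM_REF, HOM_REF), panel
        )[0]


class TestScanGenome:
    def test_recovers_planted_loci_exactly(self):
        panel = panel_20_19()
        spec = GenoSimSpec(missing_rate=0.0, seed=11)
        gm, truth = simulate_genotypes(spec, panel)
        selected = scan_genome(gm, panel)
        got = set(zip(selected["chrom"], selected["pos"]))
        want = set(zip(truth["chrom"], truth["pos"]))
        assert got == want and len(want) == 12

    def test_matches_per_locus_oracle_on_random_calls(self, small_panel):
        rng = np.random.default_rng(21)
        calls = rng.choice(
            [HOM_REF, HET, HOM_ALT, MISSING],
            p=[0.42, 0.2, 0.35, 0.03],
            size=(500, 6),
        ).astype(np.int8)
        gm = make_genotype_matrix(calls, small_panel)
        selected = set(scan_genome(gm, small_panel)["locus_index"])

        # independent re-statement of the rule, checked locus by locus
        def oracle(row):
            soft, hard = row[:3], row[3:]
            if (soft == MISSING).any() or (hard == MISSING).any():
                return False

            def fixed(side, allele):
                other = HOM_ALT if allele == HOM_REF else HOM_REF
                return (
                    (side == other).sum() == 0
                    and (side == HET).sum() <= 1
                    and (side == allele).sum() >= 1
                )

            return (fixed(soft, HOM_REF) and fixed(hard, HOM_ALT)) or (
                fixed(soft, HOM_ALT) and fixed(hard, HOM_REF)
            )

        expected = {i for i in range(500) if oracle(calls[i])}
        assert selected == expected

    def test_monomorphic_panel_empty(self, small_panel):
        calls = np.full((50, 6), HOM_REF, dtype=np.int8)
        gm = make_genotype_matrix(calls, small_panel)
        assert scan_genome(gm, small_panel).empty

    def test_het_perturbation_robustness(self):
        panel = panel_20_19()
        spec = GenoSimSpec(missing_rate=0.0, seed=11)
        gm, truth = simulate_genotypes(spec, panel)
        truth_key = set(zip(truth["chrom"], truth["pos"]))
        planted_rows = [
            i
            for i, (c, p) in enumerate(zip(gm.loci["chrom"], gm.loci["pos"]))
            if (c, p) in truth_key
        ]
        soft_idx, hard_idx = panel.indices("soft"), panel.indices("hard")

        one_het = gm.calls.copy()
        for i in planted_rows:
            one_het[i, soft_idx[0]] = HET
            one_het[i, hard_idx[0]] = HET
        gm.calls = one_het
        sel = scan_genome(gm, panel)
        got = set(zip(sel["chrom"], sel["pos"]))
        assert truth_key <= got  # recall stays 1 with one het per side

        two_het = one_het.copy()
        for i in planted_rows:
            two_het[i, soft_idx[1]] = HET
            two_het[i, hard_idx[1]] = HET
        gm.calls = two_het
        sel = scan_genome(gm, panel)
        got = set(zip(sel["chrom"], sel["pos"]))
        assert not (truth_key & got)  # recall drops to 0 with two


def selected_frame(pairs):
    return pd.DataFrame(
        [(c, p, i, "ref_fixed_in_soft") for i, (c, p) in enumerate(pairs)],
        columns=["chrom", "pos", "locus_index", "orientation"],
    )


class TestMergeRegions:
    def test_observed_cluster_merges_at_default_gap(self):
        sel = selected_frame([("Chr5", 11_360_872), ("Chr5", 11_495_723)])
        regions = merge_regions(sel, merge_gap=150_000)
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (11_360_872, 11_495_723)

    def test_smaller_gap_splits(self):
        sel = selected_frame([("Chr5", 11_360_872), ("Chr5", 11_495_723)])
        regions = merge_regions(sel, merge_gap=100_000)
        assert len(regions) == 2
        assert all(r.start == r.end for r in regions)

    def test_chromosomes_never_merge(self):
        sel = selected_frame([("Chr1", 100), ("Chr2", 200)])
        assert len(merge_regions(sel, merge_gap=10**9)) == 2

    def test_order_independent_and_idempotent(self):
        pairs = [("c1", 500), ("c1", 100), ("c2", 90), ("c1", 400_000)]
        a = merge_regions(selected_frame(pairs), merge_gap=1000)
        b = merge_regions(selected_frame(list(reversed(pairs))), merge_gap=1000)
        assert [(r.chromosome, r.start, r.end) for r in a] == [
            (r.chromosome, r.start, r.end) for r in b
        ]
        # re-merging the merged members changes nothing
        again = merge_regions(
            selected_frame([(r.chromosome, p) for r in a for p in r.members]),
            merge_gap=1000,
        )
        assert [(r.chromosome, r.start, r.end) for r in again] == [
            (r.chromosome, r.start, r.end) for r in a
        ]

    def test_region_count_monotone_in_gap(self):
        rng = np.random.default_rng(2)
        pos = np.sort(rng.choice(1_000_000, size=40, replace=False))
        sel = selected_frame([("c1", int(p)) for p in pos])
        counts = [
            len(merge_regions(sel, merge_gap=g))
            for g in (0, 1_000, 10_000, 100_000, 1_000_000)
        ]
        assert counts == sorted(counts, reverse=True)
        assert counts[-1] == 1 and counts[0] == 40


class TestNearestGene:
    GENES = [
        GeneModel("LOC116195387", "Chr1", 11_267_388, 11_268_657, "Lea5-like"),
        GeneModel("other", "Chr1", 20_000_000, 20_001_000, ""),
    ]

    def test_observed_locus_distance(self):
        region = Region("Chr1", 11_265_285, 11_265_285)
        gene_id, dist = nearest_gene(region, self.GENES)
        assert gene_id == "LOC116195387" and dist == 2_103

    def test_overlap_is_distance_zero(self):
        region = Region("Chr1", 11_268_000, 11_268_100)
        assert nearest_gene(region, self.GENES) == ("LOC116195387", 0)

    def test_tie_broken_by_lower_start(self):
        genes = [
            GeneModel("right", "c", 200, 210),
            GeneModel("left", "c", 90, 100),
        ]
        region = Region("c", 150, 150)
        assert nearest_gene(region, genes) == ("left", 50)

    def test_no_genes_on_chromosome(self):
        region = Region("Chr9", 1, 2)
        assert nearest_gene(region, self.GENES) == (None, None)


class TestRegionR2:
    def test_identical_vectors_give_one(self, small_panel):
        row = np.array([0, 0, 1, 2, 2, 1], dtype=np.int8)
        calls = np.vstack([row] * 4)
        gm = make_genotype_matrix(calls, small_panel)
        region = Region("chr1", 100, 3100, members=list(gm.loci["pos"]))
        min_r2, ok = region_r2_check(region, gm)
        assert min_r2 == pytest.approx(1.0) and ok

    def test_independent_locus_fails(self):
        panel = CultivarPanel.from_mapping(
            {f"c{i}": "unassigned" for i in range(40)}
        )
        rng = np.random.default_rng(5)
        base = rng.choice([0, 1, 2], size=40).astype(np.int8)
        indep = rng.choice([0, 1, 2], size=40).astype(np.int8)
        calls = np.vstack([base, base, indep])
        gm = make_genotype_matrix(calls, panel)
        region = Region("chr1", 100, 2100, members=list(gm.loci["pos"]))
        min_r2, ok = region_r2_check(region, gm)
        assert not ok and min_r2 < 0.95

    def test_single_locus_not_applicable(self, small_panel):
        calls = np.zeros((1, 6), dtype=np.int8)
        gm = make_genotype_matrix(calls, small_panel)
        region = Region("chr1", 100, 100, members=[100])
        assert region_r2_check(region, gm) == (None, None)

    def test_strict_threshold_one_fails_under_noise(self, small_panel):
        rng = np.random.default_rng(9)
        base = rng.choice([0, 2], size=6).astype(np.int8)
        noisy = base.copy()
        noisy[0] = 1
        gm = make_genotype_matrix(np.vstack([base, noisy]), small_panel)
        region = Region("chr1", 100, 1100, members=[100, 1100])
        _, ok = region_r2_check(region, gm, threshold=1.0)
        assert not ok
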