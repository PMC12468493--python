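"""Downsampling, variant normalization/comparison, GC strata, pileup caller."""

from __future__ import annotations

import numpy as np
import pytest

import covuniform as cv
from covuniform.intervals import GenomicInterval
from covuniform.varianteval import (
    VariantKey,
    compare_variants,
    downsample_fastq,
    make_gc_strata,
    naive_pileup_caller,
    normalize_variant,
    read_vcf,
    stratify_by_gc,
)


class TestDownsample:
    def test_full_sample_is_identity(self, library_30x, tmp_path):
        d = library_30x["dir"]
        n_pairs = len(library_30x["pairs"])
        o1, o2 = tmp_path / "o1.fq", tmp_path / "o2.fq"
        assert downsample_fastq(d / "r1.fastq", d / "r2.fastq", n_pairs, 1, o1, o2) == n_pairs
        assert o1.read_bytes() == (d / "r1.fastq").read_bytes()
        assert o2.read_bytes() == (d / "r2.fastq").read_bytes()

    def test_zero_pairs_gives_empty_files(self, library_30x, tmp_path):
        d = library_30x["dir"]
        o1, o2 = tmp_path / "o1.fq", tmp_path / "o2.fq"
        downsample_fastq(d / "r1.fastq", d / "r2.fastq", 0, 1, o1, o2)
        assert o1.read_bytes() == b"" and o2.read_bytes() == b""

    def test_deterministic_and_seed_sensitive(self, library_30x, tmp_path):
        d = library_30x["dir"]
        outs = []
        for tag, seed in (("a", 5), ("b", 5), ("c", 6)):
            o1, o2 = tmp_path / f"{tag}1.fq", tmp_path / f"{tag}2.fq"
            downsample_fastq(d / "r1.fastq", d / "r2.fastq", 1000, seed, o1, o2)
            outs.append(o1.read_bytes())
        assert outs[0] == outs[1]
        assert outs[0] != outs[2]

    def test_order_preserved_and_pairs_kept_together(self, library_30x, tmp_path):
        d = library_30x["dir"]
        o1, o2 = tmp_path / "o1.fq", tmp_path / "o2.fq"
        downsample_fastq(d / "r1.fastq", d / "r2.fastq", 500, 2, o1, o2)
        ids1 = [l.split("/")[0] for l in o1.read_text().splitlines()[::4]]
        ids2 = [l.split("/")[0] for l in o2.read_text().splitlines()[::4]]
        assert ids1 == ids2 and ids1 == sorted(ids1)

    def test_desynchronized_pairs_detected(self, tmp_path):
        r1, r2 = tmp_path / "r1.fq", tmp_path / "r2.fq"
        r1.write_text("@a/1\nACGT\n+\nIIII\n@b/1\nACGT\n+\nIIII\n")
        r2.write_text("@a/2\nACGT\n+\nIIII\n@c/2\nACGT\n+\nIIII\n")
        with pytest.raises(ValueError, match="desynchronized"):
            downsample_fastq(r1, r2, 1, 0, tmp_path / "o1", tmp_path / "o2")

    def test_oversampling_rejected(self, tmp_path):
        r1 = tmp_path / "r1.fq"
        r1.write_text("@a/1\nACGT\n+\nIIII\n")
        with pytest.raises(ValueError):
            downsample_fastq(r1, r1, 2, 0, tmp_path / "o1", tmp_path / "o2")


class TestNormalizeVariant:
    REF = {"chr1": "GGGCACACACTTTT"}  # CA repeat from pos 4 (1-based 5)

    def test_snp_passthrough(self):
        k = normalize_variant("chr1", 5, "A", "T", "het", self.REF)
        assert (k.pos, k.ref, k.alt) == (5, "A", "T")
        assert k.is_snp and k.variant_class == "SNP"

    def test_multibase_snp_trimmed(self):
        k = normalize_variant("chr1", 4, "CAC", "CGC", "het", self.REF)
        assert (k.pos, k.ref, k.alt) == (5, "A", "G")

    def test_indel_left_aligned_in_repeat(self):
        # deleting one CA unit anywhere in the repeat normalizes to pos 3
        k1 = normalize_variant("chr1", 6, "CAC", "C", "het", self.REF)
        k2 = normalize_variant("chr1", 8, "CAC", "C", "het", self.REF)
        assert k1.site == k2.site
        assert k1.pos == 3

    def test_insertion_left_aligned(self):
        k1 = normalize_variant("chr1", 6, "C", "CAC", "het", self.REF)
        k2 = normalize_variant("chr1", 8, "C", "CAC", "het", self.REF)
        assert k1.site == k2.site

    def test_identity_alleles_rejected(self):
        with pytest.raises(ValueError):
            normalize_variant("chr1", 5, "A", "A", "het", self.REF)


class TestCompareVariants:
    CONF = [GenomicInterval("chr1", 0, 10_000)]

    def test_query_equals_truth(self):
        t = [VariantKey("chr1", 100, "A", "G", "het"), VariantKey("chr1", 200, "C", "T", "hom")]
        res = compare_variants(t, t, self.CONF)
        assert res["SNP"].fp == res["SNP"].fn == 0
        assert res["SNP"].f1 == 1.0

    def test_enumerated_mixed_case(self):
        truth = [VariantKey("chr1", 100, "A", "G", "het"), VariantKey("chr1", 200, "C", "T", "hom")]
        query = [VariantKey("chr1", 100, "A", "G", "het"), VariantKey("chr1", 300, "G", "A", "het")]
        res = compare_variants(query, truth, self.CONF)["SNP"]
        assert (res.tp, res.fn, res.fp) == (1, 1, 1)
        assert res.precision == res.recall == res.f1 == 0.5

    def test_genotype_mismatch_is_fp_plus_fn(self):
        truth = [VariantKey("chr1", 100, "A", "G", "hom")]
        query = [VariantKey("chr1", 100, "A", "G", "het")]
        res = compare_variants(query, truth, self.CONF)["SNP"]
        assert (res.tp, res.fp, res.fn) == (0, 1, 1)

    def test_confinement_drops_outside_calls(self):
        truth = [VariantKey("chr1", 100, "A", "G", "het")]
        query = [VariantKey("chr1", 100, "A", "G", "het"), VariantKey("chr1", 20_000, "A", "C", "het")]
        res = compare_variants(query, truth, self.CONF)["SNP"]
        assert (res.tp, res.fp) == (1, 0)

    def test_classes_scored_separately(self):
        truth = [VariantKey("chr1", 100, "A", "G", "het"), VariantKey("chr1", 200, "CT", "C", "het")]
        res = compare_variants([], truth, self.CONF)
        assert res["SNP"].fn == 1 and res["indel"].fn == 1

    def test_empty_truth_raises(self):
        with pytest.raises(ValueError):
            compare_variants([VariantKey("chr1", 5, "A", "G", "het")], [], self.CONF)

    def test_agrees_with_set_intersection_oracle(self):
        """1000 random query/truth pairs: tallies equal a brute-force
        O(n^2) scan, and tp + fn always equals the confined truth count."""
        rng = np.random.default_rng(7)
        for _ in range(1000):
            def rand_keys(n):
                keys = set()
                while len(keys) < n:
                    pos = int(rng.integers(1, 60))
                    ref, alt = "AG" if rng.random() < 0.5 else ("C", "CT")[0:2]
                    if rng.random() < 0.3:
                        ref, alt = "C", "CTT"
                    keys.add(
                        VariantKey(
                            "chr1", pos, ref, alt, "het" if rng.random() < 0.5 else "hom"
                        )
                    )
                return list(keys)

            truth = rand_keys(int(rng.integers(1, 12)))
            query = rand_keys(int(rng.integers(0, 12)))
            conf = [GenomicInterval("chr1", 0, int(rng.integers(30, 70)))]
            res = compare_variants(query, truth, conf, require_truth=False)
            for cls in ("SNP", "indel"):
                t_in = [k for k in truth if k.variant_class == cls and k.pos - 1 < conf[0].end]
                q_in = [k for k in query if k.variant_class == cls and k.pos - 1 < conf[0].end]
                tp = sum(1 for q in q_in if any(q == t for t in t_in))
                assert res[cls].tp == tp
                assert res[cls].fp == len(q_in) - tp
                assert res[cls].fn == len(t_in) - tp
                assert res[cls].tp + res[cls].fn == len(t_in)


class TestStrata:
    def test_all_g_genome_single_stratum(self):
        strata = make_gc_strata({"chr1": "G" * 500}, window=100, edges_percent=(0, 50, 95, 100))
        assert list(strata) == ["gc95to100"]
        (iv,) = strata["gc95to100"]
        assert (iv.start, iv.end) == (0, 500)

    def test_alternating_blocks_split_evenly(self):
        ref = {"chr1": ("A" * 100 + "G" * 100) * 5}
        strata = make_gc_strata(ref, window=100, edges_percent=(0, 50, 100))
        low = sum(len(iv) for iv in strata["gc0to50"])
        high = sum(len(iv) for iv in strata["gc50to100"])
        assert low == high == 500

    def test_strata_partition_random_genome(self):
        """Union covers the genome; strata are pairwise disjoint."""
        g = cv.simulate_genome(20_000, seed=9)
        strata = make_gc_strata({g.name: g.sequence}, window=100)
        covered = np.zeros(len(g), dtype=int)
        for ivs in strata.values():
            for iv in ivs:
                covered[iv.start : iv.end] += 1
        assert np.all(covered == 1)

    def test_single_stratum_equals_unstratified(self, library_30x):
        ref = library_30x["reference"]
        truth = read_vcf(library_30x["dir"] / "truth.vcf", ref)
        calls = naive_pileup_caller(library_30x["sam"], ref)
        conf = library_30x["truth"].confident_regions
        whole = {"everything": conf}
        rows = stratify_by_gc(calls, truth, conf, whole)
        overall = compare_variants(calls, truth, conf)
        by_cls = {c.variant_class: c for c in rows if c.stratum == "everything"}
        for cls in ("SNP", "indel"):
            assert (by_cls[cls].tp, by_cls[cls].fp, by_cls[cls].fn) == (
                overall[cls].tp, overall[cls].fp, overall[cls].fn,
            )

    def test_unbiased_library_has_even_f1_across_strata(self, library_30x):
        """Without GC dropout, per-stratum SNP F1 varies by <= 0.05 at 30X
        (among strata holding enough truth variants to estimate F1)."""
        ref = library_30x["reference"]
        truth = read_vcf(library_30x["dir"] / "truth.vcf", ref)
        calls = naive_pileup_caller(library_30x["sam"], ref)
        conf = library_30x["truth"].confident_regions
        rows = stratify_by_gc(calls, truth, conf, make_gc_strata(ref))
        f1s = [
            c.f1
            for c in rows
            if c.variant_class == "SNP" and c.stratum != "unstratified" and c.n_truth >= 5
        ]
        assert len(f1s) >= 2
        assert max(f1s) - min(f1s) <= 0.05

    def test_empty_stratum_flagged_without_division_error(self):
        truth = [VariantKey("chr1", 100, "A", "G", "het")]
        strata = {"hit": [GenomicInterval("chr1", 0, 200)], "miss": [GenomicInterval("chr1", 5000, 6000)]}
        rows = stratify_by_gc(truth, truth, [GenomicInterval("chr1", 0, 10_000)], strata)
        miss_snp = next(c for c in rows if c.stratum == "miss" and c.variant_class == "SNP")
        assert miss_snp.empty and miss_snp.f1 == 0.0


class TestNaivePileupCaller:
    def test_recovers_planted_variants_at_30x(self, library_30x):
        """F1 >= 0.95 against the planted truth at 30X, error rate 1e-3."""
        ref = library_30x["reference"]
        calls = naive_pileup_caller(library_30x["sam"], ref)
        truth = read_vcf(library_30x["dir"] / "truth.vcf", ref)
        res = compare_variants(calls, truth, library_30x["truth"].confident_regions)
        assert res["SNP"].recall >= 0.95
        assert res["SNP"].f1 >= 0.95
        assert res["indel"].f1 >= 0.9

    def test_hom_and_het_thresholds(self, tmp_path):
        ref = {"chr1": "A" * 200}
        sam = tmp_path / "t.sam"
        lines = ["@HD\tVN:1.6\tSO:coordinate", "@SQ\tSN:chr1\tLN:200"]
        # 10 reads with G at offset 50 (hom); 10 reads where half carry T at 120
        for i in range(10):
            seq = "A" * 30
            seq = seq[:10] + "G" + seq[11:]
            lines.append(f"r{i}\t0\tchr1\t41\t60\t30M\t*\t0\t0\t{seq}\t{'I'*30}")
        for i in range(10):
            base = "T" if i % 2 == 0 else "A"
            seq = "A" * 30
            seq = seq[:10] + base + seq[11:]
            lines.append(f"s{i}\t0\tchr1\t111\t60\t30M\t*\t0\t0\t{seq}\t{'I'*30}")
        sam.write_text("\n".join(lines) + "\n")
        calls = naive_pileup_caller(sam, ref, min_depth=8, min_alt_fraction=0.2)
        by_pos = {c.pos: c for c in calls}
        assert by_pos[51].genotype == "hom" and by_pos[51].alt == "G"
        assert by_pos[121].genotype == "het" and by_pos[121].alt == "T"

    def test_downsampling_reduces_recall(self, library_30x, tmp_path):
        """Recall at ~5X is no better than at 30X (fewer sites reach the
        depth threshold)."""
        from covuniform import coverage, simulate

        d = library_30x["dir"]
        n5 = len(library_30x["pairs"]) // 6
        o1, o2 = tmp_path / "d1.fq", tmp_path / "d2.fq"
        downsample_fastq(d / "r1.fastq", d / "r2.fastq", n5, 3, o1, o2)
        kept_ids = {l.split("/")[0][1:] for l in o1.read_text().splitlines()[::4]}
        pairs5 = [p for p in library_30x["pairs"] if p.name in kept_ids]
        sam5 = tmp_path / "d.sam"
        genome = library_30x["genome"]
        simulate.write_sam(pairs5, {genome.name: len(genome)}, sam5)
        ref = library_30x["reference"]
        truth = read_vcf(d / "truth.vcf", ref)
        conf = library_30x["truth"].confident_regions
        recall5 = compare_variants(naive_pileup_caller(sam5, ref), truth, conf)["SNP"].recall
        recall30 = compare_variants(naive_pileup_caller(library_30x["sam"], ref), truth, conf)[
            "SNP"
        ].recall
        assert recall5 <= recall30
        assert recall30 >= 0.95
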