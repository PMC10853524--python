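import numpy as np
import pandas as pd
import pytest

from xrprofile import (
    GeneModel,
    GenomicInterval,
    InputError,
    chromatin_state_repair,
    correlate_expression,
    count_overlaps,
    gene_ts_nts,
    metagene_profile,
    pairwise_state_tests,
    rpkm,
    select_longest_isoform,
    star_label,
    ts_nts_distribution_summary,
)
from xrprofile.intervals import ChromatinSegment

from conftest import make_reads


def gene(chrom, start, end, strand, gid="g"):
    return GeneModel(gid, GenomicInterval(chrom, start, end, strand))


class TestRpkm:
    def test_unit_case(self):
        assert rpkm(10, 1000, 1_000_000) == 10.0

    def test_zero_count(self):
        assert rpkm(0, 1234, 5_000_000) == 0.0

    def test_hand_evaluated(self):
        assert rpkm(5, 500, 2_000_000) == 5.0

    def test_invalid_inputs(self):
        with pytest.raises(InputError):
            rpkm(1, 0, 1000)
        with pytest.raises(InputError):
            rpkm(1, 100, 0)


def oracle_counts(features, reads, mode, t):
    """O(n*m) nested-loop reference counter."""
    out = []
    flip = {"+": "-", "-": "+"}
    for f in features:
        iv = f.interval if hasattr(f, "interval") else f
        c = 0
        for rec in reads:
            r = rec.interval
            if r.chrom != iv.chrom:
                continue
            if mode == "same" and r.strand != iv.strand:
                continue
            if mode == "opposite" and r.strand != flip.get(iv.strand):
                continue
            if min(r.end, iv.end) - max(r.start, iv.start) >= t:
                c += 1
        out.append(c)
    return np.array(out)


class TestCountOverlaps:
    reads = make_reads([("chr1", 10, 37, "+")])

    def test_same_strand_hit(self):
        f = [GenomicInterval("chr1", 0, 20, "+")]
        assert count_overlaps(f, self.reads, "same")[0] == 1

    def test_opposite_strand_miss(self):
        f = [GenomicInterval("chr1", 0, 20, "+")]
        assert count_overlaps(f, self.reads, "opposite")[0] == 0

    def test_unknown_mode(self):
        with pytest.raises(InputError):
            count_overlaps([], self.reads, "both")

    @pytest.mark.parametrize("mode", ["same", "opposite", "ignore"])
    @pytest.mark.parametrize("min_overlap", [1, 5, 20])
    def test_matches_nested_loop_oracle(self, mode, min_overlap):
        rng = np.random.default_rng(17)
        for _ in range(10):
            rows = []
            for i in range(int(rng.integers(1, 200))):
                s = int(rng.integers(0, 2000))
                rows.append(
                    (f"chr{rng.integers(1, 3)}", s, s + int(rng.integers(1, 40)),
                     "+" if rng.random() < 0.5 else "-")
                )
            reads = make_reads(rows)
            feats = []
            for i in range(int(rng.integers(1, 30))):
                s = int(rng.integers(0, 2000))
                feats.append(
                    GenomicInterval(
                        f"chr{rng.integers(1, 3)}", s, s + int(rng.integers(1, 200)),
                        "+" if rng.random() < 0.5 else "-",
                    )
                )
            got = count_overlaps(feats, reads, mode, min_overlap)
            assert (got == oracle_counts(feats, reads, mode, min_overlap)).all()


class TestMetagene:
    def test_identity_normalization_is_one(self, small_dataset):
        ds = small_dataset
        prof = metagene_profile(ds.genes, ds.reads, ds.reads, ds.genome)
        for cls in ("TS", "NTS"):
            vals = prof.normalized(cls)
            defined = vals[~np.isnan(vals)]
            assert len(defined) > 50
            assert np.all(defined == 1.0)

    def test_bin_counts_conserved_per_gene(self, small_dataset):
        """Summing the 100 bin counts reproduces a single-bin metagene count:
        binning neither loses nor double-counts reads."""
        ds = small_dataset
        g = [ds.genes[3]]
        many = metagene_profile(g, ds.reads, ds.reads, ds.genome, n_bins=100)
        one = metagene_profile(g, ds.reads, ds.reads, ds.genome, n_bins=1)
        for cls in ("TS", "NTS"):
            assert many.tables[cls]["real_count"].sum() == one.tables[cls]["real_count"].sum()

    def test_scaling_invariance(self, small_dataset, small_sim):
        from xrprofile.intervals import ReadSet

        ds = small_dataset
        sim, _ = small_sim
        base = metagene_profile(ds.genes, ds.reads, sim, ds.genome)
        doubled = metagene_profile(
            ds.genes,
            ReadSet.concat([ds.reads, ds.reads]),
            ReadSet.concat([sim, sim]),
            ds.genome,
        )
        for cls in ("TS", "NTS"):
            a, b = base.normalized(cls), doubled.normalized(cls)
            assert np.allclose(a[~np.isnan(a)], b[~np.isnan(b)])

    def test_flat_profile_on_uniform_coverage(self):
        rng = np.random.default_rng(23)
        sizes = {"chr1": 30_000}
        g = [gene("chr1", 10_000, 14_000, "+")]
        def uniform(seed):
            r = np.random.default_rng(seed)
            rows = []
            for i in range(20_000):
                s = int(r.integers(0, 30_000 - 27))
                rows.append(("chr1", s, s + 27, "+" if r.random() < 0.5 else "-"))
            return make_reads(rows)
        prof = metagene_profile(g, uniform(1), uniform(2), sizes)
        vals = np.concatenate([prof.normalized("TS"), prof.normalized("NTS")])
        assert np.nanmean(vals) == pytest.approx(1.0, abs=0.05)

    def test_minus_strand_gene_orientation(self):
        """Bin 1 is 5'-most: a read pile at the 5' end of a minus-strand gene
        lands in an early bin."""
        sizes = {"chr1": 10_000}
        g = [gene("chr1", 4_000, 6_000, "-")]
        # 5' end of a minus gene is at coordinate 6000; pile reads just inside
        real = make_reads([("chr1", 5_950, 5_977, "+") for _ in range(50)])
        rng = np.random.default_rng(3)
        sim_rows = [
            ("chr1", int(rng.integers(3_000, 7_000)), 0, "+") for _ in range(2_000)
        ]
        sim_rows = [(c, s, s + 27, "+") for c, s, _, _ in sim_rows]
        sim = make_reads(sim_rows)
        prof = metagene_profile(g, real, sim, sizes)
        ts = prof.tables["TS"]["real_count"].to_numpy()  # '+' reads on a '-' gene = TS
        peak_bin = int(np.argmax(ts))
        assert 25 <= peak_bin <= 28  # just inside the gene body start

    def test_gene_out_of_bounds_skipped(self):
        sizes = {"chr1": 3_000}
        genes = [gene("chr1", 100, 2_000, "+", "edge"), gene("chr1", 1_000, 2_000, "+", "ok")]
        reads = make_reads([("chr1", 1_200, 1_227, "+") for _ in range(10)])
        prof = metagene_profile(genes, reads, reads, sizes)
        assert prof.skipped_genes == ["edge"]
        assert prof.n_genes_used == 1

    def test_appended_layout_shape(self, small_dataset):
        ds = small_dataset
        prof = metagene_profile(
            ds.genes, ds.reads, ds.reads, ds.genome, n_bins=100, bin_layout="appended"
        )
        assert len(prof.tables["TS"]) == 150
        assert prof.body_slice == (25, 125)


class TestGeneTsNts:
    def test_formula_log2_ratio(self):
        g = [gene("chr1", 0, 1000, "+", "g1")]
        real = make_reads(
            [("chr1", i * 30, i * 30 + 27, "-") for i in range(20)]  # TS of a + gene
            + [("chr1", i * 30, i * 30 + 27, "+") for i in range(10)]
        )
        sim = make_reads(
            [("chr1", i * 30, i * 30 + 27, "-") for i in range(10)]
            + [("chr1", i * 30, i * 30 + 27, "+") for i in range(10)]
        )
        rec = gene_ts_nts(g, real, sim)
        assert rec.loc[0, "real_ts"] == 20 and rec.loc[0, "real_nts"] == 10
        assert rec.loc[0, "log2_ts_nts"] == pytest.approx(1.0)

    def test_zero_count_flagged_undefined(self):
        g = [gene("chr1", 0, 1000, "+", "g1")]
        real = make_reads([("chr1", 0, 27, "+")])  # NTS only
        sim = make_reads([("chr1", 0, 27, "+"), ("chr1", 30, 57, "-")])
        rec = gene_ts_nts(g, real, sim)
        assert not rec.loc[0, "defined"]
        assert np.isnan(rec.loc[0, "log2_ts_nts"])

    def test_identity_gives_zero_log2(self, small_dataset):
        ds = small_dataset
        rec = gene_ts_nts(ds.genes, ds.reads, ds.reads)
        vals = rec.loc[rec["defined"], "log2_ts_nts"]
        assert np.allclose(vals, 0.0)


class TestTsNtsSummary:
    def _records(self, vals):
        return pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(len(vals))],
                "log2_ts_nts": vals,
                "defined": [True] * len(vals),
            }
        )

    def test_identity_summary_zero(self, small_dataset):
        ds = small_dataset
        rec = gene_ts_nts(ds.genes, ds.reads, ds.reads)
        s = ts_nts_distribution_summary(rec)
        assert s.summary["median"].iloc[0] == 0.0

    def test_single_record_degenerate(self):
        s = ts_nts_distribution_summary(self._records([0.7]))
        assert s.summary["median"].iloc[0] == pytest.approx(0.7)
        assert s.summary["q1"].iloc[0] == pytest.approx(0.7)

    def test_stochastic_dominance_detected(self):
        rng = np.random.default_rng(4)
        strong = self._records(rng.normal(1.0, 0.3, 150))
        weak = self._records(rng.normal(0.0, 0.3, 150))
        s = ts_nts_distribution_summary(strong, weak, "strong", "weak")
        med = s.summary.set_index("label")["median"]
        assert med["strong"] > med["weak"]
        assert s.comparison_p < 1e-6


class TestChromatinStates:
    def _segs(self):
        return [
            ChromatinSegment(GenomicInterval("chr1", 0, 1000, "."), "open"),
            ChromatinSegment(GenomicInterval("chr1", 1000, 2000, "."), "hetAT"),
            ChromatinSegment(GenomicInterval("chr1", 2000, 3000, "."), "open"),
        ]

    def test_identity_is_one(self):
        reads = make_reads([("chr1", i * 100, i * 100 + 27, "+") for i in range(25)])
        table = chromatin_state_repair(self._segs(), reads, reads)
        assert np.allclose(table.segments["normalized"].dropna(), 1.0)

    def test_strandless_counting(self):
        segs = self._segs()[:1]
        reads = make_reads([("chr1", 10, 37, "+"), ("chr1", 50, 77, "-")])
        table = chromatin_state_repair(segs, reads, reads)
        assert table.segments.loc[0, "real_count"] == 2

    def test_one_segment_state_vector(self):
        reads = make_reads([("chr1", i * 100, i * 100 + 27, "+") for i in range(25)])
        table = chromatin_state_repair(self._segs(), reads, reads)
        assert len(table.vectors["hetAT"]) == 1
        assert len(table.vectors["open"]) == 2

    def test_zero_sim_segment_excluded(self):
        segs = self._segs()
        real = make_reads([("chr1", 1500, 1527, "+"), ("chr1", 10, 37, "+")])
        sim = make_reads([("chr1", 10, 37, "+"), ("chr1", 2500, 2527, "-")])
        table = chromatin_state_repair(segs, real, sim)
        assert table.n_excluded_zero_sim == 1
        assert "hetAT" in table.excluded_states


class TestPairwiseStateTests:
    def test_identical_vectors_ns(self):
        v = np.array([1.0, 1.2, 0.9, 1.1])
        segs = pd.DataFrame(
            {
                "state": ["a"] * 4 + ["b"] * 4,
                "normalized": np.concatenate([v, v]),
            }
        )
        from xrprofile.repair_profiles import StateRepairTable

        table = StateRepairTable(segs, 0, [])
        res = pairwise_state_tests(table)
        row = res.iloc[0]
        assert row["t"] == pytest.approx(0.0)
        assert row["label"] == "ns"

    def test_star_thresholds(self):
        assert star_label(0.2) == "ns"
        assert star_label(0.05) == "*"
        assert star_label(0.03) == "*"
        assert star_label(0.009) == "**"
        assert star_label(0.0005) == "***"
        assert star_label(0.00005) == "****"

    def test_separated_samples_highly_significant(self):
        """Means 0 vs 1 (sd 1, n=50): the Welch test is significant at 0.01
        in every seeded replicate and reaches '****' in the large majority."""
        from xrprofile.repair_profiles import StateRepairTable

        labels = []
        pvals = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            a = rng.normal(0.0, 1.0, 50)
            b = rng.normal(1.0, 1.0, 50)
            segs = pd.DataFrame(
                {"state": ["a"] * 50 + ["b"] * 50, "normalized": np.concatenate([a, b])}
            )
            res = pairwise_state_tests(StateRepairTable(segs, 0, []))
            labels.append(res.iloc[0]["label"])
            pvals.append(res.iloc[0]["p"])
        assert all(p <= 0.01 for p in pvals)
        assert sum(l == "****" for l in labels) >= 0.6 * len(labels)

    def test_degenerate_vector_skipped(self):
        from xrprofile.repair_profiles import StateRepairTable

        segs = pd.DataFrame({"state": ["a", "b", "b"], "normalized": [1.0, 2.0, 2.1]})
        res = pairwise_state_tests(StateRepairTable(segs, 0, []))
        assert res.iloc[0]["skipped_reason"] == "fewer than 2 segments"


class TestLongestIsoform:
    def test_longest_wins(self):
        df = pd.DataFrame(
            {
                "transcript_id": ["t1", "t2"],
                "gene_id": ["g", "g"],
                "length": [500, 800],
                "tpm": [2.0, 5.0],
            }
        )
        assert select_longest_isoform(df)["g"] == 5.0

    def test_single_isoform(self):
        df = pd.DataFrame(
            {"transcript_id": ["t1"], "gene_id": ["g"], "length": [100], "tpm": [7.0]}
        )
        assert select_longest_isoform(df)["g"] == 7.0

    def test_tie_breaks_to_smaller_transcript_id(self):
        df = pd.DataFrame(
            {
                "transcript_id": ["t9", "t1"],
                "gene_id": ["g", "g"],
                "length": [800, 800],
                "tpm": [3.0, 4.0],
            }
        )
        assert select_longest_isoform(df)["g"] == 4.0


class TestCorrelateExpression:
    def _records(self, ratios, ids=None):
        ids = ids or [f"g{i}" for i in range(len(ratios))]
        return pd.DataFrame({"gene_id": ids, "log2_ts_nts": ratios, "defined": True})

    def test_perfect_linear(self):
        tpm = pd.Series({f"g{i}": float(i + 1) for i in range(10)})
        x = np.log10(tpm.to_numpy() + 0.1)
        rec = self._records(2 * x)
        res = correlate_expression(rec, tpm)
        assert res.r == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        tpm = pd.Series({f"g{i}": float(i + 1) for i in range(10)})
        rec = self._records([1.0] * 10)
        with pytest.raises(InputError, match="variance"):
            correlate_expression(rec, tpm)

    def test_too_few_genes_rejected(self):
        tpm = pd.Series({"g0": 1.0, "g1": 2.0})
        with pytest.raises(InputError, match=">= 3"):
            correlate_expression(self._records([0.1, 0.2]), tpm)

    def test_fisher_interval_bivariate_normal(self):
        rng = np.random.default_rng(77)
        n = 500
        x = rng.normal(size=n)
        y = 0.5 * x + np.sqrt(1 - 0.25) * rng.normal(size=n)
        tpm = pd.Series(x, index=[f"g{i}" for i in range(n)])
        rec = self._records(y)
        res = correlate_expression(rec, tpm, transform="raw")
        assert 0.41 <= res.r <= 0.58  # 95% Fisher-z interval around rho=0.5
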