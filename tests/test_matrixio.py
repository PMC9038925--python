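"""Peak merging, CPM normalisation, QC and annotation against oracles."""

import numpy as np
import pandas as pd
import pytest

from atacstrat.matrixio import (
    GeneAnnotation,
    PeakSet,
    annotate_peaks,
    classify_genomic_features,
    cpm_normalize,
    merge_peak_calls,
    presence_histogram,
    read_bed,
    read_genes_tsv,
    read_matrix_tsv,
    replicate_qc,
    write_bed,
    write_genes_tsv,
    write_matrix_tsv,
)


def _peakset(intervals, chrom="chr1"):
    return PeakSet.from_arrays(
        [chrom] * len(intervals),
        [s for s, _ in intervals],
        [e for _, e in intervals],
    )


def brute_force_merge(intervals):
    """O(n^2) union via repeated pairwise merging to a fixpoint."""
    merged = [list(iv) for iv in intervals]
    changed = True
    while changed:
        changed = False
        for i in range(len(merged)):
            for j in range(i + 1, len(merged)):
                a, b = merged[i], merged[j]
                if a[0] == b[0] and a[1] <= b[2] and b[1] <= a[2]:
                    merged[i] = [a[0], min(a[1], b[1]), max(a[2], b[2])]
                    merged.pop(j)
                    changed = True
                    break
            if changed:
                break
    return sorted(tuple(m) for m in merged)


class TestMergePeakCalls:
    def test_overlap_union(self):
        peaks, presence = merge_peak_calls(
            [_peakset([(100, 200)]), _peakset([(150, 250)])]
        )
        assert peaks.df[["start", "end"]].to_numpy().tolist() == [[100, 250]]
        assert presence.to_numpy().tolist() == [[1, 1]]

    def test_disjoint(self):
        peaks, presence = merge_peak_calls(
            [_peakset([(100, 200)]), _peakset([(300, 400)])]
        )
        assert len(peaks) == 2
        assert presence.to_numpy().tolist() == [[1, 0], [0, 1]]

    def test_bookended_intervals_merge(self):
        peaks, _ = merge_peak_calls([_peakset([(100, 200), (200, 300)])])
        assert peaks.df[["start", "end"]].to_numpy().tolist() == [[100, 300]]

    def test_malformed_interval_rejected(self):
        with pytest.raises(ValueError, match="start >= end"):
            _peakset([(200, 100)])

    @pytest.mark.parametrize("trial", range(5))
    def test_random_against_quadratic_oracle(self, trial):
        rng = np.random.default_rng(500 + trial)
        sample_sets = []
        all_iv = []
        for _ in range(3):
            starts = rng.integers(0, 9_800, size=50)
            lengths = rng.integers(1, 200, size=50)
            ivs = [(int(s), int(s + l)) for s, l in zip(starts, lengths)]
            sample_sets.append(_peakset(ivs))
            all_iv.extend(("chr1", s, e) for s, e in ivs)
        merged, presence = merge_peak_calls(sample_sets)
        expected = brute_force_merge(all_iv)
        got = [
            ("chr1", int(s), int(e))
            for s, e in merged.df[["start", "end"]].to_numpy()
        ]
        assert got == expected
        # presence oracle: brute-force overlap test
        for i, (_, ms, me) in enumerate(got):
            for j, ps in enumerate(sample_sets):
                hit = any(
                    s < me and ms < e
                    for s, e in ps.df[["start", "end"]].to_numpy()
                )
                assert presence.iloc[i, j] == int(hit)

    def test_merge_idempotent(self):
        rng = np.random.default_rng(7)
        ivs = [(int(s), int(s) + int(l)) for s, l in
               zip(rng.integers(0, 5000, 100), rng.integers(1, 150, 100))]
        once, _ = merge_peak_calls([_peakset(ivs)])
        twice, _ = merge_peak_calls([once])
        assert once.df[["chrom", "start", "end"]].equals(
            twice.df[["chrom", "start", "end"]]
        )
        assert len(once) <= len(ivs)


class TestCpmNormalize:
    def test_arithmetic(self):
        raw = pd.DataFrame({"s0": [200, 1_999_800]})
        cm = cpm_normalize(raw)
        assert cm.cpm.iloc[0, 0] == pytest.approx(100.0)

    def test_equal_entries(self):
        raw = pd.DataFrame({"s0": [5] * 8})
        cm = cpm_normalize(raw)
        assert np.allclose(cm.cpm["s0"], 1e6 / 8)

    def test_column_sums(self, rng):
        raw = pd.DataFrame(rng.integers(0, 1000, size=(100, 6)))
        cm = cpm_normalize(raw)
        assert np.allclose(cm.cpm.sum(axis=0), 1e6, atol=1e-6)
        assert (cm.logcpm.to_numpy() >= 0).all()

    def test_preserves_rank_order(self, rng):
        raw = pd.DataFrame(rng.integers(0, 1000, size=(50, 3)))
        cm = cpm_normalize(raw)
        for c in raw.columns:
            assert (
                raw[c].rank(method="average") == cm.cpm[c].rank(method="average")
            ).all()

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            cpm_normalize(pd.DataFrame({"s0": [-1, 5]}))

    def test_zero_column_warns(self):
        with pytest.warns(UserWarning, match="zero total"):
            cm = cpm_normalize(pd.DataFrame({"s0": [0, 0], "s1": [1, 1]}))
        assert (cm.cpm["s0"] == 0).all()


class TestReplicateQC:
    def test_duplicate_and_negated_columns(self, rng):
        x = rng.normal(size=200)
        logcpm = pd.DataFrame({"a": x, "b": x, "c": -x})
        qc = replicate_qc(logcpm, [("a", "b"), ("a", "c")])
        assert qc["r"].tolist() == pytest.approx([1.0, -1.0])
        assert qc["below_threshold"].tolist() == [False, True]

    def test_constant_column_reported_missing(self):
        logcpm = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]})
        qc = replicate_qc(logcpm, [("a", "b")])
        assert np.isnan(qc["r"].iloc[0])

    def test_noisy_replicate_matches_fisher_z_oracle(self):
        # population r = 0.9 via noise_sd chosen from the signal SD
        rng = np.random.default_rng(3)
        n, r_pop, sims = 300, 0.9, 200
        rs = np.empty(sims)
        for i in range(sims):
            x = rng.normal(size=n)
            noise = np.sqrt(1.0 / r_pop**2 - 1.0)
            y = x + rng.normal(0, noise, size=n)
            qc = replicate_qc(pd.DataFrame({"a": x, "b": y}), [("a", "b")])
            rs[i] = qc["r"].iloc[0]
        # Fisher z: mean atanh(r) ~ atanh(0.9), SE = 1/sqrt(n-3)
        z_mean = np.arctanh(rs).mean()
        se = 1.0 / np.sqrt(n - 3) / np.sqrt(sims)
        assert abs(z_mean - np.arctanh(r_pop)) < 3 * se + 1e-3


class TestPresenceHistogram:
    def test_all_ones(self):
        h = presence_histogram(np.ones((7, 4), dtype=int))
        assert h.loc[4] == 7 and h.drop(4).sum() == 0

    def test_identity_like(self):
        h = presence_histogram(np.eye(5, dtype=int))
        assert h.loc[1] == 5 and h.sum() == 5

    def test_random_matches_row_sum_tally(self, rng):
        mat = (rng.random((1000, 10)) < 0.3).astype(int)
        h = presence_histogram(mat)
        tally = np.bincount(mat.sum(axis=1), minlength=11)
        assert h.tolist() == tally[1:].tolist()
        assert h.sum() == (mat.sum(axis=1) > 0).sum()


class TestAnnotatePeaks:
    def test_midpoint_at_tss_is_promoter(self, toy_genes):
        peaks = _peakset([(99_750, 100_250)])
        ann = annotate_peaks(peaks, toy_genes)
        assert ann.iloc[0]["nearest_gene_id"] == "gA"
        assert ann.iloc[0]["distance"] == 0
        assert ann.iloc[0]["region_class"] == "promoter"

    def test_10kb_downstream_is_dre(self, toy_genes):
        peaks = _peakset([(109_750, 110_250)])
        ann = annotate_peaks(peaks, toy_genes)
        assert ann.iloc[0]["distance"] == 10_000
        assert ann.iloc[0]["region_class"] == "DRE"

    def test_minus_strand_signed_distance(self, toy_genes):
        # midpoint 10 kb to the right of a minus-strand TSS = upstream
        peaks = _peakset([(909_750, 910_250)])
        ann = annotate_peaks(peaks, toy_genes)
        assert ann.iloc[0]["nearest_gene_id"] == "gB"
        assert ann.iloc[0]["distance"] == -10_000

    def test_empty_gene_set_warns_all_other(self):
        peaks = _peakset([(0, 100)])
        with pytest.warns(UserWarning):
            ann = annotate_peaks(peaks, GeneAnnotation(
                pd.DataFrame(columns=["gene_id", "chrom", "strand", "tss"])
            ))
        assert (ann["region_class"] == "other").all()

    def test_random_against_all_pairs_oracle(self):
        rng = np.random.default_rng(99)
        tss = np.sort(rng.choice(np.arange(1000, 2_000_000), size=20, replace=False))
        genes = GeneAnnotation(
            pd.DataFrame(
                {
                    "gene_id": [f"g{i:02d}" for i in range(20)],
                    "chrom": "chr1",
                    "strand": rng.choice(["+", "-"], size=20),
                    "tss": tss,
                }
            )
        )
        starts = rng.integers(0, 2_000_000, size=200)
        peaks = _peakset([(int(s), int(s) + 400) for s in starts])
        ann = annotate_peaks(peaks, genes)
        gdf = genes.df
        for pid, (s, e) in zip(peaks.peak_ids, peaks.df[["start", "end"]].to_numpy()):
            mid = (s + e) // 2
            # exhaustive all-pairs oracle
            dists = [
                (abs(mid - t), gid, (mid - t) if st == "+" else (t - mid))
                for gid, t, st in gdf[["gene_id", "tss", "strand"]].to_numpy()
            ]
            dists.sort()
            best_abs, best_gene, best_signed = dists[0]
            assert ann.loc[pid, "nearest_gene_id"] == best_gene
            assert ann.loc[pid, "distance"] == best_signed
            if -1000 <= best_signed <= 100:
                expect = "promoter"
            elif 3000 < best_abs <= 500_000:
                expect = "DRE"
            else:
                expect = "other"
            assert ann.loc[pid, "region_class"] == expect


class TestClassifyGenomicFeatures:
    @pytest.fixture()
    def gene_model(self):
        # + strand gene: TSS 10_000, exon1 [10_000, 12_000), intron,
        # exon2 [18_000, 20_000), TTS 20_000, UTRs at the exon edges
        return GeneAnnotation(
            pd.DataFrame(
                {
                    "gene_id": ["g"],
                    "chrom": ["chr1"],
                    "strand": ["+"],
                    "tss": [10_000],
                    "tts": [20_000],
                    "exons": [[(10_000, 12_000), (18_000, 20_000)]],
                    "utr5": [[(10_000, 10_500)]],
                    "utr3": [[(19_500, 20_000)]],
                }
            )
        )

    def test_exon_only(self, gene_model):
        peaks = _peakset([(11_200, 11_400)])
        assert classify_genomic_features(peaks, gene_model).iloc[0] == "exon"

    def test_gene_free_chromosome_intergenic(self, gene_model):
        peaks = PeakSet.from_arrays(["chr9"], [100], [200])
        assert classify_genomic_features(peaks, gene_model).iloc[0] == "intergenic"

    def test_tiling_matches_hand_enumerated_oracle(self, gene_model):
        positions = range(8_500, 21_500, 100)
        peaks = _peakset([(p, p + 1) for p in positions])
        got = classify_genomic_features(peaks, gene_model)

        def oracle(p):
            if 9_000 <= p <= 10_100:
                return "TSS"  # promoter window [-1000, +100]
            if 19_900 <= p <= 20_100:
                return "TTS"
            if 10_000 <= p < 10_500:
                return "5'UTR"
            if 19_500 <= p < 20_000:
                return "3'UTR"
            if 10_000 <= p < 12_000 or 18_000 <= p < 20_000:
                return "exon"
            if 10_000 <= p < 20_000:
                return "intron"
            return "intergenic"

        for p, label in zip(positions, got):
            assert label == oracle(p), f"position {p}"


class TestRoundTrips:
    def test_bed(self, tmp_path, small_cohort):
        path = tmp_path / "p.bed"
        write_bed(small_cohort.peaks, path)
        back = read_bed(path)
        assert back.df.equals(small_cohort.peaks.df)

    def test_matrix_integers_bitwise(self, tmp_path, small_cohort):
        path = tmp_path / "m.tsv"
        write_matrix_tsv(small_cohort.counts.raw, path)
        back = read_matrix_tsv(path)
        assert (back.to_numpy() == small_cohort.counts.raw.to_numpy()).all()
        assert list(back.columns) == list(small_cohort.counts.raw.columns)

    def test_matrix_reals(self, tmp_path, rng):
        df = pd.DataFrame(
            rng.normal(size=(40, 5)),
            index=[f"p{i}" for i in range(40)],
            columns=[f"s{j}" for j in range(5)],
        )
        path = tmp_path / "r.tsv"
        write_matrix_tsv(df, path)
        back = read_matrix_tsv(path)
        assert np.allclose(back.to_numpy(), df.to_numpy(), atol=1e-12, rtol=0)

    def test_genes(self, tmp_path, small_cohort):
        path = tmp_path / "g.tsv"
        write_genes_tsv(small_cohort.genes, path)
        back = read_genes_tsv(path)
        assert back.df["gene_id"].equals(small_cohort.genes.df["gene_id"])
        assert back.df["tss"].equals(small_cohort.genes.df["tss"])
        assert back.df["exons"].map(tuple).equals(
            small_cohort.genes.df["exons"].map(tuple)
        )
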