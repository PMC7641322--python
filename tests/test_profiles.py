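import numpy as np
import pandas as pd
import pytest

from epiwindow import (
    ChromSizes,
    GeneModel,
    GenomicInterval,
    Peak,
    PeakSet,
    WindowGrid,
    consensus_de_sets,
    element_profile,
    genebody_profile,
    nearest_gene_within,
    promoter_mean,
    promoter_profile,
    promoter_state_stratify,
    quartile_stratify,
)
from epiwindow.windows import WindowTrack

from conftest import simple_gene


W = 200


def track_of(scores, w=W):
    scores = np.asarray(scores, dtype=float)
    grid = WindowGrid(ChromSizes({"chr1": scores.size * w}), w)
    return WindowTrack(grid, {"chr1": scores}, 1000)


def reversed_genome(track):
    """Reverse the genome: window k -> n-1-k (chromosome length a multiple of w)."""
    arr = track.scores["chr1"][::-1].copy()
    return track_of(arr)


def reversed_gene(g, L):
    strand = "-" if g.strand == "+" else "+"
    body = GenomicInterval(g.chrom, L - g.body.end, L - g.body.start, strand)
    exons = [GenomicInterval(g.chrom, L - e.end, L - e.start, strand) for e in g.exons]
    return GeneModel(g.gene_id, body, exons)


class TestPromoterProfile:
    def test_flat_signal_identity(self):
        track = track_of(np.full(50, 2.5))
        genes = [simple_gene(start=4000, end=6000)]
        prof = promoter_profile(track, genes)
        np.testing.assert_allclose(prof.mean_signal, 2.5)

    def test_strand_mirror_equivariance(self):
        rng = np.random.default_rng(3)
        track = track_of(rng.random(50) * 4)
        L = 50 * W
        genes = [simple_gene("a", start=3000, end=5200, strand="+"),
                 simple_gene("b", start=6400, end=8000, strand="-")]
        fwd = promoter_profile(track, genes)
        rev = promoter_profile(reversed_genome(track), [reversed_gene(g, L) for g in genes])
        np.testing.assert_allclose(fwd.mean_signal, rev.mean_signal, atol=1e-12)

    def test_signal_at_tss_peaks_centrally(self):
        scores = np.zeros(50)
        scores[20] = 10.0  # window containing the TSS
        track = track_of(scores)
        prof = promoter_profile(track, [simple_gene(start=4100, end=6000)])
        central = prof.mean_signal[18:22].mean()
        outer = np.concatenate([prof.mean_signal[:5], prof.mean_signal[-5:]]).mean()
        assert central > outer

    def test_flank_truncated_at_chromosome_start(self):
        track = track_of(np.full(50, 1.0))
        prof = promoter_profile(track, [simple_gene(start=500, end=3000)])
        # upstream bins beyond the chromosome are NaN, covered bins keep the value
        assert np.isnan(prof.per_feature_matrix[0, 0])
        np.testing.assert_allclose(prof.mean_signal[-10:], 1.0)


class TestGenebodyProfile:
    def test_flat(self):
        track = track_of(np.full(60, 3.0))
        prof = genebody_profile(track, [simple_gene(start=4000, end=8000)])
        np.testing.assert_allclose(prof.mean_signal, 3.0)

    def test_profiled_span_is_150_percent_of_gene(self):
        track = track_of(np.zeros(120))
        g = simple_gene(start=10000, end=20000)  # 10 kb gene, flanks 2.5 kb each
        # profiled span is [7500, 22500): marks at both ends must reach the
        # outermost bins
        arr = track.scores["chr1"]
        arr[7500 // W] = arr[22400 // W] = 5.0
        prof = genebody_profile(track, [g])
        assert prof.mean_signal[0] > 0 and prof.mean_signal[-1] > 0

    def test_body_enriched_fixture(self):
        scores = np.zeros(60)
        g = simple_gene(start=4000, end=8000)
        scores[20:40] = 4.0  # exactly the gene body windows
        prof = genebody_profile(track_of(scores), [g])
        body = prof.mean_signal[25:125].mean()
        flank = np.concatenate([prof.mean_signal[:25], prof.mean_signal[125:]]).mean()
        assert body > flank

    def test_strand_mirror_equivariance(self):
        rng = np.random.default_rng(4)
        track = track_of(rng.random(60) * 2)
        L = 60 * W
        genes = [simple_gene("a", start=3000, end=7000, strand="+")]
        fwd = genebody_profile(track, genes)
        rev = genebody_profile(reversed_genome(track), [reversed_gene(genes[0], L)])
        np.testing.assert_allclose(fwd.mean_signal, rev.mean_signal, atol=1e-12)

    def test_zero_length_gene_rejected(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 100, 100, "+")


class TestElementProfile:
    def test_flat(self):
        track = track_of(np.full(30, 1.5))
        prof = element_profile(track, [GenomicInterval("chr1", 2000, 2400)])
        np.testing.assert_allclose(prof.mean_signal, 1.5)

    def test_depleted_center_fixture(self):
        scores = np.full(30, 2.0)
        el = GenomicInterval("chr1", 2000, 2400)
        scores[10:12] = 0.0  # element body windows
        prof = element_profile(track_of(scores), [el])
        assert prof.mean_signal[25:50].mean() < 0.5
        assert prof.mean_signal[:25].mean() > 1.5

    def test_span_is_three_element_lengths(self):
        # 200 bp element with 100% flanks -> 600 bp profiled
        scores = np.zeros(30)
        scores[9] = scores[10] = scores[11] = 1.0
        el = GenomicInterval("chr1", 2000, 2200)
        prof = element_profile(track_of(scores), [el])
        np.testing.assert_allclose(prof.mean_signal, 1.0)

    def test_empty_elements_error(self):
        with pytest.raises(ValueError):
            element_profile(track_of(np.zeros(10)), [])


class TestPromoterMean:
    def test_uniform(self):
        track = track_of(np.full(50, 7.0))
        pm = promoter_mean(track, [simple_gene(start=4000, end=6000)])
        assert pm["g1"] == pytest.approx(7.0)

    def test_linearity(self):
        rng = np.random.default_rng(5)
        track = track_of(rng.random(50))
        doubled = track_of(track.scores["chr1"] * 2)
        genes = [simple_gene(start=4000, end=6000), simple_gene("g2", start=7000, end=9000, strand="-")]
        np.testing.assert_allclose(promoter_mean(doubled, genes), 2 * promoter_mean(track, genes))

    def test_equals_per_bp_oracle(self):
        rng = np.random.default_rng(6)
        scores = rng.random(50) * 3
        track = track_of(scores)
        flank = 1000
        genes = [simple_gene(f"g{i}", start=int(s), end=int(s) + 1500,
                             strand="+" if i % 2 else "-")
                 for i, s in enumerate(rng.integers(0, 8000, size=10))]
        pm = promoter_mean(track, genes, flank)
        L = 50 * W
        for g in genes:
            a, b = max(g.tss - flank, 0), min(g.tss + flank + 1, L)
            per_bp = [scores[x // W] for x in range(a, b)]  # independent expansion
            assert pm[g.gene_id] == pytest.approx(float(np.mean(per_bp)), abs=1e-9)


class TestStratification:
    def test_eight_genes_distinct(self):
        genes = [simple_gene(f"g{i}", start=100 + 1200 * i, end=1100 + 1200 * i) for i in range(8)]
        expr = pd.Series({f"g{i}": float(i) for i in range(8)})
        sets = quartile_stratify(genes, expr)
        assert all(len(v) == 2 for v in sets.values())
        assert set(sets["Q1"]) == {"g7", "g6"}  # Q1 = high expression
        assert set(sets["Q4"]) == {"g0", "g1"}

    def test_tie_rule_deterministic(self):
        genes = [simple_gene(f"g{i}", start=100 + 1200 * i, end=1100 + 1200 * i) for i in range(4)]
        expr = pd.Series({g.gene_id: 1.0 for g in genes})
        sets = quartile_stratify(genes, expr)
        assert sets == {"Q1": ["g0"], "Q2": ["g1"], "Q3": ["g2"], "Q4": ["g3"]}

    def test_quota_sizes_ten_genes(self):
        genes = [simple_gene(f"g{i}", start=100 + 1200 * i, end=1100 + 1200 * i) for i in range(10)]
        expr = pd.Series({f"g{i}": float(i) for i in range(10)})
        sets = quartile_stratify(genes, expr)
        assert [len(sets[q]) for q in ["Q1", "Q2", "Q3", "Q4"]] == [3, 3, 2, 2]

    def test_partition_disjoint_exhaustive(self):
        rng = np.random.default_rng(9)
        genes = [simple_gene(f"g{i}", start=100 + 1200 * i, end=1100 + 1200 * i) for i in range(13)]
        expr = pd.Series({g.gene_id: float(rng.random()) for g in genes})
        sets = quartile_stratify(genes, expr)
        allg = [g for v in sets.values() for g in v]
        assert len(allg) == len(set(allg)) == 13

    def test_promoter_state_no_peaks(self):
        genes = [simple_gene()]
        sets = promoter_state_stratify(genes, PeakSet([]))
        assert sets == {"enriched": [], "depleted": ["g1"]}

    def test_promoter_state_peak_at_tss(self):
        g = simple_gene(start=5000, end=8000)
        ps = PeakSet([Peak(GenomicInterval("chr1", 5000, 5600))])
        assert promoter_state_stratify([g], ps)["enriched"] == ["g1"]

    def test_promoter_state_matches_overlap_oracle(self):
        rng = np.random.default_rng(10)
        for _ in range(50):
            genes = [simple_gene(f"g{i}", start=int(s), end=int(s) + 2000,
                                 strand="+" if rng.random() < 0.5 else "-")
                     for i, s in enumerate(rng.integers(0, 30000, size=5))]
            peaks = PeakSet([
                Peak(GenomicInterval("chr1", int(s), int(s) + 600))
                for s in rng.integers(0, 35000, size=4)
            ])
            sets = promoter_state_stratify(genes, peaks, flank=1000)
            for g in genes:
                lo, hi = max(g.tss - 1000, 0), g.tss + 1001
                expect = any(
                    p.interval.start < hi and p.interval.end > lo for p in peaks
                )
                assert (g.gene_id in sets["enriched"]) == expect


class TestNearestGene:
    def test_simple_upstream(self):
        g = simple_gene(start=10000, end=12000)
        sites = [GenomicInterval("chr1", 4800, 5000)]  # 5 kb upstream
        assert nearest_gene_within(sites, [g]) == ["g1"]

    def test_beyond_cutoff(self):
        g = simple_gene(start=20000, end=22000)
        sites = [GenomicInterval("chr1", 4800, 5000)]  # 15 kb away
        assert nearest_gene_within(sites, [g]) == [None]

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(11)
        genes = [simple_gene(f"g{i}", start=int(s), end=int(s) + 2000)
                 for i, s in enumerate(rng.integers(0, 100000, size=8))]
        sites = [GenomicInterval("chr1", int(s), int(s) + 300)
                 for s in rng.integers(0, 110000, size=30)]
        got = nearest_gene_within(sites, genes, 10000)
        for site, res in zip(sites, got):
            best = None
            for g in genes:  # O(n^2) oracle
                if site.start < g.body.end and site.end > g.body.start:
                    d = 0
                elif site.end <= g.body.start:
                    d = g.body.start - site.end + 1
                else:
                    d = site.start - g.body.end + 1
                if d <= 10000 and (best is None or (d, g.gene_id) < best):
                    best = (d, g.gene_id)
            assert res == (best[1] if best else None)


class TestConsensusDeSets:
    def table(self, rows):
        return pd.DataFrame(rows, columns=["gene", "log2fc", "adj_p"])

    def test_shared_up_gene(self):
        t = {e: self.table([("a", 2.0, 0.01), ("b", 0.2, 0.01)]) for e in "xyz"}
        up, down = consensus_de_sets(t)
        assert up == {"a"} and down == set()

    def test_subthreshold_fold_excluded(self):
        t = {e: self.table([("a", 0.9, 0.001)]) for e in "xy"}
        up, down = consensus_de_sets(t)  # |log2FC| < 1 everywhere
        assert up == set() and down == set()

    def test_opposite_directions_in_neither(self):
        t = {"x": self.table([("a", 2.0, 0.01)]), "y": self.table([("a", -2.0, 0.01)])}
        up, down = consensus_de_sets(t)
        assert up == set() and down == set()

    def test_duplicate_gene_errors(self):
        t = {"x": self.table([("a", 2.0, 0.01), ("a", 2.0, 0.01)]),
             "y": self.table([("a", 2.0, 0.01)])}
        with pytest.raises(ValueError, match="duplicate"):
            consensus_de_sets(t)

    def test_matches_set_algebra_oracle(self):
        rng = np.random.default_rng(12)
        genes = [f"g{i}" for i in range(30)]
        tables = {}
        for e in ["J1", "TKO", "3B3l"]:
            tables[e] = self.table([
                (g, float(rng.normal(0, 2)), float(rng.random())) for g in genes
            ])
        up, down = consensus_de_sets(tables, 2.0, 0.05)
        per_up, per_down = [], []
        for df in tables.values():  # independent set-algebra oracle
            per_up.append({r.gene for r in df.itertuples() if r.adj_p <= 0.05 and r.log2fc >= 1})
            per_down.append({r.gene for r in df.itertuples() if r.adj_p <= 0.05 and r.log2fc <= -1})
        assert up == set.intersection(*per_up)
        assert down == set.intersection(*per_down)
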