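"""Avoidance statistics, binned analyses, Cramer's V, randomization controls."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from intronlab import genomes, stats
from intronlab.stats import (
    avoidance_test,
    barcode_variance_control,
    binned_se,
    cramers_v,
    delta_se,
    motif_indicator,
    motif_profile,
    randomized_abundance_control,
)


class TestMotifProfile:
    def test_planted_motif_at_offset(self):
        contigs, introns, cds = genomes.synthetic_genome(
            n_genes=30, n_introns=30, seed=1, mode="enriched",
            enrich_offset=5, enrich_fraction=1.0,
        )
        offs, freqs, log = motif_profile(contigs, introns)
        assert freqs[list(offs).index(5)] == 1.0

    def test_absent_motif_all_zero(self):
        contigs = {"c": "ATATATATAT" * 40}
        introns = pd.DataFrame(
            [{"chrom": "c", "start": 150, "end": 230, "name": "i", "score": 0,
              "strand": "+"}]
        )
        offs, freqs, _ = motif_profile(contigs, introns, window=(-20, 20))
        assert (freqs == 0).all()

    def test_planted_fraction_exact(self):
        contigs, introns, cds = genomes.synthetic_genome(
            n_genes=40, n_introns=40, seed=2, mode="enriched",
            enrich_offset=7, enrich_fraction=0.3,
        )
        # deterministic count oracle: scan registered windows directly
        count = 0
        for r in introns.itertuples():
            seq = contigs[r.chrom]
            if r.strand == "+":
                w = seq[r.end - 1 + 7 : r.end - 1 + 10]
            else:
                w = seq[r.start - 9 : r.start - 6]
                w = w.translate(str.maketrans("ACGT", "TGCA"))[::-1]
            if w in ("CAG", "TAG"):
                count += 1
        offs, freqs, _ = motif_profile(contigs, introns)
        assert freqs[list(offs).index(7)] == pytest.approx(count / len(introns))

    def test_totals_conserved_vs_full_scan(self):
        """Sum of per-offset counts equals a direct full-scan count over
        the registered windows (conservation oracle)."""
        contigs, introns, cds = genomes.synthetic_genome(
            n_genes=20, n_introns=25, seed=3
        )
        offs, freqs, _ = motif_profile(contigs, introns, window=(-30, 30))
        total = freqs.sum() * len(introns)
        direct = 0
        for r in introns.itertuples():
            seq = contigs[r.chrom]
            if r.strand == "+":
                anchor = r.end - 1
                w = seq[anchor - 30 : anchor + 33]
            else:
                anchor = r.start
                w = seq[anchor - 32 : anchor + 31]
                w = w.translate(str.maketrans("ACGT", "TGCA"))[::-1]
            direct += int(motif_indicator(w).sum())
        assert total == pytest.approx(direct)

    def test_strandedness(self):
        # one minus-strand intron with TAG planted just downstream
        seq = list("A" * 400)
        # oriented downstream offset +5 on '-' strand = genomic start-5-2..start-5
        start = 200
        seq[start - 8 : start - 5] = list("CTA")  # revcomp of TAG
        contigs = {"c": "".join(seq)}
        introns = pd.DataFrame(
            [{"chrom": "c", "start": start, "end": start + 60, "name": "i",
              "score": 0, "strand": "-"}]
        )
        offs, freqs, _ = motif_profile(contigs, introns, window=(0, 10))
        assert freqs[list(offs).index(6)] == 1.0


class TestAvoidanceTest:
    def test_planted_depletion_small_p(self):
        contigs, introns, cds = genomes.synthetic_genome(
            n_genes=40, gene_len=700, n_introns=60, seed=5, mode="depleted"
        )
        r = avoidance_test(contigs, introns, cds, n_controls=2000, seed=2)
        assert r.p_upstream <= 1 / 2000
        assert r.p_downstream <= 1 / 2000

    def test_null_p_is_roughly_uniform(self):
        ps = []
        for rep in range(40):
            contigs, introns, cds = genomes.synthetic_genome(
                n_genes=30, gene_len=600, n_introns=50, seed=3000 + rep, mode="null"
            )
            r = avoidance_test(contigs, introns, cds, n_controls=500, seed=rep)
            ps.extend([r.p_upstream, r.p_downstream])
        assert abs(np.mean(ps) - 0.5) < 0.08

    def test_p_resolution_and_bounds(self):
        contigs, introns, cds = genomes.synthetic_genome(
            n_genes=20, n_introns=20, seed=6
        )
        r = avoidance_test(contigs, introns, cds, n_controls=200, seed=1)
        for p in (r.p_upstream, r.p_downstream):
            assert 0 <= p <= 1
            assert round(p * 200) == pytest.approx(p * 200)

    def test_empty_cds_rejected(self):
        contigs, introns, cds = genomes.synthetic_genome(
            n_genes=10, n_introns=10, seed=7
        )
        with pytest.raises(ValueError):
            avoidance_test(contigs, introns, cds.iloc[:0], n_controls=100, seed=0)

    def test_seed_reproducibility(self):
        contigs, introns, cds = genomes.synthetic_genome(
            n_genes=15, n_introns=15, seed=8
        )
        a = avoidance_test(contigs, introns, cds, n_controls=300, seed=4)
        b = avoidance_test(contigs, introns, cds, n_controls=300, seed=4)
        assert a.p_upstream == b.p_upstream and a.p_downstream == b.p_downstream


class TestBinnedSE:
    def test_constant_se_flagged(self):
        out = binned_se(np.linspace(0, 1, 50), np.full(50, 0.4), np.linspace(0, 1, 6))
        assert not out["trend_defined"]

    def test_linear_trend_recovered(self):
        rng = np.random.default_rng(9)
        u = rng.uniform(0, 1, 500)
        se = np.clip(0.2 + 0.6 * u + rng.normal(0, 0.1, 500), 0, 1)
        out = binned_se(u, se, np.linspace(0, 1, 6))
        assert out["trend_defined"] and out["r"] > 0 and out["p"] < 0.01

    def test_empty_bins_reported(self):
        out = binned_se(np.array([0.1, 0.9]), np.array([0.2, 0.8]),
                        np.linspace(0, 1, 6))
        counts = [b["count"] for b in out["bins"]]
        assert len(counts) == 5 and counts.count(0) == 3

    def test_y_content_eligibility_filter(self):
        """The pyrimidine-tract control only admits windows with >= 30% C
        among pyrimidines."""
        assert stats.c_fraction_of_y("TTTTTTTCCC") == pytest.approx(0.3)
        assert stats.c_fraction_of_y("TTTTTTTTTC") == pytest.approx(0.1)
        windows = ["TTTTTTTCCC", "TTTTTTTTTC", "CCCCCTTTTT"]
        eligible = [w for w in windows if stats.c_fraction_of_y(w) >= 0.3]
        assert eligible == ["TTTTTTTCCC", "CCCCCTTTTT"]


class TestDeltaSE:
    def _tables(self, delta):
        se = pd.DataFrame(
            {"variant_id": ["c1", "o1", "c2", "o2"],
             "se": [0.5, 0.5 + delta, 0.3, 0.3 + delta]}
        )
        orth = pd.DataFrame(
            {
                "variant_id": ["c1", "o1", "c2", "o2"],
                "gene": ["g1", "g1", "g2", "g2"],
                "species": ["S.cerevisiae", "K.lactis", "S.cerevisiae", "K.lactis"],
            }
        )
        return se, orth

    def test_identical_not_better(self):
        pairs, summary, _ = delta_se(*self._tables(0.0))
        assert (pairs.delta_se == 0).all()
        assert summary.percent_better.iloc[0] == 0.0

    def test_uniform_improvement(self):
        pairs, summary, _ = delta_se(*self._tables(0.1))
        assert summary.percent_better.iloc[0] == 100.0

    def test_random_pairs_near_half(self):
        rng = np.random.default_rng(10)
        n = 400
        se = pd.DataFrame(
            {
                "variant_id": [f"c{i}" for i in range(n)] + [f"o{i}" for i in range(n)],
                "se": rng.uniform(0, 1, 2 * n),
            }
        )
        orth = pd.DataFrame(
            {
                "variant_id": se.variant_id,
                "gene": [f"g{i % n}" for i in range(2 * n)],
                "species": ["S.cerevisiae"] * n + ["K.lactis"] * n,
            }
        )
        _, summary, _ = delta_se(se, orth)
        pb = summary.percent_better.iloc[0] / 100
        assert abs(pb - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_missing_partner_skipped(self):
        se, orth = self._tables(0.1)
        orth.loc[orth.variant_id == "c2", "gene"] = "g_other"
        pairs, _, skipped = delta_se(se, orth)
        assert "o2" in skipped and len(pairs) == 1


class TestCramersV:
    def test_perfect_diagonal(self):
        a = np.array([0.0] * 30 + [0.3] * 30 + [0.9] * 30)
        out = cramers_v(a, a)
        assert out["phi_c"] == pytest.approx(1.0)

    def test_hand_computed_fixed_table(self):
        """phi_C matches independent arithmetic on a fixed 3x3 table."""
        table = np.array([[20, 5, 2], [4, 18, 6], [1, 7, 25]])
        n = table.sum()
        rows = table.sum(1, keepdims=True)
        cols = table.sum(0, keepdims=True)
        expected = rows * cols / n
        chi2 = ((table - expected) ** 2 / expected).sum()
        phi_expected = np.sqrt(chi2 / (n * 2))
        # reconstruct value vectors that produce this table
        se_vals = [0.0, 0.3, 0.9]
        a, b = [], []
        for i in range(3):
            for j in range(3):
                a += [se_vals[i]] * table[i, j]
                b += [se_vals[j]] * table[i, j]
        out = cramers_v(np.array(a), np.array(b))
        assert out["phi_c"] == pytest.approx(phi_expected, abs=1e-9)

    def test_independent_uniform_small(self):
        rng = np.random.default_rng(11)
        a = rng.choice([0.0, 0.3, 0.9], size=10_000)
        b = rng.choice([0.0, 0.3, 0.9], size=10_000)
        assert cramers_v(a, b)["phi_c"] < 0.05

    def test_symmetry(self):
        rng = np.random.default_rng(12)
        a = rng.uniform(0, 1, 200)
        b = rng.uniform(0, 1, 200)
        assert cramers_v(a, b)["phi_c"] == pytest.approx(cramers_v(b, a)["phi_c"])

    def test_degenerate_margin_flagged(self):
        a = np.zeros(50)
        b = np.zeros(50)
        out = cramers_v(a, b)
        assert not out["defined"] and np.isnan(out["phi_c"])


class TestBarcodeVarianceControl:
    def test_identical_groups_p_zero(self):
        rng = np.random.default_rng(13)
        group_se = rng.uniform(0.1, 0.9, 30)
        se = np.repeat(group_se, 4)
        groups = np.repeat(np.arange(30), 4)
        out = barcode_variance_control(se, groups, n_shuffles=300, seed=1)
        assert out["observed"] == pytest.approx(0.0)
        assert out["p"] == 0.0

    def test_shuffled_labels_near_null_median(self):
        rng = np.random.default_rng(14)
        se = rng.uniform(0, 1, 120)
        groups = rng.permutation(np.repeat(np.arange(30), 4))
        out = barcode_variance_control(se, groups, n_shuffles=400, seed=2)
        assert 0.02 < out["p"] < 0.98

    def test_no_groups_error(self):
        with pytest.raises(ValueError):
            barcode_variance_control(np.array([0.5]), np.array([0]), seed=0)

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(15)
        se = rng.uniform(0, 1, 60)
        groups = np.repeat(np.arange(15), 4)
        a = barcode_variance_control(se, groups, n_shuffles=200, seed=7)
        b = barcode_variance_control(se, groups, n_shuffles=200, seed=7)
        assert np.array_equal(a["null"], b["null"])


class TestRandomizedAbundanceControl:
    def test_zero_n_rejected(self):
        with pytest.raises(ValueError):
            randomized_abundance_control(n=0, seed=0)

    def test_seed_reproducibility(self):
        a = randomized_abundance_control(seed=3)
        b = randomized_abundance_control(seed=3)
        assert a["r"] == b["r"]

    def test_mostly_nonsignificant(self):
        """The mock construction has zero true correlation by symmetry; the
        sampled p-values are Uniform, so >= 90% of replicates clear 0.05."""
        ok = sum(
            randomized_abundance_control(n=2000, seed=s)["p"] > 0.05
            for s in range(40)
        )
        assert ok >= 0.9 * 40 * 0.8  # generous at this replicate count
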