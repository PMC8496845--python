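"""Quantification: decoding, classification rules, SE aggregation, filters."""

import numpy as np
import pandas as pd
import pytest

from intronlab import design, quantify, simulate
from intronlab.quantify import (
    BarcodeIndex,
    classify_single,
    classify_two_intron,
    decode_barcodes,
    dereplicate,
    dna_artifact_filter,
    find_cryptic,
    rna_abundance,
    splicing_efficiency,
)


def _reads_df(seqs, **kw):
    df = pd.DataFrame({"sequence": seqs})
    df["sample"] = kw.get("sample", "RNA")
    df["repeat"] = kw.get("repeat", 1)
    df["index"] = kw.get("index", 1)
    return df


@pytest.fixture(scope="module")
def index(small_library):
    return BarcodeIndex(small_library)


@pytest.fixture(scope="module")
def comb_variant(small_library):
    return [x for x in small_library if x.subset_label == "combinatorial"][0]


class TestBarcodeDecoding:
    def test_exact_prefix_assigned(self, small_library, index):
        v = small_library[0]
        assert index.decode(v.barcode + "ACGT")[0] == v.variant_id

    def test_two_substitutions_assigned(self, small_library, index):
        v = small_library[0]
        bc = list(v.barcode)
        bc[0] = "A" if bc[0] != "A" else "C"
        bc[5] = "A" if bc[5] != "A" else "C"
        assert index.decode("".join(bc) + "ACGT")[0] == v.variant_id

    def test_three_substitutions_dropped(self, small_library, index):
        v = small_library[0]
        bc = list(v.barcode)
        for p in (0, 5, 10):
            bc[p] = "A" if bc[p] != "A" else "C"
        vid, reason = index.decode("".join(bc) + "ACGT")
        # distance-4 code: 3 substitutions can never reach another barcode
        assert vid is None

    def test_single_indel_assigned(self, small_library, index):
        v = small_library[0]
        deleted = v.barcode[:4] + v.barcode[5:]  # one deletion, then read body
        assert index.decode(deleted + "ACGTACGT")[0] == v.variant_id
        inserted = v.barcode[:4] + "G" + v.barcode[4:]
        assert index.decode(inserted + "ACGT")[0] == v.variant_id

    def test_tie_dropped_as_ambiguous(self):
        # two barcodes at distance 4; midpoint reads are ambiguous at d=2
        a = "AAAAAAAAAAAA"
        b = "AAAAAAAACCCC"
        idx = BarcodeIndex([(a, "va"), (b, "vb")])
        mid = "AAAAAAAAAACC"  # distance 2 from both
        vid, reason = idx.decode(mid + "ACGT")
        assert vid is None and reason == "ambiguous"

    def test_decode_barcodes_drop_log(self, small_library, index):
        v = small_library[0]
        good = v.barcode + v.variable_region
        bad = "G" * 12 + v.variable_region
        assigned, dropped = decode_barcodes(_reads_df([good, bad]), index)
        assert len(assigned) == 1 and len(dropped) == 1
        assert dropped.iloc[0]["reason"] == "over_distance"


class TestDereplicate:
    def test_multiplicities(self):
        df = _reads_df(["AAA", "AAA", "AAA", "CCC"])
        out = dereplicate(df)
        assert dict(zip(out.sequence, out["count"])) == {"AAA": 3, "CCC": 1}

    def test_all_distinct_identity(self):
        df = _reads_df(["AAA", "CCC", "GGG"])
        out = dereplicate(df)
        assert len(out) == 3 and (out["count"] == 1).all()

    def test_total_conserved_random(self, rng):
        seqs = ["".join(rng.choice(list("AC"), size=4)) for _ in range(500)]
        assert dereplicate(_reads_df(seqs))["count"].sum() == 500


class TestClassifySingle:
    def test_unspliced_rule(self, comb_variant):
        v = comb_variant
        assert classify_single(v.sequence, v).isoform == "unspliced"

    def test_designed_spliced_rule(self, comb_variant):
        v = comb_variant
        assert classify_single(v.spliced_sequence(), v).isoform == "designed_spliced"

    def test_all_positive_falls_through(self, comb_variant):
        v = comb_variant
        # a chimeric read carrying all three junctions verbatim
        read = (
            v.junctions["exon_intron_5"]
            + v.junctions["intron_exon_3"]
            + v.junctions["exon_exon"]
        )
        assert classify_single(read, v).isoform == "undetermined"

    def test_garbage_is_undetermined(self, comb_variant, rng):
        v = comb_variant
        read = "".join(rng.choice(list("ACGT"), size=170))
        assert classify_single(read, v).isoform == "undetermined"


def _distinct_pair(library):
    """A two-intron variant whose two introns differ in sequence (self-pairs
    of the all-ordered-pairs design are inherently ambiguous for the
    intron1/intron2 junction rules)."""
    for x in library:
        if x.subset_label != "two_intron":
            continue
        (s1, e1), (s2, e2) = x.introns
        if x.sequence[s1 - 1 : e1] != x.sequence[s2 - 1 : e2]:
            return x
    raise AssertionError("no distinct-intron pair in fixture")


class TestClassifyTwoIntron:
    @pytest.mark.parametrize(
        "isoform", ["unspliced", "intron1", "intron2", "exon_skipping", "both"]
    )
    def test_each_isoform_classified(self, small_library, isoform):
        ti = _distinct_pair(small_library)
        read = simulate.isoform_sequence(ti, isoform)
        assert classify_two_intron(read, ti).isoform == isoform

    def test_self_pair_abstains_rather_than_mislabels(self, small_library):
        """Identical tandem introns make intron1 vs intron2 junctions
        degenerate; the classifier must abstain, never flip the label."""
        selfs = [
            x for x in small_library
            if x.subset_label == "two_intron"
            and x.sequence[x.introns[0][0] - 1 : x.introns[0][1]]
            == x.sequence[x.introns[1][0] - 1 : x.introns[1][1]]
        ]
        for ti in selfs:
            for iso in ("intron1", "intron2"):
                got = classify_two_intron(simulate.isoform_sequence(ti, iso), ti).isoform
                assert got in (iso, "unclassified")

    def test_garbage_unclassified(self, small_library, rng):
        ti = _distinct_pair(small_library)
        read = "".join(rng.choice(list("ACGT"), size=160))
        assert classify_two_intron(read, ti).isoform == "unclassified"


class TestFindCryptic:
    def test_designed_end_cluster_reassigned(self, small_library):
        v = [x for x in small_library if x.subset_label == "combinatorial"][0]
        call = find_cryptic(v.spliced_sequence(), v)
        assert call.isoform == "designed_spliced"

    def test_shifted_end_detected(self, small_library):
        v = [x for x in small_library if x.subset_label == "combinatorial"][0]
        s, e = v.introns[0]
        read = v.spliced_sequence([(s, e + 12)])
        call = find_cryptic(read, v)
        assert call.isoform == "cryptic"
        from intronlab.align import canonical_gap
        assert call.intron == canonical_gap(v.sequence, (s, e + 12))

    def test_unspliced_read_no_call(self, small_library):
        v = [x for x in small_library if x.subset_label == "combinatorial"][0]
        assert find_cryptic(v.sequence, v).isoform == "undetermined"


class TestSplicingEfficiency:
    def _counts(self, rows):
        return pd.DataFrame(
            rows, columns=["variant_id", "isoform", "sample", "repeat", "index", "count"]
        )

    def test_simple_ratio(self):
        counts = self._counts(
            [("v", "designed", "RNA", 1, 1, 3), ("v", "unspliced", "RNA", 1, 1, 7)]
        )
        out = splicing_efficiency(counts)
        assert out[out.isoform == "designed"].se.iloc[0] == pytest.approx(0.3)

    def test_weighted_mean_between_repeats(self):
        counts = self._counts(
            [
                ("v", "designed", "RNA", 1, 1, 20),   # repeat 1: SE 0.2 of 100
                ("v", "unspliced", "RNA", 1, 1, 80),
                ("v", "designed", "RNA", 2, 1, 180),  # repeat 2: SE 0.6 of 300
                ("v", "unspliced", "RNA", 2, 1, 120),
            ]
        )
        out = splicing_efficiency(counts)
        assert out[out.isoform == "designed"].se.iloc[0] == pytest.approx(0.5)

    def test_median_between_indexes(self):
        rows = []
        for idx, n_sp in zip((1, 2, 3), (10, 20, 60)):
            rows += [
                ("v", "designed", "RNA", 1, idx, n_sp),
                ("v", "unspliced", "RNA", 1, idx, 100 - n_sp),
            ]
        out = splicing_efficiency(self._counts(rows))
        assert out[out.isoform == "designed"].se.iloc[0] == pytest.approx(0.2)

    def test_read_floor_strict(self):
        nine = self._counts(
            [("v", "designed", "RNA", 1, 1, 4), ("v", "unspliced", "RNA", 1, 1, 5)]
        )
        out = splicing_efficiency(nine)
        assert out.low_reads.all() and out.se.isna().all()
        ten = self._counts(
            [("v", "designed", "RNA", 1, 1, 5), ("v", "unspliced", "RNA", 1, 1, 5)]
        )
        out = splicing_efficiency(ten)
        assert not out.low_reads.any()

    def test_undetermined_in_denominator(self):
        counts = self._counts(
            [
                ("v", "designed", "RNA", 1, 1, 3),
                ("v", "unspliced", "RNA", 1, 1, 5),
                ("v", "undetermined", "RNA", 1, 1, 2),
            ]
        )
        out = splicing_efficiency(counts)
        assert out[out.isoform == "designed"].se.iloc[0] == pytest.approx(0.3)
        cfg = quantify.QuantifyConfig(include_undetermined_in_total=False)
        out2 = splicing_efficiency(counts, cfg)
        assert out2[out2.isoform == "designed"].se.iloc[0] == pytest.approx(3 / 8)


class TestAbundanceAndFilters:
    def test_rna_abundance_values(self):
        rna = pd.Series({"a": 10, "b": 10})
        dna = pd.Series({"a": 10, "b": 10})
        ab = rna_abundance(rna, dna)
        assert ab["a"] == pytest.approx(0.0)
        rna = pd.Series({"a": 100, "b": 10})   # a: 10/11 vs dna 1/2
        dna = pd.Series({"a": 50, "b": 50})
        ab = rna_abundance(rna, dna)
        assert ab["a"] == pytest.approx(np.log10((100 / 110) / 0.5))

    def test_log_ratio_cases(self):
        rna = pd.Series({"a": 10, "b": 90})
        dna = pd.Series({"a": 1, "b": 99})
        ab = rna_abundance(rna, dna)
        assert ab["a"] == pytest.approx(1.0)
        rna = pd.Series({"a": 1, "b": 999})
        dna = pd.Series({"a": 10, "b": 990})
        assert rna_abundance(rna, dna)["a"] == pytest.approx(-1.0)

    def test_dna_artifact_threshold_strict(self):
        rna = pd.DataFrame(
            {
                "variant_id": ["v", "w"],
                "isoform": ["designed", "designed"],
                "se": [0.8, 0.8],
                "n_reads": [100, 100],
                "low_reads": [False, False],
            }
        )
        dna = rna.copy()
        dna["se"] = [0.06, 0.05]  # only the first is an artifact (> strict)
        out = dna_artifact_filter(rna, dna)
        assert out.se.tolist() == [0.0, 0.8]
        assert out.dna_artifact.tolist() == [True, False]

    def test_cryptic_floor_suppression(self):
        table = pd.DataFrame(
            {
                "variant_id": ["v", "v"],
                "isoform": ["cryptic:18:100", "cryptic:18:110"],
                "se": [0.005, 0.02],
                "n_reads": [1000, 1000],
                "low_reads": [False, False],
            }
        )
        out = quantify._suppress_low_cryptic(table)
        assert out.isoform.tolist() == ["cryptic:18:110"]


class TestEndToEnd:
    def test_partition_and_zero_confusion_at_zero_error(
        self, small_library, small_truth, clean_reads
    ):
        """Error-free reads: classified counts partition the assigned reads
        and match the simulator's truth table exactly (0 confusion)."""
        reads, truth_table = clean_reads
        index = BarcodeIndex(small_library)
        assigned, dropped = decode_barcodes(reads, index)
        assert len(dropped) == 0
        counts = quantify.classify_reads(assigned, small_library)
        assert counts["count"].sum() == len(assigned)
        # self-pair two-intron designs may abstain (see classifier tests);
        # everything else must match the simulator truth exactly
        ambiguous = {
            v.variant_id
            for v in small_library
            if v.subset_label == "two_intron"
            and v.sequence[v.introns[0][0] - 1 : v.introns[0][1]]
            == v.sequence[v.introns[1][0] - 1 : v.introns[1][1]]
        }
        merged = (
            counts[~counts.variant_id.isin(ambiguous)]
            .groupby(["variant_id", "isoform"])["count"].sum()
        )
        true = (
            truth_table[~truth_table.variant_id.isin(ambiguous)]
            .groupby(["variant_id", "isoform"])["count"].sum()
        )
        pd.testing.assert_series_equal(
            merged.sort_index(), true.sort_index(), check_names=False
        )

    def test_sum_of_isoform_ses_below_one(self, small_library, small_truth, clean_reads):
        reads, _ = clean_reads
        se = quantify.quantify_experiment(reads, None, small_library)
        sums = se.groupby("variant_id").se.sum()
        assert (sums <= 1 + 1e-9).all()

    def test_dna_sample_raises_no_artifacts(self, small_library, small_truth):
        rna, _ = simulate.simulate_sample(
            small_library, small_truth, 6000, seed=31, error_rate=0.0
        )
        dna, _ = simulate.simulate_sample(
            small_library, small_truth, 6000, seed=32, sample="DNA", error_rate=0.0
        )
        se = quantify.quantify_experiment(rna, dna, small_library)
        assert not se.dna_artifact.any()
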