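import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from ptrseq import sequence_features as sf
from ptrseq.core_io import TranscriptRecord

utr5_strategy = st.text(alphabet="ACGT", min_size=7, max_size=60)


def _rec(utr5="GCCACCA", cds="ATGAAATAA", utr3="TAAATAA", tid="tx"):
    return TranscriptRecord(tid, "g", utr5, cds, utr3)


class TestCodonFrequencies:
    def test_two_codon_cds(self):
        v = sf.codon_log2_freq("ATGAAATAA")
        assert v["codon:ATG"] == pytest.approx(-1.0)
        assert v["codon:AAA"] == pytest.approx(-1.0)
        # absent codon gets the 0.5 pseudocount: log2(0.5/2) = -2
        assert v["codon:GGG"] == pytest.approx(-2.0)

    def test_uniform_cds_all_equal(self):
        cds = "ATG" + "".join(c for c in sf.SENSE_CODONS if c != "ATG") + "TAA"
        v = sf.codon_log2_freq(cds)
        np.testing.assert_allclose(v, np.log2(1 / 61), atol=1e-12)

    def test_duplication_invariance_for_present_codons(self):
        # absent codons are deliberately length-dependent (pseudocount),
        # so frequency invariance applies to the codons actually present
        cds = "ATGAAACCCGGGTGA"
        doubled = cds[:-3] * 2 + cds[-3:]  # duplicate the sense-codon body
        a, b = sf.codon_log2_freq(cds), sf.codon_log2_freq(doubled)
        present = [f"codon:{c}" for c in ("ATG", "AAA", "CCC", "GGG")]
        pd.testing.assert_series_equal(a[present], b[present])

    def test_aa_freq_translation(self):
        v = sf.aa_log2_freq("ATGAAATAA")
        assert v["aa:M"] == pytest.approx(-1.0)
        assert v["aa:K"] == pytest.approx(-1.0)
        assert v["aa:G"] == pytest.approx(np.log2(0.5 / 2))

    def test_synonymous_recoding_preserves_aa_but_not_codon_vector(self):
        cds1 = "ATGAAACCCTAA"
        cds2 = "ATGAAGCCATAA"  # K: AAA->AAG, P: CCC->CCA
        pd.testing.assert_series_equal(sf.aa_log2_freq(cds1), sf.aa_log2_freq(cds2))
        assert not sf.codon_log2_freq(cds1).equals(sf.codon_log2_freq(cds2))


class TestCodonPairPcs:
    def test_identical_genes_give_zero(self):
        with pytest.warns(UserWarning, match="degenerate"):
            pcs = sf.codon_pair_pcs(["ATGAAACCCTAA"] * 5)
        np.testing.assert_allclose(pcs, 0.0)

    def test_rank_one_variation_captured_by_pc1(self):
        # genes differ along a single axis: fraction of AAA vs GGG codons
        cdss = ["ATG" + "AAA" * k + "GGG" * (30 - k) + "TAA" for k in range(3, 28, 2)]
        pcs = sf.codon_pair_pcs(cdss)
        pair_index = {p: i for i, p in enumerate(
            __import__("itertools").product(sf.SENSE_CODONS, sf.SENSE_CODONS))}
        X = np.zeros((len(cdss), 3721))
        for g, cds in enumerate(cdss):
            codons = [cds[i:i + 3] for i in range(0, len(cds) - 3, 3)]
            for a, b in zip(codons[:-1], codons[1:]):
                X[g, pair_index[(a, b)]] += 1 / (len(codons) - 1)
        X -= X.mean(0)
        total = (X ** 2).sum()
        explained = (pcs[:, 0] ** 2).sum()
        assert explained / total > 0.999

    def test_permutation_equivariance(self):
        cdss = ["ATG" + "AAA" * k + "GGG" * (10 - k) + "TAA" for k in (2, 5, 8, 3, 6)]
        pcs = sf.codon_pair_pcs(cdss)
        perm = [3, 1, 4, 0, 2]
        pcs_perm = sf.codon_pair_pcs([cdss[i] for i in perm])
        np.testing.assert_allclose(pcs_perm, pcs[perm], atol=1e-10)


class TestContextFeatures:
    def test_reference_record_is_all_zero_in_dropped_encoding(self):
        rec = _rec(utr5="GCCACC" + "", cds="ATGGCCAAAAAA" + "TAA",
                   utr3="AAAATAA")
        feats = sf.context_features(rec, "dropped")
        assert set(feats.values()) == {0}

    def test_c_at_minus_3_sets_indicator(self):
        rec = _rec(utr5="GCCCCC", cds="ATGGCCAAAAAATAA", utr3="AAAATAA")
        feats = sf.context_features(rec, "dropped")
        assert feats["kozak:-3:C"] == 1

    def test_stop_identity_indicator(self):
        rec = _rec(utr5="GCCACC", cds="ATGGCCAAAAAATGA", utr3="AAAATAA")
        feats = sf.context_features(rec, "dropped")
        assert feats["stop_context:stop:UGA"] == 1
        onehot = sf.context_features(rec, "onehot")
        assert onehot["stop_context:stop:UGA"] == 1
        assert onehot["stop_context:stop:UAA"] == 0

    def test_column_counts_by_encoding(self):
        kozak_oh, stop_oh = sf.context_feature_names("onehot")
        kozak_dr, stop_dr = sf.context_feature_names("dropped")
        assert (len(kozak_oh), len(stop_oh)) == (36, 39)
        assert (len(kozak_dr), len(stop_dr)) == (27, 29)

    def test_short_utr3_padded_with_reference(self):
        rec = TranscriptRecord("t", "g", "GCCACC", "ATGGCCAAAAAATAA", "GG")
        feats = sf.context_features(rec, "onehot")
        # position +5 beyond the 2-nt UTR encodes the reference A
        assert feats["stop_context:+5:A"] == 1
        assert feats["stop_context:+3:G"] == 1


class TestUpstreamAug:
    @pytest.mark.parametrize(
        "utr5, expected",
        [
            ("GCATGGC", dict(out_of_frame_uAUG=1, in_frame_uAUG=0, uORF=0, n_uAUG=1)),
            ("ATGTAACC", dict(out_of_frame_uAUG=1, in_frame_uAUG=0, uORF=1, n_uAUG=1)),
            ("ATGGGG", dict(out_of_frame_uAUG=0, in_frame_uAUG=1, uORF=0, n_uAUG=1)),
            ("CCCCCCC", dict(out_of_frame_uAUG=0, in_frame_uAUG=0, uORF=0, n_uAUG=0)),
        ],
    )
    def test_frame_arithmetic(self, utr5, expected):
        assert sf.upstream_aug_features(_rec(utr5=utr5)) == expected

    @given(utr5_strategy)
    def test_matches_three_frame_brute_force(self, utr5):
        feats = sf.upstream_aug_features(_rec(utr5=utr5))
        oracle = brute_force_uaug(utr5)
        assert feats == oracle


def brute_force_uaug(utr5: str) -> dict:
    """Independent oracle: enumerate AUGs and downstream in-frame stops."""
    stops = {"TAA", "TAG", "TGA"}
    out_of_frame = in_frame = uorf = n = 0
    for p in range(len(utr5)):
        if utr5[p:p + 3] != "ATG":
            continue
        n += 1
        if (len(utr5) - p) % 3 == 0:
            in_frame = 1
        else:
            out_of_frame = 1
        q = p + 3
        while q + 3 <= len(utr5):
            if utr5[q:q + 3] in stops:
                uorf = 1
                break
            q += 3
    return dict(out_of_frame_uAUG=out_of_frame, in_frame_uAUG=in_frame,
                uORF=uorf, n_uAUG=n)


class TestKmersAndMotifs:
    def test_overlap_counting(self):
        assert sf.kmer_counts("AAAA", 3, 3) == {"AAA": 2}

    @given(st.text(alphabet="ACGT", min_size=3, max_size=40))
    def test_count_bound(self, seq):
        counts = sf.kmer_counts(seq, 3, 5)
        for kmer, c in counts.items():
            assert c <= len(seq) - len(kmer) + 1

    def test_reverse_complement_maps_counts(self):
        seq = "AATAAAG"
        rc = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        fwd = sf.kmer_counts(seq, 3, 3)
        rev = sf.kmer_counts(rc, 3, 3)
        for kmer, c in fwd.items():
            kmer_rc = kmer.translate(str.maketrans("ACGT", "TGCA"))[::-1]
            assert rev.get(kmer_rc, 0) == c

    def test_polya_signal_overlapping_count_and_binary(self):
        rec = _rec(utr3="AATAAAATAAA")
        count_spec = sf.MotifSpec("AATAAA", "utr3", "count")
        binary_spec = sf.MotifSpec("AATAAA", "utr3", "binary")
        feats = sf.motif_site_features(rec, [count_spec])
        assert feats["utr3_motif:AAUAAA"] == 2
        feats_b = sf.motif_site_features(rec, [binary_spec])
        assert feats_b["utr3_motif:AAUAAA"] == 1

    def test_absent_motif_is_zero(self):
        feats = sf.motif_site_features(_rec(), [sf.MotifSpec("GGGGGG", "utr3")])
        assert feats["utr3_motif:GGGGGG"] == 0

    def test_uaug_binary_uses_out_of_frame_rule(self):
        spec = sf.MotifSpec("ATG", "utr5", "binary")
        in_frame_only = _rec(utr5="ATGGGG")   # in frame -> 0
        out_frame = _rec(utr5="GCATGGC")
        assert sf.motif_site_features(in_frame_only, [spec])["utr5_motif:AUG"] == 0
        assert sf.motif_site_features(out_frame, [spec])["utr5_motif:AUG"] == 1


class TestRegionBasics:
    def test_gc_and_length(self):
        rec = _rec(utr5="GGCC")
        basics = sf.region_basics(rec)
        assert basics["gc:utr5"] == 1.0
        assert basics["length:utr5"] == pytest.approx(2.0)

    def test_at_only_gc_zero(self):
        assert sf.region_basics(_rec(utr5="ATATATA"))["gc:utr5"] == 0.0

    @given(st.text(alphabet="ACGT", min_size=7, max_size=30))
    def test_gc_invariant_under_reversal(self, seq):
        a = sf.region_basics(_rec(utr5=seq))["gc:utr5"]
        b = sf.region_basics(_rec(utr5=seq[::-1]))["gc:utr5"]
        assert a == b


class TestCds5PrimeWindows:
    def test_window_one_all_same_codon(self):
        cds = "ATG" + "AAA" * 170 + "TAA"   # 516 nt
        tensor, included, excluded = sf.cds_5prime_window_freqs({"t": cds})
        assert included == ["t"] and not excluded
        idx = list(sf.SENSE_CODONS).index("AAA")
        assert tensor[0, 0, idx] == pytest.approx(0.0)  # freq 1 -> log2 = 0

    def test_short_cds_excluded(self):
        cds = "ATG" + "AAA" * 30 + "TAA"
        _, included, excluded = sf.cds_5prime_window_freqs({"t": cds})
        assert excluded == ["t"] and not included

    def test_windows_partition_codons_2_to_166(self):
        rng = np.random.default_rng(0)
        body = "".join(rng.choice([c for c in sf.SENSE_CODONS]) for _ in range(200))
        cds = "ATG" + body + "TAA"
        tensor, _, _ = sf.cds_5prime_window_freqs({"t": cds})
        codons = [cds[i:i + 3] for i in range(0, len(cds) - 3, 3)]
        target = codons[1:166]
        # undo the log/pseudocount to recover counts and compare totals
        counts = np.where(tensor[0] > np.log2(0.6 / 15), 2.0 ** tensor[0] * 15, 0.0)
        assert counts.sum() == pytest.approx(len(target))


@pytest.fixture(scope="module")
def long_records():
    from ptrseq import synthetic_data as sd
    cfg = sd.SimulationConfig(n_genes=60, n_tissues=2, seed=13, cds_codons_mean=120,
                              utr5_length_log_mean=float(np.log(180.0)),
                              utr3_length_log_mean=float(np.log(250.0)))
    tx, _ = sd.simulate_transcripts(cfg)
    return tx


class TestAssembly:
    def test_default_matrix_has_204_columns(self, long_records):
        fm = sf.assemble_feature_matrix(long_records)
        assert fm.values.shape[1] == 204

    def test_dropped_reference_has_185_columns(self, long_records):
        fm = sf.assemble_feature_matrix(
            long_records, sf.FeatureOptions(context_encoding="dropped"))
        assert fm.values.shape[1] == 185

    def test_disabling_folding_removes_three_columns(self, long_records):
        fm = sf.assemble_feature_matrix(
            long_records, sf.FeatureOptions(include_folding=False))
        assert fm.values.shape[1] == 201

    def test_groups_partition_columns(self, long_records):
        fm = sf.assemble_feature_matrix(long_records)
        assert set(fm.groups.index) == set(fm.values.columns)
        assert fm.groups.notna().all()
        sizes = fm.groups.value_counts()
        assert sizes.sum() == 204

    def test_indicator_and_count_scales(self, long_records):
        fm = sf.assemble_feature_matrix(long_records)
        for col in fm.scale.index[fm.scale == "indicator"]:
            assert set(np.unique(fm.values[col])) <= {0.0, 1.0}
        for col in fm.scale.index[fm.scale == "count"]:
            vals = fm.values[col].to_numpy()
            assert (vals >= 0).all() and np.allclose(vals, np.round(vals))

    def test_empty_record_set_errors(self):
        with pytest.raises(ValueError):
            sf.assemble_feature_matrix([])
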