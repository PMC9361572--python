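import math
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ksdater import (
    SequenceRecord,
    compute_kaks,
    count_codon_differences,
    count_codon_sites,
    jukes_cantor,
    preprocess_pair,
)
from ksdater.ng86 import AlignedCodonPair, GENETIC_CODE

from .conftest import SENSE_CODONS, random_codon_pair_seqs
from .oracle_ng86 import oracle_differences, oracle_kaks, oracle_sites

sense_codon = st.sampled_from(SENSE_CODONS)


class TestSiteCounts:
    def test_phenylalanine_codon(self):
        # TTT: only TTT->TTC (Phe) of the 9 neighbours is synonymous
        sc = count_codon_sites("TTT")
        assert sc.S == pytest.approx(1 / 3)
        assert sc.N == pytest.approx(8 / 3)

    def test_tryptophan_codon_fully_nonsynonymous(self):
        sc = count_codon_sites("TGG")
        assert sc.S == 0.0 and sc.N == 3.0

    @pytest.mark.parametrize("codon", SENSE_CODONS)
    def test_sites_conserve_three_per_codon(self, codon):
        sc = count_codon_sites(codon)
        assert sc.S + sc.N == pytest.approx(3.0, abs=1e-12)
        assert sc.S >= 0 and sc.N >= 0

    @pytest.mark.parametrize("codon", ["TAA", "TAG", "TGA", "NNN", "AT-"])
    def test_stop_or_invalid_codon_rejected(self, codon):
        with pytest.raises(ValueError):
            count_codon_sites(codon)

    @given(codon=sense_codon)
    @settings(deadline=None)
    def test_matches_naive_enumeration(self, codon):
        s, n = oracle_sites(codon)
        sc = count_codon_sites(codon)
        assert sc.S == pytest.approx(s) and sc.N == pytest.approx(n)


class TestDifferenceCounts:
    def test_single_synonymous_change(self):
        dc = count_codon_differences("TTT", "TTC")
        assert (dc.Sd, dc.Nd) == (1.0, 0.0)

    def test_two_pathway_average(self):
        # TTT->GTT->GTA: 1 syn + 1 nonsyn; TTT->TTA->GTA: 2 nonsyn
        dc = count_codon_differences("TTT", "GTA")
        assert dc.Sd == pytest.approx(0.5)
        assert dc.Nd == pytest.approx(1.5)

    def test_identical_codons(self):
        dc = count_codon_differences("AAA", "AAA")
        assert (dc.Sd, dc.Nd) == (0.0, 0.0)

    def test_stop_codon_input_rejected(self):
        with pytest.raises(ValueError):
            count_codon_differences("TAA", "AAA")

    @given(ca=sense_codon, cb=sense_codon)
    @settings(deadline=None)
    def test_differences_sum_to_changed_positions(self, ca, cb):
        k = sum(1 for i in range(3) if ca[i] != cb[i])
        dc = count_codon_differences(ca, cb)
        assert dc.Sd + dc.Nd == pytest.approx(k, abs=1e-12)

    @given(ca=sense_codon, cb=sense_codon)
    @settings(deadline=None)
    def test_matches_naive_pathway_enumeration(self, ca, cb):
        sd, nd = oracle_differences(ca, cb)
        dc = count_codon_differences(ca, cb)
        assert dc.Sd == pytest.approx(sd) and dc.Nd == pytest.approx(nd)


class TestJukesCantor:
    def test_zero_maps_to_zero(self):
        assert jukes_cantor(0.0) == 0.0

    def test_saturation_boundary_is_nan(self):
        assert math.isnan(jukes_cantor(0.75))
        assert math.isnan(jukes_cantor(0.9))

    def test_closed_form_value(self):
        assert jukes_cantor(0.1) == pytest.approx(0.107326, abs=1e-6)

    def test_negative_proportion_rejected(self):
        with pytest.raises(ValueError):
            jukes_cantor(-0.01)

    @given(st.floats(min_value=0.0, max_value=0.7499))
    @settings(deadline=None)
    def test_correction_never_below_observed(self, p):
        assert jukes_cantor(p) >= p - 1e-12

    def test_strictly_increasing(self):
        grid = [i * 0.7499 / 200 for i in range(201)]
        values = [jukes_cantor(p) for p in grid]
        assert all(b > a for a, b in zip(values, values[1:]))


class TestPreprocess:
    def test_terminal_stop_stripped(self):
        pair = preprocess_pair(
            SequenceRecord("a", "ATGAAATAA"), SequenceRecord("b", "ATGAAGTAA")
        )
        assert pair.seq_a == "ATGAAA" and pair.seq_b == "ATGAAG"
        assert pair.excluded_codons == 0

    def test_gap_codon_column_dropped(self):
        pair = preprocess_pair(
            SequenceRecord("a", "ATG---AAA"), SequenceRecord("b", "ATGCCCAAA")
        )
        assert len(pair.seq_a) == 6
        assert pair.excluded_codons == 1

    def test_internal_stop_rejected_with_index(self):
        with pytest.raises(ValueError, match="codon index 1"):
            preprocess_pair(
                SequenceRecord("a", "ATGTGAAAA"), SequenceRecord("b", "ATGTGCAAA")
            )

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            preprocess_pair(SequenceRecord("a", "ATGAAA"), SequenceRecord("b", "ATG"))

    def test_length_not_multiple_of_three_rejected(self):
        with pytest.raises(ValueError):
            preprocess_pair(SequenceRecord("a", "ATGA"), SequenceRecord("b", "ATGA"))

    def test_ambiguity_codon_dropped(self):
        pair = preprocess_pair(
            SequenceRecord("a", "ATGANAAAA"), SequenceRecord("b", "ATGAAAAAA")
        )
        assert pair.excluded_codons == 1 and pair.n_codons == 2


class TestComputeKaKs:
    def test_identical_sequences(self):
        seq = "".join(random.Random(1).choice(SENSE_CODONS) for _ in range(50))
        result = compute_kaks(AlignedCodonPair("p", seq, seq))
        assert result.ks == 0.0 and result.ka == 0.0
        assert math.isnan(result.omega)

    @pytest.mark.parametrize("seed", range(10))
    def test_symmetric_under_argument_swap(self, seed):
        rng = random.Random(seed)
        a, b = random_codon_pair_seqs(rng, 40, 12)
        r1 = compute_kaks(AlignedCodonPair("ab", a, b))
        r2 = compute_kaks(AlignedCodonPair("ba", b, a))
        for attr in ("S", "N", "Sd", "Nd", "ks", "ka"):
            assert getattr(r1, attr) == pytest.approx(getattr(r2, attr), abs=1e-12)

    @pytest.mark.parametrize("seed", range(25))
    def test_site_conservation(self, seed):
        rng = random.Random(1000 + seed)
        a, b = random_codon_pair_seqs(rng, 35, 10)
        r = compute_kaks(AlignedCodonPair("p", a, b))
        assert r.S + r.N == pytest.approx(3 * r.n_codons, abs=1e-9)

    def test_too_short_flagged_not_refused(self):
        r = compute_kaks(AlignedCodonPair("p", "ATGAAA", "ATGAAA"))
        assert r.too_short

    def test_matches_brute_force_oracle(self):
        rng = random.Random(42)
        for _ in range(60):
            a, b = random_codon_pair_seqs(rng, 30, rng.randint(0, 25))
            mine = compute_kaks(AlignedCodonPair("p", a, b))
            ref = oracle_kaks(a, b)
            for key in ("S", "N", "Sd", "Nd"):
                assert getattr(mine, key) == pytest.approx(ref[key], abs=1e-9)
            for key in ("ks", "ka"):
                theirs = ref[key]
                ours = getattr(mine, key)
                if math.isnan(theirs):
                    assert math.isnan(ours)
                else:
                    assert ours == pytest.approx(theirs, abs=1e-9)

    def test_saturated_pair_reports_nan_not_clamp(self):
        rng = random.Random(7)
        # unrelated random sequences: synonymous sites saturate
        a = "".join(rng.choice(SENSE_CODONS) for _ in range(60))
        b = "".join(rng.choice(SENSE_CODONS) for _ in range(60))
        r = compute_kaks(AlignedCodonPair("p", a, b))
        if r.saturated_s:
            assert math.isnan(r.ks)
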