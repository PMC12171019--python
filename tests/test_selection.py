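"""NG86 ka/ks estimation: site/difference counting against independent
oracles (exhaustive pathway enumeration and Biopython's implementation)."""

import itertools
import math
import warnings

import numpy as np
import pytest

from deuteromics import (CodonSequencePair, count_differences, count_sites,
                         jukes_cantor, kaks_screen, ng86)
from deuteromics.selection import SENSE_CODONS, STOP_CODONS, translate_codon

# ---------------------------------------------------------------------------
# independent oracle: recursive enumeration of every single-step pathway
# ---------------------------------------------------------------------------


def _paths(a, b):
    """All orderings of single-nucleotide steps from codon a to codon b,
    as lists of intermediate codons (including endpoints)."""
    if a == b:
        return [[a]]
    out = []
    for pos in range(3):
        if a[pos] != b[pos]:
            step = a[:pos] + b[pos] + a[pos + 1:]
            for rest in _paths(step, b):
                out.append([a] + rest)
    return out


def oracle_differences(a, b):
    """Pathway-averaged (sd, nd) by exhaustive enumeration."""
    paths = _paths(a, b)
    ok = [p for p in paths if not any(c in STOP_CODONS for c in p[1:-1])]
    chosen = ok if ok else paths

    def classify(path):
        sd = nd = 0.0
        for x, y in zip(path, path[1:]):
            if x in STOP_CODONS or y in STOP_CODONS:
                nd += 1
            elif translate_codon(x) == translate_codon(y):
                sd += 1
            else:
                nd += 1
        return sd, nd

    scored = [classify(p) for p in chosen]
    return (sum(s for s, _ in scored) / len(scored),
            sum(n for _, n in scored) / len(scored))


class TestCountSites:
    @pytest.mark.parametrize("codon, s, n", [
        ("TTT", 1 / 3, 8 / 3),   # Phe: only 3rd-position C is synonymous
        ("GCA", 1.0, 2.0),       # Ala: fourfold-degenerate third position
        ("ATG", 0.0, 3.0),       # Met has no synonym
    ])
    def test_enumerated_examples(self, codon, s, n):
        got_s, got_n = count_sites(codon)
        assert got_s == pytest.approx(s)
        assert got_n == pytest.approx(n)

    def test_sites_sum_to_three_for_all_sense_codons(self):
        assert len(SENSE_CODONS) == 61
        for codon in SENSE_CODONS:
            s, n = count_sites(codon)
            assert s + n == pytest.approx(3.0, abs=1e-12)
            assert 0.0 <= s <= 3.0

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            count_sites("TAA")


class TestCountDifferences:
    @pytest.mark.parametrize("a, b, sd, nd", [
        ("TTT", "TTT", 0.0, 0.0),
        ("GTT", "GTA", 1.0, 0.0),     # Val -> Val, synonymous
        ("TTT", "GTA", 0.5, 1.5),     # two pathways, one has a synonymous leg
    ])
    def test_examples(self, a, b, sd, nd):
        assert count_differences(a, b) == pytest.approx((sd, nd))

    def test_matches_enumeration_oracle_on_random_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            a, b = rng.choice(SENSE_CODONS, size=2)
            got = count_differences(a, b)
            want = oracle_differences(a, b)
            assert got == pytest.approx(want, abs=1e-12)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            a, b = rng.choice(SENSE_CODONS, size=2)
            assert count_differences(a, b) == pytest.approx(
                count_differences(b, a), abs=1e-12)

    def test_total_differences_bounded_by_hamming(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            a, b = rng.choice(SENSE_CODONS, size=2)
            sd, nd = count_differences(a, b)
            hamming = sum(x != y for x, y in zip(a, b))
            assert sd + nd == pytest.approx(hamming)


class TestNg86:
    def test_worked_example(self):
        est = ng86(CodonSequencePair("GTTGCA", "GTAGCA"))
        assert est.S == pytest.approx(2.0)
        assert est.N == pytest.approx(4.0)
        assert (est.Sd, est.Nd) == (1.0, 0.0)
        assert est.pS == pytest.approx(0.5)
        assert est.pN == 0.0
        assert est.dS == pytest.approx(-0.75 * math.log(1 / 3), abs=1e-9)
        assert est.dS == pytest.approx(0.8239, abs=1e-4)
        assert est.dN == 0.0
        assert est.regime == "purifying"

    def test_identical_sequences_undefined(self):
        seq = "".join(np.random.default_rng(0).choice(SENSE_CODONS, size=100))
        est = ng86(CodonSequencePair(seq, seq))
        assert (est.Sd, est.Nd) == (0.0, 0.0)
        assert est.regime == "undefined"
        assert math.isnan(est.ratio)

    def test_symmetry_in_sequence_order(self):
        rng = np.random.default_rng(5)
        a = "".join(rng.choice(SENSE_CODONS, size=50))
        b = "".join(rng.choice(SENSE_CODONS, size=50))
        try:
            ea, eb = ng86(CodonSequencePair(a, b)), ng86(CodonSequencePair(b, a))
        except ValueError:
            pytest.skip("random pair invalid")
        for field in ("S", "N", "Sd", "Nd", "pS", "pN"):
            assert getattr(ea, field) == pytest.approx(getattr(eb, field))

    def test_ds_zero_dn_positive_is_positive_regime(self):
        # ATG -> ATA is nonsynonymous (Met -> Ile); no synonymous change
        est = ng86(CodonSequencePair("ATGGCA", "ATAGCA"))
        assert est.Nd == 1.0 and est.Sd == 0.0
        assert est.regime == "positive"
        assert math.isinf(est.ratio)

    def test_jc_correction_approaches_p_at_small_p(self):
        for p in (1e-6, 5e-7):
            assert jukes_cantor(p) == pytest.approx(p, rel=1e-5)

    def test_saturated_proportion_flagged(self):
        assert math.isnan(jukes_cantor(0.75))
        assert math.isnan(jukes_cantor(0.9))

    def test_matches_biopython_on_random_pairs(self):
        """Cross-check dN/dS against an independent NG86 implementation."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds
        rng = np.random.default_rng(13)
        checked = 0
        while checked < 25:
            seed = int(rng.integers(1 << 30))
            from deuteromics import OmegaConfig, generate_codon_pair
            pair = generate_codon_pair(OmegaConfig(
                omega=1.0, n_codons=60, n_events=25, seed=seed))
            est = ng86(pair)
            if est.saturated or not math.isfinite(est.dS):
                continue
            dn, ds = cal_dn_ds(CodonSeq(pair.seq_a), CodonSeq(pair.seq_b),
                               method="NG86")
            assert est.dN == pytest.approx(dn, abs=1e-4)
            assert est.dS == pytest.approx(ds, abs=1e-4)
            checked += 1


class TestKaksScreen:
    def test_batch_composition(self):
        pairs = [
            CodonSequencePair("GTTGCA", "GTAGCA"),           # purifying
            CodonSequencePair("ATGGCA", "ATGGCA"),           # undefined
            CodonSequencePair("ATGGCA", "ATAGCA"),           # positive
        ]
        screen = kaks_screen(pairs)
        assert list(screen.table["regime"]) == ["purifying", "undefined",
                                                "positive"]
        assert screen.regime_counts["purifying"] == 1
        assert screen.regime_counts["positive"] == 1

    def test_empty_batch(self):
        screen = kaks_screen([])
        assert len(screen) == 0
        assert sum(screen.regime_counts.values()) == 0

    def test_invalid_pair_collected_not_fatal(self):
        good = CodonSequencePair("GTTGCA", "GTAGCA")
        screen = kaks_screen([good, "not a pair", good])
        assert len(screen) == 2
        assert len(screen.errors) == 1


class TestPairValidation:
    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            CodonSequencePair("GTTGCA", "GTT")

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            CodonSequencePair("TAAGCA", "GTAGCA")

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError):
            CodonSequencePair("GTNGCA", "GTAGCA")
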