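import numpy as np
import pytest

from deuteromics import (CommunityConfig, ConfigError, OmegaConfig,
                         PowerLawRichnessModel, generate_aa_groups,
                         generate_codon_pair, generate_orf_table,
                         generate_presence_sets, jaccard, ng86,
                         transposase_census, write_orf_table)
from deuteromics.tables_io import TPM_TOTAL


def small_cfg(**kw):
    base = dict(n_taxa=40, n_orfs=1500, n_samples=2, seed=5)
    base.update(kw)
    return CommunityConfig(**base)


class TestGenerateOrfTable:
    def test_same_seed_byte_identical(self, tmp_path):
        t1 = generate_orf_table(small_cfg())
        t2 = generate_orf_table(small_cfg())
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_orf_table(t1, p1)
        write_orf_table(t2, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_different_seed_differs(self):
        t1 = generate_orf_table(small_cfg(seed=1))
        t2 = generate_orf_table(small_cfg(seed=2))
        assert t1.to_dataframe().iloc[0].tolist() != t2.to_dataframe().iloc[0].tolist()

    def test_tpm_normalized_per_sample(self):
        table = generate_orf_table(small_cfg())
        for s in table.sample_ids:
            assert table.sample_total(s) == pytest.approx(TPM_TOTAL, rel=1e-9)

    def test_length_bounds_respected(self):
        table = generate_orf_table(small_cfg(n_orfs=3000))
        lengths = [rec.length_bp for rec in table]
        assert min(lengths) >= 60
        assert max(lengths) <= 8748

    def test_gc_in_unit_interval(self):
        table = generate_orf_table(small_cfg())
        assert all(0.0 <= rec.gc_fraction <= 1.0 for rec in table)

    def test_noiseless_points_lie_exactly_on_power_law(self):
        cfg = small_cfg(n_samples=1, richness_intercept=0.2, richness_slope=1.0,
                        noiseless=True, normalize=False)
        table = generate_orf_table(cfg)
        fit = PowerLawRichnessModel.from_orf_table(table, "exact").fit()
        assert fit.gamma == pytest.approx(1.0, abs=1e-9)
        assert fit.c == pytest.approx(0.2, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_zero_transposase_fraction_gives_zero_census(self):
        table = generate_orf_table(small_cfg(transposase_fraction=0.0))
        assert transposase_census(table).mean_count_pct == 0.0

    def test_transposase_fraction_concentrates_at_scale(self):
        cfg = CommunityConfig(n_taxa=200, n_orfs=50_000, n_samples=1,
                              transposase_fraction=0.0271, seed=9)
        table = generate_orf_table(cfg)
        realized = 100.0 * sum(rec.gene_name == "transposase" for rec in table) / len(table)
        assert realized == pytest.approx(2.71, abs=0.3)

    def test_transposase_tpm_share_exact(self):
        cfg = small_cfg(transposase_tpm_share=0.0114)
        table = generate_orf_table(cfg)
        res = transposase_census(table)
        for s in table.sample_ids:
            assert res.per_sample_tpm[s] == pytest.approx(0.0114 * TPM_TOTAL,
                                                          rel=1e-9)

    def test_too_few_orfs_rejected(self):
        with pytest.raises(ConfigError):
            CommunityConfig(n_taxa=100, n_orfs=50)

    def test_zero_richness_taxa_flagged(self):
        # tiny community with low intercept: some taxa realize zero ORFs
        cfg = CommunityConfig(n_taxa=30, n_orfs=30, n_samples=1, seed=2,
                              abundance_log10_range=(0.0, 1.0))
        table = generate_orf_table(cfg)
        tags = {rec.species_tag for rec in table}
        for tag in table.metadata["zero_richness_taxa"]:
            assert tag not in tags


class TestGenerateCodonPair:
    def test_zero_events_identical(self):
        pair = generate_codon_pair(OmegaConfig(omega=1.0, n_codons=50,
                                               n_events=0, seed=3))
        assert pair.seq_a == pair.seq_b
        est = ng86(pair)
        assert (est.Sd, est.Nd) == (0.0, 0.0)

    def test_omega_zero_only_synonymous_changes(self):
        pair = generate_codon_pair(OmegaConfig(omega=0.0, n_codons=200,
                                               n_events=100, seed=4))
        est = ng86(pair)
        assert est.Nd == 0.0
        assert est.Sd > 0

    def test_high_omega_median_ratio_above_one(self):
        ratios = []
        for seed in range(50):
            pair = generate_codon_pair(OmegaConfig(omega=5.0, n_codons=300,
                                                   n_events=60, seed=seed))
            ratios.append(ng86(pair).ratio)
        assert np.median(ratios) > 1.0

    def test_determinism(self):
        cfg = OmegaConfig(omega=2.0, n_codons=100, n_events=30, seed=8)
        assert generate_codon_pair(cfg).seq_b == generate_codon_pair(cfg).seq_b


class TestGenerateAaGroups:
    def test_determinism(self):
        a1, b1 = generate_aa_groups(10, 8, None, seed=6)
        a2, b2 = generate_aa_groups(10, 8, None, seed=6)
        assert np.array_equal(a1.data, a2.data)
        assert np.array_equal(b1.data, b2.data)

    def test_rows_on_simplex(self):
        a, b = generate_aa_groups(20, 20, None, seed=1)
        assert np.allclose(a.data.sum(axis=1), 1.0)
        assert np.allclose(b.data.sum(axis=1), 1.0)

    def test_profile_shifts_group_means(self):
        profile = np.zeros(20)
        profile[0] = 0.02
        profile[1] = -0.02
        a, b = generate_aa_groups(2000, 2000, profile, seed=2)
        diff = a.data.mean(axis=0) - b.data.mean(axis=0)
        assert diff[0] == pytest.approx(0.02, abs=0.002)
        assert diff[1] == pytest.approx(-0.02, abs=0.002)

    def test_infeasible_profile_rejected(self):
        profile = np.zeros(20)
        profile[0] = 0.2  # would push a frequency past the 0.05 base
        with pytest.raises(ConfigError):
            generate_aa_groups(5, 5, profile, seed=0)


class TestGeneratePresenceSets:
    def test_requested_sizes_and_overlap(self):
        sets = generate_presence_sets([170, 168], {(0, 1): 106}, seed=0)
        assert len(sets[0]) == 170
        assert len(sets[1]) == 168
        assert len(sets[0] & sets[1]) == 106
        assert jaccard(sets[0], sets[1]) == pytest.approx(106 / 232, abs=1e-12)

    def test_full_overlap_gives_jaccard_one(self):
        sets = generate_presence_sets([5, 5], {(0, 1): 5}, seed=0)
        assert jaccard(sets[0], sets[1]) == 1.0

    def test_disjoint_gives_jaccard_zero(self):
        sets = generate_presence_sets([5, 5], {(0, 1): 0}, seed=0)
        assert jaccard(sets[0], sets[1]) == 0.0

    def test_three_samples_pairwise_overlaps(self):
        sets = generate_presence_sets(
            [30, 25, 20], {(0, 1): 10, (0, 2): 8, (1, 2): 8}, seed=1)
        assert [len(s) for s in sets] == [30, 25, 20]
        assert len(sets[0] & sets[1]) == 10
        assert len(sets[0] & sets[2]) == 8
        assert len(sets[1] & sets[2]) == 8

    def test_inconsistent_overlap_rejected(self):
        with pytest.raises(ConfigError):
            generate_presence_sets([5, 5], {(0, 1): 6}, seed=0)
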