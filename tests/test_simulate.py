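"""Synthetic genome/read generators: determinism, truth sets, error models."""

import numpy as np
import pytest

from sexmer import (
    GenomeConfig,
    KmerSpec,
    LongReadSimConfig,
    ShortReadSimConfig,
    count_kmers,
    derive_individual,
    generate_genome,
    simulate_long_reads,
    simulate_population,
    simulate_short_reads,
    true_specific_kmers,
)
from sexmer.kmers import codes_to_str, window_keys

SMALL = GenomeConfig(autosome_len=50_000, x_len=30_000, y_len=10_000, par_len=1_000,
                     xy_divergence=0.01, seed=3)


class TestGenomeGeneration:
    def test_determinism(self):
        a = generate_genome(SMALL)
        b = generate_genome(SMALL)
        for name in ("autosome", "X", "Y"):
            assert np.array_equal(a.chroms[name], b.chroms[name])

    def test_par_shared_verbatim(self):
        t = generate_genome(SMALL)
        assert np.array_equal(t.chroms["Y"][:1_000], t.chroms["X"][:1_000])

    def test_zero_divergence_full_par_means_no_specific_kmers(self):
        cfg = GenomeConfig(autosome_len=20_000, x_len=10_000, y_len=10_000,
                           par_len=10_000, xy_divergence=0.0, seed=1)
        t = generate_genome(cfg)
        assert len(t.true_specific_kmers(KmerSpec(21))) == 0

    def test_invalid_configs(self):
        with pytest.raises(ValueError):
            GenomeConfig(par_len=10**9)
        with pytest.raises(ValueError):
            GenomeConfig(xy_divergence=1.5)

    def test_truth_set_equals_brute_force_difference(self):
        t = generate_genome(SMALL)
        spec = KmerSpec(21)
        got = t.true_specific_kmers(spec)
        y = set(window_keys(t.chroms["Y"], spec).tolist())
        ax = set(window_keys(t.chroms["autosome"], spec).tolist()) | set(
            window_keys(t.chroms["X"], spec).tolist()
        )
        assert set(got.tolist()) == y - ax
        assert len(got) > 0

    def test_longer_k_contains_specific_shorter_k(self):
        """Any 51-mer of Y containing a Y-specific 21-mer is itself specific."""
        t = generate_genome(GenomeConfig(autosome_len=20_000, x_len=10_000, y_len=5_000,
                                         par_len=500, xy_divergence=0.02, seed=9))
        k21 = set(t.true_specific_kmers(KmerSpec(21)).tolist())
        k51 = set(k.tobytes() if hasattr(k, "tobytes") else k for k in t.true_specific_kmers(KmerSpec(51)).tolist())
        y = t.chroms["Y"]
        spec21, spec51 = KmerSpec(21), KmerSpec(51)
        keys21 = window_keys(y, spec21)
        keys51 = window_keys(y, spec51)
        # position i of a 51-window covers 21-windows i..i+30
        for i in range(0, len(keys51), 257):
            covers_specific = any(keys21[j] in k21 for j in range(i, i + 31))
            if covers_specific:
                assert keys51[i] in k51


class TestIndividuals:
    def test_h_zero_haplotypes_identical(self):
        t = generate_genome(SMALL)
        ind = derive_individual(t, 0.0, "male", seed=5)
        haps = dict(ind.haplotypes)
        assert np.array_equal(haps["A_hap1"], haps["A_hap2"])
        assert "Y" in haps

    def test_female_has_no_y(self):
        t = generate_genome(SMALL)
        ind = derive_individual(t, 0.001, "female", seed=5)
        names = [n for n, _ in ind.haplotypes]
        assert "Y" not in names and names.count("X_hap1") + names.count("X_hap2") == 2

    def test_het_site_count_binomial(self):
        t = generate_genome(GenomeConfig(autosome_len=200_000, x_len=10_000, y_len=5_000,
                                         par_len=500, seed=2))
        h = 0.002
        ind = derive_individual(t, h, "male", seed=7)
        haps = dict(ind.haplotypes)
        n_het = int((haps["A_hap1"] != haps["A_hap2"]).sum())
        mean = h * 200_000
        sd = np.sqrt(mean * (1 - h))
        assert abs(n_het - mean) < 4 * sd

    def test_het_rate_domain(self):
        t = generate_genome(SMALL)
        with pytest.raises(ValueError):
            derive_individual(t, 0.5, "male", 1)

    def test_shared_variants_calibrated_to_het_rate(self):
        from sexmer import sample_population_variants

        t = generate_genome(GenomeConfig(autosome_len=500_000, x_len=10_000, y_len=5_000,
                                         par_len=500, seed=4))
        h = 0.004
        variants = sample_population_variants(t, h, seed=3)
        inds = [derive_individual(t, h, "male", seed=s, variants=variants) for s in (1, 2, 3)]
        rates = []
        for ind in inds:
            haps = dict(ind.haplotypes)
            rates.append((haps["A_hap1"] != haps["A_hap2"]).mean())
        # per-individual heterozygosity close to h
        assert np.mean(rates) == pytest.approx(h, rel=0.15)
        # alt alleles are shared between individuals (population polymorphism)
        a = dict(inds[0].haplotypes)
        b = dict(inds[1].haplotypes)
        alt_sites_a = set(np.flatnonzero((a["A_hap1"] != t.chroms["autosome"]) |
                                         (a["A_hap2"] != t.chroms["autosome"])).tolist())
        alt_sites_b = set(np.flatnonzero((b["A_hap1"] != t.chroms["autosome"]) |
                                         (b["A_hap2"] != t.chroms["autosome"])).tolist())
        assert len(alt_sites_a & alt_sites_b) > 0.2 * len(alt_sites_a)


class TestShortReads:
    def test_coverage_accounting(self):
        t = generate_genome(SMALL)
        ind = derive_individual(t, 0.0, "male", seed=1)
        cfg = ShortReadSimConfig(depth=5.0, seed=4)
        reads = simulate_short_reads(ind, cfg)
        expected = 5.0 * ind.total_len / 150
        sd = np.sqrt(expected)
        assert abs(reads.n_reads - expected) < 4 * sd

    def test_error_free_reads_are_substrings(self):
        t = generate_genome(SMALL)
        ind = derive_individual(t, 0.0, "male", seed=1)
        reads = simulate_short_reads(ind, ShortReadSimConfig(depth=0.2, error_rate=0.0, seed=2))
        genome = "|".join(codes_to_str(h) for _, h in ind.haplotypes)
        checked = 0
        for _, seq in reads.records():
            assert seq in genome
            checked += 1
            if checked >= 25:
                break

    def test_tiling_mode_guarantees_min_coverage_two(self):
        t = generate_genome(GenomeConfig(autosome_len=5_000, x_len=2_000, y_len=1_000,
                                         par_len=100, seed=8))
        ind = derive_individual(t, 0.0, "male", seed=1)
        reads = simulate_short_reads(ind, ShortReadSimConfig(mode="tiling", error_rate=0.0))
        spec = KmerSpec(21)
        table = count_kmers(reads.packed, spec)
        genome_keys = np.unique(np.concatenate([window_keys(h, spec) for _, h in ind.haplotypes]))
        assert np.all(np.isin(genome_keys, table.keys))
        assert table.counts.min() >= 2

    def test_determinism_and_distinct_population_seeds(self):
        t = generate_genome(SMALL)
        cfg = ShortReadSimConfig(depth=1.0, seed=0)
        pops = [
            [r.packed.tobytes() for _, r in simulate_population(t, 2, 2, 0.001, cfg, master_seed=9)]
            for _ in range(2)
        ]
        assert pops[0] == pops[1]  # reproducible
        assert len(set(pops[0])) == 4  # no two individuals share reads


class TestLongReads:
    def test_error_free_reads_are_exact_substrings(self):
        t = generate_genome(SMALL)
        cfg = LongReadSimConfig(depth=0.5, sub_rate=0.0, ins_rate=0.0, del_rate=0.0,
                                length_mean=2_000, length_sd=300, seed=3)
        lr = simulate_long_reads(t, cfg)
        for (rid, seq), row in zip(lr.records(), lr.origins.itertuples()):
            src = codes_to_str(t.chroms[row.chrom][row.start : row.start + row.ref_len])
            assert seq == src

    def test_base_share_proportional_to_copy_number(self):
        t = generate_genome(SMALL)
        cfg = LongReadSimConfig(depth=3.0, length_mean=1_500, length_sd=200, seed=5)
        lr = simulate_long_reads(t, cfg)
        by = lr.origins.groupby("chrom")["ref_len"].sum()
        total = by.sum()
        expected_share = {
            "autosome": 2 * 50_000, "X": 30_000, "Y": 10_000,
        }
        denom = sum(expected_share.values())
        for chrom, share in expected_share.items():
            assert by[chrom] / total == pytest.approx(share / denom, abs=0.05)

    def test_presets_differ_only_by_parameters(self):
        t = generate_genome(SMALL)
        hifi = LongReadSimConfig(preset="hifi").rates()
        ont = LongReadSimConfig(preset="ont").rates()
        assert hifi != ont
        with pytest.raises(ValueError):
            LongReadSimConfig(preset="nanopore2000")

    def test_indel_rates_change_read_lengths(self):
        t = generate_genome(SMALL)
        no_indel = LongReadSimConfig(depth=1.0, sub_rate=0.0, ins_rate=0.0, del_rate=0.0,
                                     length_mean=2_000, length_sd=0, seed=6)
        heavy_del = LongReadSimConfig(depth=1.0, sub_rate=0.0, ins_rate=0.0, del_rate=0.1,
                                      length_mean=2_000, length_sd=0, seed=6)
        a = simulate_long_reads(t, no_indel)
        b = simulate_long_reads(t, heavy_del)
        mean_a = np.mean([len(s) for s in a.seqs])
        mean_b = np.mean([len(s) for s in b.seqs])
        assert mean_b == pytest.approx(0.9 * mean_a, rel=0.02)

    def test_read_ids_encode_origin(self):
        t = generate_genome(SMALL)
        lr = simulate_long_reads(t, LongReadSimConfig(depth=0.3, length_mean=1_000,
                                                      length_sd=100, seed=1))
        for rid, chrom in zip(lr.origins["read_id"], lr.origins["chrom"]):
            assert rid.endswith(chrom)


class TestModuleAlias:
    def test_true_specific_kmers_function(self):
        t = generate_genome(SMALL)
        spec = KmerSpec(21)
        assert np.array_equal(true_specific_kmers(t, spec), t.true_specific_kmers(spec))
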