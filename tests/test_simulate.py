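"""Simulator truth structure, determinism, and the observation noise model."""

import numpy as np
import pytest
from scipy import stats

import algapop as ap

HOM_REF, HET, HOM_ALT, MISSING = ap.HOM_REF, ap.HET, ap.HOM_ALT, ap.MISSING


def small_config(**kw):
    base = dict(seed=0, n_chrom=1, chrom_length=20_000, n_clusters=2,
                n_samples_per_cluster=3, n_admixed=1, strain_subgroups=2,
                shared_mutations_per_subgroup=5, private_mutations_per_sample=2,
                rrna_mask=[("chr1", 1_001, 2_000)], organelle_length=5_000)
    base.update(kw)
    return ap.SimConfig(**base)


class TestTruthStructure:
    def test_determinism_byte_identical(self, tmp_path):
        cfg = small_config(seed=42)
        t1, t2 = ap.simulate_truth(cfg), ap.simulate_truth(small_config(seed=42))
        for s in t1.haplotypes:
            assert (t1.haplotypes[s] == t2.haplotypes[s]).all()
        assert t1.organelle_truth.cp.sequences == t2.organelle_truth.cp.sequences
        assert t1.organelle_truth.tree_newick == t2.organelle_truth.tree_newick
        noise = ap.NoiseModel.from_config(cfg)
        p1 = ap.observe(t1, noise, seed=42, path=tmp_path / "a.vcf")
        p2 = ap.observe(t2, noise, seed=42, path=tmp_path / "b.vcf")
        assert p1.read_bytes() == p2.read_bytes()

    def test_no_divergence_means_no_informative_sites(self):
        truth = ap.simulate_truth(small_config(species_divergence=0.0))
        m = truth.truth_matrix()
        pa, pb = truth.hybrid_composition
        assert len(ap.informative_trio_sites(m, pa, pb)) == 0

    def test_sister_divergence_matches_binomial_expectation(self):
        # brute-force count of sister-vs-reference differences over 20 seeds
        L, p = 100_000, 0.01
        counts = []
        for seed in range(20):
            cfg = ap.SimConfig(seed=seed, n_chrom=1, chrom_length=L,
                               n_clusters=1, n_samples_per_cluster=2,
                               n_admixed=0, species_divergence=p,
                               strain_subgroups=1,
                               shared_mutations_per_subgroup=2,
                               private_mutations_per_sample=1,
                               rrna_mask=[("chr1", 11, 20)],
                               organelle_length=1_000)
            truth = ap.simulate_truth(cfg)
            counts.append(int(truth.haplotypes["B_1"].sum()))
        sd = np.sqrt(L * p * (1 - p))
        assert abs(np.mean(counts) - L * p) < 3 * sd

    def test_non_hybrid_truth_is_homozygous_everywhere(self, default_truth):
        G = default_truth.truth_genotype_array()
        rows = [i for i, s in enumerate(default_truth.samples)
                if s != default_truth.hybrid_name]
        assert (G[rows] != HET).all()

    def test_hybrid_het_outside_mask_parent_b_inside(self, default_truth):
        truth = default_truth
        G = default_truth.truth_genotype_array()
        hyb = truth.samples.index(truth.hybrid_name)
        pa, pb = truth.hybrid_composition
        fixed = (truth.haplotypes[pa] == 0) & (truth.haplotypes[pb] == 1)
        inside = truth._mask_global()
        assert (G[hyb, fixed & ~inside] == HET).all()
        assert (G[hyb, fixed & inside] == 2 * truth.haplotypes[pb][fixed & inside]).all()
        assert (G[hyb, inside] != HET).all()

    def test_hybrid_organelles_equal_donor(self, default_truth):
        org = default_truth.organelle_truth
        hyb = default_truth.hybrid_name
        assert org.cp.sequence(hyb) == org.cp.sequence(org.donor)
        assert org.mt.sequence(hyb) == org.mt.sequence(org.donor)

    def test_planted_loci_exist_in_truth_haplotypes(self, default_truth):
        truth = default_truth
        meta = truth.sample_table
        L = truth.config.chrom_length
        chrom_idx = {c: i for i, c in enumerate(truth.config.chrom_names)}
        for _, row in truth.planted_group_loci.iterrows():
            g = chrom_idx[row["chrom"]] * L + int(row["pos"]) - 1
            members = meta.loc[meta["subgroup"] == row["subgroup"], "sample"]
            assert all(truth.haplotypes[s][g] == 1 for s in members)

    def test_rejects_excess_planted_mutations(self):
        with pytest.raises(ValueError, match="monomorphic"):
            small_config(chrom_length=100, rrna_mask=[("chr1", 11, 20)],
                         shared_mutations_per_subgroup=100).validate()

    def test_rejects_mask_outside_genome(self):
        with pytest.raises(ValueError, match="rrna_mask"):
            small_config(rrna_mask=[("chr1", 1, 10 ** 9)]).validate()

    def test_config_json_round_trip(self, tmp_path):
        cfg = small_config(seed=9, fst=0.3)
        cfg.to_json(tmp_path / "c.json")
        assert ap.SimConfig.from_json(tmp_path / "c.json") == cfg


class TestObservation:
    def test_zero_noise_reproduces_truth(self, default_truth, zero_noise_matrix):
        t = default_truth.truth_matrix()
        assert zero_noise_matrix.samples == t.samples
        assert (zero_noise_matrix.calls == t.calls).all()

    def test_refuses_overwrite_without_force(self, tmp_path):
        truth = ap.simulate_truth(small_config())
        noise = ap.NoiseModel(error_rate=0, missing_rate=0)
        path = ap.observe(truth, noise, seed=1, path=tmp_path / "o.vcf")
        with pytest.raises(FileExistsError):
            ap.observe(truth, noise, seed=1, path=path)
        ap.observe(truth, noise, seed=1, path=path, force=True)

    def test_error_rate_drives_het_fraction_on_doubled_haploids(
            self, default_truth, tmp_path):
        # errors on a homozygous call land on HET with probability 1/2
        e = 0.01
        noise = ap.NoiseModel(error_rate=e, missing_rate=0.0)
        path = ap.observe(default_truth, noise, seed=77, path=tmp_path / "e.vcf")
        m = ap.read_multisample_vcf(path)
        rows = [i for i, s in enumerate(m.samples)
                if s != default_truth.hybrid_name]
        n_calls = len(rows) * m.n_sites
        n_het = int((m.calls[rows] == ap.HET).sum())
        lo, hi = stats.binom.ppf([0.005, 0.995], n_calls, e / 2)
        assert lo <= n_het <= hi

    def test_missing_rate_half(self, tmp_path):
        truth = ap.simulate_truth(small_config(seed=5))
        noise = ap.NoiseModel(error_rate=0.0, missing_rate=0.5)
        path = ap.observe(truth, noise, seed=5, path=tmp_path / "m.vcf")
        m = ap.read_multisample_vcf(path)
        frac = float((m.calls == MISSING).mean())
        assert m.calls.size >= 1000
        assert 0.45 <= frac <= 0.55
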