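"""Genotype-matrix I/O and the three doubled-haploid filters."""

import numpy as np
import pytest

import algapop as ap
from algapop.genotypes import GQ_UNKNOWN

from conftest import make_matrix, random_matrix

HOM_REF, HET, HOM_ALT, MISSING = ap.HOM_REF, ap.HET, ap.HOM_ALT, ap.MISSING


class TestReadVcf:
    def test_biallelic_snvs_and_genotype_mapping(self, toy_vcf, toy_metadata):
        meta = ap.read_sample_metadata(toy_metadata)
        m = ap.read_multisample_vcf(toy_vcf, meta)
        assert m.samples == ["S1", "S2"]
        assert list(m.sites["pos"]) == [10, 20, 30]
        # 0/0 -> HOM_REF, phased 1|0 -> HET, half-call ./1 -> MISSING
        assert list(m.calls[0]) == [HOM_REF, HET, MISSING]
        # 0/1 -> HET, ./. -> MISSING, 1/1 -> HOM_ALT
        assert list(m.calls[1]) == [HET, MISSING, HOM_ALT]
        assert m.provenance["n_sites_dropped_multiallelic"] == 1
        assert m.provenance["n_sites_dropped_non_snv"] == 1
        assert m.gq[1, 2] == 19
        assert m.gq[1, 1] == GQ_UNKNOWN  # '.' GQ on a missing call

    def test_unknown_sample_is_a_hard_error(self, toy_vcf, toy_metadata):
        meta = ap.read_sample_metadata(toy_metadata)
        meta = meta[meta["sample"] != "S2"]
        with pytest.raises(ValueError, match="S2"):
            ap.read_multisample_vcf(toy_vcf, meta)

    def test_vcf_round_trip(self, toy_vcf, tmp_path):
        m = ap.read_multisample_vcf(toy_vcf)
        out = ap.write_vcf(m, tmp_path / "rt.vcf")
        m2 = ap.read_multisample_vcf(out)
        assert (m2.calls == m.calls).all()
        assert list(m2.sites["pos"]) == list(m.sites["pos"])
        with pytest.raises(FileExistsError):
            ap.write_vcf(m, out)


class TestFilterGenotypes:
    def test_gq_mask_then_missingness_drop(self):
        # one GQ=19 call -> MISSING; site missing fraction 0.5 > 0.1 -> dropped
        m = make_matrix([[HOM_REF], [HOM_ALT]], gq=[[19], [50]])
        out, rep = ap.filter_genotypes(m, min_gq=20, max_missing=0.1)
        assert out.n_sites == 0
        assert rep.n_calls_masked_by_gq == 1
        assert rep.n_sites_dropped_missingness == 1
        rep.check()

    def test_noop_when_all_pass(self):
        m = make_matrix([[HOM_REF, HET], [HOM_ALT, HOM_REF]],
                        gq=[[50, 60], [70, 80]])
        out, rep = ap.filter_genotypes(m)
        assert (out.calls == m.calls).all()
        assert rep.n_calls_masked_by_gq == 0
        assert rep.n_sites_dropped_missingness == 0

    def test_max_missing_one_drops_nothing(self):
        m = make_matrix([[MISSING, MISSING], [MISSING, HOM_REF]],
                        gq=[[50, 50], [50, 50]])
        out, _ = ap.filter_genotypes(m, max_missing=1.0)
        assert out.n_sites == 2

    def test_gq_absent_requires_explicit_disable(self):
        m = make_matrix([[HOM_REF], [HOM_ALT]])
        with pytest.raises(ValueError, match="min_gq=0"):
            ap.filter_genotypes(m, min_gq=20)
        out, _ = ap.filter_genotypes(m, min_gq=0)
        assert out.n_sites == 1


class TestDropHeterozygousSites:
    def test_het_in_designated_sample_drops_site(self):
        m = make_matrix([[HOM_REF, HET, HOM_REF],
                         [HOM_ALT, HOM_REF, HOM_REF],
                         [HOM_REF, HOM_REF, HOM_ALT]])
        out, rep = ap.drop_heterozygous_sites(m, ["S1", "S2", "S3"])
        assert out.n_sites == 2
        assert rep.n_sites_dropped_het == 1

    def test_het_only_in_non_designated_sample_is_retained(self):
        # the hybrid (S3) is HET but not in the designated homozygous set
        m = make_matrix([[HOM_REF], [HOM_ALT], [HET]])
        out, rep = ap.drop_heterozygous_sites(m, ["S1", "S2"])
        assert out.n_sites == 1
        assert rep.n_sites_dropped_het == 0

    def test_empty_set_warns_and_is_noop(self):
        m = make_matrix([[HET], [HET]])
        with pytest.warns(UserWarning):
            out, _ = ap.drop_heterozygous_sites(m, [])
        assert out.n_sites == 1


class TestRegionMask:
    def test_exclude_and_restrict_by_hand(self):
        m = make_matrix([[HOM_REF, HOM_ALT]])
        m.sites.loc[:, "pos"] = [10, 100]
        mask = ap.RegionMask([("chr1", 50, 150)])
        assert list(ap.apply_region_mask(m, mask, "exclude").sites["pos"]) == [10]
        assert list(ap.apply_region_mask(m, mask, "restrict").sites["pos"]) == [100]

    def test_empty_mask_exclude_is_identity(self):
        m = make_matrix([[HOM_REF, HET]])
        out = ap.apply_region_mask(m, ap.RegionMask([]), "exclude")
        assert out.n_sites == m.n_sites

    def test_unknown_chromosome_errors(self):
        m = make_matrix([[HOM_REF]])
        with pytest.raises(ValueError, match="chrX"):
            ap.apply_region_mask(m, ap.RegionMask([("chrX", 1, 5)]), "exclude")

    def test_exclude_restrict_partition_property(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            m = random_matrix(rng)
            lo = int(rng.integers(1, m.n_sites * 10 + 1))
            hi = int(rng.integers(lo, m.n_sites * 10 + 1))
            mask = ap.RegionMask([("chr1", lo, hi)])
            ex = ap.apply_region_mask(m, mask, "exclude")
            re = ap.apply_region_mask(m, mask, "restrict")
            union = sorted(list(ex.sites["pos"]) + list(re.sites["pos"]))
            assert union == sorted(m.sites["pos"])

    def test_bed_round_trip_converts_coordinates(self, tmp_path):
        mask = ap.RegionMask([("chr1", 101, 200)])
        path = tmp_path / "m.bed"
        mask.to_bed(path)
        assert path.read_text() == "chr1\t100\t200\n"
        assert ap.RegionMask.from_bed(path).intervals == [("chr1", 101, 200)]


def test_filter_report_reconciliation_enforced():
    rep = ap.FilterReport(n_input_sites=10, n_sites_dropped_missingness=2,
                          n_output_sites=7)
    with pytest.raises(ValueError, match="reconcile"):
        rep.check()


def test_site_order_preserved_and_sample_reorder_commutes():
    rng = np.random.default_rng(3)
    m = random_matrix(rng, n_samples=4, n_sites=12)
    gq = rng.integers(0, 100, size=m.calls.shape)
    m = make_matrix(m.calls, gq=gq)
    perm = [2, 0, 3, 1]
    m_perm = ap.GenotypeMatrix([m.samples[i] for i in perm], m.sites,
                               m.calls[perm], m.gq[perm])
    a, _ = ap.filter_genotypes(m, min_gq=50, max_missing=0.5)
    b, _ = ap.filter_genotypes(m_perm, min_gq=50, max_missing=0.5)
    assert list(a.sites["pos"]) == list(b.sites["pos"])
    assert (a.calls[perm] == b.calls).all()
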