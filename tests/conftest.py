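import numpy as np
import pandas as pd
import pytest

import algapop as ap


def make_matrix(calls, gq=None, chrom="chr1", ref="A", alt="G", samples=None):
    """Build a GenotypeMatrix from a (samples x sites) list of class codes."""
    calls = np.asarray(calls, dtype=np.int8)
    n_samples, n_sites = calls.shape
    samples = samples or [f"S{i + 1}" for i in range(n_samples)]
    sites = pd.DataFrame({"chrom": [chrom] * n_sites,
                          "pos": np.arange(1, n_sites + 1) * 10,
                          "ref": [ref] * n_sites, "alt": [alt] * n_sites})
    gq = None if gq is None else np.asarray(gq, dtype=np.int16)
    return ap.GenotypeMatrix(samples, sites, calls, gq)


def random_matrix(rng, n_samples=None, n_sites=None, missing=True):
    n_samples = n_samples or int(rng.integers(3, 7))
    n_sites = n_sites or int(rng.integers(1, 31))
    lo = -1 if missing else 0
    calls = rng.integers(lo, 3, size=(n_samples, n_sites)).astype(np.int8)
    return make_matrix(calls)


@pytest.fixture(scope="session")
def default_truth():
    """One simulated study at the default design (seed 11)."""
    return ap.simulate_truth(ap.SimConfig(seed=11))


@pytest.fixture(scope="session")
def zero_noise_matrix(default_truth, tmp_path_factory):
    """Observed matrix with error_rate = missing_rate = 0 (equals truth)."""
    path = tmp_path_factory.mktemp("sim") / "observed.vcf"
    ap.observe(default_truth, ap.NoiseModel(error_rate=0.0, missing_rate=0.0),
               seed=11, path=path)
    return ap.read_multisample_vcf(path)


@pytest.fixture()
def toy_vcf(tmp_path):
    """Tiny hand-written VCF: 3 biallelic SNVs, 1 multiallelic, 1 indel."""
    text = "\n".join([
        "##fileformat=VCFv4.2",
        "##contig=<ID=chr1,length=1000>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2",
        "chr1\t10\t.\tA\tG\t.\t.\t.\tGT:GQ\t0/0:50\t0/1:45",
        "chr1\t20\t.\tC\tT\t.\t.\t.\tGT:GQ\t1|0:50\t./.:.",
        "chr1\t30\t.\tG\tA\t.\t.\t.\tGT:GQ\t./1:50\t1/1:19",
        "chr1\t40\t.\tT\tA,C\t.\t.\t.\tGT:GQ\t0/0:50\t0/0:50",
        "chr1\t50\t.\tT\tTA\t.\t.\t.\tGT:GQ\t0/0:50\t0/0:50",
    ]) + "\n"
    path = tmp_path / "toy.vcf"
    path.write_text(text)
    return path


@pytest.fixture()
def toy_metadata(tmp_path):
    meta = pd.DataFrame({
        "sample": ["S1", "S2"], "species": ["sp_A", "sp_A"],
        "strain": ["", ""], "subgroup": ["", ""],
        "phenotype": ["normal", "normal"],
        "homozygous_expected": ["true", "true"]})
    path = tmp_path / "meta.tsv"
    meta.to_csv(path, sep="\t", index=False)
    return path
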