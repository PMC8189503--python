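"""Synthetic study-design generator: truth genomes and a noisy observed VCF.

The generator emulates the design of a clonal-seaweed resequencing study:

* several clusters of doubled-haploid samples of a focal species, drawn
  from a Balding–Nichols allele-frequency model (per-cluster frequencies
  Beta-distributed around an ancestral frequency with differentiation
  ``fst``), every sample homozygous diploid at every locus;
* a diverged sister species differing from the reference by independent
  per-site substitutions;
* an interspecific F1 observed as a diploid: its conchocelis genome is
  allotetraploid (both parental chromosome sets), so a diploid-coded
  caller reports it heterozygous at every parental fixed difference —
  except inside the nuclear-rRNA mask, where concerted evolution has
  homogenised the repeat to the second parent's type;
* one aquaculture strain (the first cluster) split into subgroups that
  share exclusive planted mutations, each member carrying additional
  private mutations (within-strain mutation accumulation);
* uniparentally inherited chloroplast and mitochondrial genomes evolved
  under Jukes–Cantor along one seeded Yule genealogy, the mitochondrial
  rate a fixed multiple (default 10) of the chloroplast rate, and the
  hybrid carrying the donor parent's organelles unchanged;
* an observation layer that adds genotyping errors, missingness, and GQ
  scores, and writes a multi-sample VCF v4.2 (FORMAT GT:GQ).

One master seed determines every output; stage-specific streams are
derived with fixed offsets so stages are independently reproducible.
"""

from __future__ import annotations

import json
import random as _pyrandom
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import dendropy
from dendropy.simulate import treesim

from .genotypes import (GenotypeMatrix, HET, HOM_ALT, HOM_REF, MISSING,
                        RegionMask, write_vcf)
from .organelle import SeqAlignment

BASES = np.array(["A", "C", "G", "T"])

# fixed stream offsets off the master seed (determinism contract)
_S_REF, _S_POLY, _S_SISTER, _S_PLANT, _S_ORG, _S_OBS = range(6)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(stream)])


@dataclass
class SimConfig:
    """Study-design parameters for the simulator.

    Defaults are the desk-scale study conditions used throughout the test
    suite: 3 clusters x 7 doubled haploids plus 2 admixed samples, one
    sister-species sample and one allotetraploid F1, a 2 x 50 kb nuclear
    genome, 20 kb organelles with a 10-fold mt:cp rate contrast.
    """

    seed: int = 0
    n_chrom: int = 2
    chrom_length: int = 50_000
    n_clusters: int = 3
    fst: float = 0.2
    n_samples_per_cluster: int = 7
    n_admixed: int = 2
    species_divergence: float = 0.01
    strain_subgroups: int = 2
    shared_mutations_per_subgroup: int = 20
    private_mutations_per_sample: int = 5
    rrna_mask: list = field(default_factory=lambda: [("chr1", 10_001, 12_000)])
    organelle_length: int = 20_000
    cp_rate: float = 0.01
    mt_cp_ratio: float = 10.0
    error_rate: float = 0.002
    missing_rate: float = 0.02
    min_polymorphic_fraction: float = 0.02
    organelle_donor: str | None = None  # None -> the sister-species parent

    # ------------------------------------------------------------- helpers
    @property
    def genome_length(self) -> int:
        return self.n_chrom * self.chrom_length

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chrom)]

    def validate(self) -> None:
        for name in ("fst", "species_divergence"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name}={v} out of [0, 1)")
        for name in ("error_rate", "missing_rate", "min_polymorphic_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} out of [0, 1]")
        if self.mt_cp_ratio <= 0:
            raise ValueError("mt_cp_ratio must be positive")
        for c in (self.n_chrom, self.chrom_length, self.n_clusters,
                  self.n_samples_per_cluster, self.organelle_length):
            if c <= 0:
                raise ValueError("counts and lengths must be positive")
        if self.strain_subgroups > self.n_samples_per_cluster:
            raise ValueError("more strain subgroups than strain members")
        known = set(self.chrom_names)
        for chrom, start, end in self.rrna_mask:
            if chrom not in known:
                raise ValueError(f"rrna_mask chromosome {chrom!r} not in genome")
            if not (1 <= start <= end <= self.chrom_length):
                raise ValueError(f"rrna_mask interval {chrom}:{start}-{end} outside genome")
        n_poly = round(self.min_polymorphic_fraction * self.genome_length)
        n_planted = (self.strain_subgroups * self.shared_mutations_per_subgroup
                     + self.n_samples_per_cluster * self.private_mutations_per_sample)
        if n_planted > self.genome_length - n_poly:
            raise ValueError(
                f"requested {n_planted} planted mutations exceed the "
                f"{self.genome_length - n_poly} available monomorphic sites")

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["rrna_mask"] = [list(t) for t in self.rrna_mask]
        Path(path).write_text(json.dumps(d, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimConfig":
        d = json.loads(Path(path).read_text())
        d["rrna_mask"] = [tuple(t) for t in d.get("rrna_mask", [])]
        return cls(**d)


@dataclass
class NoiseModel:
    """Per-call genotyping-error / missingness model with GQ emission.

    Erroneous calls are replaced by a uniformly chosen *different*
    genotype class; GQ is drawn uniformly from ``gq_correct`` for faithful
    calls and ``gq_error`` for erroneous ones (inclusive integer ranges).
    """

    error_rate: float = 0.002
    missing_rate: float = 0.02
    gq_correct: tuple[int, int] = (30, 99)
    gq_error: tuple[int, int] = (2, 40)

    def validate(self) -> None:
        if not 0 <= self.error_rate <= 1 or not 0 <= self.missing_rate <= 1:
            raise ValueError("rates must be in [0, 1]")
        for lo, hi in (self.gq_correct, self.gq_error):
            if not (0 <= lo <= hi <= 99):
                raise ValueError("GQ ranges must satisfy 0 <= lo <= hi <= 99")

    @classmethod
    def from_config(cls, config: SimConfig) -> "NoiseModel":
        return cls(error_rate=config.error_rate, missing_rate=config.missing_rate)


@dataclass
class OrganelleTruth:
    cp: SeqAlignment
    mt: SeqAlignment
    tree_newick: str
    donor: str


@dataclass
class TruthDataset:
    """Simulator output: reference, haplotypes, metadata, planted loci,
    organelle truth, and (after :func:`observe`) the observed VCF path."""

    config: SimConfig
    ref_codes: np.ndarray                  # (L,) uint8 base codes
    alt_codes: np.ndarray                  # (L,) uint8, != ref at every site
    haplotypes: dict[str, np.ndarray]      # sample -> (L,) uint8 ALT indicator
    sample_table: pd.DataFrame
    hybrid_composition: tuple[str, str]    # (parent_a, parent_b) source haplotypes
    hybrid_name: str
    planted_group_loci: pd.DataFrame       # chrom, pos, subgroup
    organelle_truth: OrganelleTruth
    observed_vcf_path: Path | None = None

    # ------------------------------------------------------------ geometry
    def _global_to_site(self, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        chrom = np.array(self.config.chrom_names)[idx // self.config.chrom_length]
        pos = idx % self.config.chrom_length + 1
        return chrom, pos

    def rrna_mask(self) -> RegionMask:
        return RegionMask([tuple(t) for t in self.config.rrna_mask])

    def _mask_global(self) -> np.ndarray:
        inside = np.zeros(self.config.genome_length, dtype=bool)
        for chrom, start, end in self.config.rrna_mask:
            c = self.config.chrom_names.index(chrom)
            off = c * self.config.chrom_length
            inside[off + start - 1: off + end] = True
        return inside

    # ---------------------------------------------------------- genotypes
    @property
    def samples(self) -> list[str]:
        return list(self.sample_table["sample"])

    def truth_genotype_array(self) -> np.ndarray:
        """(n_samples, L) truth diploid genotype classes (ALT dose)."""
        names = self.samples
        G = np.zeros((len(names), self.config.genome_length), dtype=np.int8)
        pa, pb = self.hybrid_composition
        for i, s in enumerate(names):
            if s == self.hybrid_name:
                g = self.haplotypes[pa].astype(np.int8) + self.haplotypes[pb]
                inside = self._mask_global()
                g[inside] = 2 * self.haplotypes[pb][inside]
                G[i] = g
            else:
                G[i] = 2 * self.haplotypes[s]
        return G

    def variant_site_index(self) -> np.ndarray:
        """Global indices of truth-polymorphic sites (any non-reference allele)."""
        return np.flatnonzero(self.truth_genotype_array().any(axis=0))

    def truth_matrix(self) -> GenotypeMatrix:
        """Noise-free genotype matrix over the truth-polymorphic sites."""
        idx = self.variant_site_index()
        chrom, pos = self._global_to_site(idx)
        sites = pd.DataFrame({
            "chrom": chrom, "pos": pos,
            "ref": BASES[self.ref_codes[idx]], "alt": BASES[self.alt_codes[idx]]})
        return GenotypeMatrix(self.samples, sites,
                              self.truth_genotype_array()[:, idx],
                              provenance={"source": "simulated truth"})

    # -------------------------------------------------------------- output
    def write_metadata(self, path: str | Path) -> Path:
        path = Path(path)
        self.sample_table.to_csv(path, sep="\t", index=False)
        return path

    def write_reference_fasta(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            for c, name in enumerate(self.config.chrom_names):
                seg = self.ref_codes[c * self.config.chrom_length:
                                     (c + 1) * self.config.chrom_length]
                fh.write(f">{name}\n")
                fh.write("".join(BASES[seg]) + "\n")
        return path


# ------------------------------------------------------------------ truth

def _simulate_organelles(names: list[str], length: int, cp_rate: float,
                         mt_cp_ratio: float, seed: int
                         ) -> tuple[SeqAlignment, SeqAlignment, str]:
    """Evolve cp and mt alignments under Jukes–Cantor along one seeded
    Yule genealogy; branch lengths scaled so the root-to-tip path equals
    ``cp_rate`` expected substitutions/site (mt: ``cp_rate*mt_cp_ratio``)."""
    n = len(names)
    tree = treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n,
        rng=_pyrandom.Random(int(seed) % 2**31))
    tree.seed_node.edge.length = 0.0
    leaves = list(tree.leaf_node_iter())
    for leaf, name in zip(leaves, names):
        leaf.taxon.label = name
    height = leaves[0].distance_from_root()
    scale = cp_rate / height if height > 0 else 0.0

    def evolve(rate_mult: float, rng: np.random.Generator) -> dict[str, np.ndarray]:
        seqs: dict[str, np.ndarray] = {}
        root_seq = rng.integers(0, 4, length, dtype=np.uint8)
        stack = [(tree.seed_node, root_seq)]
        while stack:
            node, seq = stack.pop()
            for child in node.child_nodes():
                b = (child.edge.length or 0.0) * scale * rate_mult
                p = 0.75 * -np.expm1(-4.0 * b / 3.0)
                s = seq.copy()
                hit = rng.random(length) < p
                k = int(hit.sum())
                if k:
                    s[hit] = (s[hit] + rng.integers(1, 4, k, dtype=np.uint8)) % 4
                stack.append((child, s))
            if node.is_leaf():
                seqs[node.taxon.label] = seq
        return seqs

    rng = _rng(seed, _S_ORG)
    cp_seqs = evolve(1.0, rng)
    mt_seqs = evolve(mt_cp_ratio, rng)
    cp = SeqAlignment(names, ["".join(BASES[cp_seqs[s]]) for s in names])
    mt = SeqAlignment(names, ["".join(BASES[mt_seqs[s]]) for s in names])
    return cp, mt, tree.as_string(schema="newick")


def simulate_organelle_alignments(n_samples: int, length: int, cp_rate: float,
                                  mt_cp_ratio: float, seed: int
                                  ) -> tuple[SeqAlignment, SeqAlignment, str]:
    """Standalone organelle simulation for generic sample sets (S01..SNN)."""
    names = [f"S{i + 1:02d}" for i in range(n_samples)]
    return _simulate_organelles(names, length, cp_rate, mt_cp_ratio, seed)


def simulate_truth(config: SimConfig) -> TruthDataset:
    """Generate the full truth dataset for one study-design configuration."""
    config.validate()
    L = config.genome_length
    seed = config.seed

    rng_ref = _rng(seed, _S_REF)
    ref = rng_ref.integers(0, 4, L, dtype=np.uint8)
    alt = (ref + rng_ref.integers(1, 4, L, dtype=np.uint8)) % 4

    # sample naming and metadata -----------------------------------------
    names: list[str] = []
    cluster_of: dict[str, int] = {}
    for c in range(config.n_clusters):
        for i in range(config.n_samples_per_cluster):
            s = f"A{c + 1}_{i + 1:02d}"
            names.append(s)
            cluster_of[s] = c
    admixed = [f"ADM_{i + 1:02d}" for i in range(config.n_admixed)]
    names += admixed
    sister = "B_1"
    hybrid = "HYB_1"
    strain_members = [s for s in names if cluster_of.get(s) == 0]
    subgroup_of: dict[str, str] = {}
    chunks = np.array_split(np.array(strain_members), config.strain_subgroups)
    for k, chunk in enumerate(chunks):
        for s in chunk:
            subgroup_of[str(s)] = f"sg{k + 1}"

    # within-species polymorphism (Balding–Nichols per cluster) ----------
    rng = _rng(seed, _S_POLY)
    n_poly = round(config.min_polymorphic_fraction * L)
    poly_idx = np.sort(rng.choice(L, size=n_poly, replace=False))
    p_anc = rng.uniform(0.05, 0.95, n_poly)
    F = config.fst
    if F > 0:
        a = p_anc * (1 - F) / F
        b = (1 - p_anc) * (1 - F) / F
        cluster_freq = [rng.beta(a, b) for _ in range(config.n_clusters)]
    else:
        cluster_freq = [p_anc.copy() for _ in range(config.n_clusters)]

    haplotypes: dict[str, np.ndarray] = {}
    for s in names:
        h = np.zeros(L, dtype=np.uint8)
        if s in admixed:
            freq = 0.5 * (cluster_freq[0] + cluster_freq[min(1, config.n_clusters - 1)])
        else:
            freq = cluster_freq[cluster_of[s]]
        h[poly_idx] = rng.random(n_poly) < freq
        haplotypes[s] = h

    # sister species: independent per-site substitutions ----------------
    h_sister = (_rng(seed, _S_SISTER).random(L) < config.species_divergence
                ).astype(np.uint8)
    haplotypes[sister] = h_sister

    # planted strain mutations (subgroup-shared + private) ---------------
    rng_p = _rng(seed, _S_PLANT)
    mono = np.setdiff1d(np.arange(L), poly_idx, assume_unique=False)
    n_shared = config.strain_subgroups * config.shared_mutations_per_subgroup
    n_private = len(strain_members) * config.private_mutations_per_sample
    planted = rng_p.choice(mono, size=n_shared + n_private, replace=False)
    shared_sites = planted[:n_shared].reshape(config.strain_subgroups, -1)
    private_sites = planted[n_shared:].reshape(len(strain_members), -1)
    planted_rows = []
    for k in range(config.strain_subgroups):
        members = [str(s) for s in chunks[k]]
        for s in members:
            haplotypes[s][shared_sites[k]] = 1
        for g in np.sort(shared_sites[k]):
            planted_rows.append((int(g), f"sg{k + 1}"))
    for i, s in enumerate(strain_members):
        haplotypes[s][private_sites[i]] = 1

    # organelles ---------------------------------------------------------
    organelle_names = names + [sister]
    cp, mt, newick = _simulate_organelles(
        organelle_names, config.organelle_length, config.cp_rate,
        config.mt_cp_ratio, seed)
    donor = config.organelle_donor or sister
    if donor not in organelle_names:
        raise ValueError(f"organelle donor {donor!r} is not a simulated sample")
    cp = SeqAlignment(cp.samples + [hybrid], cp.sequences + [cp.sequence(donor)])
    mt = SeqAlignment(mt.samples + [hybrid], mt.sequences + [mt.sequence(donor)])

    # metadata table ------------------------------------------------------
    all_names = names + [sister, hybrid]
    rows = []
    for s in all_names:
        if s == sister:
            sp, strain, sg, ph, hom = "sp_B", "", "", "normal", True
        elif s == hybrid:
            sp, strain, sg, ph, hom = "sp_AxB", "", "", "normal", False
        else:
            sp = "sp_A"
            strain = "strain1" if s in strain_members else ""
            sg = subgroup_of.get(s, "")
            ph = "abnormal" if sg == "sg1" else "normal"
            hom = True
        rows.append({"sample": s, "species": sp, "strain": strain,
                     "subgroup": sg, "phenotype": ph, "homozygous_expected": hom})
    table = pd.DataFrame(rows)

    cfg_chroms = np.array(config.chrom_names)
    g_idx = np.array([g for g, _ in planted_rows], dtype=int)
    planted_df = pd.DataFrame({
        "chrom": cfg_chroms[g_idx // config.chrom_length] if len(g_idx) else [],
        "pos": g_idx % config.chrom_length + 1 if len(g_idx) else [],
        "subgroup": [sg for _, sg in planted_rows]})

    parent_a = strain_members[0]
    return TruthDataset(
        config=config, ref_codes=ref, alt_codes=alt, haplotypes=haplotypes,
        sample_table=table, hybrid_composition=(parent_a, sister),
        hybrid_name=hybrid, planted_group_loci=planted_df,
        organelle_truth=OrganelleTruth(cp=cp, mt=mt, tree_newick=newick,
                                       donor=donor))


# ------------------------------------------------------------ observation

def observe(truth: TruthDataset, noise: NoiseModel, seed: int,
            path: str | Path, force: bool = False) -> Path:
    """Apply the noise model to the truth genotypes and write a VCF.

    With probability ``error_rate`` a call is replaced by a uniformly
    chosen different genotype class; with probability ``missing_rate`` it
    becomes missing.  GQ is drawn from ``gq_correct`` for faithful calls
    and ``gq_error`` for erroneous ones.
    """
    noise.validate()
    path = Path(path)
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists; pass force=True to overwrite")
    m = truth.truth_matrix()
    rng = _rng(seed, _S_OBS)
    calls = m.calls.copy()
    shape = calls.shape
    err = rng.random(shape) < noise.error_rate
    shift = rng.integers(1, 3, shape, dtype=np.int8)  # uniform over the 2 wrong classes
    calls[err] = (calls[err] + shift[err]) % 3
    lo_c, hi_c = noise.gq_correct
    lo_e, hi_e = noise.gq_error
    gq = rng.integers(lo_c, hi_c + 1, shape, dtype=np.int16)
    gq_err = rng.integers(lo_e, hi_e + 1, shape, dtype=np.int16)
    gq[err] = gq_err[err]
    miss = rng.random(shape) < noise.missing_rate
    calls[miss] = MISSING
    observed = GenotypeMatrix(m.samples, m.sites, calls, gq,
                              provenance={"source": "simulated observation"})
    contigs = {c: truth.config.chrom_length for c in truth.config.chrom_names}
    write_vcf(observed, path, contig_lengths=contigs, force=force)
    truth.observed_vcf_path = path
    return path
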