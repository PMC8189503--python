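"""Variable-site alignments, parsimony-informative accounting, and the
chloroplast-vs-mitochondrial substitution-rate comparison.

Genotype matrices are exported as equal-length per-sample sequences over
{A,C,G,T,N,-} (HET and MISSING become N) for downstream phylogenetics.
The organelle rate comparison is a ratio of mean pairwise distances over
the sample pairs shared by the two alignments — a reproducible surrogate
for comparing tree branch lengths between uniparentally inherited genomes.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genotypes import (GenotypeMatrix, HET, HOM_ALT, HOM_REF, MISSING,
                        RegionMask, apply_region_mask)

_CALLED = frozenset("ACGT")


@dataclass
class SeqAlignment:
    """Equal-length per-sample nucleotide sequences.

    ``source_coords`` carries the originating (chrom, pos) of each column
    when the alignment was derived from a genotype matrix.
    """

    samples: list[str]
    sequences: list[str]
    source_coords: list[tuple[str, int]] | None = None

    def __post_init__(self) -> None:
        if len(self.samples) != len(self.sequences):
            raise ValueError("samples and sequences differ in length")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample names in alignment")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError(f"unequal sequence lengths: {sorted(lengths)}")
        if self.source_coords is not None and self.sequences and \
                len(self.source_coords) != len(self.sequences[0]):
            raise ValueError("source_coords length does not match alignment width")

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def char_matrix(self) -> np.ndarray:
        return np.array([list(s) for s in self.sequences], dtype="U1") \
            if self.sequences else np.zeros((0, 0), dtype="U1")

    def sequence(self, sample: str) -> str:
        try:
            return self.sequences[self.samples.index(sample)]
        except ValueError:
            raise KeyError(f"unknown sample {sample!r}") from None

    @classmethod
    def from_fasta(cls, path: str | Path) -> "SeqAlignment":
        recs = list(SeqIO.parse(str(path), "fasta"))
        return cls([r.id for r in recs], [str(r.seq).upper() for r in recs])

    def to_fasta(self, path: str | Path) -> Path:
        path = Path(path)
        SeqIO.write(
            (SeqRecord(Seq(s), id=n, description="") for n, s in
             zip(self.samples, self.sequences)),
            str(path), "fasta")
        return path


@dataclass
class RateRatioEstimate:
    """Mitochondrial : chloroplast substitution-rate ratio from mean
    pairwise distances over shared sample pairs."""

    ratio: float
    cp_mean_distance: float
    mt_mean_distance: float
    n_pairs: int
    correction: str
    pair_table: pd.DataFrame = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {"ratio": self.ratio, "cp_mean_distance": self.cp_mean_distance,
                "mt_mean_distance": self.mt_mean_distance,
                "n_pairs": self.n_pairs, "correction": self.correction}


def variable_site_alignment(m: GenotypeMatrix,
                            mask: RegionMask | None = None) -> SeqAlignment:
    """Export the variable sites of a genotype matrix as an alignment.

    A site is variable when its called genotypes span >= 2 classes.  Per
    sample: HOM_REF emits the reference base, HOM_ALT the alternate base,
    HET and MISSING emit N.  Column order follows site order.
    """
    if mask is not None:
        m = apply_region_mask(m, mask, mode="exclude")
    var = m.variable_site_mask()
    if not var.any():
        warnings.warn("no variable sites: emitting an empty alignment")
    idx = np.flatnonzero(var)
    ref = m.sites["ref"].to_numpy()[idx]
    alt = m.sites["alt"].to_numpy()[idx]
    coords = list(zip(m.sites["chrom"].to_numpy()[idx],
                      (int(p) for p in m.sites["pos"].to_numpy()[idx])))
    seqs = []
    for i in range(m.n_samples):
        row = m.calls[i, idx]
        chars = np.where(row == HOM_REF, ref, np.where(row == HOM_ALT, alt, "N"))
        seqs.append("".join(chars))
    return SeqAlignment(list(m.samples), seqs, coords)


def parsimony_informative_count(a: SeqAlignment) -> int:
    """Number of columns with >= 2 distinct called states each present in
    >= 2 sequences (N and gaps are not states)."""
    if not a.sequences:
        raise ValueError("empty alignment")
    mat = a.char_matrix()
    count = 0
    for j in range(mat.shape[1]):
        states, n = np.unique(mat[:, j], return_counts=True)
        called = [int(c) for s, c in zip(states, n) if s in _CALLED]
        if sum(c >= 2 for c in called) >= 2:
            count += 1
    return count


_CALLED_BYTES = np.frombuffer(b"ACGT", dtype="S1")


def _pairwise_distance(s1: str, s2: str, correction: str) -> tuple[float, int]:
    a = np.frombuffer(s1.encode(), dtype="S1")
    b = np.frombuffer(s2.encode(), dtype="S1")
    called = np.isin(a, _CALLED_BYTES) & np.isin(b, _CALLED_BYTES)
    n = int(called.sum())
    if n == 0:
        return np.nan, 0
    p = float((a[called] != b[called]).mean())
    if correction == "JC69":
        if p >= 0.75:
            return np.inf, n
        return -0.75 * np.log1p(-4.0 * p / 3.0), n
    return p, n


def pairwise_rate_ratio(cp: SeqAlignment, mt: SeqAlignment,
                        correction: str = "p-distance") -> RateRatioEstimate:
    """Estimate the mt:cp substitution-rate ratio from mean pairwise
    distances computed over the sample pairs shared by both alignments.

    ``correction`` is ``"p-distance"`` (raw mismatch fraction over
    co-called columns) or ``"JC69"`` (Jukes–Cantor multiple-hit
    correction, d = -3/4 ln(1 - 4p/3)).
    """
    if correction not in {"p-distance", "JC69"}:
        raise ValueError(f"unknown correction {correction!r}")
    shared = [s for s in cp.samples if s in set(mt.samples)]
    if len(shared) < 2:
        raise ValueError(f"only {len(shared)} shared sample(s); need >= 2")
    rows = []
    for s1, s2 in itertools.combinations(shared, 2):
        d_cp, n_cp = _pairwise_distance(cp.sequence(s1), cp.sequence(s2), correction)
        d_mt, n_mt = _pairwise_distance(mt.sequence(s1), mt.sequence(s2), correction)
        rows.append({"sample1": s1, "sample2": s2, "cp_distance": d_cp,
                     "mt_distance": d_mt, "cp_sites": n_cp, "mt_sites": n_mt})
    table = pd.DataFrame(rows)
    cp_mean = float(table["cp_distance"].mean())
    mt_mean = float(table["mt_distance"].mean())
    if cp_mean == 0.0 and mt_mean > 0.0:
        warnings.warn("chloroplast mean distance is zero: rate ratio is infinite")
        ratio = np.inf
    elif cp_mean == 0.0:
        ratio = np.nan
    else:
        ratio = mt_mean / cp_mean
    return RateRatioEstimate(ratio=ratio, cp_mean_distance=cp_mean,
                             mt_mean_distance=mt_mean, n_pairs=len(rows),
                             correction=correction, pair_table=table)
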