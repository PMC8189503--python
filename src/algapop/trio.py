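"""Allotetraploidy test from trio genotypes at parental fixed differences.

An interspecific F1 whose conchocelis genome carries both full parental
chromosome sets (AABB) is genotyped by a diploid-coded caller as
heterozygous wherever its two parents are fixed for different alleles.
Conditioning on loci where parent A is homozygous reference and parent B
is homozygous alternate, the hybrid's genotype classes are tabulated into
two-reference / heterozygous / two-alternate / unclassified (missing); a
heterozygous fraction near 1 over the classified loci is the
allotetraploid signature.  Conditioning on parental fixed differences
also makes the test robust to mismapped contaminant reads, which rarely
satisfy the two-parent condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotypes import (GenotypeMatrix, HET, HOM_ALT, HOM_REF, MISSING,
                        RegionMask, apply_region_mask)


@dataclass
class TrioClassCounts:
    """Contingency of the hybrid's genotype classes at informative loci."""

    n_informative: int
    n_two_ref: int
    n_het: int
    n_two_alt: int
    n_unclassified: int
    loci: dict[str, list[tuple[str, int]]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        total = self.n_two_ref + self.n_het + self.n_two_alt + self.n_unclassified
        if total != self.n_informative:
            raise ValueError(
                f"class counts sum to {total}, expected n_informative={self.n_informative}")
        if min(self.n_two_ref, self.n_het, self.n_two_alt, self.n_unclassified) < 0:
            raise ValueError("negative class count")

    @property
    def n_classified(self) -> int:
        return self.n_two_ref + self.n_het + self.n_two_alt

    def to_dict(self) -> dict:
        return {"n_informative": self.n_informative, "n_two_ref": self.n_two_ref,
                "n_het": self.n_het, "n_two_alt": self.n_two_alt,
                "n_unclassified": self.n_unclassified}


@dataclass
class PloidyVerdict:
    """Threshold verdict on the heterozygous fraction of classified loci."""

    het_fraction: float | None
    threshold: float
    is_allotetraploid: bool | None
    n_classified: int
    status: str  # "ok" or "insufficient data"

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def class_percentages(c: TrioClassCounts) -> dict:
    """Percentages of the three classified classes, unrounded and rounded
    to the nearest ten percentage points."""
    n = c.n_classified
    if n == 0:
        raise ValueError("no classified loci")
    pct = {"two_ref": 100.0 * c.n_two_ref / n,
           "het": 100.0 * c.n_het / n,
           "two_alt": 100.0 * c.n_two_alt / n}
    rounded = {k: int(round(v / 10.0)) * 10 for k, v in pct.items()}
    return {"percent": pct, "percent_rounded_to_ten": rounded, "n_classified": n}


def informative_trio_sites(m: GenotypeMatrix, parent_a: str, parent_b: str,
                           mirrored: bool = False) -> np.ndarray:
    """Indices of loci where parent A is HOM_REF and parent B is HOM_ALT
    (both called).  ``mirrored=True`` tests the complementary orientation
    (A HOM_ALT, B HOM_REF)."""
    ia, ib = m.sample_index(parent_a), m.sample_index(parent_b)
    a, b = m.calls[ia], m.calls[ib]
    if mirrored:
        cond = (a == HOM_ALT) & (b == HOM_REF)
    else:
        cond = (a == HOM_REF) & (b == HOM_ALT)
    return np.flatnonzero(cond)


def classify_trio(m: GenotypeMatrix, parent_a: str, parent_b: str,
                  hybrid: str, mask: RegionMask | None = None,
                  mirrored: bool = False) -> TrioClassCounts:
    """Tabulate the hybrid's genotype classes at parental fixed-difference loci."""
    if hybrid in (parent_a, parent_b):
        raise ValueError(f"hybrid {hybrid!r} must differ from both parents")
    if mask is not None:
        m = apply_region_mask(m, mask, mode="exclude")
    idx = informative_trio_sites(m, parent_a, parent_b, mirrored=mirrored)
    h = m.calls[m.sample_index(hybrid), idx]
    chrom = m.sites["chrom"].to_numpy()[idx]
    pos = m.sites["pos"].to_numpy()[idx]
    loci = {}
    for label, code in (("two_ref", HOM_REF), ("het", HET),
                        ("two_alt", HOM_ALT), ("unclassified", MISSING)):
        sel = h == code
        loci[label] = [(str(c), int(p)) for c, p in zip(chrom[sel], pos[sel])]
    return TrioClassCounts(
        n_informative=len(idx),
        n_two_ref=int((h == HOM_REF).sum()),
        n_het=int((h == HET).sum()),
        n_two_alt=int((h == HOM_ALT).sum()),
        n_unclassified=int((h == MISSING).sum()),
        loci=loci)


def allotetraploid_verdict(c: TrioClassCounts, threshold: float = 0.8,
                           min_classified: int = 100) -> PloidyVerdict:
    """Verdict on allotetraploidy: heterozygous fraction of classified
    loci (unclassified excluded) compared against ``threshold`` (>=).

    With fewer than ``min_classified`` classified loci the verdict is
    "insufficient data" rather than a boolean guess.
    """
    n = c.n_classified
    if n < min_classified:
        return PloidyVerdict(het_fraction=(c.n_het / n if n else None),
                             threshold=threshold, is_allotetraploid=None,
                             n_classified=n, status="insufficient data")
    het_fraction = c.n_het / n
    return PloidyVerdict(het_fraction=het_fraction, threshold=threshold,
                         is_allotetraploid=bool(het_fraction >= threshold),
                         n_classified=n, status="ok")
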