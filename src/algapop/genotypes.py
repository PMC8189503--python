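"""Multi-sample genotype matrices and doubled-haploid-aware filtering.

The central in-memory object is :class:`GenotypeMatrix`: samples x biallelic
SNV sites with a per-call genotype class (HOM_REF / HET / HOM_ALT / MISSING)
and an optional conditional genotype quality (GQ) per call.  Matrices are
read from merged multi-sample VCFs (as produced by joint-calling pipelines
such as DeepVariant + GLnexus) and passed through three filters that mirror
standard practice for clonal / doubled-haploid study designs:

1. per-call GQ masking (default GQ < 20 -> MISSING),
2. site-level missingness (default: drop sites with > 10% missing calls),
3. removal of sites heterozygous in any sample expected to be a homozygous
   diploid (a doubled haploid derived from a single haploid cell cannot be
   truly heterozygous; residual HET calls flag paralogy, collapsed repeats
   or contaminating reads and are removed genome-wide).

All genomic positions are 1-based inclusive.  BED inputs are 0-based
half-open and converted on read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

# genotype class codes; MISSING sorts first so dose == code for called genotypes
HOM_REF: int = 0
HET: int = 1
HOM_ALT: int = 2
MISSING: int = -1

GQ_UNKNOWN: int = -1  # sentinel in the gq matrix when a call carries no GQ

_BASES = frozenset("ACGT")

METADATA_COLUMNS = ("sample", "species", "strain", "subgroup", "phenotype",
                    "homozygous_expected")


@dataclass
class FilterReport:
    """Site/call accounting for one filtering step.

    ``n_output_sites`` must always reconcile exactly with ``n_input_sites``
    minus the site-level drop counts (``check()`` asserts this), matching the
    habit of reporting variant-site counts after every pipeline step.
    """

    n_input_sites: int = 0
    n_calls_masked_by_gq: int = 0
    n_sites_dropped_missingness: int = 0
    n_sites_dropped_het: int = 0
    n_sites_dropped_multiallelic: int = 0
    n_sites_dropped_non_snv: int = 0
    n_output_sites: int = 0
    thresholds: dict = field(default_factory=dict)

    def check(self) -> None:
        dropped = (self.n_sites_dropped_missingness + self.n_sites_dropped_het
                   + self.n_sites_dropped_multiallelic + self.n_sites_dropped_non_snv)
        if self.n_output_sites != self.n_input_sites - dropped:
            raise ValueError(
                f"filter accounting does not reconcile: {self.n_input_sites} in, "
                f"{dropped} dropped, {self.n_output_sites} out")
        for name, value in self.__dict__.items():
            if name != "thresholds" and value < 0:
                raise ValueError(f"negative count {name}={value}")

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items()}
        return d


@dataclass
class RegionMask:
    """Genomic intervals, stored 1-based inclusive."""

    intervals: list[tuple[str, int, int]]

    def __post_init__(self) -> None:
        for chrom, start, end in self.intervals:
            if start > end:
                raise ValueError(f"empty interval {chrom}:{start}-{end}")

    @classmethod
    def from_bed(cls, path: str | Path) -> "RegionMask":
        """Read a BED file (0-based half-open) and convert to 1-based inclusive."""
        ivals = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            ivals.append((chrom, int(start) + 1, int(end)))
        return cls(ivals)

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom, start, end in self.intervals:
                fh.write(f"{chrom}\t{start - 1}\t{end}\n")

    def contains(self, chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
        """Vectorised membership of (chrom, pos) pairs in any interval."""
        chrom = np.asarray(chrom)
        pos = np.asarray(pos)
        inside = np.zeros(pos.shape, dtype=bool)
        for c, start, end in self.intervals:
            inside |= (chrom == c) & (pos >= start) & (pos <= end)
        return inside

    @property
    def chroms(self) -> set[str]:
        return {c for c, _, _ in self.intervals}


class GenotypeMatrix:
    """Samples x biallelic-SNV-sites genotype-class matrix with optional GQ.

    Parameters
    ----------
    samples
        Ordered, unique sample names.
    sites
        DataFrame with columns ``chrom, pos, ref, alt`` (pos 1-based),
        strictly sorted by (chromosome appearance order, position).
    calls
        int8 array of shape (n_samples, n_sites) holding genotype class
        codes; the code of a called genotype equals its ALT-allele dose.
    gq
        Optional int16 array of the same shape; ``GQ_UNKNOWN`` where a call
        carries no GQ.
    provenance
        Free-form source-path / applied-filter log.
    """

    def __init__(self, samples: Sequence[str], sites: pd.DataFrame,
                 calls: np.ndarray, gq: np.ndarray | None = None,
                 provenance: dict | None = None):
        self.samples = list(samples)
        self.sites = sites.reset_index(drop=True)
        self.calls = np.asarray(calls, dtype=np.int8)
        self.gq = None if gq is None else np.asarray(gq, dtype=np.int16)
        self.provenance = provenance or {}
        self._validate()

    def _validate(self) -> None:
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample names")
        if self.calls.shape != (len(self.samples), len(self.sites)):
            raise ValueError("calls shape does not match samples x sites")
        if self.gq is not None and self.gq.shape != self.calls.shape:
            raise ValueError("gq shape does not match calls")
        if not set(np.unique(self.calls)) <= {HOM_REF, HET, HOM_ALT, MISSING}:
            raise ValueError("invalid genotype class code in calls")
        # strict (chrom-block, pos) sorting; chromosome blocks must be contiguous
        chrom = self.sites["chrom"].to_numpy()
        pos = self.sites["pos"].to_numpy()
        seen: dict[str, int] = {}
        for c in chrom:
            if c not in seen:
                seen[c] = len(seen)
        order = np.array([seen[c] for c in chrom])
        if np.any(np.diff(order) < 0):
            raise ValueError("chromosome blocks are interleaved")
        same = np.diff(order) == 0
        if np.any(np.diff(pos)[same] <= 0):
            raise ValueError("positions not strictly increasing within chromosome")

    # ------------------------------------------------------------------ views
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def sample_index(self, name: str) -> int:
        try:
            return self.samples.index(name)
        except ValueError:
            raise KeyError(f"unknown sample {name!r}") from None

    def dose(self) -> np.ndarray:
        """ALT-allele dosage per call as float, NaN where missing."""
        d = self.calls.astype(float)
        d[self.calls == MISSING] = np.nan
        return d

    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to the given site indices (order preserved)."""
        index = np.asarray(index)
        return GenotypeMatrix(
            self.samples, self.sites.iloc[index],
            self.calls[:, index],
            None if self.gq is None else self.gq[:, index],
            dict(self.provenance))

    def variable_site_mask(self) -> np.ndarray:
        """Boolean mask of sites with >= 2 genotype classes among called genotypes."""
        out = np.zeros(self.n_sites, dtype=bool)
        for j in range(self.n_sites):
            classes = set(self.calls[:, j][self.calls[:, j] != MISSING])
            out[j] = len(classes) >= 2
        return out

    def __repr__(self) -> str:  # pragma: no cover
        return f"<GenotypeMatrix {self.n_samples} samples x {self.n_sites} sites>"


# --------------------------------------------------------------------- I/O

def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Read the sample-metadata TSV (sample, species, strain, subgroup,
    phenotype, homozygous_expected)."""
    meta = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(METADATA_COLUMNS) - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    if meta["sample"].duplicated().any():
        dup = meta.loc[meta["sample"].duplicated(), "sample"].iloc[0]
        raise ValueError(f"duplicate sample in metadata: {dup!r}")
    meta["homozygous_expected"] = meta["homozygous_expected"].map(
        lambda s: s.strip().lower() in {"true", "1", "yes", "+"})
    return meta


def read_multisample_vcf(path: str | Path,
                         metadata: pd.DataFrame | None = None) -> GenotypeMatrix:
    """Read a merged multi-sample VCF into a :class:`GenotypeMatrix`.

    Only biallelic SNV records are retained; multiallelic and non-SNV
    records are dropped and counted in ``provenance``.  Genotype strings
    map as 0/0 -> HOM_REF, 0/1 and 1/0 -> HET, 1/1 -> HOM_ALT, ./. ->
    MISSING; phased separators are accepted and half-calls (./1) are
    treated as MISSING.
    """
    path = Path(path)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if metadata is not None:
        known = set(metadata["sample"])
        for s in samples:
            if s not in known:
                raise ValueError(f"sample {s!r} in VCF is absent from the metadata table")

    chroms: list[str] = []
    pos: list[int] = []
    ref: list[str] = []
    alt: list[str] = []
    call_rows: list[np.ndarray] = []
    gq_rows: list[np.ndarray] = []
    any_gq = False
    n_multi = 0
    n_non_snv = 0
    n_records = 0
    for rec in vcf:
        n_records += 1
        try:
            alts = rec.ALT
            if len(alts) != 1:
                n_multi += 1
                continue
            if len(rec.REF) != 1 or len(alts[0]) != 1 or \
                    rec.REF not in _BASES or alts[0] not in _BASES:
                n_non_snv += 1
                continue
            g = np.array(rec.genotypes, dtype=np.int16)  # (n, >=3): a1, a2, phased
            a1, a2 = g[:, 0], g[:, 1]
            row = np.where((a1 < 0) | (a2 < 0), MISSING, a1 + a2).astype(np.int8)
            gq_arr = rec.format("GQ")
            if gq_arr is None:
                gq_row = np.full(len(samples), GQ_UNKNOWN, dtype=np.int16)
            else:
                any_gq = True
                gq_row = gq_arr.reshape(-1).astype(np.int64)
                gq_row = np.where((gq_row < 0) | (gq_row > 10_000),
                                  GQ_UNKNOWN, gq_row).astype(np.int16)
        except Exception as exc:  # pragma: no cover - malformed inputs
            raise ValueError(
                f"malformed VCF record in {path} near {rec.CHROM}:{rec.POS}: {exc}"
            ) from exc
        chroms.append(rec.CHROM)
        pos.append(rec.POS)
        ref.append(rec.REF)
        alt.append(alts[0])
        call_rows.append(row)
        gq_rows.append(gq_row)

    sites = pd.DataFrame({"chrom": chroms, "pos": pos, "ref": ref, "alt": alt})
    calls = (np.array(call_rows, dtype=np.int8).T if call_rows
             else np.zeros((len(samples), 0), dtype=np.int8))
    gq = (np.array(gq_rows, dtype=np.int16).T if (gq_rows and any_gq) else None)
    prov = {"source": str(path), "n_records": n_records,
            "n_sites_dropped_multiallelic": n_multi,
            "n_sites_dropped_non_snv": n_non_snv, "filters": []}
    return GenotypeMatrix(samples, sites, calls, gq, prov)


def write_vcf(m: GenotypeMatrix, path: str | Path,
              contig_lengths: dict[str, int] | None = None,
              force: bool = False) -> Path:
    """Write the matrix as a minimal VCF v4.2 with FORMAT GT:GQ."""
    path = Path(path)
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists; pass force=True to overwrite")
    gt_str = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}
    lines = ["##fileformat=VCFv4.2"]
    contigs = contig_lengths or {}
    for c in dict.fromkeys(m.sites["chrom"]):
        if c in contigs:
            lines.append(f"##contig=<ID={c},length={contigs[c]}>")
        else:
            lines.append(f"##contig=<ID={c}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Conditional genotype quality">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(m.samples))
    chrom = m.sites["chrom"].to_numpy()
    pos = m.sites["pos"].to_numpy()
    ref = m.sites["ref"].to_numpy()
    alt = m.sites["alt"].to_numpy()
    for j in range(m.n_sites):
        cells = []
        for i in range(m.n_samples):
            gq = GQ_UNKNOWN if m.gq is None else m.gq[i, j]
            gq_s = "." if gq == GQ_UNKNOWN else str(int(gq))
            cells.append(f"{gt_str[int(m.calls[i, j])]}:{gq_s}")
        lines.append(f"{chrom[j]}\t{pos[j]}\t.\t{ref[j]}\t{alt[j]}\t.\t.\t.\tGT:GQ\t"
                     + "\t".join(cells))
    path.write_text("\n".join(lines) + "\n")
    return path


# ----------------------------------------------------------------- filters

def filter_genotypes(m: GenotypeMatrix, min_gq: int = 20,
                     max_missing: float = 0.1) -> tuple[GenotypeMatrix, FilterReport]:
    """GQ mask then site-missingness filter.

    Calls with known GQ < ``min_gq`` are set to MISSING first; then every
    site whose missing-call fraction exceeds ``max_missing`` is dropped.
    The order is fixed: masking low-GQ calls feeds the missingness filter.
    """
    if not 0 <= max_missing <= 1:
        raise ValueError("max_missing must be in [0, 1]")
    report = FilterReport(n_input_sites=m.n_sites,
                          thresholds={"min_gq": min_gq, "max_missing": max_missing})
    calls = m.calls.copy()
    if min_gq > 0:
        if m.gq is None:
            raise ValueError(
                "matrix has no GQ values; pass min_gq=0 to disable the GQ filter explicitly")
        low = (m.gq != GQ_UNKNOWN) & (m.gq < min_gq) & (calls != MISSING)
        report.n_calls_masked_by_gq = int(low.sum())
        calls[low] = MISSING
    missing_frac = (calls == MISSING).mean(axis=0)
    keep = missing_frac <= max_missing
    report.n_sites_dropped_missingness = int((~keep).sum())
    report.n_output_sites = int(keep.sum())
    report.check()
    out = GenotypeMatrix(m.samples, m.sites.iloc[np.flatnonzero(keep)],
                         calls[:, keep],
                         None if m.gq is None else m.gq[:, keep],
                         dict(m.provenance))
    out.provenance.setdefault("filters", []).append(report.to_dict())
    return out, report


def drop_heterozygous_sites(m: GenotypeMatrix,
                            homozygous_samples: Iterable[str]
                            ) -> tuple[GenotypeMatrix, FilterReport]:
    """Drop every site at which any designated doubled-haploid sample is HET.

    A sample derived from a single haploid cell is homozygous at every true
    locus, so residual HET calls mark unreliable loci (collapsed repeats,
    mismapped contaminant reads) that are removed for all samples.
    """
    designated = list(homozygous_samples)
    report = FilterReport(n_input_sites=m.n_sites,
                          thresholds={"homozygous_samples": designated})
    if not designated:
        warnings.warn("empty homozygous sample set: heterozygous-site filter is a no-op")
        report.n_output_sites = m.n_sites
        report.check()
        return m, report
    rows = [m.sample_index(s) for s in designated]
    het_any = (m.calls[rows, :] == HET).any(axis=0)
    report.n_sites_dropped_het = int(het_any.sum())
    report.n_output_sites = int((~het_any).sum())
    report.check()
    out = m.take_sites(np.flatnonzero(~het_any))
    out.provenance.setdefault("filters", []).append(report.to_dict())
    return out, report


def apply_region_mask(m: GenotypeMatrix, mask: RegionMask,
                      mode: str = "exclude") -> GenotypeMatrix:
    """Drop (``exclude``) or keep only (``restrict``) sites inside the mask."""
    if mode not in {"exclude", "restrict"}:
        raise ValueError(f"mode must be 'exclude' or 'restrict', got {mode!r}")
    known = set(m.sites["chrom"])
    unknown = mask.chroms - known
    if unknown and m.n_sites > 0:
        raise ValueError(f"mask names unknown chromosome(s): {sorted(unknown)}")
    inside = mask.contains(m.sites["chrom"].to_numpy(), m.sites["pos"].to_numpy())
    keep = inside if mode == "restrict" else ~inside
    return m.take_sites(np.flatnonzero(keep))
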