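"""End-to-end orchestration: simulate -> filter -> trio -> structure ->
screen -> organelle, from one JSON config, with a machine-readable report.

Every stage writes its artifacts under a stage subdirectory of the output
directory; the bundle report (``report.json`` + ``report.txt``) carries
each stage's summary, the config hash, the seed and package versions.  A
stage failure aborts the run with the stage name and leaves a ``FAILED``
marker next to the partial outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .genotypes import (GenotypeMatrix, RegionMask, drop_heterozygous_sites,
                        filter_genotypes, read_multisample_vcf,
                        read_sample_metadata)
from .organelle import (SeqAlignment, pairwise_rate_ratio,
                        parsimony_informative_count, variable_site_alignment)
from .screen import group_specific_variants
from .simulate import NoiseModel, SimConfig, observe, simulate_truth
from .structure import classical_mds, hybrid_midpoint, ibs_distance_matrix
from .trio import allotetraploid_verdict, class_percentages, classify_trio

REPORT_SCHEMA_VERSION = 1


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, separators=(",", ":")).encode()
    return hashlib.sha256(canon).hexdigest()[:16]


def load_config(source: str | Path | dict) -> dict:
    if isinstance(source, dict):
        return json.loads(json.dumps(source))
    return json.loads(Path(source).read_text())


def run_pipeline(config: str | Path | dict, out_dir: str | Path) -> dict:
    """Run all enabled stages in fixed order and return the report bundle."""
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = cfg.get("stages",
                     ["simulate", "filter", "trio", "mds", "screen", "organelle"])
    report: dict = {"schema_version": REPORT_SCHEMA_VERSION,
                    "config_hash": _config_hash(cfg),
                    "seed": cfg.get("seed"),
                    "versions": {"algapop": __version__, "numpy": np.__version__,
                                 "pandas": pd.__version__},
                    "stages": {}}
    state: dict = {}
    try:
        for stage in stages:
            t0 = time.perf_counter()
            section = _STAGES[stage](cfg, out, state)
            section["seconds"] = round(time.perf_counter() - t0, 3)
            report["stages"][stage] = section
        for stage in _STAGES:
            report["stages"].setdefault(stage, {"skipped": True})
    except Exception as exc:
        (out / "FAILED").write_text(f"{type(exc).__name__}: {exc}\n")
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, exc) from exc
    (out / "report.json").write_text(json.dumps(report, indent=2, default=str) + "\n")
    (out / "report.txt").write_text(_render_text(report))
    return report


# ------------------------------------------------------------------ stages

def _stage_simulate(cfg: dict, out: Path, state: dict) -> dict:
    d = out / "simulate"
    d.mkdir(exist_ok=True)
    sim_cfg = dict(cfg.get("sim", {}))
    if "seed" in cfg:
        sim_cfg.setdefault("seed", cfg["seed"])
    sim_cfg["rrna_mask"] = [tuple(t) for t in sim_cfg.get(
        "rrna_mask", SimConfig().rrna_mask)]
    config = SimConfig(**sim_cfg)
    truth = simulate_truth(config)
    noise = NoiseModel(**cfg.get("noise", {})) if "noise" in cfg \
        else NoiseModel.from_config(config)
    vcf_path = observe(truth, noise, seed=config.seed, path=d / "observed.vcf",
                       force=True)
    truth.write_metadata(d / "metadata.tsv")
    truth.rrna_mask().to_bed(d / "rrna_mask.bed")
    truth.planted_group_loci.to_csv(d / "planted_group_loci.tsv", sep="\t",
                                    index=False)
    truth.organelle_truth.cp.to_fasta(d / "chloroplast.fasta")
    truth.organelle_truth.mt.to_fasta(d / "mitochondria.fasta")
    config.to_json(d / "sim_config.json")
    state["truth"] = truth
    state["vcf"] = vcf_path
    state["metadata"] = read_sample_metadata(d / "metadata.tsv")
    state["cp"] = truth.organelle_truth.cp
    state["mt"] = truth.organelle_truth.mt
    state["mask"] = truth.rrna_mask()
    return {"vcf": str(vcf_path), "n_samples": len(truth.samples),
            "n_truth_variant_sites": int(len(truth.variant_site_index()))}


def _stage_filter(cfg: dict, out: Path, state: dict) -> dict:
    d = out / "filter"
    d.mkdir(exist_ok=True)
    if "vcf" not in state:
        state["vcf"] = Path(cfg["vcf"])
        state["metadata"] = read_sample_metadata(cfg["metadata"])
    meta = state["metadata"]
    m = read_multisample_vcf(state["vcf"], meta)
    params = cfg.get("filter", {})
    m_gq, rep_gq = filter_genotypes(m, min_gq=params.get("min_gq", 20),
                                    max_missing=params.get("max_missing", 0.1))
    hom = list(meta.loc[meta["homozygous_expected"], "sample"])
    hom = [s for s in hom if s in m.samples]
    m_hom, rep_het = drop_heterozygous_sites(m_gq, hom)
    state["matrix_all"] = m_gq       # GQ/missingness-filtered, HET sites kept
    state["matrix_hom"] = m_hom      # additionally heterozygous-site-free
    for rep, name in ((rep_gq, "gq_missingness"), (rep_het, "heterozygous_sites")):
        (d / f"report_{name}.json").write_text(json.dumps(rep.to_dict(), indent=2) + "\n")
    return {"n_input_sites": m.n_sites,
            "n_sites_dropped_multiallelic": m.provenance.get("n_sites_dropped_multiallelic", 0),
            "n_sites_dropped_non_snv": m.provenance.get("n_sites_dropped_non_snv", 0),
            "gq_missingness": rep_gq.to_dict(),
            "heterozygous_sites": rep_het.to_dict(),
            "n_sites_all": m_gq.n_sites, "n_sites_homozygous_set": m_hom.n_sites}


def _trio_names(cfg: dict, state: dict) -> tuple[str, str, str]:
    t = cfg.get("trio", {})
    truth = state.get("truth")
    if truth is not None:
        pa, pb = truth.hybrid_composition
        return (t.get("parent_a", pa), t.get("parent_b", pb),
                t.get("hybrid", truth.hybrid_name))
    return t["parent_a"], t["parent_b"], t["hybrid"]


def _stage_trio(cfg: dict, out: Path, state: dict) -> dict:
    d = out / "trio"
    d.mkdir(exist_ok=True)
    pa, pb, hyb = _trio_names(cfg, state)
    m = state["matrix_all"]
    for s in (pa, pb, hyb):
        if s not in m.samples:
            raise KeyError(f"trio sample {s!r} absent from the genotype matrix")
    counts = classify_trio(m, pa, pb, hyb)
    verdict = allotetraploid_verdict(counts,
                                     threshold=cfg.get("trio", {}).get("threshold", 0.8),
                                     min_classified=cfg.get("trio", {}).get("min_classified", 100))
    section = {"parent_a": pa, "parent_b": pb, "hybrid": hyb,
               "counts": counts.to_dict(), "verdict": verdict.to_dict()}
    if counts.n_classified:
        section["percentages"] = class_percentages(counts)
    rows = [(cls, c, p) for cls, lst in counts.loci.items() for c, p in lst]
    pd.DataFrame(rows, columns=["class", "chrom", "pos"]).to_csv(
        d / "trio_loci.tsv", sep="\t", index=False)
    (d / "trio.json").write_text(json.dumps(section, indent=2) + "\n")
    return section


def _stage_mds(cfg: dict, out: Path, state: dict) -> dict:
    d = out / "mds"
    d.mkdir(exist_ok=True)
    m = state["matrix_all"]
    k = cfg.get("mds", {}).get("k", 2)
    dist = ibs_distance_matrix(m)
    ord_res = classical_mds(dist, k=k)
    dist.to_frame().to_csv(d / "ibs_distances.tsv", sep="\t")
    ord_res.to_frame().to_csv(d / "coordinates.tsv", sep="\t")
    section = {"k": k, "eigenvalues": [float(x) for x in ord_res.eigenvalues],
               "goodness": ord_res.goodness,
               "coordinates": str(d / "coordinates.tsv")}
    try:
        pa, pb, hyb = _trio_names(cfg, state)
        t, off = hybrid_midpoint(ord_res, pa, pb, hyb)
        section["hybrid_midpoint"] = {"t": t, "off_axis": off}
    except KeyError:
        pass
    return section


def _stage_screen(cfg: dict, out: Path, state: dict) -> dict:
    d = out / "screen"
    d.mkdir(exist_ok=True)
    meta = state["metadata"]
    params = cfg.get("screen", {})
    phenotype = params.get("case_phenotype", "abnormal")
    m = state["matrix_hom"]
    cases = [s for s in meta.loc[meta["phenotype"] == phenotype, "sample"]
             if s in m.samples]
    if not cases:
        raise ValueError(f"no samples with phenotype {phenotype!r}")
    case_species = set(meta.loc[meta["sample"].isin(cases), "species"])
    ctrl_mask = (meta["species"].isin(case_species)
                 & meta["homozygous_expected"]
                 & ~meta["sample"].isin(cases))
    controls = [s for s in meta.loc[ctrl_mask, "sample"] if s in m.samples]
    res = group_specific_variants(
        m, cases, controls,
        max_missing_cases=params.get("max_missing_cases", 0),
        max_missing_controls=params.get("max_missing_controls", 0))
    res.to_frame().to_csv(d / "candidates.tsv", sep="\t", index=False)
    return {"phenotype": phenotype, "n_case": res.n_case,
            "n_control": res.n_control, "n_candidates": len(res.candidates),
            "candidates": str(d / "candidates.tsv")}


def _stage_organelle(cfg: dict, out: Path, state: dict) -> dict:
    d = out / "organelle"
    d.mkdir(exist_ok=True)
    params = cfg.get("organelle", {})
    section: dict = {}
    m = state.get("matrix_hom")
    if m is not None:
        mask = state.get("mask")
        if mask is None and "rrna_bed" in cfg:
            mask = RegionMask.from_bed(cfg["rrna_bed"])
        aln = variable_site_alignment(m, mask=mask)
        aln.to_fasta(d / "nuclear_variable_sites.fasta")
        section["nuclear_variable_sites"] = aln.n_columns
        if aln.n_columns:
            section["nuclear_parsimony_informative"] = parsimony_informative_count(aln)
    cp = state.get("cp") or (SeqAlignment.from_fasta(cfg["cp_fasta"])
                             if "cp_fasta" in cfg else None)
    mt = state.get("mt") or (SeqAlignment.from_fasta(cfg["mt_fasta"])
                             if "mt_fasta" in cfg else None)
    if cp is not None and mt is not None:
        est = pairwise_rate_ratio(cp, mt,
                                  correction=params.get("correction", "p-distance"))
        est.pair_table.to_csv(d / "pair_distances.tsv", sep="\t", index=False)
        section["rate_ratio"] = est.to_dict()
    return section


_STAGES = {"simulate": _stage_simulate, "filter": _stage_filter,
           "trio": _stage_trio, "mds": _stage_mds, "screen": _stage_screen,
           "organelle": _stage_organelle}


def _render_text(report: dict) -> str:
    lines = [f"algapop pipeline report (schema v{report['schema_version']})",
             f"config hash: {report['config_hash']}  seed: {report['seed']}", ""]
    for stage, section in report["stages"].items():
        lines.append(f"[{stage}]")
        if section.get("skipped"):
            lines.append("  skipped")
        else:
            for key, val in section.items():
                if key == "seconds":
                    continue
                lines.append(f"  {key}: {val}")
        lines.append("")
    return "\n".join(lines)
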