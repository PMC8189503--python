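"""Phenotype-group-specific variant screening.

A locus is a candidate for a case group (e.g. samples with frequent
abnormal budding, or a green mutant) when every called case shares one
genotype class, that class is observed in zero called controls, and the
per-group missing-call counts are within the configured tolerances.  The
screen replaces manual genome-browser inspection with exportable
per-locus evidence (class and missingness counts).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, MISSING


@dataclass
class CandidateLocus:
    chrom: str
    pos: int
    case_allele_class: int            # genotype class shared by the cases
    n_case_nonmissing: int
    n_control_nonmissing: int


@dataclass
class ScreenResult:
    candidates: list[CandidateLocus]
    n_case: int
    n_control: int
    parameters: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        names = {0: "HOM_REF", 1: "HET", 2: "HOM_ALT"}
        return pd.DataFrame(
            [{"chrom": c.chrom, "pos": c.pos,
              "case_allele_class": names[c.case_allele_class],
              "n_case_nonmissing": c.n_case_nonmissing,
              "n_control_nonmissing": c.n_control_nonmissing}
             for c in self.candidates])

    @property
    def positions(self) -> set[tuple[str, int]]:
        return {(c.chrom, c.pos) for c in self.candidates}


def group_specific_variants(m: GenotypeMatrix, cases: list[str],
                            controls: list[str], max_missing_cases: int = 0,
                            max_missing_controls: int = 0) -> ScreenResult:
    """Loci whose genotype class is fixed in the cases and absent from
    the controls.

    A locus with every case missing is never a candidate.  Increasing the
    missingness tolerances can only enlarge the candidate set.
    """
    cases, controls = list(cases), list(controls)
    if not cases or not controls:
        raise ValueError("cases and controls must both be nonempty")
    overlap = set(cases) & set(controls)
    if overlap:
        raise ValueError(f"samples in both groups: {sorted(overlap)}")
    ci = [m.sample_index(s) for s in cases]
    ki = [m.sample_index(s) for s in controls]
    case_calls = m.calls[ci]          # (n_case, n_sites)
    ctrl_calls = m.calls[ki]
    case_missing = (case_calls == MISSING).sum(axis=0)
    ctrl_missing = (ctrl_calls == MISSING).sum(axis=0)
    n_case, n_ctrl = len(ci), len(ki)

    # the shared case class, if any: max equals min over called case genotypes
    case_masked = np.ma.masked_equal(case_calls, MISSING)
    case_min = case_masked.min(axis=0)
    case_max = case_masked.max(axis=0)
    all_case_missing = case_missing == n_case
    uniform = (~all_case_missing) & (case_min == case_max).filled(False)
    shared = case_min.filled(MISSING)

    in_controls = np.zeros(m.n_sites, dtype=bool)
    for j in np.flatnonzero(uniform):
        in_controls[j] = (ctrl_calls[:, j] == shared[j]).any()

    ok = (uniform & ~in_controls
          & (case_missing <= max_missing_cases)
          & (ctrl_missing <= max_missing_controls))
    chrom = m.sites["chrom"].to_numpy()
    pos = m.sites["pos"].to_numpy()
    candidates = [
        CandidateLocus(chrom=str(chrom[j]), pos=int(pos[j]),
                       case_allele_class=int(shared[j]),
                       n_case_nonmissing=int(n_case - case_missing[j]),
                       n_control_nonmissing=int(n_ctrl - ctrl_missing[j]))
        for j in np.flatnonzero(ok)]
    return ScreenResult(candidates=candidates, n_case=n_case, n_control=n_ctrl,
                        parameters={"max_missing_cases": max_missing_cases,
                                    "max_missing_controls": max_missing_controls})
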