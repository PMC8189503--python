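"""Identity-by-state distances and classical multidimensional scaling.

IBS similarity at a site is allele-dosage agreement, 1 - |dose_i - dose_j|/2
with dose in {0,1,2}; the pairwise distance is one minus the mean
similarity over sites called in both samples (missing data handled
pairwise).  Classical (Torgerson) MDS double-centres the squared
distances, eigendecomposes, and takes coordinates from the top-k
nonnegative eigenpairs; negative eigenvalues are truncated to zero and
their mass reported.  Coordinates are determined only up to
translation/rotation/reflection, so comparisons should use reconstructed
distances, never raw axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, MISSING


@dataclass
class DistanceMatrix:
    samples: list[str]
    d: np.ndarray                    # symmetric, zero diagonal
    n_sites_used: np.ndarray         # per-pair co-called site counts

    def __post_init__(self) -> None:
        n = len(self.samples)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.d, self.d.T) or not np.allclose(np.diag(self.d), 0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")
        if (self.d < 0).any():
            raise ValueError("negative distances")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.samples, columns=self.samples)


@dataclass
class OrdinationResult:
    samples: list[str]
    coordinates: np.ndarray          # samples x k
    eigenvalues: np.ndarray          # k, descending, nonnegative
    goodness: float                  # captured fraction of positive eigenvalue mass
    negative_eigenvalue_mass: float = 0.0

    def row(self, sample: str) -> np.ndarray:
        try:
            return self.coordinates[self.samples.index(sample)]
        except ValueError:
            raise KeyError(f"unknown sample {sample!r}") from None

    def to_frame(self) -> pd.DataFrame:
        cols = [f"axis{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.samples, columns=cols)


def ibs_distance_matrix(m: GenotypeMatrix) -> DistanceMatrix:
    """Pairwise IBS distances over sites called in both samples."""
    if m.n_samples < 2:
        raise ValueError("need >= 2 samples")
    dose = m.calls.astype(np.int16)
    called = m.calls != MISSING
    n = m.n_samples
    d = np.zeros((n, n))
    used = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            both = called[i] & called[j]
            k = int(both.sum())
            if k == 0:
                raise ValueError(
                    f"samples {m.samples[i]!r} and {m.samples[j]!r} share no called sites")
            sim = 1.0 - np.abs(dose[i, both] - dose[j, both]) / 2.0
            d[i, j] = d[j, i] = 1.0 - float(sim.mean())
            used[i, j] = used[j, i] = k
        used[i, i] = int(called[i].sum())
    return DistanceMatrix(list(m.samples), d, used)


def classical_mds(d: DistanceMatrix, k: int = 2) -> OrdinationResult:
    """Torgerson scaling: B = -1/2 J D^2 J, eigendecomposition, coordinates
    from the top-k nonnegative eigenpairs."""
    n = len(d.samples)
    if not 1 <= k <= n - 1:
        raise ValueError(f"k must be in [1, {n - 1}], got {k}")
    D2 = d.d ** 2
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ D2 @ J
    lam, vec = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(lam)[::-1]
    lam, vec = lam[order], vec[:, order]
    pos_mass = float(lam[lam > 0].sum())
    neg_mass = float(-lam[lam < 0].sum())
    lam_k = np.clip(lam[:k], 0.0, None)
    coords = vec[:, :k] * np.sqrt(lam_k)
    goodness = float(lam_k.sum() / pos_mass) if pos_mass > 0 else 1.0
    return OrdinationResult(list(d.samples), coords, lam_k, goodness, neg_mass)


def reconstructed_distances(o: OrdinationResult) -> np.ndarray:
    """Euclidean distances among the ordination coordinates."""
    x = o.coordinates
    diff = x[:, None, :] - x[None, :, :]
    return np.sqrt((diff ** 2).sum(axis=-1))


def hybrid_midpoint(o: OrdinationResult, a: str, b: str, h: str
                    ) -> tuple[float, float]:
    """Position of sample ``h`` along the A–B axis in ordination space.

    Returns ``t`` (projection of H onto the A->B segment, 0 at A, 1 at B,
    0.5 at the exact middle) and ``off_axis`` (distance from H to the A–B
    line, divided by |B-A|).
    """
    A, B, H = o.row(a), o.row(b), o.row(h)
    ab = B - A
    denom = float(ab @ ab)
    if denom == 0:
        raise ValueError(f"samples {a!r} and {b!r} coincide in ordination space")
    t = float((H - A) @ ab) / denom
    perp = (H - A) - t * ab
    off_axis = float(np.linalg.norm(perp)) / float(np.sqrt(denom))
    return t, off_axis


def plot_ordination(o: OrdinationResult, path: str | Path,
                    labels: bool = True) -> Path:
    """Scatter plot of the first two ordination axes (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    x = o.coordinates[:, 0]
    y = o.coordinates[:, 1] if o.coordinates.shape[1] > 1 else np.zeros_like(x)
    ax.scatter(x, y, s=18)
    if labels:
        for name, xi, yi in zip(o.samples, x, y):
            ax.annotate(name, (xi, yi), fontsize=6)
    ax.set_xlabel("axis 1")
    ax.set_ylabel("axis 2")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
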