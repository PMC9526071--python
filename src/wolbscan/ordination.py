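"""Principal coordinates analysis of haplotype distances and
within/among-strain divergence summaries.

PCoA here is classical metric scaling (Gower): the squared distance matrix
is double-centered, eigendecomposed, and coordinates are the eigenvectors
scaled by the square roots of their (non-negative) eigenvalues.  Hamming
distance matrices need not be Euclidean-embeddable, so negative
eigenvalues can occur; they are reported, excluded from the variance
proportions, and their axes carry zero coordinates.

Divergence tables report uncorrected p-distance (fraction of differing
sites), scaled to percent, within and between strains.  Pairs are weighted
per distinct haplotype by default; weighting per individual (multiplicity)
is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations, combinations_with_replacement
from typing import Mapping

import numpy as np
import pandas as pd

from wolbscan.errors import ConfigError, WolbscanError
from wolbscan.network import DistanceMatrix, StrainAssignment

__all__ = ["PCoAResult", "DivergenceSummary", "pcoa", "divergence_table"]


@dataclass
class PCoAResult:
    """Coordinates, eigenvalues and explained variance of a PCoA."""

    labels: list[str]
    coordinates: np.ndarray          # (n, n_axes); column means ~ 0
    eigenvalues: np.ndarray          # all n, sorted descending
    proportion_explained: np.ndarray  # over positive eigenvalues only

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PCo{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.labels,
                            columns=cols)


def pcoa(distance: DistanceMatrix | np.ndarray,
         n_axes: int | None = None) -> PCoAResult:
    """Classical metric scaling of a symmetric distance matrix.

    Eigenvalues are reported in full (including negative ones); axes with
    non-positive eigenvalues get zero coordinates.  ``n_axes`` truncates
    the returned coordinate columns.
    """
    if isinstance(distance, DistanceMatrix):
        d = np.asarray(distance.steps, dtype=float)
        labels = list(distance.labels)
    else:
        d = np.asarray(distance, dtype=float)
        labels = [f"obj{i + 1}" for i in range(d.shape[0])]
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ConfigError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ConfigError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-12):
        raise ConfigError("distance matrix must have a zero diagonal")
    n = d.shape[0]
    # Gower double-centering of -0.5 * D^2
    a = -0.5 * d ** 2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    b = a - row - col + a.mean()
    from scipy.linalg import eigh
    eigval, eigvec = eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    # zero out numerically-zero eigenvalues
    tol = max(abs(eigval).max(), 1.0) * 1e-12
    eigval[np.abs(eigval) < tol] = 0.0
    if (eigval < 0).any():
        warnings.warn(
            "distance matrix is not Euclidean-embeddable: "
            f"{int((eigval < 0).sum())} negative eigenvalues reported and "
            "excluded from variance proportions", stacklevel=2)
    coords = eigvec * np.sqrt(np.clip(eigval, 0.0, None))
    pos = eigval[eigval > 0].sum()
    prop = np.where(eigval > 0, eigval / pos, 0.0) if pos > 0 \
        else np.zeros(n)
    if n_axes is not None:
        coords = coords[:, :n_axes]
    return PCoAResult(labels, coords, eigval, prop)


@dataclass
class DivergenceSummary:
    """Mean and SD of percent sequence divergence within/between strains.

    ``mean`` and ``sd`` are strain x strain DataFrames of p-distance x 100;
    the diagonal holds within-strain values (NaN when a strain has a
    single haplotype under haplotype weighting).
    """

    mean: pd.DataFrame
    sd: pd.DataFrame
    n_pairs: pd.DataFrame
    weighting: str

    def lower_triangle(self) -> pd.DataFrame:
        """Render mean (sd) strings in the conventional lower-triangle
        layout."""
        strains = list(self.mean.index)
        out = pd.DataFrame("", index=strains, columns=strains)
        for i, si in enumerate(strains):
            for j, sj in enumerate(strains[:i + 1]):
                m = self.mean.loc[si, sj]
                s = self.sd.loc[si, sj]
                if np.isnan(m):
                    continue
                cell = f"{m:.1f}%"
                cell += f" ({s:.1f}%)" if not np.isnan(s) else ""
                out.loc[si, sj] = cell
        return out


def divergence_table(haplotypes: Mapping[str, str],
                     assignment: StrainAssignment | Mapping[str, str],
                     weighting: str = "haplotype") -> DivergenceSummary:
    """Within- and between-strain percent divergence (p-distance x 100).

    ``haplotypes`` maps haplotype label -> 0/1 string; ``assignment`` maps
    haplotype label -> strain (a :class:`StrainAssignment` works).  With
    ``weighting='haplotype'`` each distinct unordered haplotype pair
    counts once; with ``weighting='individual'`` pairs are weighted by the
    product of multiplicities (same-haplotype individual pairs contribute
    zero distances within strains).
    """
    if weighting not in ("haplotype", "individual"):
        raise ConfigError(f"unknown weighting '{weighting}'")
    if isinstance(assignment, StrainAssignment):
        strain_of = assignment.haplotype_to_strain
        mult = assignment.haplotype_counts
    else:
        strain_of = dict(assignment)
        mult = {h: 1 for h in strain_of}
    missing = sorted(set(haplotypes) - set(strain_of))
    if missing:
        raise WolbscanError(f"haplotypes without a strain: {missing[:10]}")
    labels = list(haplotypes)
    if not labels:
        raise WolbscanError("no haplotypes given")
    n_sites = len(haplotypes[labels[0]])
    strains = sorted(set(strain_of[h] for h in labels))
    arr = {h: np.frombuffer(haplotypes[h].encode(), dtype=np.uint8)
           for h in labels}
    by_strain: dict[str, list[str]] = {s: [] for s in strains}
    for h in labels:
        by_strain[strain_of[h]].append(h)

    mean = pd.DataFrame(np.nan, index=strains, columns=strains)
    sd = pd.DataFrame(np.nan, index=strains, columns=strains)
    npairs = pd.DataFrame(0, index=strains, columns=strains)
    for si, sj in combinations_with_replacement(strains, 2):
        dists = []
        weights = []
        if si == sj:
            for a, b in combinations(by_strain[si], 2):
                dists.append((arr[a] != arr[b]).sum() / n_sites * 100)
                weights.append(mult[a] * mult[b])
            if weighting == "individual":
                for a in by_strain[si]:
                    w = mult[a] * (mult[a] - 1) / 2
                    if w > 0:
                        dists.append(0.0)
                        weights.append(w)
        else:
            for a in by_strain[si]:
                for b in by_strain[sj]:
                    dists.append((arr[a] != arr[b]).sum() / n_sites * 100)
                    weights.append(mult[a] * mult[b])
        if not dists:
            continue
        d = np.asarray(dists, dtype=float)
        w = (np.asarray(weights, dtype=float)
             if weighting == "individual" else np.ones(len(dists)))
        wsum = w.sum()
        mu = float((w * d).sum() / wsum)
        var = float((w * (d - mu) ** 2).sum() / (wsum - 1)) \
            if wsum > 1 else np.nan
        for a, b in ((si, sj), (sj, si)):
            mean.loc[a, b] = mu
            sd.loc[a, b] = np.sqrt(var) if not np.isnan(var) else np.nan
            npairs.loc[a, b] = len(dists)
    return DivergenceSummary(mean, sd, npairs, weighting)
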