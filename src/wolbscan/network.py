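"""Statistical-parsimony haplotype networks and strain assignment.

Distinct haplotypes are joined by edges of one or more mutational steps
whenever their Hamming distance does not exceed the statistical-parsimony
connection limit; the connected components of that graph are the strains.
Within each component the retained edges form a minimum spanning structure
with deterministic tie-breaking, and multi-step edges carry (cosmetic)
inferred intermediate haplotypes for rendering.

The connection limit is the largest number of observed differences j for
which the estimated probability of a parsimonious connection still reaches
the requested confidence (0.95 by default).  The probability model: the
true number of mutations q separating two sequences of length m is given a
geometric (coalescent pairwise) prior whose mean is the observed difference
count; mutations fall uniformly over sites and follow a symmetric 4-state
substitution scheme.  A connection is counted parsimonious when no site
reverted to the ancestral state — reversions hide true changes and are
what make too-distant haplotypes look spuriously close, whereas a repeated
hit that leaves the site divergent does not corrupt the connection.  The
posterior P(no reversion | j observed differences) is evaluated exactly
with generating functions.  At the package default of 115 sites the 95%
limit works out to 5 steps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from wolbscan.errors import ConfigError, WolbscanError

__all__ = [
    "DistanceMatrix",
    "HaplotypeNetwork",
    "StrainAssignment",
    "hamming_matrix",
    "parsimony_probability",
    "parsimony_connection_limit",
    "build_network",
    "assign_strains",
    "haplotype_spectrum",
]


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    """Pairwise Hamming steps between equal-length haplotypes."""

    labels: list[str]
    steps: np.ndarray  # int, shape (n, n)
    n_sites: int

    @property
    def p_distance(self) -> np.ndarray:
        """Uncorrected proportion of differing sites."""
        return self.steps / self.n_sites

    def __len__(self) -> int:
        return len(self.labels)


def hamming_matrix(haplotypes: Mapping[str, str] | Sequence[str]
                   ) -> DistanceMatrix:
    """Pairwise Hamming distances among haplotype strings.

    ``haplotypes`` maps label -> string (or is a sequence of strings,
    which are labelled by position).  All strings must have equal length
    and no missing characters.
    """
    if isinstance(haplotypes, Mapping):
        labels = list(haplotypes)
        strings = [haplotypes[k] for k in labels]
    else:
        strings = list(haplotypes)
        labels = [f"H{i + 1:03d}" for i in range(len(strings))]
    if not strings:
        raise WolbscanError("no haplotypes given")
    n_sites = len(strings[0])
    for lab, s in zip(labels, strings):
        if len(s) != n_sites:
            raise WolbscanError(
                f"haplotype {lab} has length {len(s)}, expected {n_sites}")
    arr = np.frombuffer("".join(strings).encode(), dtype=np.uint8)
    arr = arr.reshape(len(strings), n_sites)
    from scipy.spatial.distance import pdist, squareform
    steps = squareform(
        np.rint(pdist(arr, metric="hamming") * n_sites).astype(int)
    ) if len(strings) > 1 else np.zeros((1, 1), dtype=int)
    return DistanceMatrix(labels, steps.astype(int), n_sites)


# ---------------------------------------------------------------------------
# Statistical-parsimony connection limit
# ---------------------------------------------------------------------------

def _series_mul(a: np.ndarray, b: np.ndarray, n: int) -> np.ndarray:
    return np.convolve(a, b)[:n + 1]


def _series_pow(a: np.ndarray, power: float, n: int) -> np.ndarray:
    """(a)^power for a power series with a[0] == 1, via exp(power*log a)."""
    u = a.copy()
    u[0] = 0.0
    log_a = np.zeros(n + 1)
    uk = u.copy()
    sign = 1.0
    for k in range(1, n + 1):
        log_a += sign * uk / k
        uk = _series_mul(uk, u, n)
        sign = -sign
    out = np.zeros(n + 1)
    out[0] = 1.0
    x = power * log_a
    xk = np.zeros(n + 1)
    xk[0] = 1.0
    fact = 1.0
    for k in range(1, n + 1):
        xk = _series_mul(xk, x, n)
        fact *= k
        out += xk / fact
    return out


@lru_cache(maxsize=512)
def _conditional_probs(j: int, m: int, qmax: int
                       ) -> tuple[tuple[float, ...], tuple[float, ...]]:
    """For q = 0..qmax mutations uniform over m sites (4-state symmetric):
    P(exactly j sites differ | q) and P(j sites differ and no site
    reverted | q)."""
    n = qmax
    # P(site differs after k hits): p0 = 0, p_{k+1} = 1 - p_k / 3
    pk = [0.0] * (n + 1)
    for k in range(n):
        pk[k + 1] = 1.0 - pk[k] / 3.0
    kfact = [1.0] * (n + 1)
    for k in range(1, n + 1):
        kfact[k] = kfact[k - 1] * k
    # exponential generating functions per site (x carries a 1/m per hit):
    #   A: site mutated and divergent;  B: site mutated but reverted
    A = np.array([0.0] + [pk[k] / (kfact[k] * m ** k)
                          for k in range(1, n + 1)])
    B = np.array([0.0] + [(1.0 - pk[k]) / (kfact[k] * m ** k)
                          for k in range(1, n + 1)])
    Aj = np.zeros(n + 1)
    Aj[0] = 1.0
    for _ in range(j):
        Aj = _series_mul(Aj, A, n)
    one_plus_B = B.copy()
    one_plus_B[0] = 1.0
    choose = math.comb(m, j)
    observed = _series_mul(Aj, _series_pow(one_plus_B, m - j, n), n) * choose
    parsimonious = Aj * choose
    fac = np.exp([math.lgamma(q + 1) for q in range(n + 1)])
    return tuple(observed * fac), tuple(parsimonious * fac)


def parsimony_probability(n_differences: int, n_sites: int) -> float:
    """Probability that ``n_differences`` observed differences over
    ``n_sites`` arose without superimposed (reverting) changes.

    Posterior under a geometric prior on the true mutation count with mean
    equal to the observed difference count.  Equals 1 for zero differences
    and decreases as the observed divergence grows relative to the
    sequence length.
    """
    j, m = int(n_differences), int(n_sites)
    if m < 1:
        raise ConfigError("n_sites must be >= 1")
    if j < 0 or j > m:
        raise ConfigError(f"n_differences must be in [0, {m}]")
    if j == 0:
        return 1.0
    r = j / (1.0 + j)
    qmax = j + 60
    observed, parsimonious = _conditional_probs(j, m, qmax)
    w = r ** np.arange(qmax + 1)
    num = float((w * np.asarray(parsimonious))[j:].sum())
    den = float((w * np.asarray(observed))[j:].sum())
    return num / den if den > 0 else 0.0


def parsimony_connection_limit(n_sites: int,
                               confidence: float = 0.95) -> int:
    """Largest step count still connectable at the given confidence.

    Scans j upward and returns the last j whose parsimony probability
    reaches ``confidence``; capped at ``n_sites``.  As confidence tends to
    zero the limit tends to ``n_sites``.
    """
    if n_sites < 1:
        raise ConfigError("n_sites must be >= 1")
    if not 0.0 < confidence < 1.0:
        raise ConfigError("confidence must be in (0, 1)")
    limit = 0
    for j in range(1, n_sites + 1):
        if parsimony_probability(j, n_sites) >= confidence:
            limit = j
        else:
            break
    return limit


# ---------------------------------------------------------------------------
# Network construction
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeNetwork:
    """Statistical-parsimony network over distinct haplotypes.

    Edges are the minimum-spanning subset (per component) of all pairs
    within ``connection_limit`` steps; ``components`` partition all nodes.
    ``inferred_nodes`` counts the unsampled intermediate haplotypes drawn
    on multi-step edges (steps - 1 per edge); they are cosmetic and play
    no role in components or statistics.
    """

    labels: list[str]
    multiplicities: dict[str, int]
    edges: list[tuple[str, str, int]]
    components: list[frozenset]
    connection_limit: int
    distance: DistanceMatrix = field(repr=False)

    @property
    def inferred_nodes(self) -> int:
        return sum(steps - 1 for _, _, steps in self.edges)

    def component_of(self) -> dict[str, int]:
        out = {}
        for ci, comp in enumerate(self.components):
            for lab in comp:
                out[lab] = ci
        return out

    def to_edge_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.edges,
                            columns=["haplotype_a", "haplotype_b", "steps"])

    def to_graph(self):
        """networkx Graph of observed haplotypes (edge attr ``steps``)."""
        import networkx as nx

        g = nx.Graph()
        for lab in self.labels:
            g.add_node(lab, multiplicity=self.multiplicities.get(lab, 1),
                       observed=True)
        for u, v, steps in self.edges:
            g.add_edge(u, v, steps=steps)
        return g


class _DSU:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def build_network(distance: DistanceMatrix,
                  multiplicities: Mapping[str, int] | None = None,
                  limit: int | None = None,
                  confidence: float = 0.95) -> HaplotypeNetwork:
    """Build the parsimony network at the given (or estimated) limit.

    Components are the connected components of the graph joining every
    pair at most ``limit`` steps apart.  Within a component, edges are a
    minimum spanning tree of those pairs; ties are broken toward the edge
    with the larger joint multiplicity, then lexically by labels, so the
    result is reproducible.
    """
    if limit is None:
        limit = parsimony_connection_limit(distance.n_sites, confidence)
    if limit < 1:
        raise ConfigError("connection limit must be >= 1")
    labels = distance.labels
    mult = {lab: int((multiplicities or {}).get(lab, 1)) for lab in labels}
    n = len(labels)
    candidates = []
    for i in range(n):
        for k in range(i + 1, n):
            d = int(distance.steps[i, k])
            if 0 < d <= limit:
                joint = mult[labels[i]] * mult[labels[k]]
                a, b = sorted((labels[i], labels[k]))
                candidates.append((d, -joint, a, b, i, k))
    candidates.sort()
    dsu = _DSU(n)
    edges = []
    for d, _, a, b, i, k in candidates:
        if dsu.union(i, k):
            edges.append((a, b, d))
    comp_members: dict[int, set] = {}
    for i, lab in enumerate(labels):
        comp_members.setdefault(dsu.find(i), set()).add(lab)
    components = sorted((frozenset(s) for s in comp_members.values()),
                        key=lambda s: sorted(s))
    return HaplotypeNetwork(list(labels), mult, edges, components,
                            int(limit), distance)


# ---------------------------------------------------------------------------
# Strain assignment
# ---------------------------------------------------------------------------

@dataclass
class StrainAssignment:
    """Strains = network components, labelled by decreasing individual
    count (A, B, C, ...); components with fewer than ``min_major``
    individuals are flagged rare."""

    haplotype_to_strain: dict[str, str]
    strain_counts: dict[str, int]          # individuals per strain
    haplotype_counts: dict[str, int]       # individuals per haplotype
    major: dict[str, bool]
    min_major: int

    @property
    def strains(self) -> list[str]:
        return list(self.strain_counts)

    def rare_strains(self) -> list[str]:
        return [s for s, is_major in self.major.items() if not is_major]

    def to_frame(self) -> pd.DataFrame:
        rows = [(h, s, self.haplotype_counts.get(h, 0))
                for h, s in self.haplotype_to_strain.items()]
        return pd.DataFrame(rows, columns=["haplotype", "strain",
                                           "n_individuals"])


def assign_strains(network: HaplotypeNetwork,
                   individual_haplotypes: Mapping[str, str],
                   min_major: int = 11) -> StrainAssignment:
    """Assign every network component a strain label.

    ``individual_haplotypes`` maps individual -> haplotype label; every
    value must be a node of the network.  Components are ordered by
    decreasing total individual count (ties: lexically smallest member
    label) and named A, B, C, ... (AA, AB, ... beyond 26).
    """
    known = set(network.labels)
    unmapped = sorted({h for h in individual_haplotypes.values()
                       if h not in known})
    if unmapped:
        raise WolbscanError(
            f"haplotypes not present in the network: {unmapped[:10]}")
    hap_counts: dict[str, int] = {lab: 0 for lab in network.labels}
    for hap in individual_haplotypes.values():
        hap_counts[hap] += 1
    comp_count = [(sum(hap_counts[h] for h in comp), comp)
                  for comp in network.components]
    comp_count.sort(key=lambda t: (-t[0], sorted(t[1])))

    def strain_name(i: int) -> str:
        name = ""
        while True:
            name = chr(ord("A") + i % 26) + name
            i = i // 26 - 1
            if i < 0:
                return name

    hap_to_strain: dict[str, str] = {}
    strain_counts: dict[str, int] = {}
    major: dict[str, bool] = {}
    for idx, (count, comp) in enumerate(comp_count):
        label = strain_name(idx)
        strain_counts[label] = count
        major[label] = count >= min_major
        for h in comp:
            hap_to_strain[h] = label
    return StrainAssignment(hap_to_strain, strain_counts, hap_counts,
                            major, min_major)


def haplotype_spectrum(assignment: StrainAssignment) -> pd.DataFrame:
    """Per-strain haplotype frequency spectrum.

    One row per strain: number of distinct haplotypes, total individuals,
    and the sorted (descending) multiplicity list.
    """
    rows = []
    by_strain: dict[str, list[int]] = {}
    for hap, strain in assignment.haplotype_to_strain.items():
        by_strain.setdefault(strain, []).append(
            assignment.haplotype_counts.get(hap, 0))
    for strain in assignment.strain_counts:
        mults = sorted(by_strain.get(strain, []), reverse=True)
        rows.append((strain, len(mults), int(sum(mults)),
                     ";".join(map(str, mults))))
    return pd.DataFrame(rows, columns=["strain", "n_haplotypes",
                                       "n_individuals", "multiplicities"])
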