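"""Seeded synthetic data with the statistical structure of an endosymbiont
survey built on host genotyping-by-sequencing (GBS) reads.

The generator plants, per locality, a known infection status for every host
individual and, for infected hosts, a haploid endosymbiont haplotype drawn
from one of a few deeply divergent strains.  Strain founders are far apart
in Hamming distance while within-strain variants form star-like clouds
around their founder, so dominant haplotypes are common and most variants
are rare (a right-skewed frequency spectrum).  Read counts of
quality-passing endosymbiont-mapped reads separate infected from uninfected
hosts, and an imperfect PCR assay provides gold-standard labels for a
calibration subset.

All randomness flows from one integer seed; named substreams are derived
deterministically from it, so identical configurations give byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from wolbscan.errors import ConfigError

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_truth",
    "simulate_strain_haplotypes",
    "simulate_read_data",
    "simulate_pcr_labels",
    "write_sam",
    "write_reads_tsv",
    "write_depths_tsv",
]

# Distribution specs are ("name", {params}) pairs; supported names below.
_COUNT_DISTS = ("poisson", "negative_binomial", "constant", "uniform_int")


def _default_read_length_dist() -> dict[int, float]:
    # >=0.90 of the probability mass above 80 bp, maximum read length 87 bp.
    d = {87: 0.55, 86: 0.10, 85: 0.08, 84: 0.07, 83: 0.05, 82: 0.04, 81: 0.03}
    d.update({80: 0.02, 70: 0.015, 60: 0.015, 50: 0.01, 40: 0.01, 30: 0.01})
    return d


def _default_mapq_dist() -> dict[int, float]:
    # 90% of reads above the MAPQ 20 filter; a boundary class at exactly 20.
    return {42: 0.82, 30: 0.08, 20: 0.04, 7: 0.03, 0: 0.03}


@dataclass
class SimulationConfig:
    """Parameters of a synthetic endosymbiont survey.

    Defaults emulate the scale of a continental GBS survey: ~100 localities
    of a couple dozen hosts each, three deeply divergent strains typed at
    115 biallelic sites, high planted prevalence, and infected hosts whose
    quality-passing read counts (negative binomial, mean 3500) dwarf the
    sparse background of uninfected hosts (Poisson, mean 0.2).
    """

    n_localities: int = 107
    individuals_per_locality: int | tuple[int, int] = (8, 36)
    n_strains: int = 3
    strain_divergence: float = 0.30
    within_strain_mutations: float = 1.5
    n_sites: int = 115
    prevalence_per_locality: float | Sequence[float] = 0.9
    infected_read_count_dist: tuple[str, dict] = (
        "negative_binomial", {"mean": 3500.0, "dispersion": 1.0})
    uninfected_read_count_dist: tuple[str, dict] = ("poisson", {"mean": 0.2})
    read_length_dist: dict[int, float] = field(
        default_factory=_default_read_length_dist)
    mapq_dist: dict[int, float] = field(default_factory=_default_mapq_dist)
    pcr_sensitivity: float = 0.96
    pcr_specificity: float = 0.98
    depth_per_site_dist: tuple[str, dict] = ("poisson", {"mean": 5.5})
    depth_scaled_by_reads: bool = True
    # Dirichlet-process-style concentration controlling how many distinct
    # within-strain haplotypes arise (larger -> more rare variants).
    haplotype_concentration: float = 3.0
    seed: int = 0

    # -- validation ------------------------------------------------------
    def validate(self) -> "SimulationConfig":
        errs = []
        if self.n_localities < 0:
            errs.append("n_localities must be >= 0")
        if self.n_strains < 1:
            errs.append("n_strains must be >= 1")
        if self.n_sites < 1:
            errs.append("n_sites must be >= 1")
        for name in ("strain_divergence", "pcr_sensitivity",
                     "pcr_specificity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                errs.append(f"{name} must be in [0, 1], got {v}")
        prev = np.atleast_1d(np.asarray(self.prevalence_per_locality,
                                        dtype=float))
        if ((prev < 0) | (prev > 1)).any():
            errs.append("prevalence_per_locality values must be in [0, 1]")
        if self.within_strain_mutations < 0:
            errs.append("within_strain_mutations must be >= 0")
        for nm in ("infected_read_count_dist", "uninfected_read_count_dist",
                   "depth_per_site_dist"):
            kind, _ = getattr(self, nm)
            if kind not in _COUNT_DISTS:
                errs.append(f"{nm}: unknown distribution '{kind}'")
        if not errs:
            if (_dist_mean(self.infected_read_count_dist)
                    <= _dist_mean(self.uninfected_read_count_dist)):
                errs.append("infected read-count mean must exceed the "
                            "uninfected mean")
        for nm in ("read_length_dist", "mapq_dist"):
            d = getattr(self, nm)
            if not d or abs(sum(d.values()) - 1.0) > 1e-9:
                errs.append(f"{nm} probabilities must sum to 1")
        if self.n_strains > 1:
            # Strains must be separable: within-strain clouds (radius up to
            # ~3x the mean mutation count) may not reach the next founder.
            sep = self.founder_step_distance()
            if 3.0 * self.within_strain_mutations >= sep:
                errs.append(
                    "strains would not be separable: within_strain_mutations"
                    f" * 3 = {3 * self.within_strain_mutations} >= "
                    f"between-strain step count {sep}")
            if self.n_strains * ((self.founder_step_distance() + 1) // 2) \
                    > self.n_sites:
                errs.append("n_sites too small for the requested number of "
                            "strains at this divergence")
        if errs:
            raise ConfigError("; ".join(errs))
        return self

    def founder_step_distance(self) -> int:
        """Planted Hamming distance between any two strain founders."""
        target = max(1, math.floor(self.strain_divergence * self.n_sites
                                   + 0.5))
        return 2 * ((target + 1) // 2)

    def locality_sizes(self, rng: np.random.Generator) -> np.ndarray:
        ipl = self.individuals_per_locality
        if isinstance(ipl, int):
            return np.full(self.n_localities, ipl, dtype=int)
        lo, hi = ipl
        return rng.integers(lo, hi + 1, size=self.n_localities)

    def prevalences(self) -> np.ndarray:
        prev = np.asarray(self.prevalence_per_locality, dtype=float)
        if prev.ndim == 0:
            prev = np.full(self.n_localities, float(prev))
        if prev.shape != (self.n_localities,):
            raise ConfigError(
                "prevalence_per_locality must be a scalar or one value per "
                f"locality (expected {self.n_localities}, got {prev.shape})")
        return prev

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        text = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha1(text.encode()).hexdigest()[:12]


def _substream(config: SimulationConfig, name: str) -> np.random.Generator:
    """Deterministic named substream of the config's master seed."""
    tag = int.from_bytes(hashlib.sha256(name.encode()).digest()[:4], "big")
    return np.random.default_rng(np.random.SeedSequence((config.seed, tag)))


def _dist_mean(dist: tuple[str, dict]) -> float:
    kind, p = dist
    if kind == "poisson":
        return float(p["mean"])
    if kind == "negative_binomial":
        return float(p["mean"])
    if kind == "constant":
        return float(p["value"])
    if kind == "uniform_int":
        return (p["low"] + p["high"]) / 2.0
    raise ConfigError(f"unknown distribution '{kind}'")


def _sample_counts(dist: tuple[str, dict], rng: np.random.Generator,
                   size: int) -> np.ndarray:
    kind, p = dist
    if kind == "poisson":
        return rng.poisson(p["mean"], size=size)
    if kind == "negative_binomial":
        k = float(p.get("dispersion", 1.0))
        mean = float(p["mean"])
        return rng.negative_binomial(k, k / (k + mean), size=size)
    if kind == "constant":
        return np.full(size, int(p["value"]))
    if kind == "uniform_int":
        return rng.integers(int(p["low"]), int(p["high"]) + 1, size=size)
    raise ConfigError(f"unknown distribution '{kind}'")


# ---------------------------------------------------------------------------
# Truth: localities, infection status, strains, haplotypes
# ---------------------------------------------------------------------------

@dataclass
class SyntheticTruth:
    """Planted ground truth of a simulated survey.

    ``individuals`` has one row per host with columns ``individual_id``,
    ``locality``, ``lineage``, ``infected``, ``strain`` and ``haplotype``
    (empty strings for uninfected hosts).  ``localities`` records the
    planted per-locality prevalence and the locality's dominant strain.
    """

    individuals: pd.DataFrame
    localities: pd.DataFrame
    config: SimulationConfig

    def __post_init__(self):
        ind = self.individuals
        bad = ind[~ind.infected & (ind.haplotype != "")]
        if len(bad):
            raise ValueError("uninfected individuals must not carry a "
                             f"haplotype: {list(bad.individual_id[:5])}")
        bad = ind[ind.infected & (ind.strain == "")]
        if len(bad):
            raise ValueError("infected individuals must carry a strain "
                             f"label: {list(bad.individual_id[:5])}")

    def strain_haplotype_counts(self) -> dict[str, Counter]:
        """Map strain label -> Counter of haplotype strings (multiplicity =
        number of infected individuals carrying the haplotype)."""
        out: dict[str, Counter] = {}
        inf = self.individuals[self.individuals.infected]
        for strain, group in inf.groupby("strain", sort=True):
            out[str(strain)] = Counter(group.haplotype)
        return out


def _founder_haplotypes(config: SimulationConfig,
                        rng: np.random.Generator) -> np.ndarray:
    """Strain founders on {0,1}^n_sites with equal pairwise distances.

    Each founder flips a private block of sites of a shared random base
    haplotype, so every founder pair differs at exactly twice the block
    size, which is at least round(strain_divergence * n_sites).
    """
    n, k = config.n_sites, config.n_strains
    base = rng.integers(0, 2, size=n, dtype=np.int8)
    founders = np.tile(base, (k, 1))
    if k == 1:
        return founders
    block = (config.founder_step_distance() + 1) // 2
    sites = rng.choice(n, size=k * block, replace=False)
    for i in range(k):
        founders[i, sites[i * block:(i + 1) * block]] ^= 1
    return founders


def _truncated_poisson(rng: np.random.Generator, mean: float,
                       kmax: int) -> int:
    """Poisson(mean) right-truncated at kmax (keeps strain clouds inside
    the separability radius the config validation assumes)."""
    if mean == 0:
        return 0
    ks = np.arange(kmax + 1)
    logp = ks * math.log(mean) - mean - np.array(
        [math.lgamma(k + 1) for k in ks])
    p = np.exp(logp - logp.max())
    p /= p.sum()
    return int(rng.choice(ks, p=p))


class _StrainPool:
    """Preferential-attachment pool of within-strain haplotypes.

    The first draw returns the founder; later draws reuse an existing
    haplotype with probability proportional to its multiplicity, or (with
    probability alpha / (n + alpha)) mutate a fresh variant off the
    founder.  This produces the right-skewed spectra seen in real strain
    clouds: one or a few dominant haplotypes plus many rare ones.
    """

    def __init__(self, founder: np.ndarray, config: SimulationConfig,
                 rng: np.random.Generator):
        self.founder = founder
        self.config = config
        self.rng = rng
        self.haps: list[np.ndarray] = []
        self.counts: list[int] = []
        self._index: dict[bytes, int] = {}
        self.kmax = max(1, math.ceil(3 * config.within_strain_mutations))

    def _add(self, hap: np.ndarray) -> int:
        key = hap.tobytes()
        idx = self._index.get(key)
        if idx is None:
            idx = len(self.haps)
            self.haps.append(hap)
            self.counts.append(0)
            self._index[key] = idx
        return idx

    def draw(self) -> str:
        total = sum(self.counts)
        alpha = self.config.haplotype_concentration
        if total == 0:
            idx = self._add(self.founder.copy())
        elif self.rng.random() < alpha / (total + alpha):
            k = _truncated_poisson(self.rng,
                                   self.config.within_strain_mutations,
                                   self.kmax)
            hap = self.founder.copy()
            if k:
                sites = self.rng.choice(self.config.n_sites, size=k,
                                        replace=False)
                hap[sites] ^= 1
            idx = self._add(hap)
        else:
            p = np.asarray(self.counts, dtype=float) / total
            idx = int(self.rng.choice(len(self.counts), p=p))
        self.counts[idx] += 1
        return "".join("01"[b] for b in self.haps[idx])


def simulate_truth(config: SimulationConfig) -> SyntheticTruth:
    """Plant localities, infection statuses, strains and haplotypes.

    Localities are partitioned into ``n_strains`` contiguous blocks of
    "host lineages"; each lineage's localities are dominated by one strain,
    emulating strain dominance by host lineage.
    """
    config.validate()
    rng = _substream(config, "truth")
    founders = _founder_haplotypes(config, rng)
    pools = [_StrainPool(founders[i], config, rng)
             for i in range(config.n_strains)]
    strain_names = [f"S{i + 1}" for i in range(config.n_strains)]

    sizes = config.locality_sizes(rng)
    prevs = config.prevalences()
    ind_rows = []
    loc_rows = []
    for li in range(config.n_localities):
        loc = f"L{li + 1:03d}"
        strain_idx = (li * config.n_strains) // max(config.n_localities, 1)
        strain_idx = min(strain_idx, config.n_strains - 1)
        lineage = f"lineage_{strain_idx + 1}"
        n = int(sizes[li])
        infected = rng.random(n) < prevs[li]
        for j in range(n):
            iid = f"{loc}i{j + 1:03d}"
            if infected[j]:
                hap = pools[strain_idx].draw()
                ind_rows.append((iid, loc, lineage, True,
                                 strain_names[strain_idx], hap))
            else:
                ind_rows.append((iid, loc, lineage, False, "", ""))
        loc_rows.append((loc, lineage, n, float(prevs[li]),
                         strain_names[strain_idx]))
    individuals = pd.DataFrame(
        ind_rows, columns=["individual_id", "locality", "lineage",
                           "infected", "strain", "haplotype"])
    localities = pd.DataFrame(
        loc_rows, columns=["locality", "lineage", "n",
                           "planted_prevalence", "dominant_strain"])
    return SyntheticTruth(individuals, localities, config)


def simulate_strain_haplotypes(config: SimulationConfig
                               ) -> dict[str, Counter]:
    """Planted haplotypes per strain, with multiplicities.

    Returns a map from strain label to a Counter of haplotype strings over
    {0,1}; multiplicities count infected individuals.  Deterministic given
    ``config.seed`` (shares the truth substream with :func:`simulate_truth`).
    """
    return simulate_truth(config).strain_haplotype_counts()


# ---------------------------------------------------------------------------
# Reads and per-site depths
# ---------------------------------------------------------------------------

def _categorical(rng, values, probs, size):
    return np.asarray(values)[rng.choice(len(values), size=size, p=probs)]


def simulate_read_data(config: SimulationConfig, truth: SyntheticTruth
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-read alignment records and a per-site allele-depth table.

    Counts of quality-passing reads (length >= 80 bp, MAPQ > 20, primary
    alignment) are drawn from the infected or uninfected read-count
    distribution; additional failing and flag-masked reads are added so the
    marginal length and MAPQ distributions match the configured ones.
    Depths at variant sites are emitted for infected individuals only and
    scale with each individual's read count when ``depth_scaled_by_reads``.
    """
    if truth.config.config_hash() != config.config_hash():
        raise ConfigError("truth was generated from a different config")
    rng = _substream(config, "reads")
    ind = truth.individuals
    n_ind = len(ind)

    lengths = np.array(sorted(config.read_length_dist))
    lprobs = np.array([config.read_length_dist[v] for v in lengths])
    lprobs = lprobs / lprobs.sum()
    mapqs = np.array(sorted(config.mapq_dist))
    mprobs = np.array([config.mapq_dist[v] for v in mapqs])
    mprobs = mprobs / mprobs.sum()

    pass_len = lengths >= 80
    pass_mq = mapqs > 20
    p_pass = float(lprobs[pass_len].sum() * mprobs[pass_mq].sum())

    n_pass = np.where(
        ind.infected.to_numpy(dtype=bool),
        _sample_counts(config.infected_read_count_dist, rng, n_ind),
        _sample_counts(config.uninfected_read_count_dist, rng, n_ind))
    n_fail = rng.poisson(n_pass * (1.0 - p_pass) / p_pass)
    n_mask = rng.poisson(0.02 * n_pass)

    # passing reads: length and MAPQ conditioned on passing both filters
    lv, lp = lengths[pass_len], lprobs[pass_len] / lprobs[pass_len].sum()
    mv, mp = mapqs[pass_mq], mprobs[pass_mq] / mprobs[pass_mq].sum()
    tot_pass = int(n_pass.sum())
    pass_lengths = _categorical(rng, lv, lp, tot_pass)
    pass_mapqs = _categorical(rng, mv, mp, tot_pass)

    # failing reads: joint (length, mapq) conditioned on failing
    joint = np.outer(lprobs, mprobs)
    fail_mask = ~(pass_len[:, None] & pass_mq[None, :])
    fj = (joint * fail_mask).ravel()
    fj = fj / fj.sum()
    tot_fail = int(n_fail.sum())
    cells = rng.choice(fj.size, size=tot_fail, p=fj)
    fail_lengths = lengths[cells // mapqs.size]
    fail_mapqs = mapqs[cells % mapqs.size]

    # masked reads: secondary/supplementary alignments, unconditioned
    tot_mask = int(n_mask.sum())
    mask_lengths = _categorical(rng, lengths, lprobs, tot_mask)
    mask_mapqs = _categorical(rng, mapqs, mprobs, tot_mask)
    mask_flags = rng.choice(np.array([256, 2048]), size=tot_mask)

    ids = ind.individual_id.to_numpy()
    codes = np.arange(len(ids))
    # group the three read classes per individual without a costly sort
    rep = np.concatenate([np.repeat(codes, n_pass),
                          np.repeat(codes, n_fail),
                          np.repeat(codes, n_mask)])
    order = np.argsort(rep, kind="stable")
    flags = np.concatenate([np.zeros(tot_pass, dtype=np.int32),
                            np.zeros(tot_fail, dtype=np.int32),
                            mask_flags.astype(np.int32)])[order]
    mapq_all = np.concatenate([pass_mapqs, fail_mapqs,
                               mask_mapqs]).astype(np.int32)[order]
    len_all = np.concatenate([pass_lengths, fail_lengths,
                              mask_lengths]).astype(np.int32)[order]
    reads = pd.DataFrame({
        "individual_id": pd.Categorical.from_codes(rep[order], ids),
        "flag": flags,
        "mapq": mapq_all,
        "read_length": len_all,
    })

    depths = _simulate_depths(config, truth, n_pass, _substream(config,
                                                                "depths"))
    return reads, depths


def _simulate_depths(config, truth, n_pass, rng) -> pd.DataFrame:
    ind = truth.individuals
    inf_mask = ind.infected.to_numpy(dtype=bool)
    inf_ids = ind.individual_id.to_numpy()[inf_mask]
    haps = ind.haplotype.to_numpy()[inf_mask]
    n_inf = inf_ids.size
    n_sites = config.n_sites
    if n_inf == 0:
        return pd.DataFrame(columns=["site", "individual_id",
                                     "ref_depth", "alt_depth"])
    kind, params = config.depth_per_site_dist
    if config.depth_scaled_by_reads and kind in ("poisson",
                                                 "negative_binomial"):
        base = _dist_mean(config.depth_per_site_dist)
        scale = n_pass[inf_mask] / max(
            _dist_mean(config.infected_read_count_dist), 1.0)
        lam = np.clip(base * scale, 0.0, None)
        depth = rng.poisson(lam[:, None], size=(n_inf, n_sites))
    else:
        depth = _sample_counts(config.depth_per_site_dist, rng,
                               n_inf * n_sites).reshape(n_inf, n_sites)
    alleles = np.frombuffer(
        "".join(haps).encode(), dtype=np.uint8
    ).reshape(n_inf, n_sites) - ord("0")
    alt_depth = depth * alleles
    ref_depth = depth * (1 - alleles)
    sites = np.array([f"site{j + 1:04d}" for j in range(n_sites)])
    return pd.DataFrame({
        "site": np.tile(sites, n_inf),
        "individual_id": np.repeat(inf_ids, n_sites),
        "ref_depth": ref_depth.ravel(),
        "alt_depth": alt_depth.ravel(),
    })


# ---------------------------------------------------------------------------
# PCR gold labels
# ---------------------------------------------------------------------------

def simulate_pcr_labels(truth: SyntheticTruth, sensitivity: float,
                        specificity: float, seed: int,
                        subset_size: int | None = 128) -> pd.DataFrame:
    """Imperfect PCR assay results for a calibration subset.

    ``P(positive | infected) = sensitivity`` and
    ``P(negative | uninfected) = specificity``.  ``subset_size`` hosts are
    sampled without replacement (all hosts when None).
    """
    if not 0 <= sensitivity <= 1 or not 0 <= specificity <= 1:
        raise ConfigError("sensitivity and specificity must be in [0, 1]")
    rng = np.random.default_rng(seed)
    ind = truth.individuals
    if subset_size is None or subset_size >= len(ind):
        subset = ind
    else:
        idx = np.sort(rng.choice(len(ind), size=subset_size, replace=False))
        subset = ind.iloc[idx]
    u = rng.random(len(subset))
    infected = subset.infected.to_numpy()
    positive = np.where(infected, u < sensitivity, u >= specificity)
    return pd.DataFrame({
        "individual_id": subset.individual_id.to_numpy(),
        "pcr_positive": positive,
    })


# ---------------------------------------------------------------------------
# Writers (text SAM subset, TSV, CSV)
# ---------------------------------------------------------------------------

def _header_comment(config: SimulationConfig) -> str:
    return f"config_hash={config.config_hash()} seed={config.seed}"


def write_sam(reads: pd.DataFrame, path, config: SimulationConfig,
              ref_name: str = "wolb_ref", ref_len: int = 1_620_000,
              id_delimiter: str = "|") -> None:
    """Write reads as a text SAM subset (no sequences; length in CIGAR)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        fh.write(f"@SQ\tSN:{ref_name}\tLN:{ref_len}\n")
        fh.write(f"@CO\t{_header_comment(config)}\n")
        serial = 0
        for row in reads.itertuples(index=False):
            serial += 1
            fh.write(f"{row.individual_id}{id_delimiter}r{serial}\t"
                     f"{row.flag}\t{ref_name}\t1\t{row.mapq}\t"
                     f"{row.read_length}M\t*\t0\t0\t*\t*\n")


def write_reads_tsv(reads: pd.DataFrame, path,
                    config: SimulationConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {_header_comment(config)}\n")
        fh.write("# individual_id\tflag\tmapq\tread_length\n")
        reads.to_csv(fh, sep="\t", header=False, index=False)


def write_depths_tsv(depths: pd.DataFrame, path,
                     config: SimulationConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {_header_comment(config)}\n")
        depths.to_csv(fh, sep="\t", index=False)
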