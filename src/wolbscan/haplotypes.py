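"""Haploid haplotype calling from per-site allele depths, with the
standard conservative filters: biallelic sites only, sites with at most 25%
missingness among infected hosts, then only individuals with complete data
across the retained sites.

Endosymbionts are effectively clonal within a single infection, so a
haploid model is used: at each site the called allele is simply the one
with the larger quality-passing depth; a site with no coverage is missing.
Multiple infections would require a polyploid model and are out of scope.

Formats: haploid VCF 4.2 (GT 0, 1 or .), NEXUS for downstream coalescent
tools, and a FASTA rendering (0 -> A, 1 -> C) for tool compatibility.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from wolbscan.errors import ConfigError, ParseError, WolbscanError

__all__ = [
    "HaplotypeMatrix",
    "call_haploid",
    "filter_sites",
    "filter_complete_individuals",
    "write_vcf",
    "read_vcf",
    "export_nexus",
    "write_haplotype_fasta",
    "read_haplotype_fasta",
]

MISSING = -1


@dataclass
class HaplotypeMatrix:
    """Individuals x sites matrix of haploid alleles.

    ``alleles`` holds 0 (reference), 1 (alternate) or -1 (missing), one row
    per individual in ``individuals`` order and one column per site in
    ``sites`` order.
    """

    individuals: list[str]
    sites: list[str]
    alleles: np.ndarray  # int8, shape (n_individuals, n_sites)

    def __post_init__(self):
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.shape != (len(self.individuals), len(self.sites)):
            raise ValueError("allele matrix shape does not match labels")
        bad = ~np.isin(self.alleles, (0, 1, MISSING))
        if bad.any():
            raise ValueError("alleles must be 0, 1 or -1 (missing)")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def site_missingness(self, individuals: Sequence[str] | None = None
                         ) -> np.ndarray:
        """Fraction missing per site, optionally over a subset of rows."""
        a = self.alleles
        if individuals is not None:
            keep = set(individuals)
            rows = [i for i, iid in enumerate(self.individuals)
                    if iid in keep]
            a = a[rows]
        if a.shape[0] == 0:
            return np.zeros(self.n_sites)
        return (a == MISSING).mean(axis=0)

    def complete_rows(self) -> np.ndarray:
        return ~(self.alleles == MISSING).any(axis=1)

    def haplotype_strings(self) -> dict[str, str]:
        """Individual -> '0'/'1' string; only for complete rows."""
        out = {}
        for i, iid in enumerate(self.individuals):
            row = self.alleles[i]
            if (row == MISSING).any():
                raise WolbscanError(
                    f"individual {iid} has missing data; apply "
                    "filter_complete_individuals first")
            out[iid] = "".join("01"[v] for v in row)
        return out

    def unique_haplotypes(self) -> tuple[dict[str, str], dict[str, int],
                                         dict[str, str]]:
        """Deduplicate complete haplotypes.

        Returns (label -> haplotype string, label -> multiplicity,
        individual -> label).  Labels are H001, H002, ... ordered by
        decreasing multiplicity then haplotype string.
        """
        strings = self.haplotype_strings()
        counts: dict[str, int] = {}
        for s in strings.values():
            counts[s] = counts.get(s, 0) + 1
        ordered = sorted(counts, key=lambda s: (-counts[s], s))
        label_of = {s: f"H{i + 1:03d}" for i, s in enumerate(ordered)}
        haps = {label_of[s]: s for s in ordered}
        mult = {label_of[s]: counts[s] for s in ordered}
        ind_to_label = {iid: label_of[s] for iid, s in strings.items()}
        return haps, mult, ind_to_label


def call_haploid(depths: pd.DataFrame, tie: str = "missing"
                 ) -> HaplotypeMatrix:
    """Call one allele (or missing) per individual and site from depths.

    ``depths`` is a long-format table with columns ``site``,
    ``individual_id``, ``ref_depth``, ``alt_depth`` of quality-passing read
    counts.  The called allele is the argmax of the two depths; a site with
    zero total depth is missing.  Equal non-zero depths are missing under
    the default conservative tie rule (``tie='missing'``); ``tie='ref'``
    or ``tie='alt'`` resolve ties to a fixed allele instead.
    """
    if tie not in ("missing", "ref", "alt"):
        raise ConfigError(f"unknown tie rule '{tie}'")
    required = {"site", "individual_id", "ref_depth", "alt_depth"}
    missing_cols = required - set(depths.columns)
    if missing_cols:
        raise ConfigError(f"depth table lacks columns {sorted(missing_cols)}")
    if len(depths) and ((depths.ref_depth < 0).any()
                        or (depths.alt_depth < 0).any()):
        raise ConfigError("depths must be non-negative")
    ref = depths.pivot_table(index="individual_id", columns="site",
                             values="ref_depth", aggfunc="sum",
                             fill_value=0, sort=True)
    alt = depths.pivot_table(index="individual_id", columns="site",
                             values="alt_depth", aggfunc="sum",
                             fill_value=0, sort=True)
    alt = alt.reindex(index=ref.index, columns=ref.columns, fill_value=0)
    r, a = ref.to_numpy(), alt.to_numpy()
    alleles = np.full(r.shape, MISSING, dtype=np.int8)
    alleles[r > a] = 0
    alleles[a > r] = 1
    ties = (r == a) & (r > 0)
    if tie == "ref":
        alleles[ties] = 0
    elif tie == "alt":
        alleles[ties] = 1
    return HaplotypeMatrix(list(ref.index), list(ref.columns), alleles)


def filter_sites(matrix: HaplotypeMatrix, max_missing: float = 0.25,
                 individuals: Sequence[str] | None = None
                 ) -> HaplotypeMatrix:
    """Drop sites whose missing fraction exceeds ``max_missing``.

    The denominator is ``individuals`` when given (normally the infected
    subset: uninfected hosts have no endosymbiont reads at all, and
    counting them would discard every site), otherwise all rows.
    """
    if not 0 <= max_missing <= 1:
        raise ConfigError("max_missing must be in [0, 1]")
    frac = matrix.site_missingness(individuals)
    keep = frac <= max_missing
    return HaplotypeMatrix(
        list(matrix.individuals),
        [s for s, k in zip(matrix.sites, keep) if k],
        matrix.alleles[:, keep])


def filter_complete_individuals(matrix: HaplotypeMatrix) -> HaplotypeMatrix:
    """Keep only individuals with no missing calls at any retained site."""
    keep = matrix.complete_rows()
    return HaplotypeMatrix(
        [iid for iid, k in zip(matrix.individuals, keep) if k],
        list(matrix.sites),
        matrix.alleles[keep])


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_VCF_CONTIG = "wolb_ref"


def write_vcf(matrix: HaplotypeMatrix, path,
              ref_allele: str = "A", alt_allele: str = "C") -> None:
    """Write a haploid VCF 4.2 (GT per sample: 0, 1 or '.')."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={_VCF_CONTIG},length={10 * 10**6}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,'
                 'Description="Haploid genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.individuals) + "\n")
        for j, site in enumerate(matrix.sites):
            col = matrix.alleles[:, j]
            gts = "\t".join("." if v == MISSING else str(int(v))
                            for v in col)
            fh.write(f"{_VCF_CONTIG}\t{j + 1}\t{site}\t{ref_allele}\t"
                     f"{alt_allele}\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf(path) -> HaplotypeMatrix:
    """Read a haploid, biallelic VCF back into a matrix.

    Rejects records with more than one ALT allele and samples with diploid
    (or higher) genotypes, naming the offending record.
    """
    import pysam

    try:
        vf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise ParseError(f"cannot parse VCF: {exc}", path=path) from exc
    individuals = list(vf.header.samples)
    sites: list[str] = []
    rows: list[np.ndarray] = []
    with vf:
        for k, rec in enumerate(vf.fetch() if vf.index else vf, start=1):
            alts = rec.alts or ()
            if len(alts) != 1:
                raise ParseError(
                    f"record {rec.id or rec.pos} is not biallelic "
                    f"({len(alts)} ALT alleles)", path=path, line=k)
            col = np.full(len(individuals), MISSING, dtype=np.int8)
            for i, iid in enumerate(individuals):
                gt = rec.samples[iid]["GT"]
                if gt is None or len(gt) == 0 or gt[0] is None:
                    continue
                if len(gt) > 1:
                    raise ParseError(
                        f"sample {iid} at {rec.id or rec.pos} has ploidy "
                        f"{len(gt)}; expected haploid genotypes",
                        path=path, line=k)
                if gt[0] not in (0, 1):
                    raise ParseError(
                        f"sample {iid} at {rec.id or rec.pos} has allele "
                        f"index {gt[0]}", path=path, line=k)
                col[i] = gt[0]
            sites.append(rec.id or f"{rec.chrom}:{rec.pos}")
            rows.append(col)
    alleles = (np.array(rows, dtype=np.int8).T if rows
               else np.empty((len(individuals), 0), dtype=np.int8))
    return HaplotypeMatrix(individuals, sites, alleles)


# ---------------------------------------------------------------------------
# NEXUS / FASTA export
# ---------------------------------------------------------------------------

def export_nexus(matrix: HaplotypeMatrix, path) -> None:
    """Write complete haplotypes as a NEXUS DATA block (symbols 0/1)."""
    if matrix.n_individuals == 0 or matrix.n_sites == 0:
        raise WolbscanError("nothing to export: empty haplotype matrix")
    strings = matrix.haplotype_strings()
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nBEGIN DATA;\n")
        fh.write(f"  DIMENSIONS NTAX={matrix.n_individuals} "
                 f"NCHAR={matrix.n_sites};\n")
        fh.write('  FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=? '
                 "GAP=-;\n")
        fh.write("  MATRIX\n")
        width = max(len(i) for i in matrix.individuals) + 2
        for iid in matrix.individuals:
            fh.write(f"    {iid:<{width}}{strings[iid]}\n")
        fh.write("  ;\nEND;\n")


_FASTA_ENCODING = {0: "A", 1: "C"}


def write_haplotype_fasta(matrix: HaplotypeMatrix, path) -> None:
    """Write complete haplotypes as FASTA, 0 -> A and 1 -> C.

    The encoding is recorded in every record description so external tools
    and the reader can invert it.
    """
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    strings = matrix.haplotype_strings()
    records = [
        SeqRecord(Seq("".join(_FASTA_ENCODING[int(c)] for c in s)),
                  id=iid, description="encoding=0:A,1:C")
        for iid, s in strings.items()]
    SeqIO.write(records, str(path), "fasta")


def read_haplotype_fasta(path) -> dict[str, str]:
    """Read an encoded haplotype FASTA back to '0'/'1' strings."""
    from Bio import SeqIO

    decode = {v: str(k) for k, v in _FASTA_ENCODING.items()}
    out = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            out[rec.id] = "".join(decode[c] for c in str(rec.seq).upper())
        except KeyError as exc:
            raise ParseError(
                f"record {rec.id} contains symbol {exc} outside the "
                "0/1 encoding", path=path) from exc
    return out
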