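"""Locality- and lineage-level prevalence and strain-distribution
summaries.

The package ships a transcription of a 107-locality *Lycaeides* survey
table (per locality: host species/lineage, hosts sampled, hosts infected,
and the endosymbiont haplotypes observed with their counts, e.g.
``A1:14;A8:1``).  Haplotype labels follow the strain-prefix convention:
the leading letter names the strain (A, B, C major; D-J rare), the number
distinguishes haplotypes within a strain.  The same summaries run on any
user table with the identical schema, or on call sets produced by the
detection pipeline.

Counts are exact integers and rates exact rationals; rendering rounds at
output time only.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from fractions import Fraction
from importlib import resources
from typing import Callable, Mapping

import pandas as pd

from wolbscan.errors import ConfigError, ParseError

__all__ = [
    "LocalityTable",
    "load_locality_table",
    "locality_stats",
    "lineage_stats",
    "strain_tallies",
    "cooccurrence_table",
    "default_lineage_map",
]

_HAP_RE = re.compile(r"^[A-Z]\d+$")


def parse_haplotype_counts(text: str) -> dict[str, int]:
    """Parse ``'A1:14;B2:3'`` into ``{'A1': 14, 'B2': 3}``."""
    if not text or pd.isna(text):
        return {}
    out: dict[str, int] = {}
    for part in str(text).split(";"):
        part = part.strip()
        if not part:
            continue
        try:
            label, count = part.split(":")
            count = int(count)
        except ValueError as exc:
            raise ParseError(
                f"malformed haplotype count '{part}'") from exc
        if not _HAP_RE.match(label):
            raise ParseError(f"unparseable haplotype label '{label}'")
        out[label] = out.get(label, 0) + count
    return out


@dataclass
class LocalityTable:
    """Validated per-locality survey table.

    ``frame`` columns: number, locality, species, n, n_infected,
    data_source, haplotypes (semicolon-separated ``label:count``).
    """

    frame: pd.DataFrame

    def __post_init__(self):
        f = self.frame
        required = {"number", "locality", "species", "n", "n_infected",
                    "haplotypes"}
        missing = required - set(f.columns)
        if missing:
            raise ConfigError(
                f"locality table lacks columns {sorted(missing)}")
        for row in f.itertuples(index=False):
            if not 0 <= row.n_infected <= row.n:
                raise ParseError(
                    f"locality '{row.locality}' (no. {row.number}): "
                    f"infected count {row.n_infected} outside [0, {row.n}]")
            haps = parse_haplotype_counts(row.haplotypes)
            total = sum(haps.values())
            if total > row.n_infected:
                # Survey tables occasionally carry this inconsistency
                # (haplotype tallies drawn from a different denominator);
                # the table is kept verbatim and the quirk is surfaced,
                # not corrected.
                warnings.warn(
                    f"locality '{row.locality}' (no. {row.number}): "
                    f"haplotype counts sum to {total} > infected "
                    f"{row.n_infected}", stacklevel=2)

    def haplotype_counts(self) -> list[dict[str, int]]:
        return [parse_haplotype_counts(t) for t in self.frame.haplotypes]

    def rates(self) -> list[Fraction]:
        return [Fraction(int(i), int(n))
                for i, n in zip(self.frame.n_infected, self.frame.n)]

    def __len__(self) -> int:
        return len(self.frame)


def load_locality_table(path=None) -> LocalityTable:
    """Load the packaged survey table, or a user CSV of the same schema."""
    if path is None:
        src = resources.files("wolbscan").joinpath(
            "data/locality_table.csv")
        with resources.as_file(src) as p:
            frame = pd.read_csv(p, keep_default_na=False)
    else:
        frame = pd.read_csv(path, keep_default_na=False)
    return LocalityTable(frame)


def locality_stats(table: LocalityTable,
                   cutoffs: tuple[float, ...] = (0.9,)) -> dict:
    """Survey-wide aggregates of per-locality infection frequencies.

    Frequency cutoffs are strict (a locality at exactly the cutoff is not
    counted above it); the mean rate is the unweighted mean over
    localities, kept as an exact rational.
    """
    f = table.frame
    rates = table.rates()
    n_loc = len(f)
    stats = {
        "n_localities": n_loc,
        "localities_infected": int((f.n_infected > 0).sum()),
        "localities_at_100pct": sum(r == 1 for r in rates),
        "total_n": int(f.n.sum()),
        "total_infected": int(f.n_infected.sum()),
        "mean_rate": (sum(rates, Fraction(0)) / n_loc if n_loc
                      else Fraction(0)),
    }
    for c in cutoffs:
        frac = Fraction(c).limit_denominator(10**6)
        stats[f"localities_above_{c:g}"] = sum(r > frac for r in rates)
    return stats


def default_lineage_map(table: LocalityTable) -> dict[int, str]:
    """Locality number -> host lineage.

    Nominal species are their own lineages; localities recorded only as
    'Hybrid' are split by geography into the Jackson, Warner, Hinkley,
    Jarbidge and Sierra/Whites hybrid lineages following the survey's
    locality numbering.
    """
    out = {}
    for row in table.frame.itertuples(index=False):
        sp = str(row.species)
        num = int(row.number)
        if sp != "Hybrid":
            out[num] = sp
        elif 82 <= num <= 92:
            out[num] = "Jackson Hybrid"
        elif 93 <= num <= 95:
            out[num] = "Warner Hybrid"
        elif num == 96:
            out[num] = "Hinkley Hybrid"
        elif num == 97:
            out[num] = "Jarbidge Hybrid"
        else:
            out[num] = "Sierra/Whites Hybrid"
    return out


def _strain_of(label: str, split_a: bool = True) -> str:
    """Strain accounting label of a haplotype.

    A1 and A2, the two dominant A-group haplotypes, are treated as strains
    in lineage accounting (``split_a=True``); remaining A haplotypes fall
    in 'A-other'.  Other prefixes map to their leading letter.
    """
    prefix = label[0]
    if split_a and prefix == "A":
        return label if label in ("A1", "A2") else "A-other"
    return prefix


def lineage_stats(table: LocalityTable,
                  lineage_map: Mapping[int, str] | Callable[[int], str]
                  | None = None) -> pd.DataFrame:
    """Per-lineage totals, infection rate and dominant/minor strains.

    Every locality must map to exactly one lineage.  The rate is total
    infected over total sampled, rounded to two decimals in the rendered
    column (the exact Fraction is also returned).  Dominant/minor strains
    are tallied at the accounting granularity that treats haplotypes A1
    and A2 as separate strains; rare strains (prefixes beyond C) and
    unsplit A variants are excluded from the dominant/minor listing.
    """
    if lineage_map is None:
        lineage_map = default_lineage_map(table)
    if callable(lineage_map):
        mapper = lineage_map
    else:
        def mapper(num, _m=lineage_map):
            if num not in _m:
                raise ConfigError(f"locality number {num} has no lineage")
            return _m[num]
    f = table.frame
    rows: dict[str, dict] = {}
    for row, haps in zip(f.itertuples(index=False),
                         table.haplotype_counts()):
        lin = mapper(int(row.number))
        agg = rows.setdefault(lin, {"localities": [], "n": 0,
                                    "n_infected": 0, "strains": {}})
        agg["localities"].append(int(row.number))
        agg["n"] += int(row.n)
        agg["n_infected"] += int(row.n_infected)
        for hap, count in haps.items():
            s = _strain_of(hap)
            agg["strains"][s] = agg["strains"].get(s, 0) + count
    out = []
    for lin in sorted(rows):
        agg = rows[lin]
        rate = Fraction(agg["n_infected"], agg["n"]) if agg["n"] else None
        majors = {s: c for s, c in agg["strains"].items()
                  if s in ("A1", "A2", "B", "C")}
        dominant = max(majors, key=lambda s: (majors[s], s)) \
            if majors else ""
        minors = sorted(s for s in majors if s != dominant)
        out.append({
            "lineage": lin,
            "localities": ",".join(map(str, sorted(agg["localities"]))),
            "n": agg["n"],
            "n_infected": agg["n_infected"],
            "rate": None if rate is None else round(float(rate), 2),
            "rate_exact": rate,
            "dominant_strain": dominant,
            "minor_strains": ",".join(minors),
        })
    return pd.DataFrame(out)


def strain_tallies(table: LocalityTable) -> pd.DataFrame:
    """Per-strain individual and distinct-haplotype counts.

    Strains are haplotype prefixes (leading letter).  The returned frame
    has one row per prefix plus columns flagging rare strains (every
    prefix beyond the majors A, B, C).
    """
    counts: dict[str, int] = {}
    labels: dict[str, set] = {}
    for haps in table.haplotype_counts():
        for hap, count in haps.items():
            s = hap[0]
            counts[s] = counts.get(s, 0) + count
            labels.setdefault(s, set()).add(hap)
    rows = [(s, counts[s], len(labels[s]), s not in ("A", "B", "C"))
            for s in sorted(counts)]
    return pd.DataFrame(rows, columns=["strain", "n_individuals",
                                       "n_haplotypes", "rare"])


def cooccurrence_table(table: LocalityTable
                       ) -> tuple[pd.DataFrame, dict]:
    """Strains present per locality and counts of multi-strain localities.

    Reported at two granularities: coarse (prefixes A, B, C; A1/A2
    collapsed into A) and fine (A1 and A2 as separate strains alongside B
    and C).  Rare-strain prefixes are listed but not counted as major.
    """
    rows = []
    multi_coarse = multi_fine = 0
    for row, haps in zip(table.frame.itertuples(index=False),
                         table.haplotype_counts()):
        coarse = {h[0] for h in haps if h[0] in "ABC"}
        fine = {_strain_of(h) for h in haps if h[0] in "ABC"}
        fine.discard("A-other")
        rare = sorted({h[0] for h in haps if h[0] not in "ABC"})
        multi_coarse += len(coarse) > 1
        multi_fine += len(fine) > 1
        rows.append({
            "number": int(row.number),
            "locality": row.locality,
            "major_strains": ",".join(sorted(coarse)),
            "major_strains_fine": ",".join(sorted(fine)),
            "rare_strains": ",".join(rare),
            "n_major_strains": len(coarse),
        })
    summary = {
        "multi_strain_localities_coarse": multi_coarse,
        "multi_strain_localities_fine": multi_fine,
    }
    return pd.DataFrame(rows), summary
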