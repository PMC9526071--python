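"""Reading alignment records and summarising them per host individual.

The pipeline never aligns reads itself; it consumes alignment summaries —
either a text SAM subset of endosymbiont-mapped reads or an equivalent
4-column TSV (individual_id, flag, mapq, read_length).  Individual identity
is taken from the read-name prefix before a configurable delimiter, the
usual GBS demultiplexing convention.

Filtering follows the standard samtools idiom: reads are counted as
quality-passing when MAPQ is strictly greater than ``mapq_min``, length is
at least ``len_min`` and no bit of ``exclude_mask`` (default 2432 =
secondary + QC-fail + supplementary) is set.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from statistics import median
from typing import Iterator, Mapping, NamedTuple

import pandas as pd

from wolbscan.errors import ConfigError, ParseError

__all__ = [
    "ReadRecord",
    "IndividualReadSummary",
    "read_alignments",
    "summarize_reads",
    "merge_summaries",
    "summaries_to_frame",
    "write_summary_csv",
    "DEFAULT_EXCLUDE_MASK",
]

DEFAULT_EXCLUDE_MASK = 2432  # secondary (256) + QC fail (512) + suppl (2048)


class ReadRecord(NamedTuple):
    """One endosymbiont-mapped alignment record."""

    individual_id: str
    flag: int
    mapq: int
    read_length: int


@dataclass
class IndividualReadSummary:
    """Per-individual counts of flag/MAPQ-passing reads by length.

    ``length_counts`` tallies read lengths among records that already pass
    the flag mask and MAPQ filter, so the count passing any length
    threshold can be recovered without re-reading the alignments.
    """

    individual_id: str
    n_total: int = 0
    length_counts: Counter = field(default_factory=Counter)

    def n_pass(self, len_min: int = 80) -> int:
        return sum(c for ln, c in self.length_counts.items()
                   if ln >= len_min)

    def median_length(self) -> float | None:
        if not self.length_counts:
            return None
        return float(median(
            ln for ln, c in self.length_counts.items() for _ in range(c)))


def read_alignments(path, dialect: str = "sam",
                    id_delimiter: str = "|") -> Iterator[ReadRecord]:
    """Stream :class:`ReadRecord` from a text SAM subset or a 4-column TSV.

    Header lines (``@`` in SAM, ``#`` in TSV) are skipped; records preserve
    input order.  Malformed lines raise :class:`ParseError` naming the line.
    """
    if dialect == "sam":
        yield from _read_sam(path, id_delimiter)
    elif dialect == "tsv":
        yield from _read_tsv(path)
    else:
        raise ConfigError(f"unknown alignment dialect '{dialect}' "
                          "(expected 'sam' or 'tsv')")


def _read_sam(path, id_delimiter: str) -> Iterator[ReadRecord]:
    import pysam

    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for i, rec in enumerate(fh, start=1):
            try:
                qname = rec.query_name or ""
                length = rec.query_length or rec.infer_read_length()
                if not length:
                    raise ValueError("cannot determine read length "
                                     "(no sequence and no CIGAR)")
                yield ReadRecord(qname.split(id_delimiter)[0],
                                 int(rec.flag),
                                 int(rec.mapping_quality), int(length))
            except (ValueError, TypeError) as exc:
                raise ParseError(f"malformed SAM record: {exc}",
                                 path=path, line=i) from exc


def _read_tsv(path) -> Iterator[ReadRecord]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ParseError(
                    f"expected 4 tab-separated fields, got {len(parts)}",
                    path=path, line=lineno)
            try:
                yield ReadRecord(parts[0], int(parts[1]), int(parts[2]),
                                 int(parts[3]))
            except ValueError as exc:
                raise ParseError(f"malformed TSV record: {exc}",
                                 path=path, line=lineno) from exc


def summarize_reads(records, mapq_min: int = 20, len_min: int = 1,
                    exclude_mask: int = DEFAULT_EXCLUDE_MASK
                    ) -> dict[str, IndividualReadSummary]:
    """Summarise alignment records per individual.

    ``records`` may be an iterable of :class:`ReadRecord` or a DataFrame
    with the same columns (fast path for large simulations).  A read counts
    toward the length histogram when ``flag & exclude_mask == 0`` and
    ``mapq > mapq_min`` (strict).  ``len_min`` here only restricts the
    histogram's lower bound; detection thresholds apply their own length
    cut via :meth:`IndividualReadSummary.n_pass`.
    """
    if mapq_min < 0:
        raise ConfigError("mapq_min must be >= 0")
    if len_min < 1:
        raise ConfigError("len_min must be >= 1")
    if isinstance(records, pd.DataFrame):
        return _summarize_frame(records, mapq_min, len_min, exclude_mask)
    out: dict[str, IndividualReadSummary] = {}
    for rec in records:
        s = out.get(rec.individual_id)
        if s is None:
            s = out[rec.individual_id] = IndividualReadSummary(
                rec.individual_id)
        s.n_total += 1
        if (rec.flag & exclude_mask) == 0 and rec.mapq > mapq_min \
                and rec.read_length >= len_min:
            s.length_counts[rec.read_length] += 1
    return out


def _summarize_frame(df: pd.DataFrame, mapq_min, len_min, exclude_mask):
    out = {iid: IndividualReadSummary(iid, int(n))
           for iid, n in df.groupby("individual_id", sort=False,
                                    observed=False).size().items()}
    keep = ((df.flag.to_numpy() & exclude_mask) == 0) \
        & (df.mapq.to_numpy() > mapq_min) \
        & (df.read_length.to_numpy() >= len_min)
    counts = (df[keep].groupby(["individual_id", "read_length"],
                               sort=False, observed=True).size())
    for (iid, ln), c in counts.items():
        out[iid].length_counts[int(ln)] = int(c)
    return out


def merge_summaries(*summary_maps: Mapping[str, IndividualReadSummary]
                    ) -> dict[str, IndividualReadSummary]:
    """Merge summaries of disjoint record streams (summarisation is
    additive over concatenation)."""
    out: dict[str, IndividualReadSummary] = {}
    for m in summary_maps:
        for iid, s in m.items():
            t = out.get(iid)
            if t is None:
                out[iid] = IndividualReadSummary(
                    iid, s.n_total, Counter(s.length_counts))
            else:
                t.n_total += s.n_total
                t.length_counts.update(s.length_counts)
    return out


def summaries_to_frame(summaries: Mapping[str, IndividualReadSummary],
                       len_min: int = 80) -> pd.DataFrame:
    rows = [(s.individual_id, s.n_pass(len_min), s.n_total,
             s.median_length()) for s in summaries.values()]
    return pd.DataFrame(rows, columns=["individual_id", "n_pass",
                                       "n_total", "median_length"])


def write_summary_csv(summaries, path, len_min: int = 80) -> None:
    summaries_to_frame(summaries, len_min).to_csv(path, index=False)
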