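"""Infection calling from read summaries and threshold calibration.

A host is called infected when it has at least ``min_reads`` quality-passing
endosymbiont-mapped reads of at least ``min_len`` bp.  The threshold pair is
calibrated against gold-standard (PCR) infection labels by sweeping a grid
and scoring accuracy, false-negative rate and false-positive rate; ties in
accuracy are broken toward the smallest read threshold.

Rates are kept as exact rationals internally and rendered to three decimals
in tabular output.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Sequence

import pandas as pd

from wolbscan.alignment import IndividualReadSummary
from wolbscan.errors import ConfigError, WolbscanError

__all__ = [
    "InfectionCallSet",
    "ConfusionStats",
    "classify_infection",
    "confusion_vs_gold",
    "threshold_sweep",
    "prevalence_by_group",
    "DEFAULT_READ_GRID",
]

# Log-style grid over the plausible range of read thresholds, mirroring how
# detection-threshold sweeps are usually examined on a log axis; includes
# the default detection threshold of 5 reads.
DEFAULT_READ_GRID = (1, 5, 10, 20, 50, 100, 200, 500, 1000)


@dataclass
class InfectionCallSet:
    """Infected/uninfected calls under one threshold pair."""

    threshold_reads: int
    threshold_length: int
    calls: dict[str, bool]

    @property
    def n_infected(self) -> int:
        return sum(self.calls.values())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"individual_id": list(self.calls),
             "infected": list(self.calls.values())})


@dataclass
class ConfusionStats:
    """Concordance of infection calls with gold-standard labels.

    ``fnr`` is P(called uninfected | gold infected), ``fpr`` is
    P(called infected | gold uninfected).  A rate whose denominator is
    empty is reported as None (missing), never as zero.
    """

    threshold_reads: int
    threshold_length: int
    accuracy: Fraction
    fnr: Fraction | None
    fpr: Fraction | None
    n_compared: int
    n_gold_without_summary: int = 0

    def as_row(self) -> dict:
        def render(x):
            return None if x is None else round(float(x), 3)
        return {
            "min_reads": self.threshold_reads,
            "min_len": self.threshold_length,
            "accuracy": render(self.accuracy),
            "fnr": render(self.fnr),
            "fpr": render(self.fpr),
            "n_compared": self.n_compared,
        }


def classify_infection(summaries: Mapping[str, IndividualReadSummary],
                       min_reads: int = 5,
                       min_len: int = 80) -> InfectionCallSet:
    """Call every summarised individual infected or uninfected.

    Infected iff the count of quality-passing reads of at least ``min_len``
    bp is at least ``min_reads``.
    """
    if min_reads < 1:
        raise ConfigError("min_reads must be >= 1")
    if min_len < 1:
        raise ConfigError("min_len must be >= 1")
    calls = {iid: s.n_pass(min_len) >= min_reads
             for iid, s in summaries.items()}
    return InfectionCallSet(min_reads, min_len, calls)


def confusion_vs_gold(callset: InfectionCallSet,
                      gold_labels: Mapping[str, bool]) -> ConfusionStats:
    """Score calls against gold labels.

    Individuals in the gold set without a read summary are treated as
    having zero mapped reads, i.e. called uninfected (that is what absence
    from the alignment output means); their number is reported.
    Individuals with calls but no gold label are ignored.
    """
    if not gold_labels:
        raise WolbscanError("no gold labels supplied")
    tp = tn = fp = fn = 0
    missing = 0
    for iid, gold in gold_labels.items():
        called = callset.calls.get(iid)
        if called is None:
            called = False
            missing += 1
        if gold and called:
            tp += 1
        elif gold and not called:
            fn += 1
        elif not gold and called:
            fp += 1
        else:
            tn += 1
    n = tp + tn + fp + fn
    if n == 0:
        raise WolbscanError("no overlap between calls and gold labels")
    acc = Fraction(tp + tn, n)
    fnr = Fraction(fn, tp + fn) if (tp + fn) else None
    fpr = Fraction(fp, tn + fp) if (tn + fp) else None
    return ConfusionStats(callset.threshold_reads, callset.threshold_length,
                          acc, fnr, fpr, n, missing)


def threshold_sweep(summaries: Mapping[str, IndividualReadSummary],
                    gold_labels: Mapping[str, bool],
                    read_grid: Sequence[int] = DEFAULT_READ_GRID,
                    len_grid: Sequence[int] = (80,)
                    ) -> tuple[pd.DataFrame, list[ConfusionStats]]:
    """Score every (min_reads, min_len) pair on the grids.

    Returns a DataFrame (one row per pair, rates to three decimals, the
    argmax-accuracy row flagged in column ``best``) plus the exact
    :class:`ConfusionStats`.  Accuracy ties are broken toward smaller
    ``min_reads``, then smaller ``min_len``.
    """
    if not read_grid or not len_grid:
        raise ConfigError("threshold grids must be non-empty")
    stats: list[ConfusionStats] = []
    for min_len in sorted(set(len_grid)):
        for min_reads in sorted(set(read_grid)):
            cs = confusion_vs_gold(
                classify_infection(summaries, min_reads, min_len),
                gold_labels)
            stats.append(cs)
    best_acc = max(s.accuracy for s in stats)
    best = min((s for s in stats if s.accuracy == best_acc),
               key=lambda s: (s.threshold_reads, s.threshold_length))
    rows = []
    for s in stats:
        row = s.as_row()
        row["best"] = (s is best)
        row["tied_with_best"] = (s.accuracy == best_acc)
        rows.append(row)
    return pd.DataFrame(rows), stats


def prevalence_by_group(callset: InfectionCallSet, metadata: pd.DataFrame,
                        group_key: str) -> pd.DataFrame:
    """Per-group infected fraction with counts.

    ``metadata`` must map every called individual (column
    ``individual_id``) to a group under ``group_key``.
    """
    if group_key not in metadata.columns:
        raise ConfigError(f"metadata has no column '{group_key}'")
    meta = metadata.set_index("individual_id")[group_key]
    missing = [iid for iid in callset.calls if iid not in meta.index]
    if missing:
        shown = ", ".join(missing[:10])
        more = "" if len(missing) <= 10 else f" (+{len(missing) - 10} more)"
        raise WolbscanError(
            f"individuals missing metadata: {shown}{more}")
    df = pd.DataFrame({
        "group": [meta[iid] for iid in callset.calls],
        "infected": list(callset.calls.values()),
    })
    out = df.groupby("group", sort=True).agg(
        n=("infected", "size"), n_infected=("infected", "sum"))
    out["fraction"] = out.n_infected / out.n
    return out.reset_index().rename(columns={"group": group_key})
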