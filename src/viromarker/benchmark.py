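"""Alignment-based truth labelling and precision/recall/F1 scoring.

A contig is truly viral when the union of its reference alignments at >= 90%
identity covers >= 70% of its length (both thresholds inclusive and
configurable; a single-best-alignment mode is available behind a flag).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

DEFAULT_MIN_COVERAGE = 0.70
DEFAULT_MIN_IDENTITY = 90.0


@dataclass(frozen=True)
class AlignmentRecord:
    """One alignment block, contig coordinates 0-based half-open, forward."""

    contig_id: str
    reference_id: str
    contig_start: int
    contig_end: int
    percent_identity: float

    def __post_init__(self) -> None:
        if self.contig_start >= self.contig_end:
            raise ValueError(
                f"{self.contig_id}: start {self.contig_start} >= end {self.contig_end}"
            )
        if self.percent_identity > 100:
            raise ValueError(f"identity {self.percent_identity} > 100")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class Metrics:
    precision: float | None
    recall: float | None
    f1: float | None


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals as a sorted list of disjoint intervals."""
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def parse_show_coords(path: str | Path) -> list[AlignmentRecord]:
    """Parse a nucmer show-coords tab (-T) table.

    Column order: S1 E1 S2 E2 LEN1 LEN2 %IDY REF QRY, coordinates 1-based
    inclusive with reversed pairs on the minus strand; the query (contig)
    interval is normalized to a 0-based half-open forward interval.
    Header/banner lines are skipped.
    """
    records: list[AlignmentRecord] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) < 9:
                continue  # banner / path lines
            try:
                s2, e2 = int(f[2]), int(f[3])
                idy = float(f[6])
            except ValueError:
                continue  # column-header line
            lo, hi = min(s2, e2), max(s2, e2)
            records.append(
                AlignmentRecord(
                    contig_id=f[8].strip(), reference_id=f[7].strip(),
                    contig_start=lo - 1, contig_end=hi, percent_identity=idy,
                )
            )
    return records


def truth_labels(
    alignments: Iterable[AlignmentRecord],
    contig_lengths: Mapping[str, int],
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    mode: str = "union",
) -> dict[str, bool]:
    """Label every contig in ``contig_lengths`` viral (True) or not.

    ``mode="union"`` merges all qualifying alignments; ``mode="best"`` uses
    only the single longest qualifying alignment.
    """
    if mode not in {"union", "best"}:
        raise ValueError(f"unknown coverage mode {mode!r}")
    qualifying: dict[str, list[tuple[int, int]]] = {}
    for aln in alignments:
        if aln.contig_id not in contig_lengths:
            raise KeyError(
                f"alignment contig {aln.contig_id!r} absent from the lengths map"
            )
        if aln.contig_end > contig_lengths[aln.contig_id]:
            raise ValueError(
                f"{aln.contig_id}: alignment end {aln.contig_end} beyond "
                f"contig length {contig_lengths[aln.contig_id]}"
            )
        if aln.percent_identity >= min_identity:
            qualifying.setdefault(aln.contig_id, []).append(
                (aln.contig_start, aln.contig_end)
            )
    labels: dict[str, bool] = {}
    for contig, length in contig_lengths.items():
        intervals = qualifying.get(contig, [])
        if not intervals:
            labels[contig] = False
            continue
        if mode == "union":
            covered = sum(e - s for s, e in merge_intervals(intervals))
        else:
            covered = max(e - s for s, e in intervals)
        labels[contig] = covered / length >= min_coverage
    return labels


def confusion(predicted_viral: set[str], truth: Mapping[str, bool]) -> ConfusionCounts:
    """Standard 2x2 tally over every contig in the truth map."""
    outside = predicted_viral - set(truth)
    if outside:
        raise KeyError(
            f"predicted contigs outside the evaluated set: {sorted(outside)[:5]}"
        )
    tp = tn = fp = fn = 0
    for contig, is_viral in truth.items():
        predicted = contig in predicted_viral
        if is_viral and predicted:
            tp += 1
        elif is_viral:
            fn += 1
        elif predicted:
            fp += 1
        else:
            tn += 1
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def metrics(counts: ConfusionCounts) -> Metrics:
    """Precision, recall, F1; undefined values come back as None."""
    precision = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else None
    recall = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else None
    denom = 2 * counts.tp + counts.fp + counts.fn
    f1 = 2 * counts.tp / denom if denom else None
    return Metrics(precision=precision, recall=recall, f1=f1)


# -- IO -----------------------------------------------------------------------------


def read_lengths_tsv(path: str | Path) -> dict[str, int]:
    out: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            a, b = line.split("\t")[:2]
            if a.lower() in {"contig_id", "contig", "name"}:
                continue
            out[a] = int(b)
    return out


def read_predictions_tsv(path: str | Path) -> set[str]:
    """Predicted-viral contig ids from a triage assignments TSV.

    HC, LC and PP verdicts all count the (host) contig as predicted viral.
    """
    predicted: set[str] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        try:
            i_id = header.index("contig_id")
            i_verdict = header.index("verdict")
        except ValueError:
            raise ValueError(f"{path}: need contig_id/verdict columns, got {header}")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if f[i_verdict] in {"HC", "LC", "PP"}:
                predicted.add(f[i_id])
    return predicted


def write_truth_tsv(truth: Mapping[str, bool], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("contig_id\tlabel\n")
        for contig in sorted(truth):
            fh.write(f"{contig}\t{'viral' if truth[contig] else 'non-viral'}\n")


def write_confusion_tsv(counts: ConfusionCounts, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("tp\ttn\tfp\tfn\n")
        fh.write(f"{counts.tp}\t{counts.tn}\t{counts.fp}\t{counts.fn}\n")


def write_metrics_tsv(m: Metrics, path: str | Path) -> None:
    def fmt(x: float | None, pct: bool = False) -> str:
        if x is None:
            return "NA"
        return f"{100 * x:.1f}" if pct else f"{x:.2f}"

    with open(path, "w") as fh:
        fh.write("precision_pct\trecall_pct\tf1\n")
        fh.write(f"{fmt(m.precision, True)}\t{fmt(m.recall, True)}\t{fmt(m.f1)}\n")
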