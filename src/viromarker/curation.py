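"""Selection of taxon-informative marker models and bit-score calibration.

Given per-model homology hits (each carrying the source sequence's taxon id),
a model is *informative* at the finest working rank where either a single
taxon is hit or the best taxon's bit-score range is separated from every
competitor's. The range bounds give the S1/S2 scores from which the
GA/TC/NC header thresholds are derived and written into HMMER3 model files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .taxonomy import WORKING_RANKS, TaxonomyTree

REPORTING_EVALUE = 1.0e-3  # per-sequence reporting threshold used upstream
DOMAIN_TRIM_BITS = 3.0


class CalibrationError(ValueError):
    """Raised when S1/S2 violate the non-overlap premise (S2 >= S1)."""


class HmmFormatError(ValueError):
    """Malformed HMMER3 model text; message carries the offending line number."""


@dataclass(frozen=True)
class HomologyHit:
    """One reported model-vs-sequence match.

    ``taxid`` is the source taxon of the hit sequence (curation mode); it is
    ``None`` in classification mode where queries are anonymous CDS.
    """

    model_id: str
    seq_id: str
    evalue: float
    full_score: float
    best_domain_score: float = float("nan")
    taxid: str | None = None

    def __post_init__(self) -> None:
        if not self.evalue > 0:
            raise ValueError(f"evalue must be positive, got {self.evalue}")
        if not math.isfinite(self.full_score):
            raise ValueError("full_score must be finite")


@dataclass(frozen=True)
class ScoreRange:
    taxon: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ValueError(f"low {self.low} > high {self.high}")

    def overlaps_or_touches(self, other_high: float) -> bool:
        return self.low <= other_high


@dataclass(frozen=True)
class Thresholds:
    ga_seq: float
    ga_dom: float
    tc_seq: float
    tc_dom: float
    nc_seq: float | None
    nc_dom: float | None


@dataclass(frozen=True)
class InformativeMarker:
    """A calibrated taxon-informative model."""

    model_id: str
    rank: str
    taxon: str
    s1: float
    s2: float | None
    ga_seq: float
    ga_dom: float
    tc_seq: float
    tc_dom: float
    nc_seq: float | None
    nc_dom: float | None

    @classmethod
    def from_scores(
        cls, model_id: str, rank: str, taxon: str, s1: float, s2: float | None
    ) -> "InformativeMarker":
        t = derive_thresholds(s1, s2)
        return cls(model_id, rank, taxon, s1, s2, t.ga_seq, t.ga_dom, t.tc_seq,
                   t.tc_dom, t.nc_seq, t.nc_dom)


def best_scores_by_taxon(
    hits: Iterable[HomologyHit], tree: TaxonomyTree, rank: str
) -> dict[str, ScoreRange]:
    """Group per-taxid best full-sequence scores by their ancestor at ``rank``.

    Taxids whose lineage lacks a node at ``rank`` are dropped from that
    rank's competition. Returns one ScoreRange (min/max of the per-taxid
    bests) per rank-level taxon.
    """
    best_per_taxid: dict[str, float] = {}
    for hit in hits:
        if hit.taxid is None:
            raise ValueError(f"hit {hit.model_id}/{hit.seq_id} has no source taxid")
        prev = best_per_taxid.get(hit.taxid)
        if prev is None or hit.full_score > prev:
            best_per_taxid[hit.taxid] = hit.full_score
    grouped: dict[str, list[float]] = {}
    for taxid, score in best_per_taxid.items():
        anc = tree.ancestor_at(taxid, rank)
        if anc is None:
            continue
        grouped.setdefault(anc, []).append(score)
    return {
        taxon: ScoreRange(taxon, min(scores), max(scores))
        for taxon, scores in grouped.items()
    }


def select_informative(
    hits: Sequence[HomologyHit],
    tree: TaxonomyTree,
    rank_order: Sequence[str] = WORKING_RANKS,
) -> tuple[str, str, float, float | None] | None:
    """Find the finest rank at which a model is taxon-informative.

    Returns ``(rank, taxon, S1, S2)`` or ``None`` for a non-informative
    model. At each rank the best taxon is the one with the highest range
    upper bound (ties: higher lower bound, then lexicographically smallest
    id); it wins if it is the only taxon or its lower bound strictly exceeds
    every other taxon's upper bound. S1 is the winner's lower bound; S2 the
    maximum upper bound among the other taxa (absent when there are none).
    """
    if not hits:
        return None
    for rank in rank_order:
        ranges = best_scores_by_taxon(hits, tree, rank)
        if not ranges:
            continue
        best = min(ranges.values(), key=lambda r: (-r.high, -r.low, r.taxon))
        others = [r for r in ranges.values() if r.taxon != best.taxon]
        if not others:
            return rank, best.taxon, best.low, None
        other_max = max(r.high for r in others)
        if best.low > other_max:
            return rank, best.taxon, best.low, other_max
    return None


def derive_thresholds(s1: float, s2: float | None) -> Thresholds:
    """Turn the S1/S2 calibration scores into the six header thresholds.

    GA_seq = TC_seq = S1. The per-domain gathering threshold is S1 trimmed
    by three bits, unless trimming would drop to or below S2, in which case
    it stays at S1. NC (both components) equals S2 and is omitted when S2
    is absent.
    """
    if s2 is not None and s2 >= s1:
        raise CalibrationError(f"S2 ({s2}) must be strictly below S1 ({s1})")
    trimmed = s1 - DOMAIN_TRIM_BITS
    dom = trimmed if (s2 is None or trimmed > s2) else s1
    return Thresholds(ga_seq=s1, ga_dom=dom, tc_seq=s1, tc_dom=dom,
                      nc_seq=s2, nc_dom=s2)


def calibrate_model(
    model_id: str, hits: Sequence[HomologyHit], tree: TaxonomyTree
) -> InformativeMarker | None:
    """select_informative + derive_thresholds for a single model's hits."""
    core = select_informative(hits, tree)
    if core is None:
        return None
    rank, taxon, s1, s2 = core
    return InformativeMarker.from_scores(model_id, rank, taxon, s1, s2)


def calibrate_all(
    hits: Iterable[HomologyHit], tree: TaxonomyTree
) -> dict[str, InformativeMarker]:
    """Calibrate every model present in a pooled hit list."""
    by_model: dict[str, list[HomologyHit]] = {}
    for h in hits:
        by_model.setdefault(h.model_id, []).append(h)
    out: dict[str, InformativeMarker] = {}
    for model_id in sorted(by_model):
        marker = calibrate_model(model_id, by_model[model_id], tree)
        if marker is not None:
            out[model_id] = marker
    return out


# -- HMMER3 header annotation -------------------------------------------------------

_CUTOFF_TAGS = ("GA", "TC", "NC")


def _cutoff_line(tag: str, seq: float, dom: float) -> str:
    return f"{tag}    {seq:.2f} {dom:.2f};"


def annotate_hmm(model_text: str, marker: InformativeMarker) -> str:
    """Insert (or replace) GA/TC/NC cutoff lines in a HMMER3 model header.

    The lines go directly after the CKSUM line; the model body after the
    ``HMM`` column-header line is preserved byte-for-byte. Re-annotating is
    idempotent.
    """
    lines = model_text.splitlines(keepends=True)
    if not lines or not lines[0].startswith("HMMER3"):
        raise HmmFormatError("line 1: missing HMMER3 format line")
    hmm_idx = None
    cksum_idx = None
    for i, line in enumerate(lines):
        if line.startswith("HMM "):
            hmm_idx = i
            break
        if line.startswith("CKSUM"):
            cksum_idx = i
    if hmm_idx is None:
        raise HmmFormatError(f"line {len(lines)}: no HMM table header found")
    if cksum_idx is None:
        raise HmmFormatError(f"line {hmm_idx + 1}: no CKSUM line before HMM header")

    newline = "\r\n" if lines[0].endswith("\r\n") else "\n"
    header = [
        line for line in lines[:hmm_idx]
        if not (line.strip() and line.split()[0] in _CUTOFF_TAGS)
    ]
    # CKSUM position may have shifted after dropping old cutoff lines
    cksum_idx = next(i for i, l in enumerate(header) if l.startswith("CKSUM"))
    cutoffs = [
        _cutoff_line("GA", marker.ga_seq, marker.ga_dom) + newline,
        _cutoff_line("TC", marker.tc_seq, marker.tc_dom) + newline,
    ]
    if marker.nc_seq is not None and marker.nc_dom is not None:
        cutoffs.append(_cutoff_line("NC", marker.nc_seq, marker.nc_dom) + newline)
    out = header[: cksum_idx + 1] + cutoffs + header[cksum_idx + 1 :]
    return "".join(out) + "".join(lines[hmm_idx:])


def read_hmm_cutoffs(model_text: str) -> dict[str, tuple[float, float]]:
    """Parse GA/TC/NC lines from a model header into (seq, dom) pairs."""
    out: dict[str, tuple[float, float]] = {}
    for line in model_text.splitlines():
        if line.startswith("HMM "):
            break
        parts = line.rstrip(";").split()
        if len(parts) == 3 and parts[0] in _CUTOFF_TAGS:
            out[parts[0]] = (float(parts[1]), float(parts[2]))
    return out


# -- tabular IO ---------------------------------------------------------------------

MARKER_COLUMNS = (
    "model_id", "rank", "taxon", "S1", "S2",
    "GA_seq", "GA_dom", "NC_seq", "NC_dom",
)


def _fmt(x: float | None) -> str:
    return "" if x is None else f"{x:g}"


def write_markers_tsv(markers: Mapping[str, InformativeMarker], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(MARKER_COLUMNS) + "\n")
        for model_id in sorted(markers):
            m = markers[model_id]
            fh.write(
                "\t".join(
                    [m.model_id, m.rank, m.taxon, _fmt(m.s1), _fmt(m.s2),
                     _fmt(m.ga_seq), _fmt(m.ga_dom), _fmt(m.nc_seq), _fmt(m.nc_dom)]
                )
                + "\n"
            )


def read_markers_tsv(path: str | Path) -> dict[str, InformativeMarker]:
    markers: dict[str, InformativeMarker] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != MARKER_COLUMNS:
            raise ValueError(f"{path}: unexpected marker TSV header {header}")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            s2 = float(f[4]) if f[4] else None
            markers[f[0]] = InformativeMarker(
                model_id=f[0], rank=f[1], taxon=f[2],
                s1=float(f[3]), s2=s2,
                ga_seq=float(f[5]), ga_dom=float(f[6]),
                tc_seq=float(f[5]), tc_dom=float(f[6]),
                nc_seq=float(f[7]) if f[7] else None,
                nc_dom=float(f[8]) if f[8] else None,
            )
    return markers


def read_hits_tsv(path: str | Path) -> list[HomologyHit]:
    """Read the simplified curation hits TSV.

    Columns: model_id, seq_id, taxid, evalue, full_score.
    """
    hits: list[HomologyHit] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["model_id", "seq_id", "taxid", "evalue", "full_score"]
        if header[:5] != expected:
            raise ValueError(f"{path}: expected header {expected}, got {header}")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            hits.append(
                HomologyHit(
                    model_id=f[0], seq_id=f[1], taxid=f[2],
                    evalue=float(f[3]), full_score=float(f[4]),
                )
            )
    return hits


def read_tblout(
    path: str | Path, seq2taxid: Mapping[str, str] | None = None
) -> list[HomologyHit]:
    """Parse a HMMER3 per-sequence table (``--tblout``) from hmmsearch.

    Target name is the sequence, query name the model. If ``seq2taxid`` is
    given, hit taxids are filled from it (unmapped sequences are skipped).
    """
    hits: list[HomologyHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            f = line.split()
            if len(f) < 10:
                raise ValueError(f"{path}:{lineno}: short tblout row")
            seq_id, model_id = f[0], f[2]
            taxid = None
            if seq2taxid is not None:
                taxid = seq2taxid.get(seq_id)
                if taxid is None:
                    continue
            hits.append(
                HomologyHit(
                    model_id=model_id, seq_id=seq_id, taxid=taxid,
                    evalue=float(f[4]), full_score=float(f[5]),
                    best_domain_score=float(f[8]),
                )
            )
    return hits


def read_seq2taxid(path: str | Path) -> dict[str, str]:
    """Two-column (seq_id, taxid) mapping TSV, header optional."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            a, b = line.split("\t")[:2]
            if a.lower() in {"seq_id", "sequence_id"}:
                continue
            out[a] = b
    return out
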