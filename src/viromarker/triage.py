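"""Evidence-based triage of contigs into HC / LC / PP / excluded sets.

High confidence (HC): whole-contig viral calls (search-tool categories 1-2).
Putative prophage (PP): prophage categories 4-5 with excisable regions.
Low confidence (LC): score/p-value rules over the k-mer classifiers, with
optional corroboration. Precedence HC > PP > LC. All coordinates are stored
0-based half-open internally; predictor tables are read as 1-based inclusive
and converted at the boundary.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DEFAULT_MIN_LENGTH = 1500

HC_CATEGORIES = frozenset({1, 2})
PP_CATEGORIES = frozenset({4, 5})
LC_PVALUE = 0.05          # exclusive
LC_SCORE_STRONG = 0.9     # inclusive
LC_SCORE_WEAK = 0.7       # inclusive


class EvidenceError(ValueError):
    pass


@dataclass
class PredictorEvidence:
    contig_id: str
    contig_length: int
    virsorter_category: int | None = None
    prophage_regions: list[tuple[int, int]] = field(default_factory=list)
    virfinder_score: float | None = None
    virfinder_pvalue: float | None = None
    pprmeta_class: str | None = None

    def validate(self) -> None:
        if self.virsorter_category is not None and not (
            1 <= self.virsorter_category <= 6
        ):
            raise EvidenceError(
                f"{self.contig_id}: virsorter category must be 1-6, "
                f"got {self.virsorter_category}"
            )
        for start, end in self.prophage_regions:
            if not (0 <= start < end <= self.contig_length):
                raise EvidenceError(
                    f"{self.contig_id}: region ({start},{end}) outside "
                    f"[0,{self.contig_length})"
                )


@dataclass(frozen=True)
class ContigAssignment:
    contig_id: str
    verdict: str  # HC | LC | PP | excluded
    prophage_regions: tuple[tuple[int, int], ...] = ()
    triggering_rule: str = ""


@dataclass(frozen=True)
class FilterReport:
    kept: int
    dropped: int


def length_filter(
    records: Iterable[SeqRecord], min_length: int = DEFAULT_MIN_LENGTH
) -> tuple[list[SeqRecord], FilterReport]:
    """Keep records at least ``min_length`` bp long."""
    kept, dropped = [], 0
    for rec in records:
        if len(rec.seq) >= min_length:
            kept.append(rec)
        else:
            dropped += 1
    return kept, FilterReport(kept=len(kept), dropped=dropped)


def triage(evidence: PredictorEvidence, allow_category6: bool = False) -> ContigAssignment:
    """Assign one triage verdict per contig, precedence HC > PP > LC.

    Missing predictor fields mean "tool did not report", never failure.
    """
    evidence.validate()
    cid = evidence.contig_id
    cat = evidence.virsorter_category
    if cat in HC_CATEGORIES:
        return ContigAssignment(cid, "HC", triggering_rule=f"virsorter-category-{cat}")
    pp_cats = PP_CATEGORIES | ({6} if allow_category6 else set())
    if cat in pp_cats:
        regions = tuple(evidence.prophage_regions) or ((0, evidence.contig_length),)
        return ContigAssignment(
            cid, "PP", prophage_regions=regions,
            triggering_rule=f"virsorter-category-{cat}",
        )
    p, s = evidence.virfinder_pvalue, evidence.virfinder_score
    if p is not None and s is not None and p < LC_PVALUE:
        if s >= LC_SCORE_STRONG:
            return ContigAssignment(cid, "LC", triggering_rule="virfinder-0.9")
        if s >= LC_SCORE_WEAK and cat == 3:
            return ContigAssignment(
                cid, "LC", triggering_rule="virfinder-0.7+virsorter-3"
            )
        if s >= LC_SCORE_WEAK and evidence.pprmeta_class == "phage":
            return ContigAssignment(
                cid, "LC", triggering_rule="virfinder-0.7+pprmeta-phage"
            )
    return ContigAssignment(cid, "excluded")


def extract_regions(
    record: SeqRecord, regions: Sequence[tuple[int, int]]
) -> list[SeqRecord]:
    """Excise 0-based half-open sub-sequences, named contigID|prophage-start:end."""
    out = []
    for start, end in regions:
        if not (0 <= start < end <= len(record.seq)):
            raise ValueError(
                f"{record.id}: region ({start},{end}) outside [0,{len(record.seq)})"
            )
        sub = SeqRecord(
            Seq(str(record.seq[start:end])),
            id=f"{record.id}|prophage-{start}:{end}",
            description="",
        )
        out.append(sub)
    return out


# -- predictor table readers --------------------------------------------------------


def read_virsorter_csv(path: str | Path) -> dict[str, tuple[int, list[tuple[int, int]]]]:
    """Affiliation CSV: contig, category[, region_start, region_end].

    Region coordinates are 1-based inclusive in the file; converted here.
    Multiple rows per contig accumulate regions (the category of the first
    row wins).
    """
    out: dict[str, tuple[int, list[tuple[int, int]]]] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if not row or row[0].lower() in {"contig", "contig_id", "name"}:
                continue
            cid, cat = row[0].strip(), int(row[1])
            regions = out.setdefault(cid, (cat, []))[1]
            if len(row) >= 4 and row[2].strip() and row[3].strip():
                start1, end1 = int(row[2]), int(row[3])
                regions.append((start1 - 1, end1))
    return out


def read_virfinder_tsv(path: str | Path) -> dict[str, tuple[float, float]]:
    """VirFinder table: name, length, score, pvalue (TSV, header required)."""
    out: dict[str, tuple[float, float]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        cols = [c.strip().lower() for c in header]
        try:
            i_name = cols.index("name")
            i_score = cols.index("score")
            i_p = cols.index("pvalue")
        except ValueError:
            raise ValueError(f"{path}: need name/score/pvalue columns, got {header}")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            out[f[i_name]] = (float(f[i_score]), float(f[i_p]))
    return out


def read_pprmeta_csv(path: str | Path) -> dict[str, str]:
    """PPR-Meta CSV with a header naming the class column (phage/chromosome/plasmid)."""
    out: dict[str, str] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = [c.strip().lower() for c in next(reader)]
        try:
            i_name = next(
                i for i, c in enumerate(header) if c in {"header", "name", "contig"}
            )
            i_class = next(
                i for i, c in enumerate(header) if "class" in c or c == "possible_source"
            )
        except StopIteration:
            raise ValueError(f"{path}: cannot locate name/class columns in {header}")
        for row in reader:
            if row:
                out[row[i_name].strip()] = row[i_class].strip().lower()
    return out


def gather_evidence(
    records: Sequence[SeqRecord],
    virsorter: dict[str, tuple[int, list[tuple[int, int]]]] | None = None,
    virfinder: dict[str, tuple[float, float]] | None = None,
    pprmeta: dict[str, str] | None = None,
) -> list[PredictorEvidence]:
    """Join per-tool tables into one PredictorEvidence per contig."""
    out = []
    for rec in records:
        ev = PredictorEvidence(contig_id=rec.id, contig_length=len(rec.seq))
        if virsorter and rec.id in virsorter:
            cat, regions = virsorter[rec.id]
            ev.virsorter_category = cat
            ev.prophage_regions = list(regions)
        if virfinder and rec.id in virfinder:
            ev.virfinder_score, ev.virfinder_pvalue = virfinder[rec.id]
        if pprmeta and rec.id in pprmeta:
            ev.pprmeta_class = pprmeta[rec.id]
        out.append(ev)
    return out


def run_triage(
    fasta: str | Path,
    virsorter_csv: str | Path | None = None,
    virfinder_tsv: str | Path | None = None,
    pprmeta_csv: str | Path | None = None,
    min_length: int = DEFAULT_MIN_LENGTH,
    allow_category6: bool = False,
) -> tuple[list[SeqRecord], list[ContigAssignment], FilterReport]:
    """Length-filter a FASTA and triage every retained contig."""
    records = list(SeqIO.parse(str(fasta), "fasta"))
    kept, report = length_filter(records, min_length)
    vs = read_virsorter_csv(virsorter_csv) if virsorter_csv else None
    vf = read_virfinder_tsv(virfinder_tsv) if virfinder_tsv else None
    ppr = read_pprmeta_csv(pprmeta_csv) if pprmeta_csv else None
    assignments = [
        triage(ev, allow_category6=allow_category6)
        for ev in gather_evidence(kept, vs, vf, ppr)
    ]
    return kept, assignments, report


# -- output writers -----------------------------------------------------------------


def write_assignments_tsv(
    assignments: Iterable[ContigAssignment],
    path: str | Path,
    checkv: dict[str, str] | None = None,
) -> None:
    """Assignments TSV; an optional CheckV quality map is merged verbatim."""
    with open(path, "w") as fh:
        cols = ["contig_id", "verdict", "triggering_rule", "prophage_regions"]
        if checkv is not None:
            cols.append("checkv_quality")
        fh.write("\t".join(cols) + "\n")
        for a in assignments:
            regions = ";".join(f"{s}-{e}" for s, e in a.prophage_regions)
            row = [a.contig_id, a.verdict, a.triggering_rule, regions]
            if checkv is not None:
                row.append(checkv.get(a.contig_id, ""))
            fh.write("\t".join(row) + "\n")


def write_regions_bed(assignments: Iterable[ContigAssignment], path: str | Path) -> None:
    with open(path, "w") as fh:
        for a in assignments:
            for start, end in a.prophage_regions:
                fh.write(f"{a.contig_id}\t{start}\t{end}\tprophage\n")


def write_triage_fastas(
    records: Sequence[SeqRecord],
    assignments: Sequence[ContigAssignment],
    outdir: str | Path,
) -> None:
    """Write HC/LC FASTAs plus a PP FASTA of excised prophage regions."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    by_id = {r.id: r for r in records}
    buckets: dict[str, list[SeqRecord]] = {"HC": [], "LC": [], "PP": []}
    for a in assignments:
        if a.verdict in ("HC", "LC"):
            buckets[a.verdict].append(by_id[a.contig_id])
        elif a.verdict == "PP":
            buckets["PP"].extend(
                extract_regions(by_id[a.contig_id], a.prophage_regions)
            )
    SeqIO.write(buckets["HC"], str(outdir / "high_confidence.fasta"), "fasta")
    SeqIO.write(buckets["LC"], str(outdir / "low_confidence.fasta"), "fasta")
    SeqIO.write(buckets["PP"], str(outdir / "putative_prophages.fasta"), "fasta")
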