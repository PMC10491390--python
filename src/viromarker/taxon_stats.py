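"""Per-taxon CDS statistics, descendant-aggregated marker counts, and TSR.

The taxon-specific ratio (TSR) scales the voting proportion threshold: it is
the number of informative markers linked to a taxon divided by that taxon's
mean CDS count, capped at 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .curation import InformativeMarker
from .taxonomy import WORKING_RANKS, TaxonomyTree, UnknownTaxonError


@dataclass(frozen=True)
class AssemblyRecord:
    assembly_id: str
    taxid: str
    cds_count: int

    def __post_init__(self) -> None:
        if self.cds_count < 0:
            raise ValueError(f"cds_count must be >= 0, got {self.cds_count}")


@dataclass(frozen=True)
class TaxonStats:
    taxon: str
    rank: str
    mean_cds: float
    sd_cds: float
    n_assemblies: int
    n_markers: int
    tsr: float


def cds_stats(
    records: Iterable[AssemblyRecord], tree: TaxonomyTree
) -> tuple[dict[str, tuple[float, float, int]], list[AssemblyRecord]]:
    """Mean/SD/count of per-assembly CDS numbers at each working-rank taxon.

    Each assembly contributes to every working-rank ancestor in its lineage.
    Assemblies with zero annotated CDS are excluded; unresolvable taxids are
    skipped with a warning and returned in the rejects list. SD is the
    sample (n-1) standard deviation, 0 for singletons.
    """
    samples: dict[str, list[int]] = {}
    rejects: list[AssemblyRecord] = []
    for rec in records:
        if rec.cds_count == 0:
            continue
        try:
            lineage = tree.lineage_of(rec.taxid)
        except UnknownTaxonError:
            warnings.warn(f"assembly {rec.assembly_id}: unknown taxid {rec.taxid!r}")
            rejects.append(rec)
            continue
        for rank in WORKING_RANKS:
            taxon = lineage.at(rank)
            if taxon is not None:
                samples.setdefault(taxon, []).append(rec.cds_count)
    out: dict[str, tuple[float, float, int]] = {}
    for taxon, counts in samples.items():
        arr = np.asarray(counts, dtype=float)
        sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
        out[taxon] = (float(arr.mean()), sd, len(arr))
    return out, rejects


def marker_counts(
    markers: Iterable[InformativeMarker], tree: TaxonomyTree
) -> dict[str, int]:
    """Number of informative markers per taxon.

    Genus counts are direct links only; subfamily/family/order counts also
    include markers linked to any descendant taxon, which for working-rank
    taxa equals adding each marker to the coarser working-rank ancestors of
    its target taxon.
    """
    rank_level = {rank: i for i, rank in enumerate(WORKING_RANKS)}
    counts: dict[str, int] = {}
    for m in markers:
        counts[m.taxon] = counts.get(m.taxon, 0) + 1
        lineage = tree.lineage_of(m.taxon)
        level = rank_level.get(m.rank)
        if level is None:
            continue
        for rank in WORKING_RANKS[level + 1 :]:
            anc = lineage.at(rank)
            if anc is not None and anc != m.taxon:
                counts[anc] = counts.get(anc, 0) + 1
    return counts


def tsr(n_markers: int, mean_cds: float) -> float:
    """min(1, markers / mean CDS); undefined inputs raise ValueError."""
    if n_markers < 1:
        raise ValueError("TSR undefined for taxa without informative markers")
    if mean_cds <= 0:
        raise ValueError("TSR undefined for non-positive mean CDS count")
    return min(1.0, n_markers / mean_cds)


def compute_taxon_stats(
    records: Iterable[AssemblyRecord],
    markers: Iterable[InformativeMarker],
    tree: TaxonomyTree,
) -> dict[str, TaxonStats]:
    """Join CDS statistics with marker counts into per-taxon TSR records.

    Only taxa with both defined CDS statistics and at least one associated
    marker receive a TaxonStats entry; the voting stage treats missing taxa
    under its own fallback rule.
    """
    stats, _ = cds_stats(records, tree)
    counts = marker_counts(markers, tree)
    out: dict[str, TaxonStats] = {}
    for taxon, n in counts.items():
        if taxon not in stats:
            continue
        mean, sd, n_asm = stats[taxon]
        out[taxon] = TaxonStats(
            taxon=taxon, rank=tree.rank(taxon), mean_cds=mean, sd_cds=sd,
            n_assemblies=n_asm, n_markers=n, tsr=tsr(n, mean),
        )
    return out


def rank_coverage(stats: Mapping[str, TaxonStats]) -> dict[str, int]:
    """Number of covered taxa per working rank (plain-text cladogram stand-in)."""
    out = {rank: 0 for rank in WORKING_RANKS}
    for s in stats.values():
        if s.rank in out:
            out[s.rank] += 1
    return out


# -- tabular IO ---------------------------------------------------------------------

STATS_COLUMNS = (
    "taxon", "rank", "mean_cds", "sd_cds", "n_assemblies", "n_markers", "tsr"
)


def read_assemblies_tsv(path: str | Path) -> list[AssemblyRecord]:
    records: list[AssemblyRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["assembly_id", "taxid", "cds_count"]
        if header[:3] != expected:
            raise ValueError(f"{path}: expected header {expected}, got {header}")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            records.append(AssemblyRecord(f[0], f[1], int(f[2])))
    return records


def write_stats_tsv(stats: Mapping[str, TaxonStats], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(STATS_COLUMNS) + "\n")
        for taxon in sorted(stats):
            s = stats[taxon]
            fh.write(
                f"{s.taxon}\t{s.rank}\t{s.mean_cds:.6g}\t{s.sd_cds:.6g}\t"
                f"{s.n_assemblies}\t{s.n_markers}\t{s.tsr:.6g}\n"
            )


def read_stats_tsv(path: str | Path) -> dict[str, TaxonStats]:
    out: dict[str, TaxonStats] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != STATS_COLUMNS:
            raise ValueError(f"{path}: unexpected stats TSV header {header}")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            out[f[0]] = TaxonStats(
                taxon=f[0], rank=f[1], mean_cds=float(f[2]), sd_cds=float(f[3]),
                n_assemblies=int(f[4]), n_markers=int(f[5]), tsr=float(f[6]),
            )
    return out
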