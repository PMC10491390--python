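"""Threshold-gated hit filtering and the rank-escalating taxonomic vote.

Hits from a profile-HMM scan of a contig's CDS are gated against each
model's calibrated bit-score thresholds (high confidence) or, for models
without thresholds, against a full-sequence E-value cutoff (low confidence).
After collapsing to the best hit per CDS, voting proceeds from genus up to
order: candidates are ranked by their hit proportion and the first one
satisfying both the proportion >= factor * TSR condition and the
CDS-count condition (n_cds <= mean + 2*sd) wins; its lineage from the
deciding rank upward is reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .curation import REPORTING_EVALUE, HomologyHit, InformativeMarker
from .taxon_stats import TaxonStats
from .taxonomy import WORKING_RANKS, Lineage, TaxonomyTree

DEFAULT_FACTOR = 0.6


class DomTableError(ValueError):
    pass


@dataclass(frozen=True)
class RetainedHit:
    cds_id: str
    model_id: str
    marker_taxon: str | None  # None for low-confidence (unthresholded) models
    marker_rank: str | None
    confidence: str  # "high" | "low"
    full_score: float
    best_domain_score: float


@dataclass
class ContigHitProfile:
    contig_id: str
    n_cds: int
    hits: list[RetainedHit] = field(default_factory=list)


@dataclass(frozen=True)
class Classification:
    contig_id: str
    outcome: str  # "classified" | "unclassified"
    deciding_rank: str | None = None
    winning_taxon: str | None = None
    lineage: Lineage | None = None
    proportion: float = 0.0
    n_informative_hits: int = 0
    n_hits_high: int = 0
    n_hits_low: int = 0
    n_cds: int = 0


# -- HMMER3 per-domain table --------------------------------------------------------

_DOMTBL_MIN_FIELDS = 23  # 22 fixed columns + description (possibly "-")


def parse_domain_table(path: str | Path) -> list[HomologyHit]:
    """Parse an hmmscan ``--domtblout`` file.

    Multiple domain rows for the same (model, query) pair collapse to a
    single hit keeping the best per-domain score; the full-sequence E-value
    and score are shared across rows.
    """
    best: dict[tuple[str, str], HomologyHit] = {}
    order: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            f = line.split()
            if len(f) < _DOMTBL_MIN_FIELDS:
                raise DomTableError(
                    f"{path}:{lineno}: expected >= {_DOMTBL_MIN_FIELDS} columns, "
                    f"got {len(f)}"
                )
            model_id, cds_id = f[0], f[3]
            try:
                evalue = float(f[6])
                full_score = float(f[7])
                dom_score = float(f[13])
            except ValueError as exc:
                raise DomTableError(f"{path}:{lineno}: {exc}") from None
            key = (model_id, cds_id)
            prev = best.get(key)
            if prev is None:
                best[key] = HomologyHit(
                    model_id=model_id, seq_id=cds_id, evalue=evalue,
                    full_score=full_score, best_domain_score=dom_score,
                )
                order.append(key)
            elif dom_score > prev.best_domain_score:
                best[key] = HomologyHit(
                    model_id=model_id, seq_id=cds_id, evalue=prev.evalue,
                    full_score=prev.full_score, best_domain_score=dom_score,
                )
    return [best[k] for k in order]


def gate_hits(
    hits: Iterable[HomologyHit],
    markers: Mapping[str, InformativeMarker],
    all_models: set[str] | None = None,
    evalue_cutoff: float = REPORTING_EVALUE,
) -> list[RetainedHit]:
    """Apply calibrated bit-score gates, falling back to the E-value filter.

    Thresholded models require full-sequence score >= GA_seq and best
    domain score >= GA_dom (confidence "high"). Unthresholded models known
    to ``all_models`` are retained at E <= cutoff (confidence "low"). When
    ``all_models`` is None every unthresholded model takes the E-value
    route; otherwise hits to models in neither set are dropped.
    """
    retained: list[RetainedHit] = []
    for h in hits:
        marker = markers.get(h.model_id)
        if marker is not None:
            if h.full_score >= marker.ga_seq and h.best_domain_score >= marker.ga_dom:
                retained.append(
                    RetainedHit(h.seq_id, h.model_id, marker.taxon, marker.rank,
                                "high", h.full_score, h.best_domain_score)
                )
        elif all_models is None or h.model_id in all_models:
            if h.evalue <= evalue_cutoff:
                retained.append(
                    RetainedHit(h.seq_id, h.model_id, None, None, "low",
                                h.full_score, h.best_domain_score)
                )
    return retained


def contig_of_cds(cds_id: str) -> str | None:
    """contigID_ordinal -> contigID; None when the id has no ordinal suffix."""
    contig, sep, ordinal = cds_id.rpartition("_")
    if not sep or not ordinal.isdigit():
        return None
    return contig


def best_hit_per_cds(
    retained: Iterable[RetainedHit],
) -> tuple[dict[str, list[RetainedHit]], list[RetainedHit]]:
    """Collapse to one hit per CDS and bucket by contig.

    Tie-break: highest full-sequence score, then highest domain score, then
    lexicographically smallest model id. Unparseable CDS ids are routed to
    the orphans list.
    """
    best: dict[str, RetainedHit] = {}
    for h in retained:
        prev = best.get(h.cds_id)
        if prev is None or (
            (-h.full_score, -h.best_domain_score, h.model_id)
            < (-prev.full_score, -prev.best_domain_score, prev.model_id)
        ):
            best[h.cds_id] = h
    by_contig: dict[str, list[RetainedHit]] = {}
    orphans: list[RetainedHit] = []
    for cds_id in sorted(best):
        contig = contig_of_cds(cds_id)
        if contig is None:
            orphans.append(best[cds_id])
        else:
            by_contig.setdefault(contig, []).append(best[cds_id])
    return by_contig, orphans


def vote(
    profile: ContigHitProfile,
    stats: Mapping[str, TaxonStats],
    tree: TaxonomyTree,
    factor: float = DEFAULT_FACTOR,
    rank_order: Sequence[str] = WORKING_RANKS,
) -> Classification:
    """Rank-escalating taxonomic vote over a contig's retained hits.

    At each rank every hit votes through its marker taxon's ancestor at that
    rank; hits whose marker lineage lacks the rank (including all
    low-confidence hits, which carry no marker taxon) stay in the
    denominator without supporting any candidate.
    """
    informative = [h for h in profile.hits if h.marker_taxon is not None]
    n_high = sum(1 for h in profile.hits if h.confidence == "high")
    n_low = sum(1 for h in profile.hits if h.confidence == "low")
    total = len(informative)
    base = dict(
        contig_id=profile.contig_id, n_informative_hits=total,
        n_hits_high=n_high, n_hits_low=n_low, n_cds=profile.n_cds,
    )
    if total == 0:
        return Classification(outcome="unclassified", **base)

    lineage_cache: dict[str, Lineage] = {}

    def lineage_at(taxon: str, rank: str) -> str | None:
        if taxon not in lineage_cache:
            lineage_cache[taxon] = tree.lineage_of(taxon)
        return lineage_cache[taxon].at(rank)

    for rank in rank_order:
        tallies: dict[str, int] = {}
        for h in informative:
            candidate = lineage_at(h.marker_taxon, rank)
            if candidate is not None:
                tallies[candidate] = tallies.get(candidate, 0) + 1
        if not tallies:
            continue

        def sort_key(taxon: str) -> tuple[float, float, str]:
            s = stats.get(taxon)
            cand_tsr = s.tsr if s is not None else 1.0
            return (-tallies[taxon] / total, -cand_tsr, taxon)

        for taxon in sorted(tallies, key=sort_key):
            proportion = tallies[taxon] / total
            s = stats.get(taxon)
            if s is None:
                warnings.warn(
                    f"{profile.contig_id}: no taxon stats for candidate "
                    f"{taxon!r}; TSR=1, CDS-count condition waived"
                )
                cand_tsr, cds_ok = 1.0, True
            else:
                cand_tsr = s.tsr
                cds_ok = profile.n_cds <= s.mean_cds + 2.0 * s.sd_cds
            if proportion >= factor * cand_tsr and cds_ok:
                return Classification(
                    outcome="classified", deciding_rank=rank, winning_taxon=taxon,
                    lineage=_lineage_from(tree, taxon, rank), proportion=proportion,
                    **base,
                )
    return Classification(outcome="unclassified", **base)


def _lineage_from(tree: TaxonomyTree, taxon: str, rank: str) -> Lineage:
    """Lineage filled only at the deciding rank and coarser slots."""
    full = tree.lineage_of(taxon)
    level = WORKING_RANKS.index(rank)
    slots = {
        r: (full.at(r) if i >= level else None)
        for i, r in enumerate(WORKING_RANKS)
    }
    return Lineage(chain=full.chain, **slots)


def build_profiles(
    by_contig: Mapping[str, list[RetainedHit]],
    cds_counts: Mapping[str, int],
    only_with_hits: bool = False,
) -> list[ContigHitProfile]:
    """Assemble profiles for every contig in the CDS inventory.

    Contigs without any retained hit still get an (empty) profile unless
    ``only_with_hits``; n_cds is the gene-caller total, never the hit count.
    """
    contigs = set(by_contig) if only_with_hits else set(cds_counts) | set(by_contig)
    profiles = []
    for contig in sorted(contigs):
        hits = by_contig.get(contig, [])
        n_cds = cds_counts.get(contig, len({h.cds_id for h in hits}))
        profiles.append(ContigHitProfile(contig, n_cds, list(hits)))
    return profiles


# -- CDS inventories ----------------------------------------------------------------


def cds_counts_from_gff3(path: str | Path) -> dict[str, int]:
    """Count CDS features per seqid in a GFF3 file."""
    counts: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) >= 3 and f[2] == "CDS":
                counts[f[0]] = counts.get(f[0], 0) + 1
    return counts


def cds_counts_from_faa(path: str | Path) -> dict[str, int]:
    """Count protein records per contig from contigID_ordinal FASTA headers."""
    counts: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith(">"):
                cds_id = line[1:].split()[0]
                contig = contig_of_cds(cds_id)
                if contig is not None:
                    counts[contig] = counts.get(contig, 0) + 1
    return counts


# -- outputs ------------------------------------------------------------------------


def lineage_string(tree: TaxonomyTree, lineage: Lineage | None) -> str:
    """Semicolon-joined taxon names, coarse to fine, skipping empty slots."""
    if lineage is None:
        return ""
    names = []
    for rank in reversed(WORKING_RANKS):  # order -> genus
        taxon = lineage.at(rank)
        if taxon is not None:
            names.append(tree.name(taxon))
    return ";".join(names)


def write_classifications_tsv(
    classifications: Iterable[Classification], tree: TaxonomyTree, path: str | Path
) -> None:
    cols = ("contig_id", "outcome", "deciding_rank", "taxon", "lineage",
            "proportion", "n_hits_high", "n_hits_low", "n_cds")
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for c in classifications:
            fh.write(
                "\t".join([
                    c.contig_id, c.outcome, c.deciding_rank or "",
                    c.winning_taxon or "", lineage_string(tree, c.lineage),
                    f"{c.proportion:.4f}", str(c.n_hits_high), str(c.n_hits_low),
                    str(c.n_cds),
                ]) + "\n"
            )


def write_krona_text(
    classifications: Iterable[Classification], tree: TaxonomyTree, path: str | Path
) -> None:
    """Krona-compatible text: count TAB rank-ordered lineage name fields."""
    tallies: dict[tuple[str, ...], int] = {}
    for c in classifications:
        if c.outcome == "classified" and c.lineage is not None:
            key = tuple(
                tree.name(c.lineage.at(r))
                for r in reversed(WORKING_RANKS)
                if c.lineage.at(r) is not None
            )
        else:
            key = ("unclassified",)
        tallies[key] = tallies.get(key, 0) + 1
    with open(path, "w") as fh:
        for key in sorted(tallies):
            fh.write(str(tallies[key]) + "\t" + "\t".join(key) + "\n")


def write_cds_annotations_tsv(
    by_contig: Mapping[str, list[RetainedHit]], path: str | Path
) -> None:
    cols = ("cds_id", "contig_id", "model_id", "marker_taxon", "marker_rank",
            "confidence", "full_score", "best_domain_score")
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for contig in sorted(by_contig):
            for h in by_contig[contig]:
                fh.write(
                    "\t".join([
                        h.cds_id, contig, h.model_id, h.marker_taxon or "",
                        h.marker_rank or "", h.confidence,
                        f"{h.full_score:.2f}", f"{h.best_domain_score:.2f}",
                    ]) + "\n"
                )


def classify_contigs(
    domtbl: str | Path,
    markers: Mapping[str, InformativeMarker],
    stats: Mapping[str, TaxonStats],
    tree: TaxonomyTree,
    cds_counts: Mapping[str, int],
    factor: float = DEFAULT_FACTOR,
    restrict_to: set[str] | None = None,
) -> tuple[list[Classification], dict[str, list[RetainedHit]]]:
    """End-to-end classification of every contig in the CDS inventory.

    ``restrict_to`` limits classification to a triage-selected contig set;
    None classifies everything (the annotate-only mode).
    """
    hits = parse_domain_table(domtbl)
    retained = gate_hits(hits, markers)
    by_contig, _orphans = best_hit_per_cds(retained)
    if restrict_to is not None:
        by_contig = {c: h for c, h in by_contig.items() if c in restrict_to}
        cds_counts = {c: n for c, n in cds_counts.items() if c in restrict_to}
    profiles = build_profiles(by_contig, cds_counts)
    classifications = [vote(p, stats, tree, factor=factor) for p in profiles]
    return classifications, by_contig
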