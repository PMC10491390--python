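"""Seeded generators for every input format the other modules consume.

All randomness flows through a single ``numpy.random.Generator`` built from
``FixtureSpec.seed``; identical specs produce byte-identical files. Ground
truth (planted marker targets and scores, per-contig source lineage, triage
verdict and viral label) is recorded alongside so recovery can be checked
exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .curation import HomologyHit, InformativeMarker
from .taxon_stats import AssemblyRecord
from .taxonomy import TaxonNode, TaxonomyTree, write_lineage_tsv

_VERDICT_CYCLE = ("HC", "LC1", "PP", "LC2", "LC3")


@dataclass
class FixtureSpec:
    seed: int = 0
    # taxonomy shape
    n_orders: int = 1
    families_per_order: int = 2
    subfamilies_per_family: int = 0
    genera_per_family: int = 2  # per subfamily when subfamilies are present
    taxids_per_genus: int = 3
    # curation hits
    n_models: int = 30
    score_separation: float = 10.0
    tight_gap_every: int = 5    # every k-th model gets a sub-3-bit S1-S2 gap
    family_level_every: int = 10  # every k-th model planted above genus (S2 absent)
    noninformative_fraction: float = 0.0  # needs >= 2 orders to take effect
    # contig set
    n_contigs: int = 100
    viral_fraction: float = 0.5
    length_range: tuple[int, int] = (8000, 16000)
    cds_per_kb: float = 1.0
    hit_density: float = 0.9
    noise: float = 0.0          # cross-genus fraction of contig hits
    predictor_error_rate: float = 0.0
    assemblies_per_genus: int = 5

    def __post_init__(self) -> None:
        for name in ("n_orders", "families_per_order", "genera_per_family",
                     "taxids_per_genus", "n_models", "n_contigs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("noninformative_fraction", "viral_fraction", "hit_density",
                     "noise", "predictor_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        self.length_range = tuple(self.length_range)  # type: ignore[assignment]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FixtureSpec":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["length_range"] = list(self.length_range)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


@dataclass(frozen=True)
class PlantedMarker:
    model_id: str
    rank: str | None  # None => planted non-informative
    taxon: str | None
    s1: float | None
    s2: float | None


@dataclass(frozen=True)
class ContigTruth:
    contig_id: str
    length: int
    viral: bool
    source_genus: str | None
    verdict: str  # HC | LC | PP | excluded
    triage_kind: str  # HC / LC1 / LC2 / LC3 / PP / none
    prophage_regions: tuple[tuple[int, int], ...] = ()


@dataclass
class GroundTruth:
    markers: dict[str, PlantedMarker] = field(default_factory=dict)
    contigs: dict[str, ContigTruth] = field(default_factory=dict)


@dataclass
class FixtureBundle:
    spec: FixtureSpec
    tree: TaxonomyTree
    curation_hits: list[HomologyHit]
    planted_markers: dict[str, InformativeMarker]  # informative subset, calibrated
    assemblies: list[AssemblyRecord]
    truth: GroundTruth
    genera: list[str]
    outdir: Path | None = None


# -- taxonomy -----------------------------------------------------------------------


def make_taxonomy(spec: FixtureSpec) -> TaxonomyTree:
    """Balanced tree with deterministic ids: root > orders > families
    [> subfamilies] > genera > species taxids."""
    nodes: dict[str, TaxonNode] = {
        "root": TaxonNode("root", "root", "no-rank", "root")
    }
    gi = ti = fi = si = 0
    for oi in range(spec.n_orders):
        order = f"o{oi + 1:02d}"
        nodes[order] = TaxonNode(order, f"Order{oi + 1:02d}", "order", "root")
        for _ in range(spec.families_per_order):
            fi += 1
            family = f"f{fi:02d}"
            nodes[family] = TaxonNode(family, f"Family{fi:02d}", "family", order)
            sub_parents = [family]
            if spec.subfamilies_per_family > 0:
                sub_parents = []
                for _ in range(spec.subfamilies_per_family):
                    si += 1
                    sf = f"sf{si:02d}"
                    nodes[sf] = TaxonNode(sf, f"Subfamily{si:02d}", "subfamily", family)
                    sub_parents.append(sf)
            for parent in sub_parents:
                for _ in range(spec.genera_per_family):
                    gi += 1
                    genus = f"g{gi:02d}"
                    nodes[genus] = TaxonNode(genus, f"Genus{gi:02d}", "genus", parent)
                    for _ in range(spec.taxids_per_genus):
                        ti += 1
                        taxid = f"t{ti:04d}"
                        nodes[taxid] = TaxonNode(
                            taxid, f"Species{ti:04d}", "species", genus
                        )
    return TaxonomyTree(nodes)


def _genera(tree: TaxonomyTree) -> list[str]:
    return sorted(t for t, n in tree.nodes.items() if n.rank == "genus")


def _species_of(tree: TaxonomyTree, genus: str) -> list[str]:
    return sorted(tree.children(genus))


# -- curation hits ------------------------------------------------------------------


def _r1(x: float) -> float:
    return round(float(x), 1)


def make_curation_hits(
    tree: TaxonomyTree, spec: FixtureSpec, rng: np.random.Generator
) -> tuple[list[HomologyHit], dict[str, PlantedMarker]]:
    """Plant per-model hit sets with known informative outcome.

    Most models are genus-informative with an S1-S2 gap of
    ``score_separation`` bits; every ``tight_gap_every``-th model gets a gap
    below 3 bits (exercising the per-domain trim guard); every
    ``family_level_every``-th model is planted with overlapping genus ranges
    confined to one subfamily/family (escalation, S2 absent). A trailing
    ``noninformative_fraction`` of models overlaps across orders and is only
    truly non-informative when the taxonomy has >= 2 orders.
    """
    genera = _genera(tree)
    orders = sorted(t for t, n in tree.nodes.items() if n.rank == "order")
    hits: list[HomologyHit] = []
    planted: dict[str, PlantedMarker] = {}
    n_noninf = int(round(spec.noninformative_fraction * spec.n_models))

    def emit(model_id: str, taxid: str, score: float) -> None:
        evalue = 10.0 ** (-float(rng.uniform(5, 30)))
        hits.append(HomologyHit(model_id=model_id, seq_id=f"{taxid}_p{len(hits)}",
                                taxid=taxid, evalue=evalue, full_score=score))

    def overlapping_pair(model_id: str, ga: str, gb: str) -> float:
        """Emit guaranteed-overlapping genus score ranges; return overall min."""
        base_a, base_b = (62.0, 68.0, 74.0), (66.0, 71.0, 76.0)
        lows = []
        for genus, bases in ((ga, base_a), (gb, base_b)):
            for k, taxid in enumerate(_species_of(tree, genus)):
                score = _r1(bases[k % 3] + rng.uniform(-1.0, 1.0))
                emit(model_id, taxid, score)
                lows.append(score)
        return min(lows)

    for i in range(spec.n_models):
        model_id = f"m{i + 1:04d}"
        genus = genera[i % len(genera)]
        noninformative = i >= spec.n_models - n_noninf and spec.taxids_per_genus >= 2
        family_level = (
            not noninformative
            and spec.family_level_every > 0
            and spec.taxids_per_genus >= 2  # overlap needs >= 2 scores per range
            and i % spec.family_level_every == 0
        )
        tight = (
            not noninformative and not family_level
            and spec.tight_gap_every > 0
            and i % spec.tight_gap_every == spec.tight_gap_every - 1
        )

        if noninformative:
            # overlap across two different orders -> overlap at every rank
            other = next(
                (g for g in genera
                 if tree.ancestor_at(g, "order") != tree.ancestor_at(genus, "order")),
                None,
            )
            if other is None:  # single-order taxonomy: cannot plant these
                other = genera[(genera.index(genus) + 1) % len(genera)]
            overlapping_pair(model_id, genus, other)
            planted[model_id] = PlantedMarker(model_id, None, None, None, None)
            continue

        if family_level:
            parent = tree.nodes[genus].parent  # subfamily or family
            siblings = [g for g in tree.children(parent) if g != genus]
            if siblings:
                s1 = overlapping_pair(model_id, genus, siblings[0])
                rank = tree.rank(parent)
                planted[model_id] = PlantedMarker(model_id, rank, parent, s1, None)
                continue
            # no sibling genus: fall through to genus-level planting

        # genus-informative model
        target_scores = []
        for taxid in _species_of(tree, genus):
            score = _r1(rng.uniform(60.0, 80.0))
            emit(model_id, taxid, score)
            if rng.random() < 0.3:  # duplicate lower hit: per-taxid max must win
                emit(model_id, taxid, _r1(score - rng.uniform(5.0, 20.0)))
            target_scores.append(score)
        s1 = min(target_scores)
        other = genera[(genera.index(genus) + 1) % len(genera)]
        if other == genus:  # single-genus taxonomy: no competitor, S2 absent
            planted[model_id] = PlantedMarker(model_id, "genus", genus, s1, None)
            continue
        gap = float(rng.uniform(0.5, 2.5)) if tight else spec.score_separation
        s2 = _r1(s1 - gap)
        off_taxids = _species_of(tree, other)
        emit(model_id, off_taxids[0], s2)  # force the off-target max
        for taxid in off_taxids[1:]:
            emit(model_id, taxid, _r1(s2 - rng.uniform(1.0, 15.0)))
        planted[model_id] = PlantedMarker(model_id, "genus", genus, s1, s2)

    return hits, planted


def write_curation_hits_tsv(hits: Sequence[HomologyHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("model_id\tseq_id\ttaxid\tevalue\tfull_score\n")
        for h in hits:
            fh.write(f"{h.model_id}\t{h.seq_id}\t{h.taxid}\t{h.evalue:.3e}\t"
                     f"{h.full_score:g}\n")


# -- assemblies ---------------------------------------------------------------------


def make_assemblies(
    tree: TaxonomyTree, spec: FixtureSpec, rng: np.random.Generator
) -> list[AssemblyRecord]:
    """Per-genus assembly CDS counts sized so that planted contigs always
    satisfy the CDS-count voting condition (mean + 2*sd covers the maximum
    contig CDS count)."""
    base = max(1, math.ceil(spec.length_range[1] / 1000.0 * spec.cds_per_kb))
    factors = np.linspace(0.7, 1.3, max(2, spec.assemblies_per_genus))
    records = []
    for genus in _genera(tree):
        species = _species_of(tree, genus)
        for k, f in enumerate(factors):
            records.append(
                AssemblyRecord(
                    assembly_id=f"asm_{genus}_{k + 1}",
                    taxid=species[k % len(species)],
                    cds_count=max(1, int(round(base * f))),
                )
            )
    return records


def write_assemblies_tsv(records: Sequence[AssemblyRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("assembly_id\ttaxid\tcds_count\n")
        for r in records:
            fh.write(f"{r.assembly_id}\t{r.taxid}\t{r.cds_count}\n")


# -- contig set ---------------------------------------------------------------------

_DOMTBL_HEADER = (
    "#                                                               "
    "--- full sequence --- -------------- this domain -------------   "
    "hmm coord   ali coord   env coord\n"
    "# target name        accession   tlen query name           accession  "
    " qlen   E-value  score  bias   #  of  c-Evalue  i-Evalue  score  bias  "
    "from    to  from    to  from    to  acc description of target\n"
)


class ContigSetWriter:
    """Accumulates the per-contig fixture files emitted by make_contig_set."""

    def __init__(self) -> None:
        self.fasta: list[str] = []
        self.gff3: list[str] = ["##gff-version 3\n"]
        self.domtbl: list[str] = [_DOMTBL_HEADER]
        self.virsorter: list[str] = ["contig,category,region_start,region_end\n"]
        self.virfinder: list[str] = ["name\tlength\tscore\tpvalue\n"]
        self.pprmeta: list[str] = [
            "Header,Length,phage_score,chromosome_score,plasmid_score,Possible_source\n"
        ]
        self.coords: list[str] = []


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def _emit_domtbl_row(
    writer: ContigSetWriter, model_id: str, cds_id: str,
    evalue: float, full: float, dom: float,
) -> None:
    writer.domtbl.append(
        f"{model_id:<20s} -            200 {cds_id:<20s} -            150 "
        f"{evalue:9.2e} {full:6.1f}   0.1   1   1 {evalue:9.2e} {evalue:9.2e} "
        f"{dom:6.1f}   0.1     1   140     3   145     1   148 0.95 -\n"
    )


def make_contig_set(
    tree: TaxonomyTree,
    markers: Mapping[str, InformativeMarker],
    spec: FixtureSpec,
    rng: np.random.Generator,
) -> tuple[ContigSetWriter, dict[str, ContigTruth]]:
    """Emit FASTA + GFF3 + domain table + predictor tables + coords.

    Viral contigs draw CDS hits from their source genus's genus-rank
    markers (cross-genus with probability ``noise``), always above the
    marker's calibrated gates. Triage evidence cycles HC / LC (all three
    rules) / PP and is corrupted with ``predictor_error_rate`` (viral
    contigs lose their evidence; non-viral contigs gain a spurious HC
    call). Alignments cover viral contigs at 90% length / 95% identity and
    non-viral contigs below one of the two truth thresholds.
    """
    genus_markers: dict[str, list[InformativeMarker]] = {}
    for m in markers.values():
        if m.rank == "genus":
            genus_markers.setdefault(m.taxon, []).append(m)
    for ms in genus_markers.values():
        ms.sort(key=lambda m: m.model_id)
    source_genera = sorted(genus_markers)
    if not source_genera:
        raise ValueError("no genus-rank markers available for contig planting")
    all_marker_list = [m for g in source_genera for m in genus_markers[g]]

    writer = ContigSetWriter()
    truth: dict[str, ContigTruth] = {}
    n_viral = int(round(spec.viral_fraction * spec.n_contigs))
    lo, hi = spec.length_range

    for j in range(spec.n_contigs):
        cid = f"contig_{j + 1:04d}"
        viral = j < n_viral
        length = int(rng.integers(lo, hi + 1))
        seq = _random_sequence(rng, length)
        writer.fasta.append(f">{cid}\n{seq}\n")
        n_cds = max(1, int(round(length / 1000.0 * spec.cds_per_kb)))
        step = length // n_cds
        for k in range(n_cds):
            start = k * step + 1
            end = min(start + max(90, step // 2), length)
            writer.gff3.append(
                f"{cid}\tsim\tCDS\t{start}\t{end}\t.\t+\t0\tID={cid}_{k + 1}\n"
            )

        source_genus: str | None = None
        if viral:
            source_genus = source_genera[j % len(source_genera)]
            own = genus_markers[source_genus]
            for k in range(n_cds):
                if k > 0 and rng.random() > spec.hit_density:
                    continue
                if rng.random() < spec.noise:
                    marker = all_marker_list[int(rng.integers(len(all_marker_list)))]
                else:
                    marker = own[k % len(own)]
                full = _r1(marker.ga_seq + rng.uniform(1.0, 20.0))
                dom = _r1(full - 1.0)
                cds_id = f"{cid}_{k + 1}"
                evalue = 10.0 ** (-float(rng.uniform(10, 40)))
                _emit_domtbl_row(writer, marker.model_id, cds_id, evalue, full, dom)
                if k % 7 == 3:  # extra weaker domain row: parser must keep the max
                    _emit_domtbl_row(writer, marker.model_id, cds_id, evalue,
                                     full, _r1(dom - 5.0))
        elif rng.random() < 0.3 and all_marker_list:
            # sub-threshold decoy hit on a non-viral contig: must be gated out
            marker = all_marker_list[int(rng.integers(len(all_marker_list)))]
            full = _r1(marker.ga_seq - 5.0)
            _emit_domtbl_row(writer, marker.model_id, f"{cid}_1", 0.5, full,
                             _r1(full - 1.0))

        # --- predictor evidence + planted verdict
        verdict, kind, regions = "excluded", "none", ()
        dropped = viral and rng.random() < spec.predictor_error_rate
        spurious = (not viral) and rng.random() < spec.predictor_error_rate
        if viral and not dropped:
            kind = _VERDICT_CYCLE[j % len(_VERDICT_CYCLE)]
            if kind == "HC":
                verdict = "HC"
                writer.virsorter.append(f"{cid},{1 + j % 2},,\n")
            elif kind == "PP":
                verdict = "PP"
                start1, end1 = length // 4 + 1, (3 * length) // 4
                cat = 4 + (j // len(_VERDICT_CYCLE)) % 2
                writer.virsorter.append(f"{cid},{cat},{start1},{end1}\n")
                regions = ((start1 - 1, end1),)
            else:
                verdict = "LC"
                if kind == "LC1":
                    writer.virfinder.append(f"{cid}\t{length}\t0.95\t0.01\n")
                elif kind == "LC2":
                    writer.virfinder.append(f"{cid}\t{length}\t0.75\t0.01\n")
                    writer.virsorter.append(f"{cid},3,,\n")
                else:  # LC3
                    writer.virfinder.append(f"{cid}\t{length}\t0.75\t0.01\n")
                    writer.pprmeta.append(f"{cid},{length},0.9,0.05,0.05,phage\n")
        elif spurious:
            verdict, kind = "HC", "HC"
            writer.virsorter.append(f"{cid},1,,\n")
        elif not viral:
            writer.virfinder.append(f"{cid}\t{length}\t0.30\t0.60\n")
            writer.pprmeta.append(f"{cid},{length},0.1,0.8,0.1,chromosome\n")

        # --- alignment coords (truth labelling)
        ref = f"ref_{source_genus}" if source_genus else "ref_host"
        if viral:
            end = max(1, int(round(0.9 * length)))
            if j % 3 == 0 and end > 400:  # split into two overlapping pieces
                mid = end // 2
                for qs, qe in ((1, mid + 100), (mid, end)):
                    writer.coords.append(
                        f"{qs}\t{qe}\t{qs}\t{qe}\t{qe - qs + 1}\t{qe - qs + 1}\t"
                        f"95.00\t{ref}\t{cid}\n"
                    )
            else:
                writer.coords.append(
                    f"1\t{end}\t1\t{end}\t{end}\t{end}\t95.00\t{ref}\t{cid}\n"
                )
        else:
            if j % 2 == 0:  # high identity, low coverage
                end = max(1, int(round(0.4 * length)))
                writer.coords.append(
                    f"1\t{end}\t1\t{end}\t{end}\t{end}\t95.00\t{ref}\t{cid}\n"
                )
            else:  # high coverage, low identity
                end = max(1, int(round(0.8 * length)))
                writer.coords.append(
                    f"1\t{end}\t1\t{end}\t{end}\t{end}\t85.00\t{ref}\t{cid}\n"
                )

        truth[cid] = ContigTruth(
            contig_id=cid, length=length, viral=viral, source_genus=source_genus,
            verdict=verdict, triage_kind=kind, prophage_regions=tuple(regions),
        )
    return writer, truth


# -- ground-truth IO ----------------------------------------------------------------


def write_truth_markers_tsv(planted: Mapping[str, PlantedMarker], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("model_id\trank\ttaxon\tS1\tS2\n")
        for model_id in sorted(planted):
            p = planted[model_id]
            fh.write(
                "\t".join([
                    p.model_id, p.rank or "", p.taxon or "",
                    "" if p.s1 is None else f"{p.s1:g}",
                    "" if p.s2 is None else f"{p.s2:g}",
                ]) + "\n"
            )


def write_truth_contigs_tsv(truth: Mapping[str, ContigTruth], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("contig_id\tlength\tlabel\tsource_genus\tverdict\tkind\tregions\n")
        for cid in sorted(truth):
            t = truth[cid]
            regions = ";".join(f"{s}-{e}" for s, e in t.prophage_regions)
            fh.write(
                f"{cid}\t{t.length}\t{'viral' if t.viral else 'non-viral'}\t"
                f"{t.source_genus or ''}\t{t.verdict}\t{t.triage_kind}\t{regions}\n"
            )


# -- orchestration ------------------------------------------------------------------


def generate_bundle(spec: FixtureSpec, outdir: str | Path | None = None) -> FixtureBundle:
    """Generate the full fixture bundle, optionally writing it to ``outdir``."""
    rng = np.random.default_rng(spec.seed)
    tree = make_taxonomy(spec)
    hits, planted = make_curation_hits(tree, spec, rng)
    markers = {
        p.model_id: InformativeMarker.from_scores(
            p.model_id, p.rank, p.taxon, p.s1, p.s2
        )
        for p in planted.values()
        if p.rank is not None
    }
    assemblies = make_assemblies(tree, spec, rng)
    writer, contig_truth = make_contig_set(tree, markers, spec, rng)
    truth = GroundTruth(markers=dict(planted), contigs=contig_truth)
    bundle = FixtureBundle(
        spec=spec, tree=tree, curation_hits=hits, planted_markers=markers,
        assemblies=assemblies, truth=truth, genera=_genera(tree),
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_lineage_tsv(tree, outdir / "taxonomy.tsv")
        write_curation_hits_tsv(hits, outdir / "curation_hits.tsv")
        write_assemblies_tsv(assemblies, outdir / "assemblies.tsv")
        (outdir / "contigs.fasta").write_text("".join(writer.fasta))
        (outdir / "genes.gff3").write_text("".join(writer.gff3))
        (outdir / "scan.domtbl").write_text("".join(writer.domtbl))
        (outdir / "virsorter.csv").write_text("".join(writer.virsorter))
        (outdir / "virfinder.tsv").write_text("".join(writer.virfinder))
        (outdir / "pprmeta.csv").write_text("".join(writer.pprmeta))
        (outdir / "alignments.coords").write_text("".join(writer.coords))
        write_truth_markers_tsv(truth.markers, outdir / "truth_markers.tsv")
        write_truth_contigs_tsv(truth.contigs, outdir / "truth_contigs.tsv")
        spec.to_yaml(outdir / "spec.yaml")
        bundle.outdir = outdir
    return bundle
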