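"""Shared fixtures and independent oracles.

The oracles here deliberately re-derive results with naive algorithms
(parent walks, literal condition checks, exhaustive enumeration) so the
production code paths are checked against something that does not share
their implementation.
"""

from __future__ import annotations

import pytest

from viromarker.taxonomy import TaxonNode, TaxonomyTree, WORKING_RANKS


def make_tree(edges: list[tuple[str, str, str]]) -> TaxonomyTree:
    """Build a tree from (taxid, rank, parent) triples; parent '' => root."""
    nodes = {}
    for taxid, rank, parent in edges:
        nodes[taxid] = TaxonNode(taxid, taxid.upper(), rank, parent or taxid)
    return TaxonomyTree(nodes)


@pytest.fixture
def small_tree() -> TaxonomyTree:
    """root > order O > family F > {genus A > (t1,t2), genus B > (t3)}."""
    return make_tree(
        [
            ("O", "order", ""),
            ("F", "family", "O"),
            ("A", "genus", "F"),
            ("B", "genus", "F"),
            ("t1", "species", "A"),
            ("t2", "species", "A"),
            ("t3", "species", "B"),
        ]
    )


# -- naive taxonomy oracles ---------------------------------------------------------


def naive_ancestor_at(tree: TaxonomyTree, taxid: str, rank: str) -> str | None:
    """Walk parent pointers literally, no Lineage machinery."""
    cur = taxid
    while True:
        node = tree.nodes[cur]
        if node.rank == rank:
            return cur
        if node.parent == cur:
            return None
        cur = node.parent


def naive_descendants(tree: TaxonomyTree, taxon: str) -> set[str]:
    """Brute force: a node is a descendant iff taxon sits on its root path."""
    out = set()
    for t in tree.nodes:
        if t == taxon:
            continue
        cur = t
        while True:
            node = tree.nodes[cur]
            if node.parent == cur:
                break
            cur = node.parent
            if cur == taxon:
                out.add(t)
                break
    return out


# -- curation oracle ----------------------------------------------------------------


def curation_oracle(hits, tree):
    """Literal exhaustive re-statement of the informative-selection rules.

    hits: iterable of (taxid, score) pairs for one model.
    Returns (rank, taxon, S1, S2) or None.
    """
    best_per_taxid: dict[str, float] = {}
    for taxid, score in hits:
        best_per_taxid[taxid] = max(best_per_taxid.get(taxid, float("-inf")), score)
    for rank in WORKING_RANKS:
        groups: dict[str, list[float]] = {}
        for taxid, score in best_per_taxid.items():
            anc = naive_ancestor_at(tree, taxid, rank)
            if anc is not None:
                groups.setdefault(anc, []).append(score)
        if not groups:
            continue
        ranges = {t: (min(v), max(v)) for t, v in groups.items()}
        best = sorted(ranges, key=lambda t: (-ranges[t][1], -ranges[t][0], t))[0]
        others = {t: r for t, r in ranges.items() if t != best}
        if not others:
            return rank, best, ranges[best][0], None
        other_max = max(r[1] for r in others.values())
        if ranges[best][0] > other_max:
            return rank, best, ranges[best][0], other_max
    return None


# -- voting oracle ------------------------------------------------------------------


def vote_oracle(hit_taxa, n_cds, stats, tree, factor=0.6):
    """Literal brute-force re-statement of the two voting conditions.

    hit_taxa: list of marker taxon ids (one per retained informative hit).
    stats: taxon -> (tsr, mean_cds, sd_cds); missing taxa get TSR 1 and a
    waived CDS condition.
    Returns (rank, taxon, proportion) or None.
    """
    total = len(hit_taxa)
    if total == 0:
        return None
    for rank in WORKING_RANKS:
        tallies: dict[str, int] = {}
        for taxon in hit_taxa:
            anc = naive_ancestor_at(tree, taxon, rank)
            if anc is not None:
                tallies[anc] = tallies.get(anc, 0) + 1
        if not tallies:
            continue

        def tsr_of(t):
            return stats[t][0] if t in stats else 1.0

        ordered = sorted(
            tallies, key=lambda t: (-tallies[t] / total, -tsr_of(t), t)
        )
        for taxon in ordered:
            proportion = tallies[taxon] / total
            cond1 = proportion >= factor * tsr_of(taxon)
            if taxon in stats:
                _, mean, sd = stats[taxon]
                cond2 = n_cds <= mean + 2 * sd
            else:
                cond2 = True
            if cond1 and cond2:
                return rank, taxon, proportion
    return None
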