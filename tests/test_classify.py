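import random

import pytest

from conftest import make_tree, vote_oracle
from viromarker.classify import (
    ContigHitProfile,
    DomTableError,
    RetainedHit,
    best_hit_per_cds,
    cds_counts_from_faa,
    cds_counts_from_gff3,
    contig_of_cds,
    gate_hits,
    parse_domain_table,
    vote,
)
from viromarker.curation import HomologyHit, InformativeMarker
from viromarker.taxon_stats import TaxonStats
from viromarker.taxonomy import WORKING_RANKS

DOMTBL_ROW = (
    "{model:<20s} -            200 {cds:<20s} -            150 "
    "{ev:9.2e} {full:6.1f}   0.1   1   2 {ev:9.2e} {ev:9.2e} {dom:6.1f}   0.1"
    "     1   140     3   145     1   148 0.95 -\n"
)


def write_domtbl(path, rows):
    path.write_text("# comment\n" + "".join(
        DOMTBL_ROW.format(model=m, cds=c, ev=e, full=f, dom=d)
        for m, c, e, f, d in rows
    ))


def tstat(taxon, rank, mean, sd, n_markers=5, tsr=None):
    if tsr is None:
        tsr = min(1.0, n_markers / mean)
    return TaxonStats(taxon=taxon, rank=rank, mean_cds=mean, sd_cds=sd,
                      n_assemblies=3, n_markers=n_markers, tsr=tsr)


def marker(model, rank, taxon, s1=50.0, s2=40.0):
    return InformativeMarker.from_scores(model, rank, taxon, s1, s2)


def rhit(cds, model, taxon, rank="genus", conf="high"):
    return RetainedHit(cds, model, taxon, rank, conf, 60.0, 58.0)


# -- domain table parser ------------------------------------------------------------


def test_parser_contract_single_row(tmp_path):
    p = tmp_path / "scan.domtbl"
    write_domtbl(p, [("m0001", "c1_1", 1e-20, 62.3, 58.1)])
    hits = parse_domain_table(p)
    assert len(hits) == 1
    h = hits[0]
    assert (h.model_id, h.seq_id) == ("m0001", "c1_1")
    assert h.evalue == pytest.approx(1e-20)
    assert h.full_score == pytest.approx(62.3)
    assert h.best_domain_score == pytest.approx(58.1)


def test_parser_collapses_domain_rows_to_best(tmp_path):
    p = tmp_path / "scan.domtbl"
    write_domtbl(p, [("m0001", "c1_1", 1e-20, 62.3, 30.0),
                     ("m0001", "c1_1", 1e-20, 62.3, 45.0)])
    hits = parse_domain_table(p)
    assert len(hits) == 1
    assert hits[0].best_domain_score == pytest.approx(45.0)


def test_parser_comment_only_file(tmp_path):
    p = tmp_path / "scan.domtbl"
    p.write_text("# only\n# comments\n")
    assert parse_domain_table(p) == []


def test_parser_short_row_error_names_line(tmp_path):
    p = tmp_path / "scan.domtbl"
    p.write_text("m0001 c1_1 1e-20\n")
    with pytest.raises(DomTableError, match=":1"):
        parse_domain_table(p)


# -- gating -------------------------------------------------------------------------


def hh(model, cds, ev, full, dom):
    return HomologyHit(model_id=model, seq_id=cds, evalue=ev, full_score=full,
                       best_domain_score=dom)


def test_gate_thresholded_pass_and_fail():
    markers = {"m1": marker("m1", "genus", "A", 50.0, 40.0)}  # GA 50/47
    kept = gate_hits([hh("m1", "c1_1", 1e-9, 52.0, 48.0)], markers)
    assert len(kept) == 1 and kept[0].confidence == "high"
    assert gate_hits([hh("m1", "c1_1", 1e-9, 52.0, 46.0)], markers) == []
    assert gate_hits([hh("m1", "c1_1", 1e-9, 49.0, 48.0)], markers) == []


def test_gate_unthresholded_evalue_route():
    kept = gate_hits([hh("mX", "c1_1", 5e-4, 20.0, 18.0)], {})
    assert len(kept) == 1
    assert kept[0].confidence == "low" and kept[0].marker_taxon is None
    assert gate_hits([hh("mX", "c1_1", 0.01, 20.0, 18.0)], {}) == []


def test_gate_unknown_models_dropped_when_catalog_given():
    kept = gate_hits([hh("mX", "c1_1", 1e-9, 20.0, 18.0)], {}, all_models={"mY"})
    assert kept == []


# -- per-CDS dedup ------------------------------------------------------------------


def test_contig_of_cds_naming():
    assert contig_of_cds("NODE_22_7") == "NODE_22"
    assert contig_of_cds("contig_0001_3") == "contig_0001"
    assert contig_of_cds("nounderscore") is None
    assert contig_of_cds("c1_notanumber") is None


def test_best_hit_per_cds_keeps_highest_full_score():
    a = RetainedHit("c1_1", "mA", "A", "genus", "high", 40.0, 39.0)
    b = RetainedHit("c1_1", "mB", "B", "genus", "high", 55.0, 50.0)
    by_contig, orphans = best_hit_per_cds([a, b])
    assert by_contig == {"c1": [b]} and orphans == []


def test_best_hit_tie_broken_by_domain_then_model():
    a = RetainedHit("c1_1", "mA", "A", "genus", "high", 55.0, 30.0)
    b = RetainedHit("c1_1", "mB", "B", "genus", "high", 55.0, 40.0)
    by_contig, _ = best_hit_per_cds([a, b])
    assert by_contig["c1"] == [b]
    c = RetainedHit("c1_1", "mC", "C", "genus", "high", 55.0, 40.0)
    by_contig, _ = best_hit_per_cds([b, c])
    assert by_contig["c1"] == [b]  # lexicographically smaller model id


def test_single_hit_identity_and_orphans():
    a = RetainedHit("c1_1", "mA", "A", "genus", "high", 40.0, 39.0)
    o = RetainedHit("weird", "mA", "A", "genus", "high", 40.0, 39.0)
    by_contig, orphans = best_hit_per_cds([a, o])
    assert by_contig == {"c1": [a]}
    assert orphans == [o]


# -- voting -------------------------------------------------------------------------


@pytest.fixture
def vote_tree():
    return make_tree(
        [("O", "order", ""), ("F", "family", "O"), ("S", "subfamily", "F"),
         ("G", "genus", "S"), ("H", "genus", "S")]
    )


def six_hit_profile(n_cds):
    hits = [rhit(f"c1_{i}", f"m{i}", "G") for i in range(1, 6)]
    hits.append(rhit("c1_6", "m6", "H"))
    return ContigHitProfile("c1", n_cds, hits)


def test_vote_classifies_at_genus(vote_tree):
    stats = {"G": tstat("G", "genus", 12.0, 2.0, tsr=0.8),
             "H": tstat("H", "genus", 12.0, 2.0, tsr=0.8)}
    c = vote(six_hit_profile(n_cds=10), stats, vote_tree)
    assert c.outcome == "classified"
    assert (c.deciding_rank, c.winning_taxon) == ("genus", "G")
    assert c.proportion == pytest.approx(5 / 6)
    assert c.lineage.genus == "G" and c.lineage.family == "F"


def test_vote_escalates_on_cds_condition(vote_tree):
    stats = {"G": tstat("G", "genus", 12.0, 2.0, tsr=0.8),
             "H": tstat("H", "genus", 12.0, 2.0, tsr=0.8),
             "S": tstat("S", "subfamily", 25.0, 5.0, tsr=1.0)}
    c = vote(six_hit_profile(n_cds=20), stats, vote_tree)
    # G fails n_cds <= 12 + 2*2; H fails the proportion condition;
    # at subfamily S: proportion 1 >= 0.6 and 20 <= 35
    assert (c.deciding_rank, c.winning_taxon) == ("subfamily", "S")
    assert c.proportion == pytest.approx(1.0)
    assert c.lineage.genus is None  # lineage reported from deciding rank upward
    assert c.lineage.subfamily == "S" and c.lineage.order == "O"


def test_vote_zero_hits_unclassified(vote_tree):
    c = vote(ContigHitProfile("c1", 5, []), {}, vote_tree)
    assert c.outcome == "unclassified"
    low_only = ContigHitProfile(
        "c1", 5, [RetainedHit("c1_1", "mX", None, None, "low", 20.0, 18.0)]
    )
    c2 = vote(low_only, {}, vote_tree)
    assert c2.outcome == "unclassified" and c2.n_hits_low == 1


def test_vote_factor_zero_accepts_top_candidate(vote_tree):
    stats = {"G": tstat("G", "genus", 100.0, 50.0, tsr=1.0),
             "H": tstat("H", "genus", 100.0, 50.0, tsr=1.0)}
    c = vote(six_hit_profile(n_cds=10), stats, vote_tree, factor=0.0)
    assert (c.deciding_rank, c.winning_taxon) == ("genus", "G")


def test_vote_missing_stats_waives_with_warning(vote_tree):
    profile = ContigHitProfile("c1", 500, [rhit("c1_1", "m1", "G")])
    with pytest.warns(UserWarning, match="no taxon stats"):
        c = vote(profile, {}, vote_tree)
    assert (c.deciding_rank, c.winning_taxon) == ("genus", "G")


def test_vote_proportion_counts_denominator_only_hits(vote_tree):
    # an order-rank marker hit contributes to no genus candidate but stays
    # in the denominator during genus voting
    hits = [rhit("c1_1", "m1", "G"), rhit("c1_2", "m2", "O", rank="order")]
    stats = {"G": tstat("G", "genus", 12.0, 2.0, tsr=0.8)}
    c = vote(ContigHitProfile("c1", 5, hits), stats, vote_tree)
    assert (c.deciding_rank, c.winning_taxon) == ("genus", "G")
    assert c.proportion == pytest.approx(0.5)


# -- oracle equivalence + monotone coarsening ---------------------------------------


def _random_vote_setup(rng):
    edges = [("root", "no-rank", "")]
    genera = []
    for o in range(2):
        edges.append((f"o{o}", "order", "root"))
        for f in range(2):
            fam = f"o{o}f{f}"
            edges.append((fam, "family", f"o{o}"))
            for g in range(2):
                gen = f"{fam}g{g}"
                edges.append((gen, "genus", fam))
                genera.append(gen)
    tree = make_tree(edges)
    stats = {}
    for t, node in tree.nodes.items():
        if node.rank in WORKING_RANKS and rng.random() < 0.8:
            mean = rng.uniform(5, 30)
            sd = rng.uniform(0, 5)
            stats[t] = (round(min(1.0, rng.uniform(0.1, 2.0)), 3), mean, sd)
    return tree, genera, stats


def _stats_objects(tree, stats):
    return {
        t: TaxonStats(taxon=t, rank=tree.rank(t), mean_cds=m, sd_cds=s,
                      n_assemblies=3, n_markers=1, tsr=r)
        for t, (r, m, s) in stats.items()
    }


def test_vote_agrees_with_bruteforce_oracle_randomized():
    rng = random.Random(99)
    for trial in range(300):
        tree, genera, stats = _random_vote_setup(rng)
        n_hits = rng.randrange(1, 9)
        hit_taxa = [rng.choice(genera) for _ in range(n_hits)]
        n_cds = rng.randrange(1, 40)
        factor = rng.choice([0.0, 0.3, 0.6, 0.9])
        profile = ContigHitProfile(
            "c1", n_cds,
            [rhit(f"c1_{i}", f"m{i}", t) for i, t in enumerate(hit_taxa, 1)],
        )
        got = vote(profile, _stats_objects(tree, stats), tree, factor=factor)
        expected = vote_oracle(hit_taxa, n_cds, stats, tree, factor=factor)
        if expected is None:
            assert got.outcome == "unclassified", f"trial {trial}"
        else:
            assert (got.deciding_rank, got.winning_taxon) == expected[:2]
            assert got.proportion == pytest.approx(expected[2])


def test_monotone_rank_coarsening_in_factor():
    rng = random.Random(5)
    rank_index = {r: i for i, r in enumerate(WORKING_RANKS)}
    for _ in range(50):
        tree, genera, stats = _random_vote_setup(rng)
        hit_taxa = [rng.choice(genera) for _ in range(rng.randrange(1, 7))]
        n_cds = rng.randrange(1, 40)
        profile = ContigHitProfile(
            "c1", n_cds,
            [rhit(f"c1_{i}", f"m{i}", t) for i, t in enumerate(hit_taxa, 1)],
        )
        prev = -1
        for factor in (0.0, 0.25, 0.5, 0.75, 1.0):
            c = vote(profile, _stats_objects(tree, stats), tree, factor=factor)
            idx = (rank_index[c.deciding_rank]
                   if c.outcome == "classified" else len(WORKING_RANKS))
            assert idx >= prev
            prev = idx


# -- CDS inventories ----------------------------------------------------------------


def test_cds_counts_from_gff3(tmp_path):
    p = tmp_path / "genes.gff3"
    p.write_text(
        "##gff-version 3\n"
        "c1\tsim\tCDS\t1\t300\t.\t+\t0\tID=c1_1\n"
        "c1\tsim\tCDS\t400\t700\t.\t+\t0\tID=c1_2\n"
        "c1\tsim\tgene\t1\t700\t.\t+\t.\tID=g1\n"
        "c2\tsim\tCDS\t1\t300\t.\t-\t0\tID=c2_1\n"
    )
    assert cds_counts_from_gff3(p) == {"c1": 2, "c2": 1}


def test_cds_counts_from_faa(tmp_path):
    p = tmp_path / "prot.faa"
    p.write_text(">c1_1 x\nMA\n>c1_2\nMA\n>c2_1\nMA\n")
    assert cds_counts_from_faa(p) == {"c1": 2, "c2": 1}
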