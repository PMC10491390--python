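import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import curation_oracle, make_tree
from viromarker.curation import (
    CalibrationError,
    HmmFormatError,
    HomologyHit,
    InformativeMarker,
    annotate_hmm,
    best_scores_by_taxon,
    calibrate_all,
    derive_thresholds,
    read_hmm_cutoffs,
    read_markers_tsv,
    select_informative,
    write_markers_tsv,
)


def hit(model, taxid, score, evalue=1e-10):
    return HomologyHit(model_id=model, seq_id=f"{taxid}_{score}", evalue=evalue,
                       full_score=score, taxid=taxid)


@pytest.fixture
def two_genus_tree():
    return make_tree(
        [("O", "order", ""), ("F", "family", "O"),
         ("A", "genus", "F"), ("B", "genus", "F"),
         ("t1", "species", "A"), ("t2", "species", "A"), ("t3", "species", "B")]
    )


# -- best_scores_by_taxon -----------------------------------------------------------


def test_best_scores_per_taxid_max_then_grouped(two_genus_tree):
    hits = [hit("m", "t1", 60.0), hit("m", "t1", 42.0), hit("m", "t2", 55.0)]
    ranges = best_scores_by_taxon(hits, two_genus_tree, "genus")
    assert set(ranges) == {"A"}
    assert (ranges["A"].low, ranges["A"].high) == (55.0, 60.0)


def test_best_scores_singleton(two_genus_tree):
    ranges = best_scores_by_taxon([hit("m", "t1", 60.0)], two_genus_tree, "genus")
    assert (ranges["A"].low, ranges["A"].high) == (60.0, 60.0)


def test_best_scores_drops_taxids_without_rank_ancestor(two_genus_tree):
    # the order node itself has no genus ancestor
    assert best_scores_by_taxon([hit("m", "O", 60.0)], two_genus_tree, "genus") == {}


def test_best_scores_empty(two_genus_tree):
    assert best_scores_by_taxon([], two_genus_tree, "genus") == {}


# -- select_informative -------------------------------------------------------------


def test_select_separated_genus(two_genus_tree):
    hits = [hit("m", "t1", 55.0), hit("m", "t2", 60.0), hit("m", "t3", 40.0)]
    assert select_informative(hits, two_genus_tree) == ("genus", "A", 55.0, 40.0)


def test_select_escalates_to_family_on_overlap(two_genus_tree):
    hits = [hit("m", "t1", 55.0), hit("m", "t2", 60.0), hit("m", "t3", 58.0)]
    # genus ranges A=[55,60], B=[58,58] overlap; family F is the sole taxon
    assert select_informative(hits, two_genus_tree) == ("family", "F", 55.0, None)


def test_select_single_taxon_branch(two_genus_tree):
    hits = [hit("m", "t1", 60.0)]
    assert select_informative(hits, two_genus_tree) == ("genus", "A", 60.0, None)


def test_select_empty_returns_none(two_genus_tree):
    assert select_informative([], two_genus_tree) is None


def test_select_exact_boundary_overlap_is_not_informative(two_genus_tree):
    # best low == other high: strict comparison -> overlap -> escalate
    hits = [hit("m", "t1", 58.0), hit("m", "t2", 60.0), hit("m", "t3", 58.0)]
    assert select_informative(hits, two_genus_tree) == ("family", "F", 58.0, None)


def test_select_invariant_to_duplicates_and_order(two_genus_tree):
    hits = [hit("m", "t1", 55.0), hit("m", "t2", 60.0), hit("m", "t3", 40.0)]
    shuffled = hits[::-1] + [hit("m", "t3", 40.0), hit("m", "t1", 55.0)]
    assert select_informative(hits, two_genus_tree) == select_informative(
        shuffled, two_genus_tree
    )


def _random_forest_tree(rng):
    edges = [("root", "no-rank", "")]
    taxids = []
    for o in range(2):
        edges.append((f"o{o}", "order", "root"))
        for f in range(2):
            fam = f"o{o}f{f}"
            edges.append((fam, "family", f"o{o}"))
            for g in range(2):
                gen = f"{fam}g{g}"
                edges.append((gen, "genus", fam))
                for s in range(2):
                    sp = f"{gen}s{s}"
                    edges.append((sp, "species", gen))
                    taxids.append(sp)
    return make_tree(edges), taxids


def test_select_agrees_with_exhaustive_oracle_randomized():
    rng = random.Random(123)
    tree, taxids = _random_forest_tree(rng)
    for trial in range(300):
        n = rng.randrange(1, 8)
        raw = [(rng.choice(taxids), round(rng.uniform(20, 90), 1)) for _ in range(n)]
        hits = [hit("m", t, s) for t, s in raw]
        got = select_informative(hits, tree)
        expected = curation_oracle(raw, tree)
        assert got == expected, f"trial {trial}: {raw}"


# -- derive_thresholds --------------------------------------------------------------


def test_thresholds_direct_formula():
    t = derive_thresholds(50.0, 40.0)
    assert (t.ga_seq, t.tc_seq) == (50.0, 50.0)
    assert (t.ga_dom, t.tc_dom) == (47.0, 47.0)
    assert (t.nc_seq, t.nc_dom) == (40.0, 40.0)


def test_thresholds_trim_guard():
    t = derive_thresholds(50.0, 48.5)
    assert t.ga_dom == t.tc_dom == 50.0
    assert t.nc_seq == 48.5


def test_thresholds_without_s2():
    t = derive_thresholds(50.0, None)
    assert (t.ga_seq, t.ga_dom) == (50.0, 47.0)
    assert t.nc_seq is None and t.nc_dom is None


def test_thresholds_reject_s2_at_or_above_s1():
    with pytest.raises(CalibrationError):
        derive_thresholds(50.0, 50.0)
    with pytest.raises(CalibrationError):
        derive_thresholds(50.0, 51.0)


@given(
    s1=st.floats(min_value=-100, max_value=500, allow_nan=False),
    gap=st.floats(min_value=1e-6, max_value=50, allow_nan=False),
)
@settings(max_examples=200, deadline=None)
def test_threshold_ordering_property(s1, gap):
    s2 = s1 - gap
    t = derive_thresholds(s1, s2)
    assert t.nc_dom == t.nc_seq == s2
    assert s2 < t.tc_dom <= t.tc_seq == s1


# -- annotate_hmm -------------------------------------------------------------------

HMM_TEXT = (
    "HMMER3/f [3.2.1 | June 2018]\n"
    "NAME  m0001\n"
    "LENG  120\n"
    "ALPH  amino\n"
    "CKSUM 1234567\n"
    "STATS LOCAL MSV  -10.1  0.7\n"
    "HMM          A        C        D\n"
    "            m->m     m->i     m->d\n"
    "  COMPO   2.56    3.90    2.76\n"
    "//\n"
)


def marker(s1, s2):
    return InformativeMarker.from_scores("m0001", "genus", "A", s1, s2)


def test_annotate_inserts_cutoff_lines_after_cksum():
    out = annotate_hmm(HMM_TEXT, marker(50.0, 40.0))
    lines = out.splitlines()
    i = lines.index("CKSUM 1234567")
    assert lines[i + 1] == "GA    50.00 47.00;"
    assert lines[i + 2] == "TC    50.00 47.00;"
    assert lines[i + 3] == "NC    40.00 40.00;"
    # body untouched
    assert out.split("HMM          A")[1] == HMM_TEXT.split("HMM          A")[1]


def test_annotate_without_nc_omits_line():
    out = annotate_hmm(HMM_TEXT, marker(50.0, None))
    assert "NC" not in read_hmm_cutoffs(out)
    assert read_hmm_cutoffs(out)["GA"] == (50.0, 47.0)


def test_annotate_idempotent():
    m = marker(50.0, 40.0)
    once = annotate_hmm(HMM_TEXT, m)
    assert annotate_hmm(once, m) == once


def test_annotate_replaces_existing_cutoffs():
    once = annotate_hmm(HMM_TEXT, marker(50.0, 40.0))
    again = annotate_hmm(once, marker(60.0, None))
    cutoffs = read_hmm_cutoffs(again)
    assert cutoffs == {"GA": (60.0, 57.0), "TC": (60.0, 57.0)}


def test_annotate_roundtrip_matches_marker():
    m = marker(52.5, 44.25)
    cutoffs = read_hmm_cutoffs(annotate_hmm(HMM_TEXT, m))
    assert cutoffs["GA"] == (round(m.ga_seq, 2), round(m.ga_dom, 2))
    assert cutoffs["NC"] == (round(m.nc_seq, 2), round(m.nc_dom, 2))


def test_annotate_rejects_malformed_header():
    with pytest.raises(HmmFormatError, match="line 1"):
        annotate_hmm("not a model\n", marker(50.0, None))
    with pytest.raises(HmmFormatError, match="CKSUM"):
        annotate_hmm("HMMER3/f\nNAME x\nHMM  A\n", marker(50.0, None))


# -- markers TSV round trip ---------------------------------------------------------


def test_markers_tsv_roundtrip(tmp_path, two_genus_tree):
    hits = [hit("m1", "t1", 55.0), hit("m1", "t2", 60.0), hit("m1", "t3", 40.0),
            hit("m2", "t3", 33.5)]
    markers = calibrate_all(hits, two_genus_tree)
    p = tmp_path / "markers.tsv"
    write_markers_tsv(markers, p)
    assert read_markers_tsv(p) == markers
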