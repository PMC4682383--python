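import numpy as np
import pytest

from oracles import interval_union_oracle
from stitch16s._dna import IUPAC_SETS, revcomp
from stitch16s.config import PipelineConfig
from stitch16s.insilico import (
    AmpliconHit,
    compare_single_primer,
    epcr,
    epcr_naive,
    expected_amplicon_span,
    locate_spans,
    merge_intervals,
    primer_sensitivity,
    stitch_amplicons,
)
from stitch16s.panel import canonical_anchor, default_panel, full_length_pair, fwd_site, rev_site
from stitch16s.seq_io import PrimerPair, ReferenceDB, SequenceRecord


def test_panel_spans_from_names(panel):
    spans = {p.display: expected_amplicon_span(p) for p in panel}
    assert spans == {
        "8F-534R": 527, "343F-798R": 456, "517F-926R": 410,
        "784F-1114R": 331, "917F-1407R": 491, "1099F-1541R": 443,
    }


def _pair(fwd, rev, display="100F-599R", imin=400, imax=600, name="X"):
    return PrimerPair(name, display, fwd, rev, imin, imax)


def _template_with_sites(rng, fwd, rev, gap=463):
    """Random template with exact binding sites; product = len(fwd)+gap+len(rev)."""
    pad1 = "".join(rng.choice(list("ACGT"), 50))
    mid = "".join(rng.choice(list("ACGT"), gap))
    pad2 = "".join(rng.choice(list("ACGT"), 50))
    return pad1 + fwd + mid + revcomp(rev) + pad2


def test_exact_sites_one_hit(cfg, rng):
    fwd, rev = "ACGTTGCAGGCTATCGAT", "TTGCAACGGATCCATGCA"
    pair = _pair(fwd, rev)
    t = _template_with_sites(rng, fwd, rev)
    hits = epcr(t, pair, cfg)
    assert len(hits) == 1
    assert hits[0].product_len == len(fwd) + 463 + len(rev)
    assert hits[0].fwd_start == 50


def test_three_mismatches_kill_amplification(cfg, rng):
    fwd, rev = "ACGTTGCAGGCTATCGAT", "TTGCAACGGATCCATGCA"
    pair = _pair(fwd, rev)
    t = _template_with_sites(rng, fwd, rev)
    broken = list(t)
    for p in (52, 55, 60):  # inside the forward site
        broken[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[broken[p]]
    assert epcr("".join(broken), pair, cfg) == []
    two = list(t)
    for p in (52, 55):
        two[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[two[p]]
    assert len(epcr("".join(two), pair, cfg)) == 1


def test_product_outside_insert_range_rejected(cfg, rng):
    fwd, rev = "ACGTTGCAGGCTATCGAT", "TTGCAACGGATCCATGCA"
    pair = _pair(fwd, rev, imin=450, imax=550)
    t = _template_with_sites(rng, fwd, rev, gap=560 - len(fwd) - len(rev))
    assert epcr(t, pair, cfg) == []  # product 560 > 550


def test_degenerate_codes_match_without_penalty(cfg, rng):
    fwd = "ACGTRYSWKMCGTAGCAT"
    concrete = "ACGTGCCATCCGTAGCAT"  # every code satisfied
    rev = "TTGCAACGGATCCATGCA"
    pair = _pair(fwd, rev)
    t = _template_with_sites(rng, concrete, rev)
    hits = epcr(t, pair, cfg)
    assert len(hits) == 1 and hits[0].mm_fwd == 0


def test_epcr_matches_naive_scan(cfg, rng, panel):
    """Vectorised scan equals the position-by-position oracle on fuzzed
    templates with planted, randomly mutated sites."""
    for i in range(60):
        pair = panel[int(rng.integers(len(panel)))]
        gap = int(rng.integers(250, 560))
        fwd_c = "".join(
            s[rng.integers(len(s))] for s in (IUPAC_SETS[c] for c in pair.fwd_seq)
        )
        t = _template_with_sites(rng, fwd_c, pair.rev_seq, gap=gap)
        t = list(t)
        for p in rng.choice(len(t), int(rng.integers(0, 8)), replace=False):
            t[p] = "ACGT"[rng.integers(4)]
        t = "".join(t)
        a = epcr(t, pair, cfg, "f")
        b = epcr_naive(t, pair, cfg, "f")
        key = lambda h: (h.fwd_start, h.rev_end)
        assert sorted(map(key, a)) == sorted(map(key, b))


def test_raising_mismatch_budget_is_monotone(rng, panel):
    refs = []
    for i in range(30):
        t = list(canonical_anchor())
        for p in rng.choice(len(t), int(rng.integers(0, 40)), replace=False):
            t[p] = "ACGT"[rng.integers(4)]
        refs.append(SequenceRecord(f"m{i}", "".join(t)))
    db = ReferenceDB(refs, {r.id: ("B", "P", "C", "O", "F", "G") for r in refs})
    pcts = []
    for mm in (0, 1, 2, 3):
        cfg = PipelineConfig(epcr_mm=mm)
        rep = primer_sensitivity(db, panel, canonical_anchor(), cfg)
        pcts.append([row.pct for row in rep.rows] + [rep.union.pct])
    for lo, hi in zip(pcts, pcts[1:]):
        assert all(h >= l for l, h in zip(lo, hi))


@pytest.mark.parametrize(
    "ivs,expected",
    [
        ([(0, 500), (490, 900)], [(0, 900)]),     # 10 bp overlap merges
        ([(0, 500), (491, 900)], [(0, 500), (491, 900)]),  # 9 bp does not
    ],
)
def test_stitch_overlap_boundary(ivs, expected, cfg):
    assert merge_intervals(ivs, cfg.stitch_min_ovl) == expected


def test_merge_matches_interval_union_oracle(rng, cfg):
    for _ in range(300):
        n = int(rng.integers(1, 10))
        ivs = []
        for _ in range(n):
            s = int(rng.integers(0, 1200))
            ivs.append((s, s + int(rng.integers(20, 600))))
        assert merge_intervals(ivs, cfg.stitch_min_ovl) == interval_union_oracle(
            ivs, cfg.stitch_min_ovl
        )


def test_full_panel_amplification_counts_long(cfg, panel, anchor):
    """All six primers on the anchor: one merged run >= 1400 bp, counted long."""
    hits = []
    for p in panel:
        got = epcr(anchor, p, cfg, "anchor")
        assert len(got) == 1
        hits.extend(got)
    lengths, n_long, frac = stitch_amplicons({"anchor": hits}, cfg)
    assert len(lengths["anchor"]) == 1
    assert lengths["anchor"][0] >= 1400
    assert n_long == 1 and frac == 1.0


def test_sensitivity_all_exact_sites(cfg, panel, anchor):
    refs = [SequenceRecord(f"r{i}", anchor) for i in range(5)]
    db = ReferenceDB(refs, {r.id: ("B", "P", "C", "O", "F", "G") for r in refs})
    rep = primer_sensitivity(db, panel, anchor, cfg)
    assert all(row.pct == 100.0 for row in rep.rows)
    assert rep.union.pct == 100.0


def test_short_reference_excluded_from_denominator(cfg, panel, anchor):
    """A sequence starting past primer A's site doesn't count against A."""
    refs = [
        SequenceRecord("full", anchor),
        SequenceRecord("short", anchor[600:]),
    ]
    db = ReferenceDB(refs, {r.id: ("B", "P", "C", "O", "F", "G") for r in refs})
    rep = primer_sensitivity(db, panel, anchor, cfg)
    rows = {r.primer: r for r in rep.rows}
    assert rows["A"].n_covering == 1      # only the full-length sequence
    assert rows["E"].n_covering == 2


def test_engineered_sensitivity_fixture(cfg, panel, anchor, rng):
    """20 full-span refs, 3 with a 3-mismatch primer-C forward site: 85.0%."""
    c = next(p for p in panel if p.name == "C")
    fs = fwd_site(c)
    refs = []
    for i in range(20):
        seq = list(anchor)
        if i < 3:
            for p in range(fs[0] + 1, fs[0] + 4):
                seq[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[p]]
        refs.append(SequenceRecord(f"r{i}", "".join(seq)))
    db = ReferenceDB(refs, {r.id: ("B", "P", "C", "O", "F", "G") for r in refs})
    rep = primer_sensitivity(db, panel, anchor, cfg)
    rows = {r.primer: r for r in rep.rows}
    assert rows["C"].n_covering == 20 and rows["C"].n_amplifiable == 17
    assert rows["C"].pct == pytest.approx(85.0)
    # union on the same restriction is at least the best single primer
    assert rep.union.pct >= max(r.pct for r in rep.rows)


def test_compare_single_primer(cfg, panel, anchor, rng):
    single = full_length_pair()
    refs = []
    for i in range(50):
        seq = list(anchor)
        if i == 0:  # mutate >=3 positions in every panel primer site
            for p in panel:
                for site in (fwd_site(p), rev_site(p)):
                    for pos in range(site[0], site[0] + 3):
                        seq[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[pos]]
        refs.append(SequenceRecord(f"r{i}", "".join(seq)))
    # one extra ref that stops before the 1492R site: excluded from both
    refs.append(SequenceRecord("truncated", anchor[:1400]))
    db = ReferenceDB(refs, {r.id: ("B", "P", "C", "O", "F", "G") for r in refs})
    pct_panel, pct_single, n = compare_single_primer(db, panel, single, cfg, anchor)
    assert n == 50
    assert pct_panel == pytest.approx(2.0)
    assert pct_single == pytest.approx(2.0)  # the mutant also broke 8F=27F


def test_all_exact_single_sites_never_missed(cfg, panel, anchor):
    refs = [SequenceRecord(f"r{i}", anchor) for i in range(10)]
    db = ReferenceDB(refs, {r.id: ("B", "P", "C", "O", "F", "G") for r in refs})
    _, pct_single, n = compare_single_primer(
        db, panel, full_length_pair(), cfg, anchor
    )
    assert n == 10 and pct_single == 0.0
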