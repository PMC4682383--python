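import numpy as np
import pandas as pd
import pytest

from stitch16s.classify import ConfidentGenusSet, TaxAssignment
from stitch16s.metrics import (
    GenusResult,
    SampleRunStats,
    composition,
    percent,
    primer_bias,
    summary_table,
)


@pytest.mark.parametrize(
    "num,den,expected",
    [
        (1747, 29170, 6.0),        # non-confident share of trimmed reads
        (10909, 35456, 30.8),      # confident share
        (28482, 29976, 95.0),      # spiked-in share of confident reads
        (1796209, 1877993, 95.6),  # best per-primer sensitivity
        (47650, 61634, 77.3),      # worst per-primer sensitivity
        (2455930, 2472276, 99.3),  # union-of-panel sensitivity
        (633240, 894701, 70.8),    # long-assembly fraction
    ],
)
def test_percent_reproduces_printed_ratios(num, den, expected):
    assert percent(num, den) == expected


def test_percent_rounds_half_away_from_zero():
    assert percent(125, 1000) == 12.5
    assert percent(1245, 10000) == 12.5   # 12.45 -> 12.5, not 12.4
    assert percent(1, 3, 0) == 33.0


def _cset(by_genus):
    n = sum(len(v) for v in by_genus.values())
    return ConfidentGenusSet(by_genus, len(by_genus), n, n)


def test_bias_zero_when_every_primer_hits_every_genus():
    labels = {}
    by_genus = {}
    for g in "WXYZ":
        ids = []
        for p in "ABCDEF":
            for i in range(3):
                rid = f"{g}{p}{i}"
                labels[rid] = p
                ids.append(rid)
        by_genus[f"Genus{g}"] = ids
    bias = primer_bias(_cset(by_genus), labels)
    assert bias == {p: 0 for p in "ABCDEF"}


def test_bias_counts_missed_genera():
    labels = {}
    by_genus = {}
    for gi, g in enumerate("WXYZ"):
        ids = []
        for p in "ABCDEF":
            if p == "B" and g == "W":
                continue  # primer B misses genus W
            rid = f"{g}{p}"
            labels[rid] = p
            ids.append(rid)
        by_genus[f"Genus{g}"] = ids
    bias = primer_bias(_cset(by_genus), labels, list("ABCDEF"))
    assert bias["B"] == 25
    assert all(bias[p] == 0 for p in "ACDEF")


def test_bias_single_genus_all_or_nothing():
    labels = {"r1": "A"}
    bias = primer_bias(_cset({"G": ["r1"]}), labels, ["A", "B"])
    assert bias == {"A": 0, "B": 100}


def test_bias_requires_confident_genera():
    with pytest.raises(ValueError):
        primer_bias(_cset({}), {})


def test_bias_invariant_to_read_order(rng):
    labels = {f"r{i}": "ABCDEF"[i % 6] for i in range(60)}
    ids = list(labels)
    by1 = {"G1": ids[:30], "G2": ids[30:]}
    by2 = {"G1": ids[29::-1], "G2": ids[:29:-1]}
    assert primer_bias(_cset(by1), labels) == primer_bias(_cset(by2), labels)


def _assign(genus, score, rid, phylum="P1"):
    return TaxAssignment(rid, ("Bacteria", phylum, "C", "O", "F", genus), score)


def test_composition_single_taxon(cfg):
    a = [_assign("G1", 95, f"r{i}") for i in range(10)]
    df = composition({"S1": a}, "genus", cfg)
    assert df.loc["G1", "S1"] == 100.0


def test_composition_orders_by_cross_sample_mean(cfg):
    s1 = [_assign("G1", 95, f"a{i}") for i in range(30)] + [
        _assign("G2", 95, f"b{i}") for i in range(15)
    ] + [_assign("G3", 10, f"c{i}") for i in range(55)]
    s2 = [_assign("G1", 95, f"d{i}") for i in range(10)] + [
        _assign("G2", 95, f"e{i}") for i in range(20)
    ] + [_assign("G3", 10, f"f{i}") for i in range(70)]
    df = composition({"S1": s1, "S2": s2}, "genus", cfg)
    # means: G1 (30+10)/2 = 20, G2 (15+20)/2 = 17.5 -> G1 first
    assert list(df.index) == ["G1", "G2"]
    assert df.loc["G1", "S1"] == 30.0 and df.loc["G1", "S2"] == 10.0
    # headroom to 100% is the non-confident share
    assert df["S1"].sum() == pytest.approx(45.0)


def test_composition_top_n_lumps_others(cfg):
    a = [_assign(f"G{i:02d}", 95, f"r{i}_{j}") for i in range(20) for j in range(i + 1)]
    df = composition({"S": a}, "genus", cfg, top_n=15)
    assert len(df) == 16 and "others" in df.index


def test_composition_no_confident_reads(cfg):
    a = [_assign("G1", 10, f"r{i}") for i in range(5)]
    df = composition({"S": a}, "genus", cfg)
    assert df.empty or df["S"].sum() == 0.0


def _genus(name, lcl, ratio, assembled, ident):
    return GenusResult(name, lcl, ratio, assembled, ident)


def test_summary_table_fixture_bookkeeping():
    stats = SampleRunStats(
        sample="S1",
        raw_reads=1000,
        trimmed_reads=940,
        confident_reads=884,
        total_genus=8,
        confident_genus=5,
        genus_results=[
            _genus("G1", 1480, 4.2, True, 100.0),
            _genus("G2", 700, 2.0, True, 99.1),
            _genus("G3", 600, 1.7, True, 96.8),
            _genus("G4", 400, 1.1, True, 97.0),
            _genus("G5", 350, 1.0, False, None),
        ],
    )
    row = summary_table([stats]).loc["S1"]
    assert row["Raw reads"] == 1000
    assert row["No. of contigs"] == 4
    assert row["lcl/mrl>=1.5"] == 3
    assert row["lcl/mrl>=2"] == 2
    assert row["lc identity>=97%"] == 3


def test_summary_nesting_invariant(rng):
    """lcl/mrl>=2 <= lcl/mrl>=1.5 <= contigs <= confident genera, always."""
    for trial in range(20):
        n = int(rng.integers(1, 12))
        results = [
            _genus(
                f"G{i}",
                int(rng.integers(200, 1600)),
                float(rng.uniform(0.5, 4.0)),
                bool(rng.random() < 0.8),
                float(rng.uniform(90, 100)) if rng.random() < 0.7 else None,
            )
            for i in range(n)
        ]
        stats = SampleRunStats("S", 100, 90, 80, n + 2, n, results)
        row = summary_table([stats]).iloc[0]
        assert (
            row["lcl/mrl>=2"]
            <= row["lcl/mrl>=1.5"]
            <= row["No. of contigs"]
            <= row["Confident genus"]
        )
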