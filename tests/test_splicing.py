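"""Junction evidence extraction, splicing indices, filters and comparisons."""

import numpy as np
import pandas as pd
import pysam
import pytest

from intronspace.catalog import IntronCatalog
from intronspace.splicing import (
    GeneModel,
    JunctionEvidence,
    compare_distributions,
    compute_si_es,
    compute_si_ret,
    extract_junction_evidence,
    filter_for_analysis,
    improved_splicing_intersection,
    load_gene_models_bed12,
    matched_location_sets,
    pool_evidence,
    splicing_index_table,
)
from tests.conftest import make_record

# one gene on chr1: exons [0,100) [400,500) [800,900), introns [100,400) [500,800)
GENE = GeneModel("g1", "chr1", "+", [(0, 100), (400, 500), (800, 900)])


def _catalog():
    recs = [
        make_record("i1", "chr1", 100, 400, "major", gene="g1"),
        make_record("i2", "chr1", 500, 800, "minor", gene="g1"),
    ]
    return IntronCatalog(recs, {"chr1": 2000})


def _write_sam(path, reads):
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": "chr1", "LN": 2000}]}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for i, (pos, cigar, extra) in enumerate(reads):
            a = pysam.AlignedSegment(out.header)
            a.query_name = f"r{i}"
            a.reference_id = 0
            a.reference_start = pos
            a.mapping_quality = extra.get("mapq", 60)
            a.cigarstring = cigar
            a.flag = extra.get("flag", 0)
            for tag, val in extra.get("tags", []):
                a.set_tag(tag, val)
            out.write(a)


def _extract(tmp_path, reads, **kw):
    sam = tmp_path / "r.sam"
    _write_sam(sam, reads)
    return extract_junction_evidence(sam, _catalog(), {"g1": GENE}, **kw)


class TestEvidenceExtraction:
    def test_contiguous_read_across_5prime_junction(self, tmp_path):
        # aligned [60,140): 40 bases left of the junction at 100, 40 right
        ev = _extract(tmp_path, [(60, "80M", {})])
        assert ev["i1"].n5 == 1 and ev["i1"].n3 == 0

    def test_single_nucleotide_anchor_excluded(self, tmp_path):
        # read ends 1 bp into the intron: [60,101)
        ev = _extract(tmp_path, [(60, "41M", {})])
        assert ev["i1"].n5 == 0

    def test_exact_gap_is_spliced(self, tmp_path):
        ev = _extract(tmp_path, [(80, "20M300N20M", {})])
        assert ev["i1"].n_spliced == 1
        assert ev["i1"].n_cryptic == 0

    def test_gap_inside_intron_is_cryptic(self, tmp_path):
        # gap [150,170) strictly inside intron [100,400)
        ev = _extract(tmp_path, [(130, "20M20N20M", {})])
        assert ev["i1"].n_cryptic == 1
        assert ev["i1"].n_spliced == 0

    def test_one_annotated_end_is_cryptic(self, tmp_path):
        # gap [100,300): starts at the donor, ends inside the intron
        ev = _extract(tmp_path, [(80, "20M200N20M", {})])
        assert ev["i1"].n_cryptic == 1

    def test_skip_gap_counts_both_introns_it_removes(self, tmp_path):
        # gap [100,800) removes intron i1, exon [400,500) and intron i2
        ev = _extract(tmp_path, [(80, "20M700N20M", {})])
        assert ev["i1"].n_skip == 1
        assert ev["i2"].n_skip == 1
        assert ev["i1"].n_spliced == 0

    def test_spliced_read_with_short_anchor_excluded(self, tmp_path):
        ev = _extract(tmp_path, [(99, "1M300N20M", {})])
        assert ev["i1"].n_spliced == 0

    def test_secondary_and_duplicate_records_excluded(self, tmp_path):
        ev = _extract(tmp_path, [
            (80, "20M300N20M", {"flag": 256}),
            (80, "20M300N20M", {"flag": 1024}),
        ])
        assert ev["i1"].n_spliced == 0

    def test_multimapper_excluded_when_unique_only(self, tmp_path):
        reads = [(80, "20M300N20M", {"tags": [("NH", 2)]}),
                 (80, "20M300N20M", {"mapq": 0})]
        ev = _extract(tmp_path, reads)
        assert ev["i1"].n_spliced == 0
        ev2 = _extract(tmp_path, reads, unique_only=False)
        assert ev2["i1"].n_spliced == 2

    def test_agrees_with_brute_force_rescan(self, tmp_path):
        """Oracle: re-classify every record with independent plain-python
        arithmetic, no interval index."""
        rng = np.random.default_rng(12)
        reads = []
        for _ in range(300):
            kind = rng.integers(0, 4)
            if kind == 0:   # contiguous somewhere near a junction
                pos = int(rng.integers(40, 900))
                reads.append((pos, f"{int(rng.integers(10, 80))}M", {}))
            elif kind == 1:  # spliced over i1 or i2
                s, e = (100, 400) if rng.random() < 0.5 else (500, 800)
                reads.append((s - 20, f"20M{e - s}N20M", {}))
            elif kind == 2:  # skip
                reads.append((80, "20M700N20M", {}))
            else:            # cryptic inside i1
                reads.append((130, "20M40N20M", {}))
        ev = _extract(tmp_path, reads)

        def brute():
            cat = _catalog()
            counts = {r.intron_id: dict(n5=0, n3=0, n_spliced=0, n_skip=0, n_cryptic=0)
                      for r in cat.records}
            boundaries = {0, 100, 400, 500, 800, 900}
            for pos, cigar, _extra in reads:
                # parse cigar by hand
                import re
                blocks, gaps, p = [], [], pos
                bs, open_ = p, False
                for n, op in re.findall(r"(\d+)([MIDNSHP=X])", cigar):
                    n = int(n)
                    if op in "M=XD":
                        if not open_:
                            bs, open_ = p, True
                        p += n
                    elif op == "N":
                        if open_:
                            blocks.append((bs, p)); open_ = False
                        gaps.append((p, p + n)); p += n
                if open_:
                    blocks.append((bs, p))
                for rec in cat.records:
                    c = counts[rec.intron_id]
                    for b0, b1 in blocks:
                        if b0 <= rec.start - 2 and b1 >= rec.start + 2:
                            c["n5"] += 1
                        if b0 <= rec.end - 2 and b1 >= rec.end + 2:
                            c["n3"] += 1
                    for gi, (g0, g1) in enumerate(gaps):
                        if (blocks[gi][1] - blocks[gi][0] < 2
                                or blocks[gi + 1][1] - blocks[gi + 1][0] < 2):
                            continue
                        if (g0, g1) == (rec.start, rec.end):
                            c["n_spliced"] += 1
                        elif g0 <= rec.start and g1 >= rec.end:
                            exons = [(s, e) for s, e in GENE.exons
                                     if e == rec.start or s == rec.end]
                            if any(g0 <= s and e <= g1 for s, e in exons):
                                c["n_skip"] += 1
                        elif rec.start < g0 and g1 < rec.end:
                            c["n_cryptic"] += 1
                        elif (g0 == rec.start) != (g1 == rec.end):
                            other = g1 if g0 == rec.start else g0
                            if other not in boundaries and (
                                    rec.start <= g0 < rec.end or rec.start < g1 <= rec.end):
                                c["n_cryptic"] += 1
            return counts

        oracle = brute()
        for iid, c in oracle.items():
            got = ev[iid]
            assert (got.n5, got.n3, got.n_spliced, got.n_skip, got.n_cryptic) == (
                c["n5"], c["n3"], c["n_spliced"], c["n_skip"], c["n_cryptic"]
            ), iid

    def test_pooling_sums_counts(self):
        a = {"i1": JunctionEvidence("i1", n5=1, n_spliced=3)}
        b = {"i1": JunctionEvidence("i1", n3=2, n_spliced=4)}
        pooled = pool_evidence([a, b])
        assert (pooled["i1"].n5, pooled["i1"].n3, pooled["i1"].n_spliced) == (1, 2, 7)

    def test_single_replicate_pooling_is_identity(self):
        a = {"i1": JunctionEvidence("i1", n5=1, n3=2, n_spliced=3)}
        pooled = pool_evidence([a])
        assert (pooled["i1"].n5, pooled["i1"].n3, pooled["i1"].n_spliced) == (1, 2, 3)


class TestSplicingIndices:
    @pytest.mark.parametrize("n5,n3,nspl,si,cat_", [
        (4, 6, 10, 100 * 5 / 15, "both"),
        (0, 0, 10, 0.0, "spliced_only"),
        (5, 5, 0, 100.0, "retained_only"),
    ])
    def test_si_ret_formula_and_category(self, n5, n3, nspl, si, cat_):
        ev = JunctionEvidence("i", n5=n5, n3=n3, n_spliced=nspl)
        got_si, got_cat = compute_si_ret(ev)
        assert got_si == pytest.approx(si)
        assert got_cat == cat_

    def test_si_ret_undefined_without_evidence(self):
        assert compute_si_ret(JunctionEvidence("i")) == (None, None)

    def test_cryptic_evidence_vetoes_boundary_reads(self):
        ev = JunctionEvidence("i", n5=5, n3=5, n_spliced=10, n_cryptic=1)
        si, cat_ = compute_si_ret(ev)
        assert si == 0.0 and cat_ == "spliced_only"
        ev2 = JunctionEvidence("i", n5=5, n3=5, n_cryptic=1)
        assert compute_si_ret(ev2) == (None, None)

    @pytest.mark.parametrize("nskip,nspl,si", [(2, 8, 20.0), (0, 8, 0.0), (3, 0, 100.0)])
    def test_si_es_formula(self, nskip, nspl, si):
        ev = JunctionEvidence("i", n_skip=nskip, n_spliced=nspl)
        assert compute_si_es(ev) == pytest.approx(si)

    def test_si_es_undefined_without_junction_reads(self):
        assert compute_si_es(JunctionEvidence("i", n5=4)) is None

    def test_indices_bounded(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            ev = JunctionEvidence("i", *[int(x) for x in rng.integers(0, 20, 5)])
            si, _ = compute_si_ret(ev)
            es = compute_si_es(ev)
            assert si is None or 0 <= si <= 100
            assert es is None or 0 <= es <= 100


def _records_frame(rows):
    cols = ["intron_id", "intron_class", "gene_id", "n5", "n3", "n_spliced",
            "n_skip", "n_cryptic", "si_ret", "si_es", "category",
            "gene_mean_tpm", "location", "cell_line"]
    return pd.DataFrame(rows, columns=cols)


def _row(iid, cls="major", si_ret=50.0, category="both", tpm=5.0,
         location="SPAD", cell="K562", n_spliced=5, n5=5):
    return [iid, cls, f"g_{iid}", n5, n5, n_spliced, 0, 0, si_ret, 0.0,
            category, tpm, location, cell]


class TestFilters:
    def test_low_tpm_removed(self):
        df = _records_frame([_row("a", tpm=0.8), _row("b", tpm=1.0)])
        out = filter_for_analysis(df)
        assert list(out["intron_id"]) == ["b"]

    def test_category_both_restriction(self):
        df = _records_frame([
            _row("a", category="spliced_only", si_ret=0.0, n5=0),
            _row("b", category="both"),
        ])
        out = filter_for_analysis(df, category_filter="both")
        assert list(out["intron_id"]) == ["b"]

    def test_no_supporting_read_removed(self):
        df = _records_frame([_row("a", si_ret=None, n_spliced=0, n5=0)])
        assert len(filter_for_analysis(df)) == 0

    def test_subsampling_deterministic(self):
        df = _records_frame([_row(f"m{i}") for i in range(60)])
        a = filter_for_analysis(df, subsample={"major": 50}, seed=4)
        b = filter_for_analysis(df, subsample={"major": 50}, seed=4)
        assert len(a) == 50
        assert list(a["intron_id"]) == list(b["intron_id"])

    def test_subsample_larger_than_available_keeps_all(self):
        df = _records_frame([_row(f"m{i}") for i in range(10)])
        assert len(filter_for_analysis(df, subsample={"major": 5000})) == 10


class TestComparisons:
    def test_identical_groups_p_one(self):
        df = _records_frame(
            [_row(f"a{i}", cls="major", si_ret=v) for i, v in enumerate([1, 2, 3])]
            + [_row(f"b{i}", cls="minor", si_ret=v) for i, v in enumerate([1, 2, 3])]
        )
        comp = compare_distributions(df, "intron_class")
        assert comp.test == "mann_whitney"
        assert comp.p_value == pytest.approx(1.0)

    def test_exact_mann_whitney_small_separated_groups(self):
        df = _records_frame(
            [_row(f"a{i}", cls="major", si_ret=0.0) for i in range(4)]
            + [_row(f"b{i}", cls="minor", si_ret=10.0) for i in range(4)]
        )
        comp = compare_distributions(df, "intron_class")
        assert comp.p_value == pytest.approx(2 / 70, rel=1e-9)

    def test_null_groups_rarely_significant(self):
        rng = np.random.default_rng(21)
        rows = []
        for g, cls in enumerate(["major", "minor", "hybrid"]):
            for i, v in enumerate(rng.normal(size=50)):
                rows.append(_row(f"{cls}{i}", cls=cls, si_ret=float(v)))
        comp = compare_distributions(_records_frame(rows), "intron_class")
        assert comp.test == "kruskal_wallis_dunn"
        assert comp.p_value > 0.05
        assert (comp.pairwise["p_adjusted"] > 0.05).all()

    def test_dunn_adjusted_never_below_raw(self):
        rng = np.random.default_rng(22)
        rows = []
        for cls, shift in [("major", 0), ("minor", 1), ("hybrid", 0.5), ("minor_like", 2)]:
            for i, v in enumerate(rng.normal(shift, 1, size=30)):
                rows.append(_row(f"{cls}{i}", cls=cls, si_ret=float(v)))
        comp = compare_distributions(_records_frame(rows), "intron_class")
        assert (comp.pairwise["p_adjusted"] >= comp.pairwise["p_raw"] - 1e-12).all()

    def test_small_groups_reported_untestable(self):
        df = _records_frame(
            [_row("a", cls="major", si_ret=1.0)]
            + [_row(f"b{i}", cls="minor", si_ret=float(i)) for i in range(5)]
            + [_row(f"c{i}", cls="hybrid", si_ret=float(i)) for i in range(5)]
        )
        comp = compare_distributions(df, "intron_class")
        assert comp.untestable == ["major"]


class TestCrossCellLine:
    def _matrices_and_records(self):
        from intervaltree import IntervalTree  # noqa: F401
        from intronspace.features import FeatureTrack, assign_membership
        recs = [make_record(f"i{j}", "chr1", j * 1000, j * 1000 + 200, "minor",
                            gene=f"g{j}") for j in range(8)]
        cat = IntronCatalog(recs, {"chr1": 10_000})
        # cell A: i0..i4 in SPADs; cell B: i0..i4 in SPADs too (i5+ neither)
        spad = [(j * 1000, j * 1000 + 200) for j in range(5)]
        mA = assign_membership(cat, [FeatureTrack("SPAD", "A", {"chr1": spad})])
        mB = assign_membership(cat, [FeatureTrack("SPAD", "B", {"chr1": spad})])
        rows_a = [_row(f"i{j}", cls="minor", si_ret=50.0, cell="A") for j in range(8)]
        rows_b = [_row(f"i{j}", cls="minor", si_ret=20.0 if j < 1 else 50.0, cell="B")
                  for j in range(8)]
        return cat, {"A": mA, "B": mB}, {"A": _records_frame(rows_a),
                                         "B": _records_frame(rows_b)}

    def test_shared_spad_sets(self):
        _, matrices, records = self._matrices_and_records()
        out = matched_location_sets(matrices, records, "A", intron_class="minor")
        assert out["shared_all"]["SPAD"] == {f"i{j}" for j in range(5)}
        info = out["pairwise"][("B", "SPAD")]
        assert info["n_shared"] == 5 and info["test"] is not None

    def test_empty_track_yields_empty_sets(self):
        from intronspace.features import FeatureTrack, assign_membership
        recs = [make_record("i0", "chr1", 0, 200, "minor")]
        cat = IntronCatalog(recs, {"chr1": 1000})
        m1 = assign_membership(cat, [FeatureTrack("SPAD", "A", {"chr1": [(0, 200)]})])
        m2 = assign_membership(cat, [FeatureTrack("SPAD", "B", {"chr1": []})])
        rows = [_row("i0", cls="minor")]
        out = matched_location_sets({"A": m1, "B": m2}, {"A": _records_frame(rows),
                                                         "B": _records_frame(rows)}, "A")
        assert out["shared_all"]["SPAD"] == set()

    def test_improved_splicing_strict_inequality(self):
        ref = _records_frame([
            _row("i1", cls="minor", si_ret=50.0),
            _row("i2", cls="minor", si_ret=10.0),
            _row("i3", cls="minor", si_ret=30.0),
        ])
        other = _records_frame([
            _row("i1", cls="minor", si_ret=20.0),
            _row("i2", cls="minor", si_ret=10.0),
            _row("i3", cls="minor", si_ret=40.0),
        ])
        out = improved_splicing_intersection(
            ref, {"K562": other}, {"K562": ["i1", "i2", "i3"]}
        )
        assert out["per_line"]["K562"] == {"i1"}
        assert out["intersection"] == {"i1"}
        assert out["intersection_genes"] == {"g_i1"}

    def test_identical_si_yields_empty_improved_set(self):
        ref = _records_frame([_row("i1", cls="minor", si_ret=50.0)])
        out = improved_splicing_intersection(
            ref, {"X": ref.copy()}, {"X": ["i1"]}
        )
        assert out["per_line"]["X"] == set()

    def test_intersection_across_two_lines(self):
        ref = _records_frame([
            _row("i1", cls="minor", si_ret=50.0),
            _row("i2", cls="minor", si_ret=50.0),
        ])
        o1 = _records_frame([
            _row("i1", cls="minor", si_ret=10.0),
            _row("i2", cls="minor", si_ret=10.0),
        ])
        o2 = _records_frame([
            _row("i1", cls="minor", si_ret=10.0),
            _row("i2", cls="minor", si_ret=60.0),
        ])
        out = improved_splicing_intersection(
            ref, {"L1": o1, "L2": o2}, {"L1": ["i1", "i2"], "L2": ["i1", "i2"]}
        )
        assert out["per_line"]["L1"] == {"i1", "i2"}
        assert out["per_line"]["L2"] == {"i1"}
        assert out["intersection"] == {"i1"}


class TestGeneModels:
    def test_bed12_round_trip(self, tmp_path):
        from intronspace.simulate import write_gene_models_bed12
        write_gene_models_bed12({"g1": GENE}, tmp_path / "g.bed12")
        models = load_gene_models_bed12(tmp_path / "g.bed12")
        assert models["g1"].exons == GENE.exons
        assert models["g1"].introns == [(100, 400), (500, 800)]
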