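"""Shared fixtures: hand-built catalogs and a session-scoped synthetic study."""

from __future__ import annotations

from math import comb

import numpy as np
import pytest

from intronspace.catalog import IntronCatalog, IntronRecord
from intronspace.features import assign_membership
from intronspace.simulate import (
    SyntheticConfig,
    generate_annotation,
    generate_expression,
    generate_feature_tracks,
)


def fisher_two_sided_enum(table) -> float:
    """Independent oracle: exhaustive hypergeometric enumeration with fixed
    margins; two-sided p sums all tables no more probable than the observed."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)

    def pmf(k: int) -> float:
        return comb(r1, k) * comb(r2, c1 - k) / denom

    p0 = pmf(a)
    return sum(
        pmf(k)
        for k in range(max(0, c1 - r2), min(r1, c1) + 1)
        if pmf(k) <= p0 * (1 + 1e-9)
    )


def make_record(iid, chrom, start, end, cls="major", gene=None, strand="+"):
    return IntronRecord(
        intron_id=iid, chrom=chrom, start=start, end=end, strand=strand,
        gene_id=gene or f"g_{iid}", intron_class=cls,
    )


@pytest.fixture
def tiny_catalog():
    recs = [
        make_record("i1", "chr1", 100, 200, "minor"),
        make_record("i2", "chr1", 320, 400, "major"),
        make_record("i3", "chr1", 650, 700, "major"),
    ]
    return IntronCatalog(records=recs, chrom_sizes={"chr1": 1000})


@pytest.fixture(scope="session")
def small_study():
    """A moderate synthetic study shared by overlap/resampling tests."""
    cfg = SyntheticConfig(
        class_counts={
            "major": 4000, "major_like": 600, "hybrid": 150,
            "minor_like": 180, "minor": 400, "non_canonical": 400,
        },
        seed=11,
    )
    catalog, models, truth = generate_annotation(cfg)
    tracks = generate_feature_tracks(cfg, catalog, truth)
    tpm = generate_expression(cfg, models, truth)
    matrix = assign_membership(catalog, tracks)
    return {
        "config": cfg, "catalog": catalog, "models": models,
        "truth": truth, "tracks": tracks, "tpm": tpm, "matrix": matrix,
    }


@pytest.fixture(scope="session")
def calibrated_study():
    """The full calibrated preset; generated once per session."""
    cfg = SyntheticConfig(seed=20)
    catalog, models, truth = generate_annotation(cfg)
    tracks = generate_feature_tracks(cfg, catalog, truth)
    matrix = assign_membership(catalog, tracks)
    return {
        "config": cfg, "catalog": catalog, "models": models,
        "truth": truth, "tracks": tracks, "matrix": matrix,
    }


def brute_force_membership(catalog, tracks, min_overlap_frac=0.5):
    """Per-pair overlap scan with no interval index (oracle)."""
    out = {}
    for rec in catalog.records:
        row = {}
        for t in tracks:
            best = 0
            for s, e in t.intervals.get(rec.chrom, []):
                best = max(best, min(rec.end, e) - max(rec.start, s))
            row[t.feature_type] = best >= min_overlap_frac * rec.length
        out[rec.intron_id] = row
    return out
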