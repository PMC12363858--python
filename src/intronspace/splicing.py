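"""Junction-read evidence and splicing indices for intron retention/skipping.

For each annotated intron, spliced alignments yield five read counts:

* ``n5`` / ``n3`` — reads contiguously spanning the exon-intron (5')
  and intron-exon (3') boundary with at least ``min_anchor`` aligned bases on
  each side (single-nucleotide overhangs are excluded);
* ``n_spliced`` — gapped reads whose gap matches the annotated intron exactly;
* ``n_skip`` — gapped reads whose gap contains the intron plus at least one
  whole annotated adjacent exon (exon skipping);
* ``n_cryptic`` — gapped reads using a non-annotated splice site within or at
  one edge of the intron.

The splicing index for intron retention is
``SI_RET = 100 * B / (B + n_spliced)`` with ``B = (n5 + n3) / 2``, and for
exon skipping ``SI_ES = 100 * n_skip / (n_skip + n_spliced)``.  Cryptic
evidence vetoes boundary reads as retention support.  Downstream filters
(expressed parent gene, at least one supporting read, both-evidence category,
per-class subsampling) and the rank-based group comparisons live here too.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree

from ._stats import dunn_test, kruskal_wallis, mann_whitney
from .catalog import IntronCatalog
from .features import OverlapMatrix
from .gene_context import ExpressionTable

logger = logging.getLogger(__name__)


class SplicingError(ValueError):
    pass


@dataclass
class GeneModel:
    """Exon structure of one gene; introns are the gaps between exons."""

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [(e1[1], e2[0]) for e1, e2 in zip(self.exons, self.exons[1:])]

    def boundaries(self) -> set[int]:
        """All annotated splice-site coordinates (exon edges)."""
        out: set[int] = set()
        for s, e in self.exons:
            out.add(s)
            out.add(e)
        return out


def load_gene_models_bed12(path: str | Path) -> dict[str, GeneModel]:
    """Read gene models from BED12 (one transcript per line; blocks = exons)."""
    models: dict[str, GeneModel] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            p = line.split("\t")
            if len(p) < 12:
                raise SplicingError(f"{path}:{ln}: expected 12 BED columns")
            chrom, start, name, strand = p[0], int(p[1]), p[3], p[5]
            sizes = [int(x) for x in p[10].rstrip(",").split(",")]
            starts = [int(x) for x in p[11].rstrip(",").split(",")]
            exons = [(start + off, start + off + sz) for off, sz in zip(starts, sizes)]
            models[name] = GeneModel(gene_id=name, chrom=chrom, strand=strand, exons=exons)
    return models


@dataclass
class JunctionEvidence:
    intron_id: str
    cell_line: str = "NA"
    replicate: str = "NA"
    n5: int = 0
    n3: int = 0
    n_spliced: int = 0
    n_skip: int = 0
    n_cryptic: int = 0

    def __add__(self, other: "JunctionEvidence") -> "JunctionEvidence":
        if other.intron_id != self.intron_id:
            raise SplicingError("cannot pool evidence across introns")
        return JunctionEvidence(
            intron_id=self.intron_id,
            cell_line=self.cell_line,
            replicate="pooled",
            n5=self.n5 + other.n5,
            n3=self.n3 + other.n3,
            n_spliced=self.n_spliced + other.n_spliced,
            n_skip=self.n_skip + other.n_skip,
            n_cryptic=self.n_cryptic + other.n_cryptic,
        )


def _reference_blocks(read: pysam.AlignedSegment) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Reference-aligned blocks separated only by N operations, plus the gaps.

    Deletions (D) are absorbed into blocks so that a junction is only where
    the aligner spliced (N), matching standard spliced-alignment semantics.
    """
    blocks: list[tuple[int, int]] = []
    gaps: list[tuple[int, int]] = []
    pos = read.reference_start
    block_start = pos
    open_block = False
    for op, length in read.cigartuples or []:
        if op in (0, 7, 8, 2):  # M, =, X, D advance the reference within a block
            if not open_block:
                block_start = pos
                open_block = True
            pos += length
        elif op == 3:  # N closes the block
            if open_block:
                blocks.append((block_start, pos))
                open_block = False
            gaps.append((pos, pos + length))
            pos += length
        # I, S, H, P do not advance the reference
    if open_block:
        blocks.append((block_start, pos))
    return blocks, gaps


def _is_unique(read: pysam.AlignedSegment, min_mapq: int) -> bool:
    if read.mapping_quality < min_mapq:
        return False
    try:
        if read.get_tag("NH") > 1:
            return False
    except KeyError:
        pass
    return True


def extract_junction_evidence(
    alignments: str | Path | pysam.AlignmentFile,
    catalog: IntronCatalog,
    gene_models: Mapping[str, GeneModel],
    min_anchor: int = 2,
    unique_only: bool = True,
    min_mapq: int = 1,
    cell_line: str = "NA",
    replicate: str = "NA",
) -> dict[str, JunctionEvidence]:
    """Count junction-level read support for every intron in the catalog.

    Works as a single linear pass over the alignment file (SAM or BAM),
    classifying each primary, non-duplicate, uniquely mapped read against an
    interval index of catalog introns.  Anchor and cryptic rules follow the
    module docstring.
    """
    evidence = {
        r.intron_id: JunctionEvidence(r.intron_id, cell_line, replicate)
        for r in catalog.records
    }
    intron_of = {r.intron_id: r for r in catalog.records}
    # index introns padded by min_anchor so junction-spanning reads are found
    trees: dict[str, IntervalTree] = {}
    for r in catalog.records:
        trees.setdefault(r.chrom, IntervalTree()).addi(
            max(0, r.start - min_anchor), r.end + min_anchor, r.intron_id
        )
    adjacent_exons: dict[str, list[tuple[int, int]]] = {}
    gene_boundaries: dict[str, set[int]] = {}
    for r in catalog.records:
        gm = gene_models.get(r.gene_id)
        if gm is None:
            adjacent_exons[r.intron_id] = []
            gene_boundaries[r.intron_id] = set()
            continue
        adjacent_exons[r.intron_id] = [
            (s, e) for s, e in gm.exons if e == r.start or s == r.end
        ]
        gene_boundaries[r.intron_id] = gm.boundaries()

    owns_handle = not isinstance(alignments, pysam.AlignmentFile)
    af = (
        pysam.AlignmentFile(str(alignments), check_sq=False)
        if owns_handle
        else alignments
    )
    try:
        for read in af:
            if read.is_unmapped or read.is_secondary or read.is_supplementary or read.is_duplicate:
                continue
            if unique_only and not _is_unique(read, min_mapq):
                continue
            chrom = read.reference_name
            tree = trees.get(chrom)
            if tree is None:
                continue
            blocks, gaps = _reference_blocks(read)
            # boundary-spanning (contiguous) evidence
            for bs, be in blocks:
                for iv in tree.overlap(bs, be):
                    rec = intron_of[iv.data]
                    ev = evidence[iv.data]
                    if bs <= rec.start - min_anchor and be >= rec.start + min_anchor:
                        ev.n5 += 1
                    if bs <= rec.end - min_anchor and be >= rec.end + min_anchor:
                        ev.n3 += 1
            # spliced-junction evidence
            for gi, (gs, ge) in enumerate(gaps):
                left = blocks[gi][1] - blocks[gi][0]
                right = blocks[gi + 1][1] - blocks[gi + 1][0]
                if left < min_anchor or right < min_anchor:
                    continue
                for iv in tree.overlap(gs, ge):
                    rec = intron_of[iv.data]
                    ev = evidence[iv.data]
                    if gs == rec.start and ge == rec.end:
                        ev.n_spliced += 1
                    elif gs <= rec.start and ge >= rec.end:
                        if any(
                            gs <= es and ee <= ge for es, ee in adjacent_exons[rec.intron_id]
                        ):
                            ev.n_skip += 1
                    elif rec.start < gs and ge < rec.end:
                        ev.n_cryptic += 1
                    elif (gs == rec.start) != (ge == rec.end):
                        other = ge if gs == rec.start else gs
                        if other not in gene_boundaries[rec.intron_id]:
                            ev.n_cryptic += 1
    finally:
        if owns_handle:
            af.close()
    return evidence


def pool_evidence(
    per_replicate: Sequence[Mapping[str, JunctionEvidence]]
) -> dict[str, JunctionEvidence]:
    """Sum junction counts across replicates of one cell line."""
    pooled: dict[str, JunctionEvidence] = {}
    for evd in per_replicate:
        for iid, ev in evd.items():
            pooled[iid] = pooled[iid] + ev if iid in pooled else replace(ev)
    return pooled


CATEGORY_RETAINED = "retained_only"
CATEGORY_SPLICED = "spliced_only"
CATEGORY_BOTH = "both"


def compute_si_ret(ev: JunctionEvidence) -> tuple[float | None, str | None]:
    """Retention index and category; cryptic evidence vetoes boundary reads.

    Returns (SI_RET in [0, 100], category) or (None, None) when no usable
    evidence remains.
    """
    boundary = (ev.n5 + ev.n3) / 2.0
    if ev.n_cryptic > 0:
        boundary = 0.0  # cryptic splicing disqualifies retention support
    if boundary + ev.n_spliced == 0:
        return None, None
    si = 100.0 * boundary / (boundary + ev.n_spliced)
    if boundary > 0 and ev.n_spliced == 0:
        cat = CATEGORY_RETAINED
    elif boundary == 0:
        cat = CATEGORY_SPLICED
    else:
        cat = CATEGORY_BOTH
    return si, cat


def compute_si_es(ev: JunctionEvidence) -> float | None:
    if ev.n_skip + ev.n_spliced == 0:
        return None
    return 100.0 * ev.n_skip / (ev.n_skip + ev.n_spliced)


def splicing_index_table(
    evidence: Mapping[str, JunctionEvidence],
    catalog: IntronCatalog,
    expr: ExpressionTable | None = None,
    matrix: OverlapMatrix | None = None,
    location_partition: str = "nuclear_bodies",
    cell_line: str = "NA",
) -> pd.DataFrame:
    """Per-intron splicing-index records joined with class, TPM and location."""
    mean_tpm = expr.mean_tpm if expr is not None else None
    location = (
        matrix.category(location_partition)
        if matrix is not None and location_partition in matrix.partitions
        else None
    )
    rows = []
    for rec in catalog.records:
        ev = evidence.get(rec.intron_id)
        if ev is None:
            continue
        si_ret, category = compute_si_ret(ev)
        si_es = compute_si_es(ev)
        rows.append(
            {
                "intron_id": rec.intron_id,
                "intron_class": rec.intron_class,
                "gene_id": rec.gene_id,
                "cell_line": cell_line,
                "n5": ev.n5,
                "n3": ev.n3,
                "n_spliced": ev.n_spliced,
                "n_skip": ev.n_skip,
                "n_cryptic": ev.n_cryptic,
                "si_ret": si_ret,
                "si_es": si_es,
                "category": category,
                "gene_mean_tpm": float(mean_tpm.get(rec.gene_id, 0.0))
                if mean_tpm is not None
                else np.nan,
                "location": location.get(rec.intron_id, "neither")
                if location is not None
                else "NA",
            }
        )
    return pd.DataFrame(rows)


DEFAULT_SUBSAMPLE = {"major": 5000, "major_like": 5000}


def filter_for_analysis(
    records: pd.DataFrame,
    tpm_threshold: float = 1.0,
    require_read: bool = True,
    category_filter: str = "any",
    subsample: Mapping[str, int] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Expression, supporting-read, category and subsampling filters.

    Keeps introns in genes expressed at ``tpm_threshold`` (replicate-mean)
    with at least one supporting read; ``category_filter='both'`` restricts
    to introns with reads supporting both retention and canonical splicing;
    the abundant classes are down-sampled to the configured sizes (default
    5000 for major and major-like), reproducibly under ``seed``.
    """
    if subsample is None:
        subsample = DEFAULT_SUBSAMPLE
    df = records.copy()
    n0 = len(df)
    df = df[df["gene_mean_tpm"] >= tpm_threshold]
    if require_read:
        support = df[["n5", "n3", "n_spliced", "n_skip"]].sum(axis=1)
        df = df[(support > 0) & df["si_ret"].notna()]
    if category_filter == "both":
        df = df[df["category"] == CATEGORY_BOTH]
    elif category_filter != "any":
        raise SplicingError(f"unknown category_filter {category_filter!r}")
    parts = []
    rng = np.random.default_rng(seed)
    for cls, sub in df.groupby("intron_class", observed=True):
        cap = subsample.get(cls)
        if cap is not None and len(sub) > cap:
            idx = rng.choice(len(sub), size=cap, replace=False)
            sub = sub.iloc[np.sort(idx)]
        parts.append(sub)
    out = pd.concat(parts) if parts else df.iloc[:0]
    logger.info("filter_for_analysis: %d -> %d records", n0, len(out))
    return out.reset_index(drop=True)


@dataclass
class GroupComparison:
    grouping: str
    metric: str
    test: str
    statistic: float | None
    p_value: float | None
    group_sizes: dict[str, int]
    group_medians: dict[str, float]
    pairwise: pd.DataFrame | None = None
    untestable: list[str] = field(default_factory=list)


def compare_distributions(
    records: pd.DataFrame,
    group_by: str,
    metric: str = "si_ret",
    grouping_label: str | None = None,
) -> GroupComparison:
    """Two groups: Mann-Whitney; more: Kruskal-Wallis then all-pairs Dunn/BH."""
    df = records[records[metric].notna()]
    groups = {
        str(name): sub[metric].to_numpy(dtype=float)
        for name, sub in df.groupby(group_by, observed=True)
    }
    untestable = [g for g, v in groups.items() if len(v) < 2]
    groups = {g: v for g, v in groups.items() if len(v) >= 2}
    sizes = {g: len(v) for g, v in groups.items()}
    medians = {g: float(np.median(v)) for g, v in groups.items()}
    label = grouping_label or group_by
    if len(groups) < 2:
        return GroupComparison(label, metric, "none", None, None, sizes, medians,
                               untestable=untestable)
    if len(groups) == 2:
        (x, y) = groups.values()
        u, p = mann_whitney(x, y)
        return GroupComparison(label, metric, "mann_whitney", u, p, sizes, medians,
                               untestable=untestable)
    h, p = kruskal_wallis(groups)
    pairwise = dunn_test(groups)
    return GroupComparison(label, metric, "kruskal_wallis_dunn", h, p, sizes, medians,
                           pairwise=pairwise, untestable=untestable)


def matched_location_sets(
    matrices: Mapping[str, OverlapMatrix],
    records: Mapping[str, pd.DataFrame],
    reference_cell_line: str,
    partition: str = "nuclear_bodies",
    intron_class: str | None = None,
) -> dict:
    """Introns sharing a nuclear-body location category across cell lines.

    Returns (i) per-category sets shared across *all* cell lines, (ii)
    pairwise reference-vs-other shared sets with counts, and (iii)
    Mann-Whitney comparisons of SI_RET between cell lines over each shared
    set (introns lacking an SI in either line are excluded, with counts
    logged).
    """
    if reference_cell_line not in matrices:
        raise SplicingError(f"reference cell line {reference_cell_line!r} missing")
    cats = {cl: m.category(partition) for cl, m in matrices.items()}
    categories = sorted(set().union(*[set(c.unique()) for c in cats.values()]))

    def _class_ids(cl: str) -> set[str]:
        df = records[cl]
        if intron_class is not None:
            df = df[df["intron_class"] == intron_class]
        return set(df["intron_id"])

    def _si(cl: str) -> pd.Series:
        df = records[cl]
        return df.set_index("intron_id")["si_ret"]

    shared_all: dict[str, set[str]] = {}
    for cat in categories:
        sets = [
            set(cats[cl][cats[cl] == cat].index) & _class_ids(cl) for cl in matrices
        ]
        shared_all[cat] = set.intersection(*sets) if sets else set()

    pairwise = {}
    ref_si = _si(reference_cell_line)
    for cl in matrices:
        if cl == reference_cell_line:
            continue
        for cat in categories:
            ids = (
                set(cats[reference_cell_line][cats[reference_cell_line] == cat].index)
                & set(cats[cl][cats[cl] == cat].index)
                & _class_ids(reference_cell_line)
                & _class_ids(cl)
            )
            other_si = _si(cl)
            usable = [
                i for i in ids
                if i in ref_si.index and i in other_si.index
                and pd.notna(ref_si[i]) and pd.notna(other_si[i])
            ]
            if len(usable) < len(ids):
                logger.info(
                    "%s vs %s / %s: %d shared introns lack SI in one line",
                    reference_cell_line, cl, cat, len(ids) - len(usable),
                )
            test = None
            if len(usable) >= 2:
                u, p = mann_whitney(ref_si[usable].to_numpy(), other_si[usable].to_numpy())
                test = {"u": u, "p": p,
                        "median_ref": float(np.median(ref_si[usable])),
                        "median_other": float(np.median(other_si[usable]))}
            pairwise[(cl, cat)] = {
                "n_shared": len(ids),
                "n_compared": len(usable),
                "intron_ids": sorted(ids),
                "test": test,
            }
    return {"shared_all": shared_all, "pairwise": pairwise}


def improved_splicing_intersection(
    records_ref: pd.DataFrame,
    records_other: Mapping[str, pd.DataFrame],
    shared_ids: Mapping[str, Iterable[str]],
    intron_classes: Iterable[str] = ("minor",),
) -> dict:
    """Introns spliced more efficiently (strictly lower SI_RET) outside the
    reference line, per comparison line and intersected across lines, with
    deduplicated parent-gene lists for external GO analysis."""
    classes = set(intron_classes)
    ref = records_ref[records_ref["intron_class"].isin(classes)].set_index("intron_id")
    per_line: dict[str, set[str]] = {}
    genes_per_line: dict[str, set[str]] = {}
    for cl, df in records_other.items():
        other = df[df["intron_class"].isin(classes)].set_index("intron_id")
        improved = set()
        for iid in shared_ids.get(cl, []):
            if iid in ref.index and iid in other.index:
                a, b = ref.loc[iid, "si_ret"], other.loc[iid, "si_ret"]
                if pd.notna(a) and pd.notna(b) and b < a:
                    improved.add(iid)
        per_line[cl] = improved
        genes_per_line[cl] = {ref.loc[i, "gene_id"] for i in improved}
    inter = set.intersection(*per_line.values()) if per_line else set()
    return {
        "per_line": per_line,
        "genes_per_line": genes_per_line,
        "intersection": inter,
        "intersection_genes": {ref.loc[i, "gene_id"] for i in inter},
    }
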