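"""Class-labelled intron catalogs and linear-genome statistics.

Introns are carried along a six-class continuum — major, major-like, hybrid,
minor-like, minor and non-canonical — defined upstream by splice-site and
branch-point motif similarity to the major (U2-type) versus minor (U12-type)
consensus.  This module loads a catalog of such introns, computes inter-intron
distances within each class, fits the abundance–distance relationship, bins
intron density along the genome, and scans density bins for class-specific
clusters.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

INTRON_CLASSES = (
    "major",
    "major_like",
    "hybrid",
    "minor_like",
    "minor",
    "non_canonical",
)

#: Input dialects for interval coordinates.
DIALECTS = ("bed_zero_half_open", "tsv_one_based_inclusive")

CATALOG_COLUMNS = ["chrom", "start", "end", "intron_id", "strand", "gene_id", "intron_class"]


class CatalogError(ValueError):
    """Raised for malformed or inconsistent catalog input."""


@dataclass(frozen=True)
class IntronRecord:
    """One class-labelled intron interval (0-based, half-open) with gene linkage."""

    intron_id: str
    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str
    intron_class: str
    rank: int | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise CatalogError(
                f"intron {self.intron_id}: end ({self.end}) must exceed start ({self.start})"
            )
        if self.intron_class not in INTRON_CLASSES:
            raise CatalogError(
                f"intron {self.intron_id}: unknown class {self.intron_class!r}; "
                f"expected one of {INTRON_CLASSES}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class IntronCatalog:
    """An ordered collection of introns together with chromosome sizes."""

    records: list[IntronRecord]
    chrom_sizes: dict[str, int]
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.intron_id in seen:
                raise CatalogError(f"duplicate intron_id {rec.intron_id!r}")
            seen.add(rec.intron_id)
            if rec.chrom not in self.chrom_sizes:
                raise CatalogError(
                    f"intron {rec.intron_id}: chromosome {rec.chrom!r} missing from chrom_sizes"
                )
            if rec.end > self.chrom_sizes[rec.chrom] or rec.start < 0:
                raise CatalogError(
                    f"intron {rec.intron_id}: interval [{rec.start},{rec.end}) outside "
                    f"{rec.chrom} bounds [0,{self.chrom_sizes[rec.chrom]})"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in INTRON_CLASSES}
        for rec in self.records:
            counts[rec.intron_class] += 1
        return {c: n for c, n in counts.items() if n > 0}

    def by_class(self, intron_class: str) -> list[IntronRecord]:
        return [r for r in self.records if r.intron_class == intron_class]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "intron_id": r.intron_id,
                    "chrom": r.chrom,
                    "start": r.start,
                    "end": r.end,
                    "strand": r.strand,
                    "gene_id": r.gene_id,
                    "intron_class": r.intron_class,
                }
                for r in self.records
            ]
        )


@dataclass
class DistanceSummary:
    """Gaps between consecutive same-class introns, pooled genome-wide."""

    intron_class: str
    distances: np.ndarray
    n_pairs: int = field(init=False)
    median_bp: float | None = field(init=False)

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        self.n_pairs = len(self.distances)
        self.median_bp = float(np.median(self.distances)) if self.n_pairs else None


@dataclass
class DensityBin:
    """Per-class intron counts in one fixed-width genomic window."""

    chrom: str
    bin_start: int
    bin_end: int
    counts: dict[str, int]
    flags: dict[str, tuple[bool, float]] = field(default_factory=dict)


def _read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2:
                raise CatalogError(f"{path}:{ln}: expected 'chrom<TAB>length'")
            sizes[parts[0]] = int(parts[1])
    return sizes


def load_intron_catalog(
    path: str | Path,
    dialect: str = "bed_zero_half_open",
    chrom_sizes: str | Path | Mapping[str, int] | None = None,
) -> IntronCatalog:
    """Load a class-labelled intron catalog from BED6+2 or headered TSV.

    BED layout: chrom, start, end, intron_id, score (ignored), strand,
    gene_id, intron_class.  The TSV dialect carries the same columns by
    header name with 1-based inclusive coordinates, converted on load so
    both dialects yield identical internal 0-based half-open catalogs.
    """
    if dialect not in DIALECTS:
        raise CatalogError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    if chrom_sizes is None:
        raise CatalogError("chrom_sizes is required")
    sizes = dict(chrom_sizes) if isinstance(chrom_sizes, Mapping) else _read_chrom_sizes(chrom_sizes)

    records: list[IntronRecord] = []
    with open(path) as fh:
        header: list[str] | None = None
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if dialect == "tsv_one_based_inclusive" and header is None:
                header = parts
                missing = set(CATALOG_COLUMNS) - set(header)
                if missing:
                    raise CatalogError(f"{path}:{ln}: TSV header missing columns {sorted(missing)}")
                continue
            try:
                if dialect == "bed_zero_half_open":
                    if len(parts) < 8:
                        raise ValueError("expected 8 BED columns")
                    chrom, start, end, iid, _score, strand, gene, cls = parts[:8]
                    start_i, end_i = int(start), int(end)
                else:
                    row = dict(zip(header, parts))  # type: ignore[arg-type]
                    chrom, iid = row["chrom"], row["intron_id"]
                    strand, gene, cls = row["strand"], row["gene_id"], row["intron_class"]
                    start_i, end_i = int(row["start"]) - 1, int(row["end"])
                if cls not in INTRON_CLASSES:
                    raise ValueError(f"unknown intron class {cls!r}")
                if strand not in ("+", "-"):
                    raise ValueError(f"bad strand {strand!r}")
                records.append(
                    IntronRecord(
                        intron_id=iid, chrom=chrom, start=start_i, end=end_i,
                        strand=strand, gene_id=gene, intron_class=cls,
                    )
                )
            except (ValueError, KeyError, CatalogError) as exc:
                raise CatalogError(f"{path}:{ln}: {exc}") from exc
    return IntronCatalog(records=records, chrom_sizes=sizes, provenance=str(path))


def inter_intron_distances(catalog: IntronCatalog, intron_class: str) -> DistanceSummary:
    """Gap (next.start − current.end) between consecutive same-class introns.

    Introns are sorted by start within each chromosome; cross-chromosome
    pairs are excluded and negative gaps from overlapping isoform introns
    are clamped to zero.  The summary pools all pairs genome-wide.
    """
    if not catalog.records:
        raise CatalogError("catalog is empty")
    by_chrom: dict[str, list[IntronRecord]] = {}
    for rec in catalog.by_class(intron_class):
        by_chrom.setdefault(rec.chrom, []).append(rec)
    gaps: list[int] = []
    for recs in by_chrom.values():
        recs.sort(key=lambda r: (r.start, r.end))
        for cur, nxt in zip(recs, recs[1:]):
            gaps.append(max(0, nxt.start - cur.end))
    return DistanceSummary(intron_class=intron_class, distances=np.array(gaps, dtype=float))


def abundance_distance_fit(
    counts: Sequence[float], medians: Sequence[float]
) -> dict[str, float]:
    """Pearson correlation of log10(class abundance) vs log10(median gap).

    Returns ``r``, ``r_squared`` at full precision and ``r_squared_2dp``
    rounded to two decimals as conventionally reported.
    """
    counts = np.asarray(counts, dtype=float)
    medians = np.asarray(medians, dtype=float)
    if len(counts) != len(medians) or len(counts) < 2:
        raise CatalogError("need matched counts and medians for >= 2 classes")
    if np.any(counts <= 0) or np.any(medians <= 0):
        raise CatalogError("counts and medians must be positive (log10 undefined otherwise)")
    r, p = stats.pearsonr(np.log10(counts), np.log10(medians))
    return {
        "r": float(r),
        "p": float(p),
        "r_squared": float(r**2),
        "r_squared_2dp": round(float(r**2), 2),
    }


def bin_intron_density(catalog: IntronCatalog, bin_size_bp: int = 250_000) -> list[DensityBin]:
    """Count introns per class in fixed windows tiling every chromosome.

    Each intron lands in exactly one bin, by midpoint; the terminal bin of
    each chromosome may be shorter than ``bin_size_bp``.
    """
    if bin_size_bp <= 0:
        raise CatalogError("bin_size_bp must be positive")
    bins: list[DensityBin] = []
    index: dict[tuple[str, int], DensityBin] = {}
    for chrom, size in catalog.chrom_sizes.items():
        n_bins = max(1, math.ceil(size / bin_size_bp))
        for i in range(n_bins):
            b = DensityBin(
                chrom=chrom,
                bin_start=i * bin_size_bp,
                bin_end=min((i + 1) * bin_size_bp, size),
                counts={c: 0 for c in INTRON_CLASSES},
            )
            bins.append(b)
            index[(chrom, i)] = b
    for rec in catalog.records:
        i = rec.midpoint // bin_size_bp
        index[(rec.chrom, i)].counts[rec.intron_class] += 1
    return bins


def scan_density_clusters(
    bins: list[DensityBin], fdr: float = 0.05
) -> list[DensityBin]:
    """Flag bins whose per-class intron count exceeds a uniform genome-wide rate.

    Under the null each class scatters uniformly, so a bin of width w on a
    genome of length G carries Poisson(lambda = N_class * w / G) introns.  The
    upper-tail p-value per bin is Benjamini-Hochberg adjusted within class and
    bins with adjusted p < ``fdr`` are flagged.
    """
    from statsmodels.stats.multitest import multipletests

    genome_length = sum(b.bin_end - b.bin_start for b in bins)
    totals = {c: sum(b.counts.get(c, 0) for b in bins) for c in INTRON_CLASSES}
    for cls in INTRON_CLASSES:
        if totals[cls] == 0:
            for b in bins:
                b.flags[cls] = (False, 1.0)
            continue
        pvals = np.empty(len(bins))
        for i, b in enumerate(bins):
            lam = totals[cls] * (b.bin_end - b.bin_start) / genome_length
            # P(X >= k) under Poisson(lam)
            pvals[i] = stats.poisson.sf(b.counts.get(cls, 0) - 1, lam)
        _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")
        for b, p in zip(bins, p_adj):
            b.flags[cls] = (bool(p < fdr), float(p))
    return bins


def distance_summaries_frame(summaries: Iterable[DistanceSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "intron_class": s.intron_class,
                "n_pairs": s.n_pairs,
                "median_bp": s.median_bp,
            }
            for s in summaries
        ]
    )


def density_bins_frame(bins: Iterable[DensityBin]) -> pd.DataFrame:
    rows = []
    for b in bins:
        row: dict = {"chrom": b.chrom, "bin_start": b.bin_start, "bin_end": b.bin_end}
        row.update({f"n_{c}": b.counts.get(c, 0) for c in INTRON_CLASSES})
        for c, (flag, p) in b.flags.items():
            row[f"flag_{c}"] = flag
            row[f"padj_{c}"] = p
        rows.append(row)
    return pd.DataFrame(rows)


def write_fit_json(fit: Mapping[str, float], path: str | Path) -> None:
    Path(path).write_text(json.dumps(dict(fit), indent=2) + "\n")
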