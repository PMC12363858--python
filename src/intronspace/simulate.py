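"""Self-contained synthetic study generator with known ground truth.

Builds a toy genome whose gene models carry class-labelled introns, places
introns into 3D-feature tracks (compartments, subcompartments, SPADs, LADs,
TADs/boundaries/loop anchors) with class-specific probabilities, writes
replicate TPM tables, and simulates spliced single-end alignments from
per-intron true retention (psi) and skipping (sigma) rates.

The calibrated preset encodes the published K562 placement rates as
generative probabilities — e.g. compartment A 0.62 for major and 0.71 for
minor introns; SPADs 0.21 vs 0.25; LADs 0.19 vs 0.14 — so that pipeline
stages can be validated against a genome where those rates are true by
construction.  Genes carrying a rare intron carry exactly one, with all
remaining introns major, matching the empirical structure of rare-intron
genes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import pysam

from .catalog import INTRON_CLASSES, IntronCatalog, IntronRecord
from .features import FeatureTrack
from .splicing import GeneModel


class SimulationError(ValueError):
    pass


RARE_CLASSES = ("major_like", "hybrid", "minor_like", "minor", "non_canonical")

#: Calibrated placement probabilities (published K562 rates by class).
CALIBRATED_PLACEMENT: dict[str, dict[str, float]] = {
    #               A     B     SPAD  LAD   A1|A  B1|B  B2|B
    "major":        {"A": 0.62, "B": 0.28, "SPAD": 0.21, "LAD": 0.19,
                     "A1_given_A": 0.73, "B1_given_B": 0.39, "B2_given_B": 0.28},
    "major_like":   {"A": 0.64, "B": 0.26, "SPAD": 0.27, "LAD": 0.17,
                     "A1_given_A": 0.77, "B1_given_B": 0.41, "B2_given_B": 0.28},
    "hybrid":       {"A": 0.51, "B": 0.32, "SPAD": 0.09, "LAD": 0.31,
                     "A1_given_A": 0.73, "B1_given_B": 0.30, "B2_given_B": 0.37},
    "minor_like":   {"A": 0.62, "B": 0.28, "SPAD": 0.21, "LAD": 0.19,
                     "A1_given_A": 0.73, "B1_given_B": 0.34, "B2_given_B": 0.25},
    "minor":        {"A": 0.71, "B": 0.21, "SPAD": 0.25, "LAD": 0.14,
                     "A1_given_A": 0.73, "B1_given_B": 0.39, "B2_given_B": 0.28},
    "non_canonical": {"A": 0.50, "B": 0.28, "SPAD": 0.17, "LAD": 0.25,
                      "A1_given_A": 0.76, "B1_given_B": 0.43, "B2_given_B": 0.33},
}

#: Categorical probabilities over {TAD, boundary, loop_anchor, neither}.
CALIBRATED_THREE_D: dict[str, tuple[float, float, float, float]] = {
    cls: (0.55, 0.04, 0.04, 0.37) for cls in INTRON_CLASSES
}
CALIBRATED_THREE_D["non_canonical"] = (0.48, 0.09, 0.09, 0.34)

#: Class counts: rare classes at roughly 3x their genomic counts' ratios,
#: major scaled down so the baseline stays large but tractable.
CALIBRATED_COUNTS = {
    "major": 30_000,
    "major_like": 5_000,
    "hybrid": 1_100,
    "minor_like": 1_350,
    "minor": 2_550,
    "non_canonical": 3_000,
}

#: Per-class retention / skipping rate means (Beta-distributed per intron).
CALIBRATED_PSI = {
    "major": 0.06, "major_like": 0.14, "hybrid": 0.20,
    "minor_like": 0.15, "minor": 0.04, "non_canonical": 0.25,
}
CALIBRATED_SIGMA = {
    "major": 0.02, "major_like": 0.06, "hybrid": 0.10,
    "minor_like": 0.06, "minor": 0.01, "non_canonical": 0.12,
}


@dataclass
class SyntheticConfig:
    class_counts: dict[str, int] = field(default_factory=lambda: dict(CALIBRATED_COUNTS))
    n_chroms: int = 4
    chrom_length: int | None = None  # None: sized to fit the gene models
    exon_length: int = 150
    intron_length: int = 300
    introns_per_gene: int = 3
    intergenic_gap: int = 500
    one_rare_per_gene: bool = True
    placement: dict[str, dict[str, float]] = field(
        default_factory=lambda: {c: dict(v) for c, v in CALIBRATED_PLACEMENT.items()}
    )
    three_d: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(CALIBRATED_THREE_D)
    )
    spad_concordance: float = 1.4  # SPAD odds boost inside compartment A
    fraction_expressed: float = 0.75
    replicates: int = 2
    replicate_noise: float = 0.05
    psi_mean: dict[str, float] = field(default_factory=lambda: dict(CALIBRATED_PSI))
    sigma_mean: dict[str, float] = field(default_factory=lambda: dict(CALIBRATED_SIGMA))
    beta_concentration: float = 20.0
    junction_depth: int = 100
    read_half: int = 30  # aligned bases on each side of a simulated junction
    cryptic_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for cls, n in self.class_counts.items():
            if cls not in INTRON_CLASSES or n < 0:
                raise SimulationError(f"bad class count {cls}={n}")
        for cls, probs in self.placement.items():
            for k, p in probs.items():
                if not 0 <= p <= 1:
                    raise SimulationError(f"placement[{cls}][{k}]={p} outside [0,1]")
        if self.introns_per_gene < 1:
            raise SimulationError("introns_per_gene must be >= 1")


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside the synthetic files."""

    introns: pd.DataFrame  # per-intron memberships, psi, sigma, depth
    genes: pd.DataFrame    # per-gene mean TPM and expressed flags
    realized_rates: pd.DataFrame | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "introns": self.introns.to_dict(orient="list"),
            "genes": self.genes.to_dict(orient="list"),
        }
        if self.realized_rates is not None:
            payload["realized_rates"] = self.realized_rates.reset_index().to_dict(orient="list")
        Path(path).write_text(json.dumps(payload) + "\n")


def generate_annotation(
    config: SyntheticConfig,
) -> tuple[IntronCatalog, dict[str, GeneModel], SyntheticTruth]:
    """Lay out non-overlapping gene models carrying the configured class counts.

    Each gene alternates exons and introns.  With ``one_rare_per_gene`` the
    rare intron sits at the middle position and all flanking introns are
    major; remaining major introns fill pure-major genes.  Counts match the
    configuration exactly.
    """
    rng = np.random.default_rng(config.seed)
    k = config.introns_per_gene
    counts = {c: config.class_counts.get(c, 0) for c in INTRON_CLASSES}
    n_rare_genes = sum(counts[c] for c in RARE_CLASSES)
    majors_in_rare_genes = n_rare_genes * (k - 1) if config.one_rare_per_gene else 0
    majors_left = counts["major"] - majors_in_rare_genes
    if majors_left < 0:
        raise SimulationError(
            f"major count {counts['major']} too small to flank {n_rare_genes} rare genes "
            f"with {k - 1} majors each; need >= {majors_in_rare_genes}"
        )
    gene_plans: list[list[str]] = []
    for cls in RARE_CLASSES:
        mid = (k - 1) // 2
        for _ in range(counts[cls]):
            plan = ["major"] * k
            plan[mid] = cls
            gene_plans.append(plan)
    while majors_left > 0:
        take = min(k, majors_left)
        gene_plans.append(["major"] * take)
        majors_left -= take
    order = rng.permutation(len(gene_plans))
    gene_plans = [gene_plans[i] for i in order]

    gene_len = lambda ni: (ni + 1) * config.exon_length + ni * config.intron_length
    total_len = sum(gene_len(len(p)) + config.intergenic_gap for p in gene_plans)
    per_chrom = -(-total_len // config.n_chroms)  # ceil
    # auto-sizing leaves room for one unsplittable gene at each chromosome end
    auto = per_chrom + gene_len(k) + config.intergenic_gap
    chrom_length = config.chrom_length or auto
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chroms)]
    chrom_sizes = {c: chrom_length for c in chrom_names}

    records: list[IntronRecord] = []
    models: dict[str, GeneModel] = {}
    truth_rows = []
    ci, pos = 0, 0
    for gi, plan in enumerate(gene_plans):
        ni = len(plan)
        glen = gene_len(ni)
        if pos + glen > chrom_length:
            ci += 1
            pos = 0
            if ci >= config.n_chroms:
                raise SimulationError(
                    f"genes exceed chromosome capacity; need total length >= "
                    f"{total_len} across {config.n_chroms} chromosomes "
                    f"(chrom_length >= {per_chrom + config.intergenic_gap})"
                )
        chrom = chrom_names[ci]
        gene_id = f"gene{gi:06d}"
        strand = "+" if rng.random() < 0.5 else "-"
        exons = []
        p = pos
        for e in range(ni + 1):
            exons.append((p, p + config.exon_length))
            p += config.exon_length + (config.intron_length if e < ni else 0)
        models[gene_id] = GeneModel(gene_id=gene_id, chrom=chrom, strand=strand, exons=exons)
        for ii, ((_, e_end), (n_start, _)) in enumerate(zip(exons, exons[1:])):
            cls = plan[ii]
            iid = f"{gene_id}.i{ii}"
            records.append(
                IntronRecord(
                    intron_id=iid, chrom=chrom, start=e_end, end=n_start,
                    strand=strand, gene_id=gene_id, intron_class=cls, rank=ii,
                )
            )
            a = config.beta_concentration
            psi = float(rng.beta(a * config.psi_mean[cls], a * (1 - config.psi_mean[cls])))
            sigma = float(rng.beta(a * config.sigma_mean[cls], a * (1 - config.sigma_mean[cls])))
            if ni == 1:
                sigma = 0.0  # single-intron genes cannot exhibit exon skipping
            truth_rows.append(
                {"intron_id": iid, "gene_id": gene_id, "intron_class": cls,
                 "psi": psi, "sigma": sigma, "depth": config.junction_depth}
            )
        pos += glen + config.intergenic_gap
    catalog = IntronCatalog(records=records, chrom_sizes=chrom_sizes, provenance="synthetic")
    truth = SyntheticTruth(
        introns=pd.DataFrame(truth_rows).set_index("intron_id", drop=False),
        genes=pd.DataFrame(index=pd.Index(sorted(models), name="gene_id")),
    )
    return catalog, models, truth


def _spad_conditional(p_spad: float, p_a: float, concordance: float) -> tuple[float, float]:
    """P(SPAD | in A) and P(SPAD | not in A) preserving the marginal rate."""
    p_given_a = min(1.0, p_spad * concordance)
    if p_a >= 1.0:
        return p_given_a, 0.0
    p_given_not = (p_spad - p_a * p_given_a) / (1.0 - p_a)
    if p_given_not < 0:
        raise SimulationError(
            f"inconsistent nesting: SPAD rate {p_spad} with concordance {concordance} "
            f"inside A rate {p_a} leaves a negative outside-A probability"
        )
    return p_given_a, p_given_not


def generate_feature_tracks(
    config: SyntheticConfig,
    catalog: IntronCatalog,
    truth: SyntheticTruth,
    cell_line: str = "SYN1",
    seed_offset: int = 1,
) -> list[FeatureTrack]:
    """Draw per-intron feature memberships and materialise interval tracks.

    Feature intervals coincide with member introns, so the >= 50%-overlap rule
    recovers the intended membership exactly.  SPAD membership is drawn
    conditionally on compartment A at ``spad_concordance`` while preserving
    the marginal SPAD rate per class.
    """
    rng = np.random.default_rng(config.seed + seed_offset)
    assignments: dict[str, dict[str, bool]] = {}
    comp_col, nb_col, sub_col, td_col = {}, {}, {}, {}
    for rec in catalog.records:
        probs = config.placement[rec.intron_class]
        u = rng.random()
        if u < probs["A"]:
            comp = "compartment_A"
        elif u < probs["A"] + probs["B"]:
            comp = "compartment_B"
        else:
            comp = "neither"
        sub = "neither"
        if comp == "compartment_A":
            sub = "A1" if rng.random() < probs["A1_given_A"] else "A2"
        elif comp == "compartment_B":
            v = rng.random()
            if v < probs["B1_given_B"]:
                sub = "B1"
            elif v < probs["B1_given_B"] + probs["B2_given_B"]:
                sub = "B2"
            else:
                sub = "B3"
        p_sa, p_sn = _spad_conditional(probs["SPAD"], probs["A"], config.spad_concordance)
        p_spad_here = p_sa if comp == "compartment_A" else p_sn
        if rng.random() < p_spad_here:
            nb = "SPAD"
        elif rng.random() < probs["LAD"] / max(1e-12, 1.0 - probs["SPAD"]):
            nb = "LAD"
        else:
            nb = "neither"
        t_tad, t_bnd, t_loop, _ = config.three_d[rec.intron_class]
        w = rng.random()
        if w < t_tad:
            td = "TAD"
        elif w < t_tad + t_bnd:
            td = "boundary"
        elif w < t_tad + t_bnd + t_loop:
            td = "loop_anchor"
        else:
            td = "neither"
        assignments[rec.intron_id] = {
            comp: True, sub: True, nb: True, td: True,
        }
        comp_col[rec.intron_id] = comp
        sub_col[rec.intron_id] = sub
        nb_col[rec.intron_id] = nb
        td_col[rec.intron_id] = td

    tr = truth.introns
    tr["true_compartment"] = tr["intron_id"].map(comp_col)
    tr["true_subcompartment"] = tr["intron_id"].map(sub_col)
    tr["true_nuclear_body"] = tr["intron_id"].map(nb_col)
    tr["true_three_d"] = tr["intron_id"].map(td_col)
    rates = (
        tr.assign(
            in_A=tr["true_compartment"] == "compartment_A",
            in_SPAD=tr["true_nuclear_body"] == "SPAD",
            in_LAD=tr["true_nuclear_body"] == "LAD",
        )
        .groupby("intron_class")[["in_A", "in_SPAD", "in_LAD"]]
        .mean()
    )
    truth.realized_rates = rates

    tracks = []
    feature_types = [
        "compartment_A", "compartment_B", "A1", "A2", "B1", "B2", "B3",
        "SPAD", "LAD", "TAD", "boundary", "loop_anchor",
    ]
    member_of = {ft: [] for ft in feature_types}
    for rec in catalog.records:
        for ft in assignments[rec.intron_id]:
            if ft != "neither":
                member_of[ft].append(rec)
    for ft in feature_types:
        intervals: dict[str, list[tuple[int, int]]] = {}
        for rec in member_of[ft]:
            intervals.setdefault(rec.chrom, []).append((rec.start, rec.end))
        tracks.append(FeatureTrack(feature_type=ft, cell_line=cell_line, intervals=intervals))
    return tracks


def generate_expression(
    config: SyntheticConfig,
    gene_models: Mapping[str, GeneModel],
    truth: SyntheticTruth,
    cell_line: str = "SYN1",
    seed_offset: int = 2,
) -> pd.DataFrame:
    """Replicate TPM table with a configured expressed-gene fraction.

    Expressed genes draw mean TPM = 1.5 + LogNormal(0, 1) (safely above the
    1-TPM rule); non-expressed genes draw Uniform(0, 0.9).  Replicates jitter
    the mean multiplicatively by ``replicate_noise``.
    """
    rng = np.random.default_rng(config.seed + seed_offset)
    genes = sorted(gene_models)
    expressed = rng.random(len(genes)) < config.fraction_expressed
    mean_tpm = np.where(
        expressed,
        1.5 + rng.lognormal(0.0, 1.0, len(genes)),
        rng.uniform(0.0, 0.9, len(genes)),
    )
    reps = {}
    for r in range(config.replicates):
        jitter = 1.0 + config.replicate_noise * rng.standard_normal(len(genes))
        reps[f"{cell_line}_rep{r + 1}"] = np.clip(mean_tpm * jitter, 0.0, None)
    df = pd.DataFrame({"gene_id": genes, **reps})
    truth.genes = pd.DataFrame(
        {
            "gene_id": genes,
            "true_mean_tpm": mean_tpm,
            "expressed_1": mean_tpm >= 1.0,
            "expressed_20": mean_tpm >= 20.0,
        }
    ).set_index("gene_id", drop=False)
    return df


def simulate_alignments(
    config: SyntheticConfig,
    catalog: IntronCatalog,
    gene_models: Mapping[str, GeneModel],
    truth: SyntheticTruth,
    out_sam: str | Path,
    cell_line: str = "SYN1",
    seed_offset: int = 3,
) -> pd.DataFrame:
    """Materialise per-intron junction counts as spliced SAM records.

    Per intron with depth d: n5, n3 ~ Poisson(d*psi) independently,
    n_spliced ~ Poisson(d*(1-psi)*(1-sigma)), n_skip ~ Poisson(d*(1-psi)*sigma),
    optional cryptic reads at ``cryptic_rate``.  Reads are single-end,
    uniquely mapped, with ``read_half`` aligned bases on each side of every
    junction.  The returned truth table records the counts the extractor will
    see — including exon-skipping reads that also span a neighbouring intron.

    Requires read_half >= 2 so anchors pass the single-nucleotide exclusion.
    """
    h = config.read_half
    if h < 2:
        raise SimulationError("read_half too short for junction anchors (need >= 2)")
    if config.intron_length < 2 * h + 20 and config.cryptic_rate > 0:
        raise SimulationError("introns too short to place cryptic gaps inside")
    rng = np.random.default_rng(config.seed + seed_offset)
    tr = truth.introns
    written = {
        iid: {"n5": 0, "n3": 0, "n_spliced": 0, "n_skip": 0, "n_cryptic": 0}
        for iid in tr["intron_id"]
    }
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": int(l)} for c, l in catalog.chrom_sizes.items()],
    }
    tid = {c: i for i, c in enumerate(catalog.chrom_sizes)}
    reads: list[tuple[int, int, str, str]] = []  # (tid, pos, cigar, qname)
    introns_by_gene: dict[str, list] = {}
    for rec in catalog.records:
        introns_by_gene.setdefault(rec.gene_id, []).append(rec)
    for g in introns_by_gene.values():
        g.sort(key=lambda r: r.start)

    for rec in catalog.records:
        row = tr.loc[rec.intron_id]
        psi, sigma, d = float(row["psi"]), float(row["sigma"]), float(row["depth"])
        n5 = int(rng.poisson(d * psi))
        n3 = int(rng.poisson(d * psi))
        n_spl = int(rng.poisson(d * (1 - psi) * (1 - sigma)))
        n_skip = int(rng.poisson(d * (1 - psi) * sigma))
        n_cry = int(rng.poisson(d * config.cryptic_rate)) if config.cryptic_rate else 0
        t = tid[rec.chrom]
        L = rec.length
        for i in range(n5):
            reads.append((t, rec.start - h, f"{2 * h}M", f"{rec.intron_id}.b5.{i}"))
        for i in range(n3):
            reads.append((t, rec.end - h, f"{2 * h}M", f"{rec.intron_id}.b3.{i}"))
        for i in range(n_spl):
            reads.append((t, rec.start - h, f"{h}M{L}N{h}M", f"{rec.intron_id}.sp.{i}"))
        written[rec.intron_id]["n5"] += n5
        written[rec.intron_id]["n3"] += n3
        written[rec.intron_id]["n_spliced"] += n_spl
        if n_skip:
            sibs = introns_by_gene[rec.gene_id]
            pos_in_gene = sibs.index(rec)
            partner = None
            if pos_in_gene + 1 < len(sibs):
                partner = sibs[pos_in_gene + 1]
                gap_start, gap_end = rec.start, partner.end
            elif pos_in_gene > 0:
                partner = sibs[pos_in_gene - 1]
                gap_start, gap_end = partner.start, rec.end
            if partner is not None:
                gl = gap_end - gap_start
                for i in range(n_skip):
                    reads.append(
                        (t, gap_start - h, f"{h}M{gl}N{h}M", f"{rec.intron_id}.sk.{i}")
                    )
                written[rec.intron_id]["n_skip"] += n_skip
                written[partner.intron_id]["n_skip"] += n_skip
        if n_cry:
            gs, ge = rec.start + 2 * h + 10, rec.end - 2 * h - 10
            gl = ge - gs
            for i in range(n_cry):
                reads.append((t, gs - h, f"{h}M{gl}N{h}M", f"{rec.intron_id}.cr.{i}"))
            written[rec.intron_id]["n_cryptic"] += n_cry

    reads.sort(key=lambda r: (r[0], r[1]))
    with pysam.AlignmentFile(str(out_sam), "w", header=header) as out:
        for t, pos, cigar, qname in reads:
            a = pysam.AlignedSegment(out.header)
            a.query_name = qname
            a.reference_id = t
            a.reference_start = pos
            a.mapping_quality = 60
            a.cigarstring = cigar
            a.flag = 0
            out.write(a)

    counts = pd.DataFrame.from_dict(written, orient="index")
    counts.index.name = "intron_id"
    for col in counts.columns:
        tr[f"written_{col}"] = counts[col].reindex(tr["intron_id"]).to_numpy()
    return counts


def write_catalog_bed(catalog: IntronCatalog, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in catalog.records:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.intron_id}\t0\t{r.strand}"
                f"\t{r.gene_id}\t{r.intron_class}\n"
            )


def write_chrom_sizes(catalog: IntronCatalog, path: str | Path) -> None:
    with open(path, "w") as fh:
        for c, l in catalog.chrom_sizes.items():
            fh.write(f"{c}\t{l}\n")


def write_gene_models_bed12(models: Mapping[str, GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gm in models.values():
            start = gm.exons[0][0]
            end = gm.exons[-1][1]
            sizes = ",".join(str(e - s) for s, e in gm.exons)
            starts = ",".join(str(s - start) for s, _ in gm.exons)
            fh.write(
                f"{gm.chrom}\t{start}\t{end}\t{gm.gene_id}\t0\t{gm.strand}"
                f"\t{start}\t{end}\t0\t{len(gm.exons)}\t{sizes}\t{starts}\n"
            )


def write_feature_tracks(tracks, out_dir: str | Path) -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for t in tracks:
        p = out_dir / f"{t.cell_line}.{t.feature_type}.bed"
        with open(p, "w") as fh:
            for chrom, ivs in sorted(t.intervals.items()):
                for s, e in ivs:
                    fh.write(f"{chrom}\t{s}\t{e}\n")
        paths[t.feature_type] = p
    return paths
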