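"""Bootstrap and pollution resampling nulls for feature enrichment.

Class-level enrichment of rare introns in a 3D feature could simply reflect
the genes those introns sit in.  Two resampling designs control for this:

* **bootstrap null** — many random sets of baseline (major) introns matched
  in size to the focal class; if the median resampled proportion stays at the
  baseline rate, the focal enrichment is not a set-size artifact.
* **pollution analysis** — baseline sets in which an increasing fraction of
  members is substituted by focal-class introns; enrichment that rises
  monotonically with the substituted fraction is tethered to class identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .catalog import IntronCatalog
from .features import OverlapMatrix


class ResamplingError(ValueError):
    pass


def _substreams(seed: int, n: int) -> list[np.random.Generator]:
    # Per-replicate substreams; spawn is prefix-stable, so growing n_boot
    # never reshuffles earlier replicates.
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _class_membership(
    matrix: OverlapMatrix, catalog: IntronCatalog, intron_class: str, feature_type: str
) -> np.ndarray:
    ids = [r.intron_id for r in catalog.records if r.intron_class == intron_class]
    if feature_type not in matrix.memberships.columns:
        raise ResamplingError(f"no membership for feature {feature_type!r}")
    return matrix.memberships[feature_type].loc[ids].to_numpy(dtype=bool)


@dataclass
class BootstrapDistribution:
    feature_type: str
    baseline_class: str
    sample_size: int
    n_boot: int
    proportions: np.ndarray
    seed: int
    observed_focal: float | None = None
    median: float = field(init=False)
    percentile_of_observed: float | None = field(init=False, default=None)

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, dtype=float)
        self.median = float(np.median(self.proportions))
        if self.observed_focal is not None:
            # Two-sided empirical tail with the +1 correction.
            b_hi = int(np.sum(self.proportions >= self.observed_focal))
            b_lo = int(np.sum(self.proportions <= self.observed_focal))
            tail = min(b_hi, b_lo)
            self.percentile_of_observed = min(1.0, 2 * (tail + 1) / (self.n_boot + 1))


def bootstrap_null(
    matrix: OverlapMatrix,
    catalog: IntronCatalog,
    baseline_class: str,
    feature_type: str,
    sample_size: int,
    n_boot: int = 1000,
    seed: int = 0,
    focal_class: str | None = None,
) -> BootstrapDistribution:
    """Matched-size random sets of baseline introns; proportion in a feature.

    Each replicate draws ``sample_size`` baseline introns without replacement
    (with replacement across replicates) and records the fraction inside the
    feature.  When ``focal_class`` is given, the observed focal proportion and
    its two-sided empirical percentile in the null are also reported.
    """
    member = _class_membership(matrix, catalog, baseline_class, feature_type)
    n = len(member)
    if sample_size > n:
        raise ResamplingError(f"sample_size {sample_size} exceeds baseline class size {n}")
    props = np.empty(n_boot)
    for b, rng in enumerate(_substreams(seed, n_boot)):
        idx = rng.choice(n, size=sample_size, replace=False)
        props[b] = member[idx].mean()
    observed = None
    if focal_class is not None:
        focal = _class_membership(matrix, catalog, focal_class, feature_type)
        observed = float(focal.mean()) if len(focal) else None
    return BootstrapDistribution(
        feature_type=feature_type,
        baseline_class=baseline_class,
        sample_size=sample_size,
        n_boot=n_boot,
        proportions=props,
        seed=seed,
        observed_focal=observed,
    )


@dataclass
class PollutionCurve:
    feature_type: str
    baseline_class: str
    focal_class: str
    sample_size: int
    fractions: np.ndarray
    points: np.ndarray  # columns: fraction_minor, proportion_in_feature
    seed: int
    r: float | None = None
    p_r: float | None = None
    flagged: str = ""


DEFAULT_FRACTIONS = tuple(np.round(np.arange(0.1, 1.01, 0.1), 10))


def pollution_curve(
    matrix: OverlapMatrix,
    catalog: IntronCatalog,
    baseline_class: str,
    focal_class: str,
    feature_type: str,
    fractions: tuple[float, ...] = DEFAULT_FRACTIONS,
    n_boot: int = 1000,
    seed: int = 0,
    sample_size: int | None = None,
) -> PollutionCurve:
    """Fractional substitution of focal introns into matched baseline sets.

    At fraction f each replicate holds round(f·n) focal plus round((1−f)·n)
    baseline introns, both sampled without replacement; the sample size n
    defaults to the focal class size so that f = 1 reproduces the focal set
    exactly.  Substituted counts use banker's rounding and are recorded.
    """
    base = _class_membership(matrix, catalog, baseline_class, feature_type)
    focal = _class_membership(matrix, catalog, focal_class, feature_type)
    n = sample_size if sample_size is not None else len(focal)
    rows = []
    streams = _substreams(seed, len(fractions) * n_boot)
    for fi, f in enumerate(fractions):
        k_focal = int(np.round(f * n))
        k_base = int(np.round((1 - f) * n))
        if k_focal > len(focal) or k_base > len(base):
            raise ResamplingError(
                f"fraction {f}: needs {k_focal} focal / {k_base} baseline introns, "
                f"classes have {len(focal)} / {len(base)}"
            )
        for b in range(n_boot):
            rng = streams[fi * n_boot + b]
            hits = 0
            if k_base:
                hits += base[rng.choice(len(base), size=k_base, replace=False)].sum()
            if k_focal:
                hits += focal[rng.choice(len(focal), size=k_focal, replace=False)].sum()
            rows.append((f, hits / (k_base + k_focal)))
    points = np.array(rows)
    curve = PollutionCurve(
        feature_type=feature_type,
        baseline_class=baseline_class,
        focal_class=focal_class,
        sample_size=n,
        fractions=np.asarray(fractions, dtype=float),
        points=points,
        seed=seed,
    )
    if len(np.unique(points[:, 0])) < 2:
        curve.flagged = "single fraction; correlation not computed"
        return curve
    return pollution_correlation(curve)


def pollution_correlation(curve: PollutionCurve) -> PollutionCurve:
    """Pearson r between substituted fraction and in-feature proportion."""
    if len(np.unique(curve.points[:, 0])) < 2:
        raise ResamplingError("need points at >= 2 distinct fractions")
    if np.allclose(np.var(curve.points[:, 1]), 0):
        curve.r, curve.p_r = None, None
        curve.flagged = "zero variance in proportions; correlation undefined"
        return curve
    r, p = stats.pearsonr(curve.points[:, 0], curve.points[:, 1])
    curve.r, curve.p_r = float(r), float(p)
    return curve
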