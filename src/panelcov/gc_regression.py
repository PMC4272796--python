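"""Gene-level GC content, size, and their association with coverage.

Coverage heterogeneity between genes is tested against two candidate
drivers: the size of a gene's unique coding footprint and its GC
fraction.  Each driver enters a simple ordinary-least-squares fit of
per-gene median coverage on the untransformed predictor (GC as a
fraction in [0, 1], size in bases); the slope is tested two-sided with
a t statistic on n - 2 degrees of freedom.  A complementary two-group
check compares the GC content of the k best- against the k
worst-covered genes with Welch's t-test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
from pyfaidx import Fasta
from scipy import stats

from .annotations import AnnotationDB
from .coverage_stats import GeneCoverageSummary
from .intervals import IntervalSet

logger = logging.getLogger(__name__)

_GC = frozenset("GC")
_ACGT = frozenset("ACGT")


def gc_content(fasta: Union[str, Path, Fasta], regions: IntervalSet) -> float:
    """GC fraction over a region set: (G+C) / (A+C+G+T).

    Counting is case-insensitive (soft-masked lowercase counts like
    uppercase); ambiguity codes such as N are excluded from both
    numerator and denominator.  A region extending past the end of its
    sequence is a bounds error; a region with no unambiguous base has
    undefined GC.
    """
    fa = fasta if isinstance(fasta, Fasta) else Fasta(str(fasta))
    gc = acgt = 0
    for iv in regions:
        if iv.chrom not in fa:
            raise KeyError(f"sequence {iv.chrom!r} not in FASTA")
        seq_len = len(fa[iv.chrom])
        if iv.end > seq_len:
            raise IndexError(f"{iv.chrom}:{iv.start}-{iv.end} extends past sequence end ({seq_len})")
        seq = str(fa[iv.chrom][iv.start : iv.end]).upper()
        for ch in seq:
            if ch in _ACGT:
                acgt += 1
                if ch in _GC:
                    gc += 1
    if acgt == 0:
        raise ValueError("GC content undefined: no unambiguous A/C/G/T base in regions")
    return gc / acgt


@dataclass(frozen=True)
class GeneFeature:
    """Per-gene predictors and response for the coverage regressions."""

    gene: str
    size_bases: int
    gc_fraction: float
    median_coverage: float


def build_features(
    db: AnnotationDB,
    summaries: Sequence[GeneCoverageSummary],
    fasta: Union[str, Path, Fasta],
) -> list[GeneFeature]:
    """Join gene models, GC content and coverage medians into one table.

    Genes outside the depth-track universe and genes with undefined GC
    (all ambiguous bases) are excluded with a warning.
    """
    fa = fasta if isinstance(fasta, Fasta) else Fasta(str(fasta))
    by_gene = {s.gene: s for s in summaries}
    feats: list[GeneFeature] = []
    for gene in db.genes:
        summ = by_gene.get(gene)
        if summ is None or not summ.in_track:
            logger.warning("gene %s has no bases in the depth track; excluded from regression", gene)
            continue
        try:
            gc = gc_content(fa, db.models[gene].regions)
        except ValueError:
            logger.warning("gene %s has undefined GC content; excluded from regression", gene)
            continue
        feats.append(
            GeneFeature(
                gene=gene,
                size_bases=db.models[gene].size_bases,
                gc_fraction=gc,
                median_coverage=summ.median,
            )
        )
    return feats


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def fit_ols(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Closed-form simple linear regression of y on x.

    Returns the slope, intercept, coefficient of determination
    r^2 = 1 - SS_res / SS_tot, and the two-sided p-value of the slope
    from t = slope / SE(slope) on n - 2 degrees of freedom (identical
    to the F-test of a one-predictor model).  A perfect fit reports
    p = 0; a constant response reports r^2 = 0, p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n != y.size:
        raise ValueError("x and y must have equal length")
    if n < 3:
        raise ValueError("OLS needs at least 3 observations for a slope test")
    xm, ym = x.mean(), y.mean()
    dx, dy = x - xm, y - ym
    sxx = float(dx @ dx)
    if sxx == 0.0:
        raise ValueError("degenerate predictor: x is constant")
    sxy = float(dx @ dy)
    syy = float(dy @ dy)
    slope = sxy / sxx
    intercept = ym - slope * xm
    ss_res = float(np.sum((y - (intercept + slope * x)) ** 2))
    if syy == 0.0:
        return RegressionResult(slope=slope, intercept=intercept, r_squared=0.0, p_value=1.0, n=n)
    r_squared = 1.0 - ss_res / syy
    if ss_res <= 0.0:
        return RegressionResult(slope=slope, intercept=intercept, r_squared=1.0, p_value=0.0, n=n)
    se = np.sqrt(ss_res / (n - 2) / sxx)
    t = slope / se
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return RegressionResult(slope=slope, intercept=intercept, r_squared=r_squared, p_value=float(p), n=n)


@dataclass(frozen=True)
class ExtremesGCResult:
    top_genes: tuple[str, ...]
    bottom_genes: tuple[str, ...]
    top_mean_gc: float
    bottom_mean_gc: float
    t_statistic: float
    p_value: float


def extremes_gc_test(
    features: Iterable[GeneFeature], k: int = 5, *, equal_var: bool = False
) -> ExtremesGCResult:
    """Compare GC of the k best- vs k worst-covered genes.

    Genes are ranked by median coverage; the two GC samples are
    compared with a two-sided t-test (Welch by default; set
    ``equal_var=True`` for the pooled-variance variant).  If both
    groups have zero GC variance the test degenerates: p = 1 when the
    means coincide, otherwise p -> 0 with a warning.
    """
    feats = sorted(features, key=lambda f: f.median_coverage, reverse=True)
    if len(feats) < 2 * k:
        raise ValueError(f"need at least {2 * k} genes for a top-{k}/bottom-{k} comparison")
    top, bottom = feats[:k], feats[-k:]
    top_gc = np.array([f.gc_fraction for f in top])
    bot_gc = np.array([f.gc_fraction for f in bottom])
    if top_gc.std(ddof=1) == 0.0 and bot_gc.std(ddof=1) == 0.0:
        if top_gc.mean() == bot_gc.mean():
            t, p = 0.0, 1.0
        else:
            warnings.warn("zero GC variance in both groups; p-value degenerates to 0")
            t = np.inf if top_gc.mean() > bot_gc.mean() else -np.inf
            p = 0.0
    else:
        t, p = stats.ttest_ind(top_gc, bot_gc, equal_var=equal_var)
        t, p = float(t), float(p)
    return ExtremesGCResult(
        top_genes=tuple(f.gene for f in top),
        bottom_genes=tuple(f.gene for f in bottom),
        top_mean_gc=float(top_gc.mean()),
        bottom_mean_gc=float(bot_gc.mean()),
        t_statistic=t,
        p_value=p,
    )
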