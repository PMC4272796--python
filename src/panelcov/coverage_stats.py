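"""Coverage statistics for the panel audit.

Four summaries drive the audit's conclusions:

* cumulative coverage curves — for each depth threshold d, the
  fraction of target bases whose cross-sample mean depth is >= d
  (read at d = 3 for the minimum depth to see a heterozygous variant
  and d = 30 for a confident genotype call);
* per-gene median / quartile summaries with low-coverage flags;
* flag tallies across the panel;
* inter-sample variability as per-base 95% confidence-interval
  half-widths under a normal approximation.

Thresholding always happens on the averaged (possibly non-integer)
track with >= semantics; "below" the optimal depth means strictly
less than it.  Denominators are full target sizes: uncaptured bases
count as depth 0, never as missing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .annotations import AnnotationDB
from .depth import DepthTrack, SampleDepthMatrix
from .intervals import IntervalSet


@dataclass
class CoverageCurve:
    """Fraction of target bases at or above each integer depth threshold."""

    thresholds: np.ndarray
    fraction_covered: np.ndarray

    def at(self, d: float) -> float:
        """Read the curve at threshold ``d`` (d <= 0 is trivially 1)."""
        if d <= 0:
            return 1.0
        idx = np.searchsorted(self.thresholds, d, side="left")
        if idx >= len(self.thresholds) or self.thresholds[idx] != d:
            raise KeyError(f"threshold {d} not on the curve grid")
        return float(self.fraction_covered[idx])


def coverage_curve(track: DepthTrack, targets: IntervalSet, max_depth: int = 200) -> CoverageCurve:
    if targets.total_bases == 0:
        raise ValueError("coverage curve is undefined over an empty target")
    vals = np.sort(track.values_over(targets))
    n = vals.size
    thresholds = np.arange(1, max_depth + 1)
    # fraction >= t via one searchsorted on the sorted per-base means
    below = np.searchsorted(vals, thresholds, side="left")
    return CoverageCurve(thresholds=thresholds, fraction_covered=(n - below) / n)


def capture_fraction(track: DepthTrack, targets: IntervalSet, d: float) -> float:
    """Single point of the coverage curve (any real threshold)."""
    if targets.total_bases == 0:
        raise ValueError("capture fraction is undefined over an empty target")
    if d <= 0:
        return 1.0
    vals = track.values_over(targets)
    return float((vals >= d).mean())


@dataclass
class GeneCoverageSummary:
    """Distribution of per-base mean depth within one gene's regions."""

    gene: str
    n_bases: int
    q1: float
    median: float
    q3: float
    median_below_optimal: bool
    iqr_above_optimal: bool
    in_track: bool

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


def gene_summaries(
    track: DepthTrack,
    db: AnnotationDB,
    optimal_depth: float = 30.0,
    *,
    quantile_method: str = "linear",
    iqr_rule: str = "box_above",
) -> list[GeneCoverageSummary]:
    """Median/q1/q3 of per-base mean depth for every gene in the database.

    Quantiles use linear interpolation between order statistics by
    default (``quantile_method`` passes through to ``numpy.quantile``).
    ``iqr_rule`` selects what "IQR above the optimal depth" means:
    ``box_above`` flags genes whose lower quartile is at or above the
    optimal depth (the whole interquartile box sits at or above it);
    ``span`` flags genes whose q3 - q1 span is at least the optimal
    depth.  Genes whose regions have no base in the track universe are
    marked ``in_track=False`` (downstream regressions exclude them).
    """
    if not db.models:
        raise ValueError("empty annotation database")
    if iqr_rule not in {"box_above", "span"}:
        raise ValueError(f"unknown iqr_rule {iqr_rule!r}")
    out: list[GeneCoverageSummary] = []
    for gene in db.genes:
        model = db.models[gene]
        vals = track.values_over(model.regions)
        q1, med, q3 = np.quantile(vals, [0.25, 0.5, 0.75], method=quantile_method)
        iqr_flag = (q1 >= optimal_depth) if iqr_rule == "box_above" else (q3 - q1 >= optimal_depth)
        out.append(
            GeneCoverageSummary(
                gene=gene,
                n_bases=model.size_bases,
                q1=float(q1),
                median=float(med),
                q3=float(q3),
                median_below_optimal=bool(med < optimal_depth),
                iqr_above_optimal=bool(iqr_flag),
                in_track=track.n_present(model.regions) > 0,
            )
        )
    return out


def count_flags(summaries: Iterable[GeneCoverageSummary]) -> tuple[int, int]:
    """Tally (genes with median below optimal, genes with IQR flag set)."""
    n_below = n_iqr = 0
    for s in summaries:
        n_below += s.median_below_optimal
        n_iqr += s.iqr_above_optimal
    return n_below, n_iqr


@dataclass
class VariabilityProfile:
    """Per-base 95% CI half-widths of depth across samples.

    Half-width = 1.96 * SD / sqrt(n) with the n-1 sample standard
    deviation; the normal approximation is appropriate at the sample
    sizes capture experiments run (tens to hundreds of exomes).
    """

    half_widths: np.ndarray
    n_samples: int

    def fraction_within(self, k: float) -> float:
        """Share of bases whose half-width is at most ``k`` reads."""
        if self.half_widths.size == 0:
            raise ValueError("no bases in variability profile")
        return float((self.half_widths <= k).mean())


def intersample_variability(m: SampleDepthMatrix) -> VariabilityProfile:
    if m.n_samples < 2:
        raise ValueError("inter-sample variability needs >= 2 samples (SD undefined)")
    sd = m.depths.std(axis=1, ddof=1)
    hw = 1.96 * sd / np.sqrt(m.n_samples)
    return VariabilityProfile(half_widths=hw, n_samples=m.n_samples)
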