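"""Per-base read-depth ingestion and cross-sample aggregation.

The audit consumes the textual per-base depth export of a pileup run:
one ``chrom<TAB>pos<TAB>depth`` line per covered base, positions
1-based as pileup prints them.  The -1 shift to the package's internal
0-based convention happens in :func:`read_depth_table` and nowhere
else.

Target bases absent from a sample's file are uncaptured, not missing
data: they carry depth 0 in the sample matrix.  This zero-fill rule is
what makes "proportion of the target not captured" computable from
depth files alone, and it keeps every denominator equal to the full
target size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .intervals import IntervalSet

logger = logging.getLogger(__name__)


class DepthParseError(ValueError):
    """A depth-table line could not be parsed; message names file and line."""


class DepthDataError(ValueError):
    """Structurally valid input that violates a data contract (e.g. duplicates)."""


def read_depth_table(path: Union[str, Path]) -> pd.DataFrame:
    """Parse a 3-column per-base depth table.

    Input positions are 1-based (pileup convention); the returned frame
    has columns ``chrom`` (str), ``pos`` (0-based int) and ``depth``
    (non-negative int).
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["chrom", "pos", "depth"],
            dtype={"chrom": str, "pos": np.int64, "depth": np.int64},
            comment=None,
        )
    except (ValueError, pd.errors.ParserError):
        _raise_with_line(path)
        raise  # pragma: no cover
    if len(df.columns) != 3:
        raise DepthParseError(f"{path}: expected 3 tab-separated columns")
    if len(df) and (df["pos"] < 1).any():
        bad = int(np.flatnonzero(df["pos"].to_numpy() < 1)[0]) + 1
        raise DepthParseError(f"{path}:{bad}: position must be >= 1 (1-based input)")
    if len(df) and (df["depth"] < 0).any():
        bad = int(np.flatnonzero(df["depth"].to_numpy() < 0)[0]) + 1
        raise DepthParseError(f"{path}:{bad}: negative depth")
    df["pos"] = df["pos"] - 1
    return df


def _raise_with_line(path: Path) -> None:
    """Re-scan a file pandas rejected to report the offending line number."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise DepthParseError(f"{path}:{lineno}: expected 3 tab-separated columns")
            try:
                int(fields[1])
                int(fields[2])
            except ValueError:
                raise DepthParseError(f"{path}:{lineno}: non-integer position or depth")
    raise DepthParseError(f"{path}: malformed depth table")


def write_depth_table(df: pd.DataFrame, path: Union[str, Path]) -> None:
    """Inverse of :func:`read_depth_table` (re-applies the +1 shift)."""
    out = df[["chrom", "pos", "depth"]].copy()
    out["pos"] = out["pos"] + 1
    out.to_csv(path, sep="\t", header=False, index=False)


def target_base_arrays(targets: IntervalSet) -> tuple[np.ndarray, np.ndarray]:
    """Enumerate every base of a canonical set in (chrom, pos) order."""
    chroms: list[np.ndarray] = []
    positions: list[np.ndarray] = []
    for iv in targets:
        n = iv.end - iv.start
        chroms.append(np.full(n, iv.chrom, dtype=object))
        positions.append(np.arange(iv.start, iv.end, dtype=np.int64))
    if not chroms:
        return np.empty(0, dtype=object), np.empty(0, dtype=np.int64)
    return np.concatenate(chroms), np.concatenate(positions)


def _chrom_slices(chroms: np.ndarray) -> dict[str, tuple[int, int]]:
    """Start/stop row ranges per chromosome (rows are grouped by chrom)."""
    slices: dict[str, tuple[int, int]] = {}
    if len(chroms) == 0:
        return slices
    start = 0
    for i in range(1, len(chroms) + 1):
        if i == len(chroms) or chroms[i] != chroms[start]:
            slices[str(chroms[start])] = (start, i)
            start = i
    return slices


@dataclass
class SampleDepthMatrix:
    """Per-base x per-sample integer depths over a fixed target region.

    Rows are exactly the bases of the target set in (chrom, pos) order;
    bases a sample's file did not report are zero.
    """

    chroms: np.ndarray
    positions: np.ndarray
    sample_ids: tuple[str, ...]
    depths: np.ndarray  # shape (n_bases, n_samples), int64

    def __post_init__(self) -> None:
        self._slices = _chrom_slices(self.chroms)

    @property
    def n_bases(self) -> int:
        return len(self.positions)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def _rows_in(self, region: IntervalSet) -> np.ndarray:
        rows: list[np.ndarray] = []
        for iv in region:
            if iv.chrom not in self._slices:
                continue
            lo, hi = self._slices[iv.chrom]
            sub = self.positions[lo:hi]
            a = lo + np.searchsorted(sub, iv.start, side="left")
            b = lo + np.searchsorted(sub, iv.end, side="left")
            if b > a:
                rows.append(np.arange(a, b))
        if not rows:
            return np.empty(0, dtype=np.int64)
        return np.concatenate(rows)

    def restrict(self, region: IntervalSet) -> "SampleDepthMatrix":
        """Rows whose base lies inside ``region`` (region scan order).

        Note: bases of ``region`` outside this matrix's target are not
        re-introduced; restriction never widens the universe.
        """
        rows = self._rows_in(region)
        return SampleDepthMatrix(
            chroms=self.chroms[rows],
            positions=self.positions[rows],
            sample_ids=self.sample_ids,
            depths=self.depths[rows, :],
        )


@dataclass
class DepthTrack:
    """Per-base mean depth across the samples of one capture kit."""

    chroms: np.ndarray
    positions: np.ndarray
    mean_depth: np.ndarray

    def __post_init__(self) -> None:
        self._slices = _chrom_slices(self.chroms)

    @property
    def n_bases(self) -> int:
        return len(self.positions)

    def values_over(self, region: IntervalSet) -> np.ndarray:
        """Mean depths over every base of ``region``, zero-filled.

        Bases of the region absent from the track universe count as
        depth 0 (uncaptured).  Output follows region scan order.
        """
        chunks: list[np.ndarray] = []
        for iv in region:
            vals = np.zeros(iv.end - iv.start, dtype=float)
            if iv.chrom in self._slices:
                lo, hi = self._slices[iv.chrom]
                sub = self.positions[lo:hi]
                a = np.searchsorted(sub, iv.start, side="left")
                b = np.searchsorted(sub, iv.end, side="left")
                if b > a:
                    vals[sub[a:b] - iv.start] = self.mean_depth[lo + a : lo + b]
            chunks.append(vals)
        if not chunks:
            return np.empty(0, dtype=float)
        return np.concatenate(chunks)

    def n_present(self, region: IntervalSet) -> int:
        """Number of region bases actually present in the track universe."""
        count = 0
        for iv in region:
            if iv.chrom not in self._slices:
                continue
            lo, hi = self._slices[iv.chrom]
            sub = self.positions[lo:hi]
            a = np.searchsorted(sub, iv.start, side="left")
            b = np.searchsorted(sub, iv.end, side="left")
            count += int(b - a)
        return count

    def restrict(self, region: IntervalSet) -> "DepthTrack":
        vals = self.values_over(region)
        chroms, positions = target_base_arrays(region)
        return DepthTrack(chroms=chroms, positions=positions, mean_depth=vals)


def build_matrix(
    per_sample_records: Mapping[str, pd.DataFrame],
    targets: IntervalSet,
    sample_ids: Optional[Sequence[str]] = None,
) -> SampleDepthMatrix:
    """Align per-sample depth records onto the target base grid.

    ``per_sample_records`` maps sample id to a parsed depth frame
    (0-based ``pos`` as produced by :func:`read_depth_table`).  Records
    outside the target are ignored; target bases missing from a sample
    are zero-filled; a duplicated (chrom, pos) within one sample is a
    data error.
    """
    ids = tuple(sample_ids) if sample_ids is not None else tuple(per_sample_records)
    if not ids:
        raise DepthDataError("at least one sample is required")
    chroms, positions = target_base_arrays(targets)
    slices = _chrom_slices(chroms)
    depths = np.zeros((len(positions), len(ids)), dtype=np.int64)
    for j, sid in enumerate(ids):
        df = per_sample_records[sid]
        if df.duplicated(subset=["chrom", "pos"]).any():
            dup = df[df.duplicated(subset=["chrom", "pos"])].iloc[0]
            raise DepthDataError(
                f"sample {sid}: duplicate position {dup['chrom']}:{int(dup['pos']) + 1} (1-based)"
            )
        for chrom, grp in df.groupby("chrom", sort=False):
            chrom = str(chrom)
            if chrom not in slices:
                continue
            lo, hi = slices[chrom]
            sub = positions[lo:hi]
            pos = grp["pos"].to_numpy()
            idx = np.searchsorted(sub, pos, side="left")
            in_target = (idx < len(sub)) & (sub[np.minimum(idx, len(sub) - 1)] == pos)
            depths[lo + idx[in_target], j] = grp["depth"].to_numpy()[in_target]
    return SampleDepthMatrix(chroms=chroms, positions=positions, sample_ids=ids, depths=depths)


def mean_track(m: SampleDepthMatrix) -> DepthTrack:
    """Average the matrix across samples: one mean depth per base."""
    if m.n_bases == 0:
        raise DepthDataError("cannot average an empty matrix")
    return DepthTrack(chroms=m.chroms, positions=m.positions, mean_depth=m.depths.mean(axis=1))


def overall_mean_depth(track: DepthTrack, region: IntervalSet) -> float:
    """Mean of the mean-depth track over a region (zero-filled)."""
    vals = track.values_over(region)
    if vals.size == 0:
        raise DepthDataError("overall mean depth is undefined over an empty region")
    return float(vals.mean())


def read_manifest(path: Union[str, Path]) -> pd.DataFrame:
    """Read a sample manifest mapping sample id -> depth file -> kit.

    Accepts a header-ful TSV (columns ``sample``, ``file``, ``kit``) or
    a YAML list of mappings with the same keys.  Relative file paths
    are resolved against the manifest's directory.
    """
    path = Path(path)
    if path.suffix.lower() in {".yaml", ".yml"}:
        with open(path) as fh:
            entries = yaml.safe_load(fh) or []
        df = pd.DataFrame(entries)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"sample", "file", "kit"} - set(df.columns)
    if missing:
        raise DepthDataError(f"{path}: manifest missing columns {sorted(missing)}")
    df = df[["sample", "file", "kit"]].copy()
    df["file"] = [str((path.parent / f).resolve()) for f in df["file"]]
    if df["sample"].duplicated().any():
        raise DepthDataError(f"{path}: duplicate sample ids in manifest")
    return df
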