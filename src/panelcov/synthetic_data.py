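"""Self-contained synthetic inputs for the panel coverage audit.

The generator emulates the study design the audit was built for: a
panel of genes annotated in two nested databases (a broad superset and
a conservative subset holding a controllable fraction of each gene's
bases), several capture kits whose footprints cover increasing
fractions of the subset, and multi-sample per-base depth tables whose
mean decreases with gene GC content and whose cross-sample spread is
small.

Depth model, per captured base b in gene g, sample s of kit K:

    depth ~ NegativeBinomial(mean = exp(alpha_K + beta * GC_g + eps_s),
                             dispersion = phi)

with sample effect eps_s ~ Normal(0, sigma^2) on the log-mean
(multiplicative, so inter-sample spread grows with depth) and
``alpha_K`` anchored so the kit's expected depth at the panel's mean
GC equals its configured mean depth.  ``phi = None`` selects the
Poisson limit.  Uncaptured bases are simply absent from the emitted
files; the depth reader's zero-fill rule recovers them as 0.

Every quantity the audit can recover — realized per-gene subset
fractions, realized GC, per-kit captured footprints, per-gene expected
mean depths — is recorded in a :class:`SimulationTruth` so recovery
tests need no re-derivation.  All randomness flows from one seed
through ``numpy.random.SeedSequence`` spawning, so each stage draws
from an independent, reproducible stream.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .intervals import BedRecord, GenomicInterval, IntervalSet, merge_intervals, write_bed

logger = logging.getLogger(__name__)

BASES = np.array(list("ACGT"))


class ConfigError(ValueError):
    """The simulation configuration is infeasible or inconsistent."""


@dataclass(frozen=True)
class KitSpec:
    """One capture kit: its footprint over the subset database and its
    sequencing arm (number of samples, target mean depth)."""

    name: str
    footprint_fraction: float
    mean_depth: float
    n_samples: int


# Default kits mirror the audited study arms: four kit generations with
# footprints rising from 92% to 99% of the subset database, sequenced at
# observed mean depths 30.5X / 80X / 48X / 63X with 20 / 94 / 93 / 6
# exomes respectively.
DEFAULT_KITS: tuple[KitSpec, ...] = (
    KitSpec("kitV2", 0.92, 30.5, 20),
    KitSpec("kitV3", 0.97, 80.0, 94),
    KitSpec("kitV4", 0.98, 48.0, 93),
    KitSpec("kitV5", 0.99, 63.0, 6),
)


@dataclass
class SimulationConfig:
    """Shape and stochastic parameters of one synthetic study.

    Genome and annotation sizes are desk-scale stand-ins for a real
    50-gene clinical panel (a few hundred coding bases per gene rather
    than a few thousand); the stochastic structure — nested databases,
    kit footprints, GC-dependent depth — is what the audit exercises.
    """

    seed: int = 0
    # genome / annotation shape
    n_chroms: int = 2
    chrom_length: int = 60_000
    n_genes: int = 50
    exons_per_gene: int = 4
    exon_length: tuple[int, int] = (120, 180)
    intron_length: tuple[int, int] = (60, 200)
    gene_gap: int = 300
    background_gc: float = 0.40
    # per-gene parameters; explicit lists override the ranges
    subset_fraction_range: tuple[float, float] = (0.10, 0.97)
    subset_fractions: Optional[Sequence[float]] = None
    gc_range: tuple[float, float] = (0.35, 0.65)
    gc_levels: Optional[Sequence[float]] = None
    # kits and depth model
    kits: tuple[KitSpec, ...] = DEFAULT_KITS
    gc_slope: float = -2.0  # beta on the log-mean; negative = GC penalty
    dispersion: Optional[float] = 30.0  # NB size phi; None = Poisson limit
    sample_sd: float = 0.05  # sigma of the per-sample log-mean effect

    def validate(self) -> None:
        for name in ("n_chroms", "n_genes", "exons_per_gene"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        for rng_name in ("exon_length", "intron_length"):
            lo, hi = getattr(self, rng_name)
            if not (1 <= lo <= hi):
                raise ConfigError(f"{rng_name} must satisfy 1 <= lo <= hi")
        if not 0.0 <= self.background_gc <= 1.0:
            raise ConfigError("background_gc must be in [0, 1]")
        for kit in self.kits:
            if not 0.0 < kit.footprint_fraction <= 1.0:
                raise ConfigError(f"kit {kit.name}: footprint_fraction must be in (0, 1]")
            if kit.mean_depth <= 0 or kit.n_samples < 1:
                raise ConfigError(f"kit {kit.name}: mean_depth > 0 and n_samples >= 1 required")
        if len({k.name for k in self.kits}) != len(self.kits):
            raise ConfigError("kit names must be unique")
        if self.dispersion is not None and self.dispersion <= 0:
            raise ConfigError("dispersion must be positive (or None for Poisson)")
        if self.sample_sd < 0:
            raise ConfigError("sample_sd must be >= 0")
        for vals, lo_hi, name in (
            (self.subset_fractions, (0.0, 1.0), "subset_fractions"),
            (self.gc_levels, (0.0, 1.0), "gc_levels"),
        ):
            if vals is not None:
                if len(vals) != self.n_genes:
                    raise ConfigError(f"{name} must list one value per gene")
                if any(not lo_hi[0] <= v <= lo_hi[1] for v in vals):
                    raise ConfigError(f"{name} values must be in [0, 1]")
        # worst-case gene span must fit the per-chromosome budget
        span = (
            self.exons_per_gene * self.exon_length[1]
            + (self.exons_per_gene - 1) * self.intron_length[1]
            + self.gene_gap
        )
        per_chrom = -(-self.n_genes // self.n_chroms)  # ceil
        if per_chrom * span + self.gene_gap > self.chrom_length:
            raise ConfigError(
                f"chrom_length {self.chrom_length} cannot host {per_chrom} genes "
                f"of worst-case span {span}"
            )


@dataclass(frozen=True)
class GeneLocus:
    gene: str
    chrom: str
    exons: tuple[tuple[int, int], ...]
    gc_target: float


@dataclass
class KitSim:
    """Realized state of one simulated kit."""

    spec: KitSpec
    captured: IntervalSet
    captured_genes: list[str]  # per captured interval, its gene symbol
    sample_ids: tuple[str, ...]
    depth_frames: dict[str, pd.DataFrame]
    alpha: float
    expected_mean_depth: dict[str, float]  # gene -> mu_g


@dataclass
class SimulationTruth:
    """Ground truth the audit should recover from the emitted files."""

    subset_fractions: dict[str, float]
    gc_realized: dict[str, float]
    kit_footprint_fraction: dict[str, float]
    expected_mean_depth: dict[str, dict[str, float]]

    def to_json(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class Simulation:
    cfg: SimulationConfig
    sequences: dict[str, str]
    loci: tuple[GeneLocus, ...]
    superset_records: list[BedRecord]
    subset_records: list[BedRecord]
    kits: dict[str, KitSim]
    truth: SimulationTruth


def _stage_seeds(cfg: SimulationConfig) -> list[np.random.SeedSequence]:
    # fixed spawn order: layout, sequence, subset, then one per kit
    return np.random.SeedSequence(cfg.seed).spawn(3 + len(cfg.kits))


def _gene_name(i: int) -> str:
    return f"GENE{i + 1:03d}"


def _layout(cfg: SimulationConfig, rng: np.random.Generator) -> tuple[GeneLocus, ...]:
    if cfg.gc_levels is not None:
        gc = np.asarray(cfg.gc_levels, dtype=float)
    else:
        gc = rng.uniform(*cfg.gc_range, size=cfg.n_genes)
    loci: list[GeneLocus] = []
    per_chrom = -(-cfg.n_genes // cfg.n_chroms)
    for g in range(cfg.n_genes):
        chrom = f"chr{g // per_chrom + 1}"
        first_on_chrom = g % per_chrom == 0
        cursor = cfg.gene_gap if first_on_chrom else loci[-1].exons[-1][1] + cfg.gene_gap
        exons: list[tuple[int, int]] = []
        for e in range(cfg.exons_per_gene):
            if e > 0:
                cursor += int(rng.integers(cfg.intron_length[0], cfg.intron_length[1] + 1))
            length = int(rng.integers(cfg.exon_length[0], cfg.exon_length[1] + 1))
            exons.append((cursor, cursor + length))
            cursor += length
        if exons[-1][1] > cfg.chrom_length:
            raise ConfigError("gene layout exceeded chromosome length")  # guarded by validate()
        loci.append(GeneLocus(_gene_name(g), chrom, tuple(exons), float(gc[g])))
    return tuple(loci)


def _sequences(cfg: SimulationConfig, loci: Sequence[GeneLocus], rng: np.random.Generator) -> dict[str, str]:
    def draw(n: int, gc: float) -> np.ndarray:
        p_each_gc = gc / 2.0
        p_each_at = (1.0 - gc) / 2.0
        return rng.choice(BASES, size=n, p=[p_each_at, p_each_gc, p_each_gc, p_each_at])

    seqs: dict[str, np.ndarray] = {}
    for c in range(cfg.n_chroms):
        seqs[f"chr{c + 1}"] = draw(cfg.chrom_length, cfg.background_gc)
    for locus in loci:
        for start, end in locus.exons:
            seqs[locus.chrom][start:end] = draw(end - start, locus.gc_target)
    return {chrom: "".join(arr) for chrom, arr in seqs.items()}


def _realized_gc(sequences: dict[str, str], locus: GeneLocus) -> float:
    gc = total = 0
    for start, end in locus.exons:
        seg = sequences[locus.chrom][start:end]
        gc += seg.count("G") + seg.count("C")
        total += len(seg)
    return gc / total


def _subset_records(
    cfg: SimulationConfig, loci: Sequence[GeneLocus], rng: np.random.Generator
) -> tuple[list[BedRecord], dict[str, float]]:
    """Select round(f_g * size) bases per gene, strictly nested.

    Whole exons are kept (in a random order) while they fit the quota;
    the first exon that does not fit contributes a prefix.  This keeps
    subset dropout exon-shaped, like real consensus annotations that
    omit whole alternative exons.
    """
    if cfg.subset_fractions is not None:
        fracs = np.asarray(cfg.subset_fractions, dtype=float)
    else:
        fracs = rng.uniform(*cfg.subset_fraction_range, size=cfg.n_genes)
    records: list[BedRecord] = []
    realized: dict[str, float] = {}
    for locus, f in zip(loci, fracs):
        size = sum(end - start for start, end in locus.exons)
        quota = int(round(f * size))
        if quota == 0:
            logger.warning(
                "gene %s: subset fraction %.3g rounds to 0 bases; emitting 1-base subset", locus.gene, f
            )
            quota = 1
        order = rng.permutation(len(locus.exons))
        kept: list[GenomicInterval] = []
        remaining = quota
        for idx in order:
            if remaining == 0:
                break
            start, end = locus.exons[idx]
            take = min(end - start, remaining)
            kept.append(GenomicInterval(locus.chrom, start, start + take))
            remaining -= take
        kept.sort(key=lambda iv: iv.start)
        records.extend((iv, locus.gene) for iv in kept)
        realized[locus.gene] = quota / size
    return records, realized


def _nb_draw(
    rng: np.random.Generator, mean: np.ndarray, dispersion: Optional[float]
) -> np.ndarray:
    if dispersion is None:
        return rng.poisson(mean)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p)


def _simulate_kit(
    cfg: SimulationConfig,
    kit: KitSpec,
    subset_by_gene: dict[str, IntervalSet],
    gc_realized: dict[str, float],
    rng: np.random.Generator,
) -> KitSim:
    genes = sorted(subset_by_gene)
    flat: list[tuple[GenomicInterval, str]] = [
        (iv, g) for g in genes for iv in subset_by_gene[g]
    ]
    total = sum(len(iv) for iv, _ in flat)
    keep_quota = int(round(kit.footprint_fraction * total))
    drop_quota = total - keep_quota
    # contiguous-biased dropout: walk intervals in random order, trimming
    # whole runs off interval ends so gaps look exon-like
    kept: list[tuple[GenomicInterval, str]] = []
    order = rng.permutation(len(flat))
    for idx in order:
        iv, g = flat[idx]
        length = len(iv)
        if drop_quota >= length:
            drop_quota -= length
            continue
        if drop_quota > 0:
            iv = GenomicInterval(iv.chrom, iv.start, iv.end - drop_quota)
            drop_quota = 0
        kept.append((iv, g))
    kept.sort(key=lambda t: (t[0].chrom, t[0].start))
    captured = merge_intervals([iv for iv, _ in kept])

    gc_center = float(np.mean([gc_realized[g] for g in genes]))
    alpha = float(np.log(kit.mean_depth) - cfg.gc_slope * gc_center)
    mu_gene = {g: float(np.exp(alpha + cfg.gc_slope * gc_realized[g])) for g in genes}

    # per-base arrays aligned to the kept pieces
    chroms = np.concatenate([np.full(len(iv), iv.chrom, dtype=object) for iv, _ in kept])
    positions = np.concatenate([np.arange(iv.start, iv.end, dtype=np.int64) for iv, _ in kept])
    mu_base = np.concatenate([np.full(len(iv), mu_gene[g]) for iv, g in kept])

    sample_ids = tuple(f"{kit.name}_s{i + 1:03d}" for i in range(kit.n_samples))
    eps = cfg.sample_sd * rng.standard_normal(kit.n_samples)
    frames: dict[str, pd.DataFrame] = {}
    for s, sid in enumerate(sample_ids):
        depths = _nb_draw(rng, mu_base * np.exp(eps[s]), cfg.dispersion)
        frames[sid] = pd.DataFrame(
            {"chrom": chroms, "pos": positions, "depth": depths.astype(np.int64)}
        )
    return KitSim(
        spec=kit,
        captured=captured,
        captured_genes=[g for _, g in kept],
        sample_ids=sample_ids,
        depth_frames=frames,
        alpha=alpha,
        expected_mean_depth=mu_gene,
    )


def generate(cfg: SimulationConfig) -> Simulation:
    """Run every stage of the simulation in memory."""
    cfg.validate()
    seeds = _stage_seeds(cfg)
    loci = _layout(cfg, np.random.default_rng(seeds[0]))
    sequences = _sequences(cfg, loci, np.random.default_rng(seeds[1]))
    superset_records: list[BedRecord] = [
        (GenomicInterval(l.chrom, s, e), l.gene) for l in loci for s, e in l.exons
    ]
    subset_records, realized_f = _subset_records(cfg, loci, np.random.default_rng(seeds[2]))
    gc_realized = {l.gene: _realized_gc(sequences, l) for l in loci}
    subset_by_gene: dict[str, IntervalSet] = {}
    for iv, g in subset_records:
        subset_by_gene.setdefault(g, [])
        subset_by_gene[g].append(iv)  # type: ignore[arg-type]
    subset_by_gene = {g: merge_intervals(ivs) for g, ivs in subset_by_gene.items()}

    kits: dict[str, KitSim] = {}
    for i, kit in enumerate(cfg.kits):
        rng = np.random.default_rng(seeds[3 + i])
        kits[kit.name] = _simulate_kit(cfg, kit, subset_by_gene, gc_realized, rng)

    total_subset = sum(s.total_bases for s in subset_by_gene.values())
    truth = SimulationTruth(
        subset_fractions=realized_f,
        gc_realized=gc_realized,
        kit_footprint_fraction={
            k.spec.name: k.captured.total_bases / total_subset for k in kits.values()
        },
        expected_mean_depth={k.spec.name: k.expected_mean_depth for k in kits.values()},
    )
    return Simulation(
        cfg=cfg,
        sequences=sequences,
        loci=loci,
        superset_records=superset_records,
        subset_records=subset_records,
        kits=kits,
        truth=truth,
    )


def generate_genome(cfg: SimulationConfig) -> tuple[dict[str, str], tuple[GeneLocus, ...]]:
    """Genome sequences plus the gene layout they were built around."""
    cfg.validate()
    seeds = _stage_seeds(cfg)
    loci = _layout(cfg, np.random.default_rng(seeds[0]))
    return _sequences(cfg, loci, np.random.default_rng(seeds[1])), loci


def generate_annotations(cfg: SimulationConfig) -> tuple[list[BedRecord], list[BedRecord]]:
    """(superset records, subset records) for the configured panel."""
    sim = generate(dataclasses.replace(cfg, kits=()))
    return sim.superset_records, sim.subset_records


def write_fasta(sequences: dict[str, str], path: Union[str, Path], width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom in sequences:
            fh.write(f">{chrom}\n")
            seq = sequences[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_outputs(sim: Simulation, outdir: Union[str, Path]) -> dict[str, Path]:
    """Emit the simulation as the audit's on-disk input contract.

    Writes genome.fa, superset.bed, subset.bed, per-sample depth TSVs
    under depths/<kit>/, a manifest.tsv and truth.json; returns the
    paths keyed by role.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "genome.fa",
        "superset_bed": outdir / "superset.bed",
        "subset_bed": outdir / "subset.bed",
        "manifest": outdir / "manifest.tsv",
        "truth": outdir / "truth.json",
    }
    write_fasta(sim.sequences, paths["fasta"])
    write_bed(sim.superset_records, paths["superset_bed"])
    write_bed(sim.subset_records, paths["subset_bed"])
    manifest_rows = []
    for kit in sim.kits.values():
        kit_dir = outdir / "depths" / kit.spec.name
        kit_dir.mkdir(parents=True, exist_ok=True)
        for sid in kit.sample_ids:
            rel = Path("depths") / kit.spec.name / f"{sid}.tsv"
            df = kit.depth_frames[sid].copy()
            df["pos"] = df["pos"] + 1  # emit 1-based, pileup convention
            df.to_csv(outdir / rel, sep="\t", header=False, index=False)
            manifest_rows.append({"sample": sid, "file": str(rel), "kit": kit.spec.name})
    pd.DataFrame(manifest_rows, columns=["sample", "file", "kit"]).to_csv(
        paths["manifest"], sep="\t", index=False
    )
    with open(paths["truth"], "w") as fh:
        json.dump(sim.truth.to_json(), fh, indent=1, sort_keys=True)
    return paths


def generate_to(cfg: SimulationConfig, outdir: Union[str, Path]) -> tuple[Simulation, dict[str, Path]]:
    sim = generate(cfg)
    return sim, write_outputs(sim, outdir)
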