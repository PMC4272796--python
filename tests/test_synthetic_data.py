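"""The synthetic study generator: determinism, truth recovery, depth model."""

import json

import numpy as np
import pytest

from panelcov.annotations import build_db, representation_table
from panelcov.depth import build_matrix, mean_track, overall_mean_depth, read_depth_table, read_manifest
from panelcov.intervals import merge_intervals, read_bed
from panelcov.synthetic_data import (
    ConfigError,
    KitSpec,
    SimulationConfig,
    generate,
    generate_genome,
    write_outputs,
)


def _tiny_cfg(**overrides):
    base = dict(
        seed=5,
        n_genes=6,
        n_chroms=2,
        chrom_length=12_000,
        exons_per_gene=3,
        exon_length=(60, 100),
        intron_length=(40, 80),
        gene_gap=150,
        kits=(KitSpec("K", 0.95, 40.0, 3),),
    )
    base.update(overrides)
    return SimulationConfig(**base)


class TestConfigValidation:
    def test_infeasible_layout_rejected(self):
        with pytest.raises(ConfigError, match="chrom_length"):
            _tiny_cfg(chrom_length=500).validate()

    def test_bad_kit_rejected(self):
        with pytest.raises(ConfigError):
            _tiny_cfg(kits=(KitSpec("K", 1.5, 40.0, 3),)).validate()

    def test_per_gene_lists_must_match_n_genes(self):
        with pytest.raises(ConfigError):
            _tiny_cfg(gc_levels=[0.5, 0.5]).validate()


class TestGenome:
    def test_gc_targets_hit_in_expectation(self):
        cfg = _tiny_cfg(gc_levels=[0.35, 0.4, 0.5, 0.5, 0.6, 0.65], exon_length=(900, 1000),
                        chrom_length=40_000)
        sim = generate(cfg)
        for locus in sim.loci:
            realized = sim.truth.gc_realized[locus.gene]
            # ~2800 exon bases per gene: binomial SD ~ 0.01
            assert realized == pytest.approx(locus.gc_target, abs=0.03)

    def test_extreme_gc_target_all_gc(self):
        cfg = _tiny_cfg(gc_levels=[1.0] * 6)
        sim = generate(cfg)
        for locus in sim.loci:
            for start, end in locus.exons:
                seg = sim.sequences[locus.chrom][start:end]
                assert set(seg) <= {"G", "C"}

    def test_same_seed_identical_fasta(self, tmp_path):
        seqs1, _ = generate_genome(_tiny_cfg())
        seqs2, _ = generate_genome(_tiny_cfg())
        assert seqs1 == seqs2


class TestAnnotations:
    def test_full_subset_identical_to_superset(self):
        sim = generate(_tiny_cfg(subset_fractions=[1.0] * 6))
        assert {(iv, g) for iv, g in sim.subset_records} == {
            (iv, g) for iv, g in sim.superset_records
        }

    def test_subset_base_count_matches_fraction(self):
        sim = generate(_tiny_cfg(subset_fractions=[0.55] * 6))
        sup = build_db(sim.superset_records, "sup")
        sub = build_db(sim.subset_records, "sub")
        for gene, model in sup.models.items():
            assert sub.models[gene].size_bases == round(0.55 * model.size_bases)

    def test_representation_table_recovers_fractions_exactly(self, small_sim):
        sup = build_db(small_sim.superset_records, "sup")
        sub = build_db(small_sim.subset_records, "sub")
        table = representation_table(sub, sup).set_index("gene")
        for gene, f in small_sim.truth.subset_fractions.items():
            assert table.loc[gene, "fraction"] == f

    def test_subset_strictly_nested(self, small_sim):
        sup = merge_intervals([iv for iv, _ in small_sim.superset_records])
        sub = merge_intervals([iv for iv, _ in small_sim.subset_records])
        assert sub.subtract(sup).total_bases == 0


class TestDepths:
    def test_poisson_limit_recovers_target_mean(self):
        cfg = _tiny_cfg(
            gc_slope=0.0,
            sample_sd=0.0,
            dispersion=None,
            kits=(KitSpec("K", 1.0, 30.0, 4),),
            subset_fractions=[1.0] * 6,
        )
        sim = generate(cfg)
        kit = sim.kits["K"]
        sub = build_db(sim.subset_records, "sub").pooled_regions()
        track = mean_track(build_matrix(kit.depth_frames, sub, sample_ids=list(kit.sample_ids)))
        n_draws = sub.total_bases * 4
        tol = 4 * np.sqrt(30.0 / n_draws)  # 4 SE of the Monte-Carlo mean
        assert overall_mean_depth(track, sub) == pytest.approx(30.0, abs=tol)

    def test_footprint_fraction_realized(self, small_sim):
        sub_total = merge_intervals([iv for iv, _ in small_sim.subset_records]).total_bases
        for name, kit in small_sim.kits.items():
            expected = round(kit.spec.footprint_fraction * sub_total)
            assert kit.captured.total_bases == expected

    def test_expected_mean_depth_truth_matches_model(self, small_cfg, small_sim):
        for kit in small_sim.kits.values():
            for gene, mu in kit.expected_mean_depth.items():
                gc = small_sim.truth.gc_realized[gene]
                assert mu == pytest.approx(np.exp(kit.alpha + small_cfg.gc_slope * gc))

    def test_gene_mean_depth_tracks_expectation(self, small_sim):
        """Observed per-gene means sit near the recorded truth mus."""
        kit = small_sim.kits["kitB"]
        sub = build_db(small_sim.subset_records, "sub")
        track = mean_track(
            build_matrix(kit.depth_frames, sub.pooled_regions(), sample_ids=list(kit.sample_ids))
        )
        for gene, model in sub.models.items():
            mu = kit.expected_mean_depth[gene]
            captured = model.regions.intersect(kit.captured)
            if captured.total_bases < 50:
                continue
            obs = overall_mean_depth(track, captured)
            assert obs == pytest.approx(mu, rel=0.25)


class TestOutputs:
    def test_same_seed_byte_identical_tree(self, tmp_path, small_cfg):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_outputs(generate(small_cfg), d1)
        write_outputs(generate(small_cfg), d2)
        files1 = sorted(p.relative_to(d1) for p in d1.rglob("*") if p.is_file())
        files2 = sorted(p.relative_to(d2) for p in d2.rglob("*") if p.is_file())
        assert files1 == files2
        for rel in files1:
            assert (d1 / rel).read_bytes() == (d2 / rel).read_bytes()

    def test_emitted_files_feed_the_audit_modules(self, small_dir, small_sim):
        sup = build_db(read_bed(small_dir / "superset.bed"), "sup")
        manifest = read_manifest(small_dir / "manifest.tsv")
        assert set(manifest["kit"]) == set(small_sim.kits)
        frames = {
            r["sample"]: read_depth_table(r["file"])
            for _, r in manifest[manifest["kit"] == "kitA"].iterrows()
        }
        m = build_matrix(frames, sup.pooled_regions(), sample_ids=list(frames))
        kit = small_sim.kits["kitA"]
        for sid in kit.sample_ids:
            j = list(frames).index(sid)
            assert m.depths[:, j].sum() == kit.depth_frames[sid]["depth"].sum()

    def test_truth_json_consistent_with_files(self, small_dir, small_sim):
        truth = json.loads((small_dir / "truth.json").read_text())
        sup = build_db(read_bed(small_dir / "superset.bed"), "sup")
        sub = build_db(read_bed(small_dir / "subset.bed"), "sub")
        for gene, f in truth["subset_fractions"].items():
            assert sub.models[gene].size_bases / sup.models[gene].size_bases == pytest.approx(f)
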