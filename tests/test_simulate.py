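import filecmp
import json

import numpy as np
import pytest

from rddmkit.core import GenomeLayout, Interval, Tiling, te_end_partition
from rddmkit.counts import count_reads
from rddmkit.simulate import (
    ConfigurationError,
    LocusTruth,
    SyntheticConfig,
    build_synthetic_genome,
    export_dataset,
    simulate_ipare_library,
    simulate_wgbs,
)


def _tiny_config(**kw):
    base = dict(
        seed=5,
        n_chromosomes=1,
        chromosome_length=80_000,
        n_feedback_loci=8,
        n_multi_pathway_loci=8,
        n_tes_per_chromosome=25,
        n_genes_per_chromosome=6,
    )
    base.update(kw)
    return SyntheticConfig(**base)


def _uniform_truth(layout, rate, level=None, genotype="col0"):
    """One locus covering the whole (single) chromosome."""
    name, length = layout.chromosomes[0]
    return LocusTruth(
        Interval(name, 0, length),
        "multi_pathway",
        {genotype: rate},
        {genotype: level or {"CG": 0.0, "CHG": 0.0, "CHH": 0.0}},
    )


class TestGenome:
    def test_zero_loci_valid(self):
        cfg = _tiny_config(n_feedback_loci=0, n_multi_pathway_loci=0)
        layout, tes, genes, truths = build_synthetic_genome(cfg)
        assert truths == []
        assert layout.total_length == 80_000
        assert len(tes) == 25

    def test_determinism(self):
        a = build_synthetic_genome(_tiny_config())
        b = build_synthetic_genome(_tiny_config())
        assert a[3] == b[3]  # identical truths
        assert a[1] == b[1]  # identical TEs

    def test_te_end_placement_probability_one(self):
        cfg = _tiny_config(te_end_placement_prob=1.0, n_feedback_loci=20,
                           chromosome_length=200_000, n_tes_per_chromosome=60)
        _, tes, _, truths = build_synthetic_genome(cfg)
        ends = []
        for te in tes:
            part = te_end_partition(te)
            ends.extend(p for p in (part.five_end, part.three_end) if p is not None)
        feedback = [t for t in truths if t.locus_class == "feedback_rddm_only"]
        assert len(feedback) == 20
        for t in feedback:
            assert any(t.interval.overlaps(e) for e in ends)

    def test_loci_do_not_overlap(self):
        _, _, _, truths = build_synthetic_genome(_tiny_config())
        ivs = sorted((t.interval.start, t.interval.end) for t in truths)
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            assert e1 <= s2

    def test_genome_too_small_raises(self):
        with pytest.raises(ConfigurationError):
            build_synthetic_genome(_tiny_config(chromosome_length=5_000))


class TestIpareSimulation:
    def test_zero_rate_zero_background_gives_no_reads(self):
        layout = GenomeLayout((("Chr1", 10_000),))
        truth = _uniform_truth(layout, 0.0)
        reads = simulate_ipare_library(
            [truth], "col0", layout, depth=10**6, phi_sim=0.0, seed=1,
            background_rate=0.0,
        )
        assert reads == []

    def test_poisson_mean_recovered(self):
        layout = GenomeLayout((("Chr1", 100_000),))  # 1000 non-overlapping bins
        truth = _uniform_truth(layout, 50.0)
        reads = simulate_ipare_library(
            [truth], "col0", layout, depth=10**6, phi_sim=0.0, seed=2,
            background_rate=0.0,
        )
        counts, _ = count_reads(Tiling(layout, 100, 100), reads)
        se = np.sqrt(50 / counts.size)
        assert abs(counts.mean() - 50) < 3 * se

    def test_nb_variance_mean_relation(self):
        layout = GenomeLayout((("Chr1", 500_000),))  # 5000 bins
        truth = _uniform_truth(layout, 50.0)
        reads = simulate_ipare_library(
            [truth], "col0", layout, depth=10**6, phi_sim=0.2, seed=3,
            background_rate=0.0,
        )
        counts, _ = count_reads(Tiling(layout, 100, 100), reads)
        ratio = counts.var(ddof=1) / counts.mean()
        # NB moment identity: Var/mean = 1 + phi * mean
        assert ratio == pytest.approx(1 + 0.2 * 50, rel=0.15)

    def test_zero_depth_rejected(self):
        layout = GenomeLayout((("Chr1", 1000),))
        with pytest.raises(ConfigurationError):
            simulate_ipare_library([], "col0", layout, depth=0, phi_sim=0, seed=1)


class TestWgbsSimulation:
    def _levels(self, value):
        return {"CG": value, "CHG": value, "CHH": value}

    def test_level_zero_no_error_gives_zero_methylated(self):
        layout = GenomeLayout((("Chr1", 10_000),))
        truth = _uniform_truth(layout, 1.0, self._levels(0.0))
        sites = simulate_wgbs([truth], "col0", 30, 0.0, seed=4)
        assert all(s.n_meth == 0 for s in sites)

    def test_level_one_no_error_gives_zero_unmethylated(self):
        layout = GenomeLayout((("Chr1", 10_000),))
        truth = _uniform_truth(layout, 1.0, self._levels(1.0))
        sites = simulate_wgbs([truth], "col0", 30, 0.0, seed=4)
        assert all(s.n_unmeth == 0 for s in sites)

    def test_pooled_level_recovers_target(self):
        layout = GenomeLayout((("Chr1", 200_000),))
        truth = _uniform_truth(layout, 1.0, self._levels(0.7))
        sites = simulate_wgbs(
            [truth], "col0", 30, 0.0, seed=5,
            sites_per_locus={"CG": 400, "CHG": 400, "CHH": 400},
        )
        m = sum(s.n_meth for s in sites)
        u = sum(s.n_unmeth for s in sites)
        se = np.sqrt(0.7 * 0.3 / (m + u))
        assert abs(m / (m + u) - 0.7) < 3 * se

    def test_conversion_error_shifts_null_level(self):
        layout = GenomeLayout((("Chr1", 200_000),))
        truth = _uniform_truth(layout, 1.0, self._levels(0.0))
        sites = simulate_wgbs(
            [truth], "col0", 30, 0.02, seed=6,
            sites_per_locus={"CG": 300, "CHG": 300, "CHH": 300},
        )
        m = sum(s.n_meth for s in sites)
        u = sum(s.n_unmeth for s in sites)
        assert m > 0
        assert m / (m + u) == pytest.approx(0.02, rel=0.3)


class TestExportDataset:
    def test_replicate_structure(self, small_dataset):
        with open(f"{small_dataset.outdir}/manifest.json") as fh:
            manifest = json.load(fh)
        genotype_counts = {}
        for sample, genotype in manifest["sample_genotypes"].items():
            genotype_counts[genotype] = genotype_counts.get(genotype, 0) + 1
        assert genotype_counts["drm2"] == 2
        assert genotype_counts["met1"] == 1  # single replicate: GFOLD-path contrast

    def test_same_seed_identical_files(self, tmp_path):
        cfg = _tiny_config()
        a = export_dataset(cfg, tmp_path / "a")
        b = export_dataset(cfg, tmp_path / "b")
        for key in a.read_paths:
            assert filecmp.cmp(a.read_paths[key], b.read_paths[key], shallow=False)
        for key in a.cx_paths:
            assert filecmp.cmp(a.cx_paths[key], b.cx_paths[key], shallow=False)
        assert filecmp.cmp(a.truth_path, b.truth_path, shallow=False)

    def test_zero_depth_config_rejected(self):
        with pytest.raises(ConfigurationError):
            _tiny_config(depth=0)
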