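"""The seeded generator: determinism, conservation, planted effect sizes."""

import filecmp

import numpy as np
import pytest

from medipseq.synthetic_data import (
    SimulationConfig,
    plant_truth,
    simulate_dataset,
    simulate_expression,
    simulate_genome,
    simulate_promoter_sequence,
    simulate_reads,
    write_dataset,
)

SMALL = dict(n_chromosomes=1, chrom_length_bp=2_000_000, n_genes=60, n_cgis=40,
             reads_per_sample=40_000, n_case_samples=2, n_planted_hyper=10,
             n_planted_hypo=10)


class TestDeterminism:
    def test_fixed_seed_gives_byte_identical_outputs(self, tmp_path):
        for sub in ("a", "b"):
            ds = simulate_dataset(SimulationConfig(seed=5, **SMALL))
            write_dataset(ds, tmp_path / sub)
        cmp = filecmp.dircmp(tmp_path / "a", tmp_path / "b")
        assert not cmp.diff_files
        for name in cmp.common_files:
            assert (tmp_path / "a" / name).read_bytes() == \
                (tmp_path / "b" / name).read_bytes()

    def test_adding_case_samples_does_not_perturb_existing_ones(self):
        ds2 = simulate_dataset(SimulationConfig(seed=5, **{**SMALL,
                                                           "n_case_samples": 2}))
        ds3 = simulate_dataset(SimulationConfig(seed=5, **{**SMALL,
                                                           "n_case_samples": 3}))
        np.testing.assert_array_equal(ds2.cases[0].reads["chr1"],
                                      ds3.cases[0].reads["chr1"])


class TestGenome:
    def test_cgi_promoter_fraction_in_study_range(self):
        fracs = []
        for seed in range(3):
            ann, _ = simulate_genome(SimulationConfig(seed=seed))
            frac = sum(1 for p in ann.promoters if p.overlapping_cgis) \
                / len(ann.promoters)
            fracs.append(frac)
        assert 0.5 <= np.mean(fracs) <= 0.7

    def test_no_cgis_means_all_promoters_lack_islands(self):
        ann, _ = simulate_genome(SimulationConfig(seed=1, n_cgis=0, **{
            k: v for k, v in SMALL.items() if k != "n_cgis"}))
        assert all(not p.overlapping_cgis for p in ann.promoters)

    def test_cpg_density_elevated_inside_islands(self):
        ann, cpg = simulate_genome(SimulationConfig(seed=2))
        pos = cpg["chr1"]
        in_cgi = np.zeros(ann.chrom_sizes["chr1"], dtype=bool)
        for c in ann.cgis:
            if c.interval.chrom == "chr1":
                in_cgi[c.interval.start:c.interval.end] = True
        dens_in = in_cgi[pos].mean() * len(pos) / in_cgi.sum()
        dens_out = (~in_cgi)[pos].mean() * len(pos) / (~in_cgi).sum()
        assert dens_in / dens_out > 5

    def test_capacity_exceeded_raises(self):
        with pytest.raises(ValueError, match="capacity"):
            simulate_dataset(SimulationConfig(
                seed=0, n_chromosomes=1, chrom_length_bp=500_000, n_genes=10,
                n_cgis=8, reads_per_sample=1000, n_planted_hyper=200,
                n_planted_hypo=200))

    def test_planted_regions_are_pairwise_disjoint(self, dataset):
        planted = dataset.truth.planted
        for i, a in enumerate(planted):
            for b in planted[i + 1:]:
                assert a.interval.overlap_length(b.interval) == 0


class TestReads:
    def test_read_count_conservation_per_sample(self):
        ds = simulate_dataset(SimulationConfig(seed=7, **SMALL))
        for sample in [ds.control] + ds.cases:
            assert sample.n_reads() == sample.urc
            total = sum(len(sample.reads[c]) for c in sample.reads)
            assert total == sample.urc

    def test_library_sizes_vary_within_configured_cv(self):
        ds = simulate_dataset(SimulationConfig(seed=7, **SMALL))
        for sample in [ds.control] + ds.cases:
            assert 0.8 * 40_000 - 1 <= sample.urc <= 1.2 * 40_000 + 1

    def test_effect_fold_one_gives_identical_rate_fields(self):
        from medipseq.synthetic_data import _weight_segments_chrom

        cfg = SimulationConfig(seed=2, effect_fold=1.0, **SMALL)
        ann, _ = simulate_genome(cfg)
        truth = plant_truth(ann, cfg)
        for chrom in ann.chrom_sizes:
            for _, _, w_ctrl, w_case in _weight_segments_chrom(ann, truth, chrom):
                assert w_ctrl == w_case

    def test_planted_fold_matches_normalized_count_ratio(self):
        # Monte-Carlo oracle: mean case/control normalized in-region count
        # ratio over seeds approximates the configured fold
        ratios = []
        for seed in range(10):
            ds = simulate_dataset(SimulationConfig(seed=seed))
            ctrl, case = ds.control, ds.cases[0]
            for p in ds.truth.regions("hyper"):
                a = ctrl.count_in(p.interval.chrom, p.interval.start,
                                  p.interval.end) / ctrl.urc
                c = case.count_in(p.interval.chrom, p.interval.start,
                                  p.interval.end) / case.urc
                if a > 0:
                    ratios.append(c / a)
        assert np.mean(ratios) == pytest.approx(4.0, rel=0.1)


class TestExpression:
    def test_zero_coupling_leaves_case_and_control_exchangeable(self):
        cfg = SimulationConfig(seed=4, expression_coupling_strength=0.0)
        ann, _ = simulate_genome(cfg)
        truth = plant_truth(ann, cfg)
        df = simulate_expression(ann, truth, cfg)
        affected = set(truth.repressed_genes) | set(truth.overexpressed_genes)
        sub = df[df.gene_id.isin(affected)]
        case_cols = [c for c in df.columns if c.startswith("case")]
        ratio = sub[case_cols].to_numpy().mean() / sub["control_1"].mean()
        assert ratio == pytest.approx(1.0, rel=0.15)

    def test_threefold_coupling_represses_hyper_cgi_genes_threefold(self):
        # pooled over seeds: case mean ~ control mean / 3 for repressed genes
        ctrl_tot, case_tot = 0.0, 0.0
        coupling = float(np.log2(3))
        for seed in range(10):
            cfg = SimulationConfig(seed=seed,
                                   expression_coupling_strength=coupling)
            ann, _ = simulate_genome(cfg)
            truth = plant_truth(ann, cfg)
            df = simulate_expression(ann, truth, cfg)
            sub = df[df.gene_id.isin(truth.repressed_genes)]
            case_cols = [c for c in df.columns if c.startswith("case")]
            ctrl_tot += sub["control_1"].sum()
            case_tot += sub[case_cols].to_numpy().mean(axis=1).sum()
        assert ctrl_tot / case_tot == pytest.approx(3.0, rel=0.1)


class TestConfig:
    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_genes=0)
        with pytest.raises(ValueError):
            SimulationConfig(effect_fold=0.5)
        with pytest.raises(ValueError):
            SimulationConfig(feature_targets=("promoter_cgi", "bogus"))

    def test_yaml_echo_roundtrips(self):
        import yaml

        cfg = SimulationConfig(seed=9)
        loaded = yaml.safe_load(cfg.to_yaml())
        assert loaded["seed"] == 9
        assert loaded["reads_per_sample"] == cfg.reads_per_sample


def test_promoter_sequence_reflects_cpg_map(dataset):
    ann = dataset.annotation
    with_cgi = next(p for p in ann.promoters if p.overlapping_cgis
                    and not p.clipped)
    without = next(p for p in ann.promoters if not p.overlapping_cgis
                   and not p.clipped)
    chrom = with_cgi.interval.chrom
    s1 = simulate_promoter_sequence(with_cgi.interval,
                                    dataset.cpg_positions[chrom], seed=1)
    chrom2 = without.interval.chrom
    s2 = simulate_promoter_sequence(without.interval,
                                    dataset.cpg_positions[chrom2], seed=1)
    assert len(s1) == with_cgi.interval.length
    assert s1.count("CG") > s2.count("CG")
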