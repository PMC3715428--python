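"""Generator contracts: determinism, planted-signal conservation, structure."""

import numpy as np
import pandas as pd
import pytest

from peakstate import introns_of
from peakstate.qpcr import ddct_fold_change
from peakstate.synthetic import (
    DEFAULT_CT_FOLDS,
    SimConfig,
    default_pwm,
    generate_annotation,
    generate_ct_table,
    generate_expression,
    generate_reads,
    generate_sequences,
    simulate_study,
    simulate_to_dir,
    simulate_truth,
)


def small_cfg(**kw):
    base = dict(seed=1, n_genes=20, n_chroms=1, chrom_length=120_000,
                noise_sd=0.0)
    base.update(kw)
    return SimConfig(**base)


class TestAnnotation:
    def test_every_gene_has_an_intron(self):
        genes, _ = generate_annotation(small_cfg(n_genes=10))
        assert len(genes) == 10
        assert all(len(introns_of(g.transcripts[0])) >= 1 for g in genes)

    def test_genes_do_not_overlap(self):
        genes, _ = generate_annotation(small_cfg())
        by_chrom = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append((g.start, g.end))
        for ivs in by_chrom.values():
            ivs.sort()
            assert all(b0 <= a1 for (_, b0), (a1, _) in zip(ivs, ivs[1:]))

    def test_multi_probe_fraction_exact(self):
        _, probe_map = generate_annotation(small_cfg(n_genes=10,
                                                     frac_multi_probe=0.2))
        counts = probe_map.groupby("gene_id").size()
        assert (counts == 2).sum() == 2
        assert len(probe_map) == 12

    def test_density_error(self):
        with pytest.raises(ValueError, match="cannot place"):
            generate_annotation(small_cfg(n_genes=500, chrom_length=50_000))


class TestDeterminism:
    def test_identical_outputs_for_identical_config(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        simulate_to_dir(small_cfg(seed=7), str(d1))
        simulate_to_dir(small_cfg(seed=7), str(d2))
        files = sorted(p.name for p in d1.iterdir())
        assert files == sorted(p.name for p in d2.iterdir())
        for name in files:
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes(), name

    def test_seed_changes_output(self):
        a = simulate_study(small_cfg(seed=1))
        b = simulate_study(small_cfg(seed=2))
        assert not a.expression.equals(b.expression)


class TestExpression:
    def test_zero_noise_shift_is_exact(self):
        cfg = small_cfg(effect_size=2.0)
        genes, probe_map = generate_annotation(cfg)
        truth = simulate_truth(genes, cfg)
        expr = generate_expression(probe_map, cfg, truth)
        up = truth.dereg[truth.dereg["dir_tumour"] == 1]["gene_id"]
        assert len(up) > 0
        for gene in up:
            row = expr[(expr["gene_id"] == gene)
                       & ~expr["gene_id"].isin(truth.conflicting_genes)].iloc[0]
            t = np.mean([row[f"scrib_ab_{r}"] for r in (1, 2, 3)])
            c = np.mean([row[f"control_{r}"] for r in (1, 2, 3)])
            assert t - c == pytest.approx(2.0, abs=1e-12)

    def test_unplanted_gene_has_zero_logfc(self):
        cfg = small_cfg()
        genes, probe_map = generate_annotation(cfg)
        truth = simulate_truth(genes, cfg)
        expr = generate_expression(probe_map, cfg, truth)
        flat = truth.dereg[(truth.dereg["dir_ab"] == 0)
                           & (truth.dereg["dir_tumour"] == 0)]["gene_id"]
        sub = expr[expr["gene_id"].isin(flat)]
        for g in ("ab", "scrib_ab"):
            gcols = [f"{g}_{r}" for r in (1, 2, 3)]
            ccols = [f"control_{r}" for r in (1, 2, 3)]
            diff = sub[gcols].mean(axis=1) - sub[ccols].mean(axis=1)
            assert np.allclose(diff, 0.0)

    def test_conflicting_gene_probes_shift_oppositely(self):
        cfg = small_cfg(n_genes=40, chrom_length=250_000, frac_multi_probe=0.5,
                        frac_conflicting=1.0,
                        de_fractions={"both": 0.5, "ab_only": 0.0,
                                      "tumour_only": 0.0})
        genes, probe_map = generate_annotation(cfg)
        truth = simulate_truth(genes, cfg)
        expr = generate_expression(probe_map, cfg, truth)
        assert truth.conflicting_genes
        for gene in truth.conflicting_genes:
            rows = expr[expr["gene_id"] == gene].set_index("probe_set_id")
            tcols = [f"scrib_ab_{r}" for r in (1, 2, 3)]
            ccols = [f"control_{r}" for r in (1, 2, 3)]
            shifts = (rows[tcols].mean(axis=1) - rows[ccols].mean(axis=1))
            s1, s2 = shifts[f"ps_{gene}_1"], shifts[f"ps_{gene}_2"]
            assert abs(s1) > 1
            assert s1 == pytest.approx(-s2, abs=1e-9)


class TestReads:
    def test_pileup_at_planted_site(self):
        from peakstate.peaks import extend_and_pileup

        cfg = small_cfg(background_read_rate=0.0)
        genes, _ = generate_annotation(cfg)
        truth = simulate_truth(genes, cfg)
        reads = generate_reads(genes, cfg, truth)
        cov = extend_and_pileup(reads["scrib_ab"], cfg.chrom_sizes, 40)
        planted = truth.targets[truth.targets["target_tumour"]]
        assert len(planted) > 0
        for row in planted.itertuples(index=False):
            assert cov[row.chrom][row.site] >= cfg.reads_per_peak / 2

    def test_no_background_no_targets_is_empty(self):
        cfg = small_cfg(background_read_rate=0.0,
                        planted_target_fractions={"both": 0.0, "ab_only": 0.0,
                                                  "tumour_only": 0.0})
        genes, _ = generate_annotation(cfg)
        truth = simulate_truth(genes, cfg)
        reads = generate_reads(genes, cfg, truth)
        assert all(len(df) == 0 for df in reads.values())

    def test_condition_unique_pileups(self):
        from peakstate.peaks import extend_and_pileup

        cfg = small_cfg(background_read_rate=0.0,
                        planted_target_fractions={"both": 0.0, "ab_only": 0.2,
                                                  "tumour_only": 0.2})
        genes, _ = generate_annotation(cfg)
        truth = simulate_truth(genes, cfg)
        reads = generate_reads(genes, cfg, truth)
        cov_ab = extend_and_pileup(reads["ab"], cfg.chrom_sizes, 40)
        cov_t = extend_and_pileup(reads["scrib_ab"], cfg.chrom_sizes, 40)
        only_ab = truth.targets[truth.targets["target_ab"]
                                & ~truth.targets["target_tumour"]]
        only_t = truth.targets[truth.targets["target_tumour"]
                               & ~truth.targets["target_ab"]]
        assert len(only_ab) and len(only_t)
        for row in only_ab.itertuples(index=False):
            assert cov_ab[row.chrom][row.site] > 0 == cov_t[row.chrom][row.site]
        for row in only_t.itertuples(index=False):
            assert cov_t[row.chrom][row.site] > 0 == cov_ab[row.chrom][row.site]

    def test_planted_counts_match_config(self):
        cfg = small_cfg(n_genes=20,
                        de_fractions={"both": 0.2, "ab_only": 0.1,
                                      "tumour_only": 0.1},
                        planted_target_fractions={"both": 0.2, "ab_only": 0.1,
                                                  "tumour_only": 0.1})
        genes, _ = generate_annotation(cfg)
        truth = simulate_truth(genes, cfg)
        assert (truth.dereg["pattern"] == "both").sum() == 4
        assert (truth.dereg["pattern"] == "ab_only").sum() == 2
        assert (truth.dereg["pattern"] == "tumour_only").sum() == 2
        assert (truth.targets["target_ab"] & truth.targets["target_tumour"]).sum() == 4


class TestSequences:
    def test_full_plant_rate_gives_consensus_everywhere(self):
        cfg = small_cfg(motif_plant_rate=1.0, n_sequences=30)
        pwm = default_pwm()
        seqs, planted = generate_sequences(cfg, pwm)
        assert len(planted) == 30
        assert all(pwm.consensus in s for s in seqs.values())

    def test_zero_plant_rate_matches_background_expectation(self):
        # consensus occurrence under a uniform background is Binomial with
        # per-window probability 4^-w; compare the total count to a 5-sigma
        # band around that expectation
        cfg = small_cfg(motif_plant_rate=0.0, n_sequences=300,
                        sequence_length=200)
        pwm = default_pwm()
        seqs, planted = generate_sequences(cfg, pwm)
        assert planted == {}
        w = pwm.width
        count = sum(s.count(pwm.consensus) for s in seqs.values())
        n_windows = sum(len(s) - w + 1 for s in seqs.values())
        expected = n_windows * 0.25**w
        sigma = (n_windows * 0.25**w) ** 0.5
        assert abs(count - expected) <= max(5 * sigma, 3)


class TestCtTable:
    @pytest.mark.parametrize("fold,ddct", [(2.0, -1.0), (1.0, 0.0), (0.25, 2.0)])
    def test_planted_fold_maps_to_ddct(self, fold, ddct):
        ct = generate_ct_table({"t": fold})
        res = ddct_fold_change(ct, "t", "scrib_ab", "control")
        assert res.fold_change == pytest.approx(fold, abs=1e-12)
        assert -np.log2(res.fold_change) == pytest.approx(ddct, abs=1e-12)

    def test_default_validation_folds_recover(self):
        ct = generate_ct_table(DEFAULT_CT_FOLDS)
        for gene, fold in DEFAULT_CT_FOLDS.items():
            res = ddct_fold_change(ct, gene, "scrib_ab", "control")
            assert res.fold_change == pytest.approx(fold, abs=1e-12)


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        SimConfig(frac_multi_probe=1.5).validate()
    with pytest.raises(ValueError):
        SimConfig(n_genes=0).validate()
    with pytest.raises(ValueError):
        SimConfig(de_fractions={"both": 0.9, "ab_only": 0.9}).validate()
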