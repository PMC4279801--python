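"""Generator contracts: determinism, geometry, noise calibration and
ground-truth consistency."""

import numpy as np
import pandas as pd
import pytest

from lactokin.mutation import window_assign
from lactokin.synthetic import (
    CONDITIONS, CapacityError, SyntheticConfig, generate_counts,
    generate_gene_models, generate_mutations, generate_probe_signals,
    generate_profiles, load_archetypes,
)


class TestGeneModels:
    def test_single_gene_within_bounds(self):
        (g,) = generate_gene_models(1, 10_000, seed=0)
        assert 1 <= g.start <= g.end <= 10_000

    def test_same_seed_identical(self):
        a = generate_gene_models(50, 1_000_000, seed=3)
        b = generate_gene_models(50, 1_000_000, seed=3)
        assert a == b

    def test_windows_never_span_two_genes(self):
        """Exhaustive pairwise check: gaps >= 1601 bp keep 800-bp
        windows of neighbouring genes disjoint."""
        genes = generate_gene_models(100, 1_000_000, seed=1)
        spans = sorted((g.start, g.end) for g in genes)
        for (_, e1), (s2, _) in zip(spans, spans[1:]):
            assert s2 - e1 - 1 >= 1601

    def test_infeasible_packing_raises(self):
        with pytest.raises(CapacityError):
            generate_gene_models(100, 50_000, seed=0)


class TestProfiles:
    def test_zero_noise_rows_equal_archetypes(self):
        cfg = SyntheticConfig(n_genes=100, n_regulated=45, noise_sd=0.0)
        mat, truth = generate_profiles(cfg)
        arch = load_archetypes()
        for gid, aid in truth.true_cluster.items():
            np.testing.assert_allclose(mat.loc[gid].to_numpy(),
                                       arch[aid]["profile"])

    def test_late_hyperproducer_archetype_shape(self):
        """One archetype is induced only in the hyper producer and only
        at 24 h: zero throughout the moderate producer, above 1 only at
        the last time point."""
        arch = load_archetypes()[5]["profile"]
        ng14 = arch[:4]
        rutc30 = arch[4:]
        assert np.all(ng14 == 0)
        assert rutc30[-1] > 1
        assert np.all(rutc30[:-1] <= 1)

    def test_noise_sd_calibration(self):
        """Monte-Carlo: sample SD of (row - archetype) matches the
        configured noise level within 3 standard errors."""
        cfg = SyntheticConfig(n_genes=2000, n_regulated=540, seed=11)
        mat, truth = generate_profiles(cfg)
        arch = load_archetypes()
        resid = np.concatenate([
            mat.loc[g].to_numpy() - arch[a]["profile"]
            for g, a in truth.true_cluster.items()])
        se = cfg.noise_sd / np.sqrt(2 * (resid.size - 1))
        assert abs(resid.std(ddof=1) - cfg.noise_sd) < 3 * se

    def test_truth_marks_only_strong_archetype_conditions(self):
        cfg = SyntheticConfig(n_genes=100, n_regulated=45)
        _, truth = generate_profiles(cfg)
        arch = load_archetypes()
        for gid, aid in truth.true_cluster.items():
            for cond, v in zip(CONDITIONS, arch[aid]["profile"]):
                expected = "up" if v > 1 else "down" if v < -1 else "none"
                assert truth.true_regulated[gid][cond] == expected


class TestProbeSignals:
    def test_zero_noise_probe_m_equals_truth(self, clean_config):
        mat, _ = generate_profiles(clean_config)
        probes = generate_probe_signals(mat, clean_config)
        found = probes[probes["status"] == "found"]
        m = np.log2(found["intensity_test"] / found["intensity_ref"])
        sign = np.where(found["dye_orientation"] == "swapped", -1.0, 1.0)
        truth_m = [mat.loc[g, f"{s}_{t}h"] for g, s, t in
                   zip(found["gene_id"], found["strain"], found["time_h"])]
        np.testing.assert_allclose(sign * m, truth_m, atol=1e-9)

    def test_dye_swap_stores_negated_ratio(self, clean_config):
        """The swapped replicate's raw log ratio is the negation of the
        forward replicate's; orientation correction reconciles them."""
        mat, _ = generate_profiles(clean_config)
        probes = generate_probe_signals(mat, clean_config)
        found = probes[probes["status"] == "found"].copy()
        found["M_raw"] = np.log2(found["intensity_test"]
                                 / found["intensity_ref"])
        wide = found.pivot_table(index=["probe_id", "strain", "time_h"],
                                 columns="replicate", values="M_raw")
        np.testing.assert_allclose(wide[1], -wide[2], atol=1e-9)

    def test_not_found_population_present(self, clean_config):
        mat, _ = generate_profiles(clean_config)
        probes = generate_probe_signals(mat, clean_config)
        per_hyb = probes[probes["status"] == "not_found"].groupby(
            ["strain", "time_h", "replicate"]).size()
        assert (per_hyb == clean_config.n_not_found).all()
        assert len(per_hyb) == 16


class TestCounts:
    def test_poisson_limit_variance_over_mean(self):
        """dispersion -> 0: sample variance/mean ~ 1 (Monte-Carlo over
        repeated draws of the same gene set)."""
        cfg = SyntheticConfig(n_genes=200, n_regulated=90, nb_dispersion=0.0,
                              genome_length=1_200_000, seed=2)
        genes = generate_gene_models(cfg.n_genes, cfg.genome_length, cfg.seed)
        _, truth = generate_profiles(cfg)
        reps = []
        for s in range(30):
            c = generate_counts(cfg, truth, genes, sampling_seed=s)
            reps.append(c[c["strain"] == "NG14"]["reads"].to_numpy())
        arr = np.array(reps, dtype=float)
        mu = arr.mean(axis=0)
        ratio = arr.var(axis=0, ddof=1)[mu > 50] / mu[mu > 50]
        assert abs(np.median(ratio) - 1.0) < 0.15

    def test_unshifted_gene_has_unit_expected_ratio(self, small_config):
        genes = generate_gene_models(small_config.n_genes,
                                     small_config.genome_length,
                                     small_config.seed)
        _, truth = generate_profiles(small_config)
        counts = generate_counts(small_config, truth, genes)
        wide = counts.pivot(index="gene_id", columns="strain", values="reads")
        unshifted = [g for g, off in truth.true_basal_logratio.items()
                     if off == 0]
        ratios = (wide.loc[unshifted, "RUTC30"] + 0.5) \
            / (wide.loc[unshifted, "NG14"] + 0.5)
        assert abs(np.log2(ratios).mean()) < 0.1

    def test_shifted_genes_recovered_in_low_noise_limit(self):
        """Designated >= 16-fold genes pass the dual filter in the
        near-Poisson limit at the configured library size."""
        from lactokin.rnaseq import basal_compare
        cfg = SyntheticConfig(nb_dispersion=0.001, seed=4)
        genes = generate_gene_models(cfg.n_genes, cfg.genome_length, cfg.seed)
        _, truth = generate_profiles(cfg)
        counts = generate_counts(cfg, truth, genes)
        basal = basal_compare(counts)
        designated = {g for g, off in truth.true_basal_logratio.items()
                      if off != 0}
        flagged = set(basal.loc[basal["flagged"], "gene_id"])
        assert flagged == designated


class TestMutations:
    def test_zero_near_fraction_assigns_nothing(self, small_config):
        import dataclasses
        cfg = dataclasses.replace(small_config, near_gene_fraction=0.0)
        genes = generate_gene_models(cfg.n_genes, cfg.genome_length, cfg.seed)
        muts, target = generate_mutations(genes, cfg)
        impacts, _ = window_assign(muts, genes, 800)
        assert impacts == []
        assert all(v is None for v in target.values())

    def test_truth_matches_exhaustive_interval_scan(self, small_config):
        genes = generate_gene_models(small_config.n_genes,
                                     small_config.genome_length,
                                     small_config.seed)
        muts, target = generate_mutations(genes, small_config)
        for m in muts:
            hits = {g.gene_id for g in genes
                    if g.start - 800 <= m.position <= g.end + 800}
            expected = {target[m.mutation_id]} if target[m.mutation_id] else set()
            assert hits == expected


def test_full_determinism_under_seed(tmp_path, small_config):
    from lactokin.synthetic import generate_all
    import hashlib
    digests = []
    for d in ("a", "b"):
        out = tmp_path / d
        generate_all(small_config, out)
        digests.append({p.name: hashlib.sha256(p.read_bytes()).hexdigest()
                        for p in sorted(out.iterdir())})
    assert digests[0] == digests[1]
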