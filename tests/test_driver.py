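import dataclasses
import math

import numpy as np
import pytest

from genemod import (
    CamodiConfig,
    ExpressionMatrix,
    PlantedDesign,
    generate,
    run_bootstraps,
    run_camodi,
    score_recovery,
    tune_parameters,
    write_modules,
)


SMALL = PlantedDesign(
    n_regulators=20,
    n_modules=4,
    regulators_per_module=(1, 2),
    genes_per_module=(10, 10),
    n_background_genes=20,
    noise_sd=0.1,
    m_samples=80,
    seed=7,
)

SMALL_CFG = CamodiConfig(
    c1=4, c2=4, k=8, n_min=3, max_iterations=5, base_seed=0
)


class TestConfig:
    def test_defaults_valid(self):
        CamodiConfig()

    @pytest.mark.parametrize(
        "kw",
        [
            {"s1_init": 0},
            {"s1_init": 11},
            {"p_keep": 0},
            {"p_keep": 101},
            {"n_min": 1},
            {"n_min": 50, "n_max": 40},
            {"k_scaling": "sometimes"},
            {"variance_fraction": 0.0},
        ],
    )
    def test_invalid(self, kw):
        with pytest.raises(ValueError):
            CamodiConfig(**kw)

    def test_file_roundtrip(self, tmp_path):
        cfg = CamodiConfig(c1=5, k=12, p_keep=25.0)
        p = tmp_path / "config.yaml"
        cfg.to_file(p)
        assert CamodiConfig.from_file(p) == cfg


class TestRunCamodi:
    def test_noiseless_exact_regulator_copies(self):
        rng = np.random.default_rng(0)
        m = 60
        regs = rng.standard_normal((3, m))
        rows, ids = [], []
        for j in range(3):
            ids.append(f"r{j}")
            rows.append(regs[j])
        for i in range(30):
            ids.append(f"g{i}")
            rows.append(regs[i % 3].copy())
        vals = np.stack(rows)
        vals = (vals - vals.mean(axis=1, keepdims=True)) / vals.std(
            axis=1, ddof=1, keepdims=True
        )
        flags = np.array([True] * 3 + [False] * 30)
        x = ExpressionMatrix(
            tuple(ids), tuple(f"s{k}" for k in range(m)), vals, flags
        )
        cfg = CamodiConfig(
            c1=2, c2=2, k=4, n_min=3, n_max=40, max_iterations=3, base_seed=1
        )
        modules, unassigned = run_camodi(x, cfg)
        assigned = {g for mod in modules for g in mod.genes}
        assert {f"g{i}" for i in range(30)} <= assigned
        for mod in modules:
            if len(mod.genes) >= 3:
                assert mod.cv_r2 > 0.99

    def test_single_iteration_contract(self, planted):
        x, _ = planted
        cfg = dataclasses.replace(SMALL_CFG, max_iterations=1)
        history = []
        modules, unassigned = run_camodi(x, cfg, history=history)
        assert len(history) == 1
        assigned = {g for m in modules for g in m.genes}
        assert assigned | unassigned == set(x.gene_ids)
        assert not assigned & unassigned

    def test_modules_partition_assigned_genes(self, planted):
        x, _ = planted
        modules, unassigned = run_camodi(x, SMALL_CFG)
        seen = set()
        for mod in modules:
            assert not set(mod.genes) & seen
            seen |= set(mod.genes)
        assert not seen & unassigned

    def test_retention_floor_and_sparsity_schedule(self, planted):
        x, _ = planted
        history = []
        run_camodi(x, SMALL_CFG, history=history)
        for t, h in enumerate(history, start=1):
            expect_s = min(
                SMALL_CFG.s1_init + (t - 1) * SMALL_CFG.s1_step, SMALL_CFG.c1
            )
            assert h.sparsity == expect_s
            if h.clusters_formed:
                floor = math.ceil(SMALL_CFG.p_keep / 100 * h.clusters_formed)
                assert h.clusters_retained >= min(floor, h.clusters_formed)

    def test_simple_modules_found_before_complex(self):
        design = PlantedDesign(
            n_regulators=30,
            n_modules=10,
            regulators_per_module=(1, 1),
            genes_per_module=(12, 12),
            n_background_genes=0,
            noise_sd=0.15,
            m_samples=120,
            seed=3,
        )
        complex_design = dataclasses.replace(
            design, regulators_per_module=(4, 4), seed=4
        )
        x1, t1 = generate(design)
        x4, t4 = generate(complex_design)
        # merge: relabel the 4-regulator genes to avoid collisions
        ids = list(x1.gene_ids) + [
            g if g.startswith("R") else "C" + g for g in x4.gene_ids
        ]
        keep = [i for i, g in enumerate(ids) if not (i >= x1.n_genes and g.startswith("R"))]
        vals = np.vstack([x1.values, x4.values])
        flags = np.concatenate([x1.regulator_flags, x4.regulator_flags])
        x = ExpressionMatrix(
            tuple(ids[i] for i in keep),
            x1.sample_ids,
            vals[keep],
            flags[keep],
        )
        cfg = CamodiConfig(c1=5, c2=5, k=20, max_iterations=6, base_seed=0)
        modules, _ = run_camodi(x, cfg)
        iteration_of = {}
        history = []
        modules2, _ = run_camodi(x, cfg, history=history)
        # map each module id to its creation iteration via cumulative counts
        counts = [h.clusters_retained for h in history]
        bounds = np.cumsum(counts)
        for i, mod in enumerate(modules2):
            iteration_of[mod.module_id] = int(np.searchsorted(bounds, i, side="right")) + 1
        simple_iters, complex_iters = [], []
        for mod in modules2:
            plain = sum(1 for g in mod.genes if g.startswith("M"))
            tagged = sum(1 for g in mod.genes if g.startswith("CM"))
            if plain > tagged and plain >= 3:
                simple_iters.append(iteration_of[mod.module_id])
            elif tagged > plain and tagged >= 3:
                complex_iters.append(iteration_of[mod.module_id])
        assert simple_iters and complex_iters
        assert np.mean(simple_iters) <= np.mean(complex_iters)

    def test_no_regulators_error(self, planted):
        x, _ = planted
        bare = dataclasses.replace(
            x, regulator_flags=np.zeros(x.n_genes, dtype=bool)
        )
        with pytest.raises(ValueError):
            run_camodi(bare, SMALL_CFG)


class TestRunBootstraps:
    def test_deterministic_bit_identical_files(self, planted, tmp_path):
        x, _ = planted
        files = []
        for run in ("a", "b"):
            res = run_bootstraps(x, SMALL_CFG, 2)
            paths = []
            for r in res:
                p = tmp_path / f"{run}_modules_{r.split.index}.tsv"
                s = tmp_path / f"{run}_summary_{r.split.index}.tsv"
                write_modules(r.modules, p, summary_path=s)
                paths.append((p.read_bytes(), s.read_bytes()))
            files.append(paths)
        assert files[0] == files[1]

    def test_test_scores_use_heldout_samples(self, planted):
        x, _ = planted
        (res,) = run_bootstraps(x, SMALL_CFG, 1)
        from genemod import normalize_genes, score_module

        xn = normalize_genes(x)
        for mod in res.modules:
            r2, adj = score_module(mod, xn, res.split.test_sample_ids)
            assert mod.r2_test == pytest.approx(r2, abs=1e-10)
            assert mod.adj_r2_test == pytest.approx(adj, abs=1e-10)

    def test_smoke_scale_each_bootstrap_yields_modules(self):
        design = PlantedDesign(
            n_regulators=25,
            n_modules=6,
            regulators_per_module=(1, 3),
            genes_per_module=(15, 15),
            n_background_genes=30,
            noise_sd=0.2,
            m_samples=100,
            seed=11,
        )
        x, truth = generate(design)
        cfg = CamodiConfig(c1=5, c2=5, k=10, max_iterations=5, base_seed=2)
        results = run_bootstraps(x, cfg, 3)
        assert len(results) == 3
        for r in results:
            assert len(r.modules) >= 1
            rec = score_recovery(list(r.modules), truth)
            assert rec.mean_gene_jaccard > 0.5


class TestTuneParameters:
    def test_empty_grid_returns_start(self, planted, caplog):
        x, _ = planted
        assert tune_parameters(x, SMALL_CFG, {}, n_bootstraps=1) == SMALL_CFG
        assert any("empty" in r.message for r in caplog.records)

    def test_already_optimal_fixed_point(self, planted):
        x, _ = planted
        grid = {"k": [SMALL_CFG.k]}
        assert tune_parameters(x, SMALL_CFG, grid, n_bootstraps=1) == SMALL_CFG

    def test_adopts_strictly_better_threshold(self):
        design = PlantedDesign(
            n_regulators=15,
            n_modules=4,
            regulators_per_module=(1, 2),
            genes_per_module=(12, 12),
            n_background_genes=10,
            noise_sd=0.15,
            m_samples=80,
            seed=5,
        )
        x, _ = generate(design)
        # r_thresh=0 also retains noise clusters, dragging mean adj R^2 down
        start = CamodiConfig(
            c1=4,
            c2=4,
            k=8,
            k_scaling="fixed",
            n_min=3,
            r_thresh=0.0,
            max_iterations=3,
            base_seed=0,
        )
        tuned = tune_parameters(x, start, {"r_thresh": [0.0, 0.6]}, n_bootstraps=2)
        assert tuned.r_thresh == 0.6
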