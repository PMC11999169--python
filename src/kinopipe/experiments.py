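"""Self-validation experiments for the pipeline's statistical machinery.

Each function runs a complete, seeded experiment against an independent
oracle (closed form, exhaustive enumeration, or planted ground truth) and
returns plain numbers. They back both the acceptance checks and the
narrative analysis scripts.
"""

from __future__ import annotations

import math
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import differential, enrich, harmonize, krsa, pcsf, pipeline, qc, simulate, stats


def published_group_ttest() -> dict:
    """Pooled t-test from the printed NF-kB activity summaries
    (sedentary 12.96 +/- 2.30, n=6 vs acute exercise 5.33 +/- 1.54, n=9)."""
    t, df, p = stats.pooled_t_from_summaries(
        stats.GroupSummary("sedentary_control", 12.96, 2.30, 6),
        stats.GroupSummary("acute_exercise", 5.33, 1.54, 9))
    return {"t": t, "df": df, "p": p}


def krsa_convergence(n_iter: int = 10_000, seed: int = 0) -> dict:
    """Permutation moments vs the hypergeometric closed form on the
    worked 20-peptide instance (family covers 10; 6 hits, all mapped)."""
    universe = {f"pep{i:02d}" for i in range(20)}
    family = frozenset(sorted(universe)[:10])
    hits = set(sorted(family)[:6])
    kmap = krsa.KinaseSubstrateMap({"FAM": family})
    row = krsa.krsa(hits, universe, kmap, n_iter=n_iter, seed=seed).loc["FAM"]
    n, K, N = len(hits), len(family), len(universe)
    mean = n * K / N
    sd = math.sqrt(n * (K / N) * (1 - K / N) * (N - n) / (N - 1))
    return {
        "perm_mean": float(row["perm_mean"]), "perm_sd": float(row["perm_sd"]),
        "analytic_mean": mean, "analytic_sd": sd,
        "mean_abs_err": abs(float(row["perm_mean"]) - mean),
        "sd_abs_err": abs(float(row["perm_sd"]) - sd),
        "z": float(row["z_score"]), "n_iter": n_iter,
    }


def _random_pcsf_instance(seed: int, n_nodes: int = 10, p_edge: float = 0.35):
    rng = np.random.default_rng(seed)
    nodes = [f"N{i}" for i in range(n_nodes)]
    rows = []
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p_edge:
                rows.append((nodes[i], nodes[j], float(rng.uniform(0.05, 1.0))))
    if not rows:
        rows = [(nodes[0], nodes[1], 0.5)]
    g = pcsf.InteractionGraph.from_frame(
        pd.DataFrame(rows, columns=["protein_a", "protein_b", "confidence"]))
    prizes = {v: float(rng.uniform(0, 2.0)) * (rng.random() < 0.6)
              for v in g.nodes}
    return g, prizes


def pcsf_oracle(n_instances: int = 50, seed: int = 0, n_nodes: int = 10) -> dict:
    """Heuristic vs exhaustive optimum on random small instances.

    Returns the equality count and whether the heuristic ever produced an
    objective below the exact optimum (it must not: the enumeration is a
    global minimum over all forests).
    """
    eq = tot = 0
    never_better = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n_instances):
            g, prizes = _random_pcsf_instance(seed * 100_003 + i, n_nodes)
            if all(p <= 0 for p in prizes.values()):
                continue
            tot += 1
            ex = pcsf.solve_pcsf(g, prizes, mode="exact")
            he = pcsf.solve_pcsf(g, prizes, mode="heuristic")
            if he.objective < ex.objective - 1e-9:
                never_better = False
            if abs(he.objective - ex.objective) <= 1e-9:
                eq += 1
    return {"n_instances": tot, "n_equal": eq,
            "equality_rate": eq / tot if tot else float("nan"),
            "never_better_than_exact": never_better}


def planted_recovery(n_runs: int = 50, seed: int = 0, effect: float = 1.0,
                     family: str = "IKK", krsa_n_iter: int = 2000) -> dict:
    """Full-stack recovery of one up-shifted kinase family on the 144-
    peptide chip: does it top the resampling |z|, score ternary 'up', and
    land in quartile 4 of the harmonized mean percentile?"""
    layout = simulate.ArrayLayout.stk()
    kmap = simulate.make_kinase_map(layout, seed=0)
    top_z = direction_up = quartile4 = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n_runs):
            run_seed = (seed * 7919 + i) % (2 ** 31)
            cfg = simulate.SimulationConfig(
                layout=layout, kinase_map=kmap,
                planted_effects={family: effect}, seed=run_seed)
            reads, _ = simulate.simulate_arrays(cfg)
            fits = qc.apply_qc(qc.fit_kinetics(reads),
                               min_signal=2.0 * qc.estimate_noise_floor(reads))
            matrix = qc.build_signal_matrix(fits)
            fc = differential.log2_fold_change(matrix, "sedentary", "exercise")
            kr = krsa.krsa(set(fc.index[fc["hit15"]]), set(fc.index), kmap,
                           n_iter=krsa_n_iter, seed=run_seed)
            if kr["z_score"].abs().idxmax() == family:
                top_z += 1
            tern = differential.ternary_score(fc, kmap)
            if tern.loc[family, "direction"] == "up":
                direction_up += 1
            rankers = [harmonize.RankerOutput("krsa",
                                              kr["z_score"].fillna(0.0).to_dict())]
            for j, name in enumerate(("uka_like", "kea_like")):
                ext = simulate.make_external_ranker(name, kr["z_score"],
                                                    seed=run_seed + j + 1)
                rankers.append(harmonize.RankerOutput(
                    name, dict(zip(ext["kinase"], ext["score"]))))
            htab = harmonize.harmonize(rankers)
            mp = htab.xs(family, level="kinase")["mean_percentile"].iloc[0]
            if mp > 0.75:
                quartile4 += 1
    return {"n_runs": n_runs,
            "top_z_rate": top_z / n_runs,
            "direction_up_rate": direction_up / n_runs,
            "quartile4_rate": quartile4 / n_runs}


def qc_recovery(seed: int = 0, dead_frac: float = 0.1,
                saturating_frac: float = 0.1) -> dict:
    """Sensitivity/specificity of QC against planted failures, noise-free."""
    layout = simulate.ArrayLayout.stk()
    kmap = simulate.make_kinase_map(layout, seed=0)
    cfg = simulate.SimulationConfig(
        layout=layout, kinase_map=kmap, noise_sd=0.0,
        dead_peptide_frac=dead_frac, saturating_peptide_frac=saturating_frac,
        seed=seed)
    reads, truth = simulate.simulate_arrays(cfg)
    fits = qc.apply_qc(qc.fit_kinetics(reads),
                       min_signal=2.0 * qc.estimate_noise_floor(reads))
    passing = qc.peptides_passing_all(fits)
    failures = truth.peptides_of_class("dead") | truth.peptides_of_class("saturating")
    normal = truth.peptides_of_class("normal")
    removed = set(layout.peptide_ids) - passing
    sens = len(failures & removed) / len(failures) if failures else 1.0
    spec = len(normal & passing) / len(normal) if normal else 1.0
    return {"sensitivity": sens, "specificity": spec,
            "n_failures": len(failures), "n_normal": len(normal)}


def ora_enumeration_check(n_instances: int = 10, seed: int = 0) -> dict:
    """Hypergeometric p vs exhaustive pmf enumeration on universes <= 15,
    plus Benjamini-Hochberg step-up monotonicity."""
    rng = np.random.default_rng(seed)
    max_err = 0.0
    bh_monotone = True
    for _ in range(n_instances):
        n_u = int(rng.integers(6, 16))
        genes = [f"g{i}" for i in range(n_u)]
        library = {f"T{t}": frozenset(rng.choice(genes, int(rng.integers(1, n_u)),
                                                 replace=False))
                   for t in range(5)}
        query = set(rng.choice(genes, int(rng.integers(1, n_u)), replace=False))
        res = enrich.ora(query, library, set(genes), score_mode="neglogp")
        for _, row in res.iterrows():
            k, m = int(row["overlap"]), int(row["set_size"])
            total = sum(math.comb(m, j) * math.comb(n_u - m, len(query) - j)
                        for j in range(k, min(m, len(query)) + 1))
            expect = total / math.comb(n_u, len(query))
            max_err = max(max_err, abs(float(row["p_value"]) - expect))
        ordered = res.sort_values("p_value")["fdr"].to_numpy()
        if (np.diff(ordered) < -1e-12).any():
            bh_monotone = False
    return {"max_abs_p_error": max_err, "bh_monotone": bh_monotone,
            "n_instances": n_instances}


def pipeline_determinism(workdir: str | Path, seed: int = 1) -> dict:
    """Run the bundled demo twice under one config; compare every output."""
    workdir = Path(workdir)
    runs = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for tag in ("run1", "run2"):
            cfg = pipeline.default_demo_config(str(workdir / tag), seed=seed)
            runs.append(pipeline.run_pipeline(cfg))
    names = sorted(runs[0]["outputs"])
    identical = (runs[0]["outputs"] == runs[1]["outputs"]) and all(
        (workdir / "run1" / n).read_bytes() == (workdir / "run2" / n).read_bytes()
        for n in names)
    return {"identical": identical, "n_outputs": len(names)}
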