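"""Configuration-driven orchestration of the full kinome workflow.

One call runs: synthetic data (or provided read tables) -> kinetic QC ->
per-chip log2 fold changes -> resampling kinase enrichment -> multi-ranker
percentile harmonization -> prize-collecting Steiner forest -> gene-set
over-representation -> pathway meta-clustering -> validation statistics.
Every intermediate table is written as TSV (JSON for nested records) under
the configured output directory, and a manifest records the package
version, all parameters, seeds and output digests. Re-running the same
configuration reproduces every output byte-identically; no timestamps are
embedded.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, differential, enrich, harmonize, krsa, pcsf, qc, simulate, stats
from .errors import ConfigurationError

_CHIP_TYPES = ("STK", "PTK")


@dataclass
class PipelineConfig:
    """All knobs of the end-to-end run; defaults give the bundled demo."""

    output_dir: str = "results/demo"
    seed: int = 1
    group_control: str = "sedentary"
    group_treatment: str = "exercise"
    samples_per_group: int = 2
    n_chips: int = 3
    # synthetic generation (ignored for a chip type when a reads path is given)
    planted_effects: dict = field(default_factory=lambda: {"STK": {"IKK": 1.0}, "PTK": {}})
    dead_peptide_frac: float = 0.1
    saturating_peptide_frac: float = 0.1
    noise_sd: float = 2.0
    # thresholds
    min_r2: float = 0.90
    min_signal: float | None = None  # None -> 2x estimated noise floor
    logfc_flag: float = 0.2
    hit_fraction: float = 0.15
    alpha: float = 0.05
    # stage parameters
    krsa_n_iter: int = 2000
    pcsf_beta: float = 1.0
    pcsf_omega: float = 1.0
    pcsf_cost_mode: str = "one_minus"
    pcsf_mode: str = "heuristic"
    cluster_k: int | None = None
    # optional external inputs (paths); None -> synthesized deterministically
    reads_paths: dict = field(default_factory=dict)          # chip_type -> TSV
    kinase_map_paths: dict = field(default_factory=dict)     # chip_type -> GMT
    ppi_edges_path: str | None = None
    gene_sets_path: str | None = None
    embeddings_path: str | None = None
    external_ranker_paths: list = field(default_factory=list)
    # printed group summaries for the validation t-test stage
    stats_summaries: list = field(default_factory=lambda: [
        {"label": "sedentary_control", "mean": 12.96, "se": 2.30, "n": 6},
        {"label": "acute_exercise", "mean": 5.33, "se": 1.54, "n": 9},
    ])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text())
        except yaml.YAMLError as exc:
            raise ConfigurationError(f"{path}: cannot parse YAML: {exc}") from exc
        if not isinstance(raw, dict):
            raise ConfigurationError(f"{path}: config must be a mapping")
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"{path}: unknown keys {sorted(unknown)}")
        return cls(**raw)

    def violations(self) -> list[str]:
        v: list[str] = []
        if not 0 <= self.min_r2 <= 1:
            v.append(f"min_r2 {self.min_r2} outside [0, 1]")
        if self.min_signal is not None and self.min_signal < 0:
            v.append("min_signal must be >= 0")
        if not 0 < self.alpha < 1:
            v.append(f"alpha {self.alpha} outside (0, 1)")
        if self.logfc_flag <= 0:
            v.append("logfc_flag must be > 0")
        if not 0 < self.hit_fraction < 1:
            v.append(f"hit_fraction {self.hit_fraction} outside (0, 1)")
        if self.krsa_n_iter < 1:
            v.append("krsa_n_iter must be >= 1")
        if self.pcsf_beta <= 0 or self.pcsf_omega <= 0:
            v.append("pcsf beta and omega must be > 0")
        if not 0 <= self.dead_peptide_frac < 1:
            v.append("dead_peptide_frac outside [0, 1)")
        if not 0 <= self.saturating_peptide_frac < 1:
            v.append("saturating_peptide_frac outside [0, 1)")
        if self.dead_peptide_frac + self.saturating_peptide_frac >= 1:
            v.append("dead + saturating fractions must be < 1")
        if self.samples_per_group < 1 or self.n_chips < 1:
            v.append("samples_per_group and n_chips must be >= 1")
        for name, path in [*self.reads_paths.items(), *self.kinase_map_paths.items(),
                           ("ppi_edges", self.ppi_edges_path),
                           ("gene_sets", self.gene_sets_path),
                           ("embeddings", self.embeddings_path),
                           *[(f"ranker[{i}]", p) for i, p in
                             enumerate(self.external_ranker_paths)]]:
            if path is not None and not Path(path).exists():
                v.append(f"input path for {name} does not exist: {path}")
        return v


def validate_config(path: str | Path) -> list[str]:
    """Parse a YAML config and return the list of violations (empty = valid)."""
    return PipelineConfig.from_yaml(path).violations()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full workflow; returns the manifest (also written to disk)."""
    problems = config.violations()
    if problems:
        raise ConfigurationError("; ".join(problems))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    groups = ((config.group_control, config.samples_per_group),
              (config.group_treatment, config.samples_per_group))

    harmonized_by_chip: dict[str, pd.DataFrame] = {}
    ternary_by_chip: dict[str, pd.DataFrame] = {}
    stage = "setup"
    try:
        for chip_offset, chip_type in enumerate(_CHIP_TYPES):
            layout = simulate.ArrayLayout.stk() if chip_type == "STK" else simulate.ArrayLayout.ptk()
            stage = f"{chip_type}:inputs"
            if chip_type in config.kinase_map_paths:
                kmap = krsa.read_gmt(config.kinase_map_paths[chip_type])
            else:
                kmap = simulate.make_kinase_map(layout, seed=config.seed)
            if chip_type in config.reads_paths:
                reads = simulate.read_reads(config.reads_paths[chip_type])
                truth = None
            else:
                sim = simulate.SimulationConfig(
                    layout=layout, kinase_map=kmap, groups=groups,
                    n_chips=config.n_chips,
                    planted_effects=dict(config.planted_effects.get(chip_type, {})),
                    dead_peptide_frac=config.dead_peptide_frac,
                    saturating_peptide_frac=config.saturating_peptide_frac,
                    noise_sd=config.noise_sd, seed=config.seed + chip_offset)
                reads, truth = simulate.simulate_arrays(sim)
                truth.to_json(out / f"{chip_type.lower()}_ground_truth.json")
            simulate.write_reads(reads, out / f"{chip_type.lower()}_reads.tsv")
            krsa.write_gmt(kmap, out / f"{chip_type.lower()}_kinase_map.gmt")

            stage = f"{chip_type}:qc"
            fits = qc.fit_kinetics(reads)
            min_signal = (config.min_signal if config.min_signal is not None
                          else 2.0 * qc.estimate_noise_floor(reads))
            fits = qc.apply_qc(fits, min_signal=min_signal, min_r2=config.min_r2)
            _write_tsv(fits, out / f"{chip_type.lower()}_fits.tsv", index=False)
            matrix = qc.build_signal_matrix(fits, chip_type=chip_type,
                                            qc_thresholds={"min_signal": min_signal,
                                                           "min_r2": config.min_r2})
            _write_tsv(matrix.values, out / f"{chip_type.lower()}_signal_matrix.tsv")

            stage = f"{chip_type}:differential"
            fc = differential.log2_fold_change(
                matrix, config.group_control, config.group_treatment,
                flag_threshold=config.logfc_flag, hit_fraction=config.hit_fraction)
            _write_tsv(fc, out / f"{chip_type.lower()}_log2fc.tsv")
            ternary = differential.ternary_score(fc, kmap)
            ternary_by_chip[chip_type] = ternary
            _write_tsv(ternary, out / f"{chip_type.lower()}_ternary.tsv")
            if len(fc) >= 2 and matrix.values.shape[1] >= 2:
                hm = differential.heatmap_matrix(matrix)
                _write_tsv(hm.ordered(), out / f"{chip_type.lower()}_heatmap.tsv")

            stage = f"{chip_type}:krsa"
            universe = set(fc.index)
            hits = set(fc.index[fc["hit15"]])
            kr = krsa.krsa(hits, universe, kmap, n_iter=config.krsa_n_iter,
                           seed=config.seed + chip_offset)
            _write_tsv(kr, out / f"{chip_type.lower()}_krsa.tsv")

            stage = f"{chip_type}:harmonize"
            rankers = [harmonize.RankerOutput(
                "krsa", kr["z_score"].fillna(0.0).to_dict())]
            if config.external_ranker_paths:
                for p in config.external_ranker_paths:
                    rankers.append(harmonize.read_ranker_table(p))
            else:
                for j, name in enumerate(("uka_like", "kea_like")):
                    ext = simulate.make_external_ranker(
                        name, kr["z_score"], agreement=0.8,
                        seed=config.seed + 10 * (chip_offset + 1) + j)
                    rankers.append(harmonize.RankerOutput(
                        name, dict(zip(ext["kinase"], ext["score"]))))
            htab = harmonize.harmonize(rankers)
            harmonized_by_chip[chip_type] = htab
            _write_tsv(htab, out / f"{chip_type.lower()}_harmonized.tsv")
            _write_tsv(harmonize.bubble_table(htab),
                       out / f"{chip_type.lower()}_bubble.tsv", index=False)

        # ---- integration across chip chemistries -------------------------
        stage = "network:prizes"
        merged = pd.concat([h.reset_index() for h in harmonized_by_chip.values()])
        # on collision the stronger (max mean percentile) evidence wins
        merged = (merged.sort_values("mean_percentile", ascending=False, kind="stable")
                  .drop_duplicates("kinase").set_index("kinase"))
        prize_rank = merged["mean_percentile"].rank(method="average") / len(merged)
        prizes = {str(k): float(v) for k, v in prize_rank.items()}
        pd.DataFrame({"prize": pd.Series(prizes).sort_index()}).to_csv(
            out / "node_prizes.tsv", sep="\t")

        stage = "network:pcsf"
        if config.ppi_edges_path:
            graph = pcsf.InteractionGraph.from_tsv(config.ppi_edges_path)
        else:
            edges = simulate.make_ppi_edges(sorted(prizes), seed=config.seed)
            edges.to_csv(out / "ppi_edges.tsv", sep="\t", index=False)
            graph = pcsf.InteractionGraph.from_frame(edges)
        forest = pcsf.solve_pcsf(graph, prizes, beta=config.pcsf_beta,
                                 omega=config.pcsf_omega,
                                 cost_mode=config.pcsf_cost_mode,
                                 mode=config.pcsf_mode, seed=config.seed)
        _write_tsv(forest.edge_frame(), out / "forest_edges.tsv", index=False)
        (out / "forest_nodes.json").write_text(json.dumps({
            "nodes": forest.nodes, "terminals": forest.terminals,
            "hidden_nodes": forest.hidden_nodes, "n_trees": forest.n_trees,
            "objective": round(forest.objective, 10), "params": forest.params,
        }, indent=1, sort_keys=True) + "\n")

        stage = "enrichment:ora"
        universe_nodes = set(graph.nodes)
        query_nodes = set(forest.nodes) or universe_nodes
        if config.gene_sets_path:
            library = krsa.read_gmt(config.gene_sets_path).sets
        else:
            top_prized = sorted(k for k, v in prizes.items() if v > 0.75)
            library = simulate.make_gene_sets(sorted(universe_nodes),
                                              seed=config.seed + 99,
                                              focus=top_prized)
        ora_res = enrich.ora(query_nodes, library, universe_nodes,
                             alpha=config.alpha, seed=config.seed)
        _write_tsv(ora_res, out / "ora.tsv")

        stage = "enrichment:clustering"
        sig_terms = list(ora_res.index[ora_res["significant"]])
        cluster_rows = []
        if sig_terms:
            if config.embeddings_path:
                emb = pd.read_csv(config.embeddings_path, sep="\t", index_col=0)
            else:
                emb = simulate.make_term_embeddings(sorted(library),
                                                    seed=config.seed + 7)
            clusters = enrich.cluster_terms(sig_terms, emb, k=config.cluster_k)
            scores = ora_res.loc[sig_terms, ["combined_score"]].rename(
                columns={"combined_score": "log_combined_score"})
            scores["log_combined_score"] = np.log1p(
                np.clip(scores["log_combined_score"], 0.0, None))
            heat = enrich.cluster_heatmap_table(clusters, scores)
            _write_tsv(heat, out / "pathway_cluster_heatmap.tsv")
            for cl in clusters:
                for m in cl.members:
                    x, y = cl.coordinates[m]
                    cluster_rows.append((cl.cluster_id, m, cl.representative_term,
                                         round(cl.member_similarity[m], 6),
                                         round(x, 6), round(y, 6)))
        pd.DataFrame(cluster_rows, columns=["cluster_id", "term_id",
                                            "representative_term",
                                            "cosine_to_centroid", "x", "y"]
                     ).to_csv(out / "pathway_clusters.tsv", sep="\t", index=False)

        stage = "stats"
        stats_out: dict = {}
        if len(config.stats_summaries) == 2:
            a, b = (stats.GroupSummary(**s) for s in config.stats_summaries)
            t, df_, p = stats.pooled_t_from_summaries(a, b)
            stats_out["pooled_t"] = {"t": round(t, 6), "df": df_, "p": round(p, 6),
                                     "groups": [a.label, b.label]}
        (out / "validation_stats.json").write_text(
            json.dumps(stats_out, indent=1, sort_keys=True) + "\n")
    except Exception as exc:
        (out / "FAILED").write_text(f"stage {stage}: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage}: {exc}") from exc

    stage = "manifest"
    outputs = sorted(p for p in out.iterdir()
                     if p.is_file() and p.name != "manifest.json")
    manifest = {
        "package_version": __version__,
        "config": asdict(config),
        "outputs": {p.name: _digest(p) for p in outputs},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest


def default_demo_config(output_dir: str = "results/demo", seed: int = 1) -> PipelineConfig:
    """The bundled demo: synthetic STK+PTK arrays with a planted IKK-family
    up-shift, default thresholds, heuristic Steiner forest."""
    return PipelineConfig(output_dir=output_dir, seed=seed)
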