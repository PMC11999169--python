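"""Synthetic kinome-array data with known ground truth.

Emulates multi-exposure kinetic capture on peptide microarrays of the
PamChip type: a serine/threonine (STK) chip carries 144 reporter peptides
in a 12x12 grid, a tyrosine (PTK) chip carries 196 peptides in a 14x14
grid, and each spot's fluorescence is read at a ladder of exposure times
(10, 20, 50, 100, 200 ms by default). A well-behaved spot grows linearly
in exposure time; the generator plants known violations (dead spots,
early-saturating spots) and known kinase-family activity shifts so that
every downstream stage can be scored against ground truth.

Signal model, per (sample, peptide, exposure):

    intensity = slope * exposure_ms + intercept + N(0, noise_sd)

clipped at zero. A peptide mapped to a planted family has its slope in the
treatment group multiplied by 2**effect, so the planted effect equals the
expected log2 fold change of the slope-derived signal. Dead peptides emit
|N(0, noise_sd/10)|; saturating peptides follow A*(1 - exp(-t/tau)) with a
small time constant, a concave curve that violates the linearity QC.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError
from .krsa import KinaseSubstrateMap

READ_COLUMNS = ["chip_id", "sample_id", "group", "peptide_id", "exposure_ms", "intensity"]

DEFAULT_EXPOSURES_MS = (10.0, 20.0, 50.0, 100.0, 200.0)

# Kinase families used by the bundled synthetic maps; names follow the
# family vocabulary customary for each chip chemistry.
STK_FAMILIES = (
    "AKT", "CAMK2", "CK2", "ERK", "GSK3", "IKK",
    "JNK", "P38", "PKA", "PKC", "PKD", "RIPK",
)
PTK_FAMILIES = (
    "ABL", "CSK", "EGFR", "EPH", "FAK", "INSR", "JAK",
    "RET", "SRC", "SYK", "TRK", "VEGFR",
)


@dataclass(frozen=True)
class ArrayLayout:
    """Geometry of one chip chemistry: a full grid of reporter peptides."""

    chip_type: str
    grid_rows: int
    grid_cols: int
    peptide_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.chip_type not in ("STK", "PTK"):
            raise ConfigurationError(f"chip_type must be STK or PTK, got {self.chip_type!r}")
        if len(self.peptide_ids) != self.grid_rows * self.grid_cols:
            raise ConfigurationError(
                f"{len(self.peptide_ids)} peptides do not fill a "
                f"{self.grid_rows}x{self.grid_cols} grid"
            )
        if len(set(self.peptide_ids)) != len(self.peptide_ids):
            raise ConfigurationError("peptide_ids must be unique")

    @property
    def n_peptides(self) -> int:
        return self.grid_rows * self.grid_cols

    @classmethod
    def stk(cls) -> "ArrayLayout":
        """The 144-peptide serine/threonine layout (12x12)."""
        ids = tuple(f"STK_{i:03d}" for i in range(1, 145))
        return cls("STK", 12, 12, ids)

    @classmethod
    def ptk(cls) -> "ArrayLayout":
        """The 196-peptide tyrosine layout (14x14)."""
        ids = tuple(f"PTK_{i:03d}" for i in range(1, 197))
        return cls("PTK", 14, 14, ids)


def make_kinase_map(layout: ArrayLayout, families: tuple[str, ...] | None = None,
                    seed: int = 0) -> KinaseSubstrateMap:
    """Deterministic kinase-family -> substrate-peptide map for a layout.

    Each peptide is assigned one primary family round-robin and, with
    probability 1/3, one extra family (real substrate maps are many-to-many).
    """
    if families is None:
        families = STK_FAMILIES if layout.chip_type == "STK" else PTK_FAMILIES
    rng = np.random.default_rng(seed)
    sets: dict[str, set[str]] = {f: set() for f in families}
    for i, pep in enumerate(layout.peptide_ids):
        sets[families[i % len(families)]].add(pep)
        if rng.random() < 1 / 3:
            extra = families[int(rng.integers(len(families)))]
            sets[extra].add(pep)
    return KinaseSubstrateMap(
        sets={k: frozenset(v) for k, v in sets.items() if v},
        level="family",
        source_name=f"synthetic_{layout.chip_type.lower()}_map",
    )


@dataclass(frozen=True)
class SimulationConfig:
    layout: ArrayLayout
    kinase_map: KinaseSubstrateMap
    groups: tuple[tuple[str, int], tuple[str, int]] = (("sedentary", 2), ("exercise", 2))
    n_chips: int = 3
    exposures_ms: tuple[float, ...] = DEFAULT_EXPOSURES_MS
    planted_effects: dict[str, float] = field(default_factory=dict)
    dead_peptide_frac: float = 0.0
    saturating_peptide_frac: float = 0.0
    noise_sd: float = 2.0
    base_slope_range: tuple[float, float] = (0.5, 3.0)
    intercept: float = 5.0
    saturation_tau_ms: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.groups) != 2:
            raise ConfigurationError("exactly two groups are required")
        if any(n < 1 for _, n in self.groups):
            raise ConfigurationError("each group needs at least one sample")
        if self.n_chips < 1:
            raise ConfigurationError("n_chips must be >= 1")
        exp = list(self.exposures_ms)
        if len(exp) < 2 or any(b <= a for a, b in zip(exp, exp[1:])):
            raise ConfigurationError("exposures_ms must be strictly increasing")
        if any(e <= 0 for e in exp):
            raise ConfigurationError("exposures must be positive")
        if not (0 <= self.dead_peptide_frac < 1 and 0 <= self.saturating_peptide_frac < 1):
            raise ConfigurationError("QC-failure fractions must be in [0, 1)")
        if self.dead_peptide_frac + self.saturating_peptide_frac >= 1:
            raise ConfigurationError("dead + saturating fractions must be < 1")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        missing = set(self.planted_effects) - set(self.kinase_map.sets)
        if missing:
            raise ConfigurationError(
                f"planted families absent from kinase map: {sorted(missing)}"
            )


@dataclass(frozen=True)
class GroundTruth:
    """What the generator planted: per-peptide class and per-family effect."""

    peptide_class: dict[str, str]  # peptide_id -> normal | dead | saturating
    family_effects: dict[str, float]
    seed: int
    chip_type: str

    def peptides_of_class(self, cls: str) -> set[str]:
        return {p for p, c in self.peptide_class.items() if c == cls}

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "peptide_class": self.peptide_class,
            "family_effects": self.family_effects,
            "seed": self.seed,
            "chip_type": self.chip_type,
        }, indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(d["peptide_class"], d["family_effects"], d["seed"], d["chip_type"])


def simulate_arrays(config: SimulationConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a long-format kinetic read table plus its ground truth.

    Returns a DataFrame with columns chip_id, sample_id, group, peptide_id,
    exposure_ms, intensity (one row per chip x sample x peptide x exposure)
    and the GroundTruth record. Identical config (including seed) yields a
    byte-identical table.
    """
    layout = config.layout
    rng = np.random.default_rng(config.seed)

    # Planted QC failures: floor(frac * n), disjoint, by seeded shuffle.
    n_dead = math.floor(config.dead_peptide_frac * layout.n_peptides)
    n_sat = math.floor(config.saturating_peptide_frac * layout.n_peptides)
    shuffled = list(layout.peptide_ids)
    rng.shuffle(shuffled)
    dead = set(shuffled[:n_dead])
    saturating = set(shuffled[n_dead:n_dead + n_sat])
    peptide_class = {
        p: "dead" if p in dead else "saturating" if p in saturating else "normal"
        for p in layout.peptide_ids
    }

    # Per-peptide baseline kinetic slope (intensity per ms), shared by all
    # samples; group effects multiply the treatment-group slope.
    lo, hi = config.base_slope_range
    base_slope = {p: float(s) for p, s in
                  zip(layout.peptide_ids, rng.uniform(lo, hi, layout.n_peptides))}
    effect_log2 = {p: 0.0 for p in layout.peptide_ids}
    for fam, eff in config.planted_effects.items():
        for p in config.kinase_map.sets[fam]:
            if p in effect_log2:
                effect_log2[p] += eff

    (group_a, n_a), (group_b, n_b) = config.groups
    samples = [(f"{group_a}_{i+1}", group_a) for i in range(n_a)] + \
              [(f"{group_b}_{i+1}", group_b) for i in range(n_b)]

    exposures = np.asarray(config.exposures_ms, dtype=float)
    rows: list[tuple] = []
    for chip_idx in range(config.n_chips):
        chip_id = f"{layout.chip_type}_chip{chip_idx + 1}"
        for sample_id, group in samples:
            treated = group == group_b
            for pep in layout.peptide_ids:
                cls = peptide_class[pep]
                if cls == "dead":
                    vals = np.abs(rng.normal(0.0, config.noise_sd / 10, exposures.size))
                elif cls == "saturating":
                    amp = base_slope[pep] * 100.0
                    vals = amp * (1.0 - np.exp(-exposures / config.saturation_tau_ms))
                    vals = vals + rng.normal(0.0, config.noise_sd, exposures.size)
                else:
                    slope = base_slope[pep]
                    if treated:
                        slope *= 2.0 ** effect_log2[pep]
                    vals = slope * exposures + config.intercept
                    vals = vals + rng.normal(0.0, config.noise_sd, exposures.size)
                vals = np.clip(vals, 0.0, None)
                for t, v in zip(exposures, vals):
                    rows.append((chip_id, sample_id, group, pep, float(t), float(v)))

    reads = pd.DataFrame(rows, columns=READ_COLUMNS)
    truth = GroundTruth(peptide_class, dict(config.planted_effects),
                        config.seed, layout.chip_type)
    return reads, truth


# ---------------------------------------------------------------------------
# Read-table I/O (long-format TSV)
# ---------------------------------------------------------------------------

def write_reads(reads: pd.DataFrame, path: str | Path) -> None:
    """Write a kinetic read table as tab-separated text with header."""
    # full float repr so a write/read round-trip is exact
    reads[READ_COLUMNS].to_csv(path, sep="\t", index=False)


def read_reads(path: str | Path) -> pd.DataFrame:
    """Read and validate a kinetic read table written by :func:`write_reads`.

    Raises FormatError naming the offending row for missing columns,
    non-numeric or negative intensities, and duplicate
    (chip, sample, peptide, exposure) keys.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in READ_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    df = df[READ_COLUMNS]
    for col in ("exposure_ms", "intensity"):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise FormatError(
                f"{path}: non-numeric {col} {df[col].iloc[row]!r} at data row {row + 1}"
            )
        df[col] = converted.astype(float)
    if (df["intensity"] < 0).any():
        row = int(np.flatnonzero((df["intensity"] < 0).to_numpy())[0])
        raise FormatError(f"{path}: negative intensity at data row {row + 1}")
    if not np.isfinite(df["intensity"]).all():
        row = int(np.flatnonzero(~np.isfinite(df["intensity"]).to_numpy())[0])
        raise FormatError(f"{path}: non-finite intensity at data row {row + 1}")
    key = ["chip_id", "sample_id", "peptide_id", "exposure_ms"]
    dup = df.duplicated(key)
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise FormatError(f"{path}: duplicate read key at data row {row + 1}")
    return df


# ---------------------------------------------------------------------------
# Companion synthetic fixtures for the downstream stages
# ---------------------------------------------------------------------------

def make_ppi_edges(kinase_symbols: list[str], n_connectors: int = 6,
                   n_background: int = 30, seed: int = 0) -> pd.DataFrame:
    """Synthetic protein-protein interaction edge list with confidences.

    Emulates a STRING-style confidence-scored network: the given kinases,
    a few well-connected connector proteins (candidate hidden nodes for
    the Steiner forest), and a larger loosely-wired background of
    non-kinase proteins so the enrichment universe is realistically
    bigger than the kinomic hit list.
    """
    rng = np.random.default_rng(seed)
    connectors = [f"CONN{i+1}" for i in range(n_connectors)]
    background = [f"BG{i+1:02d}" for i in range(n_background)]
    nodes = list(kinase_symbols) + connectors + background
    edges: list[tuple[str, str, float]] = []
    # ring over connectors guarantees a connected backbone
    for i, c in enumerate(connectors):
        edges.append((c, connectors[(i + 1) % n_connectors], float(rng.uniform(0.7, 0.95))))
    for k in kinase_symbols:
        hub = connectors[int(rng.integers(n_connectors))]
        edges.append((k, hub, float(rng.uniform(0.5, 0.95))))
    # background proteins hang off the backbone with mediocre confidence
    for b in background:
        other = connectors[int(rng.integers(n_connectors))] if rng.random() < 0.5 \
            else background[int(rng.integers(n_background))]
        if other != b:
            edges.append((b, other, float(rng.uniform(0.2, 0.6))))
    # sprinkle of direct edges anywhere
    for _ in range(len(nodes) // 2):
        a, b = rng.choice(nodes, 2, replace=False)
        if a != b:
            edges.append((str(a), str(b), float(rng.uniform(0.3, 0.9))))
    df = pd.DataFrame(edges, columns=["protein_a", "protein_b", "confidence"])
    return df.round({"confidence": 4})


def make_gene_sets(symbols: list[str], n_sets: int = 8, seed: int = 0,
                   prefix: str = "GO_SYN", focus: list[str] | None = None,
                   n_focus_sets: int = 3) -> dict[str, frozenset[str]]:
    """Synthetic gene-set library over the given symbols (GMT-shaped dict).

    When `focus` is given, the first `n_focus_sets` sets draw most of
    their members from it, planting gene sets genuinely related to those
    symbols (the way curated pathways concentrate on implicated kinases);
    the remaining sets are uniform background.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, frozenset[str]] = {}
    focus = [f for f in (focus or []) if f in symbols]
    for i in range(n_sets):
        size = int(rng.integers(3, max(4, len(symbols) // 2 + 1)))
        size = min(size, len(symbols))
        if focus and i < n_focus_sets:
            n_foc = min(len(focus), max(2, int(round(0.8 * size))))
            members = list(rng.choice(focus, n_foc, replace=False))
            rest = [s for s in symbols if s not in members]
            if size > n_foc and rest:
                members += list(rng.choice(rest, min(size - n_foc, len(rest)),
                                           replace=False))
        else:
            members = list(rng.choice(symbols, size, replace=False))
        out[f"{prefix}_{i+1:03d}"] = frozenset(str(m) for m in members)
    return out


def make_term_embeddings(term_ids: list[str], n_clusters: int = 2, dim: int = 8,
                         noise: float = 0.05, seed: int = 0) -> pd.DataFrame:
    """Synthetic pathway-term embeddings drawn around cluster prototypes.

    Real term embeddings come from text models; here each term is a
    prototype vector (one per planted cluster, assigned round-robin) plus
    Gaussian noise, which preserves the property the meta-clustering
    relies on: within-cluster cosine similarity far above between-cluster.
    """
    rng = np.random.default_rng(seed)
    protos = rng.normal(0.0, 1.0, (n_clusters, dim))
    protos /= np.linalg.norm(protos, axis=1, keepdims=True)
    vecs = [protos[i % n_clusters] + rng.normal(0.0, noise, dim)
            for i in range(len(term_ids))]
    return pd.DataFrame(vecs, index=pd.Index(term_ids, name="term_id"),
                        columns=[f"v{j+1}" for j in range(dim)])


def make_external_ranker(name: str, krsa_z: pd.Series, agreement: float = 0.8,
                         seed: int = 0) -> pd.DataFrame:
    """Synthetic external upstream-kinase ranker score table.

    Stands in for tools whose internals are out of scope (BioNavigator's
    upstream kinase analysis, kinase enrichment web services): scores are a
    noisy monotone transform of the internal resampling z-scores, with
    `agreement` controlling the signal-to-noise of the correlation.
    """
    rng = np.random.default_rng(seed)
    z = krsa_z.fillna(0.0)
    scale = float(z.std(ddof=0)) or 1.0
    noise = rng.normal(0.0, (1.0 - agreement) * 2.0 * scale, len(z))
    scores = agreement * z.to_numpy() + noise
    return pd.DataFrame({"kinase": z.index, "score": np.round(scores, 6),
                         "ranker": name})
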