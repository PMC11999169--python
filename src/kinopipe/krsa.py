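"""Kinase-family enrichment by random resampling of reporter peptides.

Given the set of differentially phosphorylated ("hit") peptides and the
universe of QC-passing peptides, each kinase family is scored by how many
hit peptides map to it, compared against the null distribution obtained by
repeatedly drawing |hits| peptides uniformly without replacement from the
universe:

    z = (observed - mean_permuted) / sd_permuted

Because each draw is a simple random sample without replacement, the
permutation mean and sd converge to the hypergeometric closed form
mean = n*K/N and var = n*(K/N)*(1-K/N)*(N-n)/(N-1), where N is the
universe size, K the family's universe coverage and n = |hits|; the test
suite uses that closed form as the oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError

DEFAULT_N_ITER = 2000


@dataclass(frozen=True)
class KinaseSubstrateMap:
    """Mapping kinase (or kinase family) -> set of substrate peptide IDs."""

    sets: dict[str, frozenset[str]]
    level: str = "family"  # family | kinase
    source_name: str = ""

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"set {name!r} is empty")

    @property
    def names(self) -> list[str]:
        return sorted(self.sets)

    def restrict(self, universe: set[str]) -> "KinaseSubstrateMap":
        """Intersect every set with a peptide universe, dropping empty sets."""
        kept = {k: frozenset(v & universe) for k, v in self.sets.items()}
        return KinaseSubstrateMap({k: v for k, v in kept.items() if v},
                                  self.level, self.source_name)


def read_gmt(path: str | Path) -> KinaseSubstrateMap:
    """Parse a GMT file (name <tab> description <tab> member...).

    Duplicate members within a set are deduplicated; a set with no members
    is a format error. Used both for kinase-substrate maps and for
    gene-set libraries.
    """
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected name, description "
                                  f"and at least one member")
            name = parts[0].strip()
            members = frozenset(m.strip() for m in parts[2:] if m.strip())
            if not name:
                raise FormatError(f"{path}:{lineno}: empty set name")
            if not members:
                raise FormatError(f"{path}:{lineno}: set {name!r} has no members")
            sets[name] = members
    if not sets:
        raise FormatError(f"{path}: no sets found")
    return KinaseSubstrateMap(sets, source_name=str(path))


def write_gmt(sets: dict[str, frozenset[str]] | KinaseSubstrateMap,
              path: str | Path, description: str = "na") -> None:
    if isinstance(sets, KinaseSubstrateMap):
        sets = sets.sets
    with open(path, "w") as fh:
        for name in sorted(sets):
            fh.write("\t".join([name, description, *sorted(sets[name])]) + "\n")


def krsa(hits: set[str], universe: set[str], kmap: KinaseSubstrateMap,
         n_iter: int = DEFAULT_N_ITER, seed: int = 0) -> pd.DataFrame:
    """Resampling enrichment z-scores for every kinase family in `kmap`.

    Parameters
    ----------
    hits
        Differentially phosphorylated peptides (must be a subset of the
        universe).
    universe
        All QC-passing peptides eligible for resampling.
    n_iter
        Number of random draws of |hits| peptides without replacement.
    seed
        Seed for the permutation stream; recorded in the output.

    Returns a DataFrame indexed by family with columns observed_count,
    perm_mean, perm_sd, z_score (NaN where perm_sd == 0), n_iterations,
    seed, sorted by descending |z|.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if not hits <= universe:
        raise ValueError("hits must be a subset of the universe")
    if len(hits) > len(universe):
        raise ValueError("more hits than universe members")

    universe_sorted = sorted(universe)
    restricted = kmap.restrict(universe)
    dropped = set(kmap.sets) - set(restricted.sets)
    if dropped:
        warnings.warn(f"families with no universe members dropped: {sorted(dropped)}")
    families = restricted.names
    if not families:
        return pd.DataFrame(columns=["observed_count", "perm_mean", "perm_sd",
                                     "z_score", "n_iterations", "seed"])

    # peptide x family membership matrix for vectorized counting
    idx = {p: i for i, p in enumerate(universe_sorted)}
    member = np.zeros((len(universe_sorted), len(families)), dtype=np.int64)
    for j, fam in enumerate(families):
        for p in restricted.sets[fam]:
            member[idx[p], j] = 1

    hit_vec = np.zeros(len(universe_sorted), dtype=np.int64)
    for p in hits:
        hit_vec[idx[p]] = 1
    observed = hit_vec @ member

    rng = np.random.default_rng(seed)
    n = len(hits)
    counts = np.empty((n_iter, len(families)), dtype=np.int64)
    for it in range(n_iter):
        draw = rng.choice(len(universe_sorted), size=n, replace=False)
        counts[it] = member[draw].sum(axis=0)

    perm_mean = counts.mean(axis=0)
    perm_sd = counts.std(axis=0, ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(perm_sd > 0, (observed - perm_mean) / perm_sd, np.nan)

    out = pd.DataFrame({
        "observed_count": observed,
        "perm_mean": perm_mean,
        "perm_sd": perm_sd,
        "z_score": z,
        "n_iterations": n_iter,
        "seed": seed,
    }, index=pd.Index(families, name="family"))
    return out.reindex(out["z_score"].abs().sort_values(ascending=False, kind="stable").index)
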