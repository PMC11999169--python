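"""Harmonization of upstream-kinase rankers into unified percentile ranks.

Different upstream-kinase tools (the internal resampling z-scores, plus
external score tables standing in for tools like BioNavigator's upstream
kinase analysis or kinase-enrichment web services) report incommensurable
metrics. Each ranker is reduced to percentile ranks in (0, 1]:

    percentile = rank / K        (average rank on ties, K kinases scored)

after orienting scores so higher means more implicated. Kinase names are
mapped to official HGNC symbols and subfamilies before joining; the mean
and median percentile are taken over the rankers in which a kinase is
present (absence is missing evidence, not zero evidence, matching the
empty circles of the bubble plots). Quartiles are ceil(4 * percentile)
clipped to 1..4, so quartile 4 means percentile > 0.75.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError

# Compact alias/family fixture covering the kinases named in the analyses
# this package emulates plus the synthetic families. A full HGNC dump is
# deliberately out of scope.
_DEFAULT_ALIASES: dict[str, str] = {
    "IKKA": "CHUK", "IKK-ALPHA": "CHUK", "IKKALPHA": "CHUK",
    "IKKB": "IKBKB", "IKK-BETA": "IKBKB",
    "IKKE": "IKBKE", "IKK-EPSILON": "IKBKE",
    "NAK": "TBK1", "T2K": "TBK1",
    "PKD": "PRKD1", "PKD1": "PRKD1",
    "CAMKII-ALPHA": "CAMK2A", "CAMK2": "CAMK2A",
    "CTK": "MATK", "HYL": "MATK",
    "ERBB1": "EGFR", "HER1": "EGFR",
    "FLT1": "VEGFR1", "KDR": "VEGFR2", "VEGFR-2": "VEGFR2",
    "JNK1": "MAPK8", "JNK": "MAPK8",
    "ERK1": "MAPK3", "ERK2": "MAPK1", "ERK": "MAPK3",
    "P38A": "MAPK14", "P38": "MAPK14",
    "FAK1": "PTK2", "FAK": "PTK2",
    "SRC-1": "SRC",
}
_DEFAULT_FAMILIES: dict[str, str] = {
    "CHUK": "IKK", "IKBKB": "IKK", "IKBKE": "IKK", "TBK1": "IKK",
    "PRKD1": "PKD", "PRKD2": "PKD",
    "CAMK2A": "CAMK2", "CAMK2B": "CAMK2",
    "CSK": "CSK", "MATK": "CSK",
    "EGFR": "EGFR", "ERBB2": "EGFR", "ERBB4": "EGFR",
    "VEGFR1": "VEGFR", "VEGFR2": "VEGFR", "RYK": "RYK",
    "MAPK8": "JNK", "MAPK9": "JNK", "MAPK3": "ERK", "MAPK1": "ERK",
    "MAPK14": "P38", "PTK2": "FAK", "SRC": "SRC",
}


@dataclass(frozen=True)
class RankerOutput:
    """Scores from one upstream-kinase tool."""

    ranker_name: str
    scores: dict[str, float]
    orientation: str = "higher_better"  # or lower_better

    def __post_init__(self) -> None:
        if self.orientation not in ("higher_better", "lower_better"):
            raise ValueError(f"bad orientation {self.orientation!r}")
        bad = [k for k, v in self.scores.items() if not np.isfinite(v)]
        if bad:
            raise FormatError(f"{self.ranker_name}: non-finite scores for {sorted(bad)}")
        if any(not k for k in self.scores):
            raise FormatError(f"{self.ranker_name}: empty kinase name")


@dataclass
class SymbolAliasMap:
    """alias -> HGNC symbol, HGNC symbol -> kinase family."""

    aliases: dict[str, str] = field(default_factory=lambda: dict(_DEFAULT_ALIASES))
    families: dict[str, str] = field(default_factory=lambda: dict(_DEFAULT_FAMILIES))
    unknown_seen: set[str] = field(default_factory=set)

    def to_symbol(self, name: str) -> str:
        key = name.strip().upper()
        if key in self.families:
            return key
        if key in self.aliases:
            return self.aliases[key]
        self.unknown_seen.add(name)  # reported, never silently dropped
        return key

    def family_of(self, symbol: str) -> str:
        return self.families.get(symbol, symbol)


def percentile_normalize(ranker: RankerOutput) -> pd.Series:
    """Percentile ranks in (0, 1] with average-rank ties; best score -> 1.0."""
    if not ranker.scores:
        raise ValueError(f"{ranker.ranker_name}: no entries")
    s = pd.Series(ranker.scores, dtype=float)
    if ranker.orientation == "lower_better":
        s = -s
    pct = s.rank(method="average") / len(s)
    pct.name = ranker.ranker_name
    return pct


def harmonize(rankers: list[RankerOutput],
              aliases: SymbolAliasMap | None = None,
              absent_as_zero: bool = False) -> pd.DataFrame:
    """Join rankers on HGNC symbol into the unified percentile table.

    Returns a DataFrame indexed by (family, kinase) with one percentile
    column per ranker (NaN where absent), mean_percentile and
    median_percentile over present rankers (or over all rankers with
    absent counted as 0 when absent_as_zero), and one quartile column per
    ranker (0 encodes absent).
    """
    if not rankers:
        raise ValueError("at least one ranker required")
    aliases = aliases or SymbolAliasMap()
    cols = {}
    for r in rankers:
        pct = percentile_normalize(r)
        mapped: dict[str, float] = {}
        for name, value in pct.items():
            sym = aliases.to_symbol(name)
            if sym in mapped:
                raise FormatError(
                    f"{r.ranker_name}: aliases {name!r} collide on symbol {sym} "
                    f"after HGNC mapping")
            mapped[sym] = float(value)
        if not mapped:
            warnings.warn(f"ranker {r.ranker_name} has no mappable kinases, skipped")
            continue
        cols[r.ranker_name] = pd.Series(mapped)
    if not cols:
        raise ValueError("no ranker contributed any mappable kinase")

    table = pd.DataFrame(cols)
    filled = table.fillna(0.0) if absent_as_zero else table.copy()
    table["mean_percentile"] = filled.mean(axis=1, skipna=True)
    table["median_percentile"] = filled.median(axis=1, skipna=True)
    for name in cols:
        q = np.ceil(4.0 * table[name]).clip(1, 4)
        table[f"quartile_{name}"] = q.fillna(0).astype(int)  # 0 = absent
    table.index.name = "kinase"
    table["family"] = [aliases.family_of(k) for k in table.index]
    out = table.reset_index().set_index(["family", "kinase"]).sort_index()
    return out


def bubble_table(harmonized: pd.DataFrame) -> pd.DataFrame:
    """Long-format quartile export for bubble plots.

    One row per (family, kinase, ranker) with quartile 1..4 or 'absent',
    grouped by family then kinase — the layout of the published bubble
    plots where filled circle size encodes the quartile and empty circles
    mark kinases missing from a tool's output.
    """
    if harmonized.empty:
        raise ValueError("harmonized table is empty")
    qcols = [c for c in harmonized.columns if c.startswith("quartile_")]
    rows = []
    for (family, kinase), rec in harmonized.iterrows():
        for qc in qcols:
            q = int(rec[qc])
            rows.append((family, kinase, qc.removeprefix("quartile_"),
                         "absent" if q == 0 else q))
    return pd.DataFrame(rows, columns=["family", "kinase", "ranker", "quartile"])


def read_ranker_table(path, ranker_name: str | None = None,
                      orientation: str = "higher_better") -> RankerOutput:
    """Load an external ranker score TSV (columns: kinase, score[, ranker])."""
    df = pd.read_csv(path, sep="\t")
    for col in ("kinase", "score"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    name = ranker_name or (str(df["ranker"].iloc[0]) if "ranker" in df.columns
                           else str(path))
    if df["kinase"].duplicated().any():
        dup = sorted(df.loc[df["kinase"].duplicated(), "kinase"].unique())
        raise FormatError(f"{path}: duplicate kinases {dup}")
    return RankerOutput(name, dict(zip(df["kinase"].astype(str), df["score"].astype(float))),
                        orientation)
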