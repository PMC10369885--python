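"""CASP-style evaluation arithmetic: Z-scores, strategy selection, Wilcoxon.

Each prediction strategy is scored per domain by GDT_TS; its standing
against the field is the Z-score of that GDT_TS with respect to the server
groups' scores for the same domain, and a strategy's headline number is the
sum of its positive Z-scores across domains ("Sum Z (> 0)"). Model1 picks,
per domain, the strategy with the highest pLDDT (what a blind predictor can
do); Model_best picks the highest GDT_TS (the oracle ceiling). Paired
strategy comparisons use the Wilcoxon signed-rank test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm


@dataclass
class ScoreTable:
    """Per-(domain, strategy) GDT_TS and mean pLDDT, plus server score fields.

    ``gdt`` and ``plddt`` are domain x strategy DataFrames; ``server_scores``
    maps each domain to the vector of server-group GDT_TS values it is
    ranked against (at least 2 per domain).
    """

    gdt: pd.DataFrame
    plddt: pd.DataFrame
    server_scores: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        if list(self.gdt.index) != list(self.plddt.index) or list(
            self.gdt.columns
        ) != list(self.plddt.columns):
            raise ValueError("gdt and plddt must share domains and strategies")
        for name, df in (("gdt", self.gdt), ("plddt", self.plddt)):
            vals = df.to_numpy(dtype=float)
            if np.isnan(vals).any():
                raise ValueError(f"missing {name} entries")
            if vals.min() < 0 or vals.max() > 100:
                raise ValueError(f"{name} values must lie in [0, 100]")
        self.server_scores = {
            d: np.asarray(v, dtype=float) for d, v in self.server_scores.items()
        }
        for d, v in self.server_scores.items():
            if len(v) < 2:
                raise ValueError(f"server field for {d} needs >= 2 entries")

    @property
    def domains(self) -> list[str]:
        return list(self.gdt.index)

    @property
    def strategies(self) -> list[str]:
        return list(self.gdt.columns)

    @classmethod
    def from_long(
        cls, scores: pd.DataFrame, servers: pd.DataFrame | None = None
    ) -> "ScoreTable":
        """Build from long-format tables.

        ``scores`` columns: domain_id, strategy, gdt_ts, plddt;
        ``servers`` columns: domain_id, server_id, gdt_ts.
        """
        gdt = scores.pivot(index="domain_id", columns="strategy", values="gdt_ts")
        plddt = scores.pivot(index="domain_id", columns="strategy", values="plddt")
        order = scores["strategy"].drop_duplicates().tolist()
        dom_order = scores["domain_id"].drop_duplicates().tolist()
        gdt = gdt.loc[dom_order, order]
        plddt = plddt.loc[dom_order, order]
        server_scores = {}
        if servers is not None:
            for d, grp in servers.groupby("domain_id", sort=False):
                server_scores[d] = grp["gdt_ts"].to_numpy(dtype=float)
        return cls(gdt=gdt, plddt=plddt, server_scores=server_scores)


@dataclass(frozen=True)
class StrategyReport:
    strategy: str
    gdt_mean: float
    gdt_sd: float
    sum_pos_z: float
    high_acc_fraction: float


def domain_zscore(own: float, servers: np.ndarray, ddof: int = 1) -> float:
    """Z-score of a score against the server field for one domain.

    (own - mean) / sd with sample sd (ddof=1) by default; a degenerate
    field (sd == 0) maps to z = 0.
    """
    servers = np.asarray(servers, dtype=float)
    if servers.size == 0:
        raise ValueError("empty server score vector")
    if servers.size == 1:
        return 0.0
    sd = float(np.std(servers, ddof=ddof))
    if sd == 0.0:
        return 0.0
    return (float(own) - float(np.mean(servers))) / sd


def sum_positive_z(zs) -> float:
    """Sum of positive Z-scores (negative values contribute nothing)."""
    zs = np.asarray(zs, dtype=float)
    return float(np.maximum(zs, 0.0).sum())


def high_accuracy_fraction(scores, threshold: float = 70.0) -> float:
    """Fraction of scores strictly above the high-accuracy threshold."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        return 0.0
    return float((scores > threshold).mean())


def _argmax_with_priority(row: pd.Series, priority: list[str]) -> str:
    best = row.max()
    for s in priority:
        if row[s] == best:
            return s
    raise AssertionError("unreachable")


def select_model1(
    table: ScoreTable, priority: list[str] | None = None
) -> pd.DataFrame:
    """Per-domain strategy with the highest mean pLDDT, and its GDT_TS.

    Ties are broken by ``priority`` (default: the table's column order).
    Returns a DataFrame indexed by domain with columns strategy, plddt,
    gdt_ts.
    """
    priority = priority or table.strategies
    rows = []
    for d in table.domains:
        s = _argmax_with_priority(table.plddt.loc[d], priority)
        rows.append((d, s, float(table.plddt.loc[d, s]), float(table.gdt.loc[d, s])))
    return pd.DataFrame(
        rows, columns=["domain_id", "strategy", "plddt", "gdt_ts"]
    ).set_index("domain_id")


def select_model_best(
    table: ScoreTable, priority: list[str] | None = None
) -> pd.DataFrame:
    """Per-domain strategy with the highest GDT_TS (the oracle selection)."""
    priority = priority or table.strategies
    rows = []
    for d in table.domains:
        s = _argmax_with_priority(table.gdt.loc[d], priority)
        rows.append((d, s, float(table.plddt.loc[d, s]), float(table.gdt.loc[d, s])))
    return pd.DataFrame(
        rows, columns=["domain_id", "strategy", "plddt", "gdt_ts"]
    ).set_index("domain_id")


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    # Exact two-sided p over all 2^n sign assignments, via the DP
    # distribution of W+ on doubled ranks (average ranks may be .5).
    r2 = np.rint(2 * ranks).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(round(2 * w_plus))
    lower = counts[: w2 + 1].sum()
    upper = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


def wilcoxon_paired(a, b, exact_max_n: int = 25) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired score vectors.

    Zero differences are dropped (p = 1.0 if none remain); ties in |d| get
    average ranks. The p-value is exact (full sign-assignment distribution)
    for n <= ``exact_max_n`` and a normal approximation with continuity and
    tie corrections above. Symmetric in its arguments.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    d = a - b
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 1.0
    absd = np.abs(d)
    order = np.argsort(absd, kind="stable")
    ranks = np.empty(n, dtype=float)
    sorted_abs = absd[order]
    i = 0
    pos = np.empty(n, dtype=float)
    while i < n:
        j = i
        while j < n and sorted_abs[j] == sorted_abs[i]:
            j += 1
        pos[i:j] = (i + j + 1) / 2.0  # average of ranks i+1 .. j
        i = j
    ranks[order] = pos
    w_plus = float(ranks[d > 0].sum())

    if n <= exact_max_n:
        return _exact_signed_rank_p(ranks, w_plus)

    mean = n * (n + 1) / 4.0
    # tie correction on the variance
    _, tie_counts = np.unique(absd, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
    if var <= 0:
        return 1.0
    delta = w_plus - mean
    cc = 0.5 * np.sign(delta)
    z = (delta - cc) / math.sqrt(var)
    return float(min(1.0, 2.0 * norm.sf(abs(z))))


def strategy_report(
    table: ScoreTable, strategy: str, threshold: float = 70.0
) -> StrategyReport:
    """Mean +- sd GDT_TS, Sum Z (> 0) and high-accuracy fraction of one strategy."""
    g = table.gdt[strategy].to_numpy(dtype=float)
    zs = [
        domain_zscore(table.gdt.loc[d, strategy], table.server_scores[d])
        for d in table.domains
    ] if table.server_scores else []
    return StrategyReport(
        strategy=strategy,
        gdt_mean=float(np.mean(g)),
        gdt_sd=float(np.std(g, ddof=1)) if len(g) > 1 else 0.0,
        sum_pos_z=sum_positive_z(zs) if zs else float("nan"),
        high_acc_fraction=high_accuracy_fraction(g, threshold),
    )
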