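"""TF-gene co-expression network construction.

Given log2FC profiles of transcription factors and of lipid-metabolism genes
on a shared (condition, timepoint) grid, every TF x gene pair is scored by
the Pearson product-moment correlation of the two profiles; an edge is kept
when the correlation and its two-sided p-value (Student t with n-2 df) pass
the configured thresholds. The result is a bipartite directed network,
TF -> gene, with r, p and n stored on each edge, exportable to SIF, GraphML
and a flat TSV for Cytoscape.

Two published threshold conventions are shipped as presets: the running-text
criterion (|R| > 0.9 strict, P < 0.05) and the figure-caption variant
(R >= 0.9 inclusive, P < 0.005). The default criterion is R >= 0.9,
P < 0.05, positive correlations only; a signed mode retains negative edges
for exploration. The source study's text and figure legend disagree on the
sign of the reported correlations; the positive-only default follows the
figure legend (edges drawn for positive significant correlations).

p-values are not multiplicity-adjusted by default, matching common practice
for small candidate panels; an optional Benjamini-Hochberg mode adjusts
across all evaluated pairs before thresholding.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import EmptyInput, GridMismatch, InputError, UndefinedCorrelation

__all__ = [
    "EdgeCriteria",
    "PRESETS",
    "CoexpressionNetwork",
    "pearson_r",
    "pearson_p",
    "correlate",
    "build_network",
    "hub_summary",
    "network_counts",
    "write_sif",
    "write_graphml",
    "write_edge_tsv",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EdgeCriteria:
    """Edge retention thresholds.

    r_min: minimum correlation magnitude; inclusive_r picks >= versus >.
    p_max: strict upper bound on the (optionally BH-adjusted) p-value.
    sign: "positive" keeps only r > 0 edges; "both" keeps |r|.
    adjust: None or "bh" (Benjamini-Hochberg across all evaluated pairs).
    """

    r_min: float = 0.9
    p_max: float = 0.05
    sign: str = "positive"
    inclusive_r: bool = True
    adjust: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.r_min <= 1.01:
            raise ValueError("r_min must be in [0, 1] (or just above to void edges)")
        if not 0 < self.p_max <= 1:
            raise ValueError("p_max must be in (0, 1]")
        if self.sign not in ("positive", "both"):
            raise ValueError("sign must be 'positive' or 'both'")
        if self.adjust not in (None, "bh"):
            raise ValueError("adjust must be None or 'bh'")

    def admits(self, r: float, p: float) -> bool:
        mag = r if self.sign == "positive" else abs(r)
        ok_r = mag >= self.r_min if self.inclusive_r else mag > self.r_min
        return bool(ok_r and p < self.p_max)


#: Published threshold conventions.
PRESETS: dict[str, EdgeCriteria] = {
    # running text: |R| > 0.9 (strict) and P < 0.05
    "results-text": EdgeCriteria(r_min=0.9, p_max=0.05, sign="positive",
                                 inclusive_r=False),
    # figure caption: R >= 0.9 and P < 0.005
    "figure-caption": EdgeCriteria(r_min=0.9, p_max=0.005, sign="positive",
                                   inclusive_r=True),
}


def pearson_r(x: Iterable[float], y: Iterable[float]) -> float:
    """Pearson product-moment correlation of two equal-length vectors.

    Raises :class:`UndefinedCorrelation` when either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 paired points")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = float(xc @ xc)
    sy = float(yc @ yc)
    if sx == 0.0 or sy == 0.0:
        raise UndefinedCorrelation("correlation undefined for a constant vector")
    r = float(xc @ yc) / math.sqrt(sx * sy)
    return max(-1.0, min(1.0, r))


def pearson_p(r: float, n: int) -> float:
    """Two-sided p-value for a Pearson correlation via the t transform.

    t = r sqrt(n-2) / sqrt(1-r^2), df = n-2. A perfect |r| = 1 fit is
    reported as p = 0.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if not -1.0 <= r <= 1.0:
        raise ValueError("r outside [-1, 1]")
    if abs(r) == 1.0:
        return 0.0
    t = r * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def _check_profiles(profiles: pd.DataFrame, what: str) -> None:
    if profiles.empty:
        raise EmptyInput(f"no {what} profiles")
    if profiles.isna().any().any():
        bad = profiles.index[profiles.isna().any(axis=1)][:5].tolist()
        raise InputError(
            f"incomplete {what} profiles (drop or complete first): {bad}"
        )
    if profiles.shape[1] < 3:
        raise GridMismatch("profiles need at least 3 grid points")


def correlate(tf_profiles: pd.DataFrame, gene_profiles: pd.DataFrame) -> pd.DataFrame:
    """Score every TF x gene pair: tidy frame [tf, gene, r, p_value, n].

    Pairs involving a constant profile are skipped with a warning (their
    correlation is undefined and can never support an edge).
    """
    _check_profiles(tf_profiles, "TF")
    _check_profiles(gene_profiles, "gene")
    if list(tf_profiles.columns) != list(gene_profiles.columns):
        raise GridMismatch(
            f"TF grid {list(tf_profiles.columns)} != gene grid "
            f"{list(gene_profiles.columns)}"
        )
    overlap = set(tf_profiles.index) & set(gene_profiles.index)
    if overlap:
        raise InputError(f"ids present in both TF and gene sets: {sorted(overlap)[:5]}")
    n = tf_profiles.shape[1]
    rows = []
    for tf, xv in tf_profiles.iterrows():
        for gene, yv in gene_profiles.iterrows():
            try:
                r = pearson_r(xv.to_numpy(), yv.to_numpy())
            except UndefinedCorrelation:
                logger.warning("skipping constant-profile pair (%s, %s)", tf, gene)
                continue
            rows.append((tf, gene, r, pearson_p(r, n), n))
    return pd.DataFrame(rows, columns=["tf", "gene", "r", "p_value", "n"])


class CoexpressionNetwork:
    """Bipartite TF -> gene network with retained edges and their thresholds."""

    def __init__(self, graph: nx.DiGraph, criteria: EdgeCriteria,
                 tfs: tuple[str, ...], genes: tuple[str, ...]):
        self.graph = graph
        self.criteria = criteria
        self.tfs = tfs
        self.genes = genes

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges_table(self) -> pd.DataFrame:
        rows = [
            (u, v, d["r"], d["p_value"], d["n"])
            for u, v, d in self.graph.edges(data=True)
        ]
        out = pd.DataFrame(rows, columns=["tf", "gene", "r", "p_value", "n"])
        return out.sort_values(["tf", "gene"]).reset_index(drop=True)


def build_network(
    tf_profiles: pd.DataFrame,
    gene_profiles: pd.DataFrame,
    criteria: EdgeCriteria | None = None,
    **overrides,
) -> CoexpressionNetwork:
    """Build the thresholded co-expression network.

    ``criteria`` may be an :class:`EdgeCriteria`, or keyword overrides of the
    defaults (``r_min=..., p_max=..., sign=..., inclusive_r=..., adjust=...``).
    """
    crit = criteria if criteria is not None else EdgeCriteria()
    if overrides:
        crit = replace(crit, **overrides)
    scored = correlate(tf_profiles, gene_profiles)
    pvals = scored["p_value"].copy()
    if crit.adjust == "bh" and len(scored):
        from statsmodels.stats.multitest import multipletests

        pvals = pd.Series(
            multipletests(scored["p_value"].to_numpy(), method="fdr_bh")[1],
            index=scored.index,
        )
    graph = nx.DiGraph()
    for tf in tf_profiles.index:
        graph.add_node(tf, part="tf")
    for gene in gene_profiles.index:
        graph.add_node(gene, part="gene")
    for (_, row), p_eff in zip(scored.iterrows(), pvals):
        if crit.admits(row["r"], p_eff):
            graph.add_edge(row["tf"], row["gene"], r=float(row["r"]),
                           p_value=float(row["p_value"]), n=int(row["n"]))
    return CoexpressionNetwork(graph, crit,
                               tuple(tf_profiles.index), tuple(gene_profiles.index))


def hub_summary(network: CoexpressionNetwork) -> pd.DataFrame:
    """Per-TF out-degree table, every TF included (degree 0 allowed)."""
    degrees = [(tf, network.graph.out_degree(tf)) for tf in network.tfs]
    out = pd.DataFrame(degrees, columns=["tf", "degree"])
    return out.sort_values(["degree", "tf"], ascending=[False, True]).reset_index(
        drop=True
    )


def network_counts(network: CoexpressionNetwork) -> dict[str, int]:
    """Headline counts: connected TFs (hubs), distinct target genes, edges."""
    hubs = [tf for tf in network.tfs if network.graph.out_degree(tf) > 0]
    targets = {v for _, v in network.graph.edges()}
    return {
        "n_hub_tfs": len(hubs),
        "n_target_genes": len(targets),
        "n_edges": network.n_edges,
    }


# ---------------------------------------------------------------------------
# exports (Cytoscape-compatible)


def write_sif(network: CoexpressionNetwork, path: str | Path) -> None:
    """SIF export: ``tf<TAB>coexpressed_with<TAB>gene`` per edge."""
    with open(path, "w") as fh:
        for _, row in network.edges_table().iterrows():
            fh.write(f"{row['tf']}\tcoexpressed_with\t{row['gene']}\n")


def write_graphml(network: CoexpressionNetwork, path: str | Path) -> None:
    """GraphML export with r / p_value / n edge attributes."""
    nx.write_graphml(network.graph, str(path))


def write_edge_tsv(network: CoexpressionNetwork, path: str | Path) -> None:
    crit = network.criteria
    with open(path, "w") as fh:
        fh.write(
            f"# thresholds: r_min={crit.r_min} "
            f"({'inclusive' if crit.inclusive_r else 'strict'}), "
            f"p_max={crit.p_max}, sign={crit.sign}, "
            f"adjust={crit.adjust or 'none'}\n"
        )
        network.edges_table().to_csv(fh, sep="\t", index=False,
                                     float_format="%.10g")
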