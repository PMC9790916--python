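"""Competing-endogenous-RNA network construction.

A circRNA that sponges a miRNA de-represses that miRNA's mRNA targets, so a
ceRNA triad (circRNA, miRNA, mRNA) is called when the molecules are
targeting-compatible and their expression satisfies the sign constraints:
Spearman(circ, miR) < 0, Spearman(miR, mRNA) < 0, Pearson(circ, mRNA) > 0,
each passing its significance/magnitude threshold.  Correlation cut-offs
default to sign-only plus p < 0.05 and are configurable.  Targeting relations
are an input table; a toy seed-match generator (reverse-complement match of
miRNA positions 2-8) is provided for self-contained runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .simdata import revcomp


@dataclass(frozen=True)
class TargetMap:
    """miRNA -> target genes and circRNA -> bound miRNAs."""

    mir_to_gene: dict[str, frozenset[str]]
    circ_to_mir: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        for name, mapping in (("mir_to_gene", self.mir_to_gene), ("circ_to_mir", self.circ_to_mir)):
            for key, targets in mapping.items():
                if not targets:
                    raise ValueError(f"{name}[{key}] is empty")

    @classmethod
    def from_tsv(cls, mir_to_gene_path: str | Path, circ_to_mir_path: str | Path) -> "TargetMap":
        return cls(
            mir_to_gene=_read_pairs(mir_to_gene_path),
            circ_to_mir=_read_pairs(circ_to_mir_path),
        )

    def to_tsv(self, mir_to_gene_path: str | Path, circ_to_mir_path: str | Path) -> None:
        _write_pairs(self.mir_to_gene, mir_to_gene_path)
        _write_pairs(self.circ_to_mir, circ_to_mir_path)


def _read_pairs(path: str | Path) -> dict[str, frozenset[str]]:
    out: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        a, b = line.split("\t")[:2]
        out.setdefault(a, set()).add(b)
    return {k: frozenset(v) for k, v in out.items()}


def _write_pairs(mapping: Mapping[str, frozenset[str]], path: str | Path) -> None:
    lines = [f"{a}\t{b}\n" for a in sorted(mapping) for b in sorted(mapping[a])]
    Path(path).write_text("".join(lines))


@dataclass(frozen=True)
class CeRNATriad:
    circ_id: str
    mir_id: str
    gene_id: str
    scc_circ_mir: float
    scc_mir_gene: float
    pcc_circ_gene: float


# ---------------------------------------------------------------------------
# Correlations


def _validate_pair(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    return x, y


def _t_pvalue(r: float, n: int) -> float:
    """Two-sided p for a correlation via the t statistic on n - 2 df."""
    if abs(r) >= 1.0:
        return 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) with a two-sided p
    from the t approximation on n - 2 degrees of freedom.

    A perfectly monotone pair returns exactly +/-1 (rank vectors are compared
    directly before the product-moment formula is applied)."""
    x, y = _validate_pair(np.asarray(x), np.asarray(y))
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    n = len(rx)
    if np.array_equal(rx, ry):
        rho = 1.0
    elif np.array_equal(rx, (n + 1) - ry):
        rho = -1.0
    else:
        rho = float(np.corrcoef(rx, ry)[0, 1])
    return rho, _t_pvalue(rho, n)


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson product-moment correlation with a two-sided p equivalent to the
    t test on n - 2 degrees of freedom."""
    x, y = _validate_pair(np.asarray(x), np.asarray(y))
    r = stats.pearsonr(x, y)
    return float(r.statistic), float(r.pvalue)


# ---------------------------------------------------------------------------
# Triad screen


@dataclass(frozen=True)
class CernaThresholds:
    """Sign constraints are mandatory; magnitude cut-offs default to 0
    (sign-only) and each correlation must reach p < p_max."""

    p_max: float = 0.05
    min_abs_scc: float = 0.0
    min_abs_pcc: float = 0.0


def build_cerna(
    circ_expr: pd.DataFrame,
    mir_expr: pd.DataFrame,
    mrna_expr: pd.DataFrame,
    targets: TargetMap,
    thresholds: CernaThresholds = CernaThresholds(),
    restrict_circ: Sequence[str] | None = None,
) -> tuple[list[CeRNATriad], nx.Graph]:
    """Assemble all targeting-compatible, sign-constrained triads.

    A triad (c, m, g) is kept iff m in circ_to_mir[c], g in mir_to_gene[m],
    SCC(c, m) < 0, SCC(m, g) < 0, PCC(c, g) > 0, and each correlation passes
    its significance/magnitude threshold.  The network is the union of kept
    circRNA-miRNA and miRNA-mRNA edges.  ``restrict_circ`` optionally limits
    the screen to given circRNAs (e.g. the differentially expressed set).
    """
    cols = list(circ_expr.columns)
    for name, df in (("mir", mir_expr), ("mrna", mrna_expr)):
        if set(df.columns) != set(cols):
            offending = sorted(set(df.columns) ^ set(cols))
            raise ValueError(f"sample mismatch in {name} matrix: {offending}")
    mir_expr = mir_expr[cols]
    mrna_expr = mrna_expr[cols]

    scc_cache: dict[tuple[str, str], tuple[float, float]] = {}
    pcc_cache: dict[tuple[str, str], tuple[float, float]] = {}

    def scc(key, xa, xb):
        if key not in scc_cache:
            try:
                scc_cache[key] = spearman(xa, xb)
            except ValueError:
                scc_cache[key] = (float("nan"), 1.0)
        return scc_cache[key]

    def pcc(key, xa, xb):
        if key not in pcc_cache:
            try:
                pcc_cache[key] = pearson(xa, xb)
            except ValueError:
                pcc_cache[key] = (float("nan"), 1.0)
        return pcc_cache[key]

    circ_ids = restrict_circ if restrict_circ is not None else list(circ_expr.index)
    triads: list[CeRNATriad] = []
    th = thresholds
    for c in sorted(circ_ids):
        if c not in circ_expr.index or c not in targets.circ_to_mir:
            continue
        xc = circ_expr.loc[c].to_numpy(float)
        for m in sorted(targets.circ_to_mir[c]):
            if m not in mir_expr.index:
                continue
            xm = mir_expr.loc[m].to_numpy(float)
            r_cm, p_cm = scc((c, m), xc, xm)
            if not (r_cm < 0 and abs(r_cm) >= th.min_abs_scc and p_cm < th.p_max):
                continue
            for g in sorted(targets.mir_to_gene.get(m, ())):
                if g not in mrna_expr.index:
                    continue
                xg = mrna_expr.loc[g].to_numpy(float)
                r_mg, p_mg = scc((m, g), xm, xg)
                if not (r_mg < 0 and abs(r_mg) >= th.min_abs_scc and p_mg < th.p_max):
                    continue
                r_cg, p_cg = pcc((c, g), xc, xg)
                if not (r_cg > 0 and abs(r_cg) >= th.min_abs_pcc and p_cg < th.p_max):
                    continue
                triads.append(CeRNATriad(c, m, g, r_cm, r_mg, r_cg))
    return triads, network_from_triads(triads)


def network_from_triads(triads: Sequence[CeRNATriad]) -> nx.Graph:
    graph = nx.Graph()
    for t in triads:
        graph.add_node(t.circ_id, type="circRNA")
        graph.add_node(t.mir_id, type="miRNA")
        graph.add_node(t.gene_id, type="mRNA")
        graph.add_edge(t.circ_id, t.mir_id, interaction="circRNA-miRNA", correlation=t.scc_circ_mir)
        graph.add_edge(t.mir_id, t.gene_id, interaction="miRNA-mRNA", correlation=t.scc_mir_gene)
    return graph


# ---------------------------------------------------------------------------
# Toy targeting generator


def seed_match_targets(
    mir_seqs: Mapping[str, str], transcript_seqs: Mapping[str, str]
) -> dict[str, frozenset[str]]:
    """Toy target prediction: a miRNA targets a transcript when the
    reverse complement of its seed (positions 2-8) occurs in the
    transcript."""
    out: dict[str, frozenset[str]] = {}
    for mid, mseq in mir_seqs.items():
        seed = revcomp(mseq[1:8].upper().replace("U", "T"))
        hits = frozenset(
            tid for tid, tseq in transcript_seqs.items() if seed in tseq.upper().replace("U", "T")
        )
        if hits:
            out[mid] = hits
    return out


# ---------------------------------------------------------------------------
# Export / import


def export_network(graph: nx.Graph, path: str | Path, fmt: str = "edge-tsv") -> list[Path]:
    """Write the network for graph viewers.

    ``sif``: one `source TAB interaction TAB target` line per edge.
    ``edge-tsv``: `<path>.edges.tsv` + `<path>.nodes.tsv` tables.
    ``graphml``: GraphML XML via networkx.
    Returns the written paths.
    """
    path = Path(path)
    if fmt == "sif":
        lines = [
            f"{u}\t{d['interaction']}\t{v}\n"
            for u, v, d in sorted(graph.edges(data=True))
        ]
        path.write_text("".join(lines))
        return [path]
    if fmt == "edge-tsv":
        nodes = pd.DataFrame(
            sorted((n, d.get("type", "")) for n, d in graph.nodes(data=True)),
            columns=["id", "type"],
        )
        edges = pd.DataFrame(
            sorted(
                (u, d["interaction"], v, d.get("correlation", ""))
                for u, v, d in graph.edges(data=True)
            ),
            columns=["source", "interaction", "target", "correlation"],
        )
        node_path = path.with_suffix(".nodes.tsv")
        edge_path = path.with_suffix(".edges.tsv")
        nodes.to_csv(node_path, sep="\t", index=False)
        edges.to_csv(edge_path, sep="\t", index=False)
        return [edge_path, node_path]
    if fmt == "graphml":
        nx.write_graphml(graph, path)
        return [path]
    raise ValueError(f"unknown network format {fmt!r}; use sif, edge-tsv, or graphml")


def read_network(path: str | Path, fmt: str = "edge-tsv") -> nx.Graph:
    """Read a network written by :func:`export_network` (round-trip)."""
    path = Path(path)
    if fmt == "graphml":
        return nx.read_graphml(path)
    graph = nx.Graph()
    if fmt == "sif":
        for line in path.read_text().splitlines():
            if not line.strip():
                continue
            u, interaction, v = line.split("\t")
            graph.add_edge(u, v, interaction=interaction)
        return graph
    if fmt == "edge-tsv":
        edges = pd.read_csv(path.with_suffix(".edges.tsv"), sep="\t")
        nodes = pd.read_csv(path.with_suffix(".nodes.tsv"), sep="\t")
        for _, row in nodes.iterrows():
            graph.add_node(row["id"], type=row["type"])
        for _, row in edges.iterrows():
            graph.add_edge(
                row["source"],
                row["target"],
                interaction=row["interaction"],
                correlation=float(row["correlation"]),
            )
        return graph
    raise ValueError(f"unknown network format {fmt!r}")
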