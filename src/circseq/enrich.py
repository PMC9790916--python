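"""Over-representation analysis of circRNA host genes against gene-set
collections (KEGG/Reactome/GO-style GMT files).

Significance is the one-sided upper-tail hypergeometric probability computed
from the numbers of annotated genes and annotated candidate genes overall and
within each set.  The universe is the set of genes carrying at least one
annotation in the collection under test.  Rankings use raw p-values (a BH
column is emitted alongside).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats

from .circdetect import CircRecord

log = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """set_id -> (name, members); the universe is the union of members."""

    sets: dict[str, tuple[str, frozenset[str]]]

    def __post_init__(self) -> None:
        for sid, (_, members) in self.sets.items():
            if not members:
                raise ValueError(f"gene set {sid} is empty")

    @property
    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for _, members in self.sets.values():
            out |= members
        return frozenset(out)

    @classmethod
    def from_gmt(cls, path: str | Path) -> "GeneSetCollection":
        sets = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line!r}")
            sets[parts[0]] = (parts[1], frozenset(g for g in parts[2:] if g))
        return cls(sets)

    def to_gmt(self, path: str | Path) -> None:
        lines = [
            "\t".join([sid, name, *sorted(members)]) + "\n"
            for sid, (name, members) in sorted(self.sets.items())
        ]
        Path(path).write_text("".join(lines))


@dataclass(frozen=True)
class EnrichmentRow:
    set_id: str
    name: str
    N: int  # universe size
    K: int  # set size
    n: int  # annotated candidates
    k: int  # overlap
    p_value: float

    def __post_init__(self) -> None:
        if self.k > min(self.K, self.n) or self.N < max(self.K, self.n):
            raise ValueError(f"inconsistent 2x2 counts for {self.set_id}")


def hypergeom_pvalue(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    return float(min(1.0, stats.hypergeom.sf(k - 1, N, K, n)))


def hypergeom_enrich(
    candidates: Iterable[str], collection: GeneSetCollection
) -> list[EnrichmentRow]:
    """Rank gene sets by over-representation of the candidate genes.

    Candidates outside the annotation universe are dropped (with a logged
    count).  Rows are sorted ascending by p, ties broken by set_id.
    """
    if not collection.sets:
        raise ValueError("empty gene-set collection")
    universe = collection.universe
    cand = set(candidates)
    inside = cand & universe
    dropped = len(cand) - len(inside)
    if dropped:
        log.info("dropped %d candidate genes outside the annotation universe", dropped)
    if not inside:
        log.warning("no candidate genes inside the annotation universe")
        return []
    N, n = len(universe), len(inside)
    rows = []
    for sid, (name, members) in collection.sets.items():
        K = len(members)
        k = len(inside & members)
        rows.append(EnrichmentRow(sid, name, N, K, n, k, hypergeom_pvalue(N, K, n, k)))
    rows.sort(key=lambda r: (r.p_value, r.set_id))
    return rows


def enrichment_table(rows: Sequence[EnrichmentRow]) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "rank": range(1, len(rows) + 1),
            "set_id": [r.set_id for r in rows],
            "name": [r.name for r in rows],
            "N": [r.N for r in rows],
            "K": [r.K for r in rows],
            "n": [r.n for r in rows],
            "k": [r.k for r in rows],
            "p_value": [r.p_value for r in rows],
        }
    )
    if len(df):
        df["fdr"] = stats.false_discovery_control(df["p_value"], method="bh")
    else:
        df["fdr"] = []
    return df


def top_table(rows: Sequence[EnrichmentRow], k: int = 20) -> pd.DataFrame:
    """Top-k ranked sets in the (rank, ID, description) shape."""
    return pd.DataFrame(
        {
            "No": range(1, min(k, len(rows)) + 1),
            "ID": [r.set_id for r in rows[:k]],
            "Description": [r.name for r in rows[:k]],
        }
    )


def hosts_of(de_circ: Sequence[CircRecord]) -> set[str]:
    """Unique host genes of non-intergenic DE circRNAs; intergenic records
    contribute nothing (their count is logged)."""
    hostless = 0
    hosts: set[str] = set()
    for r in de_circ:
        if r.origin is None:
            raise ValueError(f"record {r.circ_id} lacks origin annotation")
        if r.host_gene is None or r.origin == "intergenic":
            hostless += 1
        else:
            hosts.add(r.host_gene)
    if hostless:
        log.info("%d intergenic/hostless circRNAs contributed no host gene", hostless)
    return hosts
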