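"""Exon-model gene annotation: in-memory model plus GTF and BED12 readers/writers.

Coordinates are 0-based half-open internally (BED convention); the GTF
writer/reader converts to and from 1-based closed on disk.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence


@dataclass(frozen=True)
class Gene:
    """A gene as an ordered set of exons on one strand of one chromosome."""

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]  # sorted, 0-based half-open, disjoint

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id}: strand must be + or -, got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id}: needs at least one exon")
        prev_end = -1
        for s, e in self.exons:
            if not (0 <= s < e):
                raise ValueError(f"gene {self.gene_id}: bad exon interval ({s}, {e})")
            if s < prev_end:
                raise ValueError(f"gene {self.gene_id}: exons must be sorted and disjoint")
            prev_end = e

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)
        )

    def overlap(self, start: int, end: int) -> int:
        """Length of the intersection of [start, end) with the gene span."""
        return max(0, min(end, self.end) - max(start, self.start))


class GeneModel:
    """Queryable collection of genes, indexed by chromosome."""

    def __init__(self, genes: Iterable[Gene]):
        self.genes: list[Gene] = sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id))
        self._by_chrom: dict[str, list[Gene]] = {}
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene_id {g.gene_id}")
            seen.add(g.gene_id)
            self._by_chrom.setdefault(g.chrom, []).append(g)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __getitem__(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def overlapping(self, chrom: str, start: int, end: int) -> list[Gene]:
        """Genes whose span intersects [start, end) on ``chrom``."""
        return [g for g in self._by_chrom.get(chrom, []) if g.start < end and g.end > start]


# ---------------------------------------------------------------------------
# On-disk formats


def write_gtf(model: GeneModel, path: str | Path) -> None:
    """Write gene and exon features; 1-based closed coordinates."""
    lines = ["##gff-version 2\n"]
    for g in model:
        attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1";'
        lines.append(
            f"{g.chrom}\tcircseq\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
        )
        for s, e in g.exons:
            lines.append(
                f"{g.chrom}\tcircseq\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
            )
    Path(path).write_text("".join(lines))


def read_gtf(path: str | Path) -> GeneModel:
    """Read the exon-model subset of GTF written by :func:`write_gtf`.

    Only ``exon`` features are used; genes are reassembled from the
    ``gene_id`` attribute.
    """
    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) < 9 or f[2] != "exon":
            continue
        gid = _gtf_attr(f[8], "gene_id")
        exons.setdefault(gid, []).append((int(f[3]) - 1, int(f[4])))
        meta[gid] = (f[0], f[6])
    genes = [
        Gene(gid, meta[gid][0], meta[gid][1], tuple(sorted(ex)))
        for gid, ex in exons.items()
    ]
    return GeneModel(genes)


def _gtf_attr(attrs: str, key: str) -> str:
    for part in attrs.split(";"):
        part = part.strip()
        if part.startswith(key):
            return part.split('"')[1]
    raise ValueError(f"attribute {key!r} not found in {attrs!r}")


def write_bed12(model: GeneModel, path: str | Path) -> None:
    lines = []
    for g in model:
        sizes = ",".join(str(e - s) for s, e in g.exons)
        starts = ",".join(str(s - g.start) for s, _ in g.exons)
        lines.append(
            "\t".join(
                [
                    g.chrom,
                    str(g.start),
                    str(g.end),
                    g.gene_id,
                    "0",
                    g.strand,
                    str(g.start),
                    str(g.end),
                    "0",
                    str(len(g.exons)),
                    sizes,
                    starts,
                ]
            )
            + "\n"
        )
    Path(path).write_text("".join(lines))


def read_bed12(path: str | Path) -> GeneModel:
    genes = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        f = line.split("\t")
        start = int(f[1])
        sizes = [int(x) for x in f[10].rstrip(",").split(",")]
        offs = [int(x) for x in f[11].rstrip(",").split(",")]
        exons = tuple((start + o, start + o + sz) for o, sz in zip(offs, sizes))
        genes.append(Gene(f[3], f[0], f[5], exons))
    return GeneModel(genes)
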