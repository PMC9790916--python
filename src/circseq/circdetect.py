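"""Back-splice junction detection, reliability filtering, and origin classing.

The detector re-implements the anchor/extend strategy for circRNA discovery
at desk scale: the two terminal anchors of each read are located in the
genome by exact k-mer lookup; placements in inverted genomic order mark a
candidate back-splice, which is closed by extending both anchors toward the
read interior while counting mismatches.  The reliability filter applies the
standard eight-clause recipe (unique breakpoint, bounded anchor overlap and
edit distance, minimum unique read support both absolutely and relative to
sample count, anchor quality, and a genomic-span ceiling).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel
from .simdata import SimRead, revcomp

log = logging.getLogger(__name__)

MAX_QUAL = 40  # anchor uniqueness margin scale
DEFAULT_ANCHOR_LEN = 20


@dataclass(frozen=True)
class JunctionCandidate:
    """One read's evidence for a back-splice event."""

    read_id: str
    chrom: str
    strand: str
    start: int  # 0-based
    end: int  # half-open; end > start
    breakpoint: int  # distinct extension positions closing the junction
    anchor_overlap: int
    edit: int
    qual_a: int
    qual_b: int
    sample_id: str


@dataclass
class CircRecord:
    """A back-splice junction aggregated over its supporting reads."""

    circ_id: str
    chrom: str
    strand: str
    start: int
    end: int
    breakpoint: int
    anchor_overlap: int
    edit: int
    n_uniq: int
    best_qual_a: int
    best_qual_b: int
    counts: dict[str, int] = field(default_factory=dict)
    origin: str | None = None
    host_gene: str | None = None
    spliced_length: int | None = None

    @property
    def genomic_length(self) -> int:
        return self.end - self.start

    @property
    def total_reads(self) -> int:
        return sum(self.counts.values())


# ---------------------------------------------------------------------------
# Detection


class AnchorIndex:
    """Exact k-mer lookup over a genome (replaces an external aligner on toy
    genomes)."""

    def __init__(self, genome: Mapping[str, str], k: int):
        if not genome:
            raise ValueError("empty genome")
        self.k = k
        self.genome = dict(genome)
        self._index: dict[str, list[tuple[str, int]]] = {}
        for chrom, seq in self.genome.items():
            for i in range(len(seq) - k + 1):
                self._index.setdefault(seq[i : i + k], []).append((chrom, i))

    def placements(self, anchor: str) -> list[tuple[str, int]]:
        return self._index.get(anchor, [])

    def occurrences(self, anchor: str) -> int:
        """Placements of the anchor on either strand."""
        return len(self.placements(anchor)) + len(self.placements(revcomp(anchor)))

    def quality(self, anchor: str) -> int:
        """Uniqueness margin scaled to [0, MAX_QUAL]: 40 for a unique anchor,
        40/k for k placements."""
        occ = self.occurrences(anchor)
        return int(round(MAX_QUAL / occ)) if occ else 0


def detect_junctions(
    reads: Iterable[SimRead],
    genome: Mapping[str, str] | AnchorIndex,
    anchor_len: int = DEFAULT_ANCHOR_LEN,
    max_edit: int = 2,
    max_placements: int = 16,
) -> list[JunctionCandidate]:
    """Scan reads for back-splice evidence; one candidate per junction read.

    Colinear reads (terminal anchors in genomic order, read matching the
    genome contiguously) yield no candidate.  Reads shorter than twice the
    anchor length are skipped with a counted warning.
    """
    if anchor_len < 12:
        raise ValueError(f"anchor_len must be >= 12, got {anchor_len}")
    index = genome if isinstance(genome, AnchorIndex) else AnchorIndex(genome, anchor_len)
    if index.k != anchor_len:
        raise ValueError("anchor index built with a different anchor length")
    k = anchor_len
    candidates: list[JunctionCandidate] = []
    n_short = 0

    for read in reads:
        L = len(read.sequence)
        if L < 2 * k:
            n_short += 1
            continue
        best: tuple | None = None  # sort key -> candidate
        colinear = False
        for strand, q in (("+", read.sequence), ("-", revcomp(read.sequence))):
            a1, a2 = q[:k], q[-k:]
            plc1 = index.placements(a1)
            plc2 = index.placements(a2)
            if not plc1 or not plc2:
                continue
            # contiguous genome match => linear read, never a back-splice
            for chrom, p1 in plc1:
                if index.genome[chrom][p1 : p1 + L] == q:
                    colinear = True
                    break
            if colinear:
                break
            if len(plc1) > max_placements or len(plc2) > max_placements:
                continue
            qual_a = index.quality(a1)
            qual_b = index.quality(a2)
            for chrom, p1 in plc1:
                seq = index.genome[chrom]
                for chrom2, p2 in plc2:
                    if chrom2 != chrom:
                        continue
                    cand = _close_junction(q, seq, p1, p2, k, max_edit)
                    if cand is None:
                        continue
                    s, e, bp, edit, overlap = cand
                    key = (edit, bp, chrom, s, e, strand)
                    if best is None or key < best[0]:
                        best = (
                            key,
                            JunctionCandidate(
                                read.read_id, chrom, strand, s, e, bp,
                                overlap, edit, qual_a, qual_b, read.sample_id,
                            ),
                        )
        if not colinear and best is not None:
            candidates.append(best[1])
    if n_short:
        log.warning("skipped %d reads shorter than 2 x anchor_len", n_short)
    return candidates


def _close_junction(
    q: str, seq: str, p1: int, p2: int, k: int, max_edit: int
) -> tuple[int, int, int, int, int] | None:
    """Extend anchors at p1 (read prefix) and p2 (read suffix) toward the read
    interior.  Returns (start, end, breakpoint, edit, anchor_overlap) for the
    minimal-edit closure, or None if the pair cannot form a back-splice."""
    L = len(q)
    m = L - 2 * k  # interior length shared by the two extensions
    # prefix extension q[k:L-k] against genome right of p1's anchor
    g1 = seq[p1 + k : p1 + k + m]
    # suffix extension q[k:L-k] region against genome left of p2's anchor
    g2 = seq[max(0, p2 - m) : p2]
    if len(g1) < m or len(g2) < m:
        return None
    interior = q[k : L - k]
    mm1 = np.frombuffer(interior.encode(), dtype="S1") != np.frombuffer(g1.encode(), dtype="S1")
    mm2 = np.frombuffer(interior.encode(), dtype="S1") != np.frombuffer(g2.encode(), dtype="S1")
    pref = np.concatenate([[0], np.cumsum(mm1)])  # pref[j]: first j interior nt
    suf = np.concatenate([[0], np.cumsum(mm2[::-1])])[::-1]  # suf[j]: interior nt from j on
    edits = pref + suf  # edits[j] for breakpoint b = k + j
    min_edit = int(edits.min())
    if min_edit > max_edit:
        return None
    n_break = int((edits == min_edit).sum())
    j = int(np.argmin(edits))
    b = k + j
    s = p2 + k - (L - b)
    e = p1 + b
    if not (0 <= s < e <= len(seq)):
        return None
    overlap = max(0, min(e, s + (L - b)) - max(e - b, s))
    return s, e, n_break, min_edit, overlap


# ---------------------------------------------------------------------------
# Aggregation and filtering


def aggregate_candidates(
    candidates: Sequence[JunctionCandidate], samples: Sequence[str]
) -> list[CircRecord]:
    """One CircRecord per (chrom, strand, start, end).

    Per-sample counts tally supporting reads; ``n_uniq`` counts distinct read
    ids; anchor qualities take the per-junction maximum while edit and anchor
    overlap take the best (minimum) over reads, and breakpoint the worst
    (maximum), so one ambiguous read flags the whole junction.
    """
    groups: dict[tuple[str, str, int, int], list[JunctionCandidate]] = {}
    for c in candidates:
        groups.setdefault((c.chrom, c.strand, c.start, c.end), []).append(c)
    records = []
    for key in sorted(groups):
        chrom, strand, start, end = key
        members = groups[key]
        counts = {s: 0 for s in samples}
        for c in members:
            counts[c.sample_id] = counts.get(c.sample_id, 0) + 1
        records.append(
            CircRecord(
                circ_id="",
                chrom=chrom,
                strand=strand,
                start=start,
                end=end,
                breakpoint=max(c.breakpoint for c in members),
                anchor_overlap=min(c.anchor_overlap for c in members),
                edit=min(c.edit for c in members),
                n_uniq=len({c.read_id for c in members}),
                best_qual_a=max(c.qual_a for c in members),
                best_qual_b=max(c.qual_b for c in members),
                counts=counts,
            )
        )
    for i, rec in enumerate(records):
        rec.circ_id = f"bsj_{i + 1:06d}"
    return records


@dataclass(frozen=True)
class FilterThresholds:
    """The eight-clause reliability filter with its published defaults.

    The comma list is read as a conjunction with one internal disjunction
    (either anchor quality may exceed ``min_qual``); both unique-read clauses
    apply by default and are independently switchable.
    """

    breakpoint: int = 1  # required exactly
    max_anchor_overlap: int = 2
    max_edit: int = 2
    min_n_uniq: int = 2  # strict: n_uniq > 2
    min_qual: int = 35  # strict, on either anchor
    max_length: int = 100_000  # strict, genomic span
    apply_min_uniq: bool = True
    apply_half_samples: bool = True


def filter_reliable(
    records: Sequence[CircRecord],
    n_samples: int,
    thresholds: FilterThresholds = FilterThresholds(),
) -> list[CircRecord]:
    """Keep records passing every reliability clause; order preserved."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    half = n_samples // 2
    kept = []
    for r in records:
        for name in ("breakpoint", "anchor_overlap", "edit", "n_uniq", "best_qual_a", "best_qual_b"):
            if getattr(r, name) < 0:
                raise ValueError(f"record {r.circ_id}: negative {name}")
        ok = (
            r.breakpoint == thresholds.breakpoint
            and r.anchor_overlap <= thresholds.max_anchor_overlap
            and r.edit <= thresholds.max_edit
            and (not thresholds.apply_min_uniq or r.n_uniq > thresholds.min_n_uniq)
            and (r.best_qual_a > thresholds.min_qual or r.best_qual_b > thresholds.min_qual)
            and (not thresholds.apply_half_samples or r.n_uniq > half)
            and r.genomic_length < thresholds.max_length
        )
        if ok:
            kept.append(r)
    return kept


# ---------------------------------------------------------------------------
# Origin classification


def annotate_origin(record: CircRecord, model: GeneModel) -> CircRecord:
    """Classify a junction as exonic, intronic, or intergenic.

    Exonic: both endpoints coincide with exon boundaries of one same-strand
    gene (spliced length = sum of enclosed exons).  Any other gene overlap is
    intronic (hosted by the gene with the largest overlap, ties broken
    lexicographically); no overlap is intergenic.  Precedence is
    exonic > intronic > intergenic, so spans touching several genes always
    classify deterministically.
    """
    overlapping = model.overlapping(record.chrom, record.start, record.end)
    exonic: list[tuple[int, str, int]] = []  # (-overlap, gene_id, spliced)
    for g in overlapping:
        if g.strand != record.strand:
            continue
        starts = {s: i for i, (s, _) in enumerate(g.exons)}
        ends = {e: j for j, (_, e) in enumerate(g.exons)}
        i = starts.get(record.start)
        j = ends.get(record.end)
        if i is not None and j is not None and i <= j:
            spliced = sum(e - s for s, e in g.exons[i : j + 1])
            exonic.append((-g.overlap(record.start, record.end), g.gene_id, spliced))
    if exonic:
        exonic.sort()
        _, host, spliced = exonic[0]
        return replace(record, origin="exonic", host_gene=host, spliced_length=spliced)
    if overlapping:
        ranked = sorted(overlapping, key=lambda g: (-g.overlap(record.start, record.end), g.gene_id))
        return replace(
            record,
            origin="intronic",
            host_gene=ranked[0].gene_id,
            spliced_length=record.genomic_length,
        )
    return replace(
        record, origin="intergenic", host_gene=None, spliced_length=record.genomic_length
    )


def annotate_catalog(records: Sequence[CircRecord], model: GeneModel) -> list[CircRecord]:
    return [annotate_origin(r, model) for r in records]


def summarize_catalog(records: Sequence[CircRecord]) -> dict[str, pd.DataFrame]:
    """Catalog-level summaries: per-chromosome counts, origin fractions, and
    per-sample back-spliced read totals (the abundance-distribution input)."""
    per_chrom = (
        pd.Series([r.chrom for r in records], dtype="object")
        .value_counts()
        .sort_index()
        .rename("n_circ")
    )
    origins = pd.Series([r.origin for r in records], dtype="object")
    per_origin = origins.value_counts().to_frame("count")
    per_origin["fraction"] = per_origin["count"] / max(len(records), 1)
    sample_totals: dict[str, dict[str, int]] = {}
    for r in records:
        for s, c in r.counts.items():
            sample_totals.setdefault(s, {"total_bsj_reads": 0, "n_detected": 0})
            sample_totals[s]["total_bsj_reads"] += c
            sample_totals[s]["n_detected"] += int(c > 0)
    per_sample = pd.DataFrame(sample_totals).T.sort_index()
    return {
        "per_chromosome": per_chrom.to_frame(),
        "per_origin": per_origin,
        "per_sample": per_sample,
    }


# ---------------------------------------------------------------------------
# Catalog I/O


_CATALOG_META = [
    "circ_id", "chrom", "start", "end", "strand", "genomic_length",
    "spliced_length", "annotation_type", "host_gene", "breakpoint",
    "anchor_overlap", "edit", "n_uniq", "best_qual_A", "best_qual_B",
]


def write_catalog(records: Sequence[CircRecord], path: str | Path) -> None:
    samples = sorted({s for r in records for s in r.counts})
    rows = []
    for r in records:
        row = {
            "circ_id": r.circ_id,
            "chrom": r.chrom,
            "start": r.start,
            "end": r.end,
            "strand": r.strand,
            "genomic_length": r.genomic_length,
            "spliced_length": r.spliced_length if r.spliced_length is not None else "",
            "annotation_type": r.origin or "",
            "host_gene": r.host_gene or "",
            "breakpoint": r.breakpoint,
            "anchor_overlap": r.anchor_overlap,
            "edit": r.edit,
            "n_uniq": r.n_uniq,
            "best_qual_A": r.best_qual_a,
            "best_qual_B": r.best_qual_b,
        }
        for s in samples:
            row[f"count:{s}"] = r.counts.get(s, 0)
        rows.append(row)
    pd.DataFrame(rows, columns=_CATALOG_META + [f"count:{s}" for s in samples]).to_csv(
        path, sep="\t", index=False
    )


def read_catalog(path: str | Path) -> list[CircRecord]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    count_cols = [c for c in df.columns if c.startswith("count:")]
    records = []
    for _, row in df.iterrows():
        records.append(
            CircRecord(
                circ_id=row["circ_id"],
                chrom=row["chrom"],
                strand=row["strand"],
                start=int(row["start"]),
                end=int(row["end"]),
                breakpoint=int(row["breakpoint"]),
                anchor_overlap=int(row["anchor_overlap"]),
                edit=int(row["edit"]),
                n_uniq=int(row["n_uniq"]),
                best_qual_a=int(row["best_qual_A"]),
                best_qual_b=int(row["best_qual_B"]),
                counts={c.split(":", 1)[1]: int(row[c]) for c in count_cols},
                origin=row["annotation_type"] or None,
                host_gene=row["host_gene"] or None,
                spliced_length=int(row["spliced_length"]) if str(row["spliced_length"]) else None,
            )
        )
    return records


def write_junction_bed(records: Sequence[CircRecord], path: str | Path) -> None:
    lines = [
        f"{r.chrom}\t{r.start}\t{r.end}\t{r.circ_id}\t{r.n_uniq}\t{r.strand}\n"
        for r in records
    ]
    Path(path).write_text("".join(lines))


def counts_matrix(records: Sequence[CircRecord], samples: Sequence[str]) -> pd.DataFrame:
    """Feature x sample back-spliced read counts for the expression module."""
    data = {s: [r.counts.get(s, 0) for r in records] for s in samples}
    return pd.DataFrame(data, index=[r.circ_id for r in records])
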