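"""Seeded synthetic benchmark generator.

Emulates a four-group dorsal-root-ganglion injury design (DR-Exp / DR-Sham for
the central axon branch, SN-Exp / SN-Sham for the peripheral branch) on a toy
genome: planted back-splice junctions with exonic / intronic / intergenic
origins, junction-spanning chimeric reads, negative-binomial count matrices
with planted fold changes, gene-set collections with planted enrichment, and
miRNA / mRNA expression with planted sign-constrained ceRNA triads.

Every artifact is reproducible byte-for-byte from ``SimConfig.seed``; the seed
stream is split per artifact (genome / circRNA placement / reads / counts /
ceRNA) so regenerating one artifact does not perturb the others.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import Gene, GeneModel

_BASES = np.array(list("ACGT"))
_RC = str.maketrans("ACGT", "TGCA")

# spawn keys of the per-artifact seed streams
_STREAM_GENOME, _STREAM_CIRC, _STREAM_READS, _STREAM_COUNTS, _STREAM_CERNA = range(5)


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


class SimSizingError(ValueError):
    """Requested layout does not fit in the configured genome."""


class PlacementError(ValueError):
    """No compatible locus found for a requested circRNA origin class."""


@dataclass(frozen=True)
class Comparison:
    """One injury-vs-sham contrast with its planted effect counts."""

    name: str
    group_a: str  # sham / reference
    group_b: str  # injury
    n_up: int
    n_down: int


#: Planted differential counts mirror the study design: 9 up / 24 down after
#: central (dorsal root) injury and 32 up / 23 down after peripheral (sciatic
#: nerve) injury.
CENTRAL = Comparison("central", "DR-Sham", "DR-Exp", n_up=9, n_down=24)
PERIPHERAL = Comparison("peripheral", "SN-Sham", "SN-Exp", n_up=32, n_down=23)


@dataclass
class SimConfig:
    seed: int = 0
    # genome
    n_chrom: int = 4
    chrom_len: int = 250_000
    n_genes: int = 200
    exons_per_gene: tuple[int, int] = (3, 6)
    exon_len: tuple[int, int] = (150, 300)
    intron_len: tuple[int, int] = (200, 800)
    intergenic_gap: tuple[int, int] = (150, 600)
    # circRNAs; the default keeps planted DE features a small minority of the
    # catalog (as in real data), which library normalization relies on
    n_circ: int = 600
    origin_fractions: tuple[float, float, float] = (0.66, 0.16, 0.18)
    max_span: int = 100_000
    # experimental design
    groups: tuple[tuple[str, int], ...] = (
        ("DR-Sham", 3),
        ("DR-Exp", 3),
        ("SN-Sham", 3),
        ("SN-Exp", 3),
    )
    comparisons: tuple[Comparison, ...] = (CENTRAL, PERIPHERAL)
    log2fc_magnitude: float = 2.0
    nb_dispersion: float = 0.1
    planted_baseline_mean: float = 100.0
    background_log_mean: float = math.log(10.0)
    background_log_sigma: float = 1.0
    # junction reads
    mean_junction_reads: float = 6.0
    min_junction_reads: int = 0
    read_len: int = 100
    junction_offset_margin: int = 24
    background_reads_per_sample: int = 200
    error_rate: float = 0.0
    # gene sets
    n_sets: int = 20
    set_size: tuple[int, int] = (10, 20)
    planted_set_hosts: int = 12
    # ceRNA
    n_mirna: int = 30
    n_mrna: int = 60
    n_triads: int = 8
    triad_correlation: float = 0.9
    decoy_mir_per_circ: int = 2
    decoy_gene_per_mir: int = 3

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if abs(sum(self.origin_fractions) - 1.0) > 1e-9:
            raise ValueError("origin_fractions must sum to 1")
        if any(f < 0 for f in self.origin_fractions):
            raise ValueError("origin_fractions must be non-negative")
        for name in ("n_chrom", "chrom_len", "n_genes", "n_circ", "read_len",
                     "n_mirna", "n_mrna", "n_triads"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.mean_junction_reads < 0:
            raise ValueError("mean_junction_reads must be >= 0")
        if not 0.0 <= self.triad_correlation <= 1.0:
            raise ValueError("triad_correlation must lie in [0, 1]")
        planted = sum(c.n_up + c.n_down for c in self.comparisons)
        if planted > self.n_circ:
            raise ValueError(
                f"planted DE features ({planted}) exceed n_circ ({self.n_circ})"
            )
        group_names = [g for g, _ in self.groups]
        if len(set(group_names)) != len(group_names):
            raise ValueError("group labels must be unique")
        for c in self.comparisons:
            if c.group_a not in group_names or c.group_b not in group_names:
                raise ValueError(f"comparison {c.name} references unknown group")
        if self.n_triads > min(self.n_circ, self.n_mirna, self.n_mrna):
            raise SimSizingError(
                f"n_triads={self.n_triads} exceeds "
                f"min(n_circ, n_mirna, n_mrna)="
                f"{min(self.n_circ, self.n_mirna, self.n_mrna)}"
            )

    def samples(self) -> list[str]:
        return [f"{g}_{i + 1}" for g, n in self.groups for i in range(n)]

    def group_of(self) -> dict[str, str]:
        return {f"{g}_{i + 1}": g for g, n in self.groups for i in range(n)}

    def stream(self, key: int) -> np.random.Generator:
        child = np.random.SeedSequence(self.seed, spawn_key=(key,))
        return np.random.default_rng(child)


def preset(name: str, **overrides) -> SimConfig:
    """Named study conditions.

    ``central`` / ``peripheral`` run a single contrast with the study's
    planted up/down structure; ``null`` plants no effect (magnitude 0) for
    calibration checks; ``full`` runs both contrasts.
    """
    presets: dict[str, dict] = {
        "central": dict(comparisons=(CENTRAL,), groups=(("DR-Sham", 3), ("DR-Exp", 3))),
        "peripheral": dict(comparisons=(PERIPHERAL,), groups=(("SN-Sham", 3), ("SN-Exp", 3))),
        "null": dict(log2fc_magnitude=0.0),
        "full": {},
    }
    if name not in presets:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(presets)}")
    kwargs = dict(presets[name])
    kwargs.update(overrides)
    return SimConfig(**kwargs)


# ---------------------------------------------------------------------------
# Truth containers


@dataclass
class CircTruth:
    circ_id: str
    chrom: str
    strand: str
    start: int
    end: int
    origin: str  # exonic | intronic | intergenic
    host_gene: str | None
    true_log2fc: dict[str, float] = field(default_factory=dict)  # comparison -> lfc


@dataclass
class TriadTruth:
    circ_id: str
    mir_id: str
    mrna_id: str


@dataclass
class TruthSet:
    records: list[CircTruth] = field(default_factory=list)
    enriched_sets: dict[str, list[str]] = field(default_factory=dict)
    triads: list[TriadTruth] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.circ_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("truth circ_ids must be unique")

    def by_id(self) -> dict[str, CircTruth]:
        return {r.circ_id: r for r in self.records}

    def planted_ids(self, comparison: str, direction: str) -> list[str]:
        sign = 1.0 if direction == "up" else -1.0
        return [
            r.circ_id
            for r in self.records
            if sign * r.true_log2fc.get(comparison, 0.0) > 0
        ]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "records": [asdict(r) for r in self.records],
            "enriched_sets": self.enriched_sets,
            "triads": [asdict(t) for t in self.triads],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthSet":
        payload = json.loads(Path(path).read_text())
        return cls(
            records=[CircTruth(**r) for r in payload["records"]],
            enriched_sets=payload["enriched_sets"],
            triads=[TriadTruth(**t) for t in payload["triads"]],
        )


# ---------------------------------------------------------------------------
# Genome and annotation


def simulate_genome(config: SimConfig) -> tuple[dict[str, str], GeneModel]:
    """Random genome plus a non-overlapping exon-model annotation."""
    rng = config.stream(_STREAM_GENOME)
    genome = {
        f"chr{i + 1}": "".join(_BASES[rng.integers(0, 4, config.chrom_len)])
        for i in range(config.n_chrom)
    }
    chroms = list(genome)
    cursors = {c: 0 for c in chroms}
    genes: list[Gene] = []
    for gi in range(config.n_genes):
        n_ex = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        ex_lens = rng.integers(config.exon_len[0], config.exon_len[1] + 1, n_ex)
        in_lens = rng.integers(config.intron_len[0], config.intron_len[1] + 1, max(0, n_ex - 1))
        gap = int(rng.integers(config.intergenic_gap[0], config.intergenic_gap[1] + 1))
        span = int(ex_lens.sum() + in_lens.sum())
        strand = "+" if rng.random() < 0.5 else "-"
        chrom = chroms[gi % len(chroms)]
        start = cursors[chrom] + gap
        if start + span > config.chrom_len - 50:
            deficit = start + span - (config.chrom_len - 50)
            raise SimSizingError(
                f"genome too small to place gene {gi + 1}/{config.n_genes}: "
                f"need at least {deficit} more nt on {chrom}"
            )
        exons = []
        pos = start
        for k in range(n_ex):
            exons.append((pos, pos + int(ex_lens[k])))
            pos += int(ex_lens[k])
            if k < n_ex - 1:
                pos += int(in_lens[k])
        genes.append(Gene(f"g{gi + 1:04d}", chrom, strand, tuple(exons)))
        cursors[chrom] = pos
    return genome, GeneModel(genes)


def largest_remainder(total: int, fractions: Sequence[float]) -> list[int]:
    """Integer apportionment of ``total`` by ``fractions``; sums exactly."""
    quotas = [total * f for f in fractions]
    base = [int(math.floor(q)) for q in quotas]
    short = total - sum(base)
    order = sorted(range(len(fractions)), key=lambda i: (-(quotas[i] - base[i]), i))
    for i in order[:short]:
        base[i] += 1
    return base


def _junction_clear(seq: str, s: int, e: int) -> bool:
    # A back-splice at [s, e) has a unique closing position iff the bases
    # flanking the two breakpoints differ; otherwise the junction can slide
    # and the detector reports breakpoint > 1.
    if s < 1 or e >= len(seq):
        return False
    return seq[s] != seq[e] and seq[s - 1] != seq[e - 1]


def plant_circrnas(genome: Mapping[str, str], model: GeneModel, config: SimConfig) -> TruthSet:
    """Place ``n_circ`` back-splice events with the configured origin mix.

    Exonic events run between exon boundaries of one gene, intronic events sit
    strictly inside one intron, intergenic events avoid all genes.  Every span
    is shorter than ``max_span`` (the reliability filter's length ceiling) and
    long enough for a junction read; sliding-ambiguous junctions are rejected
    so planted truth is recoverable at breakpoint 1.
    """
    rng = config.stream(_STREAM_CIRC)
    n_ex, n_in, n_ig = largest_remainder(config.n_circ, config.origin_fractions)
    min_span = config.read_len + 10
    used: set[tuple[str, int, int]] = set()
    records: list[CircTruth] = []

    def try_place(origin: str) -> CircTruth | None:
        if origin == "exonic":
            if len(model) == 0:
                return None
            g = model.genes[rng.integers(0, len(model))]
            i = int(rng.integers(0, len(g.exons)))
            j = int(rng.integers(i, len(g.exons)))
            s, e = g.exons[i][0], g.exons[j][1]
            host, strand = g.gene_id, g.strand
        elif origin == "intronic":
            candidates = [g for g in model if len(g.exons) > 1]
            if not candidates:
                return None
            g = candidates[rng.integers(0, len(candidates))]
            introns = [iv for iv in g.introns if iv[1] - iv[0] >= min_span + 4]
            if not introns:
                return None
            a, b = introns[rng.integers(0, len(introns))]
            s = int(rng.integers(a + 1, b - 1 - min_span))
            e = int(rng.integers(s + min_span, b))  # e <= b - 1
            host, strand = g.gene_id, g.strand
        else:  # intergenic
            chrom_names = list(genome)
            chrom = chrom_names[rng.integers(0, len(chrom_names))]
            span = int(rng.integers(min_span, min(3000, config.chrom_len // 4)))
            s = int(rng.integers(1, config.chrom_len - span - 1))
            e = s + span
            if model.overlapping(chrom, s, e):
                return None
            host = None
            strand = "+" if rng.random() < 0.5 else "-"
            return _check(chrom, strand, s, e, origin, host)
        return _check(g.chrom, strand, s, e, origin, host)

    def _check(chrom, strand, s, e, origin, host) -> CircTruth | None:
        if e - s < min_span or e - s >= config.max_span:
            return None
        if (chrom, s, e) in used:
            return None
        if not _junction_clear(genome[chrom], s, e):
            return None
        used.add((chrom, s, e))
        return CircTruth("", chrom, strand, s, e, origin, host)

    for origin, want in (("exonic", n_ex), ("intronic", n_in), ("intergenic", n_ig)):
        placed = 0
        tries = 0
        budget = 2000 * max(want, 1)
        while placed < want:
            tries += 1
            if tries > budget:
                raise PlacementError(
                    f"could not place {want} {origin} circRNAs "
                    f"(placed {placed} after {tries} attempts)"
                )
            rec = try_place(origin)
            if rec is not None:
                records.append(rec)
                placed += 1

    # stable ids in coordinate order, echoing the novel_circ_* naming style
    records.sort(key=lambda r: (r.chrom, r.start, r.end))
    for i, r in enumerate(records):
        r.circ_id = f"circ_{i + 1:06d}"

    # plant per-comparison fold changes on disjoint feature sets
    pool = list(rng.permutation([r.circ_id for r in records]))
    by_id = {r.circ_id: r for r in records}
    for comp in config.comparisons:
        for _ in range(comp.n_up):
            by_id[pool.pop()].true_log2fc[comp.name] = +config.log2fc_magnitude
        for _ in range(comp.n_down):
            by_id[pool.pop()].true_log2fc[comp.name] = -config.log2fc_magnitude

    for r in records:
        if not (0 <= r.start < r.end <= len(genome[r.chrom])):
            raise AssertionError(f"truth coordinate outside genome: {r}")
    return TruthSet(records=records)


# ---------------------------------------------------------------------------
# Junction reads


@dataclass(frozen=True)
class SimRead:
    read_id: str
    sample_id: str
    sequence: str


def _draw_counts(rng: np.random.Generator, mean: float, dispersion: float, size: int) -> np.ndarray:
    """NB(mean, dispersion) draws with the Poisson limit at dispersion 0."""
    if mean <= 0:
        return np.zeros(size, dtype=int)
    if dispersion <= 0:
        return rng.poisson(mean, size)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size)


def simulate_junction_reads(
    truth: TruthSet,
    genome: Mapping[str, str],
    config: SimConfig,
    mean_overrides: Mapping[str, float] | None = None,
) -> tuple[list[SimRead], pd.DataFrame]:
    """Back-splice chimeric reads (tail-of-span then head-of-span) plus
    colinear background reads, with per-sample provenance.

    With ``error_rate`` 0 every junction read is an exact substring of the
    rotated span; ``min_junction_reads`` floors the per-(circRNA, sample)
    coverage for guaranteed-recovery experiments.
    """
    L = config.read_len
    margin = config.junction_offset_margin
    if L < 2 * margin:
        raise ValueError(f"read_len={L} too short for junction offset margin {margin}")
    rng = config.stream(_STREAM_READS)
    overrides = dict(mean_overrides or {})
    samples = config.samples()
    reads: list[SimRead] = []
    prov_rows: list[tuple[str, str, str]] = []
    serial = 0

    for rec in truth.records:
        seq = genome[rec.chrom]
        mean = overrides.get(rec.circ_id, config.mean_junction_reads)
        for sample in samples:
            n = int(_draw_counts(rng, mean, config.nb_dispersion, 1)[0])
            if mean > 0:
                n = max(n, config.min_junction_reads)
            for _ in range(n):
                o = int(rng.integers(margin, L - margin + 1))
                chunk = seq[rec.end - o : rec.end] + seq[rec.start : rec.start + L - o]
                if rec.strand == "-":
                    chunk = revcomp(chunk)
                chunk = _inject_errors(chunk, config.error_rate, rng)
                serial += 1
                rid = f"r{serial:07d}"
                reads.append(SimRead(rid, sample, chunk))
                prov_rows.append((rid, sample, rec.circ_id))

    chroms = list(genome)
    for sample in samples:
        for _ in range(config.background_reads_per_sample):
            chrom = chroms[rng.integers(0, len(chroms))]
            s = int(rng.integers(0, config.chrom_len - L))
            chunk = genome[chrom][s : s + L]
            if rng.random() < 0.5:
                chunk = revcomp(chunk)
            chunk = _inject_errors(chunk, config.error_rate, rng)
            serial += 1
            rid = f"r{serial:07d}"
            reads.append(SimRead(rid, sample, chunk))
            prov_rows.append((rid, sample, "colinear"))

    provenance = pd.DataFrame(prov_rows, columns=["read_id", "sample_id", "source"])
    return reads, provenance


def _inject_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        cur = arr[i].decode()
        alt = [b for b in "ACGT" if b != cur]
        arr[i] = alt[rng.integers(0, 3)].encode()
    return arr.tobytes().decode()


# ---------------------------------------------------------------------------
# Count matrices, gene sets, ceRNA


@dataclass
class CountBundle:
    circ_counts: pd.DataFrame  # features x samples, int
    group_of: dict[str, str]
    mir_expr: pd.DataFrame
    mrna_expr: pd.DataFrame
    gene_sets: "GeneSetCollection"
    targets: "TargetMap"


def simulate_counts_and_cerna(truth: TruthSet, config: SimConfig) -> CountBundle:
    """Count matrices with planted fold changes, gene sets with planted
    enrichment, and miRNA / mRNA expression with planted ceRNA triads.

    Planted circ-miR and miR-mRNA pairs are anticorrelated and circ-mRNA
    pairs correlated, at strength ``triad_correlation`` (exact at 1).
    Extends ``truth`` in place with enriched-set and triad truth.
    """
    from .enrich import GeneSetCollection
    from .cerna import TargetMap

    if len(config.groups) < 2 and any(config.comparisons):
        raise ValueError("need at least two groups for a DE comparison")
    rng = config.stream(_STREAM_COUNTS)
    samples = config.samples()
    group_of = config.group_of()
    comp_by_b: dict[str, list[Comparison]] = {}
    for comp in config.comparisons:
        comp_by_b.setdefault(comp.group_b, []).append(comp)

    counts = np.zeros((len(truth.records), len(samples)), dtype=int)
    for fi, rec in enumerate(truth.records):
        if rec.true_log2fc:
            base = config.planted_baseline_mean
        else:
            base = float(rng.lognormal(config.background_log_mean, config.background_log_sigma))
        for si, sample in enumerate(samples):
            mean = base
            for comp in comp_by_b.get(group_of[sample], []):
                mean = base * 2.0 ** rec.true_log2fc.get(comp.name, 0.0)
            counts[fi, si] = _draw_counts(rng, mean, config.nb_dispersion, 1)[0]
    circ_counts = pd.DataFrame(counts, index=[r.circ_id for r in truth.records], columns=samples)

    gene_sets = _plant_gene_sets(truth, config, rng)

    rng_c = config.stream(_STREAM_CERNA)
    mir_ids = [f"mir_{i + 1:04d}" for i in range(config.n_mirna)]
    mrna_ids = [f"tx_{i + 1:04d}" for i in range(config.n_mrna)]
    n_s = len(samples)
    mir = 50.0 + 10.0 * rng_c.standard_normal((config.n_mirna, n_s))
    mrna = 50.0 + 10.0 * rng_c.standard_normal((config.n_mrna, n_s))

    # choose triad circRNAs among features whose profile actually varies
    totals = circ_counts.sum(axis=1)
    stds = circ_counts.std(axis=1)
    eligible = [cid for cid in circ_counts.index if stds[cid] > 0 and totals[cid] > 0]
    if len(eligible) < config.n_triads:
        raise SimSizingError("not enough varying circRNA profiles to plant triads")
    triad_circs = list(rng_c.choice(eligible, size=config.n_triads, replace=False))
    rho = config.triad_correlation
    noise_w = math.sqrt(max(0.0, 1.0 - rho * rho))
    rpm_like = circ_counts.to_numpy(dtype=float)
    rpm_like = rpm_like / rpm_like.sum(axis=0, keepdims=True) * 1e6
    triads: list[TriadTruth] = []
    circ_to_mir: dict[str, set[str]] = {}
    mir_to_gene: dict[str, set[str]] = {}
    for t, cid in enumerate(triad_circs):
        z = rpm_like[circ_counts.index.get_loc(cid)]
        z = (z - z.mean()) / z.std()
        mid, gid = mir_ids[t], mrna_ids[t]
        mir[t] = 50.0 + 10.0 * (-rho * z + noise_w * rng_c.standard_normal(n_s))
        mrna[t] = 50.0 + 10.0 * (rho * z + noise_w * rng_c.standard_normal(n_s))
        triads.append(TriadTruth(cid, mid, gid))
        circ_to_mir.setdefault(cid, set()).add(mid)
        mir_to_gene.setdefault(mid, set()).add(gid)

    # decoy targeting edges whose expression is uncorrelated
    for cid in triad_circs:
        extra = rng_c.choice(mir_ids, size=min(config.decoy_mir_per_circ, len(mir_ids)), replace=False)
        circ_to_mir[cid].update(extra)
    for mid in list(mir_to_gene) + list(rng_c.choice(mir_ids, size=min(5, len(mir_ids)), replace=False)):
        extra = rng_c.choice(mrna_ids, size=min(config.decoy_gene_per_mir, len(mrna_ids)), replace=False)
        mir_to_gene.setdefault(mid, set()).update(extra)

    truth.triads = triads
    bundle = CountBundle(
        circ_counts=circ_counts,
        group_of=group_of,
        mir_expr=pd.DataFrame(mir, index=mir_ids, columns=samples),
        mrna_expr=pd.DataFrame(mrna, index=mrna_ids, columns=samples),
        gene_sets=gene_sets,
        targets=TargetMap(
            mir_to_gene={k: frozenset(v) for k, v in mir_to_gene.items()},
            circ_to_mir={k: frozenset(v) for k, v in circ_to_mir.items()},
        ),
    )
    return bundle


def _plant_gene_sets(truth: TruthSet, config: SimConfig, rng: np.random.Generator):
    """Random gene sets over all annotated genes, plus one planted set per
    comparison stuffed with host genes of that comparison's planted DE
    circRNAs."""
    from .enrich import GeneSetCollection

    universe = sorted(
        {r.host_gene for r in truth.records if r.host_gene is not None}
        | {f"g{i + 1:04d}" for i in range(config.n_genes)}
    )
    members: dict[str, set[str]] = {f"set_{i + 1:03d}": set() for i in range(config.n_sets)}
    set_ids = list(members)
    # every gene carries at least one annotation so the collection's universe
    # covers the genome
    for gene in universe:
        for sid in rng.choice(set_ids, size=int(rng.integers(1, 4)), replace=False):
            members[sid].add(gene)
    enriched: dict[str, list[str]] = {}
    for k, comp in enumerate(config.comparisons):
        sid = set_ids[k]  # reserved as the planted set for this comparison
        hosts = sorted(
            {
                r.host_gene
                for r in truth.records
                if r.host_gene is not None and r.true_log2fc.get(comp.name, 0.0) != 0.0
            }
        )
        take = min(config.planted_set_hosts, len(hosts))
        if take:
            members[sid].update(rng.choice(hosts, size=take, replace=False))
        enriched[comp.name] = [sid]
    truth.enriched_sets = enriched
    sets = {
        sid: (f"synthetic pathway {sid}", frozenset(m))
        for sid, m in members.items()
        if m
    }
    return GeneSetCollection(sets=sets)


# ---------------------------------------------------------------------------
# Writers


def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in genome:
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(reads: Iterable[SimRead], outdir: str | Path) -> dict[str, Path]:
    """One FASTQ per sample; constant quality (errors are substitution-only)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handles: dict[str, list[str]] = {}
    for r in reads:
        handles.setdefault(r.sample_id, []).append(
            f"@{r.read_id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n"
        )
    paths = {}
    for sample, chunks in handles.items():
        p = outdir / f"{sample}.fastq"
        p.write_text("".join(chunks))
        paths[sample] = p
    return paths


def read_fastq_dir(outdir: str | Path) -> list[SimRead]:
    from Bio import SeqIO

    reads = []
    for p in sorted(Path(outdir).glob("*.fastq")):
        sample = p.stem
        for rec in SeqIO.parse(str(p), "fastq"):
            reads.append(SimRead(rec.id, sample, str(rec.seq).upper()))
    return reads


def write_matrix(df: pd.DataFrame, path: str | Path, index_label: str = "feature_id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_matrix(path: str | Path) -> pd.DataFrame:
    # round_trip parsing so written matrices reload bit-identically
    return pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
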