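import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from circseq.annotation import Gene, GeneModel
from circseq.circdetect import (
    AnchorIndex,
    CircRecord,
    FilterThresholds,
    JunctionCandidate,
    aggregate_candidates,
    annotate_catalog,
    annotate_origin,
    detect_junctions,
    filter_reliable,
    read_catalog,
    summarize_catalog,
    write_catalog,
)
from circseq.simdata import SimRead, revcomp


def _random_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


# ---------------------------------------------------------------------------
# detection


def test_colinear_read_yields_no_candidate():
    rng = np.random.default_rng(0)
    genome = {"chr1": _random_seq(rng, 5000)}
    reads = [
        SimRead("fwd", "s1", genome["chr1"][1000:1100]),
        SimRead("rev", "s1", revcomp(genome["chr1"][2000:2100])),
    ]
    assert detect_junctions(reads, genome) == []


def _clear_coords(seq, s, e):
    """Advance the end until the junction cannot slide (unique closure)."""
    while seq[s] == seq[e] or seq[s - 1] == seq[e - 1]:
        e += 1
    return s, e


def test_planted_junction_recovered_at_exact_coordinates():
    rng = np.random.default_rng(1)
    genome = {"chr1": _random_seq(rng, 5000)}
    seq = genome["chr1"]
    s, e = _clear_coords(seq, 1000, 1800)
    read = seq[e - 50 : e] + seq[s : s + 50]
    cands = detect_junctions([SimRead("jr", "s1", read)], genome)
    assert len(cands) == 1
    c = cands[0]
    assert (c.chrom, c.strand, c.start, c.end) == ("chr1", "+", s, e)
    assert c.edit == 0 and c.breakpoint == 1 and c.anchor_overlap == 0
    assert c.qual_a == 40 and c.qual_b == 40


def test_minus_strand_junction_reported_in_genome_coordinates():
    rng = np.random.default_rng(2)
    genome = {"chr1": _random_seq(rng, 5000)}
    seq = genome["chr1"]
    s, e = _clear_coords(seq, 900, 2100)
    plus_chimera = seq[e - 40 : e] + seq[s : s + 60]
    cands = detect_junctions([SimRead("jr", "s1", revcomp(plus_chimera))], genome)
    assert len(cands) == 1
    c = cands[0]
    assert (c.strand, c.start, c.end) == ("-", s, e)


def _brute_force_closures(read, seq, p1, p2, k):
    """Enumerate breakpoints b that close the junction, per definition:
    positions of minimal total mismatch between both extensions."""
    L = len(read)
    edits = {}
    for b in range(k, L - k + 1):
        left = sum(a != c for a, c in zip(read[k:b], seq[p1 + k : p1 + b]))
        right = sum(
            a != c
            for a, c in zip(read[b : L - k], seq[p2 - (L - k - b) : p2])
        )
        edits[b] = left + right
    m = min(edits.values())
    return sorted(b for b, v in edits.items() if v == m), m


def test_ambiguous_junction_counts_two_breakpoints():
    """When the base after the junction equals the base entering it the
    closure can slide by one; the detector must report breakpoint = 2 and the
    count must match brute-force enumeration of closures."""
    rng = np.random.default_rng(3)
    genome_list = list(_random_seq(rng, 5000))
    s, e = 1200, 2600
    genome_list[e] = genome_list[s]  # make the +1 shift close as well
    if genome_list[e - 1] == genome_list[s - 1]:  # keep exactly one ambiguity
        genome_list[e - 1] = next(b for b in "ACGT" if b != genome_list[s - 1])
    genome = {"chr1": "".join(genome_list)}
    seq = genome["chr1"]
    read = seq[e - 50 : e] + seq[s : s + 50]
    cands = detect_junctions([SimRead("jr", "s1", read)], genome)
    assert len(cands) == 1
    k = 20
    p1 = seq.find(read[:k])
    p2 = seq.find(read[-k:])
    closures, min_edit = _brute_force_closures(read, seq, p1, p2, k)
    assert min_edit == 0 and len(closures) == 2
    assert cands[0].breakpoint == len(closures)


def test_mismatched_read_reports_edit_distance():
    rng = np.random.default_rng(4)
    genome = {"chr1": _random_seq(rng, 5000)}
    seq = genome["chr1"]
    s, e = _clear_coords(seq, 800, 1900)
    read = list(seq[e - 50 : e] + seq[s : s + 50])
    read[30] = next(b for b in "ACGT" if b != read[30])  # interior of left extension
    cands = detect_junctions([SimRead("jr", "s1", "".join(read))], genome)
    assert len(cands) == 1
    assert cands[0].edit == 1
    assert (cands[0].start, cands[0].end) == (s, e)


def test_short_reads_skipped_and_empty_genome_rejected():
    rng = np.random.default_rng(5)
    genome = {"chr1": _random_seq(rng, 1000)}
    assert detect_junctions([SimRead("r", "s1", "ACGT" * 5)], genome) == []
    with pytest.raises(ValueError):
        detect_junctions([], {})
    with pytest.raises(ValueError):
        detect_junctions([], genome, anchor_len=8)


def test_detection_on_planted_benchmark_is_exact(detection_setup):
    """Error-free reads with >= 5 unique reads per junction: precision and
    recall both 1.0 at exact coordinates."""
    cfg, genome, model, truth, reads = detection_setup
    cands = detect_junctions(reads, genome)
    records = aggregate_candidates(cands, cfg.samples())
    detected = {(r.chrom, r.strand, r.start, r.end) for r in records}
    planted = {(r.chrom, r.strand, r.start, r.end) for r in truth.records}
    assert detected == planted


# ---------------------------------------------------------------------------
# aggregation


def _cand(read_id, sample, start=100, end=600, **kw):
    base = dict(
        chrom="chr1", strand="+", breakpoint=1, anchor_overlap=0, edit=0,
        qual_a=40, qual_b=40,
    )
    base.update(kw)
    return JunctionCandidate(read_id=read_id, start=start, end=end, sample_id=sample, **base)


def test_aggregate_empty_is_empty():
    assert aggregate_candidates([], ["s1"]) == []


def test_aggregate_conserves_reads_across_samples():
    cands = [_cand(f"r{i}", s) for i, s in enumerate(["s1", "s1", "s2", "s3", "s3"])]
    (rec,) = aggregate_candidates(cands, ["s1", "s2", "s3"])
    assert rec.counts == {"s1": 2, "s2": 1, "s3": 2}
    assert rec.total_reads == 5
    assert rec.n_uniq == 5


def test_duplicate_read_ids_counted_once_in_n_uniq():
    cands = [_cand("dup", "s1"), _cand("dup", "s1"), _cand("r2", "s2")]
    (rec,) = aggregate_candidates(cands, ["s1", "s2"])
    assert rec.n_uniq == 2
    assert rec.total_reads == 3


def test_aggregate_takes_worst_breakpoint_and_best_quality():
    cands = [
        _cand("r1", "s1", breakpoint=1, edit=2, qual_a=10, qual_b=40),
        _cand("r2", "s1", breakpoint=3, edit=0, qual_a=40, qual_b=5),
    ]
    (rec,) = aggregate_candidates(cands, ["s1"])
    assert rec.breakpoint == 3
    assert rec.edit == 0
    assert (rec.best_qual_a, rec.best_qual_b) == (40, 40)


# ---------------------------------------------------------------------------
# reliability filter


def _record(**kw):
    base = dict(
        circ_id="c1", chrom="chr1", strand="+", start=0, end=500,
        breakpoint=1, anchor_overlap=2, edit=2, n_uniq=3,
        best_qual_a=36, best_qual_b=0,
    )
    base.update(kw)
    return CircRecord(**base)


def test_filter_keeps_record_on_all_boundaries():
    # every clause is exactly on its passing boundary
    kept = filter_reliable([_record()], n_samples=4)
    assert len(kept) == 1


@pytest.mark.parametrize(
    "change",
    [
        dict(breakpoint=2),
        dict(anchor_overlap=3),
        dict(edit=3),
        dict(n_uniq=2),
        dict(best_qual_a=35, best_qual_b=35),
        dict(end=100_000),
    ],
)
def test_filter_rejects_single_clause_violations(change):
    assert filter_reliable([_record(**change)], n_samples=4) == []


def test_filter_half_samples_clause_uses_floor():
    rec = _record(n_uniq=3)
    # floor(6/2) = 3 and the clause is strict, so n_uniq = 3 fails at 6 samples
    assert filter_reliable([rec], n_samples=6) == []
    assert filter_reliable([rec], n_samples=5) == [rec]  # 3 > floor(5/2) = 2


def test_filter_rejects_negative_fields():
    with pytest.raises(ValueError, match="negative"):
        filter_reliable([_record(edit=-1)], n_samples=4)


def _random_records(rng, n):
    recs = []
    for i in range(n):
        start = int(rng.integers(0, 1000))
        recs.append(
            CircRecord(
                circ_id=f"c{i}", chrom="chr1", strand="+",
                start=start, end=start + int(rng.integers(1, 200_000)),
                breakpoint=int(rng.integers(1, 4)),
                anchor_overlap=int(rng.integers(0, 5)),
                edit=int(rng.integers(0, 5)),
                n_uniq=int(rng.integers(0, 8)),
                best_qual_a=int(rng.integers(0, 41)),
                best_qual_b=int(rng.integers(0, 41)),
            )
        )
    return recs


def test_filter_matches_clause_by_clause_oracle():
    """1,000 randomized records against an independent re-evaluation of the
    printed clauses."""
    rng = np.random.default_rng(42)
    records = _random_records(rng, 1000)
    n_samples = 6
    kept = filter_reliable(records, n_samples)
    oracle = [
        r
        for r in records
        if r.breakpoint == 1
        and r.anchor_overlap <= 2
        and r.edit <= 2
        and r.n_uniq > 2
        and (r.best_qual_a > 35 or r.best_qual_b > 35)
        and r.n_uniq > n_samples // 2
        and (r.end - r.start) < 100_000
    ]
    assert [r.circ_id for r in kept] == [r.circ_id for r in oracle]


@given(
    max_overlap=st.integers(0, 4),
    max_edit=st.integers(0, 4),
    min_uniq=st.integers(0, 7),
    min_qual=st.integers(30, 40),
    max_len=st.integers(1_000, 200_000),
    seed=st.integers(0, 5),
)
@settings(max_examples=60, deadline=None, derandomize=True)
def test_filter_monotone_under_tightening(max_overlap, max_edit, min_uniq, min_qual, max_len, seed):
    """Tightening any single threshold never increases the survivor count."""
    rng = np.random.default_rng(seed)
    records = _random_records(rng, 120)
    base = FilterThresholds(
        max_anchor_overlap=max_overlap, max_edit=max_edit, min_n_uniq=min_uniq,
        min_qual=min_qual, max_length=max_len,
    )
    n_base = len(filter_reliable(records, 4, base))
    tighter = [
        FilterThresholds(max_anchor_overlap=max(0, max_overlap - 1), max_edit=max_edit,
                         min_n_uniq=min_uniq, min_qual=min_qual, max_length=max_len),
        FilterThresholds(max_anchor_overlap=max_overlap, max_edit=max(0, max_edit - 1),
                         min_n_uniq=min_uniq, min_qual=min_qual, max_length=max_len),
        FilterThresholds(max_anchor_overlap=max_overlap, max_edit=max_edit,
                         min_n_uniq=min_uniq + 1, min_qual=min_qual, max_length=max_len),
        FilterThresholds(max_anchor_overlap=max_overlap, max_edit=max_edit,
                         min_n_uniq=min_uniq, min_qual=min_qual + 1, max_length=max_len),
        FilterThresholds(max_anchor_overlap=max_overlap, max_edit=max_edit,
                         min_n_uniq=min_uniq, min_qual=min_qual, max_length=max_len // 2),
    ]
    for th in tighter:
        assert len(filter_reliable(records, 4, th)) <= n_base


# ---------------------------------------------------------------------------
# origin classification


@pytest.fixture
def gene_model():
    return GeneModel(
        [
            Gene("gA", "chr1", "+", ((100, 200), (300, 400), (500, 650))),
            Gene("gB", "chr1", "+", ((2000, 2200), (2500, 2700))),
        ]
    )


def test_span_with_no_gene_is_intergenic(gene_model):
    rec = annotate_origin(_record(start=5000, end=5600), gene_model)
    assert rec.origin == "intergenic" and rec.host_gene is None
    assert rec.spliced_length == 600


def test_exon_bounded_span_is_exonic_with_spliced_length(gene_model):
    rec = annotate_origin(_record(start=300, end=650), gene_model)
    assert rec.origin == "exonic" and rec.host_gene == "gA"
    assert rec.spliced_length == (400 - 300) + (650 - 500)


def test_strand_mismatch_blocks_exonic_call(gene_model):
    rec = annotate_origin(_record(start=300, end=650, strand="-"), gene_model)
    assert rec.origin == "intronic"  # inside gA's span but wrong strand


def test_span_inside_intron_is_intronic(gene_model):
    rec = annotate_origin(_record(start=210, end=290), gene_model)
    assert rec.origin == "intronic" and rec.host_gene == "gA"


def test_span_crossing_two_genes_resolves_by_largest_overlap(gene_model):
    rec = annotate_origin(_record(start=600, end=2100), gene_model)
    assert rec.origin == "intronic"
    assert rec.host_gene == "gB"  # 100 nt overlap with gB vs 50 with gA


def test_summary_partitions_catalog(detection_setup):
    cfg, genome, model, truth, reads = detection_setup
    cands = detect_junctions(reads, genome)
    records = aggregate_candidates(cands, cfg.samples())
    annotated = annotate_catalog(filter_reliable(records, len(cfg.samples())), model)
    summary = summarize_catalog(annotated)
    assert summary["per_chromosome"]["n_circ"].sum() == len(annotated)
    assert summary["per_origin"]["count"].sum() == len(annotated)
    assert summary["per_origin"]["fraction"].sum() == pytest.approx(1.0)
    # origins recomputed independently agree
    truth_origin = {
        (r.chrom, r.strand, r.start, r.end): r.origin for r in truth.records
    }
    for rec in annotated:
        assert truth_origin[(rec.chrom, rec.strand, rec.start, rec.end)] == rec.origin


def test_catalog_round_trip(tmp_path, gene_model):
    records = [
        annotate_origin(_record(start=300, end=650, counts={"s1": 3, "s2": 0}), gene_model),
        annotate_origin(_record(circ_id="c2", start=5000, end=5600, counts={"s1": 0, "s2": 2}), gene_model),
    ]
    write_catalog(records, tmp_path / "cat.tsv")
    back = read_catalog(tmp_path / "cat.tsv")
    assert [vars(r) for r in back] == [vars(r) for r in records]
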