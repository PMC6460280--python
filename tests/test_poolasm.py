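"""Read screening, greedy assembly, and assembly statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fostag.core import SeqRecord, revcomp
from fostag.poolasm import (
    AssemblyStats,
    Contig,
    ScreenParams,
    assembly_stats,
    greedy_assemble,
    mean_contig_size,
    screen_reads,
    theoretical_coverage,
)
from fostag.simlib import random_dna


# --- screening -------------------------------------------------------------

def test_exact_vector_substring_removed(rng):
    vector = SeqRecord("vec", random_dna(rng, 2000))
    read = SeqRecord("r1", vector.residues[300:500])
    kept, removed, report = screen_reads([read], [vector])
    assert [r.id for r in removed] == ["r1"] and not kept
    assert report[0].verdict == "removed"
    assert report[0].read_coverage == 1.0


def test_half_covered_read_kept(rng):
    vector = SeqRecord("vec", random_dna(rng, 2000))
    # 100 nt of vector + 100 nt of unrelated sequence: coverage 0.5 < 0.7
    read = SeqRecord("r1", vector.residues[300:400] + random_dna(rng, 100))
    kept, removed, report = screen_reads([read], [vector])
    assert [r.id for r in kept] == ["r1"] and not removed
    assert report[0].read_coverage < 0.7


def test_reverse_complement_vector_read_removed(rng):
    vector = SeqRecord("vec", random_dna(rng, 2000))
    read = SeqRecord("r1", revcomp(vector.residues[100:420]))
    _, removed, _ = screen_reads([read], [vector])
    assert [r.id for r in removed] == ["r1"]


def test_screen_partitions_input(small_pool, vector_ref):
    kept, removed, report = screen_reads(small_pool.reads, vector_ref)
    assert len(kept) + len(removed) == len(small_pool.reads)
    assert not ({r.id for r in kept} & {r.id for r in removed})
    assert len(report) == len(small_pool.reads)


def test_screen_agrees_with_truth_labels(small_pool, vector_ref):
    """Removal decisions match the manifest's vector fraction.

    Decision equality is exact away from the 70% boundary; junction reads
    within a few nt of the cutoff may flip either way because a local
    alignment can extend a base or two past the vector-insert junction by
    chance, so a ±5 nt/read-length band is quantization, not error.
    """
    kept, removed, _ = screen_reads(small_pool.reads, vector_ref)
    removed_ids = {r.id for r in removed}
    threshold = 0.70
    flips = 0
    for o in small_pool.manifest.reads.values():
        band = 5.0 / o.length
        if abs(o.vector_fraction - threshold) <= band:
            flips += (o.read_id in removed_ids) != (o.vector_fraction >= threshold)
            continue
        assert (o.read_id in removed_ids) == (o.vector_fraction >= threshold)
    # no majority-insert read is ever removed, no mostly-vector read kept
    assert all(
        small_pool.manifest.reads[rid].vector_fraction >= 0.5 for rid in removed_ids
    )


def test_screen_empty_reads():
    kept, removed, report = screen_reads([], [SeqRecord("vec", "ACGT" * 100)])
    assert kept == [] and removed == [] and report == []


def test_screen_requires_refs():
    with pytest.raises(ValueError):
        screen_reads([SeqRecord("r", "ACGT")], [])


# --- greedy assembly -------------------------------------------------------

def test_two_overlapping_reads_merge(rng):
    a = random_dna(rng, 150)
    b = a[-50:] + random_dna(rng, 100)
    contigs = greedy_assemble([SeqRecord("a", a), SeqRecord("b", b)], min_overlap=50)
    assert len(contigs) == 1
    assert len(contigs[0]) == 150 + 150 - 50
    assert contigs[0].residues == a + b[50:]


def test_disjoint_reads_stay_separate(rng):
    contigs = greedy_assemble(
        [SeqRecord("a", random_dna(rng, 200)), SeqRecord("b", random_dna(rng, 180))]
    )
    assert sorted(len(c) for c in contigs) == [180, 200]


def test_zero_reads_zero_contigs():
    assert greedy_assemble([]) == []


def test_single_clone_contigs_cover_insert(small_pool, vector_ref):
    """At ≥8× error-free coverage, contigs jointly cover ≥95% of the insert."""
    clone = small_pool.clones[0]
    reads = [
        r for r in small_pool.reads
        if small_pool.manifest.reads[r.id].clone_id == clone.clone_id
        and small_pool.manifest.reads[r.id].vector_fraction < 0.70
    ]
    contigs = greedy_assemble(reads)
    doubled = clone.circular_sequence * 2
    covered = np.zeros(len(clone.insert), dtype=bool)
    ins_s, _ = clone.insert_span
    for c in contigs:
        for s in (c.residues, revcomp(c.residues)):
            pos = doubled.find(s)
            if pos >= 0:
                lo = max(0, pos - ins_s)
                hi = min(len(covered), pos + len(s) - ins_s)
                if hi > lo:
                    covered[lo:hi] = True
    assert covered.mean() >= 0.95


def test_assembly_is_deterministic(small_pool, vector_ref, tmp_path):
    from fostag.core import write_fasta

    kept, _, _ = screen_reads(small_pool.reads, vector_ref)
    subset = kept[:800]
    out = []
    for name in ("x", "y"):
        contigs = greedy_assemble(subset)
        p = tmp_path / f"{name}.fasta"
        write_fasta([SeqRecord(c.contig_id, c.residues) for c in contigs], p)
        out.append(p.read_bytes())
    assert out[0] == out[1]


# --- statistics ------------------------------------------------------------

def _stats_from_lengths(lengths, rng):
    return assembly_stats([Contig(f"c{i}", random_dna(rng, L)) for i, L in enumerate(lengths)])


def test_stats_direct_enumeration(rng):
    st_ = _stats_from_lengths([5, 4, 3, 2, 1], rng)
    assert st_.total_nt == 15
    assert st_.n50_nt == 4  # 5+4 = 9 >= 7.5
    assert st_.l50_count == 2
    assert st_.mean_nt == 3


def test_stats_single_contig(rng):
    st_ = _stats_from_lengths([1234], rng)
    assert st_.n50_nt == 1234 and st_.l50_count == 1 and st_.longest_nt == 1234


def test_stats_size_class_counts(rng):
    st_ = _stats_from_lengths([15000, 10000, 1001, 1000, 120], rng)
    assert st_.n_gt_10kb == 1  # strictly greater
    assert st_.n_gt_1kb == 3


def test_mean_contig_size_rounds_half_away_from_zero():
    assert mean_contig_size(2853727, 3811) == 749
    assert mean_contig_size(15, 15) == 1
    assert mean_contig_size(3, 2) == 2  # 1.5 rounds up


def test_stats_empty_errors():
    with pytest.raises(ValueError):
        assembly_stats([])


def n50_l50_oracle(lengths):
    """Brute-force cumulative-sum reference."""
    ls = sorted(lengths, reverse=True)
    total = sum(ls)
    for i in range(len(ls)):
        if sum(ls[: i + 1]) >= total / 2:
            return ls[i], i + 1
    raise AssertionError("unreachable")


@given(st.lists(st.integers(min_value=1, max_value=10000), min_size=1, max_size=60))
@settings(derandomize=True, max_examples=300)
def test_n50_l50_match_bruteforce_oracle(lengths):
    contigs = [Contig(f"c{i}", "A" * L) for i, L in enumerate(lengths)]
    st_ = assembly_stats(contigs)
    n50, l50 = n50_l50_oracle(lengths)
    assert (st_.n50_nt, st_.l50_count) == (n50, l50)


# --- theoretical coverage --------------------------------------------------

def test_theoretical_coverage_examples():
    assert theoretical_coverage(100, 100, 1, 10000) == pytest.approx(1.0)
    cov = theoretical_coverage(135103, 369, 40, 44000)
    assert cov == pytest.approx(28.3, abs=0.05)  # "nearly 30X"
    with pytest.raises(ValueError):
        theoretical_coverage(100, 100, 0, 10000)
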