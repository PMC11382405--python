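"""SV and SNV calling from pairwise assembly alignment anchors.

Structural variants of 50-10,000 bp are classified purely from the geometry
of the gap between consecutive unique alignment anchors.  With Gr the
reference-side gap and Gq the query-side gap between two anchors on the same
chromosome pair and strand:

    insertion            Gr >= 0 and Gq > Gr
    deletion             Gq >= 0 and Gr > Gq
    tandem_expansion     Gr < 0 <= Gq
    tandem_contraction   Gq < 0 <= Gr
    repeat_expansion     Gr < 0, Gq < 0, |Gr| > |Gq|
    repeat_contraction   Gr < 0, Gq < 0, |Gq| > |Gr|

and the event size is |Gq - Gr|.  SNVs come from column-wise comparison of
the gapless alignment each anchor implies; hits inside a repeat mask are
flagged and excluded from counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np

from .seqio import AlignmentBlock, Assembly
from .telocent import reverse_complement

SV_TYPES = ("insertion", "deletion", "tandem_expansion", "tandem_contraction",
            "repeat_expansion", "repeat_contraction")


@dataclass(frozen=True)
class SVRecord:
    ref_chrom: str
    ref_start: int
    ref_end: int
    sv_type: str
    size: int
    qry_chrom: str
    qry_start: int
    qry_end: int


@dataclass(frozen=True)
class SNVRecord:
    ref_chrom: str
    ref_pos: int
    ref_base: str
    qry_base: str
    in_repeat: bool = False


@dataclass(frozen=True)
class PairwiseSummary:
    assembly_a: str
    assembly_b: str
    snv_count: int
    sv_count: int
    sv_total_bp: int


# ---------------------------------------------------------------------------
# SV calling


def classify_anchor_gap(ref_gap: int, qry_gap: int) -> tuple[str | None, int]:
    """Classify one between-anchor gap; returns (sv_type or None, size)."""
    size = abs(qry_gap - ref_gap)
    if size == 0:
        return None, 0
    if ref_gap >= 0 and qry_gap > ref_gap:
        return "insertion", size
    if qry_gap >= 0 and ref_gap > qry_gap:
        return "deletion", size
    if ref_gap < 0 <= qry_gap:
        return "tandem_expansion", size
    if qry_gap < 0 <= ref_gap:
        return "tandem_contraction", size
    if abs(ref_gap) > abs(qry_gap):
        return "repeat_expansion", size
    return "repeat_contraction", size


def call_svs_from_anchors(blocks: Sequence[AlignmentBlock], min_size: int = 50,
                          max_size: int = 10_000, min_anchor: int = 10_000,
                          ) -> list[SVRecord]:
    """Classify SVs from gaps between consecutive unique anchors.

    Anchors shorter than ``min_anchor`` on either coordinate are discarded
    as non-unique.  Consecutive retained anchors sharing reference and query
    chromosome and strand define one candidate gap each; only events with
    ``min_size <= size <= max_size`` are returned.
    """
    kept = [b for b in blocks
            if b.ref_len >= min_anchor and b.qry_len >= min_anchor]
    groups: dict[tuple[str, str, str], list[AlignmentBlock]] = {}
    for b in kept:
        groups.setdefault((b.ref_chrom, b.qry_chrom, b.strand), []).append(b)
    records: list[SVRecord] = []
    for (_, _, strand), group in sorted(groups.items()):
        group.sort(key=lambda b: (b.ref_start, b.ref_end))
        for prev, nxt in zip(group, group[1:]):
            ref_gap = nxt.ref_start - prev.ref_end
            if strand == "+":
                qry_gap = nxt.qry_start - prev.qry_end
                qs, qe = prev.qry_end, nxt.qry_start
            else:
                qry_gap = prev.qry_start - nxt.qry_end
                qs, qe = nxt.qry_end, prev.qry_start
            sv_type, size = classify_anchor_gap(ref_gap, qry_gap)
            if sv_type is None or not min_size <= size <= max_size:
                continue
            records.append(SVRecord(
                ref_chrom=prev.ref_chrom,
                ref_start=min(prev.ref_end, nxt.ref_start),
                ref_end=max(prev.ref_end, nxt.ref_start),
                sv_type=sv_type, size=size,
                qry_chrom=prev.qry_chrom,
                qry_start=min(qs, qe), qry_end=max(qs, qe)))
    records.sort(key=lambda r: (r.ref_chrom, r.ref_start, r.ref_end))
    return records


# ---------------------------------------------------------------------------
# SNV calling

_ACGT = frozenset(b"ACGT")


def _merge_intervals(intervals: Iterable[tuple[int, int]]) -> tuple[np.ndarray, np.ndarray]:
    ivs = sorted(intervals)
    starts: list[int] = []
    ends: list[int] = []
    for s, e in ivs:
        if starts and s <= ends[-1]:
            ends[-1] = max(ends[-1], e)
        else:
            starts.append(s)
            ends.append(e)
    return np.array(starts, dtype=np.int64), np.array(ends, dtype=np.int64)


def call_snvs_from_blocks(blocks: Sequence[AlignmentBlock], ref_assembly: Assembly,
                          qry_assembly: Assembly,
                          repeat_mask: Iterable = (),
                          ) -> list[SNVRecord]:
    """Column-wise mismatches inside gapless alignment anchors.

    Blocks must carry equal-length reference and query spans (indel-bearing
    alignments are split into anchors upstream); unequal blocks are skipped
    with a warning.  SNVs inside ``repeat_mask`` intervals (objects or
    tuples with chrom/start/end) are flagged ``in_repeat``.  Duplicate
    records from anchors that re-visit a reference base (tandem anchors)
    are reported once.
    """
    mask_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in repeat_mask:
        chrom, start, end = (iv[0], iv[1], iv[2]) if isinstance(iv, (tuple, list)) \
            else (iv.chrom, iv.start, iv.end)
        mask_by_chrom.setdefault(chrom, []).append((int(start), int(end)))
    merged_mask = {c: _merge_intervals(ivs) for c, ivs in mask_by_chrom.items()}

    seen: set[tuple[str, int, str, str]] = set()
    records: list[SNVRecord] = []
    for b in blocks:
        if b.ref_len != b.qry_len:
            warnings.warn(
                f"skipping anchor with unequal span lengths "
                f"({b.ref_chrom}:{b.ref_start}-{b.ref_end} vs "
                f"{b.qry_chrom}:{b.qry_start}-{b.qry_end}); split indel anchors upstream")
            continue
        ref_seq = ref_assembly.chromosomes[b.ref_chrom][b.ref_start:b.ref_end]
        qry_seq = qry_assembly.chromosomes[b.qry_chrom][b.qry_start:b.qry_end]
        if b.strand == "-":
            qry_seq = reverse_complement(qry_seq)
        r = np.frombuffer(ref_seq.encode(), dtype=np.uint8)
        q = np.frombuffer(qry_seq.encode(), dtype=np.uint8)
        valid = np.isin(r, list(_ACGT)) & np.isin(q, list(_ACGT))
        diff = np.flatnonzero((r != q) & valid)
        if diff.size == 0:
            continue
        starts_ends = merged_mask.get(b.ref_chrom)
        for off in diff:
            pos = b.ref_start + int(off)
            key = (b.ref_chrom, pos, chr(r[off]), chr(q[off]))
            if key in seen:
                continue
            seen.add(key)
            in_rep = False
            if starts_ends is not None:
                i = np.searchsorted(starts_ends[0], pos, side="right") - 1
                in_rep = i >= 0 and pos < starts_ends[1][i]
            records.append(SNVRecord(b.ref_chrom, pos, chr(r[off]), chr(q[off]), in_rep))
    records.sort(key=lambda s: (s.ref_chrom, s.ref_pos))
    return records


def snv_count(records: Iterable[SNVRecord], include_repeats: bool = False) -> int:
    return sum(1 for r in records if include_repeats or not r.in_repeat)


# ---------------------------------------------------------------------------
# Divergence and sharing


def divergence_percent(snv_count: int, sv_total_bp: int, genome_length_bp: int) -> float:
    """Percent divergence: 100 x (SNV count + SV bases) / genome length."""
    if genome_length_bp <= 0:
        raise ValueError("genome_length_bp must be positive")
    if snv_count < 0 or sv_total_bp < 0:
        raise ValueError("counts must be non-negative")
    return 100.0 * (snv_count + sv_total_bp) / genome_length_bp


def _reciprocal_overlap(a: SVRecord, b: SVRecord) -> float:
    la, lb = a.ref_end - a.ref_start, b.ref_end - b.ref_start
    if la == 0 or lb == 0:  # point events (pure insertions): match by breakpoint
        return 1.0 if (a.ref_start == b.ref_start and la == lb
                       and a.size == b.size) else 0.0
    inter = min(a.ref_end, b.ref_end) - max(a.ref_start, b.ref_start)
    if inter <= 0:
        return 0.0
    return min(inter / la, inter / lb)


def sv_sharing_counts(sv_sets: Mapping[str, Sequence[SVRecord]],
                      reciprocal_overlap: float = 0.5,
                      same_type: bool = True) -> dict[frozenset, int]:
    """Intersection counts of SV sets called against one shared reference.

    Two SVs from different assemblies match when they have the same type
    (if ``same_type``) and reciprocal overlap >= threshold on reference
    coordinates; insertions, which occupy a reference point, match on
    identical breakpoint and size.  Matching records are clustered by
    transitive closure and each cluster is assigned to exactly one subset:
    the full set of assemblies it spans.  Returns counts per subset
    (keys are frozensets of assembly names).
    """
    items: list[tuple[str, SVRecord]] = [
        (name, sv) for name, svs in sv_sets.items() for sv in svs]
    parent = list(range(len(items)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    by_chrom: dict[str, list[int]] = {}
    for idx, (_, sv) in enumerate(items):
        by_chrom.setdefault(sv.ref_chrom, []).append(idx)
    for idxs in by_chrom.values():
        idxs.sort(key=lambda i: items[i][1].ref_start)
        for ai, bi in combinations(idxs, 2):
            (name_a, a), (name_b, b) = items[ai], items[bi]
            if name_a == name_b:
                continue
            if b.ref_start > a.ref_end:
                continue  # sorted by start: no overlap, and breakpoints differ
            if same_type and a.sv_type != b.sv_type:
                continue
            if _reciprocal_overlap(a, b) >= reciprocal_overlap:
                union(ai, bi)

    clusters: dict[int, set[str]] = {}
    for idx, (name, _) in enumerate(items):
        clusters.setdefault(find(idx), set()).add(name)
    counts: dict[frozenset, int] = {}
    for members in clusters.values():
        key = frozenset(members)
        counts[key] = counts.get(key, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# Pairwise summary means


def pairwise_summary_means(table: Sequence[PairwiseSummary],
                           group_of: Mapping[str, str],
                           ) -> dict[tuple[str, str], dict[str, float]]:
    """Arithmetic means of SNV counts and SV bp by subspecies pair class.

    ``group_of`` maps assembly name to its type (e.g. swamp/river); pair
    classes are unordered type pairs.  Classes with no pairs are absent
    from the result.
    """
    buckets: dict[tuple[str, str], list[PairwiseSummary]] = {}
    for row in table:
        try:
            ga, gb = group_of[row.assembly_a], group_of[row.assembly_b]
        except KeyError as exc:
            raise KeyError(f"assembly {exc} missing from group map") from exc
        key = tuple(sorted((ga, gb)))
        buckets.setdefault(key, []).append(row)
    means: dict[tuple[str, str], dict[str, float]] = {}
    for key, rows in sorted(buckets.items()):
        means[key] = {
            "n_pairs": len(rows),
            "snv_mean": float(np.mean([r.snv_count for r in rows])),
            "sv_bp_mean": float(np.mean([r.sv_total_bp for r in rows])),
        }
    return means
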