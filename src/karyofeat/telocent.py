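"""Telomere and centromere localization from sequence and repeat annotations.

Telomeres are located by counting non-overlapping exact occurrences of the
vertebrate hexamer TTAGGG (and its reverse complement CCCTAA) inside the
terminal 20 kb of each chromosome arm; an arm is "kept" only when the unit
count strictly exceeds 50.  Interstitial telomeric arrays -- a classic
misassembly signature -- are flagged by the same counter run in sliding
windows over the chromosome interior.

Centromeres are localized from Satellite/centr repeat annotations: hits with
>60% identity to consensus are single-linkage grouped whenever adjacent hits
lie less than 1 Mb apart, and the cluster with the most repeats on each
chromosome becomes the centromere candidate.  Known satellite monomers
(e.g. the 673-bp and 1,404-bp water buffalo units) are copy-counted by tiling
the candidate span at the monomer period.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .seqio import Assembly, RepeatAnnotation

TELOMERE_MOTIF = "TTAGGG"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TelomereSignal:
    chrom: str
    arm: Literal["p", "q"]
    window_start: int
    window_end: int
    unit_count: int
    kept: bool


@dataclass(frozen=True)
class MorphologyCall:
    chrom: str
    call: Literal["sub_metacentric", "acrocentric_like", "undetermined"]
    basis: str


@dataclass(frozen=True)
class InternalTelomereFlag:
    """Merged interior window(s) whose telomere unit count exceeds threshold."""

    chrom: str
    start: int
    end: int
    unit_count: int


@dataclass
class RepeatCluster:
    chrom: str
    start: int
    end: int
    members: list[RepeatAnnotation] = field(repr=False, default_factory=list)

    @property
    def n_repeats(self) -> int:
        return len(self.members)

    @property
    def total_bp(self) -> int:
        return sum(m.length for m in self.members)

    @property
    def families(self) -> dict[str, int]:
        fam: dict[str, int] = {}
        for m in self.members:
            fam[m.family] = fam.get(m.family, 0) + m.length
        return fam

    @property
    def dominant_family(self) -> str:
        fams = self.families
        return max(sorted(fams), key=fams.__getitem__)


@dataclass(frozen=True)
class CentromereCandidate:
    chrom: str
    start: int
    end: int
    n_repeats: int
    total_bp: int
    dominant_family: str


# ---------------------------------------------------------------------------
# Telomere counting


def count_motif_units(seq: str, motif: str = TELOMERE_MOTIF,
                      both_strands: bool = True) -> int:
    """Non-overlapping exact occurrences of motif (+ reverse complement)."""
    if not motif:
        raise ValueError("motif must be nonempty")
    total = _count_nonoverlapping(seq, motif)
    rc = reverse_complement(motif)
    if both_strands and rc != motif:
        total += _count_nonoverlapping(seq, rc)
    return total


def _count_nonoverlapping(seq: str, motif: str) -> int:
    count = 0
    i = seq.find(motif)
    while i != -1:
        count += 1
        i = seq.find(motif, i + len(motif))
    return count


def count_terminal_motif_units(seq: str, motif: str = TELOMERE_MOTIF,
                               window: int = 20_000, arm: Literal["p", "q"] = "p",
                               both_strands: bool = True) -> int:
    """Count telomeric units in the terminal ``window`` bp of one arm.

    The p-arm window is the first ``window`` bp of the forward strand, the
    q-arm window the last.  A chromosome shorter than the window is scanned
    in full; shorter than the motif yields 0.
    """
    if window < len(motif):
        raise ValueError(f"window {window} shorter than motif {motif!r}")
    if len(seq) < len(motif):
        return 0
    region = seq[:window] if arm == "p" else seq[-window:]
    return count_motif_units(region, motif, both_strands=both_strands)


def call_telomeres(assembly: Assembly, motif: str = TELOMERE_MOTIF,
                   window: int = 20_000, min_units: int = 50,
                   both_strands: bool = True,
                   ) -> tuple[list[TelomereSignal], list[MorphologyCall]]:
    """Per-arm telomere signals and per-chromosome morphology calls.

    An arm is kept iff its unit count is strictly greater than ``min_units``.
    Chromosomes with both arms kept are called sub-metacentric; a kept q-arm
    with an empty p-arm is the acrocentric-like pattern; anything else is
    undetermined.
    """
    signals: list[TelomereSignal] = []
    morphology: list[MorphologyCall] = []
    for chrom in sorted(assembly.chromosomes):
        seq = assembly.chromosomes[chrom]
        n = len(seq)
        kept_arms: dict[str, bool] = {}
        for arm in ("p", "q"):
            units = count_terminal_motif_units(seq, motif, window, arm,
                                               both_strands=both_strands)
            ws, we = (0, min(window, n)) if arm == "p" else (max(0, n - window), n)
            kept = units > min_units
            kept_arms[arm] = kept
            signals.append(TelomereSignal(chrom, arm, ws, we, units, kept))
        if kept_arms["p"] and kept_arms["q"]:
            call, basis = "sub_metacentric", "p+q"
        elif kept_arms["q"] and not kept_arms["p"]:
            call, basis = "acrocentric_like", "q"
        else:
            call, basis = "undetermined", "p" if kept_arms["p"] else "none"
        morphology.append(MorphologyCall(chrom, call, basis))
    return signals, morphology


def total_kept_units(signals: Iterable[TelomereSignal]) -> int:
    return sum(s.unit_count for s in signals if s.kept)


def scan_internal_telomere_signals(seq: str, chrom: str = "",
                                   motif: str = TELOMERE_MOTIF,
                                   window: int = 20_000, step: int = 10_000,
                                   min_units: int = 50,
                                   end_exclusion: int = 20_000,
                                   ) -> list[InternalTelomereFlag]:
    """Sliding-window scan for interstitial telomeric arrays.

    Windows overlapping the terminal ``end_exclusion`` bp are skipped so that
    genuine terminal telomeres do not flag.  Overlapping or adjacent flagged
    windows are merged and the merged span recounted.
    """
    n = len(seq)
    if n <= 2 * end_exclusion:
        raise ValueError(f"sequence length {n} <= 2 x end_exclusion {end_exclusion}")
    hits: list[tuple[int, int]] = []
    start = end_exclusion
    while start + window <= n - end_exclusion:
        units = count_motif_units(seq[start:start + window], motif)
        if units > min_units:
            hits.append((start, start + window))
        start += step
    # final partial window flush against the exclusion zone
    if start < n - end_exclusion and (n - end_exclusion) - start >= len(motif):
        span = (start, n - end_exclusion)
        if count_motif_units(seq[span[0]:span[1]], motif) > min_units:
            hits.append(span)
    flags: list[InternalTelomereFlag] = []
    for s, e in hits:
        if flags and s <= flags[-1].end:
            merged = (flags[-1].start, max(flags[-1].end, e))
            flags[-1] = InternalTelomereFlag(
                chrom, *merged, count_motif_units(seq[merged[0]:merged[1]], motif))
        else:
            flags.append(InternalTelomereFlag(chrom, s, e,
                                              count_motif_units(seq[s:e], motif)))
    return flags


# ---------------------------------------------------------------------------
# Satellite clustering


def filter_satellite_annotations(annotations: Sequence[RepeatAnnotation],
                                 min_identity_pct: float = 60.0,
                                 class_filter: str = "Satellite/centr",
                                 ) -> list[RepeatAnnotation]:
    """Keep annotations of ``class_filter`` with identity strictly > threshold."""
    return [a for a in annotations
            if a.repeat_class == class_filter
            and (100.0 - a.divergence_pct) > min_identity_pct]


def cluster_satellites(annotations: Sequence[RepeatAnnotation],
                       max_gap: int = 1_000_000) -> dict[str, list[RepeatCluster]]:
    """Single-linkage grouping of repeats less than ``max_gap`` apart.

    Gap is measured end-to-start between consecutive repeats sorted by
    position; a gap of exactly ``max_gap`` starts a new cluster (strict <).
    """
    by_chrom: dict[str, list[RepeatAnnotation]] = {}
    for a in annotations:
        by_chrom.setdefault(a.chrom, []).append(a)
    clusters: dict[str, list[RepeatCluster]] = {}
    for chrom in sorted(by_chrom):
        members = sorted(by_chrom[chrom], key=lambda a: (a.start, a.end))
        chrom_clusters: list[RepeatCluster] = []
        current: list[RepeatAnnotation] = []
        reach = None  # running max end of the open cluster
        for a in members:
            if current and a.start - reach < max_gap:
                current.append(a)
                reach = max(reach, a.end)
            else:
                if current:
                    chrom_clusters.append(_make_cluster(chrom, current))
                current, reach = [a], a.end
        if current:
            chrom_clusters.append(_make_cluster(chrom, current))
        clusters[chrom] = chrom_clusters
    return clusters


def _make_cluster(chrom: str, members: list[RepeatAnnotation]) -> RepeatCluster:
    return RepeatCluster(chrom=chrom,
                         start=min(m.start for m in members),
                         end=max(m.end for m in members),
                         members=list(members))


def select_centromere_candidates(clusters: dict[str, list[RepeatCluster]],
                                 by: Literal["n_repeats", "total_bp"] = "n_repeats",
                                 ) -> dict[str, CentromereCandidate]:
    """Pick the densest cluster per chromosome as its centromere candidate.

    Selection maximizes repeat-record count by default (``by="total_bp"``
    switches to summed bp); ties break toward larger total_bp, then leftmost.
    """
    candidates: dict[str, CentromereCandidate] = {}
    for chrom, chrom_clusters in clusters.items():
        if not chrom_clusters:
            continue
        if by == "n_repeats":
            key = lambda c: (c.n_repeats, c.total_bp, -c.start)  # noqa: E731
        else:
            key = lambda c: (c.total_bp, c.n_repeats, -c.start)  # noqa: E731
        best = max(chrom_clusters, key=key)
        candidates[chrom] = CentromereCandidate(
            chrom=chrom, start=best.start, end=best.end,
            n_repeats=best.n_repeats, total_bp=best.total_bp,
            dominant_family=best.dominant_family)
    return candidates


def cluster_satellites_and_select_candidates(
        annotations: Sequence[RepeatAnnotation], max_gap: int = 1_000_000,
        by: Literal["n_repeats", "total_bp"] = "n_repeats",
) -> tuple[dict[str, list[RepeatCluster]], dict[str, CentromereCandidate]]:
    clusters = cluster_satellites(annotations, max_gap=max_gap)
    return clusters, select_centromere_candidates(clusters, by=by)


# ---------------------------------------------------------------------------
# Monomer copy counting


def count_monomer_copies(seq: str, monomer_seq: str,
                         max_mismatch_frac: float = 0.1,
                         ) -> tuple[int, tuple[int, int]]:
    """Count consecutive satellite monomer copies in a region by period tiling.

    The region is scanned for a seed position where a monomer-length tile is
    within ``max_mismatch_frac`` Hamming distance of the monomer; tiling then
    proceeds at the monomer period for as long as tiles stay within
    tolerance.  Both strands are tried once and the better array is
    returned as ``(copies, (array_start, array_end))``.
    """
    m = len(monomer_seq)
    if m < 10:
        raise ValueError("monomer must be >= 10 bp")
    if m > len(seq):
        return 0, (0, 0)
    best = (0, (0, 0))
    for mono in (monomer_seq, reverse_complement(monomer_seq)):
        copies, span = _best_tiling(seq, mono, max_mismatch_frac)
        if copies > best[0]:
            best = (copies, span)
    return best


def _best_tiling(seq: str, monomer: str, max_mismatch_frac: float,
                 ) -> tuple[int, tuple[int, int]]:
    m = len(monomer)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    mono = np.frombuffer(monomer.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(arr, m)
    mismatches = (windows != mono).sum(axis=1)
    ok = mismatches <= max_mismatch_frac * m
    if not ok.any():
        return 0, (0, 0)
    accepted = np.flatnonzero(ok)
    accepted_set = set(accepted.tolist())
    best_copies, best_span = 0, (0, 0)
    for s in accepted:
        if s - m in accepted_set:
            continue  # not a run head at this period
        copies, pos = 0, int(s)
        while pos in accepted_set:
            copies += 1
            pos += m
        if copies > best_copies:
            best_copies, best_span = copies, (int(s), int(s) + copies * m)
    return best_copies, best_span


# ---------------------------------------------------------------------------
# Repeat length summaries


def summarize_repeat_lengths(annotations: Sequence[RepeatAnnotation],
                             classes: Sequence[str] = ("LINE/L1", "LINE/RTE-BovB",
                                                       "Satellite/centr"),
                             min_len: int = 2000) -> pd.DataFrame:
    """Per-class distribution of repeat lengths strictly greater than ``min_len``.

    Returns a frame indexed by class with count, total bp, quartiles and
    median; classes with no qualifying record report zero count and NaN
    quantiles.
    """
    rows = []
    for cls in classes:
        lengths = np.array(sorted(a.length for a in annotations
                                  if a.repeat_class == cls and a.length > min_len))
        if lengths.size:
            q1, med, q3 = np.percentile(lengths, [25, 50, 75])
        else:
            q1 = med = q3 = float("nan")
        rows.append({"repeat_class": cls, "n": int(lengths.size),
                     "total_bp": int(lengths.sum()), "q1": q1,
                     "median": med, "q3": q3})
    return pd.DataFrame(rows).set_index("repeat_class")
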