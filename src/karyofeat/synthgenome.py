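"""Synthetic-genome and genotype forge with complete planted truth.

Every downstream stage of the pipeline is verifiable against this module:
it builds toy assemblies with terminal TTAGGG arrays, centromeric satellite
arrays tiled from fixed-length monomers (673 bp and 1,404 bp by default,
matching the two water buffalo centromeric units), decoy satellite clusters,
N-gaps and optional interstitial telomeric arrays; derives a diverged sister
assembly carrying SNVs and 50-10,000 bp SVs with an exact edit script; and
samples two-population diploid genotype matrices with controlled
allele-frequency classes, missingness and QC spoilers.

Everything is deterministic given the seed, and every feature detectable
downstream is recorded in the emitted :class:`TruthSet`.  Terminal windows
of the background sequence are screened so that no chance telomeric hexamer
survives outside a planted array: planted telomere unit counts are exact by
construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .asmdiff import SNVRecord, SVRecord
from .errors import SpecError
from .seqio import (AlignmentBlock, Assembly, GapInterval, GenotypeMatrix,
                    RepeatAnnotation, Site, write_alignment_blocks,
                    write_intervals, write_repeat_annotations)
from .telocent import TELOMERE_MOTIF, reverse_complement

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}

DEFAULT_GC = 0.42  # typical bovid genome-wide GC content


def random_dna(rng: np.random.Generator, n: int, gc: float = DEFAULT_GC) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=n, p=p)].tobytes().decode()


# ---------------------------------------------------------------------------
# Specifications


@dataclass(frozen=True)
class CentromereSpec:
    position: int
    monomer_len: int = 673
    copies: int = 150
    tile_mutation_rate: float = 0.02  # per-base substitution prob within a tile
    family: str | None = None  # default sat.<monomer_len>

    @property
    def span(self) -> tuple[int, int]:
        return self.position, self.position + self.monomer_len * self.copies

    @property
    def family_name(self) -> str:
        return self.family or f"sat.{self.monomer_len}"


@dataclass(frozen=True)
class DecoySpec:
    """A small annotation-only satellite cluster away from the centromere."""

    position: int
    n_repeats: int
    family: str = "BTSAT4"
    unit_len: int = 1000
    spacing: int = 2000  # start-to-start distance of consecutive units

    @property
    def span(self) -> tuple[int, int]:
        return (self.position,
                self.position + (self.n_repeats - 1) * self.spacing + self.unit_len)


@dataclass(frozen=True)
class GapSpec:
    position: int
    length: int


@dataclass(frozen=True)
class ChromosomeSpec:
    name: str
    length: int
    telomere_p_units: int = 0
    telomere_q_units: int = 0
    centromere: CentromereSpec | None = None
    decoys: tuple[DecoySpec, ...] = ()
    gaps: tuple[GapSpec, ...] = ()
    internal_telomeres: tuple[tuple[int, int], ...] = ()  # (position, units)
    other_repeats: tuple[tuple[int, int, str, str], ...] = ()  # (start, len, family, class)


@dataclass(frozen=True)
class SVEvent:
    """One planted structural variant, anchored on reference coordinates.

    ``insertion``: novel sequence of ``size`` bp enters the query at
    reference point ``position``.  ``deletion``: reference bases
    ``[position, position+size)`` are absent from the query.
    ``tandem_expansion``: the query carries the reference segment
    ``[position-size, position)`` twice in a row.
    """

    chrom: str
    position: int
    sv_type: str
    size: int

    def footprint(self) -> tuple[int, int]:
        if self.sv_type == "insertion":
            return self.position, self.position
        if self.sv_type == "deletion":
            return self.position, self.position + self.size
        if self.sv_type == "tandem_expansion":
            return self.position - self.size, self.position
        raise SpecError(f"unsupported planted SV type {self.sv_type!r}")


@dataclass
class TruthSet:
    """Planted ground truth: the acceptance surface for every stage."""

    seed: int | None = None
    telomeres: dict = field(default_factory=dict)           # (chrom, arm) -> units
    internal_telomeres: list = field(default_factory=list)  # (chrom, start, end, units)
    centromeres: dict = field(default_factory=dict)         # chrom -> dict
    gaps: list = field(default_factory=list)                # GapInterval
    decoy_clusters: dict = field(default_factory=dict)      # chrom -> [(start, end, n)]
    annotations: list = field(default_factory=list)         # RepeatAnnotation
    monomers: dict = field(default_factory=dict)            # monomer_len -> sequence
    snvs: list = field(default_factory=list)                # SNVRecord
    svs: list = field(default_factory=list)                 # SVRecord
    blocks: list = field(default_factory=list)              # AlignmentBlock
    genotypes: dict = field(default_factory=dict)           # population-stage truth


# ---------------------------------------------------------------------------
# Chromosome / assembly simulation


def _validate_spec(spec: ChromosomeSpec) -> list[tuple[int, int, str]]:
    """Collect sequence-modifying feature footprints and check disjointness."""
    feats: list[tuple[int, int, str]] = []
    if spec.telomere_p_units:
        feats.append((0, 6 * spec.telomere_p_units, "telomere_p"))
    if spec.telomere_q_units:
        feats.append((spec.length - 6 * spec.telomere_q_units, spec.length, "telomere_q"))
    if spec.centromere:
        feats.append((*spec.centromere.span, "centromere"))
    for g in spec.gaps:
        feats.append((g.position, g.position + g.length, "gap"))
    for pos, units in spec.internal_telomeres:
        feats.append((pos, pos + 6 * units, "internal_telomere"))
    feats.sort()
    for (s, e, n), (s2, e2, n2) in zip(feats, feats[1:]):
        if s2 < e:
            raise SpecError(f"{spec.name}: {n} [{s},{e}) overlaps {n2} [{s2},{e2})")
    for s, e, n in feats:
        if s < 0 or e > spec.length:
            raise SpecError(f"{spec.name}: {n} [{s},{e}) outside [0,{spec.length})")
    for d in spec.decoys:
        s, e = d.span
        if s < 0 or e > spec.length:
            raise SpecError(f"{spec.name}: decoy [{s},{e}) out of bounds")
    return feats


def _screen_terminal_windows(seq: np.ndarray, spec: ChromosomeSpec,
                             rng: np.random.Generator, window: int = 20_000) -> None:
    """Destroy chance telomeric hexamers in terminal windows, in place.

    Planted arrays are left untouched; any other occurrence of the motif or
    its reverse complement inside either terminal window has one base
    substituted until none remain, guaranteeing exact planted unit counts.
    """
    protected = []
    if spec.telomere_p_units:
        protected.append((0, 6 * spec.telomere_p_units))
    if spec.telomere_q_units:
        protected.append((spec.length - 6 * spec.telomere_q_units, spec.length))
    motifs = [TELOMERE_MOTIF.encode(), reverse_complement(TELOMERE_MOTIF).encode()]
    regions = [(0, min(window, len(seq))), (max(0, len(seq) - window), len(seq))]
    for rs, re_ in regions:
        changed = True
        while changed:
            changed = False
            segment = seq[rs:re_].tobytes()
            for motif in motifs:
                i = segment.find(motif)
                while i != -1:
                    abs_start = rs + i
                    inside = any(ps <= abs_start and abs_start + 6 <= pe
                                 for ps, pe in protected)
                    if not inside:
                        # substitute a base of the occurrence lying outside any array
                        for off in range(6):
                            pos = abs_start + off
                            if not any(ps <= pos < pe for ps, pe in protected):
                                old = seq[pos]
                                choices = [b for b in _BASES if b != old]
                                seq[pos] = choices[int(rng.integers(len(choices)))]
                                changed = True
                                break
                    i = segment.find(motif, i + 1)


def _monomer_registry(specs: Sequence[ChromosomeSpec], seed: int) -> dict[int, str]:
    """One random monomer sequence per requested length, shared across chromosomes."""
    lengths = sorted({s.centromere.monomer_len for s in specs if s.centromere})
    registry = {}
    for m in lengths:
        registry[m] = random_dna(np.random.default_rng((seed, m)), m)
    return registry


def simulate_chromosome(spec: ChromosomeSpec, rng: np.random.Generator,
                        monomers: dict[int, str], truth: TruthSet,
                        gc: float = DEFAULT_GC) -> str:
    """Build one chromosome and record its planted features in ``truth``."""
    _validate_spec(spec)
    seq = np.frombuffer(random_dna(rng, spec.length, gc).encode(),
                        dtype=np.uint8).copy()

    def paste(pos: int, s: str) -> None:
        seq[pos:pos + len(s)] = np.frombuffer(s.encode(), dtype=np.uint8)

    if spec.telomere_p_units:
        # p-arm array on the forward strand reads CCCTAA (G-strand points outward)
        paste(0, reverse_complement(TELOMERE_MOTIF) * spec.telomere_p_units)
    if spec.telomere_q_units:
        arr = TELOMERE_MOTIF * spec.telomere_q_units
        paste(spec.length - len(arr), arr)
    truth.telomeres[(spec.name, "p")] = spec.telomere_p_units
    truth.telomeres[(spec.name, "q")] = spec.telomere_q_units

    for pos, units in spec.internal_telomeres:
        paste(pos, TELOMERE_MOTIF * units)
        truth.internal_telomeres.append((spec.name, pos, pos + 6 * units, units))

    if spec.centromere:
        c = spec.centromere
        monomer = monomers[c.monomer_len]
        start, end = c.span
        for i in range(c.copies):
            tile = _mutate(monomer, c.tile_mutation_rate, rng)
            paste(start + i * c.monomer_len, tile)
            truth.annotations.append(RepeatAnnotation(
                chrom=spec.name, start=start + i * c.monomer_len,
                end=start + (i + 1) * c.monomer_len, family=c.family_name,
                repeat_class="Satellite/centr",
                divergence_pct=round(float(rng.uniform(5, 35)), 1)))
        truth.centromeres[spec.name] = {
            "start": start, "end": end, "copies": c.copies,
            "monomer_len": c.monomer_len, "family": c.family_name}

    for d in spec.decoys:
        s, e = d.span
        for i in range(d.n_repeats):
            us = d.position + i * d.spacing
            truth.annotations.append(RepeatAnnotation(
                chrom=spec.name, start=us, end=us + d.unit_len, family=d.family,
                repeat_class="Satellite/centr",
                divergence_pct=round(float(rng.uniform(5, 35)), 1)))
        truth.decoy_clusters.setdefault(spec.name, []).append((s, e, d.n_repeats))

    for start, length, family, repeat_class in spec.other_repeats:
        truth.annotations.append(RepeatAnnotation(
            chrom=spec.name, start=start, end=start + length, family=family,
            repeat_class=repeat_class,
            divergence_pct=round(float(rng.uniform(5, 35)), 1)))

    for g in spec.gaps:
        paste(g.position, "N" * g.length)
        truth.gaps.append(GapInterval(spec.name, g.position, g.position + g.length))

    _screen_terminal_windows(seq, spec, rng)
    return seq.tobytes().decode()


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.flatnonzero(rng.random(arr.size) < rate)
    for pos in hits:
        choices = [b for b in _BASES if b != arr[pos]]
        arr[pos] = choices[int(rng.integers(len(choices)))]
    return arr.tobytes().decode()


def simulate_assembly(specs: Sequence[ChromosomeSpec], name: str = "synthetic_ref",
                      seed: int = 0, gc: float = DEFAULT_GC,
                      ) -> tuple[Assembly, TruthSet]:
    """Simulate a whole assembly; deterministic given (specs, seed)."""
    truth = TruthSet(seed=seed)
    truth.monomers = _monomer_registry(specs, seed)
    rng = np.random.default_rng(seed)
    chromosomes: dict[str, str] = {}
    for spec in specs:
        chromosomes[spec.name] = simulate_chromosome(spec, rng, truth.monomers,
                                                     truth, gc=gc)
    truth.gaps.sort(key=lambda g: (g.chrom, g.start))
    truth.annotations.sort(key=lambda a: (a.chrom, a.start))
    return Assembly(name=name, chromosomes=chromosomes), truth


# ---------------------------------------------------------------------------
# Diverged sister assembly


def derive_diverged_assembly(assembly: Assembly, snv_rate: float,
                             sv_events: Sequence[SVEvent], seed: int,
                             ti_prob: float = 0.68, truth: TruthSet | None = None,
                             name: str | None = None,
                             ) -> tuple[Assembly, TruthSet]:
    """Apply SNVs and SVs to a reference, with exact truth bookkeeping.

    SNVs are drawn per base at ``snv_rate`` with transition probability
    ``ti_prob``; SV events must be non-overlapping.  The returned truth
    carries the SNV records visible in the query (those inside deleted
    segments are dropped), the SV records in the coordinates the anchor-gap
    caller reports, and the implied alignment anchors.
    """
    if truth is None:
        truth = TruthSet(seed=seed)
    rng = np.random.default_rng(seed)
    events_by_chrom: dict[str, list[SVEvent]] = {}
    for ev in sv_events:
        if ev.chrom not in assembly.chromosomes:
            raise SpecError(f"SV event on unknown chromosome {ev.chrom!r}")
        events_by_chrom.setdefault(ev.chrom, []).append(ev)
    for chrom, evs in events_by_chrom.items():
        evs.sort(key=lambda e: e.footprint())
        for a, b in zip(evs, evs[1:]):
            if b.footprint()[0] < a.footprint()[1]:
                raise SpecError(f"overlapping SV events on {chrom}: {a} / {b}")

    qry_chroms: dict[str, str] = {}
    for chrom in assembly.chromosomes:
        ref = assembly.chromosomes[chrom]
        mutated, snvs = _apply_snvs(ref, chrom, snv_rate, ti_prob, rng)
        evs = events_by_chrom.get(chrom, [])
        qry, blocks, svs, deleted = _apply_svs(mutated, chrom, evs, rng)
        del_starts = np.array([d[0] for d in deleted], dtype=np.int64)
        del_ends = np.array([d[1] for d in deleted], dtype=np.int64)
        for s in snvs:
            i = np.searchsorted(del_starts, s.ref_pos, side="right") - 1
            if i >= 0 and s.ref_pos < del_ends[i]:
                continue  # deleted from the query: not a visible SNV
            truth.snvs.append(s)
        truth.blocks.extend(blocks)
        truth.svs.extend(svs)
        qry_chroms[chrom] = qry
    truth.svs.sort(key=lambda r: (r.ref_chrom, r.ref_start, r.ref_end))
    truth.snvs.sort(key=lambda r: (r.ref_chrom, r.ref_pos))
    return Assembly(name=name or assembly.name + "_diverged",
                    chromosomes=qry_chroms), truth


def _apply_snvs(ref: str, chrom: str, snv_rate: float, ti_prob: float,
                rng: np.random.Generator) -> tuple[str, list[SNVRecord]]:
    arr = np.frombuffer(ref.encode(), dtype=np.uint8).copy()
    if snv_rate <= 0:
        return ref, []
    eligible = np.isin(arr, _BASES)
    hits = np.flatnonzero(eligible & (rng.random(arr.size) < snv_rate))
    snvs: list[SNVRecord] = []
    u = rng.random(hits.size)
    v = rng.random(hits.size)
    for k, pos in enumerate(hits):
        old = chr(arr[pos])
        if u[k] < ti_prob:
            new = _TRANSITION[old]
        else:
            tv = _TRANSVERSIONS[old]
            new = tv[0] if v[k] < 0.5 else tv[1]
        arr[pos] = ord(new)
        snvs.append(SNVRecord(chrom, int(pos), old, new))
    return arr.tobytes().decode(), snvs


def _apply_svs(mutated: str, chrom: str, events: Sequence[SVEvent],
               rng: np.random.Generator,
               ) -> tuple[str, list[AlignmentBlock], list[SVRecord], list[tuple[int, int]]]:
    L = len(mutated)
    parts: list[str] = []
    blocks: list[AlignmentBlock] = []
    svs: list[SVRecord] = []
    deleted: list[tuple[int, int]] = []
    cur_ref = 0
    qlen = 0

    def close_block(ref_end: int) -> None:
        nonlocal qlen
        if ref_end > cur_ref:
            seg = mutated[cur_ref:ref_end]
            blocks.append(AlignmentBlock(
                ref_chrom=chrom, ref_start=cur_ref, ref_end=ref_end,
                qry_chrom=chrom, qry_start=qlen, qry_end=qlen + len(seg),
                strand="+", identity_pct=99.9))
            parts.append(seg)
            qlen += len(seg)

    for ev in events:
        p = ev.position
        if ev.sv_type == "insertion":
            close_block(p)
            parts.append(random_dna(rng, ev.size))
            svs.append(SVRecord(chrom, p, p, "insertion", ev.size,
                                chrom, qlen, qlen + ev.size))
            qlen += ev.size
            cur_ref = p
        elif ev.sv_type == "deletion":
            close_block(p)
            svs.append(SVRecord(chrom, p, p + ev.size, "deletion", ev.size,
                                chrom, qlen, qlen))
            deleted.append((p, p + ev.size))
            cur_ref = p + ev.size
        elif ev.sv_type == "tandem_expansion":
            close_block(p)
            svs.append(SVRecord(chrom, p - ev.size, p, "tandem_expansion",
                                ev.size, chrom, qlen, qlen))
            cur_ref = p - ev.size  # next anchor re-walks the duplicated segment
        else:
            raise SpecError(f"unsupported planted SV type {ev.sv_type!r}")
    close_block(L)
    return "".join(parts), blocks, svs, sorted(deleted)


# ---------------------------------------------------------------------------
# Two-population genotypes


DEFAULT_CLASS_MIXTURE = {"swamp_specific": 1000, "river_specific": 2000,
                         "shared": 5000}
DEFAULT_FREQ_RANGES = {
    "swamp_specific": ((0.25, 0.5), (0.0, 0.0)),
    "river_specific": ((0.0, 0.0), (0.25, 0.5)),
    "shared": ((0.05, 0.5), (0.05, 0.5)),
    "uninformative": ((0.05, 0.18), (0.0, 0.0)),
}
_CLASS_TO_LABEL = {"swamp_specific": "swamp_specific_poly",
                   "river_specific": "river_specific_poly",
                   "shared": "shared", "uninformative": "uninformative"}
DEFAULT_QC_SPOILER_FRAC = 0.05  # of the class-mixture site count, per site filter


def simulate_two_population_genotypes(
        n_samples: tuple[int, int] = (100, 100),
        class_mixture: dict[str, int] | None = None,
        freq_ranges: dict[str, tuple[tuple[float, float], tuple[float, float]]] | None = None,
        missing_rate: float = 0.02,
        ti_prob: float = 0.68,
        seed: int = 0,
        pops: tuple[str, str] = ("swamp", "river"),
        autosomes: Sequence[str] = ("1", "2", "3", "4", "5"),
        sex_chrom: str = "X",
        qc_spoilers: dict[str, int] | None = None,
        n_bad_samples_per_pop: int = 1,
) -> tuple[GenotypeMatrix, TruthSet]:
    """Hardy-Weinberg genotypes for two populations with planted site classes.

    ``class_mixture`` gives the number of clean autosomal biallelic sites per
    class; per-class allele-frequency ranges keep a margin from the
    classifier thresholds so realized-frequency noise misclassifies well
    under 1% of sites at the default sample sizes.  ``qc_spoilers`` plants
    sites that each fail exactly one QC filter (counts default to 5% of the
    mixture size for each site filter), and ``n_bad_samples_per_pop`` extra
    samples whose missingness exceeds the mind threshold.  The truth records
    per-site class and drawn frequencies, expected per-filter removal
    counts, and expected heterozygosity moments.
    """
    if class_mixture is None:
        class_mixture = dict(DEFAULT_CLASS_MIXTURE)
    if any(v <= 0 for v in class_mixture.values()):
        raise SpecError("class mixture counts must be positive")
    ranges = dict(DEFAULT_FREQ_RANGES)
    if freq_ranges:
        ranges.update(freq_ranges)
    n_mix = sum(class_mixture.values())
    if qc_spoilers is None:
        k = max(1, round(DEFAULT_QC_SPOILER_FRAC * n_mix))
        qc_spoilers = {"non_autosomal": k, "multiallelic": k,
                       "site_missing": k, "low_maf": k}
    rng = np.random.default_rng(seed)

    nA, nB = n_samples
    nbad = n_bad_samples_per_pop
    samples = ([f"{pops[0]}_{i:03d}" for i in range(nA + nbad)]
               + [f"{pops[1]}_{i:03d}" for i in range(nB + nbad)])
    populations = {s: (pops[0] if s.startswith(pops[0]) else pops[1]) for s in samples}
    n_total = len(samples)
    # bad samples: first sample of each population block
    bad_idx = ([0] if nbad else []) + ([nA + nbad] if nbad else [])
    for b in range(1, nbad):
        bad_idx += [b, nA + nbad + b]
    bad_idx = sorted(bad_idx[:2 * nbad])
    good_mask = np.ones(n_total, bool)
    good_mask[bad_idx] = False
    a_idx = np.array([i for i, s in enumerate(samples) if populations[s] == pops[0]])
    b_idx = np.array([i for i, s in enumerate(samples) if populations[s] == pops[1]])

    sites: list[Site] = []
    rows: list[np.ndarray] = []
    site_truth: list[dict] = []

    def draw_alleles() -> tuple[str, tuple[str, ...], bool]:
        ref = "ACGT"[int(rng.integers(4))]
        if rng.random() < ti_prob:
            alt = _TRANSITION[ref]
        else:
            tv = _TRANSVERSIONS[ref]
            alt = tv[int(rng.integers(2))]
        return ref, (alt,), frozenset((ref, alt)) in ({frozenset("AG"), frozenset("CT")})

    def hw_row(fa: float, fb: float, missing: float = missing_rate) -> np.ndarray:
        row = np.empty(n_total, dtype=np.int8)
        row[a_idx] = rng.binomial(2, fa, size=a_idx.size)
        row[b_idx] = rng.binomial(2, fb, size=b_idx.size)
        if missing > 0:
            row[rng.random(n_total) < missing] = -1
        return row

    # --- clean class-mixture sites
    for cls, count in class_mixture.items():
        (alo, ahi), (blo, bhi) = ranges[cls]
        for _ in range(count):
            fa = float(rng.uniform(alo, ahi)) if ahi > alo else alo
            fb = float(rng.uniform(blo, bhi)) if bhi > blo else blo
            ref, alts, is_ti = draw_alleles()
            rows.append(hw_row(fa, fb))
            sites.append(Site("", 0, ref, alts))  # chrom/pos assigned below
            site_truth.append({"cls": _CLASS_TO_LABEL[cls], "freq_a": fa,
                               "freq_b": fb, "transition": is_ti,
                               "spoiler": None})

    # --- QC spoiler sites (each fails exactly one filter)
    spoiler_chrom: list[str | None] = []
    for _ in range(qc_spoilers.get("non_autosomal", 0)):
        fa = fb = float(rng.uniform(0.1, 0.4))
        ref, alts, is_ti = draw_alleles()
        rows.append(hw_row(fa, fb))
        sites.append(Site("", 0, ref, alts))
        site_truth.append({"cls": None, "freq_a": fa, "freq_b": fb,
                           "transition": is_ti, "spoiler": "non_autosomal"})
    for _ in range(qc_spoilers.get("multiallelic", 0)):
        fa = fb = float(rng.uniform(0.1, 0.4))
        ref, alts, is_ti = draw_alleles()
        second = next(b for b in "ACGT" if b not in (ref, alts[0]))
        rows.append(hw_row(fa, fb))
        sites.append(Site("", 0, ref, (alts[0], second)))
        site_truth.append({"cls": None, "freq_a": fa, "freq_b": fb,
                           "transition": is_ti, "spoiler": "multiallelic"})
    n_fail_missing = int(np.ceil(0.15 * n_total))
    for _ in range(qc_spoilers.get("site_missing", 0)):
        fa = fb = float(rng.uniform(0.1, 0.4))
        ref, alts, is_ti = draw_alleles()
        row = hw_row(fa, fb, missing=0.0)
        row[:n_fail_missing] = -1  # covers the bad samples too; >10% remain after mind
        rows.append(row)
        sites.append(Site("", 0, ref, alts))
        site_truth.append({"cls": None, "freq_a": fa, "freq_b": fb,
                           "transition": is_ti, "spoiler": "site_missing"})
    good_indices = np.flatnonzero(good_mask)
    for j in range(qc_spoilers.get("low_maf", 0)):
        ref, alts, is_ti = draw_alleles()
        row = np.zeros(n_total, dtype=np.int8)
        row[good_indices[j % good_indices.size]] = 1  # single het: pooled MAF ~ 1/(2N)
        rows.append(row)
        sites.append(Site("", 0, ref, alts))
        site_truth.append({"cls": None, "freq_a": 0.0, "freq_b": 0.0,
                           "transition": is_ti, "spoiler": "low_maf"})

    genotypes = np.vstack(rows)

    # bad samples: deterministic 1-in-6 missingness over autosomal biallelic sites
    autosomal_bi = np.array([t["spoiler"] not in ("non_autosomal", "multiallelic")
                             for t in site_truth])
    ab_rows = np.flatnonzero(autosomal_bi)
    for bi in bad_idx:
        genotypes[ab_rows[::6], bi] = -1

    # assign coordinates: spoof chroms for non-autosomal, round-robin otherwise
    pos_counters = {c: 0 for c in list(autosomes) + [sex_chrom]}
    ordered_autosomes = list(autosomes)
    k = 0
    for i, t in enumerate(site_truth):
        chrom = sex_chrom if t["spoiler"] == "non_autosomal" else \
            ordered_autosomes[k % len(ordered_autosomes)]
        if t["spoiler"] != "non_autosomal":
            k += 1
        pos_counters[chrom] += 997  # arbitrary stride, keeps positions increasing
        s = sites[i]
        sites[i] = Site(chrom, pos_counters[chrom], s.ref, s.alts)

    matrix = GenotypeMatrix(sites=sites, samples=samples, populations=populations,
                            genotypes=genotypes)

    # --- truth bookkeeping
    truth = TruthSet(seed=seed)
    clean = [t for t in site_truth if t["spoiler"] is None]
    class_counts: dict[str, int] = {}
    for t in clean:
        class_counts[t["cls"]] = class_counts.get(t["cls"], 0) + 1
    ti = sum(1 for t in clean if t["transition"])
    het_expect = {}
    for pop, key in ((pops[0], "freq_a"), (pops[1], "freq_b")):
        p_site = np.array([2 * t[key] * (1 - t[key]) * (1 - missing_rate)
                           for t in clean])
        het_expect[pop] = {"mean_count": float(p_site.sum()),
                           "var_count": float((p_site * (1 - p_site)).sum())}
    truth.genotypes = {
        "pops": pops,
        "n_samples": {pops[0]: nA + nbad, pops[1]: nB + nbad},
        "class_counts": class_counts,
        "site_truth": site_truth,
        "expected_removed_by": {
            "non_autosomal": qc_spoilers.get("non_autosomal", 0),
            "multiallelic": qc_spoilers.get("multiallelic", 0),
            "sample_call_rate": 2 * nbad,
            "site_call_rate": qc_spoilers.get("site_missing", 0),
            "maf": qc_spoilers.get("low_maf", 0),
        },
        "ti_prob": ti_prob,
        "n_transitions_clean": ti,
        "missing_rate": missing_rate,
        "het_expectation": het_expect,
        "autosomes": list(autosomes),
    }
    return matrix, truth


# ---------------------------------------------------------------------------
# Demo configurations (the package's standard toy genome)

TOY_CHROM_LENGTH = 2_000_000

_TOY_GAPS = {
    "chr1": ((110_000, 500), (130_000, 1_200), (160_000, 300), (200_000, 800),
             (240_000, 2_000)),
    "chr2": ((110_000, 250), (140_000, 600), (180_000, 1_500), (220_000, 3_000)),
    "chr3": ((105_000, 200), (135_000, 450), (175_000, 900), (215_000, 5_000)),
    "chr4": ((112_000, 300), (142_000, 700), (182_000, 1_100), (222_000, 2_500)),
    "chr5": ((108_000, 400), (148_000, 1_300), (188_000, 4_000)),
}

_TOY_LAYOUT = [
    # name, telo_p, telo_q, (cent_pos, monomer_len, copies), decoy(pos, n)
    ("chr1", 800, 1_200, (500_000, 673, 150), (1_700_000, 15)),
    ("chr2", 900, 700, (450_000, 673, 120), (1_650_000, 10)),
    ("chr3", 1_000, 637, (520_000, 673, 200), (1_720_000, 20)),
    ("chr4", 0, 850, (400_000, 1_404, 80), (1_600_000, 12)),
    ("chr5", 0, 2_369, (480_000, 1_404, 60), (1_640_000, 10)),
]

_TOY_LINES = (
    (340_000, 6_500, "L1_BT", "LINE/L1"),
    (360_000, 2_800, "L1_BT", "LINE/L1"),
    (380_000, 4_200, "BovB", "LINE/RTE-BovB"),
    (395_000, 1_500, "BovB", "LINE/RTE-BovB"),
    (410_000, 3_100, "L1_BT", "LINE/L1"),
)


def toy_chromosome_specs() -> list[ChromosomeSpec]:
    """The package's standard 5-chromosome, 10-Mb planted toy genome.

    Three chromosomes carry telomere arrays at both arms (sub-metacentric
    pattern) and two only at the q-arm (acrocentric pattern); each has a
    centromeric monomer array (673-bp monomers on the sub-metacentric
    chromosomes, 1,404-bp on the acrocentric ones, mirroring the buffalo
    satellites), decoy satellite clusters more than 1 Mb away, and 20 N-gaps
    overall.
    """
    specs = []
    for name, tp, tq, (cpos, mlen, copies), (dpos, dn) in _TOY_LAYOUT:
        specs.append(ChromosomeSpec(
            name=name, length=TOY_CHROM_LENGTH,
            telomere_p_units=tp, telomere_q_units=tq,
            centromere=CentromereSpec(position=cpos, monomer_len=mlen,
                                      copies=copies),
            decoys=(DecoySpec(position=dpos, n_repeats=dn),),
            gaps=tuple(GapSpec(p, l) for p, l in _TOY_GAPS[name]),
            other_repeats=_TOY_LINES if name == "chr1" else (),
        ))
    return specs


def toy_sv_events(seed: int = 0) -> list[SVEvent]:
    """30 planted SVs (10 insertions, 10 deletions, 10 tandem expansions).

    Six events per chromosome at fixed positions in the feature-free
    mid-chromosome zone, 130 kb apart so every implied anchor comfortably
    exceeds the 10-kb uniqueness filter; sizes drawn in [60, 9000].
    """
    rng = np.random.default_rng((seed, 30))
    positions = [750_000, 880_000, 1_010_000, 1_140_000, 1_270_000, 1_400_000]
    base_types = ["insertion", "deletion", "tandem_expansion"]
    events: list[SVEvent] = []
    for ci, (name, *_rest) in enumerate(_TOY_LAYOUT):
        types = [base_types[(ci + j) % 3] for j in range(6)]
        for pos, sv_type in zip(positions, types):
            size = int(rng.integers(60, 9001))
            events.append(SVEvent(chrom=name, position=pos, sv_type=sv_type,
                                  size=size))
    return events


def toy_genome(seed: int = 0, snv_rate: float = 0.002,
               ) -> tuple[Assembly, Assembly, TruthSet]:
    """Reference + diverged query + combined truth for the standard toy genome."""
    ref, truth = simulate_assembly(toy_chromosome_specs(), name="toy_ref", seed=seed)
    qry, truth = derive_diverged_assembly(ref, snv_rate=snv_rate,
                                          sv_events=toy_sv_events(seed),
                                          seed=seed + 1, truth=truth,
                                          name="toy_qry")
    return ref, qry, truth


# ---------------------------------------------------------------------------
# Truth emission


def emit_truth_files(truth: TruthSet, outdir: str | Path) -> dict[str, Path]:
    """Write alignment blocks, annotations and per-feature truth tables.

    Emits the show-coords-dialect anchors implied by the edit script, the
    RepeatMasker-dialect rows for planted satellite arrays and decoys, and
    BED/TSV truth for every feature class present.  Returns the paths
    written, keyed by content.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def path(name: str) -> Path:
        p = outdir / name
        written[name.split(".")[0]] = p
        return p

    if truth.blocks:
        write_alignment_blocks(truth.blocks, path("truth_alignment.coords"))
    if truth.annotations:
        write_repeat_annotations(truth.annotations, path("truth_repeats.out"))
    if truth.gaps:
        write_intervals(truth.gaps, path("truth_gaps.bed"), format="bed")
    if truth.telomeres:
        with open(path("truth_telomeres.tsv"), "w") as fh:
            fh.write("chrom\tarm\tunits\n")
            for (chrom, arm), units in sorted(truth.telomeres.items()):
                fh.write(f"{chrom}\t{arm}\t{units}\n")
    if truth.centromeres:
        rows = [(c, d["start"], d["end"],
                 f"{d['family']}:{d['copies']}x{d['monomer_len']}")
                for c, d in sorted(truth.centromeres.items())]
        write_intervals(rows, path("truth_centromeres.bed"), format="bed")
    if truth.svs:
        with open(path("truth_svs.tsv"), "w") as fh:
            fh.write("ref_chrom\tref_start\tref_end\tsv_type\tsize\n")
            for sv in truth.svs:
                fh.write(f"{sv.ref_chrom}\t{sv.ref_start}\t{sv.ref_end}\t"
                         f"{sv.sv_type}\t{sv.size}\n")
    if truth.snvs:
        with open(path("truth_snvs.tsv"), "w") as fh:
            fh.write("ref_chrom\tref_pos\tref_base\tqry_base\n")
            for s in truth.snvs:
                fh.write(f"{s.ref_chrom}\t{s.ref_pos}\t{s.ref_base}\t{s.qry_base}\n")
    if truth.genotypes:
        with open(path("truth_genotypes.json"), "w") as fh:
            payload = dict(truth.genotypes)
            payload["site_truth"] = payload["site_truth"]
            json.dump(payload, fh, indent=1, default=str)
    return written
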