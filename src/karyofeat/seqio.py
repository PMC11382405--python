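"""Readers and writers for the formats the pipeline touches, plus gap detection.

All coordinates are 0-based half-open internally.  Conversion to and from the
1-based inclusive conventions of RepeatMasker ``.out`` and nucmer
``show-coords`` happens only at the parse/serialize boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
from Bio import SeqIO
from cyvcf2 import VCF

from .errors import ConfigError, FormatError

_VALID_BASES = frozenset("ACGTN")
_NONSTANDARD_RE = re.compile(r"[^ACGTN]")


@dataclass
class Assembly:
    """A named set of chromosome sequences (uppercase A/C/G/T/N)."""

    name: str
    chromosomes: dict[str, str]

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.chromosomes.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.chromosomes.values())

    def __post_init__(self) -> None:
        for chrom, seq in self.chromosomes.items():
            if not seq:
                raise FormatError(f"empty sequence for chromosome {chrom!r}")


@dataclass(frozen=True)
class GapInterval:
    """A maximal run of N in a chromosome, 0-based half-open."""

    chrom: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class RepeatAnnotation:
    """One masked repeat hit (RepeatMasker row), 0-based half-open."""

    chrom: str
    start: int
    end: int
    family: str
    repeat_class: str
    divergence_pct: float

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def identity_pct(self) -> float:
        return 100.0 - self.divergence_pct


@dataclass(frozen=True)
class AlignmentBlock:
    """One aligned anchor between a reference and a query assembly.

    Query coordinates are always on the forward strand; ``strand`` records
    the alignment orientation.
    """

    ref_chrom: str
    ref_start: int
    ref_end: int
    qry_chrom: str
    qry_start: int
    qry_end: int
    strand: str = "+"
    identity_pct: float = 100.0

    def __post_init__(self) -> None:
        if self.ref_end <= self.ref_start or self.qry_end <= self.qry_start:
            raise FormatError(
                f"degenerate alignment block {self.ref_chrom}:{self.ref_start}-"
                f"{self.ref_end} / {self.qry_chrom}:{self.qry_start}-{self.qry_end}"
            )

    @property
    def ref_len(self) -> int:
        return self.ref_end - self.ref_start

    @property
    def qry_len(self) -> int:
        return self.qry_end - self.qry_start


@dataclass(frozen=True)
class Site:
    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alts: tuple[str, ...]


@dataclass
class GenotypeMatrix:
    """Diploid genotypes for many sites x samples.

    ``genotypes[i, j]`` is the alternate-allele dosage (0, 1, 2) of sample j
    at site i, or -1 for a missing call.  Multiallelic records are retained
    but flagged; downstream analyses drop them.
    """

    sites: list[Site]
    samples: list[str]
    populations: dict[str, str]
    genotypes: np.ndarray
    multiallelic: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.sites), len(self.samples)):
            raise ConfigError(
                f"genotype grid {self.genotypes.shape} inconsistent with "
                f"{len(self.sites)} sites x {len(self.samples)} samples"
            )
        if self.multiallelic is None:
            self.multiallelic = np.array([len(s.alts) > 1 for s in self.sites])
        self.multiallelic = np.asarray(self.multiallelic, dtype=bool)
        missing = [s for s in self.samples if s not in self.populations]
        if missing:
            raise ConfigError(f"samples without a population label: {missing}")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_indices(self, population: str) -> np.ndarray:
        return np.array(
            [i for i, s in enumerate(self.samples) if self.populations[s] == population],
            dtype=int,
        )

    def population_labels(self) -> list[str]:
        seen: list[str] = []
        for s in self.samples:
            lab = self.populations[s]
            if lab not in seen:
                seen.append(lab)
        return seen

    def subset(self, site_mask: np.ndarray | None = None,
               sample_mask: np.ndarray | None = None) -> "GenotypeMatrix":
        site_mask = np.ones(self.n_sites, bool) if site_mask is None else np.asarray(site_mask)
        sample_mask = (np.ones(self.n_samples, bool) if sample_mask is None
                       else np.asarray(sample_mask))
        sites = [s for s, k in zip(self.sites, site_mask) if k]
        samples = [s for s, k in zip(self.samples, sample_mask) if k]
        return GenotypeMatrix(
            sites=sites,
            samples=samples,
            populations={s: self.populations[s] for s in samples},
            genotypes=self.genotypes[np.ix_(site_mask, sample_mask)],
            multiallelic=self.multiallelic[site_mask],
        )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, name: str | None = None,
               nonstandard: Literal["error", "to_n"] = "error") -> Assembly:
    """Read a (possibly line-wrapped) FASTA file into an :class:`Assembly`.

    Sequences are uppercased; soft-masking case is not preserved.  Characters
    outside A/C/G/T/N are rejected (``nonstandard="error"``) or mapped to N.
    """
    path = Path(path)
    chromosomes: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in chromosomes:
            raise FormatError(f"duplicate FASTA header {record.id!r} in {path}")
        seq = str(record.seq).upper()
        if not seq:
            raise FormatError(f"empty record {record.id!r} in {path}")
        if _NONSTANDARD_RE.search(seq):
            if nonstandard == "to_n":
                seq = _NONSTANDARD_RE.sub("N", seq)
            else:
                bad = sorted(set(_NONSTANDARD_RE.findall(seq)))
                raise FormatError(
                    f"non-ACGTN characters {bad} in record {record.id!r} of {path}"
                )
        chromosomes[record.id] = seq
    if not chromosomes:
        raise FormatError(f"no FASTA records in {path}")
    return Assembly(name=name or path.stem, chromosomes=chromosomes)


def write_fasta(assembly: Assembly, path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom, seq in assembly.chromosomes.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Gap detection

_GAP_RE_CACHE: dict[int, re.Pattern] = {}


def find_assembly_gaps(assembly: Assembly, min_run: int = 10) -> list[GapInterval]:
    """Return all maximal N-runs of length >= ``min_run``, sorted by (chrom, start)."""
    if min_run < 1:
        raise ValueError(f"min_run must be >= 1, got {min_run}")
    pattern = _GAP_RE_CACHE.get(min_run)
    if pattern is None:
        pattern = re.compile("N{%d,}" % min_run)
        _GAP_RE_CACHE[min_run] = pattern
    gaps = [
        GapInterval(chrom, m.start(), m.end())
        for chrom in sorted(assembly.chromosomes)
        for m in pattern.finditer(assembly.chromosomes[chrom])
    ]
    return gaps


# ---------------------------------------------------------------------------
# RepeatMasker .out

_RM_HEADER = (
    "   SW  perc perc perc  query      position in query           matching"
    "       repeat              position in  repeat\n"
    "score  div. del. ins.  sequence    begin     end    (left)    repeat"
    "         class/family         begin  end (left)   ID\n"
    "\n"
)


def read_repeat_annotations(path: str | Path,
                            dialect: str = "repeatmasker_out") -> list[RepeatAnnotation]:
    """Parse a RepeatMasker ``.out`` file (3 header lines, 1-based inclusive)."""
    if dialect != "repeatmasker_out":
        raise ValueError(f"unknown repeat annotation dialect {dialect!r}")
    annotations: list[RepeatAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno <= 3 or not line.strip():
                continue
            fields = line.split()
            try:
                div = float(fields[1])
                chrom = fields[4]
                begin, end = int(fields[5]), int(fields[6])
                family = fields[9]
                repeat_class = fields[10]
            except (IndexError, ValueError) as exc:
                raise FormatError(f"{path}: malformed row at line {lineno}: {exc}") from exc
            if not 0.0 <= div <= 100.0:
                raise FormatError(f"{path}: divergence {div} out of range at line {lineno}")
            annotations.append(RepeatAnnotation(
                chrom=chrom, start=begin - 1, end=end,
                family=family, repeat_class=repeat_class, divergence_pct=div,
            ))
    return annotations


def write_repeat_annotations(annotations: Sequence[RepeatAnnotation],
                             path: str | Path) -> None:
    """Serialize annotations in RepeatMasker ``.out`` dialect (round-trips)."""
    with open(path, "w") as fh:
        fh.write(_RM_HEADER)
        for i, a in enumerate(annotations, start=1):
            fh.write(
                f"{1000:>5} {a.divergence_pct:5.1f}  0.0  0.0  {a.chrom:<10}"
                f" {a.start + 1:>9} {a.end:>9} (0) + {a.family:<14}"
                f" {a.repeat_class:<18} 1 {a.end - a.start} (0) {i}\n"
            )


# ---------------------------------------------------------------------------
# Alignment blocks: nucmer show-coords tab dialect and PAF


def read_alignment_blocks(path: str | Path,
                          dialect: Literal["coords", "paf"] = "coords") -> list[AlignmentBlock]:
    """Parse pairwise alignment anchors.

    ``coords``: the tab-separated show-coords layout
    ``S1 E1 S2 E2 LEN1 LEN2 %IDY REF QRY`` with 1-based inclusive intervals;
    a reverse-strand anchor has S2 > E2.  Header/ruler lines are skipped.
    ``paf``: standard PAF, already 0-based half-open with forward-strand
    query coordinates.
    """
    if dialect == "coords":
        return _read_coords(path)
    if dialect == "paf":
        return _read_paf(path)
    raise ValueError(f"unknown alignment dialect {dialect!r}")


def _read_coords(path: str | Path) -> list[AlignmentBlock]:
    blocks: list[AlignmentBlock] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            try:
                int(fields[0])
            except ValueError:
                continue  # header / ruler line
            if len(fields) < 9:
                raise FormatError(f"{path}: expected >=9 columns at line {lineno}")
            s1, e1, s2, e2 = (int(x) for x in fields[:4])
            idy = float(fields[6])
            ref_chrom, qry_chrom = fields[7], fields[8]
            if s2 <= e2:
                strand, qs, qe = "+", s2, e2
            else:
                strand, qs, qe = "-", e2, s2
            blocks.append(AlignmentBlock(
                ref_chrom=ref_chrom, ref_start=s1 - 1, ref_end=e1,
                qry_chrom=qry_chrom, qry_start=qs - 1, qry_end=qe,
                strand=strand, identity_pct=idy,
            ))
    return blocks


def _read_paf(path: str | Path) -> list[AlignmentBlock]:
    blocks: list[AlignmentBlock] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 12:
                raise FormatError(f"{path}: expected >=12 PAF columns at line {lineno}")
            qname, _, qstart, qend, strand, tname, _, tstart, tend = fields[:9]
            nmatch, alen = int(fields[9]), int(fields[10])
            idy = 100.0 * nmatch / alen if alen else 0.0
            blocks.append(AlignmentBlock(
                ref_chrom=tname, ref_start=int(tstart), ref_end=int(tend),
                qry_chrom=qname, qry_start=int(qstart), qry_end=int(qend),
                strand=strand, identity_pct=idy,
            ))
    return blocks


def write_alignment_blocks(blocks: Sequence[AlignmentBlock], path: str | Path,
                           dialect: Literal["coords"] = "coords") -> None:
    """Serialize anchors in the show-coords tab dialect (round-trips)."""
    if dialect != "coords":
        raise ValueError(f"unsupported write dialect {dialect!r}")
    with open(path, "w") as fh:
        for b in blocks:
            if b.strand == "+":
                s2, e2 = b.qry_start + 1, b.qry_end
            else:
                s2, e2 = b.qry_end, b.qry_start + 1
            fh.write(
                f"{b.ref_start + 1}\t{b.ref_end}\t{s2}\t{e2}\t{b.ref_len}\t"
                f"{b.qry_len}\t{b.identity_pct:.2f}\t{b.ref_chrom}\t{b.qry_chrom}\n"
            )


# ---------------------------------------------------------------------------
# VCF genotypes


def read_genotypes(path: str | Path, populations: dict[str, str],
                   name: str | None = None) -> GenotypeMatrix:
    """Load a VCF with GT into a :class:`GenotypeMatrix`.

    Every sample in the VCF must appear in the sample->population map.
    Multiallelic records are retained but flagged; missing calls become -1.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    unlabeled = [s for s in samples if s not in populations]
    if unlabeled:
        raise ConfigError(f"VCF samples missing from population map: {unlabeled}")
    sites: list[Site] = []
    rows: list[np.ndarray] = []
    for variant in vcf:
        alts = tuple(variant.ALT)
        sites.append(Site(chrom=variant.CHROM, pos=variant.POS,
                          ref=variant.REF, alts=alts))
        geno = np.asarray(variant.genotypes, dtype=np.int16)
        alleles = geno[:, :2]
        missing = (alleles < 0).any(axis=1)
        dosage = (alleles > 0).sum(axis=1).astype(np.int8)
        dosage[missing] = -1
        rows.append(dosage)
    genotypes = np.vstack(rows) if rows else np.zeros((0, len(samples)), np.int8)
    return GenotypeMatrix(sites=sites, samples=samples,
                          populations={s: populations[s] for s in samples},
                          genotypes=genotypes)


_GT_STRINGS = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(matrix: GenotypeMatrix, path: str | Path,
              contigs: Iterable[str] | None = None) -> None:
    """Write a minimal VCFv4.2 with GT only (round-trips through read_genotypes)."""
    if contigs is None:
        contigs = list(dict.fromkeys(s.chrom for s in matrix.sites))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.samples) + "\n")
        for site, row in zip(matrix.sites, matrix.genotypes):
            alt = ",".join(site.alts) if site.alts else "."
            calls = "\t".join(_GT_STRINGS[int(g)] for g in row)
            fh.write(f"{site.chrom}\t{site.pos}\t.\t{site.ref}\t{alt}\t.\tPASS\t.\tGT\t{calls}\n")


def read_population_map(path: str | Path) -> dict[str, str]:
    """Read a two-column sample<TAB>population file."""
    populations: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 2:
                raise FormatError(f"{path}: expected 2 columns at line {lineno}")
            populations[fields[0]] = fields[1]
    return populations


# ---------------------------------------------------------------------------
# Interval output


def write_intervals(records: Sequence, path: str | Path,
                    format: Literal["bed", "bedgraph", "tsv"] = "bed",
                    header: Sequence[str] = ("chrom", "start", "end", "value")) -> None:
    """Write (chrom, start, end[, value, ...]) records as BED/bedgraph/TSV.

    Records may be tuples or objects with ``chrom``/``start``/``end`` (and
    ``value`` for bedgraph) attributes.  BED and bedgraph are 0-based
    half-open; the TSV includes a header line.
    """

    def unpack(rec):
        if isinstance(rec, (tuple, list)):
            return tuple(rec)
        out = [rec.chrom, rec.start, rec.end]
        if hasattr(rec, "value"):
            out.append(rec.value)
        return tuple(out)

    with open(path, "w") as fh:
        if format == "tsv":
            fh.write("\t".join(header) + "\n")
        for rec in records:
            fields = unpack(rec)
            if format == "bedgraph" and len(fields) < 4:
                raise ValueError("bedgraph records need a value column")
            if format == "bed":
                fields = fields[:3] + fields[3:]  # extra columns allowed
            fh.write("\t".join(str(f) for f in fields) + "\n")


def read_intervals(path: str | Path, has_header: bool = False) -> list[tuple]:
    """Read BED/bedgraph/TSV intervals back as tuples (ints where possible)."""
    out: list[tuple] = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            if not line.strip():
                continue
            if has_header and i == 0:
                continue
            fields = line.rstrip("\n").split("\t")
            parsed = []
            for f in fields:
                try:
                    parsed.append(int(f))
                except ValueError:
                    try:
                        parsed.append(float(f))
                    except ValueError:
                        parsed.append(f)
            out.append(tuple(parsed))
    return out
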