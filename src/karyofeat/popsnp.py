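"""Population-genotype QC and cross-population MAF site classification.

The workflow mirrors a plink-style pipeline: autosome restriction, biallelic
restriction, sample call-rate filter (mind), site call-rate filter (geno)
and a pooled minor-allele-frequency floor, applied in that fixed order and
tallied in a :class:`QCReport`.  QC-passing sites are then classified by
their per-population minor allele frequencies: a site highly polymorphic in
one subspecies (MAF > 0.2) but fixed in the other (frequency of the pooled
minor allele < 0.01) is type-specific; sites with MAF > 0.01 in both are
shared; everything else is uninformative.

The "fixed" test deliberately uses the frequency of the *pooled* minor
allele in the other population, not that population's own MAF, so that a
site near 0.5 cannot flip its minor-allele label between populations.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .seqio import GenotypeMatrix, Site

CLASS_LABELS = ("swamp_specific_poly", "river_specific_poly", "shared", "uninformative")

TRANSITIONS = frozenset({frozenset("AG"), frozenset("CT")})


@dataclass
class QCReport:
    sites_in: int
    samples_in: int
    sites_kept: int = 0
    samples_kept: int = 0
    removed_by: dict[str, int] = field(default_factory=dict)

    FILTER_ORDER = ("non_autosomal", "multiallelic", "sample_call_rate",
                    "site_call_rate", "maf")


@dataclass(frozen=True)
class SiteClassification:
    site_id: str
    maf_a: float
    maf_b: float
    cls: str


def _freqs(genotypes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Alt-allele frequency and non-missing allele count per site (rows)."""
    missing = genotypes < 0
    alt = np.where(missing, 0, genotypes).sum(axis=1).astype(float)
    total = 2.0 * (~missing).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(total > 0, alt / np.maximum(total, 1), np.nan)
    return freq, total


# ---------------------------------------------------------------------------
# QC filtering


def apply_site_sample_filters(G: GenotypeMatrix, autosome_names: Iterable[str],
                              geno: float = 0.1, mind: float = 0.1,
                              maf: float = 0.01, biallelic_only: bool = True,
                              ) -> tuple[GenotypeMatrix, QCReport]:
    """plink-like QC: autosome -> biallelic -> mind -> geno -> maf.

    A sample is kept iff its missing fraction (over sites surviving the
    autosome and biallelic filters) is <= ``mind``; a site iff its missing
    fraction over kept samples is <= ``geno`` and its pooled MAF over kept
    samples is >= ``maf``.
    """
    autosomes = set(autosome_names)
    report = QCReport(sites_in=G.n_sites, samples_in=G.n_samples)

    site_mask = np.array([s.chrom in autosomes for s in G.sites])
    report.removed_by["non_autosomal"] = int((~site_mask).sum())

    if biallelic_only:
        bi = ~G.multiallelic & np.array([len(s.alts) == 1 for s in G.sites])
        report.removed_by["multiallelic"] = int((site_mask & ~bi).sum())
        site_mask &= bi
    else:
        report.removed_by["multiallelic"] = 0

    gt = G.genotypes[site_mask]
    n_sites_now = gt.shape[0]
    if n_sites_now == 0:
        raise ConfigError("no sites survive the autosome/biallelic filters")

    sample_missing_frac = (gt < 0).mean(axis=0)
    sample_mask = sample_missing_frac <= mind
    report.removed_by["sample_call_rate"] = int((~sample_mask).sum())
    if not sample_mask.any():
        raise ConfigError(f"all samples exceed mind={mind}")

    gt = gt[:, sample_mask]
    site_missing_frac = (gt < 0).mean(axis=1)
    call_ok = site_missing_frac <= geno
    report.removed_by["site_call_rate"] = int((~call_ok).sum())

    freq, total = _freqs(gt)
    pooled_maf = np.minimum(freq, 1.0 - freq)
    maf_ok = np.where(np.isnan(pooled_maf), False, pooled_maf >= maf)
    report.removed_by["maf"] = int((call_ok & ~maf_ok).sum())

    keep_rel = call_ok & maf_ok
    full_site_mask = site_mask.copy()
    full_site_mask[np.flatnonzero(site_mask)] = keep_rel

    filtered = G.subset(full_site_mask, sample_mask)
    report.sites_kept = filtered.n_sites
    report.samples_kept = filtered.n_samples
    return filtered, report


# ---------------------------------------------------------------------------
# MAF and classification


def population_maf(G: GenotypeMatrix, site_index: int, population: str) -> float:
    """MAF of one site within one population (nan if all calls missing)."""
    idx = G.sample_indices(population)
    freq, total = _freqs(G.genotypes[[site_index]][:, idx])
    if total[0] == 0:
        return float("nan")
    return float(min(freq[0], 1.0 - freq[0]))


def population_frequencies(G: GenotypeMatrix, populations: Sequence[str],
                           ) -> dict[str, np.ndarray]:
    """Alt-allele frequency per site for each population plus the pool."""
    out: dict[str, np.ndarray] = {}
    for pop in populations:
        idx = G.sample_indices(pop)
        if idx.size == 0:
            raise ConfigError(f"population {pop!r} has no samples")
        out[pop], _ = _freqs(G.genotypes[:, idx])
    out["__pooled__"], _ = _freqs(G.genotypes)
    return out


def classify_cross_population_sites(G: GenotypeMatrix,
                                    pops: tuple[str, str] = ("swamp", "river"),
                                    poly_thr: float = 0.2,
                                    fixed_thr: float = 0.01,
                                    shared_thr: float = 0.01,
                                    ) -> tuple[list[SiteClassification], Counter]:
    """Assign every site one class; precedence specific > shared > uninformative.

    ``pops`` orders the two population labels; class labels follow the
    (swamp, river) naming regardless, with the first label mapping to
    ``swamp_specific_poly``.
    """
    pop_a, pop_b = pops
    freqs = population_frequencies(G, [pop_a, pop_b])
    f_a, f_b, f_all = freqs[pop_a], freqs[pop_b], freqs["__pooled__"]
    minor_is_alt = f_all <= 0.5
    fm_a = np.where(minor_is_alt, f_a, 1.0 - f_a)  # pooled-minor-allele freq in A
    fm_b = np.where(minor_is_alt, f_b, 1.0 - f_b)
    maf_a = np.minimum(f_a, 1.0 - f_a)
    maf_b = np.minimum(f_b, 1.0 - f_b)

    with np.errstate(invalid="ignore"):
        a_specific = (maf_a > poly_thr) & (fm_b < fixed_thr)
        b_specific = (maf_b > poly_thr) & (fm_a < fixed_thr)
        shared = (maf_a > shared_thr) & (maf_b > shared_thr)

    classifications: list[SiteClassification] = []
    counts: Counter = Counter({c: 0 for c in CLASS_LABELS})
    for i, site in enumerate(G.sites):
        if a_specific[i]:
            cls = "swamp_specific_poly"
        elif b_specific[i]:
            cls = "river_specific_poly"
        elif shared[i]:
            cls = "shared"
        else:
            cls = "uninformative"
        counts[cls] += 1
        classifications.append(SiteClassification(
            site_id=f"{site.chrom}:{site.pos}",
            maf_a=float(maf_a[i]) if np.isfinite(maf_a[i]) else float("nan"),
            maf_b=float(maf_b[i]) if np.isfinite(maf_b[i]) else float("nan"),
            cls=cls))
    return classifications, counts


# ---------------------------------------------------------------------------
# Heterozygosity, Ti/Tv, MAF spectrum


def heterozygosity_per_kb(G: GenotypeMatrix, callable_bp: int,
                          ) -> tuple[pd.Series, dict[str, float]]:
    """Heterozygous sites per kb per sample, plus population means.

    Denominator is a caller-supplied callable length (bp); the count is the
    number of 0/1 calls for the sample across all sites in ``G``.
    """
    if callable_bp <= 0:
        raise ValueError("callable_bp must be positive")
    het_counts = (G.genotypes == 1).sum(axis=0)
    per_sample = pd.Series(1000.0 * het_counts / callable_bp, index=G.samples,
                           name="het_per_kb")
    pop_means = {pop: float(per_sample.iloc[G.sample_indices(pop)].mean())
                 for pop in G.population_labels()}
    return per_sample, pop_means


def titv_ratio(sites: Sequence[Site]) -> float:
    """Transitions (A<->G, C<->T) over transversions; nan if no transversions."""
    ti = tv = 0
    for s in sites:
        if len(s.alts) != 1:
            continue
        pair = frozenset((s.ref, s.alts[0]))
        if len(pair) != 2 or not pair <= set("ACGT"):
            continue
        if pair in TRANSITIONS:
            ti += 1
        else:
            tv += 1
    if tv == 0:
        return float("nan")
    return ti / tv


def maf_histogram_and_panel_metrics(mafs: np.ndarray, bin: float = 0.01,
                                    low_cut: float = 0.1, high_cut: float = 0.2,
                                    ) -> tuple[pd.DataFrame, dict[str, float]]:
    """MAF spectrum binned at ``bin`` over [0, 0.5] plus panel summary fractions.

    Returns the histogram (bin_start, bin_end, count) and a metrics dict:
    fraction of sites with MAF < ``low_cut``, and the count and fraction with
    MAF > ``high_cut`` -- the quantities that expose ascertainment bias of an
    array panel evaluated outside its discovery population.
    """
    mafs = np.asarray(mafs, dtype=float)
    mafs = mafs[np.isfinite(mafs)]
    edges = np.arange(0.0, 0.5 + bin / 2, bin)
    counts, _ = np.histogram(mafs, bins=edges)
    hist = pd.DataFrame({"bin_start": edges[:-1], "bin_end": edges[1:],
                         "count": counts})
    n = mafs.size
    metrics = {
        "n_sites": int(n),
        "frac_below_low_cut": float((mafs < low_cut).mean()) if n else float("nan"),
        "count_above_high_cut": int((mafs > high_cut).sum()),
        "frac_above_high_cut": float((mafs > high_cut).mean()) if n else float("nan"),
    }
    return hist, metrics


def population_mafs(G: GenotypeMatrix, population: str) -> np.ndarray:
    """Per-site MAF array for one population (nan where all calls missing)."""
    idx = G.sample_indices(population)
    freq, total = _freqs(G.genotypes[:, idx])
    maf = np.minimum(freq, 1.0 - freq)
    maf[total == 0] = np.nan
    return maf
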