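"""Published reference numbers for the six water buffalo genome assemblies.

The pairwise comparison table below holds, for every unordered pair of the
six chromosome-level assemblies, the total SNV count and the total size of
50-10,000 bp structural variants found when the pair is aligned whole-genome
(nucmer anchors, Assemblytics-style SV classes, show-snps SNVs excluding
repeats), as published by the 1000 Buffalo Genomes consortium.  These are
worked-example inputs for :func:`karyofeat.asmdiff.pairwise_summary_means`
and :func:`karyofeat.asmdiff.divergence_percent`; the package does not
re-run the multi-gigabase alignments themselves.
"""

from __future__ import annotations

from .asmdiff import PairwiseSummary

#: Assembly name -> subspecies type.
ASSEMBLY_TYPES: dict[str, str] = {
    "PCC_UOA_SB_1v2": "swamp",   # Philippine carabao, GCA_029407905.2
    "Wang_2023": "swamp",        # Chinese male swamp buffalo
    "CUSA_SWP": "swamp",         # Chinese Fuzhong swamp buffalo
    "UOA_WB_1": "river",         # Italian Mediterranean, GCA_003121395.1
    "NDDB_SH_1": "river",        # Indian Murrah, GCA_019923935.1
    "CUSA_RVB": "river",         # Chinese Murrah
}

#: Chromosome-level assembly length of the swamp reference, bp (2.70 Gb).
PCC_UOA_SB_1V2_CHROM_LENGTH_BP: int = 2_700_000_000

#: Published SNV counts per unordered assembly pair.
PAIRWISE_SNV_COUNTS: dict[tuple[str, str], int] = {
    ("PCC_UOA_SB_1v2", "Wang_2023"): 6_315_498,
    ("PCC_UOA_SB_1v2", "CUSA_SWP"): 5_969_757,
    ("Wang_2023", "CUSA_SWP"): 5_941_882,
    ("PCC_UOA_SB_1v2", "UOA_WB_1"): 12_375_163,
    ("Wang_2023", "UOA_WB_1"): 12_376_399,
    ("CUSA_SWP", "UOA_WB_1"): 11_930_093,
    ("PCC_UOA_SB_1v2", "NDDB_SH_1"): 12_437_983,
    ("Wang_2023", "NDDB_SH_1"): 12_470_447,
    ("CUSA_SWP", "NDDB_SH_1"): 11_984_056,
    ("PCC_UOA_SB_1v2", "CUSA_RVB"): 12_093_156,
    ("Wang_2023", "CUSA_RVB"): 12_082_957,
    ("CUSA_SWP", "CUSA_RVB"): 11_896_391,
    ("UOA_WB_1", "NDDB_SH_1"): 7_999_500,
    ("UOA_WB_1", "CUSA_RVB"): 7_758_580,
    ("NDDB_SH_1", "CUSA_RVB"): 7_771_824,
}

#: Published total SV sizes (bp) per unordered assembly pair.
PAIRWISE_SV_TOTAL_BP: dict[tuple[str, str], int] = {
    ("PCC_UOA_SB_1v2", "Wang_2023"): 17_507_727,
    ("PCC_UOA_SB_1v2", "CUSA_SWP"): 21_907_568,
    ("Wang_2023", "CUSA_SWP"): 22_452_637,
    ("PCC_UOA_SB_1v2", "UOA_WB_1"): 27_064_859,
    ("Wang_2023", "UOA_WB_1"): 27_918_711,
    ("CUSA_SWP", "UOA_WB_1"): 29_250_364,
    ("PCC_UOA_SB_1v2", "NDDB_SH_1"): 27_246_061,
    ("Wang_2023", "NDDB_SH_1"): 28_155_313,
    ("CUSA_SWP", "NDDB_SH_1"): 29_646_973,
    ("PCC_UOA_SB_1v2", "CUSA_RVB"): 32_173_283,
    ("Wang_2023", "CUSA_RVB"): 32_953_777,
    ("CUSA_SWP", "CUSA_RVB"): 33_998_313,
    ("UOA_WB_1", "NDDB_SH_1"): 16_771_137,
    ("UOA_WB_1", "CUSA_RVB"): 23_217_345,
    ("NDDB_SH_1", "CUSA_RVB"): 23_562_063,
}


def published_pairwise_table() -> list[PairwiseSummary]:
    """All 15 unordered pairs as :class:`PairwiseSummary` rows.

    Per-pair SV record counts were not published (only totals in bp), so
    ``sv_count`` is 0 in these rows.
    """
    rows = []
    for pair, snv in PAIRWISE_SNV_COUNTS.items():
        rows.append(PairwiseSummary(
            assembly_a=pair[0], assembly_b=pair[1],
            snv_count=snv, sv_count=0,
            sv_total_bp=PAIRWISE_SV_TOTAL_BP[pair]))
    return rows
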