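"""Telomere counting, satellite clustering and monomer copy counting."""

import numpy as np
import pytest

from karyofeat import telocent
from karyofeat.seqio import Assembly, RepeatAnnotation
from karyofeat.telocent import (cluster_satellites,
                                cluster_satellites_and_select_candidates,
                                count_monomer_copies, count_terminal_motif_units,
                                filter_satellite_annotations, reverse_complement,
                                select_centromere_candidates)

MOTIF = telocent.TELOMERE_MOTIF


def _pad(seq, n=20_000, left=False):
    pad = "A" * (n - len(seq))
    return pad + seq if left else seq + pad


# ---------------------------------------------------------------------------
# Telomere unit counting


def test_pure_array_counts_exact():
    seq = _pad(MOTIF * 100)
    assert count_terminal_motif_units(seq, arm="p") == 100


def test_reverse_complement_strand_counted():
    seq = _pad(reverse_complement(MOTIF) * 60)
    assert count_terminal_motif_units(seq, arm="p") == 60


def test_chromosome_shorter_than_motif():
    assert count_terminal_motif_units("ACG", arm="p") == 0


def test_q_arm_window_is_terminal():
    seq = _pad(MOTIF * 30, n=50_000, left=True)
    assert count_terminal_motif_units(seq, arm="q") == 30
    assert count_terminal_motif_units(seq, arm="p") == 0


@pytest.mark.parametrize("units,kept", [(50, False), (51, True)])
def test_keep_threshold_is_strictly_greater(units, kept):
    asm = Assembly("a", {"c": _pad(MOTIF * units, n=50_000)})
    signals, _ = telocent.call_telomeres(asm, min_units=50)
    by_arm = {s.arm: s for s in signals}
    assert by_arm["p"].unit_count == units
    assert by_arm["p"].kept is kept


def test_morphology_calls():
    chroms = {}
    for i in range(3):  # both arms
        chroms[f"sub{i}"] = _pad(reverse_complement(MOTIF) * 60, 25_000) + \
            _pad(MOTIF * 70, 25_000, left=True)
    for i in range(5):  # q only
        chroms[f"acro{i}"] = "A" * 25_000 + _pad(MOTIF * 70, 25_000, left=True)
    _, morphology = telocent.call_telomeres(Assembly("a", chroms))
    calls = [m.call for m in morphology]
    assert calls.count("sub_metacentric") == 3
    assert calls.count("acrocentric_like") == 5


def test_relaxing_min_units_never_decreases_kept(toy):
    ref, _, _ = toy
    strict, _ = telocent.call_telomeres(ref, min_units=50)
    loose, _ = telocent.call_telomeres(ref, min_units=0)
    assert sum(s.kept for s in loose) >= sum(s.kept for s in strict)


def test_mutations_never_increase_unit_count():
    rng = np.random.default_rng(0)
    units = 200
    arr = np.frombuffer((MOTIF * units).encode(), dtype=np.uint8).copy()
    base = count_terminal_motif_units(_pad(arr.tobytes().decode()), arm="p")
    assert base == units
    for n_mut in (1, 5, 20, 50):
        mutated = arr.copy()
        pos = rng.choice(arr.size, size=n_mut, replace=False)
        mutated[pos] = ord("A")
        count = count_terminal_motif_units(_pad(mutated.tobytes().decode()), arm="p")
        assert count <= units


def test_planted_telomere_units_exact(toy):
    ref, _, truth = toy
    signals, morphology = telocent.call_telomeres(ref)
    for s in signals:
        assert s.unit_count == truth.telomeres[(s.chrom, s.arm)]
    calls = {m.chrom: m.call for m in morphology}
    assert [calls[c] for c in sorted(calls)] == [
        "sub_metacentric", "sub_metacentric", "sub_metacentric",
        "acrocentric_like", "acrocentric_like"]


# ---------------------------------------------------------------------------
# Internal telomere scan


def test_internal_scan_clean_chromosome():
    rng = np.random.default_rng(1)
    seq = "".join(rng.choice(list("AC"), size=100_000))
    assert telocent.scan_internal_telomere_signals(seq) == []


def test_internal_scan_flags_planted_array():
    from karyofeat import synthgenome as sg
    spec = sg.ChromosomeSpec(name="c", length=2_000_000, telomere_q_units=700,
                             internal_telomeres=((1_000_000, 1333),))
    asm, truth = sg.simulate_assembly([spec], seed=7)
    flags = telocent.scan_internal_telomere_signals(asm.chromosomes["c"], chrom="c")
    assert len(flags) == 1
    (flag,) = flags
    assert flag.start <= 1_000_000 and flag.end >= 1_000_000 + 6 * 1333
    assert flag.unit_count >= 1333
    # terminal telomere must not flag
    assert flag.start >= 20_000


def test_internal_scan_below_threshold():
    seq = "A" * 60_000 + MOTIF * 40 + "A" * 60_000
    assert telocent.scan_internal_telomere_signals(seq) == []


# ---------------------------------------------------------------------------
# Satellite filtering and clustering


def _sat(chrom, start, end, div=10.0, family="BTSAT4", cls="Satellite/centr"):
    return RepeatAnnotation(chrom, start, end, family, cls, div)


def test_identity_filter_boundary():
    kept = filter_satellite_annotations([_sat("c", 0, 10, div=39.9)])
    assert len(kept) == 1
    assert filter_satellite_annotations([_sat("c", 0, 10, div=40.0)]) == []


def test_identity_filter_enumeration():
    anns = [_sat("c", i, i + 5, div=d) for i, d in enumerate((10, 20, 30, 40, 50))]
    assert len(filter_satellite_annotations(anns)) == 3


def test_class_filter():
    anns = [_sat("c", 0, 10), _sat("c", 20, 30, cls="LINE/L1")]
    assert len(filter_satellite_annotations(anns)) == 1


def test_cluster_gap_below_threshold_joins():
    anns = [_sat("c", 0, 1000), _sat("c", 901_000, 902_000)]
    clusters = cluster_satellites(anns)
    assert [c.n_repeats for c in clusters["c"]] == [2]


def test_cluster_gap_at_threshold_splits():
    anns = [_sat("c", 0, 1000), _sat("c", 1_001_000, 1_002_000)]
    clusters = cluster_satellites(anns)
    assert [c.n_repeats for c in clusters["c"]] == [1, 1]


def test_clustering_order_independent_and_idempotent():
    rng = np.random.default_rng(2)
    anns = []
    for _ in range(40):
        s = int(rng.integers(0, 8_000_000))
        anns.append(_sat("c", s, s + int(rng.integers(100, 2000))))
    ref_clusters = cluster_satellites(anns)
    shuffled = list(anns)
    rng.shuffle(shuffled)
    got = cluster_satellites(shuffled)
    key = lambda cl: [(c.start, c.end, c.n_repeats) for c in cl]  # noqa: E731
    assert key(got["c"]) == key(ref_clusters["c"])
    # idempotence: re-clustering cluster member lists changes nothing
    flat = [m for c in ref_clusters["c"] for m in c.members]
    assert key(cluster_satellites(flat)["c"]) == key(ref_clusters["c"])


def _transitive_closure_oracle(anns, max_gap):
    """Brute-force single-linkage: edges between any two repeats closer than max_gap."""
    n = len(anns)
    adj = [[False] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            a, b = anns[i], anns[j]
            gap = max(b.start - a.end, a.start - b.end)
            if a.chrom == b.chrom and gap < max_gap:
                adj[i][j] = True
    groups, seen = [], set()
    for i in range(n):
        if i in seen:
            continue
        stack, comp = [i], set()
        while stack:
            k = stack.pop()
            if k in comp:
                continue
            comp.add(k)
            stack.extend(j for j in range(n) if adj[k][j] and j not in comp)
        seen |= comp
        groups.append(sorted((anns[k].start, anns[k].end) for k in comp))
    return sorted(groups)


@pytest.mark.parametrize("trial", range(10))
def test_clustering_matches_transitive_closure_oracle(trial):
    rng = np.random.default_rng(100 + trial)
    n = int(rng.integers(1, 50))
    anns = []
    for _ in range(n):
        s = int(rng.integers(0, 5_000_000))
        anns.append(_sat("c", s, s + int(rng.integers(50, 400_000))))
    max_gap = 1_000_000
    clusters = cluster_satellites(anns, max_gap=max_gap)["c"]
    got = sorted(sorted((m.start, m.end) for m in c.members) for c in clusters)
    assert got == _transitive_closure_oracle(anns, max_gap)


# ---------------------------------------------------------------------------
# Centromere candidate selection


def test_candidate_is_dominant_cluster(toy):
    ref, _, truth = toy
    sat = filter_satellite_annotations(truth.annotations)
    clusters, cands = cluster_satellites_and_select_candidates(sat)
    for chrom, cand in cands.items():
        t = truth.centromeres[chrom]
        inter = max(0, min(cand.end, t["end"]) - max(cand.start, t["start"]))
        union = max(cand.end, t["end"]) - min(cand.start, t["start"])
        assert inter / union >= 0.9
        assert cand.n_repeats == t["copies"]


def test_candidate_tiebreak_total_bp_then_leftmost():
    # two clusters of 2 repeats each; second has more bp
    anns = [_sat("c", 0, 100), _sat("c", 200, 300),
            _sat("c", 3_000_000, 3_005_000), _sat("c", 3_010_000, 3_015_000)]
    clusters = cluster_satellites(anns)
    cand = select_centromere_candidates(clusters)["c"]
    assert cand.start == 3_000_000
    # equal bp too: leftmost wins
    anns2 = [_sat("c", 0, 100), _sat("c", 200, 300),
             _sat("c", 3_000_000, 3_000_100), _sat("c", 3_010_000, 3_010_100)]
    cand2 = select_centromere_candidates(cluster_satellites(anns2))["c"]
    assert cand2.start == 0


def test_chromosome_without_satellites_has_no_candidate():
    clusters = cluster_satellites([])
    assert select_centromere_candidates(clusters) == {}


def test_selector_by_total_bp():
    anns = [_sat("c", 0, 50_000),  # 1 big repeat
            _sat("c", 3_000_000, 3_000_100), _sat("c", 3_010_000, 3_010_100),
            _sat("c", 3_020_000, 3_020_100)]  # 3 small ones
    clusters = cluster_satellites(anns)
    assert select_centromere_candidates(clusters, by="n_repeats")["c"].start == 3_000_000
    assert select_centromere_candidates(clusters, by="total_bp")["c"].start == 0


# ---------------------------------------------------------------------------
# Monomer copy counting


def test_exact_tiling_counts_exact():
    rng = np.random.default_rng(3)
    monomer = "".join(rng.choice(list("ACGT"), size=673))
    region = monomer * 50
    copies, span = count_monomer_copies(region, monomer)
    assert copies == 50
    assert span == (0, 50 * 673)


def test_mutated_tiling_within_tolerance(toy):
    ref, _, truth = toy
    mono = truth.monomers[673]
    t = truth.centromeres["chr1"]
    region = ref.chromosomes["chr1"][t["start"]:t["end"]]
    copies, span = count_monomer_copies(region, mono)
    assert copies == t["copies"]
    assert copies * 673 <= span[1] - span[0] <= copies * 673 + 673


def test_reverse_strand_array_counted():
    rng = np.random.default_rng(4)
    monomer = "".join(rng.choice(list("ACGT"), size=100))
    region = reverse_complement(monomer * 20)
    copies, _ = count_monomer_copies(region, monomer)
    assert copies == 20


def test_no_homology_gives_zero():
    copies, _ = count_monomer_copies("A" * 10_000, "CGT" * 10)
    assert copies == 0


def test_monomer_longer_than_region():
    assert count_monomer_copies("ACGT" * 5, "ACGT" * 100)[0] == 0


# ---------------------------------------------------------------------------
# Repeat length summaries


def test_repeat_length_summary_hand_computed():
    anns = [RepeatAnnotation("c", 0, 1000, "L1", "LINE/L1", 5.0),
            RepeatAnnotation("c", 2000, 4000, "L1", "LINE/L1", 5.0),
            RepeatAnnotation("c", 5000, 8000, "L1", "LINE/L1", 5.0),
            RepeatAnnotation("c", 10_000, 15_000, "L1", "LINE/L1", 5.0)]
    frame = telocent.summarize_repeat_lengths(anns, classes=["LINE/L1"])
    row = frame.loc["LINE/L1"]
    assert row["n"] == 2  # strict > 2 kb: 3k and 5k
    assert row["median"] == 4000


def test_repeat_length_summary_empty_and_partitioned():
    frame = telocent.summarize_repeat_lengths([], classes=["LINE/L1", "LINE/RTE-BovB"])
    assert (frame["n"] == 0).all()
    anns = [RepeatAnnotation("c", 0, 3000, "L1", "LINE/L1", 5.0),
            RepeatAnnotation("c", 0, 5000, "BovB", "LINE/RTE-BovB", 5.0)]
    frame = telocent.summarize_repeat_lengths(anns, classes=["LINE/L1", "LINE/RTE-BovB"])
    assert frame.loc["LINE/L1", "n"] == 1
    assert frame.loc["LINE/RTE-BovB", "n"] == 1
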