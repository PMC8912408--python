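"""Small-inversion detection/correction and genomic inversions."""

import numpy as np
import pytest

from conftest import (EIGHT_TAXON_TREE, brute_flank_scan, call_is_precise,
                      inversion_recovered)
from plastshift import (Alignment, SmallInversion, apply_inversion_correction,
                        detect_genomic_inversion, detect_small_inversions,
                        find_flanking_ir)
from plastshift.errors import (AnchorError, BoundsError,
                               InsufficientTaxaError, OverlapError)
from plastshift.model import AnnotatedPlastome, revcomp
from plastshift.synthetic import (StructuralEvent, SyntheticPlastomeSpec,
                                  generate_plastome, random_inversion_events,
                                  simulate_alignment)


def test_planted_block_detected_with_exact_interval():
    aln, truth = simulate_alignment(
        EIGHT_TAXON_TREE, 500, seed=42,
        inversion_events=[{"start": 100, "length": 20, "flank": 6,
                           "carriers": ["E"]}])
    calls = detect_small_inversions(aln)
    assert len(calls) == 1
    (call,) = calls
    assert call.interval == (100, 120)
    assert call.carriers == ["E"]
    assert call.identity_revcomp > call.identity_forward
    assert call.flank_ir_length == 6


def test_identical_rows_give_no_calls():
    aln = Alignment(list("ABCD"), ["ACGTACGTAC"] * 4)
    assert detect_small_inversions(aln) == []


def test_too_few_rows_rejected():
    aln = Alignment(list("ABC"), ["ACGT"] * 3)
    with pytest.raises(InsufficientTaxaError):
        detect_small_inversions(aln)


def test_detector_recall_and_precision_on_planted_truth():
    """≥95% recall and precision on 20 planted inversions (lengths 3–62)
    per replicate, across seeds."""
    recovered = total = precise = calls_total = 0
    for seed in range(6):
        rng = np.random.default_rng(1000 + seed)
        events = random_inversion_events(rng, list("ABCDEFGH"), 10_000,
                                         n_events=20)
        aln, truth = simulate_alignment(EIGHT_TAXON_TREE, 10_000, seed=seed,
                                        inversion_events=events)
        calls = detect_small_inversions(aln)
        recovered += sum(inversion_recovered(t, calls)
                         for t in truth["inversions"])
        total += len(truth["inversions"])
        precise += sum(call_is_precise(c, truth["inversions"]) for c in calls)
        calls_total += len(calls)
    assert recovered / total >= 0.95
    assert precise / calls_total >= 0.95


def test_correction_restores_pre_inversion_alignment():
    rng = np.random.default_rng(77)
    events = random_inversion_events(rng, list("ABCDEFGH"), 5_000,
                                     n_events=10)
    aln, truth = simulate_alignment(EIGHT_TAXON_TREE, 5_000, seed=5,
                                    inversion_events=events)
    truth_calls = [SmallInversion(interval=t.interval, carriers=t.carriers,
                                  identity_forward=0.0,
                                  identity_revcomp=100.0)
                   for t in truth["inversions"]]
    corrected = apply_inversion_correction(aln, truth_calls)
    assert corrected.rows == truth["pre_inversion_alignment"].rows
    # involution: applying twice returns the input
    assert apply_inversion_correction(corrected, truth_calls).rows == aln.rows
    # detector finds nothing at the corrected columns
    residual = detect_small_inversions(corrected)
    for t in truth["inversions"]:
        assert not any(
            max(c.interval[0], t.interval[0]) < min(c.interval[1], t.interval[1])
            for c in residual)


def test_correction_with_gaps_preserves_geometry():
    aln = Alignment(list("ABCD"),
                    ["AACCGGTTAA", "AACCGGTTAA", "AACCGGTTAA",
                     "AA-CGG-TAA"])
    inv = SmallInversion(interval=(2, 8), carriers=["D"],
                         identity_forward=0.0, identity_revcomp=100.0)
    out = apply_inversion_correction(aln, [inv])
    row = out.row("D")
    assert row[2] == "-" and row[6] == "-"  # gaps stayed put
    assert "".join(c for c in row[2:8] if c != "-") == \
        revcomp("".join(c for c in aln.row("D")[2:8] if c != "-"))
    assert apply_inversion_correction(out, [inv]).rows == aln.rows


def test_empty_inversion_list_is_identity():
    aln = Alignment(list("ABCD"), ["ACGTAC"] * 4)
    assert apply_inversion_correction(aln, []).rows == aln.rows


def test_overlapping_intervals_rejected():
    aln = Alignment(list("ABCD"), ["ACGTACGTAC"] * 4)
    a = SmallInversion((1, 5), ["A"], 0.0, 100.0)
    b = SmallInversion((4, 8), ["B"], 0.0, 100.0)
    with pytest.raises(OverlapError):
        apply_inversion_correction(aln, [a, b])


# ---------------------------------------------------------------------------
# Flanking complementary repeats


def test_constructed_39bp_flanks_found():
    rng = np.random.default_rng(8)
    arm = "".join("ACGT"[i] for i in rng.integers(0, 4, 39))
    mid = "".join("ACGT"[i] for i in rng.integers(0, 4, 489))
    pad = "".join("ACGT"[i] for i in rng.integers(0, 4, 2000))
    seq = pad + arm + mid + revcomp(arm) + pad
    g = AnnotatedPlastome("x", seq)
    start = len(pad) + 39
    k = find_flanking_ir(g, (start, start + 489))
    assert k >= 39  # at least the constructed arm (chance can extend it)
    assert k == brute_flank_scan(seq, start, start + 489, 200)


@pytest.mark.parametrize("seed", range(5))
def test_flank_scan_matches_bruteforce_on_random_intervals(seed):
    rng = np.random.default_rng(seed)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 2000))
    g = AnnotatedPlastome("x", seq)
    s = int(rng.integers(300, 1500))
    e = s + int(rng.integers(10, 200))
    k = find_flanking_ir(g, (s, e))
    assert k == brute_flank_scan(seq, s, e, 200)
    assert k <= 6  # long chance flanks are vanishingly unlikely


def test_non_complementary_immediate_flanks_give_zero():
    g = AnnotatedPlastome("x", "AAAAACGTAAAAA")  # flanks A vs A: comp fails
    assert find_flanking_ir(g, (5, 8)) == 0


def test_linear_bounds_without_wrap_permission():
    g = AnnotatedPlastome("x", "ACGTACGTACGT")
    with pytest.raises(BoundsError):
        find_flanking_ir(g, (0, 4), wrap=False)


# ---------------------------------------------------------------------------
# Genomic inversions


@pytest.fixture(scope="module")
def inverted_pair():
    """Query/reference genomes differing only by a 489-bp inversion with
    39-bp complementary flanks around the trnE/trnY/trnD cluster."""
    common = {"region": ("psbM", "trnT-GGT"), "length": 489, "flank": 39}
    query, tq = generate_plastome(SyntheticPlastomeSpec(
        seed=5, identifier="query",
        events=[StructuralEvent("genomic_inversion", dict(common))]))
    ref, _ = generate_plastome(SyntheticPlastomeSpec(
        seed=5, identifier="ref",
        events=[StructuralEvent("genomic_inversion",
                                dict(common, invert=False))]))
    return query, ref, tq


def test_planted_genomic_inversion_recovered(inverted_pair):
    query, ref, truth = inverted_pair
    inv = detect_genomic_inversion(query, ref, ("psbM", "trnT-GGT"))
    assert inv is not None
    assert inv.length == 489
    assert inv.flank_length == 39
    assert sorted(inv.affected_features) == \
        sorted(truth.inversions[0].affected_features)
    assert set(inv.affected_features) == {"trnD-GTC", "trnY-GTA", "trnE-TTC"}


def test_identical_genomes_give_none(inverted_pair):
    _, ref, _ = inverted_pair
    assert detect_genomic_inversion(ref, ref, ("psbM", "trnT-GGT")) is None


def test_missing_anchor_raises(inverted_pair):
    query, ref, _ = inverted_pair
    with pytest.raises(AnchorError):
        detect_genomic_inversion(query, ref, ("nonexistent", "trnT-GGT"))
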