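"""Junction context, insertion screening, in-silico PCR and depth QC."""

import numpy as np
import pytest

from conftest import brute_pcr_products
from plastshift import (AnnotatedPlastome, DepthProfile, classify_junction,
                        detect_inverted_repeat, insilico_pcr,
                        junction_depth_qc, locate_junctions,
                        screen_spacer_insertion)
from plastshift.errors import (AnnotationRequiredError, PrimerAlphabetError,
                               SpacerUndefinedError, ValidationError,
                               WindowTooLargeError)
from plastshift.junctions import _find_spacer
from plastshift.model import revcomp
from plastshift.synthetic import (StructuralEvent, SyntheticPlastomeSpec,
                                  generate_plastome, payload_library,
                                  simulate_depth_profile)


def test_junction_overlap_matches_generator_truth():
    """A J_LB expansion that cuts through a gene leaves the junction
    inside that gene, with the overlap extent the generator recorded."""
    spec = SyntheticPlastomeSpec(seed=9, events=[
        StructuralEvent("jlb_expand", {"k": 1200})])
    genome, truth = generate_plastome(spec)
    part = detect_inverted_repeat(genome)
    profile = locate_junctions(genome, part)
    gene, extent = truth.junction_overlaps["J_LB"]
    entry = profile.entries["J_LB"]
    assert entry.overlapping_feature == gene
    assert entry.overlap_into_ir == extent
    assert classify_junction(profile, "J_LB").label == f"within:{gene}"


def test_junction_in_intron_classification():
    """Releasing IR bases up to the middle of the ndhB intron puts J_LB
    between that gene's exons."""
    spec = SyntheticPlastomeSpec(seed=8, events=[
        StructuralEvent("jlb_contract", {"k": 10_500})])
    genome, _ = generate_plastome(spec)
    part = detect_inverted_repeat(genome)
    profile = locate_junctions(genome, part)
    assert classify_junction(profile, "J_LB").label == "within-intron:ndhB"


def test_ycf1_spans_ssc_ira_junction(default_genome):
    genome, truth = default_genome
    part = detect_inverted_repeat(genome)
    profile = locate_junctions(genome, part)
    gene, extent = truth.junction_overlaps["J_SA"]
    assert classify_junction(profile, "J_SA").label == f"within:{gene}"
    assert profile.entries["J_SA"].overlap_into_ir == extent
    # the truncated mirror copy abuts the IRb/SSC junction
    assert profile.entries["J_SB"].left_feature == gene
    assert profile.entries["J_SB"].left_distance == 0


def test_payload_genes_mirror_between_ir_copies(insertion_genome):
    _, genome, _ = insertion_genome
    part = detect_inverted_repeat(genome)
    profile = locate_junctions(genome, part)
    payload = classify_junction(profile, "J_LB").payload_genes
    assert sorted(payload) == ["psbA", "psbA", "trnH-GTG", "trnH-GTG"]
    # mirror consistency: each payload copy in IRb has a reverse-complement
    # twin in IRa at the mirrored offset
    canonical = part.apply_to(genome)
    for name in ("psbA", "trnH-GTG"):
        copies = [f for f in canonical.features
                  if f.name == name and part.region_of(f.start) in
                  ("IRb", "IRa")]
        assert len(copies) == 2
        (b,), (a,) = ([f for f in copies if part.region_of(f.start) == r]
                      for r in ("IRb", "IRa"))
        off_b = b.start - part.irb[0]
        off_a = part.ira[1] - a.end
        assert off_b == off_a
        assert canonical.feature_sequence(b) == canonical.feature_sequence(a)


def test_missing_annotation_raises(default_genome):
    genome, _ = default_genome
    part = detect_inverted_repeat(genome)
    bare = AnnotatedPlastome("bare", genome.sequence, [])
    with pytest.raises(AnnotationRequiredError):
        locate_junctions(bare, part)


# ---------------------------------------------------------------------------
# Insertion screening


def test_payload_insertion_recovered(insertion_genome):
    spec, genome, truth = insertion_genome
    planted = truth.insertions[0]
    report = screen_spacer_insertion(
        genome, ("trnV-GAC", "rrn16"), payload_library(spec),
        baseline=planted.baseline_spacer_length)
    assert report.insertion_present
    assert abs(report.insertion_length - planted.length) <= 10
    assert sorted(f.gene for f in report.embedded_fragments) == \
        ["psbA", "trnH"]
    for frag in report.embedded_fragments:
        assert frag.identity >= 70.0
        assert report.insertion_interval[0] <= frag.spacer_offset \
            < report.insertion_interval[1]


def test_noncoding_insertion_has_no_payload_fragments():
    spec = SyntheticPlastomeSpec(seed=12, events=[
        StructuralEvent("spacer_insertion",
                        {"spacer": ("trnV-GAC", "rrn16"), "length": 1153,
                         "payload_genes": []})])
    genome, truth = generate_plastome(spec)
    report = screen_spacer_insertion(
        genome, ("trnV-GAC", "rrn16"), payload_library(spec),
        baseline=truth.insertions[0].baseline_spacer_length)
    assert report.insertion_present
    assert report.insertion_length == 1153
    assert report.embedded_fragments == []


def test_no_event_means_no_insertion(default_genome):
    genome, _ = default_genome
    baseline = _find_spacer(genome, "trnV-GAC", "rrn16")
    report = screen_spacer_insertion(genome, ("trnV-GAC", "rrn16"),
                                     baseline=baseline[1] - baseline[0])
    assert not report.insertion_present and report.insertion_length == 0


def test_reference_panel_baseline(insertion_genome):
    spec, genome, truth = insertion_genome
    base_genome, _ = generate_plastome(
        SyntheticPlastomeSpec(seed=spec.seed))
    s, e = _find_spacer(base_genome, "trnV-GAC", "rrn16")
    panel = [base_genome.fetch(s, e)] * 3
    report = screen_spacer_insertion(genome, ("trnV-GAC", "rrn16"),
                                     baseline=panel)
    assert report.insertion_present
    assert abs(report.insertion_length - truth.insertions[0].length) <= 10


def test_missing_flank_gene_raises(default_genome):
    genome, _ = default_genome
    with pytest.raises(SpacerUndefinedError):
        screen_spacer_insertion(genome, ("nadH", "rrn16"), baseline=100)


def test_screen_recovers_planted_length_across_seeds():
    """Planted insertion length recovered within ±10 bp, payload
    fragments all found, across many random seeds."""
    rng = np.random.default_rng(42)
    for _ in range(12):
        seed = int(rng.integers(0, 2**31))
        length = int(rng.integers(700, 1400))
        spec = SyntheticPlastomeSpec(seed=seed, events=[
            StructuralEvent("jla_shift_with_insertion",
                            {"spacer": ("trnV-GAC", "rrn16"),
                             "length": length,
                             "payload_genes": ["psbA-fragment", "trnH"]})])
        genome, truth = generate_plastome(spec)
        planted = truth.insertions[0]
        report = screen_spacer_insertion(
            genome, ("trnV-GAC", "rrn16"), payload_library(spec),
            baseline=planted.baseline_spacer_length)
        assert abs(report.insertion_length - length) <= 10
        assert sorted(f.gene for f in report.embedded_fragments) == \
            ["psbA", "trnH"]


# ---------------------------------------------------------------------------
# In-silico PCR


def test_pcr_amplifies_across_planted_insertion(insertion_genome):
    _, genome, truth = insertion_genome
    part = detect_inverted_repeat(genome)
    canonical = part.apply_to(genome)
    trnv = min(canonical.find_features("trnV-GAC"), key=lambda f: f.start)
    fwd = canonical.feature_sequence(trnv)[10:30]
    rrn = min(canonical.find_features("rrn16"), key=lambda f: f.start)
    rev = revcomp(canonical.sequence[rrn.start + 20:rrn.start + 40])
    amps = insilico_pcr(canonical, fwd, rev, max_product=3000)
    assert len(amps) == 2  # one product per IR copy
    expected = truth.insertions[0].length + \
        truth.insertions[0].baseline_spacer_length
    for amp in amps:
        assert amp.product_length > expected  # spans spacer + primer offsets


def test_pcr_negative_when_sites_divergent():
    """Primer pair in divergent orientation yields no product within the
    size cap — the survey's negative-control logic."""
    rng = np.random.default_rng(3)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 4000))
    fwd = seq[100:120]
    rev = seq[900:920]  # same strand as fwd: divergent pair
    g = AnnotatedPlastome("x", seq)
    amps = insilico_pcr(g, fwd, rev, max_mismatch=0, max_product=2000)
    assert amps == []


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_pcr_equals_bruteforce_scan(seed):
    rng = np.random.default_rng(seed)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 3000))
    fwd = seq[500:519]
    rev = revcomp(seq[1800:1821])
    g = AnnotatedPlastome("x", seq)
    amps = insilico_pcr(g, fwd, rev, max_mismatch=1, max_product=2500)
    got = {(a.forward_site[0], a.product_length) for a in amps}
    assert got == brute_pcr_products(seq, fwd, rev, 1, 2500)


def test_pcr_palindromic_primer_pair_deduplicated():
    rng = np.random.default_rng(9)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 2000))
    fwd = seq[300:320]
    rev = revcomp(fwd)
    g = AnnotatedPlastome("x", seq)
    amps = insilico_pcr(g, fwd, rev, max_mismatch=0, max_product=1000)
    got = {(a.forward_site[0], a.product_length) for a in amps}
    assert got == brute_pcr_products(seq, fwd, rev, 0, 1000)


def test_pcr_rejects_bad_primers(default_genome):
    genome, _ = default_genome
    with pytest.raises(PrimerAlphabetError):
        insilico_pcr(genome, "ACGTNACGTACGTACGTA", "ACGTACGTACGTACGTA")
    with pytest.raises(ValidationError):
        insilico_pcr(genome, "ACGTACG", "ACGTACGTACGTACGTA")


# ---------------------------------------------------------------------------
# Depth QC


@pytest.fixture(scope="module")
def qc_setup():
    genome, _ = generate_plastome(SyntheticPlastomeSpec(seed=7))
    part = detect_inverted_repeat(genome)
    profile = locate_junctions(genome, part)
    return genome, part, profile


def test_uniform_depth_passes_all_junctions(qc_setup):
    genome, _, profile = qc_setup
    depth = DepthProfile(genome.identifier,
                         np.full(genome.length, 60, dtype=np.int64))
    report = junction_depth_qc(profile, depth)
    assert all(e.flag == "pass" for e in report.entries.values())


def test_simulated_dip_flags_only_jlb(qc_setup):
    genome, part, profile = qc_setup
    depth = simulate_depth_profile(genome, 60, ["J_LB"], 0.05, seed=4,
                                   partition=part)
    report = junction_depth_qc(profile, depth)
    assert report.entries["J_LB"].flag == "drop-suspect"
    for j in ("J_SB", "J_SA", "J_LA"):
        assert report.entries[j].flag == "pass"


def test_zero_coverage_reported_explicitly(qc_setup):
    genome, _, profile = qc_setup
    depth = DepthProfile(genome.identifier,
                         np.zeros(genome.length, dtype=np.int64))
    report = junction_depth_qc(profile, depth)
    assert all(e.flag == "zero-coverage" for e in report.entries.values())


def test_window_larger_than_region_rejected(qc_setup):
    genome, _, profile = qc_setup
    depth = DepthProfile(genome.identifier,
                         np.full(genome.length, 60, dtype=np.int64))
    with pytest.raises(WindowTooLargeError):
        junction_depth_qc(profile, depth, window=20_000)
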