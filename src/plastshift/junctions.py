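"""IR junction localization, classification, insertion screening,
in-silico PCR and junction depth QC.

Junction naming follows the quadripartite convention: J_LB = LSC/IRb,
J_SB = IRb/SSC, J_SA = SSC/IRa, J_LA = IRa/LSC.  A junction's position
is the first base of the downstream region (0-based, canonical
rotation); overlap extents are measured into the IR.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field

import numpy as np
from Bio import Align

from .errors import (AmbiguityError, AnnotationRequiredError, BoundsError,
                     PrimerAlphabetError, SpacerUndefinedError,
                     ValidationError, WindowTooLargeError)
from .model import AnnotatedPlastome, DepthProfile, GeneFeature, revcomp, same_gene
from .quadripartite import QuadripartitePartition

JUNCTIONS = ("J_LB", "J_SB", "J_SA", "J_LA")

#: which side of each junction is the IR (for overlap-extent direction)
_IR_SIDE = {"J_LB": "right", "J_SB": "left", "J_SA": "right", "J_LA": "left"}


@dataclass
class JunctionEntry:
    junction: str
    position: int
    left_feature: str | None
    left_distance: int
    right_feature: str | None
    right_distance: int
    overlapping_feature: str | None = None
    overlap_into_ir: int = 0
    in_intron: bool = False


@dataclass
class JunctionClass:
    label: str
    payload_genes: list[str] = field(default_factory=list)


@dataclass
class JunctionProfile:
    genome: AnnotatedPlastome  # canonical orientation
    partition: QuadripartitePartition
    entries: dict[str, JunctionEntry]


@dataclass
class EmbeddedFragment:
    gene: str
    matched_length: int
    identity: float
    spacer_offset: int


@dataclass
class InsertionReport:
    spacer: tuple[str, str]
    observed_length: int
    baseline_length: int
    insertion_present: bool
    insertion_interval: tuple[int, int]  # offsets within the spacer
    insertion_length: int
    embedded_fragments: list[EmbeddedFragment] = field(default_factory=list)


@dataclass
class Amplicon:
    forward_site: tuple[int, str, int]  # (position, strand, mismatches)
    reverse_site: tuple[int, str, int]
    product_length: int
    spans_junctions: list[str] = field(default_factory=list)


@dataclass
class JunctionQC:
    junction: str
    median_left: float
    median_right: float
    inner_median: float
    drop_ratio: float
    flag: str  # pass | drop-suspect | zero-coverage


@dataclass
class JunctionQCReport:
    entries: dict[str, JunctionQC]


def _feature_span_circular(feat: GeneFeature, n: int) -> tuple[int, int]:
    """Outer span as (start, end) with end possibly > n for wrapping
    features."""
    s, e = feat.start, feat.end
    if feat.may_wrap_origin or e < s:
        return s, feat.intervals[-1][1] + n if feat.intervals[-1][1] <= s else e
    return s, e


def locate_junctions(plastome: AnnotatedPlastome,
                     partition: QuadripartitePartition) -> JunctionProfile:
    """Report per-junction gene context on the canonical orientation.

    For each junction: the nearest feature ending on its left, the
    nearest feature starting on its right (circular distances), and any
    feature overlapping the junction, with the overlap extent measured
    into the IR.
    """
    if not plastome.features:
        raise AnnotationRequiredError(
            f"{plastome.identifier}: junction context requires annotation")
    genome = partition.apply_to(plastome)
    n = genome.length
    entries: dict[str, JunctionEntry] = {}
    for junc, pos in partition.junction_positions().items():
        left_feat, left_dist = None, n
        right_feat, right_dist = None, n
        overlap_feat, overlap_extent, in_intron = None, 0, False
        for f in genome.features:
            s, e = _feature_span_circular(f, n)
            for shift in (0, -n, n):
                ss, ee = s + shift, e + shift
                if ss <= pos < ee:
                    extent = (ee - pos) if _IR_SIDE[junc] == "right" \
                        else (pos - ss)
                    if overlap_feat is None or extent > overlap_extent:
                        overlap_feat = f.name
                        overlap_extent = extent
                        in_intron = f.in_intron((pos - shift) % n) \
                            if len(f.intervals) > 1 else False
            d_left = (pos - e) % n
            if d_left < left_dist:
                left_dist, left_feat = d_left, f.name
            d_right = (s - pos) % n
            if d_right < right_dist:
                right_dist, right_feat = d_right, f.name
        entries[junc] = JunctionEntry(
            junction=junc, position=pos,
            left_feature=left_feat, left_distance=left_dist,
            right_feature=right_feat, right_distance=right_dist,
            overlapping_feature=overlap_feat,
            overlap_into_ir=overlap_extent if overlap_feat else 0,
            in_intron=in_intron,
        )
    return JunctionProfile(genome=genome, partition=partition, entries=entries)


def _payload_genes(profile: JunctionProfile) -> list[str]:
    """LSC-origin genes (trnH, psbA — full or partial copies) whose
    intervals lie inside either IR copy, in genomic order."""
    part = profile.partition
    hits = []
    for f in profile.genome.features:
        if not (same_gene(f.name, "trnH") or same_gene(f.name, "psbA")):
            continue
        s, e = f.span()
        if e < s:
            continue
        region_s = part.region_of(s)
        region_e = part.region_of(min(e, part.genome_length) - 1)
        if region_s in ("IRb", "IRa") and region_e == region_s:
            hits.append((s, f.name))
    return [name for _, name in sorted(hits)]


def classify_junction(profile: JunctionProfile, junction: str) -> JunctionClass:
    """Classify a junction as within:<gene>, within-intron:<gene>, or
    between:<A>,<B>, and list the LSC-origin payload genes captured
    inside the IR."""
    if junction not in profile.entries:
        raise KeyError(junction)
    entry = profile.entries[junction]
    payload = _payload_genes(profile)
    if entry.overlapping_feature is not None:
        if entry.in_intron:
            return JunctionClass(f"within-intron:{entry.overlapping_feature}",
                                 payload)
        return JunctionClass(f"within:{entry.overlapping_feature}", payload)
    return JunctionClass(
        f"between:{entry.left_feature},{entry.right_feature}", payload)


# ---------------------------------------------------------------------------
# Spacer insertion screening


def _find_spacer(plastome: AnnotatedPlastome, gene_a: str, gene_b: str,
                 max_span: int | None = None) -> tuple[int, int]:
    """Genomic [start, end) of the intergenic spacer between the closest
    adjacent placements of the two named genes (circular)."""
    n = plastome.length
    feats_a = plastome.find_features(gene_a)
    feats_b = plastome.find_features(gene_b)
    if not feats_a:
        raise SpacerUndefinedError(f"flanking gene {gene_a!r} absent")
    if not feats_b:
        raise SpacerUndefinedError(f"flanking gene {gene_b!r} absent")
    if max_span is None:
        max_span = n // 4
    candidates: list[tuple[int, int, int]] = []
    for fa in feats_a:
        for fb in feats_b:
            sa, ea = _feature_span_circular(fa, n)
            sb, eb = _feature_span_circular(fb, n)
            gap_ab = (sb - ea) % n  # a then b
            gap_ba = (sa - eb) % n  # b then a
            if 0 < gap_ab <= max_span:
                candidates.append((gap_ab, ea % n, (ea + gap_ab) % n))
            if 0 < gap_ba <= max_span:
                candidates.append((gap_ba, eb % n, (eb + gap_ba) % n))
    if not candidates:
        raise SpacerUndefinedError(
            f"no adjacent {gene_a}–{gene_b} placement within {max_span} bp")
    best_len = min(c[0] for c in candidates)
    best = sorted(c for c in candidates if c[0] == best_len)
    # the two IR copies carry mirror instances: identical up to
    # reverse complement
    seqs = {min(sq, revcomp(sq)) for sq in
            (plastome.fetch(s, s + length) for length, s, _ in best)}
    if len(seqs) > 1:
        raise AmbiguityError(
            f"multiple non-identical {gene_a}–{gene_b} spacer instances")
    length, s = best_len, min(s for _, s, _ in best)
    return s, s + length


def _local_align_fragments(spacer: str, payload_library: dict[str, str],
                           min_identity: float, min_length: int,
                           min_score: float = 30.0
                           ) -> list[EmbeddedFragment]:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    out = []
    for name, seq in payload_library.items():
        best = None
        for query in (seq, revcomp(seq)):
            if not spacer or not query:
                continue
            alns = aligner.align(spacer, query)
            if len(alns) == 0:
                continue
            aln = alns[0]
            if best is None or aln.score > best.score:
                best = aln
        if best is None:
            continue
        target_idx = best.aligned[0]
        query_idx = best.aligned[1]
        matches = 0
        aligned_cols = 0
        for (ts, te), (qs, qe) in zip(target_idx, query_idx):
            t_seg = spacer[ts:te]
            q_seg = str(best.query)[qs:qe]
            matches += sum(a == b for a, b in zip(t_seg, q_seg))
            aligned_cols += te - ts
        span_start = int(target_idx[0][0])
        span_end = int(target_idx[-1][1])
        span = span_end - span_start
        q_span = int(query_idx[-1][1]) - int(query_idx[0][0])
        # identity over all alignment columns, gaps included
        ncols = aligned_cols + (span - aligned_cols) + (q_span - aligned_cols)
        identity = 100.0 * matches / ncols if ncols else 0.0
        if span >= min_length and identity >= min_identity \
                and best.score >= min_score:
            out.append(EmbeddedFragment(gene=name, matched_length=span,
                                        identity=round(identity, 1),
                                        spacer_offset=span_start))
    return out


def _longest_common_prefix(a: str, b: str) -> int:
    m = min(len(a), len(b))
    for i in range(m):
        if a[i] != b[i]:
            return i
    return m


def screen_spacer_insertion(plastome: AnnotatedPlastome,
                            spacer: tuple[str, str],
                            payload_library: dict[str, str] | None = None,
                            baseline: int | str | list = 0,
                            min_excess: int = 200,
                            min_identity: float = 70.0,
                            min_fragment_length: int = 50,
                            min_fragment_score: float = 30.0) -> InsertionReport:
    """Screen a named spacer for an insertion relative to a baseline.

    ``baseline`` is an expected spacer length (int), a reference spacer
    sequence (str), or a panel of either (list; the median length is the
    baseline, and the first sequence anchors the insertion interval).
    An insertion is called when the observed spacer exceeds the baseline
    by at least ``min_excess`` bases.  Payload pseudogene fragments are
    located by local alignment (match +1, mismatch −1, gap −2) and
    reported at ≥ ``min_identity``% (over all alignment columns) over
    ≥ ``min_fragment_length`` bp, with an alignment-score floor
    (``min_fragment_score``) screening out chance similarities.
    """
    s, e = _find_spacer(plastome, *spacer)
    spacer_seq = plastome.fetch(s, e)
    observed = len(spacer_seq)

    ref_seq: str | None = None
    if isinstance(baseline, (int, np.integer)):
        baseline_len = int(baseline)
    elif isinstance(baseline, str):
        ref_seq = baseline.upper()
        baseline_len = len(ref_seq)
    else:
        lengths = [len(b) if isinstance(b, str) else int(b) for b in baseline]
        baseline_len = int(statistics.median(lengths))
        for b in baseline:
            if isinstance(b, str):
                ref_seq = b.upper()
                break

    excess = observed - baseline_len
    present = excess >= min_excess
    if not present:
        return InsertionReport(spacer=spacer, observed_length=observed,
                               baseline_length=baseline_len,
                               insertion_present=False,
                               insertion_interval=(0, 0), insertion_length=0)
    ins_len = excess
    if ref_seq is not None:
        pref = _longest_common_prefix(spacer_seq, ref_seq)
        suf = _longest_common_prefix(spacer_seq[::-1], ref_seq[::-1])
        if pref + suf > observed - ins_len:
            suf = max(observed - ins_len - pref, 0)
        start = min(pref, observed - ins_len)
    else:
        start = (observed - ins_len) // 2
    interval = (start, start + ins_len)
    fragments = []
    if payload_library:
        fragments = _local_align_fragments(
            spacer_seq[interval[0]:interval[1]], payload_library,
            min_identity, min_fragment_length, min_fragment_score)
        for fr in fragments:
            fr.spacer_offset += interval[0]
    return InsertionReport(spacer=spacer, observed_length=observed,
                           baseline_length=baseline_len,
                           insertion_present=True,
                           insertion_interval=interval,
                           insertion_length=ins_len,
                           embedded_fragments=fragments)


# ---------------------------------------------------------------------------
# In-silico PCR


def _primer_sites(genome: str, primer: str, max_mismatch: int,
                  anchor: int) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """(plus-strand sites, minus-strand sites) as (circular start,
    mismatches); the 3′-terminal ``anchor`` bases must match exactly."""
    n = len(genome)
    m = len(primer)
    arr = np.frombuffer((genome + genome[:m]).encode(), dtype=np.uint8)
    p_plus = np.frombuffer(primer.encode(), dtype=np.uint8)
    p_minus = np.frombuffer(revcomp(primer).encode(), dtype=np.uint8)

    def scan(pat: np.ndarray, anchor_idx: range) -> list[tuple[int, int]]:
        mism = np.zeros(n, dtype=np.int32)
        anchor_bad = np.zeros(n, dtype=bool)
        for t in range(m):
            neq = arr[t:t + n] != pat[t]
            mism += neq
            if t in anchor_idx:
                anchor_bad |= neq
        ok = (mism <= max_mismatch) & ~anchor_bad
        return [(int(i), int(mism[i])) for i in np.nonzero(ok)[0]]

    # plus strand: primer 3' end is the window's last `anchor` bases;
    # minus strand: the revcomp pattern's 3' end is the window's start.
    plus = scan(p_plus, range(m - anchor, m))
    minus = scan(p_minus, range(0, anchor))
    return plus, minus


def insilico_pcr(plastome: AnnotatedPlastome, forward: str, reverse: str,
                 max_mismatch: int = 1, max_product: int = 5000,
                 anchor: int = 5,
                 partition: QuadripartitePartition | None = None
                 ) -> list[Amplicon]:
    """Predict amplicons for a primer pair on the circular genome.

    Each primer may bind either strand with at most ``max_mismatch``
    mismatches and none in the 3′-terminal ``anchor`` bases; every
    convergent site pair within ``max_product`` is reported.  An empty
    list means no amplification.  When a partition is supplied, each
    amplicon lists the junctions it spans.
    """
    for name, primer in (("forward", forward), ("reverse", reverse)):
        if set(primer.upper()) - set("ACGT"):
            raise PrimerAlphabetError(f"{name} primer has non-ACGT characters")
        if len(primer) < 15:
            raise ValidationError(f"{name} primer shorter than 15 bases")
    forward, reverse = forward.upper(), reverse.upper()
    n = plastome.length
    seq = plastome.sequence
    f_plus, f_minus = _primer_sites(seq, forward, max_mismatch, anchor)
    r_plus, r_minus = _primer_sites(seq, reverse, max_mismatch, anchor)
    m_f, m_r = len(forward), len(reverse)

    junction_pos = partition.junction_positions() if partition else {}
    amplicons: list[Amplicon] = []
    seen: set[tuple[int, int]] = set()

    def emit(plus_sites, minus_sites, m_plus, m_minus):
        for ps, pm in plus_sites:
            for ms, mm in minus_sites:
                product = ((ms + m_minus) - ps) % n
                if product == 0:
                    product = n
                if product < max(m_plus, m_minus) or product > max_product:
                    continue
                key = (ps, (ps + product) % n)
                if key in seen:
                    continue
                seen.add(key)
                spans = [j for j, jp in junction_pos.items()
                         if (jp - ps) % n < product]
                amplicons.append(Amplicon(
                    forward_site=(ps, "+", pm),
                    reverse_site=(ms, "-", mm),
                    product_length=product,
                    spans_junctions=sorted(spans)))

    emit(f_plus, r_minus, m_f, m_r)
    emit(r_plus, f_minus, m_r, m_f)
    amplicons.sort(key=lambda a: (a.forward_site[0], a.product_length))
    return amplicons


# ---------------------------------------------------------------------------
# Depth QC


def junction_depth_qc(profile: JunctionProfile, depth: DepthProfile,
                      window: int = 500, drop_threshold: float = 0.3,
                      inner: int = 100) -> JunctionQCReport:
    """Flag junctions whose local coverage dips.

    For each junction: median depth in the ``window``-bp regions left
    and right of an ``inner``-bp window centered on the junction; the
    junction is drop-suspect when the inner median falls below
    ``drop_threshold`` times the median of the two flanking windows.
    Medians (not means) resist mapping spikes.
    """
    part = profile.partition
    n = part.genome_length
    if len(depth.depths) != n:
        raise ValidationError(
            f"depth profile length {len(depth.depths)} != genome {n}")
    min_region = min(part.lsc_length, part.ssc_length, part.ir_length)
    if window > min_region:
        raise WindowTooLargeError(
            f"window {window} exceeds smallest region ({min_region} bp)")
    depths = np.asarray(depth.depths)

    def circular(lo: int, hi: int) -> np.ndarray:
        idx = np.arange(lo, hi) % n
        return depths[idx]

    entries: dict[str, JunctionQC] = {}
    for junc, pos in part.junction_positions().items():
        half = inner // 2
        left = circular(pos - half - window, pos - half)
        right = circular(pos + half, pos + half + window)
        center = circular(pos - half, pos + half)
        med_l, med_r = float(np.median(left)), float(np.median(right))
        med_c = float(np.median(center))
        flank_med = float(np.median(np.concatenate([left, right])))
        if med_l == 0 and med_r == 0 and med_c == 0:
            entries[junc] = JunctionQC(junc, 0.0, 0.0, 0.0, 0.0,
                                       "zero-coverage")
            continue
        hi, lo = max(med_l, med_r), min(med_l, med_r)
        ratio = lo / hi if hi > 0 else 0.0
        flag = "drop-suspect" if med_c < drop_threshold * flank_med else "pass"
        entries[junc] = JunctionQC(junc, med_l, med_r, med_c, ratio, flag)
    return JunctionQCReport(entries=entries)
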