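"""Synthetic plastomes, alignments and depth profiles with ground truth.

The generator emits stylized quadripartite genomes (~30 named genes at
scaled canonical positions) on which every structural phenomenon the
pipeline detects can be planted with known truth: junction shifts that
capture genes into the inverted repeat, spacer insertions carrying
psbA/trnH payload fragments, hairpin-flanked inversions, alignments
evolved on a tree under a single-rate symmetric model, and
overdispersed depth profiles with localized junction dips.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .errors import InfeasibleSpecError, ValidationError
from .model import AnnotatedPlastome, DepthProfile, GeneFeature, revcomp
from .quadripartite import GeneCensus, count_genes
from .supermatrix import Alignment, TreeTopology

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


# ---------------------------------------------------------------------------
# Spec / truth containers


@dataclass
class StructuralEvent:
    """One structural mutation applied to a blueprint, in order.

    kinds: jlb_expand(k), jlb_contract(k),
    jla_shift_with_insertion(spacer, payload_genes, length),
    spacer_insertion(spacer, length, payload_genes),
    small_inversion(interval, flank), genomic_inversion(region, length, flank).
    """

    kind: str
    params: dict = field(default_factory=dict)


@dataclass
class SyntheticPlastomeSpec:
    seed: int = 0
    lsc_length: int = 90_000
    ssc_length: int = 17_000
    ir_length: int = 18_000
    gc_target: float = 37.0
    identifier: str = "synthetic"
    events: list[StructuralEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        if min(self.lsc_length, self.ssc_length, self.ir_length) <= 0:
            raise InfeasibleSpecError("region lengths must be positive")
        if self.lsc_length <= self.ssc_length:
            raise InfeasibleSpecError("lsc_length must exceed ssc_length")


@dataclass
class PlantedInsertion:
    spacer: tuple[str, str]
    length: int
    payload_genes: list[str]
    baseline_spacer_length: int


@dataclass
class PlantedInversion:
    interval: tuple[int, int]
    flank: int
    carriers: list[str] = field(default_factory=list)
    affected_features: list[str] = field(default_factory=list)


@dataclass
class TruthRecord:
    lsc_length: int
    ssc_length: int
    ir_length: int
    census: GeneCensus
    junction_overlaps: dict[str, tuple[str, int] | None]
    insertions: list[PlantedInsertion] = field(default_factory=list)
    inversions: list[PlantedInversion] = field(default_factory=list)
    events: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# Blueprint


@dataclass
class _Feat:
    name: str
    kind: str
    strand: str
    intervals: list[tuple[int, int]]  # region-relative; may overhang
    pseudo: bool = False


@dataclass
class _Blueprint:
    lsc: str
    ir: str  # IRb orientation
    ssc: str
    lsc_feats: list[_Feat]
    ir_feats: list[_Feat]
    ssc_feats: list[_Feat]


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p_gc = gc / 100.0
    probs = [(1 - p_gc) / 2, p_gc / 2, p_gc / 2, (1 - p_gc) / 2]
    return bytes(_BASES[rng.choice(4, size=n, p=probs)]).decode()


# (name, kind, strand, relative position, length, exon structure or None)
# positions are fractions of the region length; exon structure lists
# (offset, length) pairs within the gene span.
_LSC_LAYOUT = [
    ("trnH-GTG", "tRNA", "-", 0.0005, 75, None),
    ("psbA", "protein", "-", 0.004, 1062, None),
    ("matK", "protein", "-", 0.022, 1512, None),
    ("rps16", "protein", "-", 0.055, 1100, [(0, 40), (874, 226)]),
    ("atpA", "protein", "-", 0.11, 1524, None),
    ("rpoB", "protein", "-", 0.20, 3212, None),
    ("trnC-GCA", "tRNA", "+", 0.295, 71, None),
    ("petN", "protein", "+", 0.31, 90, None),
    ("psbM", "protein", "-", 0.325, 105, None),
    ("trnD-GTC", "tRNA", "-", 0.3420, 74, None),
    ("trnY-GTA", "tRNA", "-", 0.3445, 84, None),
    ("trnE-TTC", "tRNA", "-", 0.3465, 73, None),
    ("trnT-GGT", "tRNA", "+", 0.36, 72, None),
    ("psbD", "protein", "+", 0.40, 1062, None),
    ("rbcL", "protein", "+", 0.62, 1428, None),
    ("clpP", "protein", "-", 0.78, 2000, [(0, 228), (1000, 291), (1709, 291)]),
    ("petB", "protein", "+", 0.83, 1400, [(0, 6), (794, 642)]),
    ("rpoA", "protein", "-", 0.90, 1014, None),
    ("rps19", "protein", "-", 0.985, 279, None),
]

_IR_LAYOUT = [
    ("rpl2", "protein", "-", 0.012, 1490, [(0, 434), (1100, 390)]),
    ("rpl23", "protein", "-", 0.105, 282, None),
    ("ycf2", "protein", "+", 0.13, 6840, None),
    ("trnL-CAA", "tRNA", "-", 0.52, 81, None),
    ("ndhB", "protein", "-", 0.535, 2210, [(0, 756), (1435, 775)]),
    ("rps7", "protein", "-", 0.67, 468, None),
    ("trnV-GAC", "tRNA", "+", 0.715, 72, None),
    ("rrn16", "rRNA", "+", 0.74, 1490, None),
    ("trnI-GAT", "tRNA", "+", 0.825, 500, [(0, 42), (465, 35)]),
    ("trnA-TGC", "tRNA", "+", 0.855, 450, [(0, 38), (415, 35)]),
    ("rrn23", "rRNA", "+", 0.885, 1100, None),
    ("rrn4.5", "rRNA", "+", 0.948, 103, None),
    ("rrn5", "rRNA", "+", 0.955, 121, None),
]

_SSC_LAYOUT = [
    ("ndhF", "protein", "-", 0.01, 2230, None),
    ("rpl32", "protein", "+", 0.18, 174, None),
    ("ccsA", "protein", "+", 0.26, 960, None),
    ("ndhD", "protein", "-", 0.36, 1503, None),
    ("psaC", "protein", "-", 0.47, 246, None),
    ("ndhA", "protein", "-", 0.56, 2200, [(0, 553), (1640, 540)]),
    ("ndhH", "protein", "-", 0.695, 1182, None),
    ("rps15", "protein", "-", 0.778, 273, None),
]

#: ycf1 starts in SSC and overhangs this many bases into IRa; the
#: mirrored overhang becomes the classical ψycf1 at J_SB.
_YCF1_OVERHANG = 600
_YCF1_LENGTH = 4000

#: region lengths the layout fractions were tuned for; genes keep their
#: absolute lengths in larger regions and shrink proportionally in
#: smaller ones so the template stays non-overlapping at any scale.
_CANONICAL = {"lsc": 90_000, "ir": 18_000, "ssc": 17_000}


def _place(layout, region_len: int, canonical: int) -> list[_Feat]:
    scale = min(1.0, region_len / canonical)
    feats = []
    for name, kind, strand, frac, length, exons in layout:
        start = int(frac * region_len)
        glen = max(30, int(length * scale))
        if exons is None or scale < 1.0:
            intervals = [(start, start + glen)]
        else:
            intervals = [(start + off, start + off + ln) for off, ln in exons]
        feats.append(_Feat(name, kind, strand, intervals))
    return feats


def _build_template(rng: np.random.Generator,
                    spec: SyntheticPlastomeSpec) -> _Blueprint:
    lsc = _random_seq(rng, spec.lsc_length, spec.gc_target)
    ir = _random_seq(rng, spec.ir_length, spec.gc_target)
    ssc = _random_seq(rng, spec.ssc_length, spec.gc_target)
    bp = _Blueprint(lsc, ir, ssc,
                    _place(_LSC_LAYOUT, spec.lsc_length, _CANONICAL["lsc"]),
                    _place(_IR_LAYOUT, spec.ir_length, _CANONICAL["ir"]),
                    _place(_SSC_LAYOUT, spec.ssc_length, _CANONICAL["ssc"]))
    # ycf1 spans J_SA: starts in SSC, overhangs into IRa
    scale = min(1.0, spec.ssc_length / _CANONICAL["ssc"])
    y_len = max(60, int(_YCF1_LENGTH * scale))
    y_over = max(30, int(_YCF1_OVERHANG * scale))
    y_start = spec.ssc_length - (y_len - y_over)
    bp.ssc_feats.append(_Feat("ycf1", "protein", "+",
                              [(y_start, y_start + y_len)]))
    _validate_blueprint(bp)
    return bp


def _validate_blueprint(bp: _Blueprint) -> None:
    for f in bp.ir_feats:
        if f.intervals[-1][1] > len(bp.ir) or f.intervals[0][0] < 0:
            raise InfeasibleSpecError(
                f"IR feature {f.name} escapes the repeat after events")
    for f in bp.lsc_feats:
        if f.intervals[-1][1] > len(bp.lsc) + len(bp.ir):
            raise InfeasibleSpecError(f"LSC feature {f.name} out of range")
    for f in bp.ssc_feats:
        if f.intervals[-1][1] > len(bp.ssc) + len(bp.ir):
            raise InfeasibleSpecError(f"SSC feature {f.name} out of range")


# --- event application ------------------------------------------------------


def _shift_feats(feats: list[_Feat], delta: int) -> None:
    for f in feats:
        f.intervals = [(s + delta, e + delta) for s, e in f.intervals]


def _jlb_expand(bp: _Blueprint, k: int) -> None:
    """Move the last k bases of the LSC into the start of the IR (the IR
    grows by k per copy; genes fully inside the moved stretch become
    duplicated IR genes, a straddling gene overhangs J_LB)."""
    if k >= len(bp.lsc) - 1:
        raise InfeasibleSpecError(f"jlb_expand({k}) would consume the LSC")
    cut = len(bp.lsc) - k
    bp.ir = bp.lsc[cut:] + bp.ir
    bp.lsc = bp.lsc[:cut]
    _shift_feats(bp.ir_feats, k)
    moved, kept = [], []
    for f in bp.lsc_feats:
        s, e = f.intervals[0][0], f.intervals[-1][1]
        if s >= cut:  # fully captured
            f2 = _Feat(f.name, f.kind, f.strand,
                       [(si - cut, ei - cut) for si, ei in f.intervals],
                       f.pseudo)
            moved.append(f2)
        else:
            kept.append(f)  # may overhang into the IR; handled at composition
    bp.lsc_feats = kept
    bp.ir_feats = moved + bp.ir_feats


def _jlb_contract(bp: _Blueprint, k: int) -> None:
    """Release the first k bases of the IR into the LSC (single copy).
    An IR gene straddling the new boundary stays an LSC feature that
    overhangs J_LB — e.g. a junction inside the ndhB intron."""
    if k >= len(bp.ir) - 1:
        raise InfeasibleSpecError(f"jlb_contract({k}) would consume the IR")
    bp.lsc = bp.lsc + bp.ir[:k]
    bp.ir = bp.ir[k:]
    lsc_len = len(bp.lsc)
    moved, kept = [], []
    for f in bp.ir_feats:
        s, e = f.intervals[0][0], f.intervals[-1][1]
        if e <= k or s < k:  # released or straddling: owned by the LSC now
            f2 = _Feat(f.name, f.kind, f.strand,
                       [(si + lsc_len - k, ei + lsc_len - k)
                        for si, ei in f.intervals], f.pseudo)
            moved.append(f2)
        else:
            kept.append(f)
    for f in kept:
        f.intervals = [(s - k, e - k) for s, e in f.intervals]
    bp.ir_feats = kept
    bp.lsc_feats = bp.lsc_feats + moved


def _find_ir_spacer(bp: _Blueprint, gene_a: str, gene_b: str
                    ) -> tuple[int, int]:
    from .model import same_gene

    fa = [f for f in bp.ir_feats if same_gene(f.name, gene_a)]
    fb = [f for f in bp.ir_feats if same_gene(f.name, gene_b)]
    if not fa or not fb:
        raise InfeasibleSpecError(
            f"spacer {gene_a}–{gene_b} not present in the IR blueprint")
    a_end = fa[0].intervals[-1][1]
    b_start = fb[0].intervals[0][0]
    if b_start < a_end:
        a_end, b_start = fb[0].intervals[-1][1], fa[0].intervals[0][0]
    return a_end, b_start


def _spacer_insertion(bp: _Blueprint, rng: np.random.Generator,
                      spacer: tuple[str, str], length: int,
                      payload_genes: list[str], gc: float
                      ) -> PlantedInsertion:
    """Insert `length` bases midway into the named IR spacer; the payload
    genes (psbA-fragment, trnH, trnV-pseudo) are copied from their LSC/IR
    source sequences so similarity search can recover them."""
    a_end, b_start = _find_ir_spacer(bp, *spacer)
    baseline = b_start - a_end
    pieces: list[tuple[str | None, str, str, bool, str]] = []
    from .model import same_gene

    def source_seq(name: str, truncate: int | None = None,
                   from_lsc: bool = True) -> tuple[str, str, str]:
        pool = bp.lsc_feats if from_lsc else bp.ir_feats
        region = bp.lsc if from_lsc else bp.ir
        for f in pool:
            if same_gene(f.name, name):
                seq = "".join(region[s:e] for s, e in f.intervals)
                if f.strand == "-":
                    seq = revcomp(seq)
                if truncate:
                    seq = seq[:truncate]
                return f.name, seq, f.kind
        raise InfeasibleSpecError(f"payload source {name!r} not in blueprint")

    for g in payload_genes:
        if g == "psbA-fragment":
            name, seq, kind = source_seq("psbA", truncate=350)
            pieces.append((name, seq, kind, True, "-"))
        elif g == "trnH":
            name, seq, kind = source_seq("trnH-GTG")
            pieces.append((name, seq, kind, False, "-"))
        elif g == "trnV-pseudo":
            name, seq, kind = source_seq("trnV-GAC", truncate=40,
                                         from_lsc=False)
            pieces.append((name, seq, kind, True, "+"))
        elif g == "none":
            continue
        else:
            raise ValidationError(f"unknown payload gene {g!r}")
    payload_len = sum(len(p[1]) for p in pieces)
    if payload_len > length:
        raise InfeasibleSpecError(
            f"payload ({payload_len} bp) exceeds insertion length {length}")
    pad = length - payload_len
    pad_left = pad // 2
    pad_right = pad - pad_left
    insert_at = a_end + baseline // 2
    chunks = [_random_seq(rng, pad_left, gc)]
    new_feats: list[_Feat] = []
    offset = insert_at + pad_left
    for name, seq, kind, pseudo, strand in pieces:
        body = seq if strand == "+" else revcomp(seq)
        new_feats.append(_Feat(name, kind, strand,
                               [(offset, offset + len(seq))], pseudo))
        chunks.append(body)
        offset += len(seq)
    chunks.append(_random_seq(rng, pad_right, gc))
    insertion = "".join(chunks)
    bp.ir = bp.ir[:insert_at] + insertion + bp.ir[insert_at:]
    for f in bp.ir_feats:
        if f.intervals[0][0] >= insert_at:
            f.intervals = [(s + length, e + length) for s, e in f.intervals]
    bp.ir_feats.extend(new_feats)
    payload_names = [p[0] for p in pieces]
    return PlantedInsertion(spacer=spacer, length=length,
                            payload_genes=payload_names,
                            baseline_spacer_length=baseline)


def _plant_genome_inversion(bp: _Blueprint, rng: np.random.Generator,
                            region: tuple[str, str], length: int,
                            flank: int, invert: bool = True
                            ) -> PlantedInversion:
    """Reverse-complement an LSC segment between two anchor genes,
    writing complementary hairpin arms just outside it and flipping the
    strands of fully contained features.

    With ``invert=False`` only the hairpin arms are planted and the
    segment keeps its forward orientation — used to build a reference
    genome sharing the arms with an inverted query.
    """
    from .model import same_gene

    anchors = []
    for g in region:
        hit = [f for f in bp.lsc_feats if same_gene(f.name, g)]
        if not hit:
            raise InfeasibleSpecError(f"anchor {g!r} not in LSC blueprint")
        anchors.append(hit[0])
    lo = min(f.intervals[-1][1] for f in anchors)
    hi = max(f.intervals[0][0] for f in anchors)
    inner = [f for f in bp.lsc_feats
             if f.intervals[0][0] >= lo and f.intervals[-1][1] <= hi]
    if not inner:
        raise InfeasibleSpecError("no features between the anchors")
    span_lo = min(f.intervals[0][0] for f in inner)
    span_hi = max(f.intervals[-1][1] for f in inner)
    if span_hi - span_lo > length:
        raise InfeasibleSpecError(
            f"feature cluster ({span_hi - span_lo} bp) exceeds inversion "
            f"length {length}")
    margin = length - (span_hi - span_lo)
    s = span_lo - margin // 2
    e = s + length
    if s - flank <= lo or e + flank >= hi:
        raise InfeasibleSpecError("inversion + flanks exceed the window")
    arm = _random_seq(rng, flank, 50.0)
    mid = bp.lsc[s:e]
    # boundary bases must break forward identity so the reversed segment
    # is maximal exactly at [s, e)
    while mid[0] == _COMP[mid[-1]]:
        mid = _random_seq(rng, 1, 50.0) + mid[1:]
    body = revcomp(mid) if invert else mid
    seq = bp.lsc
    seq = seq[:s - flank] + arm + body + revcomp(arm) + seq[e + flank:]
    # keep the arms maximal at exactly `flank` bases
    li, ri = s - flank - 1, e + flank
    if seq[li] == _COMP[seq[ri]]:
        repl = sorted({"A", "C", "G", "T"} - {seq[li], _COMP[seq[ri]]})[0]
        seq = seq[:li] + repl + seq[li + 1:]
    bp.lsc = seq
    affected = []
    if invert:
        for f in inner:
            f.strand = "-" if f.strand == "+" else "+"
            f.intervals = sorted((s + (e - ei), s + (e - si))
                                 for si, ei in f.intervals)
            affected.append(f.name)
    return PlantedInversion(interval=(s, e), flank=flank,
                            affected_features=affected)


def _plant_small_inversion(bp: _Blueprint, rng: np.random.Generator,
                           interval: tuple[int, int], flank: int
                           ) -> PlantedInversion:
    """Write complementary hairpin arms around an LSC interval (the
    interval content itself stays forward; only the arms are planted)."""
    s, e = interval
    if s - flank < 0 or e + flank > len(bp.lsc):
        raise InfeasibleSpecError("small inversion flanks out of range")
    arm = _random_seq(rng, flank, 50.0)
    bp.lsc = bp.lsc[:s - flank] + arm + bp.lsc[s:e] + revcomp(arm) \
        + bp.lsc[e + flank:]
    # break any accidental extension of the arms
    left_i, right_i = s - flank - 1, e + flank
    if left_i >= 0 and right_i < len(bp.lsc):
        if bp.lsc[left_i] == _COMP[bp.lsc[right_i]]:
            repl = {"A", "C", "G", "T"} - {bp.lsc[left_i], _COMP[bp.lsc[right_i]]}
            bp.lsc = bp.lsc[:left_i] + sorted(repl)[0] + bp.lsc[left_i + 1:]
    return PlantedInversion(interval=(s, e), flank=flank)


# --- composition ------------------------------------------------------------


def _compose(bp: _Blueprint, identifier: str) -> AnnotatedPlastome:
    lsc_len, ir_len, ssc_len = len(bp.lsc), len(bp.ir), len(bp.ssc)
    n = lsc_len + 2 * ir_len + ssc_len

    lsc, ir, ssc = bp.lsc, bp.ir, bp.ssc
    # maximality of the IR: the bases facing each junction from the
    # single-copy side must not extend the repeat
    if lsc and ssc:
        if ssc[0] == _COMP[ssc[-1]]:
            repl = sorted({"A", "C", "G", "T"}
                          - {ssc[0], _COMP[ssc[-1]]})[0]
            ssc = repl + ssc[1:]
        if lsc[-1] == _COMP[lsc[0]]:
            repl = sorted({"A", "C", "G", "T"}
                          - {lsc[-1], _COMP[lsc[0]]})[0]
            lsc = lsc[:-1] + repl
    seq = lsc + ir + ssc + revcomp(ir)

    feats: list[GeneFeature] = []
    base_irb = lsc_len
    base_ssc = lsc_len + ir_len
    base_ira = base_ssc + ssc_len

    def flip(strand: str) -> str:
        return "-" if strand == "+" else "+"

    for f in bp.lsc_feats:
        feats.append(GeneFeature(f.name, f.kind, f.strand,
                                 [(s, e) for s, e in f.intervals],
                                 pseudo=f.pseudo))
        overhang = f.intervals[-1][1] - lsc_len
        if overhang > 0:  # mirrored fragment appears at the IRa/LSC side
            feats.append(GeneFeature(f.name, f.kind, flip(f.strand),
                                     [(n - overhang, n)], pseudo=True))
    for f in bp.ir_feats:
        feats.append(GeneFeature(f.name, f.kind, f.strand,
                                 [(base_irb + s, base_irb + e)
                                  for s, e in f.intervals],
                                 pseudo=f.pseudo))
        mirrored = sorted((base_ira + ir_len - e, base_ira + ir_len - s)
                          for s, e in f.intervals)
        feats.append(GeneFeature(f.name, f.kind, flip(f.strand), mirrored,
                                 pseudo=f.pseudo))
    for f in bp.ssc_feats:
        feats.append(GeneFeature(f.name, f.kind, f.strand,
                                 [(base_ssc + s, base_ssc + e)
                                  for s, e in f.intervals],
                                 pseudo=f.pseudo))
        overhang = f.intervals[-1][1] - ssc_len
        if overhang > 0:  # mirrored fragment at the IRb/SSC side (ψycf1)
            feats.append(GeneFeature(f.name, f.kind, flip(f.strand),
                                     [(base_ssc - overhang, base_ssc)],
                                     pseudo=True))
    feats.sort(key=lambda f: f.intervals[0][0])
    return AnnotatedPlastome(identifier, seq, feats, source="synthetic")


def _junction_truth(bp: _Blueprint) -> dict[str, tuple[str, int] | None]:
    lsc_len, ir_len, ssc_len = len(bp.lsc), len(bp.ir), len(bp.ssc)
    out: dict[str, tuple[str, int] | None] = {j: None for j in
                                              ("J_LB", "J_SB", "J_SA", "J_LA")}
    # only genuine overlaps: a feature overhanging from the LSC spans
    # J_LB, one overhanging from the SSC spans J_SA; their mirrored
    # pseudo fragments merely abut J_LA / J_SB.
    for f in bp.lsc_feats:
        overhang = f.intervals[-1][1] - lsc_len
        if overhang > 0:
            out["J_LB"] = (f.name, overhang)
    for f in bp.ssc_feats:
        overhang = f.intervals[-1][1] - ssc_len
        if overhang > 0:
            out["J_SA"] = (f.name, overhang)
    return out


def generate_plastome(spec: SyntheticPlastomeSpec
                      ) -> tuple[AnnotatedPlastome, TruthRecord]:
    """Generate an annotated quadripartite plastome realizing the spec.

    Deterministic for a given spec+seed; events are applied in order and
    the returned truth record reflects the realized structure.
    """
    rng = np.random.default_rng(spec.seed)
    bp = _build_template(rng, spec)
    insertions: list[PlantedInsertion] = []
    inversions: list[PlantedInversion] = []
    for ev in spec.events:
        p = ev.params
        if ev.kind == "jlb_expand":
            _jlb_expand(bp, p["k"])
        elif ev.kind == "jlb_contract":
            _jlb_contract(bp, p["k"])
        elif ev.kind in ("jla_shift_with_insertion", "spacer_insertion"):
            insertions.append(_spacer_insertion(
                bp, rng, tuple(p["spacer"]), p["length"],
                list(p.get("payload_genes", [])), spec.gc_target))
        elif ev.kind == "small_inversion":
            inversions.append(_plant_small_inversion(
                bp, rng, tuple(p["interval"]), p["flank"]))
        elif ev.kind == "genomic_inversion":
            inversions.append(_plant_genome_inversion(
                bp, rng, tuple(p["region"]), p["length"], p["flank"],
                invert=p.get("invert", True)))
        else:
            raise ValidationError(f"unknown event kind {ev.kind!r}")
    _validate_blueprint(bp)
    genome = _compose(bp, spec.identifier)
    truth = TruthRecord(
        lsc_length=len(bp.lsc), ssc_length=len(bp.ssc),
        ir_length=len(bp.ir),
        census=count_genes(genome),
        junction_overlaps=_junction_truth(bp),
        insertions=insertions,
        inversions=inversions,
        events=[e.kind for e in spec.events],
    )
    return genome, truth


def payload_library(spec_or_genome=None) -> dict[str, str]:
    """Reference payload sequences (psbA, trnH, trnV) for insertion
    screening, extracted from a no-event genome built with the same
    seed/lengths as ``spec_or_genome`` (a spec), or defaults."""
    if isinstance(spec_or_genome, SyntheticPlastomeSpec):
        base = dataclasses.replace(spec_or_genome, events=[])
    else:
        base = SyntheticPlastomeSpec()
    genome, _ = generate_plastome(base)
    lib = {}
    for name in ("psbA", "trnH-GTG", "trnV-GAC"):
        feats = genome.find_features(name)
        lib[name.split("-")[0] if name != "trnV-GAC" else "trnV"] = \
            genome.feature_sequence(feats[0])
    return lib


# ---------------------------------------------------------------------------
# Alignment simulation


def simulate_alignment(tree: TreeTopology | str, n_columns: int,
                       seed: int = 0,
                       inversion_events: list[dict] | None = None,
                       ) -> tuple[Alignment, dict]:
    """Evolve an alignment on a tree under a single-rate symmetric model.

    The root sequence is uniform over {A,C,G,T}; per branch each site
    receives a Poisson(branch length) number of substitution events,
    each to a uniformly chosen different base (i.e. the Jukes–Cantor
    process).  ``inversion_events`` plant hairpin-flanked
    reverse-complement blocks into named carrier taxa:
    dicts with keys start, length, flank, carriers.
    Returns the alignment and a truth dict with the planted inversions
    and the pre-inversion alignment.
    """
    if n_columns < 1:
        raise ValidationError("n_columns must be >= 1")
    if isinstance(tree, str):
        dtree = dendropy.Tree.get(data=tree, schema="newick",
                                  preserve_underscores=True)
    else:
        dtree = tree._dendropy
    rng = np.random.default_rng(seed)
    root_states = rng.integers(0, 4, size=n_columns)
    seqs: dict[str, np.ndarray] = {}

    def evolve(states: np.ndarray, t: float) -> np.ndarray:
        if t <= 0:
            return states.copy()
        k = rng.poisson(t, size=n_columns)
        out = states.copy()
        while (k > 0).any():
            hit = k > 0
            jumps = rng.integers(1, 4, size=int(hit.sum()))
            out[hit] = (out[hit] + jumps) % 4
            k = k - hit
        return out

    node_states = {}
    for node in dtree.preorder_node_iter():
        if node.parent_node is None:
            node_states[id(node)] = root_states
        else:
            t = node.edge.length or 0.0
            node_states[id(node)] = evolve(node_states[id(node.parent_node)], t)
        if node.is_leaf():
            seqs[node.taxon.label] = node_states[id(node)]

    taxa = sorted(seqs)
    mat = np.stack([seqs[t] for t in taxa])
    chars = _BASES[mat]
    truth_inversions: list[PlantedInversion] = []
    if inversion_events:
        for ev in inversion_events:
            s, length, flank = ev["start"], ev["length"], ev["flank"]
            e = s + length
            if s - flank < 0 or e + flank > n_columns:
                raise InfeasibleSpecError("inversion outside the alignment")
            carriers = list(ev["carriers"])
            # fresh block content, rejected until its reverse complement is
            # distinct enough (and distinct at both boundary columns)
            while True:
                block = _BASES[rng.integers(0, 4, size=length)]
                b = bytes(block).decode()
                rb = revcomp(b)
                ident = sum(x == y for x, y in zip(b, rb)) / length
                if ident <= 0.4 and rb[0] != b[0] and rb[-1] != b[-1]:
                    break
            arm = _BASES[rng.integers(0, 4, size=flank)] if flank else \
                np.empty(0, dtype=np.uint8)
            arm_s = bytes(arm).decode()
            for i in range(len(taxa)):
                if flank:
                    chars[i, s - flank:s] = arm
                    chars[i, e:e + flank] = np.frombuffer(
                        revcomp(arm_s).encode(), dtype=np.uint8)
                chars[i, s:e] = block
            truth_inversions.append(PlantedInversion(
                interval=(s, e), flank=flank, carriers=carriers))
    pre_rows = [bytes(chars[i]).decode() for i in range(len(taxa))]
    if inversion_events:
        for inv in truth_inversions:
            s, e = inv.interval
            for c in inv.carriers:
                i = taxa.index(c)
                seg = bytes(chars[i, s:e]).decode()
                chars[i, s:e] = np.frombuffer(revcomp(seg).encode(),
                                              dtype=np.uint8)
    rows = [bytes(chars[i]).decode() for i in range(len(taxa))]
    truth = {
        "inversions": truth_inversions,
        "pre_inversion_alignment": Alignment(list(taxa), pre_rows),
    }
    return Alignment(list(taxa), rows), truth


def simulate_homoplasy_free_alignment(tree: TreeTopology | str,
                                      n_columns: int, seed: int = 0
                                      ) -> Alignment:
    """Alignment in the infinite-sites-like regime: every variable column
    carries exactly one substitution on one branch (leaves below the
    branch share the derived state), so parsimony explains each site
    with its minimum number of changes and the homoplasy index is 0."""
    if isinstance(tree, str):
        topo = TreeTopology.from_newick(tree)
    else:
        topo = tree
    rng = np.random.default_rng(seed)
    taxa = topo.taxa
    edges = []
    for u in topo._adj:
        for v in topo._adj[u]:
            if u < v:
                side = topo._subtree_leaves(u, v)
                if 0 < len(side) < len(taxa):
                    edges.append(side)
    rows = {t: [] for t in taxa}
    for _ in range(n_columns):
        anc, der = rng.choice(4, size=2, replace=False)
        side = edges[int(rng.integers(0, len(edges)))]
        for t in taxa:
            rows[t].append("ACGT"[der] if t in side else "ACGT"[anc])
    return Alignment(list(taxa), ["".join(rows[t]) for t in taxa])


def random_inversion_events(rng: np.random.Generator, taxa: list[str],
                            n_columns: int, n_events: int = 20,
                            length_range: tuple[int, int] = (3, 62),
                            flank_range: tuple[int, int] = (3, 10),
                            ) -> list[dict]:
    """Sample non-overlapping hairpin-inversion events, one carrier each;
    lengths span the short-inversion regime (3–62 columns)."""
    events: list[dict] = []
    occupied: list[tuple[int, int]] = []
    attempts = 0
    while len(events) < n_events and attempts < 10_000:
        attempts += 1
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        flank = int(rng.integers(flank_range[0], flank_range[1] + 1))
        margin = flank + 5
        s = int(rng.integers(margin, n_columns - length - margin))
        lo, hi = s - margin, s + length + margin
        if any(lo < o_hi and o_lo < hi for o_lo, o_hi in occupied):
            continue
        occupied.append((lo, hi))
        carrier = taxa[int(rng.integers(0, len(taxa)))]
        events.append({"start": s, "length": length, "flank": flank,
                       "carriers": [carrier]})
    if len(events) < n_events:
        raise InfeasibleSpecError("could not place the requested inversions")
    return events


# ---------------------------------------------------------------------------
# Depth profiles


def simulate_depth_profile(plastome: AnnotatedPlastome, mean_depth: float,
                           drop_sites: list[str] | tuple[str, ...] = (),
                           drop_factor: float = 0.0, seed: int = 0,
                           dispersion: float = 20.0,
                           partition=None) -> DepthProfile:
    """Overdispersed per-base depth with optional localized junction dips.

    Depths are negative-binomial with the given mean and dispersion
    (smaller = more overdispersed).  At each named junction a 100–300 bp
    dip scaled by ``drop_factor`` is applied.
    """
    if mean_depth <= 0:
        raise ValidationError("mean_depth must be positive")
    if not 0 <= drop_factor < 1:
        raise ValidationError("drop_factor must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n = plastome.length
    r = dispersion
    p = r / (r + mean_depth)
    depths = rng.negative_binomial(r, p, size=n).astype(np.int64)
    if drop_sites:
        if partition is None:
            from .quadripartite import detect_inverted_repeat

            partition = detect_inverted_repeat(plastome)
        positions = partition.junction_positions()
        for site in drop_sites:
            if site not in positions:
                raise KeyError(site)
            width = int(rng.integers(100, 301))
            start = positions[site] - width // 2
            idx = np.arange(start, start + width) % n
            depths[idx] = np.round(depths[idx] * drop_factor).astype(np.int64)
    return DepthProfile(plastome.identifier, depths)
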