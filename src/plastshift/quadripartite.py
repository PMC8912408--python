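"""Quadripartite structure detection and Table-1-style statistics.

The inverted repeat (IR) pair of a plastome is found as the maximal pair
of disjoint, exactly reverse-complementary substrings on the circle; the
two single-copy gaps between the copies become the LSC (longer) and SSC
(shorter) regions.  Detection is exact-match seed-and-extend on the
doubled sequence: every reverse-complement match of length L lies on a
single anti-diagonal (i + j constant), so one maximal extension per
seeded diagonal suffices.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import (ClassificationError, DegenerateStructureError,
                     NoQuadripartiteError, ValidationError)
from .model import AnnotatedPlastome, gc_fraction, revcomp, same_gene

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class QuadripartitePartition:
    """LSC/IRb/SSC/IRa intervals on the canonical rotation.

    Canonical orientation: LSC starts at 0 and regions follow in the
    order LSC → IRb → SSC → IRa, matching the junction naming
    J_LB = LSC/IRb, J_SB = IRb/SSC, J_SA = SSC/IRa, J_LA = IRa/LSC.
    ``canonical_offset`` is the rotation applied to the (possibly
    flipped) input; ``flipped`` records whether the reverse-complement
    strand was chosen.
    """

    lsc: tuple[int, int]
    irb: tuple[int, int]
    ssc: tuple[int, int]
    ira: tuple[int, int]
    canonical_offset: int = 0
    flipped: bool = False

    @property
    def lsc_length(self) -> int:
        return self.lsc[1] - self.lsc[0]

    @property
    def ssc_length(self) -> int:
        return self.ssc[1] - self.ssc[0]

    @property
    def ir_length(self) -> int:
        return self.irb[1] - self.irb[0]

    @property
    def genome_length(self) -> int:
        return self.lsc_length + self.ssc_length + 2 * self.ir_length

    def junction_positions(self) -> dict[str, int]:
        """Junction positions, each the first base of the downstream
        region (0-based, canonical rotation)."""
        return {
            "J_LB": self.irb[0],
            "J_SB": self.ssc[0],
            "J_SA": self.ira[0],
            "J_LA": 0,
        }

    def region_of(self, pos: int) -> str:
        for name, (s, e) in (("LSC", self.lsc), ("IRb", self.irb),
                             ("SSC", self.ssc), ("IRa", self.ira)):
            if s <= pos < e:
                return name
        raise ValueError(f"position {pos} outside genome")

    def apply_to(self, plastome: AnnotatedPlastome) -> AnnotatedPlastome:
        """Return the plastome transformed to the canonical orientation
        these intervals refer to (flip first, then rotate)."""
        g = plastome.reverse_complemented() if self.flipped else plastome
        return g.rotated(self.canonical_offset)


@dataclass
class GeneCensus:
    total_genes: int
    protein: int
    protein_pseudo: int
    trna: int
    rrna: int

    def __post_init__(self) -> None:
        assert self.protein + self.trna + self.rrna == self.total_genes
        assert self.protein_pseudo <= self.protein


@dataclass
class RegionStats:
    genome_length: int
    lsc_length: int
    ssc_length: int
    ir_length: int
    gc_overall: float
    gc_lsc: float
    gc_ssc: float
    gc_ir: float


def _maximal_rc_matches(seq: str, min_len: int, k: int = 20):
    """Maximal reverse-complement substring pairs on the circle.

    Yields (a, b, length): circular start of each copy (a ≤ b) and the
    common length, for every seeded anti-diagonal whose maximal
    extension reaches ``min_len``.
    """
    n = len(seq)
    t = seq + seq
    rc = revcomp(seq)
    trc = rc + rc  # trc[p] == complement(t[2n-1-p])

    index: dict[str, list[int]] = {}
    for i in range(n):
        index.setdefault(t[i:i + k], []).append(i)

    # A match t[i:i+k] == revcomp(t[j:j+k]) corresponds to
    # trc[p:p+k] == t[i:i+k] with j = 2n - k - p (mod 2n handled via
    # scanning p over [0, 2n-k]).  Group hits by the anti-diagonal
    # d = i + j; a diagonal may carry several contiguous seed runs
    # (wrapped representations of one circular match are n apart), so
    # each run is extended once from its smallest i.
    diagonals: dict[int, list[int]] = {}
    for p in range(2 * n - k + 1):
        kmer = trc[p:p + k]
        for i in index.get(kmer, ()):
            j = 2 * n - k - p
            diagonals.setdefault(i + j, []).append(i)

    starts: list[tuple[int, int]] = []  # (d, run-start i)
    for d, ii in diagonals.items():
        ii.sort()
        prev = None
        for i in ii:
            if prev is None or i > prev + 1:
                starts.append((d, i))
            prev = i

    seen: set[tuple[int, int, int]] = set()
    for d, i0 in sorted(starts):
        j0 = d - i0
        if not (0 <= j0 <= 2 * n - k):
            continue
        i, j, length = i0, j0, k
        # left-extend the i copy (right-extend the rc partner)
        while i > 0 and length < n and j + length < 2 * n \
                and t[i - 1] == _COMP.get(t[j + length], "?"):
            i -= 1
            length += 1
        # right-extend the i copy (left-extend the rc partner)
        while j > 0 and length < n and i + length < 2 * n \
                and t[i + length] == _COMP.get(t[j - 1], "?"):
            j -= 1
            length += 1
        if length < min_len:
            continue
        a, b = i % n, j % n
        if a > b:
            a, b = b, a
        key = (a, b, length)
        if key in seen:
            continue
        seen.add(key)
        yield a, b, length


def _disjoint_on_circle(a: int, b: int, length: int, n: int) -> bool:
    """Whether circular intervals [a, a+length) and [b, b+length) are
    disjoint."""
    if 2 * length > n:
        return False
    gap1 = (b - (a + length)) % n
    gap2 = (a - (b + length)) % n
    return gap1 + gap2 == n - 2 * length


def detect_inverted_repeat(plastome: AnnotatedPlastome,
                           min_ir_length: int = 1000) -> QuadripartitePartition:
    """Detect the IR pair and partition the circle into LSC/IRb/SSC/IRa.

    The repeat pair is the maximal-length pair of disjoint, exactly
    reverse-complementary substrings of length ≥ ``min_ir_length``; ties
    are broken by the smallest start coordinate.  The result is
    canonicalized (LSC at 0, order LSC→IRb→SSC→IRa); when annotation is
    present the orientation placing the intact ycf1 copy across or next
    to the SSC/IRa junction is preferred, otherwise the
    lexicographically smaller LSC sequence decides.
    """
    n = plastome.length
    if n < 4 * min_ir_length:
        raise NoQuadripartiteError(
            f"{plastome.identifier}: genome of {n} bp cannot host two "
            f"disjoint repeats of {min_ir_length} bp plus single-copy gaps")
    best: tuple[int, int, int] | None = None
    for a, b, length in _maximal_rc_matches(plastome.sequence, min_ir_length):
        if not _disjoint_on_circle(a, b, length, n):
            if length >= n:
                raise DegenerateStructureError(
                    f"{plastome.identifier}: repeat pair covers the whole circle")
            continue
        cand = (length, -a, -b)
        if best is None or cand > (best[2], -best[0], -best[1]):
            best = (a, b, length)
    if best is None:
        raise NoQuadripartiteError(
            f"{plastome.identifier}: no inverted repeat ≥ {min_ir_length} bp")
    a, b, length = best
    gap1 = (b - (a + length)) % n  # gap following copy at a
    gap2 = (a - (b + length)) % n  # gap following copy at b
    if gap1 == 0 and gap2 == 0:
        raise DegenerateStructureError(
            f"{plastome.identifier}: repeat pair covers the whole circle")
    if gap1 == gap2:
        raise DegenerateStructureError(
            f"{plastome.identifier}: equal single-copy gaps; LSC/SSC "
            f"labelling undefined")
    # the copy *after* the LSC gap becomes IRb in forward orientation
    if gap1 > gap2:
        lsc_start, irb_start = (a + length) % n, b
    else:
        lsc_start, irb_start = (b + length) % n, a
    lsc_len, ssc_len = max(gap1, gap2), min(gap1, gap2)

    forward = _orient(plastome, lsc_start, lsc_len, length, ssc_len,
                      flipped=False)
    flipped = _orient(plastome, lsc_start, lsc_len, length, ssc_len,
                      flipped=True)
    return _choose_orientation(plastome, forward, flipped)


def _orient(plastome: AnnotatedPlastome, lsc_start: int, lsc_len: int,
            ir_len: int, ssc_len: int, flipped: bool) -> QuadripartitePartition:
    n = plastome.length
    if not flipped:
        offset = lsc_start
    else:
        # on the reverse-complement strand the region order is preserved
        # (LSC, then the other IR copy, then SSC); LSC then ends at
        # n - lsc_start, so it begins ir/ssc lengths earlier.
        offset = (n - lsc_start - lsc_len) % n
    lsc = (0, lsc_len)
    irb = (lsc_len, lsc_len + ir_len)
    ssc = (irb[1], irb[1] + ssc_len)
    ira = (ssc[1], ssc[1] + ir_len)
    part = QuadripartitePartition(lsc, irb, ssc, ira,
                                  canonical_offset=offset, flipped=flipped)
    assert part.genome_length == n
    return part


def _choose_orientation(plastome: AnnotatedPlastome,
                        forward: QuadripartitePartition,
                        flipped: QuadripartitePartition
                        ) -> QuadripartitePartition:
    if plastome.features:
        for cand in (forward, flipped):
            genome = cand.apply_to(plastome)
            jsa = cand.junction_positions()["J_SA"]
            for f in genome.find_features("ycf1"):
                if f.pseudo:
                    continue
                s, e = f.span()
                if s - 2000 <= jsa <= e + 2000:
                    return cand
    lsc_fwd = forward.apply_to(plastome).sequence[:forward.lsc_length]
    lsc_flip = flipped.apply_to(plastome).sequence[:flipped.lsc_length]
    return forward if lsc_fwd <= lsc_flip else flipped


def region_stats(plastome: AnnotatedPlastome,
                 partition: QuadripartitePartition) -> RegionStats:
    """Region lengths and GC content (to 0.1%), computed on the canonical
    orientation.  GC excludes N from the denominator; both IR copies
    contribute to the IR figure (they are identical, so it equals one
    copy's)."""
    if partition.genome_length != plastome.length:
        raise ValidationError(
            f"partition is for a {partition.genome_length}-bp genome, "
            f"got {plastome.length} bp")
    genome = partition.apply_to(plastome)
    seq = genome.sequence

    def region_gc(iv: tuple[int, int]) -> float:
        return round(gc_fraction(seq[iv[0]:iv[1]]), 1)

    ir_seq = seq[partition.irb[0]:partition.irb[1]] + \
        seq[partition.ira[0]:partition.ira[1]]
    return RegionStats(
        genome_length=plastome.length,
        lsc_length=partition.lsc_length,
        ssc_length=partition.ssc_length,
        ir_length=partition.ir_length,
        gc_overall=round(gc_fraction(seq), 1),
        gc_lsc=region_gc(partition.lsc),
        gc_ssc=region_gc(partition.ssc),
        gc_ir=round(gc_fraction(ir_seq), 1),
    )


def count_genes(plastome: AnnotatedPlastome) -> GeneCensus:
    """Census features by kind; every feature instance counts once, so a
    gene duplicated in the IR contributes two.  Pseudo features count
    within their kind and additionally as protein pseudogenes."""
    counts = {"protein": 0, "tRNA": 0, "rRNA": 0}
    pseudo_protein = 0
    for f in plastome.features:
        if f.kind not in counts:
            raise ClassificationError(f"feature {f.name!r}: kind {f.kind!r}")
        counts[f.kind] += 1
        if f.kind == "protein" and f.pseudo:
            pseudo_protein += 1
    return GeneCensus(
        total_genes=sum(counts.values()),
        protein=counts["protein"],
        protein_pseudo=pseudo_protein,
        trna=counts["tRNA"],
        rrna=counts["rRNA"],
    )


def verify_partition(plastome: AnnotatedPlastome,
                     partition: QuadripartitePartition) -> None:
    """Assert the partition invariants against the genome: tiling and
    exact reverse-complementarity of the two IR copies."""
    genome = partition.apply_to(plastome)
    seq = genome.sequence
    if partition.genome_length != len(seq):
        raise ValidationError("partition does not tile the genome")
    irb = seq[partition.irb[0]:partition.irb[1]]
    ira = seq[partition.ira[0]:partition.ira[1]]
    if revcomp(ira) != irb:
        raise ValidationError("IRa is not the exact reverse complement of IRb")
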