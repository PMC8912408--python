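"""Small-inversion detection and correction, and genomic inversions.

Short plastome segments bounded by complementary repeats can flip
orientation via hairpin formation; in an alignment such a segment shows
up as a block where one or a few taxa match the reverse complement of
the consensus far better than its forward sequence.  These blocks
inflate homoplasy and must be re-oriented before phylogenetic analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (AnchorError, BoundsError, InsufficientTaxaError,
                     OverlapError, ValidationError)
from .model import AnnotatedPlastome, revcomp
from .supermatrix import Alignment

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class SmallInversion:
    interval: tuple[int, int]  # alignment columns [start, end)
    carriers: list[str]
    identity_forward: float
    identity_revcomp: float
    flank_ir_length: int = 0

    @property
    def length(self) -> int:
        return self.interval[1] - self.interval[0]


@dataclass
class GenomicInversion:
    interval: tuple[int, int]  # query genome coordinates
    flank_length: int
    affected_features: list[str] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.interval[1] - self.interval[0]


def column_consensus(alignment: Alignment) -> str:
    """Strict majority consensus over non-gap ACGT states per column;
    ties break alphabetically; all-missing columns yield '-'."""
    mat = alignment.char_matrix()
    counts = np.stack([(mat == ord(b)).sum(axis=0) for b in "ACGT"])
    best = counts.argmax(axis=0)  # argmax takes the first (alphabetical) max
    none = counts.sum(axis=0) == 0
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)[best]
    bases = np.where(none, ord("-"), bases).astype(np.uint8)
    return bytes(bases).decode()


def _block_identities(row: str, consensus: str, start: int, end: int
                      ) -> tuple[float, float, int]:
    """(forward %, revcomp %, n compared) identity of a row block against
    the consensus, over columns where both carry unambiguous bases."""
    r_chars, c_chars = [], []
    for col in range(start, end):
        rc_, cc = row[col], consensus[col]
        if rc_ in _COMP and cc in _COMP:
            r_chars.append(rc_)
            c_chars.append(cc)
    n = len(r_chars)
    if n == 0:
        return 0.0, 0.0, 0
    fwd = sum(a == b for a, b in zip(r_chars, c_chars))
    rev = revcomp("".join(r_chars))
    rvc = sum(a == b for a, b in zip(rev, c_chars))
    return 100.0 * fwd / n, 100.0 * rvc / n, n


def _alignment_flank_length(row: str, start: int, end: int,
                            max_flank: int = 50) -> int:
    """Maximal k with the k non-gap bases left of ``start`` complementary,
    outward, to the k non-gap bases right of ``end`` in the same row."""
    left = [c for c in row[max(0, start - max_flank):start][::-1] if c in _COMP]
    right = [c for c in row[end:end + max_flank] if c in _COMP]
    k = 0
    for lc, rcv in zip(left, right):
        if lc != _COMP[rcv]:
            break
        k += 1
    return k


def detect_small_inversions(alignment: Alignment, min_len: int = 3,
                            max_len: int = 100, min_gain: float = 20.0,
                            merge_gap: int = 3, refine: int = 3,
                            min_mismatch_columns: int = 3,
                            min_margin_columns: int = 2,
                            min_flank: int = 2,
                            flank_exempt_length: int = 10
                            ) -> list[SmallInversion]:
    """Detect alignment blocks carried in reverse-complement orientation.

    Scans maximal mismatch blocks of each row against the column-majority
    consensus (mismatch runs separated by ≤ ``merge_gap`` matching
    columns are merged, and block boundaries are refined within
    ± ``refine`` columns to maximize the reverse-complement advantage).
    A block is reported when its reverse-complement identity exceeds the
    forward identity by at least ``min_gain`` percentage points and by at
    least ``min_margin_columns`` absolute columns.  Because isolated
    substitution clusters can mimic very short inversions, calls shorter
    than ``flank_exempt_length`` additionally require a complementary
    flanking repeat of ≥ ``min_flank`` bases — the hairpin arms that
    mediate these inversions.  Calls sharing columns across carriers are
    merged.
    """
    if alignment.n_taxa < 4:
        raise InsufficientTaxaError(
            f"{alignment.n_taxa} rows; need ≥ 4 for a meaningful consensus")
    consensus = column_consensus(alignment)
    ncol = alignment.n_columns
    cons_arr = np.frombuffer(consensus.encode(), dtype=np.uint8)
    calls: list[tuple[tuple[int, int], str, float, float]] = []
    for taxon, row in zip(alignment.taxa, alignment.rows):
        row_arr = np.frombuffer(row.encode(), dtype=np.uint8)
        informative = np.isin(row_arr, np.frombuffer(b"ACGT", dtype=np.uint8)) \
            & np.isin(cons_arr, np.frombuffer(b"ACGT", dtype=np.uint8))
        mism = informative & (row_arr != cons_arr)
        idx = np.nonzero(mism)[0]
        if idx.size == 0:
            continue
        # merge mismatch runs separated by <= merge_gap
        runs: list[list[int]] = [[int(idx[0]), int(idx[0]) + 1]]
        for i in idx[1:]:
            if i - runs[-1][1] <= merge_gap:
                runs[-1][1] = int(i) + 1
            else:
                runs.append([int(i), int(i) + 1])
        for s, e in runs:
            if e - s < min_len or e - s > max_len + 2 * refine:
                continue
            if int(mism[s:e].sum()) < min_mismatch_columns:
                continue
            best = None
            for ds in range(-refine, refine + 1):
                for de in range(-refine, refine + 1):
                    s2, e2 = s + ds, e + de
                    if s2 < 0 or e2 > ncol or not (min_len <= e2 - s2 <= max_len):
                        continue
                    fwd, rev, n = _block_identities(row, consensus, s2, e2)
                    if n < min_len:
                        continue
                    score = (rev - fwd) * n / 100.0
                    cand = (score, rev, -(e2 - s2), -s2, (s2, e2), fwd, n)
                    if best is None or cand > best:
                        best = cand
            if best is None:
                continue
            score, rev, _, _, (s2, e2), fwd, n = best
            margin_cols = (rev - fwd) * n / 100.0
            if not (rev - fwd >= min_gain and rev > fwd
                    and margin_cols >= min_margin_columns - 1e-9):
                continue
            if e2 - s2 < flank_exempt_length \
                    and _alignment_flank_length(row, s2, e2) < min_flank:
                continue
            calls.append(((s2, e2), taxon, fwd, rev))

    # merge calls that share the same columns
    merged: list[SmallInversion] = []
    calls.sort(key=lambda c: c[0])
    for (iv, taxon, fwd, rev) in calls:
        target = None
        for inv in merged:
            lo = max(iv[0], inv.interval[0])
            hi = min(iv[1], inv.interval[1])
            overlap = max(0, hi - lo)
            union = max(iv[1], inv.interval[1]) - min(iv[0], inv.interval[0])
            if union and overlap / union >= 0.5:
                target = inv
                break
        if target is None:
            merged.append(SmallInversion(interval=iv, carriers=[taxon],
                                         identity_forward=round(fwd, 1),
                                         identity_revcomp=round(rev, 1)))
        else:
            target.carriers.append(taxon)
            if rev > target.identity_revcomp:
                target.interval = iv
                target.identity_forward = round(fwd, 1)
                target.identity_revcomp = round(rev, 1)
    # a "carrier" set covering half the rows is a consensus artifact
    merged = [m for m in merged if len(m.carriers) * 2 < alignment.n_taxa]
    for inv in merged:
        row = alignment.row(inv.carriers[0])
        inv.flank_ir_length = _alignment_flank_length(row, *inv.interval)
    return merged


def apply_inversion_correction(alignment: Alignment,
                               inversions: list[SmallInversion]) -> Alignment:
    """Reverse-complement each carrier's ungapped block in place.

    Gap columns keep their positions (alignment geometry is preserved);
    applying the correction twice restores the original alignment.
    Intervals must be disjoint.
    """
    ivs = sorted(inv.interval for inv in inversions)
    for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
        if s2 < e1:
            raise OverlapError(f"inversion intervals [{s1},{e1}) and "
                               f"[{s2},{e2}) overlap")
    rows = {t: list(r) for t, r in zip(alignment.taxa, alignment.rows)}
    for inv in inversions:
        s, e = inv.interval
        for taxon in inv.carriers:
            row = rows[taxon]
            positions = [i for i in range(s, e) if row[i] != "-"]
            block = "".join(row[i] for i in positions)
            flipped = revcomp(block)
            for i, ch in zip(positions, flipped):
                row[i] = ch
    return Alignment(list(alignment.taxa),
                     ["".join(rows[t]) for t in alignment.taxa])


def find_flanking_ir(genome: AnnotatedPlastome, interval: tuple[int, int],
                     max_flank: int = 200, wrap: bool = True) -> int:
    """Maximal k ≤ max_flank with the k bases immediately left of the
    interval equal to the reverse complement of the k bases immediately
    right (both read outward from the interval)."""
    s, e = interval
    n = genome.length
    if not (0 <= s <= e <= n):
        raise BoundsError(f"interval {interval} outside genome of {n} bp")
    if not wrap and (s == 0 or e == n):
        raise BoundsError("interval touches sequence end and wrapping "
                          "is not permitted")
    seq = genome.sequence
    k = 0
    while k < max_flank:
        li = s - k - 1
        ri = e + k
        if not wrap and (li < 0 or ri >= n):
            break
        left = seq[li % n]
        right = seq[ri % n]
        if left not in _COMP or _COMP[right] != left:
            break
        k += 1
    return k


def _kmer_set(seq: str, k: int = 11) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def detect_genomic_inversion(query: AnnotatedPlastome,
                             reference: AnnotatedPlastome,
                             region: tuple[str, str],
                             max_flank: int = 200) -> GenomicInversion | None:
    """Compare a gene-anchored window between two genomes and report an
    inversion when the query's middle segment matches the reference in
    reverse-complement orientation.

    The window runs from the end of the first anchor gene to the start
    of the second; the inversion interval is the maximal differing
    segment (outside the longest common prefix/suffix of the windows).
    Affected features are genes inside the interval whose strand differs
    between the genomes.  Returns None when forward orientation fits.
    """
    gene_l, gene_r = region
    windows = {}
    for label, genome in (("query", query), ("reference", reference)):
        fl = genome.find_features(gene_l)
        fr = genome.find_features(gene_r)
        if not fl:
            raise AnchorError(f"{label}: anchor gene {gene_l!r} absent")
        if not fr:
            raise AnchorError(f"{label}: anchor gene {gene_r!r} absent")
        best = None
        n = genome.length
        for a in fl:
            for b in fr:
                span = (b.start - a.end) % n
                if best is None or span < best[0]:
                    best = (span, a.end % n, b.start % n)
        windows[label] = (best[1], best[1] + best[0], genome)
    qs, qe, _ = windows["query"]
    rs, re_, _ = windows["reference"]
    q_seq = query.fetch(qs, qe)
    r_seq = reference.fetch(rs, re_)
    if q_seq == r_seq:
        return None
    pref = 0
    m = min(len(q_seq), len(r_seq))
    while pref < m and q_seq[pref] == r_seq[pref]:
        pref += 1
    suf = 0
    while suf < m - pref and q_seq[-1 - suf] == r_seq[-1 - suf]:
        suf += 1
    mid_q = q_seq[pref:len(q_seq) - suf]
    mid_r = r_seq[pref:len(r_seq) - suf]
    if not mid_q or not mid_r:
        return None
    if revcomp(mid_q) == mid_r:
        rev_better = True
    else:
        kq_f = _kmer_set(mid_q)
        kq_r = _kmer_set(revcomp(mid_q))
        kr = _kmer_set(mid_r)
        fwd_score = len(kq_f & kr)
        rev_score = len(kq_r & kr)
        rev_better = rev_score > 2 * max(fwd_score, 1)
    if not rev_better:
        return None
    interval = ((qs + pref) % query.length,
                (qs + pref) % query.length + len(mid_q))
    affected = []
    ref_strand = {}
    for f in reference.features:
        ref_strand.setdefault(f.name, f.strand)
    for f in query.features:
        s, e = f.span()
        if interval[0] <= s and e <= interval[1]:
            if f.name in ref_strand and ref_strand[f.name] != f.strand:
                affected.append(f.name)
    flank = find_flanking_ir(query, interval, max_flank=max_flank)
    return GenomicInversion(interval=interval, flank_length=flank,
                            affected_features=affected)
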