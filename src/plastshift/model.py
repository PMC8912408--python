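"""Core domain types shared across the pipeline.

A plastome is modelled as a circular uppercase DNA sequence plus a flat
list of stranded, possibly multi-interval gene features.  Internally all
coordinates are 0-based half-open; report output uses 1-based inclusive
(GenBank convention).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHVacgtnryswkmbdhv",
                            "TGCANYRSWMKVHDBtgcanyrswmkvhdb")

GENE_KINDS = ("protein", "tRNA", "rRNA")

#: one-letter amino-acid code used in normalized tRNA names
_AA_LETTERS = set("ACDEFGHIKLMNPQRSTVWY")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    """GC percentage over unambiguous bases; N and other ambiguity codes are
    excluded from the denominator."""
    a = seq.count("A") + seq.count("T")
    g = seq.count("G") + seq.count("C")
    if a + g == 0:
        return 0.0
    return 100.0 * g / (a + g)


_TRNA_PAREN = re.compile(r"^trn([A-Za-z])[\s(\-_]*([ACGTUacgtu]{3})\)?$")


def normalize_gene_name(name: str) -> str:
    """Normalize gene symbols for matching.

    tRNA names are folded to the ``trnX-ANT`` form (amino-acid letter plus
    anticodon, U→T) from any of the common spellings (``trnV(GAC)``,
    ``trnV-GAC``, ``trnv_gac``).  Other symbols only have surrounding
    whitespace stripped; comparisons should go through
    :func:`same_gene` which is case-insensitive.
    """
    name = name.strip()
    m = _TRNA_PAREN.match(name)
    if m:
        aa = m.group(1).upper()
        anticodon = m.group(2).upper().replace("U", "T")
        return f"trn{aa}-{anticodon}"
    return name


def same_gene(a: str, b: str) -> bool:
    """Case-insensitive comparison of normalized gene symbols.

    A bare tRNA symbol (``trnV``) matches any anticodon-qualified form
    (``trnV-GAC``) so that user queries need not carry the anticodon.
    """
    na, nb = normalize_gene_name(a), normalize_gene_name(b)
    if na.lower() == nb.lower():
        return True
    la, lb = na.lower(), nb.lower()
    if la.startswith("trn") and lb.startswith("trn"):
        return la.split("-")[0] == lb.split("-")[0]
    return False


@dataclass
class GeneFeature:
    """A gene annotation: one or more [start, end) intervals on a strand.

    Multi-interval features represent intron-containing genes; a feature
    whose last interval wraps past the origin carries
    ``may_wrap_origin=True`` and stores the wrap as a pair of intervals.
    """

    name: str
    kind: str  # one of GENE_KINDS
    strand: str  # '+' or '-'
    intervals: list[tuple[int, int]]
    pseudo: bool = False
    may_wrap_origin: bool = False

    def __post_init__(self) -> None:
        if self.kind not in GENE_KINDS:
            raise ValueError(
                f"feature {self.name!r}: unknown kind {self.kind!r} "
                f"(expected one of {GENE_KINDS})")
        if not self.intervals:
            raise ValueError(f"feature {self.name!r}: no intervals")
        if self.strand not in "+-":
            raise ValueError(f"feature {self.name!r}: bad strand {self.strand!r}")

    @property
    def start(self) -> int:
        return self.intervals[0][0]

    @property
    def end(self) -> int:
        return self.intervals[-1][1]

    def span(self) -> tuple[int, int]:
        """Outer [start, end) span; for origin-wrapping features the end is
        smaller than the start."""
        return self.start, self.end

    def length(self) -> int:
        return sum(e - s for s, e in self.intervals)

    def contains(self, pos: int, genome_length: int | None = None) -> bool:
        """Whether genomic position ``pos`` falls in an exon interval."""
        for s, e in self.intervals:
            if s <= pos < e:
                return True
            if genome_length is not None and e > genome_length:
                # stored un-normalized wrap
                if s <= pos + genome_length < e:
                    return True
        return False

    def in_intron(self, pos: int) -> bool:
        """Whether ``pos`` lies between two exon intervals of this feature."""
        ivs = sorted(self.intervals)
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if e1 <= pos < s2:
                return True
        return False


@dataclass
class AnnotatedPlastome:
    """A circular plastid genome with its gene annotation."""

    identifier: str
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)
    source: str = "synthetic"

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if len(self.sequence) == 0:
            raise ValueError(f"{self.identifier}: zero-length sequence")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(
                f"{self.identifier}: non-ACGTN characters {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def fetch(self, start: int, end: int) -> str:
        """Subsequence [start, end) with modular (circular) coordinates;
        end may exceed the length to express an origin-spanning slice."""
        n = self.length
        start %= n
        if end - start > n:
            raise ValueError("slice longer than genome")
        if end <= n and start <= end:
            return self.sequence[start:end]
        end %= n
        return self.sequence[start:] + self.sequence[:end]

    def feature_sequence(self, feat: GeneFeature) -> str:
        parts = [self.fetch(s, e) for s, e in feat.intervals]
        seq = "".join(parts)
        return revcomp(seq) if feat.strand == "-" else seq

    def find_features(self, name: str) -> list[GeneFeature]:
        return [f for f in self.features if same_gene(f.name, name)]

    def rotated(self, offset: int) -> "AnnotatedPlastome":
        """Genome rotated so that old position ``offset`` becomes 0."""
        n = self.length
        offset %= n
        seq = self.sequence[offset:] + self.sequence[:offset]
        feats = []
        for f in self.features:
            ivs = [((s - offset) % n, (s - offset) % n + (e - s))
                   for s, e in f.intervals]
            wrap = any(e > n for _, e in ivs)
            feats.append(GeneFeature(f.name, f.kind, f.strand, ivs,
                                     pseudo=f.pseudo, may_wrap_origin=wrap))
        return AnnotatedPlastome(self.identifier, seq, feats, self.source)

    def reverse_complemented(self) -> "AnnotatedPlastome":
        n = self.length
        seq = revcomp(self.sequence)
        feats = []
        for f in self.features:
            ivs = sorted((n - e if e <= n else (2 * n - e) % n, n - s)
                         for s, e in f.intervals)
            ivs = [(s, e) for s, e in ivs]
            strand = "-" if f.strand == "+" else "+"
            feats.append(GeneFeature(f.name, f.kind, strand, ivs,
                                     pseudo=f.pseudo,
                                     may_wrap_origin=f.may_wrap_origin))
        return AnnotatedPlastome(self.identifier, seq, feats, self.source)


@dataclass
class DepthProfile:
    """Per-base read depth along a genome."""

    identifier: str
    depths: "Sequence[int]"

    def __post_init__(self) -> None:
        import numpy as np

        self.depths = np.asarray(self.depths, dtype=np.int64)
        if (self.depths < 0).any():
            raise ValueError("negative depth values")

    def __len__(self) -> int:
        return len(self.depths)
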