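"""Reading and writing the standard formats the pipeline touches.

GenBank flat files and FASTA go through Biopython; depth tables are
plain two-column TSV (1-based position, depth).  All coordinates are
converted to 0-based half-open on input and back to 1-based inclusive
on output.
"""

from __future__ import annotations

import os

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .errors import (AmbiguityError, BoundsError, FormatError,
                     RaggedAlignmentError, ValidationError)
from .model import AnnotatedPlastome, DepthProfile, GeneFeature
from .supermatrix import Alignment

_KIND_TO_GB = {"protein": "CDS", "tRNA": "tRNA", "rRNA": "rRNA"}
_GB_TO_KIND = {v: k for k, v in _KIND_TO_GB.items()}


def _infer_kind(name: str) -> str:
    low = name.lower()
    if low.startswith("trn"):
        return "tRNA"
    if low.startswith("rrn"):
        return "rRNA"
    return "protein"


def _location_to_intervals(location, genome_length: int
                           ) -> tuple[list[tuple[int, int]], bool]:
    """Biopython location → ordered [start, end) intervals + wrap flag.

    A compound location whose final part abuts the origin (prev part ends
    at genome length, next starts at 0) is an origin-wrapping feature,
    not an intron join.
    """
    parts = list(location.parts)
    if location.strand == -1:
        parts = parts[::-1]
    intervals = [(int(p.start), int(p.end)) for p in parts]
    wraps = False
    for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
        if e1 == genome_length and s2 == 0:
            wraps = True
    return intervals, wraps


def read_genbank(path: str | os.PathLike) -> AnnotatedPlastome:
    """Parse a single-record GenBank flat file into an AnnotatedPlastome.

    CDS features map to kind ``protein``, tRNA/rRNA to their kinds;
    ``gene`` features carrying a /pseudo qualifier with no same-location
    typed feature are censused as pseudogenes of the kind inferred from
    the symbol.  Raises FormatError / AmbiguityError / ValidationError
    per the contract.
    """
    try:
        records = list(SeqIO.parse(os.fspath(path), "genbank"))
    except ValueError as exc:
        raise FormatError(f"{path}: not parseable as GenBank ({exc})") from exc
    if len(records) == 0:
        raise FormatError(f"{path}: no GenBank records found")
    if len(records) > 1:
        raise AmbiguityError(
            f"{path}: {len(records)} records; expected a single circular record")
    rec = records[0]
    seq = str(rec.seq).upper()
    if len(seq) == 0:
        raise ValidationError(f"{path}: zero-length sequence")
    n = len(seq)

    features: list[GeneFeature] = []
    typed_spans: set[tuple[str, int, int]] = set()
    for f in rec.features:
        if f.type not in _GB_TO_KIND:
            continue
        name = _qualifier_name(f)
        if name is None:
            continue
        intervals, wraps = _location_to_intervals(f.location, n)
        strand = "-" if f.location.strand == -1 else "+"
        pseudo = "pseudo" in f.qualifiers or "pseudogene" in f.qualifiers
        features.append(GeneFeature(name, _GB_TO_KIND[f.type], strand,
                                    intervals, pseudo=pseudo,
                                    may_wrap_origin=wraps))
        typed_spans.add((name.lower(), intervals[0][0], intervals[-1][1]))
    for f in rec.features:
        if f.type != "gene":
            continue
        if "pseudo" not in f.qualifiers and "pseudogene" not in f.qualifiers:
            continue
        name = _qualifier_name(f)
        if name is None:
            continue
        intervals, wraps = _location_to_intervals(f.location, n)
        key = (name.lower(), intervals[0][0], intervals[-1][1])
        if key in typed_spans:
            continue
        strand = "-" if f.location.strand == -1 else "+"
        features.append(GeneFeature(name, _infer_kind(name), strand,
                                    intervals, pseudo=True,
                                    may_wrap_origin=wraps))
    return AnnotatedPlastome(rec.id or rec.name, seq, features,
                             source=os.fspath(path))


def _qualifier_name(feature) -> str | None:
    for key in ("gene", "locus_tag", "product"):
        if key in feature.qualifiers:
            return feature.qualifiers[key][0]
    return None


def write_genbank(plastome: AnnotatedPlastome, path: str | os.PathLike) -> None:
    """Write a plastome as a circular single-record GenBank flat file."""
    rec = SeqRecord(Seq(plastome.sequence), id=plastome.identifier,
                    name=plastome.identifier[:16].replace(" ", "_"),
                    description="plastid genome")
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = "circular"
    n = plastome.length
    for feat in plastome.features:
        strand = -1 if feat.strand == "-" else 1
        locs = []
        for s, e in feat.intervals:
            if e <= n:
                locs.append(SimpleLocation(s, e, strand))
            else:  # wraps the origin: emit as two parts
                locs.append(SimpleLocation(s, n, strand))
                locs.append(SimpleLocation(0, e - n, strand))
        if strand == -1:
            locs = locs[::-1]
        location = locs[0] if len(locs) == 1 else CompoundLocation(locs)
        quals = {"gene": [feat.name]}
        if feat.pseudo:
            quals["pseudo"] = [""]
        rec.features.append(SeqFeature(location, type=_KIND_TO_GB[feat.kind],
                                       qualifiers=quals))
    SeqIO.write([rec], os.fspath(path), "genbank")


def read_fasta_alignment(path: str | os.PathLike) -> Alignment:
    """Read an aligned FASTA file; rows must be equal length and taxon
    ids unique.  Gap character is '-'; ambiguity codes are retained."""
    taxa, rows = [], []
    for rec in SeqIO.parse(os.fspath(path), "fasta"):
        taxa.append(rec.id)
        rows.append(str(rec.seq).upper())
    if not taxa:
        raise FormatError(f"{path}: no FASTA records")
    lengths = {len(r) for r in rows}
    if len(lengths) > 1:
        raise RaggedAlignmentError(
            f"{path}: unequal row lengths {sorted(lengths)}")
    return Alignment(taxa, rows)


def write_fasta_alignment(alignment: Alignment, path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(r), id=t, description="")
               for t, r in zip(alignment.taxa, alignment.rows)]
    SeqIO.write(records, os.fspath(path), "fasta")


def read_depth_table(path: str | os.PathLike, genome_length: int) -> DepthProfile:
    """Read a two-column (1-based position, depth) TSV into a DepthProfile
    of exactly ``genome_length`` entries; absent positions get depth 0."""
    depths = np.zeros(genome_length, dtype=np.int64)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            try:
                pos, depth = int(fields[0]), int(fields[1])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer field") from exc
            if not 1 <= pos <= genome_length:
                raise BoundsError(
                    f"{path}:{lineno}: position {pos} outside 1..{genome_length}")
            depths[pos - 1] = depth
    name = os.path.splitext(os.path.basename(os.fspath(path)))[0]
    return DepthProfile(name, depths)


def write_depth_table(profile: DepthProfile, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for i, d in enumerate(profile.depths, 1):
            fh.write(f"{i}\t{int(d)}\n")
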