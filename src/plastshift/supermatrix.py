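"""Concatenated-matrix construction and site statistics.

Implements the character-level statistics used to describe a plastome
supermatrix: gap-rich column masking, block concatenation with a
partition table, site classification (constant / singleton /
parsimony-informative), Fitch parsimony length with consistency and
homoplasy indices, per-branch site concordance factors, and strict
bipartition synapomorphy counts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .errors import (EmptyMatrixError, InsufficientTaxaError,
                     NotInternalBranchError, TaxonMismatchError,
                     ValidationError)

GAP = ord("-")
_BASE_BITS = {"A": 1, "C": 2, "G": 4, "T": 8}
#: IUPAC codes other than ACGT (plus gap and N) are treated as missing
#: throughout: they contribute the full state set to Fitch and are
#: excluded from site classification and quartet decisiveness.
_MISSING = 15


@dataclass
class Alignment:
    """A multiple sequence alignment: ordered taxa and equal-length rows."""

    taxa: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValidationError("taxa/rows length mismatch")
        if len(set(self.taxa)) != len(self.taxa):
            dupes = {t for t in self.taxa if self.taxa.count(t) > 1}
            raise ValidationError(f"duplicate taxon ids: {sorted(dupes)}")
        if self.rows:
            ncol = len(self.rows[0])
            for t, r in zip(self.taxa, self.rows):
                if len(r) != ncol:
                    from .errors import RaggedAlignmentError

                    raise RaggedAlignmentError(
                        f"row {t!r} has length {len(r)}, expected {ncol}")
        self.rows = [r.upper() for r in self.rows]

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]

    def to_codes(self) -> np.ndarray:
        """(n_taxa, n_columns) uint8 matrix of state bitmasks; gaps, N and
        ambiguity codes map to the missing state (all bits set)."""
        arr = np.frombuffer("".join(self.rows).encode(), dtype=np.uint8)
        arr = arr.reshape(self.n_taxa, self.n_columns)
        codes = np.full(arr.shape, _MISSING, dtype=np.uint8)
        for base, bit in _BASE_BITS.items():
            codes[arr == ord(base)] = bit
        return codes

    def char_matrix(self) -> np.ndarray:
        arr = np.frombuffer("".join(self.rows).encode(), dtype=np.uint8)
        return arr.reshape(self.n_taxa, self.n_columns).copy()

    @classmethod
    def from_char_matrix(cls, taxa: list[str], mat: np.ndarray) -> "Alignment":
        rows = [bytes(mat[i]).decode() for i in range(mat.shape[0])]
        return cls(list(taxa), rows)


@dataclass
class SiteClassification:
    constant: int
    variable: int
    parsimony_informative: int
    singleton: int
    masked: int = 0

    def __post_init__(self) -> None:
        assert self.parsimony_informative + self.singleton == self.variable


@dataclass
class ParsimonyResult:
    total_length: int
    per_site_length: np.ndarray
    min_possible: np.ndarray
    ci: float
    hi: float
    degenerate: bool = False


@dataclass
class ConcordanceResult:
    branch: int
    scf: float
    sdf1: float
    sdf2: float
    n_quartets: int
    n_decisive_mean: float
    synapomorphies: int


def mask_gap_rich_columns(alignment: Alignment,
                          max_gap_fraction: float = 0.5,
                          ) -> tuple[Alignment, list[int]]:
    """Drop columns whose gap fraction reaches ``max_gap_fraction``.

    Retained columns are those with gaps in *less than* the threshold
    fraction of rows (a column with gaps in exactly half of the rows is
    removed at the default 0.5).  Returns the filtered alignment and the
    list of removed original column indices, from which original
    coordinates are recoverable.
    """
    mat = alignment.char_matrix()
    gap_frac = (mat == GAP).mean(axis=0)
    keep = gap_frac < max_gap_fraction
    if not keep.any():
        raise EmptyMatrixError("masking removed every column")
    masked = [int(i) for i in np.nonzero(~keep)[0]]
    out = Alignment.from_char_matrix(alignment.taxa, mat[:, keep])
    return out, masked


def concatenate(blocks: list[Alignment], policy: str = "strict",
                names: list[str] | None = None,
                ) -> tuple[Alignment, list[tuple[str, int, int]]]:
    """Concatenate alignment blocks column-wise.

    ``policy='strict'`` requires identical taxon sets; ``policy='fill'``
    pads taxa missing from a block with gap rows.  Returns the combined
    alignment and a partition table of (block name, start, end) column
    intervals.
    """
    if not blocks:
        raise ValidationError("no blocks to concatenate")
    if names is None:
        names = [f"block{i}" for i in range(len(blocks))]
    taxa: list[str] = []
    for b in blocks:
        for t in b.taxa:
            if t not in taxa:
                taxa.append(t)
    if policy == "strict":
        for i, b in enumerate(blocks):
            if set(b.taxa) != set(taxa):
                raise TaxonMismatchError(
                    f"block {names[i]!r} taxon set differs under strict policy")
    parts: list[tuple[str, int, int]] = []
    chunks: dict[str, list[str]] = {t: [] for t in taxa}
    pos = 0
    for name, b in zip(names, blocks):
        ncol = b.n_columns
        lookup = dict(zip(b.taxa, b.rows))
        for t in taxa:
            chunks[t].append(lookup.get(t, "-" * ncol))
        parts.append((name, pos, pos + ncol))
        pos += ncol
    rows = ["".join(chunks[t]) for t in taxa]
    return Alignment(taxa, rows), parts


def extract_partition(alignment: Alignment,
                      parts: list[tuple[str, int, int]],
                      names: set[str] | list[str]) -> Alignment:
    """Column-slice the sub-matrix of the named partitions, in table order."""
    wanted = set(names)
    pieces = [(s, e) for n, s, e in parts if n in wanted]
    rows = ["".join(r[s:e] for s, e in pieces) for r in alignment.rows]
    return Alignment(list(alignment.taxa), rows)


def classify_sites(alignment: Alignment, n_masked: int = 0) -> SiteClassification:
    """Classify columns as constant, singleton or parsimony-informative.

    Gaps, N and ambiguity codes are excluded from state counting; a
    parsimony-informative column has at least two states each carried by
    at least two rows.
    """
    mat = alignment.char_matrix()
    counts = np.stack([(mat == ord(b)).sum(axis=0) for b in "ACGT"])
    n_states = (counts > 0).sum(axis=0)
    n_frequent = (counts >= 2).sum(axis=0)
    variable = n_states >= 2
    informative = variable & (n_frequent >= 2)
    n_var = int(variable.sum())
    n_inf = int(informative.sum())
    return SiteClassification(
        constant=alignment.n_columns - n_var,
        variable=n_var,
        parsimony_informative=n_inf,
        singleton=n_var - n_inf,
        masked=n_masked,
    )


# ---------------------------------------------------------------------------
# Trees


class TreeTopology:
    """An unrooted view of a phylogeny over the alignment's taxa.

    Wraps a dendropy tree; degree-2 nodes (rooted-newick artifacts) are
    suppressed so branch enumeration is rooting-invariant.  Internal
    branches — edges whose removal leaves at least two leaves on each
    side — are numbered 1..k in newick traversal order.
    """

    def __init__(self, tree: dendropy.Tree):
        self._adj: dict[int, set[int]] = {}
        self._leaf_label: dict[int, str] = {}
        counter = itertools.count()
        ids: dict[int, int] = {}

        def nid(node) -> int:
            key = id(node)
            if key not in ids:
                ids[key] = next(counter)
                self._adj[ids[key]] = set()
            return ids[key]

        for edge in tree.preorder_edge_iter():
            if edge.tail_node is None:
                continue
            u, v = nid(edge.tail_node), nid(edge.head_node)
            self._adj[u].add(v)
            self._adj[v].add(u)
        for leaf in tree.leaf_node_iter():
            self._leaf_label[nid(leaf)] = leaf.taxon.label
        # suppress degree-2 internal nodes (e.g. the newick root)
        for u in list(self._adj):
            if u not in self._leaf_label and len(self._adj[u]) == 2:
                a, b = self._adj.pop(u)
                self._adj[a].discard(u)
                self._adj[b].discard(u)
                self._adj[a].add(b)
                self._adj[b].add(a)
        self._branches = self._enumerate_branches()
        self._dendropy = tree

    @classmethod
    def from_newick(cls, source: str) -> "TreeTopology":
        import os

        kwargs = dict(schema="newick", preserve_underscores=True)
        if os.path.exists(source):
            tree = dendropy.Tree.get(path=source, **kwargs)
        else:
            tree = dendropy.Tree.get(data=source, **kwargs)
        return cls(tree)

    @property
    def taxa(self) -> list[str]:
        return sorted(self._leaf_label.values())

    def _subtree_leaves(self, start: int, blocked: int) -> frozenset[str]:
        """Leaf labels reachable from ``start`` without crossing ``blocked``."""
        seen, stack, leaves = {blocked, start}, [start], []
        while stack:
            u = stack.pop()
            if u in self._leaf_label:
                leaves.append(self._leaf_label[u])
            for w in self._adj[u]:
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        return frozenset(leaves)

    def _enumerate_branches(self) -> dict[int, tuple[int, int]]:
        branches: dict[int, tuple[int, int]] = {}
        k = 1
        seen_pairs = set()
        for u in sorted(self._adj):
            for v in sorted(self._adj[u]):
                if (v, u) in seen_pairs:
                    continue
                seen_pairs.add((u, v))
                if u in self._leaf_label or v in self._leaf_label:
                    continue
                branches[k] = (u, v)
                k += 1
        return branches

    def internal_branches(self) -> list[int]:
        return sorted(self._branches)

    def bipartition(self, branch: int) -> tuple[frozenset[str], frozenset[str]]:
        """(near-side, far-side) leaf sets of an internal branch."""
        if branch not in self._branches:
            raise NotInternalBranchError(f"no internal branch {branch}")
        u, v = self._branches[branch]
        return self._subtree_leaves(u, v), self._subtree_leaves(v, u)

    def quartet_groups(self, branch: int) -> tuple[frozenset[str], ...]:
        """The four leaf groups (A, B | C, D) around an internal branch,
        where the tree joins A+B against C+D."""
        if branch not in self._branches:
            raise NotInternalBranchError(f"no internal branch {branch}")
        u, v = self._branches[branch]
        u_sides = [self._subtree_leaves(w, u) for w in sorted(self._adj[u] - {v})]
        v_sides = [self._subtree_leaves(w, v) for w in sorted(self._adj[v] - {u})]
        if len(u_sides) != 2 or len(v_sides) != 2:
            raise NotInternalBranchError(
                f"branch {branch} is not binary-internal "
                f"({len(u_sides)}+{len(v_sides)} incident subtrees)")
        return u_sides[0], u_sides[1], v_sides[0], v_sides[1]

    def postorder_fitch_schedule(self, taxa: list[str]
                                 ) -> list[tuple[int, list[int]]]:
        """(node, children) pairs in postorder for a rooted traversal,
        rooting arbitrarily at the first internal node."""
        internal = [u for u in sorted(self._adj) if u not in self._leaf_label]
        root = internal[0] if internal else sorted(self._adj)[0]
        order: list[tuple[int, list[int]]] = []
        stack = [(root, -1, False)]
        while stack:
            node, parent, expanded = stack.pop()
            children = [w for w in sorted(self._adj[node]) if w != parent]
            if expanded or not children:
                order.append((node, children))
            else:
                stack.append((node, parent, True))
                for w in children:
                    stack.append((w, node, False))
        return order


# ---------------------------------------------------------------------------
# Parsimony


def fitch_length(tree: TreeTopology, alignment: Alignment,
                 ci_scope: str = "variable") -> ParsimonyResult:
    """Per-site Fitch parsimony length plus consistency/homoplasy indices.

    Gaps, N and ambiguity codes are missing data (the full state set).
    ``min_possible`` per site is (distinct observed states − 1).  CI is
    Σ min_possible / Σ length over the sites selected by ``ci_scope``
    ('variable' or 'informative'); HI = 1 − CI.  On data with no
    parsimony changes CI is reported as 1 with ``degenerate=True``.
    """
    tree_taxa = set(tree.taxa)
    if tree_taxa != set(alignment.taxa):
        raise TaxonMismatchError(
            f"tree/alignment taxa differ: {sorted(tree_taxa ^ set(alignment.taxa))}")
    codes = alignment.to_codes()
    ncol = alignment.n_columns
    leaf_row = {t: i for i, t in enumerate(alignment.taxa)}
    schedule = tree.postorder_fitch_schedule(alignment.taxa)
    node_state: dict[int, np.ndarray] = {}
    changes = np.zeros(ncol, dtype=np.int64)
    for node, children in schedule:
        if not children:
            node_state[node] = codes[leaf_row[tree._leaf_label[node]]]
            continue
        acc = node_state[children[0]]
        for c in children[1:]:
            inter = acc & node_state[c]
            empty = inter == 0
            changes += empty
            acc = np.where(empty, acc | node_state[c], inter)
        node_state[node] = acc

    counts = np.stack([((codes == bit).sum(axis=0)) for bit in (1, 2, 4, 8)])
    n_states = (counts > 0).sum(axis=0)
    min_possible = np.maximum(n_states - 1, 0).astype(np.int64)
    if ci_scope == "variable":
        scope = n_states >= 2
    elif ci_scope == "informative":
        scope = ((counts >= 2).sum(axis=0) >= 2) & (n_states >= 2)
    else:
        raise ValidationError(f"unknown ci_scope {ci_scope!r}")
    num = int(min_possible[scope].sum())
    den = int(changes[scope].sum())
    degenerate = den == 0
    ci = 1.0 if degenerate else num / den
    return ParsimonyResult(
        total_length=int(changes.sum()),
        per_site_length=changes,
        min_possible=min_possible,
        ci=ci,
        hi=1.0 - ci,
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# Site concordance


def _sample_quartets(groups: tuple[frozenset[str], ...], n_quartets: int,
                     rng: np.random.Generator) -> list[tuple[str, str, str, str]]:
    sets = [sorted(g) for g in groups]
    sizes = [len(s) for s in sets]
    total = int(np.prod(sizes))
    if total <= n_quartets:
        return list(itertools.product(*sets))
    idx = rng.choice(total, size=n_quartets, replace=False)
    quartets = []
    for flat in idx:
        picks = []
        for size, s in zip(reversed(sizes), reversed(sets)):
            flat, r = divmod(int(flat), size)
            picks.append(s[r])
        quartets.append(tuple(reversed(picks)))
    return quartets


def site_concordance(tree: TreeTopology, alignment: Alignment, branch: int,
                     n_quartets: int = 100, seed: int = 0) -> ConcordanceResult:
    """Site concordance factor for one internal branch.

    For each sampled quartet (one leaf per subtree around the branch) a
    site is decisive when all four leaves carry unambiguous bases in a
    2+2 pattern supporting one of the three quartet topologies; sCF is
    the mean, over quartets with at least one decisive site, of the
    fraction of decisive sites supporting the tree's own topology
    (A,B | C,D), in percent.  sDF1 pairs A with C, sDF2 pairs A with D.
    """
    groups = tree.quartet_groups(branch)
    rng = np.random.default_rng(seed)
    quartets = _sample_quartets(groups, n_quartets, rng)
    codes = alignment.to_codes()
    row = {t: i for i, t in enumerate(alignment.taxa)}
    pure = codes != _MISSING
    cf = np.zeros(3)
    n_used = 0
    decisive_counts = []
    for a, b, c, d in quartets:
        ra, rb, rc, rd = (codes[row[t]] for t in (a, b, c, d))
        ok = pure[row[a]] & pure[row[b]] & pure[row[c]] & pure[row[d]]
        s1 = ok & (ra == rb) & (rc == rd) & (ra != rc)  # AB|CD (tree)
        s2 = ok & (ra == rc) & (rb == rd) & (ra != rb)  # AC|BD
        s3 = ok & (ra == rd) & (rb == rc) & (ra != rb)  # AD|BC
        n1, n2, n3 = int(s1.sum()), int(s2.sum()), int(s3.sum())
        dec = n1 + n2 + n3
        decisive_counts.append(dec)
        if dec == 0:
            continue
        cf += np.array([n1, n2, n3]) / dec
        n_used += 1
    if n_used:
        cf = 100.0 * cf / n_used
    syn = count_branch_synapomorphies(tree, alignment, branch)
    return ConcordanceResult(
        branch=branch,
        scf=float(cf[0]), sdf1=float(cf[1]), sdf2=float(cf[2]),
        n_quartets=len(quartets),
        n_decisive_mean=float(np.mean(decisive_counts)) if decisive_counts else 0.0,
        synapomorphies=syn,
    )


def count_branch_synapomorphies(tree: TreeTopology, alignment: Alignment,
                                branch: int) -> int:
    """Columns where the branch bipartition is a perfect two-state split:
    all non-missing taxa on one side share a state, all on the other side
    share a different state, and each side has ≥2 non-missing taxa."""
    near, far = tree.bipartition(branch)
    codes = alignment.to_codes()
    row = {t: i for i, t in enumerate(alignment.taxa)}

    def side_profile(side):
        sub = codes[[row[t] for t in sorted(side)]]
        present = sub != _MISSING
        n_present = present.sum(axis=0)
        # state carried by all non-missing rows, else 0
        masked = np.where(present, sub, 0)
        any_state = np.bitwise_or.reduce(masked, axis=0)
        uniform = np.ones(sub.shape[1], dtype=bool)
        for i in range(sub.shape[0]):
            uniform &= ~present[i] | (sub[i] == any_state)
        single = np.isin(any_state, (1, 2, 4, 8))
        return n_present, uniform & single, any_state

    n1, u1, s1 = side_profile(near)
    n2, u2, s2 = side_profile(far)
    good = (n1 >= 2) & (n2 >= 2) & u1 & u2 & (s1 != s2)
    return int(good.sum())
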