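"""Shared fixtures and independent oracle implementations.

The oracles here are deliberately naive (brute-force scans, exhaustive
enumeration) and independent of the library code paths they check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from plastshift import Alignment, AnnotatedPlastome
from plastshift.model import revcomp
from plastshift.synthetic import (StructuralEvent, SyntheticPlastomeSpec,
                                  generate_plastome)

SIX_TAXON_TREE = "((A:1,B:1):1,(C:1,(D:1,(E:1,F:1):1):1):1);"
EIGHT_TAXON_TREE = ("((((A:0.01,B:0.01):0.005,(C:0.01,D:0.01):0.005):0.005,"
                    "(E:0.01,F:0.01):0.01):0.01,(G:0.02,H:0.02):0.01);")


@pytest.fixture(scope="session")
def default_genome():
    genome, truth = generate_plastome(SyntheticPlastomeSpec(seed=7))
    return genome, truth


@pytest.fixture(scope="session")
def insertion_genome():
    """Genome carrying a 1,100-bp psbA-fragment + trnH payload insertion
    in the trnV(GAC)–rrn16 spacer."""
    spec = SyntheticPlastomeSpec(seed=11, events=[
        StructuralEvent("jla_shift_with_insertion",
                        {"spacer": ("trnV-GAC", "rrn16"), "length": 1100,
                         "payload_genes": ["psbA-fragment", "trnH"]})])
    genome, truth = generate_plastome(spec)
    return spec, genome, truth


def brute_longest_inverted_repeat(seq: str) -> int:
    """Longest length L such that some substring of the circle equals the
    reverse complement of another (possibly overlapping) substring —
    binary search over L with substring hashing on the doubled sequence."""
    n = len(seq)
    t = seq + seq

    def exists(L: int) -> bool:
        if L == 0:
            return True
        subs = {t[i:i + L] for i in range(n)}
        return any(revcomp(t[i:i + L]) in subs for i in range(n))

    lo, hi = 0, n
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if exists(mid):
            lo = mid
        else:
            hi = mid - 1
    return lo


def brute_fitch_length(newick: str, aln: Alignment) -> int:
    """Exhaustive minimization over all internal-node labelings."""
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    nodes = list(tree.preorder_node_iter())
    internal = [nd for nd in nodes if not nd.is_leaf()]
    code = {"A": 0, "C": 1, "G": 2, "T": 3}
    total = 0
    for col in range(aln.n_columns):
        states = {t: aln.row(t)[col] for t in aln.taxa}
        best = 10 ** 9
        for labeling in itertools.product(range(4), repeat=len(internal)):
            lab = dict(zip((id(nd) for nd in internal), labeling))
            cost = 0
            for nd in nodes:
                if nd.parent_node is None:
                    continue
                ps = lab[id(nd.parent_node)]
                if nd.is_leaf():
                    ch = states[nd.taxon.label]
                    if ch not in code:
                        continue
                    cs = code[ch]
                else:
                    cs = lab[id(nd)]
                cost += ps != cs
            best = min(best, cost)
        total += best
    return total


def brute_flank_scan(seq: str, s: int, e: int, max_flank: int) -> int:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    n = len(seq)
    k = 0
    while k < max_flank:
        left = seq[(s - k - 1) % n]
        right = seq[(e + k) % n]
        if comp.get(right) != left:
            break
        k += 1
    return k


def brute_pcr_products(seq: str, fwd: str, rev: str, max_mismatch: int,
                       max_product: int, anchor: int = 5
                       ) -> set[tuple[int, int]]:
    """All (plus-site start, product length) pairs from a plain nested
    scan over both primers on both strands of the circle."""
    n = len(seq)
    t = seq + seq

    def sites(primer):
        m = len(primer)
        rc = revcomp(primer)
        plus, minus = [], []
        for i in range(n):
            win = t[i:i + m]
            mm = sum(a != b for a, b in zip(win, primer))
            mm3 = sum(a != b for a, b in zip(win[m - anchor:], primer[m - anchor:]))
            if mm <= max_mismatch and mm3 == 0:
                plus.append(i)
            mmr = sum(a != b for a, b in zip(win, rc))
            mm3r = sum(a != b for a, b in zip(win[:anchor], rc[:anchor]))
            if mmr <= max_mismatch and mm3r == 0:
                minus.append(i)
        return plus, minus

    fp, fm = sites(fwd)
    rp, rm = sites(rev)
    products = set()
    for plus_sites, minus_sites, m_plus, m_minus in (
            (fp, rm, len(fwd), len(rev)), (rp, fm, len(rev), len(fwd))):
        for ps in plus_sites:
            for ms in minus_sites:
                product = ((ms + m_minus) - ps) % n
                if product == 0:
                    product = n
                if max(m_plus, m_minus) <= product <= max_product:
                    products.add((ps, product))
    return products


def recount_site_classes(aln: Alignment) -> tuple[int, int, int, int]:
    """(constant, variable, informative, singleton) by per-column loops."""
    const = var = inf = sing = 0
    for col in range(aln.n_columns):
        chars = [r[col] for r in aln.rows if r[col] in "ACGT"]
        counts = {b: chars.count(b) for b in set(chars)}
        if len(counts) <= 1:
            const += 1
        else:
            var += 1
            if sum(1 for c in counts.values() if c >= 2) >= 2:
                inf += 1
            else:
                sing += 1
    return const, var, inf, sing


def inversion_recovered(truth, calls) -> bool:
    """A planted inversion counts as recovered when calls with a shared
    carrier cover at least half of its columns."""
    cols = set()
    for c in calls:
        if set(c.carriers) & set(truth.carriers):
            lo = max(c.interval[0], truth.interval[0])
            hi = min(c.interval[1], truth.interval[1])
            cols.update(range(lo, hi))
    return len(cols) >= 0.5 * (truth.interval[1] - truth.interval[0])


def call_is_precise(call, truths) -> bool:
    span = call.interval[1] - call.interval[0]
    for t in truths:
        lo = max(call.interval[0], t.interval[0])
        hi = min(call.interval[1], t.interval[1])
        if hi - lo >= 0.5 * span:
            return True
    return False
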