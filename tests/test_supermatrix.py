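"""Supermatrix construction and site statistics."""

import numpy as np
import pytest

from conftest import (SIX_TAXON_TREE, brute_fitch_length,
                      recount_site_classes)
from plastshift import (Alignment, TreeTopology, classify_sites, concatenate,
                        count_branch_synapomorphies, extract_partition,
                        fitch_length, mask_gap_rich_columns, site_concordance)
from plastshift.errors import (EmptyMatrixError, NotInternalBranchError,
                               TaxonMismatchError)
from plastshift.synthetic import (simulate_alignment,
                                  simulate_homoplasy_free_alignment)


def _random_alignment(rng, taxa, ncol, gap_p=0.06, n_p=0.04):
    probs = [(1 - gap_p - n_p) / 4] * 4 + [gap_p, n_p]
    rows = ["".join(rng.choice(list("ACGT-N"), p=probs) for _ in range(ncol))
            for _ in taxa]
    return Alignment(list(taxa), rows)


# ---------------------------------------------------------------------------
# Masking and concatenation


def test_exactly_half_gaps_is_masked():
    aln = Alignment(list("ABCD"), ["A-GT", "A-GT", "ACG-", "AC--"])
    out, removed = mask_gap_rich_columns(aln, 0.5)
    # column 1 has 2/4 gaps, column 3 has 2/4: both removed
    assert removed == [1, 3]
    assert out.rows == ["AG", "AG", "AG", "A-"]


def test_gapfree_alignment_unchanged():
    aln = Alignment(list("ABCD"), ["ACGT"] * 4)
    out, removed = mask_gap_rich_columns(aln)
    assert out.rows == aln.rows and removed == []


def test_masking_matches_bruteforce_filter():
    rng = np.random.default_rng(0)
    aln = _random_alignment(rng, "ABCDEF", 400, gap_p=0.35)
    out, removed = mask_gap_rich_columns(aln, 0.5)
    keep = [c for c in range(aln.n_columns)
            if sum(r[c] == "-" for r in aln.rows) / aln.n_taxa < 0.5]
    assert removed == [c for c in range(aln.n_columns) if c not in keep]
    for i, row in enumerate(aln.rows):
        assert out.rows[i] == "".join(row[c] for c in keep)


def test_all_columns_masked_is_an_error():
    aln = Alignment(list("ABCD"), ["----", "----", "ACGT", "ACG-"])
    with pytest.raises(EmptyMatrixError):
        mask_gap_rich_columns(aln, 0.25)


def test_concatenate_partition_table_and_extraction():
    a = Alignment(list("ABCD"), ["ACGTACGTAC"] * 4)
    b = Alignment(list("ABCD"), ["TTTTTTTTTT"] * 4)
    combined, parts = concatenate([a, b], names=["x", "y"])
    assert combined.n_columns == 20
    assert parts == [("x", 0, 10), ("y", 10, 20)]
    sub = extract_partition(combined, parts, ["y"])
    assert sub.rows == b.rows


def test_concatenate_fill_policy_pads_missing_taxon():
    a = Alignment(list("ABCD"), ["ACGT"] * 4)
    b = Alignment(list("ABC"), ["TTTT"] * 3)
    combined, _ = concatenate([a, b], policy="fill")
    assert combined.row("D") == "ACGT----"
    with pytest.raises(TaxonMismatchError):
        concatenate([a, b], policy="strict")


# ---------------------------------------------------------------------------
# Site classification


@pytest.mark.parametrize("column,expected", [
    ("AAAA", "constant"),
    ("AACT", "singleton"),
    ("AACC", "informative"),
    ("AA--", "constant"),
    ("AANC", "singleton"),
])
def test_single_column_classes(column, expected):
    aln = Alignment(list("WXYZ"), list(column))
    cls = classify_sites(aln)
    got = ("constant" if cls.constant else
           "informative" if cls.parsimony_informative else "singleton")
    assert got == expected


def test_classification_matches_exhaustive_recount():
    rng = np.random.default_rng(3)
    for _ in range(5):
        aln = _random_alignment(rng, "ABCDEFGH", 300)
        cls = classify_sites(aln)
        assert (cls.constant, cls.variable, cls.parsimony_informative,
                cls.singleton) == recount_site_classes(aln)


def test_classification_invariant_to_row_and_column_order():
    rng = np.random.default_rng(4)
    aln = _random_alignment(rng, "ABCDEF", 200)
    cls = classify_sites(aln)
    perm = rng.permutation(aln.n_columns)
    shuffled = Alignment(
        list(reversed(aln.taxa)),
        ["".join(r[c] for c in perm) for r in reversed(aln.rows)])
    assert classify_sites(shuffled) == cls


# ---------------------------------------------------------------------------
# Parsimony


def test_textbook_four_taxon_site():
    aln = Alignment(list("ABCD"), ["A", "A", "T", "T"])
    tree = TreeTopology.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
    assert fitch_length(tree, aln).total_length == 1


def test_fitch_equals_bruteforce_on_random_data():
    rng = np.random.default_rng(11)
    aln = _random_alignment(rng, "ABCDEF", 50)
    tree = TreeTopology.from_newick(SIX_TAXON_TREE)
    assert fitch_length(tree, aln).total_length == \
        brute_fitch_length(SIX_TAXON_TREE, aln)


def test_fitch_rerooting_invariance():
    rng = np.random.default_rng(12)
    aln = _random_alignment(rng, "ABCDEF", 200)
    alt = "(C:1,((A:1,B:1):1,(D:1,(E:1,F:1):1):1):1);"
    t1 = TreeTopology.from_newick(SIX_TAXON_TREE)
    t2 = TreeTopology.from_newick(alt)
    assert fitch_length(t1, aln).total_length == \
        fitch_length(t2, aln).total_length


def test_identical_sequences_flagged_degenerate():
    aln = Alignment(list("ABCDEF"), ["ACGTACGT"] * 6)
    res = fitch_length(TreeTopology.from_newick(SIX_TAXON_TREE), aln)
    assert res.total_length == 0 and res.ci == 1.0 and res.degenerate


def test_homoplasy_free_regime_gives_hi_zero():
    aln = simulate_homoplasy_free_alignment(SIX_TAXON_TREE, 2000, seed=1)
    res = fitch_length(TreeTopology.from_newick(SIX_TAXON_TREE), aln)
    assert res.hi == 0.0 and not res.degenerate


def test_ci_scope_conventions_both_computable():
    rng = np.random.default_rng(13)
    aln = _random_alignment(rng, "ABCDEF", 300)
    tree = TreeTopology.from_newick(SIX_TAXON_TREE)
    r_var = fitch_length(tree, aln, ci_scope="variable")
    r_inf = fitch_length(tree, aln, ci_scope="informative")
    assert 0 < r_var.ci <= 1 and 0 < r_inf.ci <= 1
    assert r_var.total_length == r_inf.total_length


def test_taxon_mismatch_rejected():
    aln = Alignment(list("ABCDEX"), ["ACGT"] * 6)
    with pytest.raises(TaxonMismatchError):
        fitch_length(TreeTopology.from_newick(SIX_TAXON_TREE), aln)


# ---------------------------------------------------------------------------
# Site concordance and synapomorphies


def test_perfect_bipartition_gives_scf_100():
    tree = TreeTopology.from_newick(SIX_TAXON_TREE)
    rows = [("A" if t in "AB" else "C") * 30 for t in "ABCDEF"]
    aln = Alignment(list("ABCDEF"), rows)
    res = site_concordance(tree, aln, 1, seed=0)
    assert res.scf == 100.0 and res.sdf1 == 0.0 and res.sdf2 == 0.0


def test_scf_sums_to_100_and_exhaustive_seed_independent():
    tree = TreeTopology.from_newick(SIX_TAXON_TREE)
    aln, _ = simulate_alignment(SIX_TAXON_TREE.replace(":1", ":0.05"),
                                4000, seed=2)
    for branch in tree.internal_branches():
        res = site_concordance(tree, aln, branch, n_quartets=100, seed=3)
        assert res.scf + res.sdf1 + res.sdf2 == pytest.approx(100.0, abs=0.1)
        # the quartet universe here is small: sampling is exhaustive and
        # therefore identical across seeds
        r_a = site_concordance(tree, aln, branch, n_quartets=10**6, seed=1)
        r_b = site_concordance(tree, aln, branch, n_quartets=10**6, seed=9)
        assert (r_a.scf, r_a.sdf1, r_a.sdf2) == (r_b.scf, r_b.sdf1, r_b.sdf2)


def test_conflicted_branch_has_low_scf():
    """With a near-zero internal branch the three quartet topologies get
    comparable site support, pulling sCF toward its 1/3 floor."""
    conflicted = ("((A:0.05,B:0.05):0.0001,(C:0.05,(D:0.05,(E:0.05,"
                  "F:0.05):0.05):0.05):0.0001);")
    tree = TreeTopology.from_newick(conflicted)
    aln, _ = simulate_alignment(conflicted, 20_000, seed=4)
    res = site_concordance(tree, aln, 1, seed=0)
    assert 20.0 <= res.scf <= 55.0


def test_synapomorphy_counting_strict_bipartition():
    tree = TreeTopology.from_newick(SIX_TAXON_TREE)
    taxa = list("ABCDEF")
    rows = {t: [] for t in taxa}
    # 4 perfect columns for branch 1 ({A,B} | rest)
    for _ in range(4):
        for t in taxa:
            rows[t].append("G" if t in "AB" else "T")
    # a column with one deviant inside the near side: not counted
    for t in taxa:
        rows[t].append("G" if t == "A" else "T")
    # a column with missing data on one side but still >= 2 present
    for t in taxa:
        rows[t].append({"A": "C", "B": "C", "C": "N"}.get(t, "A"))
    aln = Alignment(taxa, ["".join(rows[t]) for t in taxa])
    assert count_branch_synapomorphies(tree, aln, 1) == 5


def test_pendant_branch_rejected():
    tree = TreeTopology.from_newick(SIX_TAXON_TREE)
    aln = Alignment(list("ABCDEF"), ["ACGT"] * 6)
    with pytest.raises(NotInternalBranchError):
        site_concordance(tree, aln, 99, seed=0)
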