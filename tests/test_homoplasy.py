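"""Parsimony reconstruction, derived/shared counting, D-loop trimming,
coding-effect classification, and the NJ helper."""

import random

import dendropy
import numpy as np
import pytest

import paleomt as pm
from paleomt.errors import DataError, UsageError
from paleomt.io import GeneAnnotation, SequenceRecord
from .conftest import brute_force_parsimony_score, random_column, random_tree


def _tree(newick):
    t = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    t.is_rooted = True
    return t


def _aln(**seqs):
    return [SequenceRecord(k, v) for k, v in seqs.items()]


# ---------------------------------------------------------------------------
# fitch / parsimony
# ---------------------------------------------------------------------------


def test_constant_column_scores_zero_everywhere():
    tree = _tree("((a,b),(c,d));")
    asg = pm.fitch(tree, _aln(a="A", b="A", c="A", d="A"))
    assert asg.total_score == 0
    assert np.all(asg.states == 0)  # every node reconstructed as A
    assert not asg.ambiguous.any()


def test_two_state_split_costs_one_change():
    tree = _tree("((a,b),(c,d));")
    asg = pm.fitch(tree, _aln(a="A", b="A", c="T", d="T"))
    assert asg.scores.tolist() == [1]


def test_missing_leaves_add_no_cost():
    tree = _tree("((a,b),(c,d));")
    asg = pm.fitch(tree, _aln(a="A", b="N", c="-", d="A"))
    assert asg.total_score == 0


def test_leaf_alignment_mismatch_names_labels():
    tree = _tree("((a,b),(c,d));")
    with pytest.raises(DataError, match="only in alignment.*'e'"):
        pm.fitch(tree, _aln(a="A", b="A", c="A", e="A"))


def test_score_matches_brute_force_on_small_trees():
    rnd = random.Random(101)
    for _ in range(60):
        n = rnd.randint(3, 6)
        tree = random_tree(rnd, n, allow_polytomy=True)
        labels = [l.taxon.label for l in tree.leaf_node_iter()]
        column = random_column(rnd, labels)
        aln = [SequenceRecord(l, column[l] or "N") for l in labels]
        asg = pm.fitch(tree, aln)
        assert asg.scores[0] == brute_force_parsimony_score(tree, column)


def test_resolved_labeling_achieves_the_minimum_score():
    # the top-down resolution must itself be a maximum-parsimony labeling:
    # the number of state-changing edges equals the reported score
    rnd = random.Random(202)
    for _ in range(40):
        tree = random_tree(rnd, rnd.randint(3, 6))
        labels = [l.taxon.label for l in tree.leaf_node_iter()]
        column = random_column(rnd, labels, p_missing=0.0)
        aln = [SequenceRecord(l, column[l]) for l in labels]
        asg = pm.fitch(tree, aln)
        changes = 0
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            k, kp = asg.node_index[id(node)], asg.node_index[id(node.parent_node)]
            changes += asg.states[0, k] != asg.states[0, kp]
        assert changes == asg.scores[0]


# ---------------------------------------------------------------------------
# derived / shared derived
# ---------------------------------------------------------------------------


def _clade_fixture(seed=0):
    cfg = pm.SimulationConfig(
        seed=seed,
        genome_length=500,
        clade_sizes={"I": 3, "II": 3, "III": 3},
        stem_mutations={"I": 7, "II": 5, "III": 4},
        homoplasy_injections={("I", "II"): 2, ("II", "III"): 1, ("I", "III"): 0},
        within_clade_mutations=1,
        outgroup_mutations=20,
    )
    return cfg, *pm.simulate_clade_dataset(cfg)


def test_injected_stem_mutations_are_recovered_exactly():
    cfg, aln, tree, cmap, truth = _clade_fixture()
    asg = pm.fitch(tree, aln)
    for clade in ("I", "II", "III"):
        derived = pm.derived_positions(asg, cmap, clade)
        assert set(derived) == set(truth.derived_columns[clade])
        for col, (anc, der) in truth.derived_columns[clade].items():
            assert derived[col] == (anc, der)


def test_star_identical_sequences_have_no_derived_positions():
    tree = _tree("((a,b),(c,d),(e,f),outgroup);")
    seq = "ACGTACGT"
    aln = _aln(a=seq, b=seq, c=seq, d=seq, e=seq, f=seq, outgroup=seq)
    cmap = {"a": "I", "b": "I", "c": "II", "d": "II", "e": "III", "f": "III",
            "outgroup": "outgroup"}
    asg = pm.fitch(tree, aln)
    for clade in ("I", "II", "III"):
        assert pm.derived_positions(asg, cmap, clade) == {}


def test_unknown_clade_errors():
    cfg, aln, tree, cmap, truth = _clade_fixture()
    asg = pm.fitch(tree, aln)
    with pytest.raises(DataError, match="absent"):
        pm.derived_positions(asg, cmap, "IV")


def test_shared_derived_recovers_injections_and_is_symmetric():
    cfg, aln, tree, cmap, truth = _clade_fixture(seed=4)
    asg = pm.fitch(tree, aln)
    for (a, b), injected in cfg.homoplasy_injections.items():
        fwd = pm.shared_derived(asg, cmap, a, b)
        rev = pm.shared_derived(asg, cmap, b, a)
        assert fwd == rev
        assert len(fwd) == injected
        assert set(fwd) == set(truth.homoplasy_columns[(a, b)])
        d_a = pm.derived_positions(asg, cmap, a)
        d_b = pm.derived_positions(asg, cmap, b)
        assert set(fwd) <= set(d_a) & set(d_b)
        assert len(fwd) <= min(len(d_a), len(d_b))


def test_shared_derived_rejects_identical_clades():
    cfg, aln, tree, cmap, truth = _clade_fixture()
    asg = pm.fitch(tree, aln)
    with pytest.raises(UsageError):
        pm.shared_derived(asg, cmap, "I", "I")


def test_inherited_state_is_not_homoplasy():
    # clades a+b are sisters within the ingroup; a mutation on their common
    # stem appears derived in both but must not count as shared/homoplasic
    tree = _tree("(((a1,a2),(b1,b2)),(c1,c2),outgroup);")
    anc = "AAAA"
    ab = "TAAA"  # inherited T at column 0
    aln = _aln(a1=ab, a2=ab, b1=ab, b2=ab, c1=anc, c2=anc, outgroup=anc)
    cmap = {"a1": "A", "a2": "A", "b1": "B", "b2": "B", "c1": "C", "c2": "C",
            "outgroup": "outgroup"}
    asg = pm.fitch(tree, aln)
    assert set(pm.derived_positions(asg, cmap, "A")) == {0}
    assert set(pm.derived_positions(asg, cmap, "B")) == {0}
    assert pm.shared_derived(asg, cmap, "A", "B") == {}


# ---------------------------------------------------------------------------
# trim_dloop
# ---------------------------------------------------------------------------


def test_trim_removes_reference_interval_columns():
    ref = "ACGTACGTAC"  # 10 bases, trim 4..7
    other = "ACGTACGTAC"
    trimmed = pm.trim_dloop(
        [SequenceRecord("ref", ref), SequenceRecord("x", other)], (4, 7), "ref"
    )
    assert all(len(r.sequence) == 6 for r in trimmed)
    assert trimmed[0].sequence == "ACGTAC"[:3] + "TAC"


def test_trim_counts_through_reference_gaps():
    # reference row has a gap; interval coordinates follow reference bases
    ref = "AC-GT"
    x = "ACTGT"
    trimmed = pm.trim_dloop(
        [SequenceRecord("ref", ref), SequenceRecord("x", x)], (2, 3), "ref"
    )
    # ref positions 2..3 are C and G; the gap column between them is inside
    assert trimmed[0].sequence == "AT"
    assert trimmed[1].sequence == "AT"


def test_trim_none_interval_is_identity():
    aln = _aln(ref="ACGT", x="ACGT")
    assert pm.trim_dloop(aln, None, "ref") == aln


def test_trim_removes_exactly_interval_length_columns():
    rng = np.random.default_rng(0)
    seq = "".join(rng.choice(list("ACGT"), size=16770))
    aln = [SequenceRecord("ref", seq), SequenceRecord("x", seq)]
    trimmed = pm.trim_dloop(aln, (15422, 16770), "ref")
    assert len(trimmed[0].sequence) == 15421


def test_trim_interval_beyond_reference_errors():
    with pytest.raises(DataError, match="beyond"):
        pm.trim_dloop(_aln(ref="ACGT"), (2, 10), "ref")


# ---------------------------------------------------------------------------
# classify_effect
# ---------------------------------------------------------------------------


def _effect_fixture(seq_anc, seq_derived_clade):
    tree = _tree("((a1,a2),(b1,b2),outgroup);")
    aln = _aln(a1=seq_derived_clade, a2=seq_derived_clade, b1=seq_anc, b2=seq_anc,
               outgroup=seq_anc)
    cmap = {"a1": "A", "a2": "A", "b1": "B", "b2": "B", "outgroup": "outgroup"}
    asg = pm.fitch(tree, aln)
    ref_row = SequenceRecord("outgroup", seq_anc)
    return asg, cmap, ref_row


def test_third_position_leucine_change_is_synonymous():
    # CTA -> CTG at codon 2 of a forward gene: Leu -> Leu
    anc = "ATGCTATAAGG"
    der = "ATGCTGTAAGG"
    asg, cmap, ref_row = _effect_fixture(anc, der)
    ann = [GeneAnnotation("nd0", 1, 9, "+")]
    effect = pm.classify_effect(asg, cmap, 5, "G", ann, ref_row)
    assert effect == "synonymous"


def test_first_position_ata_to_gta_is_nonsynonymous():
    # vertebrate mitochondrial code: ATA is Met; GTA is Val
    anc = "ATACTATAAGG"
    der = "GTACTATAAGG"
    asg, cmap, ref_row = _effect_fixture(anc, der)
    ann = [GeneAnnotation("nd0", 1, 9, "+")]
    assert pm.classify_effect(asg, cmap, 0, "G", ann, ref_row) == "nonsynonymous"


def test_column_outside_cds_is_noncoding():
    anc = "ATGCTATAAGG"
    asg, cmap, ref_row = _effect_fixture(anc, anc)
    ann = [GeneAnnotation("nd0", 1, 9, "+")]
    assert pm.classify_effect(asg, cmap, 10, "A", ann, ref_row) == "noncoding"


def test_reverse_strand_gene_complemented_before_translation():
    # '-' gene over ref 1..6; revcomp(ATGCTA) = TAGCAT -> codons TAG, CAT
    # ref position 1 A->G makes the second '-' codon CAT -> CAC (His->His)
    anc = "ATGCTAAAAA"
    der = "GTGCTAAAAA"
    asg, cmap, ref_row = _effect_fixture(anc, der)
    ann = [GeneAnnotation("rev0", 1, 6, "-")]
    assert pm.classify_effect(asg, cmap, 0, "G", ann, ref_row) == "synonymous"


def test_codon_with_missing_states_is_unresolved():
    anc = "ATGCTATAAGG"
    tree = _tree("((a1,a2),(b1,b2),outgroup);")
    # column 4 mostly missing -> excluded from countable columns
    gappy = anc[:4] + "N" + anc[5:]
    aln = _aln(a1=gappy, a2=gappy, b1=gappy, b2=gappy, outgroup=gappy)
    cmap = {"a1": "A", "a2": "A", "b1": "B", "b2": "B", "outgroup": "outgroup"}
    asg = pm.fitch(tree, aln)
    ann = [GeneAnnotation("nd0", 1, 9, "+")]
    ref_row = SequenceRecord("outgroup", gappy)
    assert pm.classify_effect(asg, cmap, 5, "G", ann, ref_row) == "unresolved"


def test_derived_site_report_tabulates_all_clades():
    cfg, aln, tree, cmap, truth = _clade_fixture(seed=9)
    asg = pm.fitch(tree, aln)
    report = pm.derived_site_report(asg, cmap)
    n_derived = len(set().union(*[set(d) for d in truth.derived_columns.values()]))
    assert len(report) == n_derived
    assert {"column", "derived_I", "derived_II", "derived_III",
            "shared_I_II", "shared_II_III", "shared_I_III"} <= set(report.columns)
    assert report["shared_I_II"].sum() == 2


# ---------------------------------------------------------------------------
# nj_tree
# ---------------------------------------------------------------------------


def test_nj_three_sequences_unique_topology():
    aln = _aln(a="AAAA", b="AAAT", c="AATT")
    tree = pm.nj_tree(aln)
    assert {l.taxon.label for l in tree.leaf_node_iter()} == {"a", "b", "c"}


def test_nj_recovers_additive_four_taxon_topology():
    # (a,b) vs (c,d): a/b differ at 1 site, c/d at 1, across groups many
    aln = _aln(
        a="AAAAAAAAAACC",
        b="AAAAAAAAAAGG",
        c="TTTTTTTTTTCC",
        d="TTTTTTTTTTGG",
    )
    tree = pm.nj_tree(aln, outgroup="d")
    pdm = tree.phylogenetic_distance_matrix()
    tax = {t.label: t for t in tree.taxon_namespace}
    # a and b must be closer to each other than either is to c
    assert pdm.path_edge_count(tax["a"], tax["b"]) < pdm.path_edge_count(
        tax["a"], tax["c"]
    )


def test_nj_identical_sequences_deterministic():
    aln = _aln(a="AAAA", b="AAAA", c="AAAA", d="AAAA")
    t1 = pm.nj_tree(aln).as_string(schema="newick")
    t2 = pm.nj_tree(aln).as_string(schema="newick")
    assert t1 == t2


def test_nj_requires_three_sequences():
    with pytest.raises(UsageError):
        pm.nj_tree(_aln(a="AA", b="AA"))


def test_root_on_outgroup_places_outgroup_at_root():
    tree = pm.nj_tree(
        _aln(a="AAAACC", b="AAAAGG", c="TTTTCC", outgroup="TTTTGG"),
        outgroup="outgroup",
    )
    root_children = tree.seed_node.child_nodes()
    labels = {c.taxon.label for c in root_children if c.is_leaf()}
    assert "outgroup" in labels
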