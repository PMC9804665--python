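"""Dollo origins, origin labels and LCA reconciliation."""

import numpy as np
import pytest

from famtrace.ancestry import dollo_origin, lca_reconcile, origins_report
from famtrace.simulate import FamilySimConfig, simulate_family
from famtrace.trees import SpeciesTree, random_species_tree
from oracles import dollo_min_losses


def _pattern(tree, present, missing=()):
    return {
        sp: "present" if sp in present else ("missing" if sp in missing else "absent")
        for sp in tree.species
    }


def test_presence_everywhere_is_ancient(euk_tree):
    a = dollo_origin(_pattern(euk_tree, set(euk_tree.species)), euk_tree)
    assert a.gain == euk_tree.root_id
    assert a.label == "Ancient"
    assert a.n_losses == 0


def test_single_leaf_presence_gains_at_that_leaf(euk_tree):
    a = dollo_origin(_pattern(euk_tree, {"Scer"}), euk_tree)
    assert a.gain == "Scer"
    assert a.n_losses == 0


def test_all_absent_yields_no_origin(euk_tree):
    a = dollo_origin(_pattern(euk_tree, set()), euk_tree)
    assert a.gain is None
    assert a.label == "no origin"
    assert a.n_losses == 0


def test_lunapark_style_pattern_is_ancient_with_sar_losses(euk_tree):
    """Present across metazoa, plants, amoebozoa, rhodophyta, glaucophyta
    and a metamonad but absent from every stramenopile and alveolate:
    the gain maps to the root (an ancient family) and the losses cover
    exactly the stramenopile + alveolate clades."""
    present = {
        "Hsap", "Mmus", "Xtro", "Drer", "Scer", "Amac",  # opisthokonts
        "Ddis",  # amoebozoa
        "Atha", "Crei", "Cmer", "Cpar",  # archaeplastida + glaucophyte
        "Tvag",  # metamonada
    }
    a = dollo_origin(_pattern(euk_tree, present), euk_tree)
    assert a.gain == euk_tree.root_id
    assert a.label == "Ancient"
    lost_leaves = set().union(*a.loss_leaf_sets(euk_tree))
    assert {"Tpse", "Esil", "Tthe", "Pfal"} <= lost_leaves
    assert not lost_leaves & present


def test_metazoan_innovation_labelled_metazoa(euk_tree):
    """A family confined to the animal clade is labelled by that clade."""
    a = dollo_origin(_pattern(euk_tree, {"Hsap", "Mmus", "Xtro", "Drer"}), euk_tree)
    assert a.label == "Metazoa"
    assert not a.flagged
    assert a.n_losses == 0


def test_unlabeled_gain_falls_back_to_labeled_ancestor(euk_tree):
    # Hsap+Mmus alone gain at an unlabeled vertebrate-interior node
    a = dollo_origin(_pattern(euk_tree, {"Hsap", "Mmus"}), euk_tree)
    assert a.label == "Metazoa"
    assert a.flagged


def test_missing_leaves_are_uninformative(euk_tree):
    """A missing species inside an otherwise absent clade neither blocks
    nor creates a loss subtree."""
    present = {"Hsap", "Mmus", "Xtro", "Drer", "Atha"}
    a1 = dollo_origin(_pattern(euk_tree, present), euk_tree)
    a2 = dollo_origin(
        _pattern(euk_tree, present, missing={"Tpse", "Esil"}), euk_tree
    )
    assert a1.gain == a2.gain
    # the all-missing stramenopile clade cannot count as an extra loss
    assert a2.n_losses <= a1.n_losses


def test_random_patterns_match_exhaustive_minimum():
    """Gain and loss count equal the exhaustive single-gain optimum."""
    rng = np.random.default_rng(123)
    for trial in range(200):
        n = int(rng.integers(4, 13))
        tree = random_species_tree(n, seed=int(rng.integers(1 << 30)))
        states = rng.choice(
            ["present", "absent", "missing"], size=n, p=[0.45, 0.45, 0.10]
        )
        pattern = dict(zip(tree.species, states))
        present = [sp for sp, s in pattern.items() if s == "present"]
        absent = [sp for sp, s in pattern.items() if s == "absent"]
        if not present:
            continue
        a = dollo_origin(pattern, tree)
        best, optimal = dollo_min_losses(tree, present, absent)
        assert a.n_losses == best, (trial, pattern)
        assert a.gain in optimal


def test_origin_invariant_under_child_rotation():
    """Rotating children (ladderization) must not change the inference."""
    t1 = SpeciesTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
    t2 = SpeciesTree.from_newick("((D:1,C:1):1,(B:1,A:1):1);")
    pattern = {"A": "present", "B": "present", "C": "absent", "D": "absent"}
    a1 = dollo_origin(pattern, t1)
    a2 = dollo_origin(pattern, t2)
    assert t1.leaves_under(a1.gain) == t2.leaves_under(a2.gain)
    assert sorted(map(sorted, a1.loss_leaf_sets(t1))) == sorted(
        map(sorted, a2.loss_leaf_sets(t2))
    )


def test_adding_presence_never_moves_gain_tipward(euk_tree):
    pattern = _pattern(euk_tree, {"Hsap", "Drer"})
    base = dollo_origin(pattern, euk_tree)
    for sp in euk_tree.species:
        if pattern[sp] == "present":
            continue
        p2 = dict(pattern)
        p2[sp] = "present"
        wider = dollo_origin(p2, euk_tree)
        assert euk_tree.leaves_under(base.gain) <= euk_tree.leaves_under(wider.gain)


# ------------------------------------------------------------ reconciliation
def test_congruent_single_copy_tree_has_no_duplications(small_tree):
    cfg = FamilySimConfig(dup_rate=0.0, loss_rate=0.0)
    truth = simulate_family(small_tree, cfg, rng=np.random.default_rng(0))
    rec = lca_reconcile(truth.tree_newick(), small_tree)
    assert rec.n_duplications == 0
    assert set(rec.events.values()) == {"speciation"}


def test_vertebrate_style_duplication_maps_to_ancestor():
    """((h1,m1),(h2,m2)) over (Human,Mouse): one duplication in their
    common ancestor — the classic pre-speciation paralog topology."""
    st = SpeciesTree.from_newick("((Hsap:1,Mmus:1)Vertebrata:1,Scer:2);")
    rec = lca_reconcile(
        "((Hsap_r_g1:1,Mmus_r_g1:1):1,(Hsap_r_g2:1,Mmus_r_g2:1):1);", st
    )
    assert rec.duplication_branches == ("Vertebrata",)


def test_unknown_species_leaf_rejected(small_tree):
    with pytest.raises(ValueError, match="unknown species"):
        lca_reconcile("((S01_f_g1:1,WHAT_f_g1:1):1,S02_f_g1:2);", small_tree)


def test_simulated_duplications_recovered_without_loss(small_tree):
    """With mu = 0 the reconciled duplication branches equal the truth."""
    cfg = FamilySimConfig(dup_rate=0.3, loss_rate=0.0)
    for seed in range(25):
        truth = simulate_family(small_tree, cfg, rng=np.random.default_rng(seed))
        rec = lca_reconcile(truth.tree_newick(), small_tree)
        expected = tuple(sorted(ev.branch for ev in truth.duplications))
        assert rec.duplication_branches == expected


def test_origins_report_round_trip(euk_tree):
    from famtrace.matrix import PresenceMatrix
    import pandas as pd

    rows = []
    for sp in euk_tree.species:
        rows.append(
            {"family": "fam1", "species": sp, "status": "+", "n_candidates": 1}
        )
        rows.append(
            {"family": "fam2", "species": sp, "status": "-", "n_candidates": 0}
        )
    m = PresenceMatrix.assemble(pd.DataFrame(rows), euk_tree.taxonomy)
    report = origins_report(m, euk_tree)
    r1 = report[report.family == "fam1"].iloc[0]
    r2 = report[report.family == "fam2"].iloc[0]
    assert r1.label == "Ancient" and r1.n_losses == 0
    assert r2.label == "no origin" and r2.gain_node == ""
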