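"""Birth-death family simulation and sequence evolution vs analytic oracles."""

import math

import numpy as np
import pytest

from famtrace import simulate as sim
from famtrace.ancestry import lca_reconcile
from famtrace.simulate import (
    FamilySimConfig,
    build_proteome,
    evolve_sequences,
    p_distance,
    simulate_family,
    simulate_survey_dataset,
)


def test_rates_validated():
    with pytest.raises(ValueError):
        FamilySimConfig(dup_rate=float("inf"))
    with pytest.raises(ValueError):
        FamilySimConfig(loss_rate=-1.0)
    with pytest.raises(ValueError):
        FamilySimConfig(seq_length=0)


def test_no_events_gives_one_to_one_orthology(small_tree):
    """delta = mu = 0: every species has exactly one copy and the gene
    tree is congruent with the species tree (zero reconciled duplications)."""
    cfg = FamilySimConfig(dup_rate=0.0, loss_rate=0.0, seed=1)
    truth = simulate_family(small_tree, cfg)
    assert [truth.copy_number(sp) for sp in small_tree.species] == [1] * 8
    assert not truth.duplications and truth.n_losses == 0
    rec = lca_reconcile(truth.tree_newick(), small_tree)
    assert rec.n_duplications == 0


def test_high_loss_rate_extinguishes_species(small_tree):
    """With mu = 20 and root-to-tip depth 0.5, per-lineage survival is
    ~exp(-20 * 0.5) = 5e-5, so nearly every seed should lose at least one
    species entirely."""
    cfg = FamilySimConfig(dup_rate=0.0, loss_rate=20.0)
    with_empty = 0
    for seed in range(300):
        truth = simulate_family(
            small_tree, cfg, rng=np.random.default_rng(seed)
        )
        if any(truth.copy_number(sp) == 0 for sp in small_tree.species):
            with_empty += 1
    assert with_empty / 300 >= 0.99


def test_mean_copy_number_matches_birth_death_expectation(small_tree):
    """Mean leaf copy number ~ exp((delta - mu) * pathlength), within 3 SE."""
    delta, mu, n = 0.3, 0.1, 2000
    cfg = FamilySimConfig(dup_rate=delta, loss_rate=mu)
    totals = np.zeros(n)
    for seed in range(n):
        truth = simulate_family(
            small_tree, cfg, rng=np.random.default_rng(10_000 + seed)
        )
        totals[seed] = truth.n_surviving
    expected = sum(
        math.exp((delta - mu) * small_tree.depth(sp)) for sp in small_tree.species
    )
    se = totals.std(ddof=1) / math.sqrt(n)
    assert abs(totals.mean() - expected) < 3 * se


def test_ground_truth_matches_gene_tree_leaves(small_tree):
    """Copy-number conservation: per-species counts equal gene-tree leaves."""
    import dendropy

    cfg = FamilySimConfig(dup_rate=0.4, loss_rate=0.2)
    for seed in range(20):
        truth = simulate_family(
            small_tree, cfg, family="f", rng=np.random.default_rng(seed)
        )
        if truth.n_surviving == 0:
            continue
        gt = dendropy.Tree.get(
            data=truth.tree_newick(), schema="newick", preserve_underscores=True
        )
        leaves = sorted(l.taxon.label for l in gt.leaf_node_iter())
        expected = sorted(
            gid for gids in truth.genes_by_species.values() for gid in gids
        )
        assert leaves == expected


def test_zero_rate_sequences_identical(small_tree):
    cfg = FamilySimConfig(dup_rate=0.0, loss_rate=0.0, subs_rate=0.0, seq_length=80)
    truth = simulate_family(small_tree, cfg, rng=np.random.default_rng(0))
    seqs = evolve_sequences(truth, cfg, rng=np.random.default_rng(1))
    assert len(set(seqs.values())) == 1


def test_p_distance_matches_analytic_form():
    """Observed differences on a single branch match the closed form."""
    d, length, n_seeds = 0.1, 10_000, 200
    diffs = np.empty(n_seeds)
    for seed in range(n_seeds):
        rng = np.random.default_rng(seed)
        root = rng.choice(20, size=length, p=sim.BACKGROUND).astype(np.uint8)
        child = sim._evolve_branch(root, d, rng)
        diffs[seed] = (root != child).mean()
    se = diffs.std(ddof=1) / math.sqrt(n_seeds)
    assert abs(diffs.mean() - p_distance(d)) < 3 * se


def test_same_seed_reproduces_identical_fasta(small_tree, tmp_path):
    cfg = FamilySimConfig(dup_rate=0.2, loss_rate=0.2, background_size=30, seed=9)
    for run in ("a", "b"):
        ds = simulate_survey_dataset(small_tree, 2, cfg)
        out = tmp_path / run
        ds.write(out)
    files = sorted(p.name for p in (tmp_path / "a").iterdir())
    assert files == sorted(p.name for p in (tmp_path / "b").iterdir())
    for name in files:
        assert (tmp_path / "a" / name).read_bytes() == (
            tmp_path / "b" / name
        ).read_bytes()


def test_proteome_sizes_and_truth_subset(small_tree):
    cfg = FamilySimConfig(background_size=100, seed=2)
    rng = np.random.default_rng(0)
    prot = build_proteome({}, cfg, "S01", rng=rng)
    assert len(prot) == 100
    fam = {"S01_f_g1": "ACDEFGH", "S01_f_g2": "MKLVNP", "S01_f_g3": "WYWYWY"}
    prot2 = build_proteome(fam, cfg, "S01", rng=np.random.default_rng(1))
    assert len(prot2) == 103
    assert set(fam) <= set(prot2.ids)


def test_decoy_length_distribution():
    """Empirical decoy mean length within 3 SE of the log-normal mean."""
    cfg = FamilySimConfig(background_size=1000)
    rng = np.random.default_rng(4)
    decoys = sim.background_sequences(1000, cfg, rng, "x")
    lengths = np.array([len(s) for _, s in decoys], dtype=float)
    expected = math.exp(
        cfg.background_log_median + cfg.background_log_sigma**2 / 2
    )
    se = lengths.std(ddof=1) / math.sqrt(len(lengths))
    assert abs(lengths.mean() - expected) < 3 * se


def test_duplicate_ids_rejected():
    from famtrace.proteome import Proteome

    with pytest.raises(ValueError):
        Proteome("sp", [("a", "ACD"), ("a", "EFG")])


def test_dataset_queries_point_at_real_members(tiny_dataset):
    tree, ds = tiny_dataset
    for fam, q in ds.queries.items():
        assert q.gene_id in ds.truths[fam].genes_by_species[q.species]
        assert ds.proteomes[q.species].sequence(q.gene_id) == q.sequence
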