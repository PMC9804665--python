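"""The classification cascade: reverse validation, architecture screen,
strategy escalation and truth recovery."""

import numpy as np
import pandas as pd
import pytest

from famtrace.align import AMINO_ACIDS, AlignmentParams, BACKGROUND
from famtrace.proteome import Proteome
from famtrace.simulate import (
    FamilyQuery,
    FamilySimConfig,
    _evolve_branch,
    background_sequences,
)
from famtrace.survey import (
    MissingProteomeError,
    OrthologCall,
    Survey,
    SurveyConfig,
    check_architecture,
    reverse_validate,
    score_against_truth,
)
from famtrace.trees import SpeciesTree

PARAMS = AlignmentParams()
AA = np.array(list(AMINO_ACIDS))


def _random_seq(rng, n):
    return "".join(AA[rng.choice(20, size=n, p=BACKGROUND)])


# --------------------------------------------------------------- config/type
def test_config_validation():
    with pytest.raises(ValueError):
        SurveyConfig(reverse_rank_window=0)
    with pytest.raises(ValueError):
        SurveyConfig(length_ratio_window=(1.2, 2.0))
    with pytest.raises(ValueError):
        SurveyConfig(strategies=("forward_reverse", "bogus"))


def test_call_invariants():
    with pytest.raises(ValueError):
        OrthologCall("f", "s", "absence", candidates=("x",))
    with pytest.raises(ValueError):
        OrthologCall("f", "s", "presence", candidates=())
    with pytest.raises(ValueError):
        OrthologCall("f", "s", "paralog", candidates=("x",), method="forward_reverse")
    call = OrthologCall("f", "s", "absence")
    assert call.symbol == "-"


# ---------------------------------------------------------- reverse validate
def _rank_fixture(n_paralogs):
    """A query proteome where a crafted candidate sees ``n_paralogs``
    same-family sequences above the query in its reverse ranking."""
    rng = np.random.default_rng(17)
    query = _random_seq(rng, 150)
    paralog = _random_seq(rng, 100)
    records = [("Q", query)]
    records += [(f"D{i}", paralog) for i in range(1, n_paralogs + 1)]
    records += background_sequences(40, FamilySimConfig(), rng, "bg")
    proteome = Proteome("qsp", records)
    # candidate: full paralog followed by a verbatim 60-residue query block,
    # so paralogs outscore the query in the reverse search
    candidate = paralog + query[:60]
    members = {"Q"} | {f"D{i}" for i in range(1, n_paralogs + 1)}
    return candidate, proteome, members


def test_reverse_rank_window_is_inclusive():
    """Query at reverse rank 5 with k=5 accepts (top-five is inclusive)."""
    candidate, proteome, members = _rank_fixture(4)
    verdict, rank, _ = reverse_validate(
        candidate, proteome, "Q", set(), members, SurveyConfig(), PARAMS
    )
    assert verdict == "accept"
    assert rank == 5


def test_rank_six_with_family_best_hit_is_paralog():
    candidate, proteome, members = _rank_fixture(5)
    verdict, rank, best = reverse_validate(
        candidate, proteome, "Q", set(), members, SurveyConfig(), PARAMS
    )
    assert verdict == "paralog"
    assert best in members - {"Q"}


def test_rank_six_without_registry_is_reject():
    candidate, proteome, _ = _rank_fixture(5)
    verdict, _, _ = reverse_validate(
        candidate, proteome, "Q", set(), set(), SurveyConfig(), PARAMS
    )
    assert verdict == "reject"


def test_decoy_candidate_rejected():
    rng = np.random.default_rng(23)
    proteome = Proteome(
        "qsp",
        [("Q", _random_seq(rng, 150))]
        + background_sequences(40, FamilySimConfig(), rng, "bg"),
    )
    verdict, rank, _ = reverse_validate(
        _random_seq(rng, 120), proteome, "Q", set(), {"Q"}, SurveyConfig(), PARAMS
    )
    assert verdict == "reject"
    assert rank is None


# ------------------------------------------------------------- architecture
def test_architecture_identical_passes():
    ok, ratio = check_architecture("ACDEFGHIKL", "ACDEFGHIKL", SurveyConfig())
    assert ok and ratio == 1.0


def test_architecture_length_window():
    cfg = SurveyConfig(length_ratio_window=(0.5, 2.0))
    query = "A" * 100
    assert not check_architecture("A" * 10, query, cfg)[0]  # 10% of query
    assert check_architecture("A" * 180, query, cfg)[0]  # ratio 1.8: inside
    assert not check_architecture("A" * 250, query, cfg)[0]  # ratio 2.5: outside


# ------------------------------------------------------------------ cascade
def test_tiny_survey_recovers_truth(tiny_dataset):
    tree, ds = tiny_dataset
    runner = Survey(tree, ds.proteomes, ds.queries, SurveyConfig())
    calls = runner.run()
    assert len(calls) == 4 * 12
    metrics = score_against_truth(calls, ds)
    assert metrics["precision"] >= 0.95
    assert metrics["recall"] >= 0.90
    # the query species cell is found by the primary strategy and lists
    # the true gene
    for fam, q in ds.queries.items():
        row = calls[(calls.family == fam) & (calls.species == q.species)].iloc[0]
        assert row.status == "+"
        assert row.method == "forward_reverse"
        assert q.gene_id in row.candidates.split(";")


def test_rerun_is_deterministic(tiny_dataset):
    tree, ds = tiny_dataset
    cfg = SurveyConfig()
    a = Survey(tree, ds.proteomes, ds.queries, cfg).run()
    b = Survey(tree, ds.proteomes, ds.queries, cfg).run()
    pd.testing.assert_frame_equal(a, b)


def test_missing_proteome_is_distinct_from_absence(tiny_dataset):
    tree, ds = tiny_dataset
    proteomes = dict(ds.proteomes)
    dropped = [sp for sp in tree.species if sp != ds.queries["fam01"].species][0]
    del proteomes[dropped]
    runner = Survey(tree, proteomes, ds.queries, SurveyConfig())
    with pytest.raises(MissingProteomeError):
        runner.classify("fam01", dropped)
    calls = runner.run()
    cells = calls[calls.species == dropped]
    assert set(cells.status) == {"."}


def test_neighbor_query_rescues_distant_ortholog():
    """Staged divergence: the primary query cannot reach species C but the
    accepted ortholog from intermediate species B can."""
    rng = np.random.default_rng(1)
    tree = SpeciesTree.from_newick("(A:1.0,(B:0.45,C:0.55):0.5);")
    cfg = FamilySimConfig()
    seq_a = rng.choice(20, size=200, p=BACKGROUND).astype(np.uint8)
    seq_b = _evolve_branch(seq_a, 0.95, rng)
    seq_c = _evolve_branch(seq_b, 1.0, rng)
    prots = {}
    for sp, enc in (("A", seq_a), ("B", seq_b), ("C", seq_c)):
        prots[sp] = Proteome(
            sp,
            [(f"{sp}_fam_g1", "".join(AA[enc]))]
            + background_sequences(60, cfg, rng, sp),
        )
    from famtrace.search import search

    assert not any(
        h.target_id == "C_fam_g1"
        for h in search("".join(AA[seq_a]), prots["C"], PARAMS)
    ), "fixture must defeat the direct search"
    q = FamilyQuery("fam", "A", "A_fam_g1", "".join(AA[seq_a]))
    calls = Survey(tree, prots, {"fam": q}, SurveyConfig(seed=0)).run()
    row_c = calls[calls.species == "C"].iloc[0]
    assert row_c.status == "+"
    assert row_c.method == "neighbor_query"
    assert row_c.candidates == "C_fam_g1"


def test_decoy_only_species_rarely_called_present():
    """False-presence guard: a species containing only background decoys
    must essentially never be called presence (rate <= 1%)."""
    tree = SpeciesTree.from_newick("(Q:0.3,D:0.3);")
    cfg = FamilySimConfig(background_size=60)
    false_presence = 0
    n_seeds = 200
    for seed in range(n_seeds):
        rng = np.random.default_rng(seed)
        q_enc = rng.choice(20, size=200, p=BACKGROUND).astype(np.uint8)
        paralog = _evolve_branch(q_enc, 0.3, rng)
        prot_q = Proteome(
            "Q",
            [("Q_fam_g1", "".join(AA[q_enc])), ("Q_fam_g2", "".join(AA[paralog]))]
            + background_sequences(60, cfg, rng, "Q"),
        )
        prot_d = Proteome("D", background_sequences(100, cfg, rng, "D"))
        q = FamilyQuery("fam", "Q", "Q_fam_g1", "".join(AA[q_enc]))
        calls = Survey(
            tree, {"Q": prot_q, "D": prot_d}, {"fam": q}, SurveyConfig(seed=0)
        ).run()
        if calls[calls.species == "D"].iloc[0].status in ("+", "p"):
            false_presence += 1
    assert false_presence / n_seeds <= 0.01
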