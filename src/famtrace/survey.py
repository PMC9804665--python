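"""The reciprocal-search classification cascade.

For every (family, species) pair the survey produces a three-state call:

* ``presence`` — at least one candidate passed the full acceptance rule:
  a forward hit at or below the E-value cutoff whose reverse search
  against the original query proteome recovers the query (or a previously
  accepted ortholog) within the top-``k`` significant hits, and whose
  length/architecture is conserved;
* ``paralog`` — forward evidence exists but the best reverse hit is a
  different registered member of the family and the query is outside the
  top-``k`` window;
* ``absence`` — every strategy failed ("not found").

Three strategies run in order until one yields an accepted candidate:
(1) the family's primary query, (2) a neighbour query — the accepted
ortholog from the prior-positive species closest to the target in the
species tree, and (3) a PSSM over all recovered members.  Species are
visited in order of increasing tree distance from the query species so
the accepted-ortholog registry grows outward from the query.

A species whose proteome is not on disk raises
:class:`MissingProteomeError` in ``classify`` and is recorded as a
distinct ``missing`` state by ``survey`` — never silently as absence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .align import AlignmentParams
from .profile import Profile, build_profile, profile_core_hit, profile_search
from .proteome import Proteome
from .search import search
from .simulate import FamilyQuery
from .trees import SpeciesTree

PRESENCE = "presence"
PARALOG = "paralog"
ABSENCE = "absence"
MISSING = "missing"
STATUS_SYMBOL = {PRESENCE: "+", PARALOG: "p", ABSENCE: "-", MISSING: "."}

STRATEGY_FORWARD = "forward_reverse"
STRATEGY_NEIGHBOR = "neighbor_query"
STRATEGY_PROFILE = "profile"
ALL_STRATEGIES = (STRATEGY_FORWARD, STRATEGY_NEIGHBOR, STRATEGY_PROFILE)


class MissingProteomeError(KeyError):
    """A species was requested whose proteome is not available."""


@dataclass(frozen=True)
class SurveyConfig:
    """Thresholds and strategy order of the cascade.

    ``reverse_rank_window`` is inclusive ("within the top five hits"):
    rank 5 with the default window accepts.  Ranks are counted among
    reverse hits passing the reverse cutoff, with the search module's
    deterministic ordering.  The length-ratio window is the protein-length
    conservation screen; candidates within ``review_margin`` (fractional)
    of any threshold are flagged for review in the evidence log.
    """

    forward_cutoff: float = 0.05
    reverse_cutoff: float = 0.05
    reverse_rank_window: int = 5
    length_ratio_window: tuple[float, float] = (0.5, 2.0)
    profile_cutoff: float = 0.05
    strategies: tuple[str, ...] = ALL_STRATEGIES
    max_candidates: int = 10
    min_query_coverage: float = 0.4
    review_margin: float = 0.10
    profile_null_samples: int = 200
    seed: int = 0

    def __post_init__(self):
        if self.reverse_rank_window < 1:
            raise ValueError("reverse rank window must be >= 1")
        for c in (self.forward_cutoff, self.reverse_cutoff, self.profile_cutoff):
            if not c > 0:
                raise ValueError("E-value cutoffs must be > 0")
        lo, hi = self.length_ratio_window
        if not (0 < lo <= 1 <= hi):
            raise ValueError("length window must satisfy 0 < lo <= 1 <= hi")
        unknown = set(self.strategies) - set(ALL_STRATEGIES)
        if unknown:
            raise ValueError(f"unknown strategies: {sorted(unknown)}")


@dataclass
class OrthologCall:
    """The cascade's verdict for one (family, species) cell."""

    family: str
    species: str
    status: str
    candidates: tuple[str, ...] = ()
    method: str = "none"
    forward_evalue: float | None = None
    reverse_rank: int | None = None
    length_ratio: float | None = None
    review: bool = False
    note: str = ""

    def __post_init__(self):
        if self.status in (ABSENCE, MISSING):
            if self.candidates or self.method != "none":
                raise ValueError(f"{self.status} call must carry no candidates")
        elif not self.candidates:
            raise ValueError(f"{self.status} call needs at least one candidate")
        if self.status == PARALOG and self.reverse_rank is None:
            raise ValueError("paralog status requires reverse evidence")

    @property
    def symbol(self) -> str:
        return STATUS_SYMBOL[self.status]


def reverse_validate(
    candidate_seq: str,
    query_proteome: Proteome,
    query_id: str,
    accepted_ids: frozenset[str] | set[str],
    family_member_ids: frozenset[str] | set[str],
    cfg: SurveyConfig,
    params: AlignmentParams,
    reverse_hits=None,
) -> tuple[str, int | None, str | None]:
    """Reverse-search acceptance rule.

    Returns ``(verdict, rank, best_id)`` with verdict in
    ``{"accept", "paralog", "reject"}``.  Accept when the original query
    or any accepted ortholog id appears at rank <= k among reverse hits
    passing the reverse cutoff; paralog when the best reverse hit is a
    different registered family member and the query is absent from the
    top-k window; reject otherwise (including an empty reverse hit list).
    """
    if reverse_hits is None:
        rparams = replace(params, evalue_cutoff=cfg.reverse_cutoff)
        reverse_hits = search(candidate_seq, query_proteome, rparams, query_id="reverse")
    if not reverse_hits:
        return "reject", None, None
    best_id = reverse_hits[0].target_id
    ok_ids = {query_id} | set(accepted_ids)
    for rank, hit in enumerate(reverse_hits[: cfg.reverse_rank_window], start=1):
        if hit.target_id in ok_ids:
            return "accept", rank, best_id
    if best_id in family_member_ids and best_id not in ok_ids:
        return PARALOG, 1, best_id
    return "reject", None, best_id


def check_architecture(
    candidate_seq: str,
    query_seq: str,
    cfg: SurveyConfig,
    profile: Profile | None = None,
) -> tuple[bool, float]:
    """Protein-length (and, when a profile exists, domain-core) screen.

    Returns ``(ok, length_ratio)``.  The ratio must fall inside the
    configured window; when a family profile is supplied its core must
    additionally align within the candidate above the profile cutoff —
    the stand-in for a domain-architecture comparison.
    """
    if len(query_seq) == 0:
        return False, float("inf")
    ratio = len(candidate_seq) / len(query_seq)
    lo, hi = cfg.length_ratio_window
    if not (lo <= ratio <= hi):
        return False, ratio
    if profile is not None and not profile_core_hit(
        profile, candidate_seq, cfg.profile_cutoff
    ):
        return False, ratio
    return True, ratio


@dataclass
class _FamilyState:
    query: FamilyQuery
    member_ids: frozenset[str] = frozenset()
    accepted: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    accepted_ids: set[str] = field(default_factory=set)
    profile: Profile | None = None
    profile_n: int = 0
    reverse_cache: dict[str, list] = field(default_factory=dict)
    reverse_db: Proteome | None = None
    reverse_db_n: int = -1


class Survey:
    """Stateful driver applying the cascade across families and species."""

    def __init__(
        self,
        tree: SpeciesTree,
        proteomes: dict[str, Proteome],
        queries: dict[str, FamilyQuery],
        cfg: SurveyConfig | None = None,
        params: AlignmentParams | None = None,
    ):
        self.tree = tree
        self.proteomes = proteomes
        self.queries = queries
        self.cfg = cfg or SurveyConfig()
        self.params = params or AlignmentParams(evalue_cutoff=self.cfg.forward_cutoff)
        self._fwd_params = replace(self.params, evalue_cutoff=self.cfg.forward_cutoff)
        self._state: dict[str, _FamilyState] = {}
        self._rng = np.random.default_rng(self.cfg.seed)
        self.log: list[dict] = []

    # ------------------------------------------------------------ internals
    def _family_state(self, family: str) -> _FamilyState:
        st = self._state.get(family)
        if st is not None:
            return st
        q = self.queries[family]
        if q.species not in self.proteomes:
            raise MissingProteomeError(q.species)
        qprot = self.proteomes[q.species]
        # deterministic family-member registry: query-proteome self-hits
        self_hits = search(q.sequence, qprot, self._fwd_params, query_id=q.gene_id)
        members = frozenset(h.target_id for h in self_hits) | {q.gene_id}
        st = _FamilyState(query=q, member_ids=members)
        self._state[family] = st
        return st

    def _family_profile(self, st: _FamilyState) -> Profile | None:
        seqs = {st.query.gene_id: st.query.sequence}
        for pairs in st.accepted.values():
            for gid, seq in pairs:
                seqs.setdefault(gid, seq)
        if len(seqs) < 2:
            return None
        # rebuild only on substantial growth: center-star construction is
        # quadratic in the member count
        if st.profile is None or len(seqs) >= int(st.profile_n * 1.5) + 1:
            st.profile = build_profile(seqs, self.params)
            st.profile.calibrate(
                np.random.default_rng(self.cfg.seed + 1),
                n_null=self.cfg.profile_null_samples,
            )
            st.profile_n = len(seqs)
        return st.profile

    def _nearest_positive_species(self, st: _FamilyState, species: str) -> str | None:
        best = None
        for sp in st.accepted:
            if sp == species or not st.accepted[sp]:
                continue
            d = self.tree.path_distance(sp, species)
            key = (d, sp)
            if best is None or key < best[0]:
                best = (key, sp)
        return best[1] if best else None

    def _reverse_database(self, st: _FamilyState) -> Proteome:
        """Query proteome plus the accepted-ortholog registry.

        The registry stands in for the 'annotated orthologs from other
        species' a curated reverse search would recognise: a candidate
        whose best reverse hits are previously accepted orthologs (rather
        than the original query itself) still validates.
        """
        if st.reverse_db is None or st.reverse_db_n != len(st.accepted_ids):
            base = self.proteomes[st.query.species]
            records = [(rid, base.sequence(rid)) for rid in base]
            seen = set(base.ids)
            for pairs in st.accepted.values():
                for gid, seq in pairs:
                    if gid not in seen:
                        records.append((gid, seq))
                        seen.add(gid)
            st.reverse_db = Proteome(st.query.species, records)
            st.reverse_db_n = len(st.accepted_ids)
            st.reverse_cache.clear()
        return st.reverse_db

    def _reverse(self, st: _FamilyState, candidate_id: str, candidate_seq: str):
        db = self._reverse_database(st)
        hits = st.reverse_cache.get(candidate_id)
        if hits is None:
            rparams = replace(self.params, evalue_cutoff=self.cfg.reverse_cutoff)
            hits = search(candidate_seq, db, rparams, query_id=candidate_id)
            st.reverse_cache[candidate_id] = hits
        return hits

    def _is_review(self, evalue, rank, ratio) -> bool:
        m = self.cfg.review_margin
        lo, hi = self.cfg.length_ratio_window
        if evalue is not None and evalue > (1 - m) * self.cfg.forward_cutoff:
            return True
        if rank is not None and rank == self.cfg.reverse_rank_window:
            return True
        if ratio is not None and (ratio < lo * (1 + m) or ratio > hi * (1 - m)):
            return True
        return False

    # ------------------------------------------------------------- cascade
    def classify(self, family: str, species: str) -> OrthologCall:
        """Apply the strategy cascade to one (family, species) cell."""
        if species not in self.proteomes:
            raise MissingProteomeError(species)
        st = self._family_state(family)
        prot = self.proteomes[species]
        cfg = self.cfg
        paralog_evidence: tuple[str, str, int, float] | None = None
        trail: list[dict] = []

        for strategy in cfg.strategies:
            if strategy == STRATEGY_FORWARD:
                fwd_query_id = st.query.gene_id
                fwd_query_seq = st.query.sequence
                hits = search(fwd_query_seq, prot, self._fwd_params, fwd_query_id)
                ref_seq = st.query.sequence
            elif strategy == STRATEGY_NEIGHBOR:
                neighbor = self._nearest_positive_species(st, species)
                if neighbor is None:
                    trail.append({"strategy": strategy, "skipped": "no prior positive"})
                    continue
                ngid, nseq = st.accepted[neighbor][0]
                hits = search(nseq, prot, self._fwd_params, ngid)
                ref_seq = nseq
            else:  # profile
                profile = self._family_profile(st)
                if profile is None:
                    trail.append({"strategy": strategy, "skipped": "fewer than 2 members"})
                    continue
                hits = profile_search(profile, prot, cfg.profile_cutoff)
                ref_seq = None

            accepted: list[tuple] = []
            arch_profile = self._family_profile(st)
            for h in hits[: cfg.max_candidates]:
                # "similarity throughout the protein length": a genuine
                # homolog aligns most of the query; chance HSPs are short
                if h.pct_query_aligned < 100.0 * cfg.min_query_coverage:
                    trail.append(
                        {
                            "strategy": strategy,
                            "candidate": h.target_id,
                            "rejected": "low query coverage",
                            "pct_query_aligned": round(h.pct_query_aligned, 1),
                        }
                    )
                    continue
                cand_seq = prot.sequence(h.target_id)
                rhits = self._reverse(st, h.target_id, cand_seq)
                verdict, rank, best_id = reverse_validate(
                    cand_seq,
                    self.proteomes[st.query.species],
                    st.query.gene_id,
                    st.accepted_ids,
                    st.member_ids,
                    cfg,
                    self.params,
                    reverse_hits=rhits,
                )
                if verdict == PARALOG and paralog_evidence is None:
                    paralog_evidence = (strategy, h.target_id, rank, h.evalue)
                if verdict != "accept":
                    continue
                if ref_seq is not None:
                    ok, ratio = check_architecture(cand_seq, ref_seq, cfg, arch_profile)
                else:
                    # profile strategy: length screen against the family median
                    median = arch_profile.median_source_length if arch_profile else None
                    ratio = len(cand_seq) / median if median else 1.0
                    lo, hi = cfg.length_ratio_window
                    ok = lo <= ratio <= hi
                if not ok:
                    trail.append(
                        {
                            "strategy": strategy,
                            "candidate": h.target_id,
                            "rejected": "architecture",
                            "length_ratio": round(ratio, 3),
                        }
                    )
                    continue
                accepted.append((h, rank, ratio))
            trail.append(
                {
                    "strategy": strategy,
                    "n_hits": len(hits),
                    "n_accepted": len(accepted),
                }
            )
            if accepted:
                ids = tuple(h.target_id for h, _, _ in accepted)
                best_hit, best_rank, best_ratio = accepted[0]
                for gid in ids:
                    if gid not in st.accepted_ids:
                        st.accepted.setdefault(species, []).append(
                            (gid, prot.sequence(gid))
                        )
                        st.accepted_ids.add(gid)
                call = OrthologCall(
                    family,
                    species,
                    PRESENCE,
                    ids,
                    strategy,
                    forward_evalue=best_hit.evalue,
                    reverse_rank=best_rank,
                    length_ratio=best_ratio,
                    review=self._is_review(best_hit.evalue, best_rank, best_ratio),
                )
                self.log.append(
                    {"family": family, "species": species, "trail": trail, "call": call.status}
                )
                return call

        if paralog_evidence is not None:
            strategy, cand_id, rank, ev = paralog_evidence
            call = OrthologCall(
                family,
                species,
                PARALOG,
                (cand_id,),
                strategy,
                forward_evalue=ev,
                reverse_rank=rank,
                review=True,
            )
        else:
            call = OrthologCall(family, species, ABSENCE)
        self.log.append(
            {"family": family, "species": species, "trail": trail, "call": call.status}
        )
        return call

    # --------------------------------------------------------------- driver
    def species_order(self, family: str) -> list[str]:
        """Species sorted by tree distance from the family's query species."""
        q = self.queries[family]
        return sorted(
            self.tree.species,
            key=lambda sp: (self.tree.path_distance(q.species, sp), sp),
        )

    def run(self, families=None) -> pd.DataFrame:
        """Classify every (family, species) pair; errors become 'missing'."""
        if families is None:
            families = sorted(self.queries)
        rows = []
        for fam in families:
            for sp in self.species_order(fam):
                try:
                    call = self.classify(fam, sp)
                except MissingProteomeError:
                    call = OrthologCall(fam, sp, MISSING, note="no proteome")
                rows.append(
                    {
                        "family": fam,
                        "species": sp,
                        "status": call.symbol,
                        "n_candidates": len(call.candidates),
                        "candidates": ";".join(call.candidates),
                        "method": call.method,
                        "forward_evalue": call.forward_evalue,
                        "reverse_rank": call.reverse_rank,
                        "length_ratio": call.length_ratio,
                        "review": call.review,
                    }
                )
        df = pd.DataFrame(rows)
        return df.sort_values(["family", "species"], kind="stable").reset_index(drop=True)


def survey(
    tree: SpeciesTree,
    proteomes: dict[str, Proteome],
    queries: dict[str, FamilyQuery],
    cfg: SurveyConfig | None = None,
    params: AlignmentParams | None = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """One-shot convenience wrapper around :class:`Survey`."""
    s = Survey(tree, proteomes, queries, cfg, params)
    calls = s.run()
    return calls, s.log


def score_against_truth(calls: pd.DataFrame, dataset) -> dict[str, float]:
    """Presence/absence precision and recall against simulation truth.

    Presence predictions are '+' and 'p' cells; truth presence is >= 1
    surviving copy.  'missing' cells are excluded from scoring.
    """
    tp = fp = fn = tn = 0
    for row in calls.itertuples():
        if row.status == ".":
            continue
        pred = row.status in ("+", "p")
        truth = dataset.truth_presence(row.family, row.species)
        if pred and truth:
            tp += 1
        elif pred and not truth:
            fp += 1
        elif truth:
            fn += 1
        else:
            tn += 1
    precision = tp / (tp + fp) if tp + fp else 1.0
    recall = tp / (tp + fn) if tp + fn else 1.0
    return {
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "tn": tn,
        "precision": precision,
        "recall": recall,
    }
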