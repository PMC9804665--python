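"""Query-vs-proteome database search with E-value filtering.

``search`` scans every target in a proteome with the Smith-Waterman
kernel, converts raw scores into E-values (analytic Karlin-Altschul by
default, seeded shuffle-rank when ``params.calibration == 'empirical'``),
keeps hits at or below the cutoff and orders them by ascending E-value
with deterministic tie-breaking (descending bit score, then target id).
An empty result list is a valid outcome and is what the survey cascade
interprets as "no candidate".
"""

from __future__ import annotations

import numpy as np

from .align import (
    AlignmentParams,
    SearchHit,
    _scan,
    _traceback,
    analytic_evalue,
    empirical_evalue,
    encode,
    profile_from_sequence,
    raw_to_bits,
    shuffled_decoy_scores,
)
from .proteome import Proteome


def search(
    query: str,
    proteome: Proteome,
    params: AlignmentParams | None = None,
    query_id: str = "query",
    rng: np.random.Generator | None = None,
) -> list[SearchHit]:
    """All hits of ``query`` against ``proteome`` with E <= the cutoff.

    In empirical calibration mode each target's E-value is the rank of the
    score among ``params.n_shuffles`` shuffles of that target (seeded via
    ``rng``), scaled by the number of targets searched.
    """
    params = params or AlignmentParams()
    if len(proteome) == 0:
        raise ValueError("cannot search an empty proteome")
    if len(query) == 0:
        return []
    if params.calibration == "empirical" and rng is None:
        rng = np.random.default_rng(0)
    qe = encode(query)
    prof = profile_from_sequence(qe, params)
    gap_first = np.float32(params.gap_open + params.gap_extend)
    gap_ext = np.float32(params.gap_extend)
    m = len(query)
    n = proteome.residue_count
    hits: list[SearchHit] = []
    for tid in proteome:
        te = proteome.encoded(tid)
        if te.shape[0] == 0:
            continue
        raw, _, _ = _scan(prof, te, gap_first, gap_ext)
        raw = float(raw)
        if params.calibration == "empirical":
            decoys = shuffled_decoy_scores(qe, te, params, params.n_shuffles, rng)
            evalue = empirical_evalue(raw, decoys, len(proteome))
        else:
            evalue = analytic_evalue(raw, m, n, params)
        if evalue <= params.evalue_cutoff:
            _, qs, qend, ts, tend, _, _, _ = _traceback(prof, te, gap_first, gap_ext)
            hits.append(
                SearchHit(
                    query_id,
                    tid,
                    raw,
                    raw_to_bits(raw, params),
                    evalue,
                    (int(qs), int(qend)),
                    (int(ts), int(tend)),
                    100.0 * (qend - qs) / m,
                )
            )
    hits.sort(key=lambda h: (h.evalue, -h.bit_score, h.target_id))
    return hits


def write_hits_tsv(hits: list[SearchHit], path) -> None:
    from .align import HIT_TSV_HEADER

    with open(path, "w") as fh:
        fh.write(HIT_TSV_HEADER + "\n")
        for h in hits:
            fh.write(h.tsv_row() + "\n")
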