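"""Position-specific scoring matrices built from a recovered-member set.

When single-query searches fail, the survey escalates to a set-level
search: all members of a family recovered so far are condensed into a
PSSM and the PSSM is slid over each target proteome with the same affine
gap costs as the pairwise search.  The profile is deliberately simple and
fully specifiable:

* the *center* sequence (the member with the highest summed pairwise
  alignment score to the others) defines the columns;
* every other member is locally aligned to the center and contributes its
  residues at the aligned (match-state) columns only — an ungapped core;
* column counts get +1 Laplace pseudocounts and become log-odds against
  the Robinson-Robinson background, scaled to half-bits so that the
  BLOSUM62 gap penalties (11/1) remain commensurate.

Profile scores have their own null distribution, so each profile carries
its own Karlin-Altschul pair estimated by a seeded Gumbel fit against
random background sequences.
"""

from __future__ import annotations

import numpy as np

from .align import (
    AlignmentParams,
    BACKGROUND,
    SearchHit,
    _scan,
    _traceback,
    encode,
    profile_from_sequence,
)


class Profile:
    """A PSSM over an ungapped center-star core of a sequence set."""

    def __init__(
        self,
        matrix: np.ndarray,
        source_ids: tuple[str, ...],
        center_id: str,
        source_lengths: tuple[int, ...],
        params: AlignmentParams,
    ):
        if matrix.shape[0] < 1:
            raise ValueError("profile needs at least one column")
        if not np.all(np.isfinite(matrix)):
            raise ValueError("profile scores must be finite")
        self.matrix = np.ascontiguousarray(matrix, dtype=np.float32)
        self.source_ids = source_ids
        self.center_id = center_id
        self.source_lengths = source_lengths
        self.params = params
        self.lambda_: float | None = None
        self.k: float | None = None

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def median_source_length(self) -> float:
        return float(np.median(self.source_lengths))

    def calibrate(
        self, rng: np.random.Generator, n_null: int = 200, null_length: int | None = None
    ) -> tuple[float, float]:
        """Fit the profile's own (lambda, K) on random background targets."""
        from scipy.stats import gumbel_r

        if null_length is None:
            null_length = max(50, int(round(self.median_source_length)))
        gap_first = np.float32(self.params.gap_open + self.params.gap_extend)
        gap_ext = np.float32(self.params.gap_extend)
        scores = np.empty(n_null)
        for i in range(n_null):
            t = rng.choice(20, size=null_length, p=BACKGROUND).astype(np.uint8)
            scores[i], _, _ = _scan(self.matrix, t, gap_first, gap_ext)
        loc, scale = gumbel_r.fit(scores)
        scale = max(scale, 1e-6)
        self.lambda_ = 1.0 / scale
        self.k = float(np.exp(loc / scale) / (len(self) * null_length))
        return self.lambda_, self.k


def build_profile(
    seqs: dict[str, str], params: AlignmentParams | None = None
) -> Profile:
    """Condense >= 2 sequences into a center-star PSSM.

    The center is the sequence with the maximum summed pairwise local
    alignment raw score against the rest (ties broken by id).  Counts at
    each center column include the center's own residue plus the residues
    other members align to that column.
    """
    params = params or AlignmentParams()
    if len(seqs) < 2:
        raise ValueError("a profile needs at least 2 source sequences")
    ids = sorted(seqs)
    enc = {i: encode(seqs[i]) for i in ids}
    gap_first = np.float32(params.gap_open + params.gap_extend)
    gap_ext = np.float32(params.gap_extend)
    totals: dict[str, float] = {}
    for i in ids:
        prof_i = profile_from_sequence(enc[i], params)
        tot = 0.0
        for j in ids:
            if i == j:
                continue
            s, _, _ = _scan(prof_i, enc[j], gap_first, gap_ext)
            tot += float(s)
        totals[i] = tot
    center = max(ids, key=lambda i: (totals[i], i))
    center_enc = enc[center]
    m = len(center_enc)
    counts = np.zeros((m, 20), dtype=np.float64)
    for col, a in enumerate(center_enc):
        if a < 20:
            counts[col, a] += 1
    prof_center = profile_from_sequence(center_enc, params)
    for j in ids:
        if j == center:
            continue
        _, _, _, _, _, npairs, qidx, tidx = _traceback(
            prof_center, enc[j], gap_first, gap_ext
        )
        other = enc[j]
        for p in range(npairs):
            a = other[tidx[p]]
            if a < 20:
                counts[qidx[p], a] += 1
    n_col = counts.sum(axis=1)
    freqs = (counts + 1.0) / (n_col + 20.0)[:, None]
    scores = 2.0 * np.log2(freqs / BACKGROUND[None, :])
    matrix = np.zeros((m, 21), dtype=np.float32)
    matrix[:, :20] = scores
    return Profile(
        matrix,
        tuple(ids),
        center,
        tuple(len(seqs[i]) for i in ids),
        params,
    )


def profile_search(
    profile: Profile,
    proteome,
    cutoff: float = 0.05,
    rng: np.random.Generator | None = None,
    n_null: int = 200,
) -> list[SearchHit]:
    """Rank proteome targets against a profile; keep hits with E <= cutoff.

    Ordering matches the pairwise search contract: ascending E-value, ties
    by descending bit score then lexicographic target id.
    """
    if profile.lambda_ is None:
        if rng is None:
            rng = np.random.default_rng(0)
        profile.calibrate(rng, n_null=n_null)
    lam, k = profile.lambda_, profile.k
    m = len(profile)
    n = proteome.residue_count
    gap_first = np.float32(profile.params.gap_open + profile.params.gap_extend)
    gap_ext = np.float32(profile.params.gap_extend)
    hits: list[SearchHit] = []
    for tid in proteome:
        te = proteome.encoded(tid)
        if te.shape[0] == 0:
            continue
        raw, _, _ = _scan(profile.matrix, te, gap_first, gap_ext)
        raw = float(raw)
        evalue = float(k * m * n * np.exp(-lam * raw))
        if evalue <= cutoff:
            raw2, qs, qe, ts, tend, _, _, _ = _traceback(
                profile.matrix, te, gap_first, gap_ext
            )
            bit = (lam * raw - np.log(k)) / np.log(2.0)
            hits.append(
                SearchHit(
                    f"profile:{profile.center_id}",
                    tid,
                    raw,
                    float(bit),
                    evalue,
                    (int(qs), int(qe)),
                    (int(ts), int(tend)),
                    100.0 * (qe - qs) / m,
                )
            )
    hits.sort(key=lambda h: (h.evalue, -h.bit_score, h.target_id))
    return hits


def profile_core_hit(
    profile: Profile,
    seq: str,
    cutoff: float = 0.05,
    rng: np.random.Generator | None = None,
) -> bool:
    """Does the profile core align within ``seq`` above the cutoff?

    Used as the domain-architecture proxy in the acceptance screen.
    """
    if profile.lambda_ is None:
        if rng is None:
            rng = np.random.default_rng(0)
        profile.calibrate(rng)
    te = encode(seq)
    if te.shape[0] == 0:
        return False
    gap_first = np.float32(profile.params.gap_open + profile.params.gap_extend)
    gap_ext = np.float32(profile.params.gap_extend)
    raw, _, _ = _scan(profile.matrix, te, gap_first, gap_ext)
    evalue = profile.k * len(profile) * te.shape[0] * np.exp(-profile.lambda_ * float(raw))
    return bool(evalue <= cutoff)
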