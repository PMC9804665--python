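"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package's implementations:
local alignment is scored by exhaustive enumeration of aligned-column
chains, and Dollo origins by exhaustive enumeration of single-gain
scenarios.
"""

from itertools import combinations


def brute_force_local_score(a, b, matrix, gap_open, gap_extend):
    """Exhaustive optimal local alignment score with affine gaps.

    A local alignment is fully determined by its chain of aligned column
    pairs (i1,j1) < ... < (ik,jk), strictly increasing in both
    coordinates.  Between consecutive columns the skipped residues of
    each sequence form one gap run charged ``gap_open + len *
    gap_extend`` (interleaving gap runs costs extra opens and can never
    win).  Enumerating all chains over sequences of length <= 8 is
    sum_k C(m,k) * C(n,k) <= C(m+n, m) = 12870 cases.

    ``matrix`` is indexable as matrix[ai][bj] over encoded residues.
    """
    m, n = len(a), len(b)
    best = 0.0
    for k in range(1, min(m, n) + 1):
        for iset in combinations(range(m), k):
            for jset in combinations(range(n), k):
                score = 0.0
                for t in range(k):
                    score += matrix[a[iset[t]]][b[jset[t]]]
                    if t:
                        di = iset[t] - iset[t - 1] - 1
                        dj = jset[t] - jset[t - 1] - 1
                        if di:
                            score -= gap_open + di * gap_extend
                        if dj:
                            score -= gap_open + dj * gap_extend
                if score > best:
                    best = score
    return best


def dollo_min_losses(tree, present, observed_absent):
    """Exhaustive single-gain minimum loss count.

    For every candidate gain node covering all presence leaves, count the
    maximal presence-free subtrees below it that contain at least one
    observed-absent leaf; return (min_losses, set of optimal gain nodes).
    ``tree`` is a famtrace SpeciesTree; ``present`` / ``observed_absent``
    are leaf-id collections.
    """
    present = set(present)
    observed_absent = set(observed_absent)

    def losses_below(gain):
        total = 0
        stack = list(tree.children(gain))
        while stack:
            node = stack.pop()
            leaves = tree.leaves_under(node)
            if leaves & present:
                stack.extend(tree.children(node))
            elif leaves & observed_absent:
                total += 1
        return total

    best = None
    optimal = set()
    for node in tree.preorder_ids():
        if not present <= tree.leaves_under(node):
            continue
        cost = losses_below(node)
        if best is None or cost < best:
            best = cost
            optimal = {node}
        elif cost == best:
            optimal.add(node)
    return best, optimal
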