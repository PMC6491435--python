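"""Independent reference implementations used only to check the package.

These deliberately avoid the code paths they validate: the matcher oracle
is a dense all-offset Hamming scan, and the bootstrap oracle is exhaustive
multinomial enumeration.
"""

from itertools import product

import numpy as np
from scipy import stats

from seqmate.matcher import Hit, revcomp


def brute_force_hits(read, targets, read_id="read", max_mm=1, strands="both"):
    """Every (target, offset, strand) within Hamming distance max_mm, by scan."""
    L = len(read)
    queries = [(read, "+")]
    if strands == "both":
        queries.append((revcomp(read), "-"))
    out = []
    for q, st in queries:
        qa = np.frombuffer(q.encode(), dtype=np.uint8)
        for tid, seq in targets.items():
            if len(seq) < L:
                continue
            ta = np.frombuffer(seq.encode(), dtype=np.uint8)
            win = np.lib.stride_tricks.sliding_window_view(ta, L)
            d = (win != qa).sum(axis=1)
            for off in np.flatnonzero(d <= max_mm):
                out.append(Hit(read_id, tid, int(off), st, int(d[off])))
    return sorted(set(out), key=lambda h: (h.target_id, h.offset, h.strand))


def enumerate_bootstrap_p_psi00(pairs, T):
    """Exact two-tail p for PSI[0,0] vs 1 under multinomial pair resampling.

    Enumerates every outcome of T pairs over the 2x2 cells with the observed
    frequencies; outcomes on which PSI[0,0] is undefined are dropped (the
    bootstrap discards them), and the remaining mass renormalized.
    """
    pairs = np.asarray(pairs, dtype=float)
    probs = (pairs / pairs.sum()).ravel()
    lo = hi = defined = 0.0
    for n00, n01, n10 in product(range(T + 1), repeat=3):
        n11 = T - n00 - n01 - n10
        if n11 < 0:
            continue
        n = np.array([n00, n01, n10, n11])
        pr = stats.multinomial.pmf(n, T, probs)
        if pr == 0:
            continue
        row0, col0 = n00 + n01, n00 + n10
        if row0 == 0 or col0 == 0:
            continue  # undefined resample
        psi = n00 * T / (row0 * col0)
        defined += pr
        if psi <= 1:
            lo += pr
        if psi >= 1:
            hi += pr
    return min(1.0, 2.0 * min(lo / defined, hi / defined))
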