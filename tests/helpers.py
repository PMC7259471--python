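"""Independent oracles used by the test suite.

These deliberately re-derive results by brute force or exhaustive
enumeration, sharing no code with the implementation they check.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import stats

BASES = "ACGT"


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, n))


def sw_softclip_oracle(read: str, ref: str, params) -> float:
    """Plain-Python affine-gap DP with per-base read-end clip costs.

    Same objective as the production aligner (alignment starts/ends on an
    aligned base pair, reference ends free, clipped read bases cost the
    flat clip penalty), written independently without traceback.
    """
    L, R = len(read), len(ref)
    NEG = float("-inf")
    H = [[NEG] * (R + 1) for _ in range(L + 1)]
    E = [[NEG] * (R + 1) for _ in range(L + 1)]
    F = [[NEG] * (R + 1) for _ in range(L + 1)]
    go, ge = params.gap_open, params.gap_extend
    clip = params.softclip_penalty_per_base
    best = NEG
    for i in range(1, L + 1):
        a = read[i - 1]
        for j in range(1, R + 1):
            b = ref[j - 1]
            E[i][j] = max(H[i][j - 1] + go + ge, E[i][j - 1] + ge)
            F[i][j] = max(H[i - 1][j] + go + ge, F[i - 1][j] + ge)
            s = params.match if (a == b and a in "ACGT") else params.mismatch
            H[i][j] = s + max(H[i - 1][j - 1], E[i - 1][j - 1],
                              F[i - 1][j - 1], clip * (i - 1))
            best = max(best, H[i][j] + clip * (L - i))
    return best


def wilcoxon_exact_enum(left, right) -> float:
    """Two-sided signed-rank p-value by enumerating all sign assignments."""
    d = np.asarray(right, dtype=float) - np.asarray(left, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n_le = n_ge = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        n_le += w <= w_obs + 1e-9
        n_ge += w >= w_obs - 1e-9
    total = 2 ** n
    return min(1.0, 2.0 * min(n_le / total, n_ge / total))


def is_two_colorable(genes, edges) -> bool:
    """Exhaustive 2-colorability check over all colorings (|genes| <= ~14)."""
    genes = sorted(genes)
    idx = {g: i for i, g in enumerate(genes)}
    for bits in range(2 ** len(genes)):
        if all((bits >> idx[a]) & 1 != (bits >> idx[b]) & 1 for a, b in edges):
            return True
    return False
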