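"""Independent brute-force oracles for the hybridization dynamic program.

The enumeration below generates every antiparallel non-crossing pairing of
two short sequences and scores each with the explicit-structure evaluator;
its minimum is the reference MFE.  It shares no code with the DP beyond the
evaluator that *defines* the energy model.
"""

from typing import List, Optional, Tuple

import mirsponge as ms
from mirsponge.thermo import PAIR_INDEX


def enumerate_pairings(t: str, q: str, wobble: bool = True) -> List[List[Tuple[int, int]]]:
    """All non-empty antiparallel non-crossing pairings with allowed pairs only."""
    n, m = len(t), len(q)
    allowed = set()
    for i in range(n):
        for j in range(m):
            p = t[i] + q[j]
            if p in PAIR_INDEX and (wobble or p not in ("GU", "UG")):
                allowed.add((i, j))
    out: List[List[Tuple[int, int]]] = []

    def rec(path, i0, j0):
        for i in range(i0, n):
            for j in range(j0, -1, -1):
                if (i, j) in allowed:
                    path.append((i, j))
                    out.append(list(path))
                    rec(path, i + 1, j - 1)
                    path.pop()

    rec([], 0, m - 1)
    return out


def brute_force_mfe(
    t: str,
    q: str,
    params,
    wobble: bool = True,
) -> Tuple[Optional[float], Optional[List[Tuple[int, int]]]]:
    """Reference MFE by exhaustive enumeration (None when nothing binds, dG < 0)."""
    best, bestp = None, None
    ts, qs = ms.rna(t), ms.rna(q)
    for pairing in enumerate_pairings(t, q, wobble):
        energy = ms.duplex_energy_of_pairing(ts, qs, pairing, params, wobble=wobble)
        if best is None or energy < best:
            best, bestp = energy, pairing
    if best is None or best >= 0:
        return None, None
    return best, bestp
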