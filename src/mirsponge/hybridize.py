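"""Intermolecular miRNA/sponge hybridization by dynamic programming.

The duplex model is pure hybridization: no intramolecular pairs in either
molecule, bounded bulge and internal loops, free (zero-cost) unpaired
overhangs on both ends of both molecules.  The DP finds the minimum
free-energy duplex between a miRNA-sized query and any region of the target
under :mod:`mirsponge.thermo`; multiple non-overlapping sites are extracted
greedily by masking each accepted site's target interval and rescanning the
flanking segments.

Energies are integer centi-kcal/mol inside the kernel, so the DP agrees
exactly (not merely within float tolerance) with the explicit-structure
evaluator ``duplex_energy_of_pairing``.  The kernel is JIT-compiled with
numba; the first call in a fresh process pays a one-off compilation cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from numba import njit

from .sequences import MiRNARecord, NucleotideSequence, ValidationError
from .thermo import (
    PAIR_INDEX,
    EnergyParameters,
    StructureError,
    default_parameters,
    duplex_energy_of_pairing,
)

__all__ = [
    "ScanLimits",
    "DuplexSite",
    "hybridize_mfe",
    "scan_sites",
    "render_site_diagram",
    "MAX_QUERY_LENGTH",
]

#: miRNA-sized queries only; the DP is quadratic in query length.
MAX_QUERY_LENGTH = 35

_BIG = 1 << 40


@dataclass(frozen=True)
class ScanLimits:
    """Loop-size caps and wobble toggle for the hybridization scan."""

    max_bulge_loop: int = 15
    max_internal_loop: int = 15
    wobble: bool = True

    def __post_init__(self) -> None:
        if self.max_bulge_loop < 0 or self.max_internal_loop < 0:
            raise ValidationError("loop caps must be >= 0")


@dataclass(frozen=True)
class DuplexSite:
    """One miRNA/sponge binding site.

    ``target_interval`` is 0-based half-open on the sponge; ``pairing`` lists
    (target_index, query_index) pairs with target indices increasing and
    query indices decreasing (antiparallel).  ``energy`` always equals
    ``duplex_energy_of_pairing`` recomputed on ``pairing``.
    """

    target_interval: Tuple[int, int]
    pairing: Tuple[Tuple[int, int], ...]
    energy: float
    mirna_name: str = ""
    diagram: str = ""


@njit(cache=True)
def _dp_kernel(P, st, bulge, internal, ends, ninio_c, ninio_m, maxb, maxi):
    n, m = P.shape
    BIG = np.int64(1) << 40
    B = np.full((n, m), BIG, dtype=np.int64)
    maxl = maxb if maxb > maxi else maxi
    best_i = -1
    best_j = -1
    best_e = BIG
    for i in range(n):
        for j in range(m):
            p = P[i, j]
            if p < 0:
                continue
            rev = p ^ 1
            best = ends[p]
            for lt in range(maxl + 1):
                ip = i - 1 - lt
                if ip < 0:
                    break
                for lq in range(maxl + 1):
                    jp = j + 1 + lq
                    if jp >= m:
                        break
                    pp = P[ip, jp]
                    if pp < 0:
                        continue
                    prev = B[ip, jp]
                    if prev >= BIG:
                        continue
                    if lt == 0 and lq == 0:
                        cost = st[pp, rev]
                    elif lt == 0 or lq == 0:
                        size = lt + lq
                        if size > maxb:
                            continue
                        cost = bulge[size]
                        if size == 1:
                            cost += st[pp, rev]
                    else:
                        if lt > maxi or lq > maxi:
                            continue
                        a = lt - lq if lt > lq else lq - lt
                        nin = ninio_c * a
                        if nin > ninio_m:
                            nin = ninio_m
                        cost = internal[lt + lq] + nin
                    cand = prev + cost
                    if cand < best:
                        best = cand
            B[i, j] = best
            tot = best + ends[p]
            if tot < best_e:
                best_e = tot
                best_i = i
                best_j = j
    return B, best_e, best_i, best_j


def _pair_matrix(t: str, q: str, wobble: bool) -> np.ndarray:
    P = np.full((len(t), len(q)), -1, dtype=np.int8)
    for i, a in enumerate(t):
        for j, b in enumerate(q):
            idx = PAIR_INDEX.get(a + b)
            if idx is None:
                continue
            if not wobble and idx in (2, 3):  # GU / UG
                continue
            P[i, j] = idx
    return P


def _traceback(P, B, st, bulge, internal, ends, ninio_c, ninio_m, maxb, maxi, i, j):
    """Reproduce the kernel's decisions backwards from the optimal end cell.

    The kernel keeps the first strict improvement it sees, scanning loops
    smallest-first (stack, then bulges/interior loops by size); the traceback
    re-runs the identical scan, so ties resolve to the same densest pairing.
    """
    maxl = max(maxb, maxi)
    path = [(i, j)]
    m = P.shape[1]
    while True:
        p = P[i, j]
        target = B[i, j]
        if target == ends[p]:
            found = None
        else:
            found = None
            for lt in range(maxl + 1):
                ip = i - 1 - lt
                if ip < 0:
                    break
                for lq in range(maxl + 1):
                    jp = j + 1 + lq
                    if jp >= m:
                        break
                    pp = P[ip, jp]
                    if pp < 0 or B[ip, jp] >= _BIG:
                        continue
                    rev = p ^ 1
                    if lt == 0 and lq == 0:
                        cost = st[pp, rev]
                    elif lt == 0 or lq == 0:
                        size = lt + lq
                        if size > maxb:
                            continue
                        cost = bulge[size]
                        if size == 1:
                            cost += st[pp, rev]
                    else:
                        if lt > maxi or lq > maxi:
                            continue
                        cost = internal[lt + lq] + min(
                            ninio_m, ninio_c * abs(lt - lq)
                        )
                    if B[ip, jp] + cost == target:
                        found = (ip, jp)
                        break
                if found:
                    break
            if found is None:  # pragma: no cover - kernel/traceback mismatch guard
                raise StructureError("traceback failed to reproduce the DP score")
        if found is None:
            break
        i, j = found
        path.append((i, j))
    path.reverse()
    return path


def hybridize_mfe(
    target: NucleotideSequence,
    query: Union[NucleotideSequence, MiRNARecord],
    params: Optional[EnergyParameters] = None,
    limits: Optional[ScanLimits] = None,
) -> Optional[DuplexSite]:
    """Minimum free-energy duplex between ``query`` and any region of ``target``.

    Returns ``None`` when no allowed pair exists or the best duplex is not
    stabilising (dG >= 0).  Unpaired flanks of both molecules are free.
    """
    params = params or default_parameters()
    limits = limits or ScanLimits()
    name = ""
    if isinstance(query, MiRNARecord):
        name = query.name
        query = query.sequence
    t = target.as_rna()
    q = query.as_rna()
    if len(q) > MAX_QUERY_LENGTH:
        raise ValidationError(
            f"query length {len(q)} exceeds the miRNA-sized limit {MAX_QUERY_LENGTH}"
        )
    st, bulge, internal, ends, nc, nm, init = params.int_tables(
        limits.max_bulge_loop, limits.max_internal_loop
    )
    P = _pair_matrix(t.residues, q.residues, limits.wobble)
    if not (P >= 0).any():
        return None
    B, best_e, bi, bj = _dp_kernel(
        P, st, bulge, internal, ends, nc, nm,
        limits.max_bulge_loop, limits.max_internal_loop,
    )
    total = int(best_e) + init
    if best_e >= _BIG or total >= 0:
        return None
    pairing = _traceback(
        P, B, st, bulge, internal, ends, nc, nm,
        limits.max_bulge_loop, limits.max_internal_loop, int(bi), int(bj),
    )
    pairing = tuple((int(a), int(b)) for a, b in pairing)
    site = DuplexSite(
        target_interval=(pairing[0][0], pairing[-1][0] + 1),
        pairing=pairing,
        energy=total / 100.0,
        mirna_name=name,
    )
    return DuplexSite(
        target_interval=site.target_interval,
        pairing=site.pairing,
        energy=site.energy,
        mirna_name=name,
        diagram=render_site_diagram(site, t, q),
    )


def _shift(site: DuplexSite, offset: int, target: NucleotideSequence,
           query: NucleotideSequence, name: str = "") -> DuplexSite:
    pairing = tuple((ti + offset, qi) for ti, qi in site.pairing)
    shifted = DuplexSite(
        target_interval=(site.target_interval[0] + offset,
                         site.target_interval[1] + offset),
        pairing=pairing,
        energy=site.energy,
        mirna_name=name or site.mirna_name,
    )
    return DuplexSite(
        target_interval=shifted.target_interval,
        pairing=shifted.pairing,
        energy=shifted.energy,
        mirna_name=shifted.mirna_name,
        diagram=render_site_diagram(shifted, target, query),
    )


def scan_sites(
    target: NucleotideSequence,
    query: Union[NucleotideSequence, MiRNARecord],
    cutoff: float = -25.0,
    params: Optional[EnergyParameters] = None,
    limits: Optional[ScanLimits] = None,
) -> List[DuplexSite]:
    """All non-overlapping sites with dG <= ``cutoff``, greedy best-first.

    The global MFE site is accepted if it meets the cut-off, its target
    interval is masked, and the two flanking segments are rescanned until no
    remaining site passes.  Results are sorted by target position.
    """
    if cutoff >= 0:
        raise ValidationError("cutoff must be negative (dG scale, kcal/mol)")
    params = params or default_parameters()
    limits = limits or ScanLimits()
    t = target.as_rna()
    if isinstance(query, MiRNARecord):
        qname, qseq = query.name, query.sequence
    else:
        qname, qseq = "", query.as_rna()
    if len(t) < 6:
        return []
    segments: List[Tuple[int, int]] = [(0, len(t))]
    memo = {}
    accepted: List[DuplexSite] = []
    while True:
        best = None
        for seg in segments:
            if seg not in memo:
                lo, hi = seg
                sub = NucleotideSequence(t.residues[lo:hi], t.alphabet)
                memo[seg] = hybridize_mfe(sub, qseq, params, limits)
            site = memo[seg]
            if site is None:
                continue
            if best is None or site.energy < best[1].energy:
                best = (seg, site)
        if best is None:
            break
        seg, site = best
        if site.energy > cutoff + 1e-9:
            break
        accepted.append(_shift(site, seg[0], t, qseq, qname))
        lo, hi = seg
        segments.remove(seg)
        del memo[seg]
        left = (lo, lo + site.target_interval[0])
        right = (lo + site.target_interval[1], hi)
        for piece in (left, right):
            if piece[1] - piece[0] >= 1:
                segments.append(piece)
    accepted.sort(key=lambda s: s.target_interval)
    return accepted


def render_site_diagram(
    site: DuplexSite,
    target: NucleotideSequence,
    query: NucleotideSequence,
) -> str:
    """Four-line RNAhybrid-style alignment block for one site.

    Line 1: unpaired target bases (loops); line 2: paired target bases;
    line 3: paired query bases; line 4: unpaired query bases (loops and the
    free 5'/3' miRNA overhangs).  The target reads 5'->3' left to right, the
    query 3'->5'.  The header reports the target interval 1-based inclusive
    and dG to 0.1 kcal/mol.
    """
    t = target.as_rna().residues
    q = query.as_rna().residues
    cols: List[Tuple[str, str, str, str]] = []
    first_q = site.pairing[0][1]
    last_q = site.pairing[-1][1]
    for qi in range(len(q) - 1, first_q, -1):  # free miRNA 3' overhang
        cols.append((" ", " ", " ", q[qi]))
    prev = None
    for ti, qi in site.pairing:
        if prev is not None:
            pt, pq = prev
            gap_t = [t[x] for x in range(pt + 1, ti)]
            gap_q = [q[x] for x in range(pq - 1, qi, -1)]
            for r in range(max(len(gap_t), len(gap_q))):
                cols.append((
                    gap_t[r] if r < len(gap_t) else " ",
                    " ",
                    " ",
                    gap_q[r] if r < len(gap_q) else " ",
                ))
        cols.append((" ", t[ti], q[qi], " "))
        prev = (ti, qi)
    for qi in range(last_q - 1, -1, -1):  # free miRNA 5' overhang
        cols.append((" ", " ", " ", q[qi]))
    start, end = site.target_interval
    name = f" {site.mirna_name}" if site.mirna_name else ""
    header = (
        f"target {start + 1}-{end} (1-based){name}  "
        f"dG = {site.energy:.1f} kcal/mol"
    )
    lines = ["".join(col[k] for col in cols).rstrip() for k in range(4)]
    return "\n".join([
        header,
        "target 5' " + lines[0],
        "          " + lines[1],
        "          " + lines[2],
        "miRNA  3' " + lines[3],
    ])
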