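"""Nearest-neighbour free-energy model for intermolecular RNA-RNA duplexes.

The model is the classic Turner/Mathews decomposition at 37 degC: a duplex is
a ladder of allowed base pairs (Watson-Crick plus the G-U wobble); its free
energy is a duplex-initiation term, a sum of stacked-dinucleotide terms for
adjacent pairs, bulge/internal-loop initiation penalties (with a Ninio
asymmetry term) for gaps between adjacent pairs, and a terminal penalty for
AU/GU pairs closing either helix end.  Single-nucleotide bulges retain the
stack of their flanking pairs, as in the Turner rules.

Two bundled profiles share one parameter table:

``turner2004``
    Absolute duplex dG: initiation 4.09 kcal/mol, terminal AU/GU 0.45.
``turner2004-screen`` (default)
    The sponge-screening convention of RNAhybrid-style tools, which report
    pure hybridization energies: both end terms are zero.  This is the
    convention under which published sponge screening energies are stated.

Energies are handled internally in integer centi-kcal/mol (exactly as read
from the two-decimal table) so that the dynamic program in
:mod:`mirsponge.hybridize` and the explicit-structure evaluator below agree
bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np

from .sequences import Alphabet, NucleotideSequence

__all__ = [
    "PAIR_ORDER",
    "EnergyParameters",
    "ParameterError",
    "StructureError",
    "load_parameters",
    "default_parameters",
    "pair_allowed",
    "duplex_energy_of_pairing",
]

#: All allowed pairs, ordered so that index^1 is the reversed pair.
PAIR_ORDER = ("CG", "GC", "GU", "UG", "AU", "UA")
PAIR_INDEX = {p: i for i, p in enumerate(PAIR_ORDER)}
_WC = frozenset(("AU", "UA", "GC", "CG"))
_WOBBLE = frozenset(("GU", "UG"))

_BIG = 1 << 40  # effectively +infinity, safe to add without overflow


class ParameterError(ValueError):
    """The parameter table is incomplete or malformed."""


class StructureError(ValueError):
    """An explicit pairing is not a valid antiparallel duplex structure."""


def pair_allowed(a: str, b: str, wobble: bool = True) -> bool:
    """True iff ``a``-``b`` is Watson-Crick, or G-U when ``wobble`` is set."""
    p = (a + b).upper()
    if p in _WC:
        return True
    return wobble and p in _WOBBLE


def _rotate(key: str) -> str:
    top, bot = key.split("/")
    return bot[::-1] + "/" + top[::-1]


@dataclass(frozen=True)
class EnergyParameters:
    """A complete dG37 parameter set for the duplex model.

    ``stack_table`` is keyed by ``"XY/ZW"`` = 5'XY3' over 3'ZW5' (X pairs Z,
    Y pairs W) and must contain every combination of allowed pairs (36 keys);
    180-degree rotational symmetry is enforced at load time.  Loop penalties
    are tabulated for bulges of 1-30 nt and internal loops of total size
    2-30 nt; larger loops use the Jacobson-Stockmayer extrapolation
    ``dG(n) = dG(30) + lxc * ln(n / 30)``.
    """

    stack_table: dict
    bulge_penalty: dict
    internal_penalty: dict
    helix_init: float
    au_end_penalty: float
    ninio_coeff: float
    ninio_max: float
    lxc: float
    temperature: float = 37.0
    name: str = "custom"

    # -- float-facing accessors ------------------------------------------------

    def stack(self, top: str, bottom: str) -> float:
        """Stack dG37 for 5'``top``3' over 3'``bottom``5' (kcal/mol)."""
        key = f"{top.upper()}/{bottom.upper()}"
        try:
            return self.stack_table[key]
        except KeyError:
            raise ParameterError(f"no stack entry for {key}") from None

    def bulge_dg(self, size: int) -> float:
        if size < 1:
            raise ParameterError("bulge size must be >= 1")
        if size in self.bulge_penalty:
            return self.bulge_penalty[size]
        return self._cint(self.bulge_penalty[30], size) / 100.0

    def internal_dg(self, n1: int, n2: int) -> float:
        """Internal-loop penalty incl. the Ninio asymmetry term."""
        if n1 < 1 or n2 < 1:
            raise ParameterError("internal loop requires >= 1 unpaired nt per side")
        total = n1 + n2
        if total in self.internal_penalty:
            init = self.internal_penalty[total]
        else:
            init = self._cint(self.internal_penalty[30], total) / 100.0
        return init + min(self.ninio_max, self.ninio_coeff * abs(n1 - n2))

    def end_penalty(self, pair: str) -> float:
        """Terminal penalty for the pair closing a helix end."""
        return self.au_end_penalty if pair.upper() not in ("GC", "CG") else 0.0

    def _cint(self, base30: float, n: int) -> int:
        # centi-kcal Jacobson-Stockmayer extrapolation beyond the table
        return round(base30 * 100) + round(100 * self.lxc * math.log(n / 30.0))

    # -- integer tables for the dynamic program --------------------------------

    def int_tables(self, max_bulge: int, max_internal: int):
        """Integer (centi-kcal) arrays: stack 6x6, bulge, internal-init, ends.

        Cached per (max_bulge, max_internal) since the tables are immutable.
        """
        cache = getattr(self, "_int_cache", None)
        if cache is None:
            cache = {}
            object.__setattr__(self, "_int_cache", cache)
        key = (max_bulge, max_internal)
        if key in cache:
            return cache[key]
        st = np.zeros((6, 6), dtype=np.int64)
        for i, p1 in enumerate(PAIR_ORDER):
            for j, p2 in enumerate(PAIR_ORDER):
                key = p1[0] + p2[1] + "/" + p1[1] + p2[0]
                st[i, j] = round(self.stack_table[key] * 100)
        nb = max(max_bulge, 1)
        bulge = np.full(nb + 1, _BIG, dtype=np.int64)
        for n in range(1, nb + 1):
            bulge[n] = round(self.bulge_dg(n) * 100)
        ni = max(2 * max_internal, 2)
        internal = np.full(ni + 1, _BIG, dtype=np.int64)
        for n in range(2, ni + 1):
            if n in self.internal_penalty:
                internal[n] = round(self.internal_penalty[n] * 100)
            else:
                internal[n] = self._cint(self.internal_penalty[30], n)
        ends = np.zeros(6, dtype=np.int64)
        for i, p in enumerate(PAIR_ORDER):
            ends[i] = round(self.end_penalty(p) * 100)
        cache[key] = (
            st,
            bulge,
            internal,
            ends,
            round(self.ninio_coeff * 100),
            round(self.ninio_max * 100),
            round(self.helix_init * 100),
        )
        return cache[key]

    # -- serialisation ---------------------------------------------------------

    def dump(self, path) -> None:
        """Write the table in the bundled plain-text format (load/dump stable)."""
        lines = ["[STACKS]"]
        for k in sorted(self.stack_table):
            lines.append(f"{k}  {self.stack_table[k]:6.2f}")
        lines.append("")
        lines.append("[BULGE]")
        for n in sorted(self.bulge_penalty):
            lines.append(f"{n:2d}  {self.bulge_penalty[n]:5.2f}")
        lines.append("")
        lines.append("[INTERNAL]")
        for n in sorted(self.internal_penalty):
            lines.append(f"{n:2d}  {self.internal_penalty[n]:5.2f}")
        lines.append("")
        lines.append("[MISC]")
        lines.append(f"helix_init      {self.helix_init:.2f}")
        lines.append(f"au_end_penalty  {self.au_end_penalty:.2f}")
        lines.append(f"ninio_coeff     {self.ninio_coeff:.2f}")
        lines.append(f"ninio_max       {self.ninio_max:.2f}")
        lines.append(f"lxc             {self.lxc:.5f}")
        lines.append("")
        Path(path).write_text("\n".join(lines))


def _parse_table(text: str, name: str) -> EnergyParameters:
    stacks: dict = {}
    bulge: dict = {}
    internal: dict = {}
    misc: dict = {}
    section = None
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            section = line[1:-1].upper()
            continue
        toks = line.split()
        if section == "STACKS":
            if len(toks) != 2 or "/" not in toks[0]:
                raise ParameterError(f"{name}:{lineno}: malformed stack line {raw!r}")
            stacks[toks[0].upper()] = float(toks[1])
        elif section == "BULGE":
            bulge[int(toks[0])] = float(toks[1])
        elif section == "INTERNAL":
            internal[int(toks[0])] = float(toks[1])
        elif section == "MISC":
            misc[toks[0].lower()] = float(toks[1])
        else:
            raise ParameterError(f"{name}:{lineno}: data outside any section")

    missing = []
    for p1 in PAIR_ORDER:
        for p2 in PAIR_ORDER:
            key = p1[0] + p2[1] + "/" + p1[1] + p2[0]
            if key not in stacks:
                missing.append(key)
    if missing:
        raise ParameterError(
            f"{name}: missing stack {', '.join(sorted(set(missing)))}"
        )
    for key, val in stacks.items():
        if abs(stacks.get(_rotate(key), val) - val) > 1e-9:
            raise ParameterError(f"{name}: stack {key} breaks 180-degree symmetry")
        top, bot = key.split("/")
        if {top[0] + bot[0], top[1] + bot[1]} <= _WC and val > 0:
            raise ParameterError(f"{name}: Watson-Crick stack {key} must be <= 0")
    for n in range(1, 31):
        if n not in bulge:
            raise ParameterError(f"{name}: missing bulge penalty for size {n}")
        if bulge[n] < 0:
            raise ParameterError(f"{name}: bulge penalty for size {n} is negative")
    for n in range(2, 31):
        if n not in internal:
            raise ParameterError(f"{name}: missing internal penalty for size {n}")
        if internal[n] < 0:
            raise ParameterError(f"{name}: internal penalty for size {n} is negative")
    for key in ("helix_init", "au_end_penalty", "ninio_coeff", "ninio_max", "lxc"):
        if key not in misc:
            raise ParameterError(f"{name}: missing MISC entry {key}")
    return EnergyParameters(
        stack_table=stacks,
        bulge_penalty=bulge,
        internal_penalty=internal,
        helix_init=misc["helix_init"],
        au_end_penalty=misc["au_end_penalty"],
        ninio_coeff=misc["ninio_coeff"],
        ninio_max=misc["ninio_max"],
        lxc=misc["lxc"],
        name=name,
    )


def _bundled_text() -> str:
    return (
        resources.files("mirsponge").joinpath("data/turner2004_dg37.nn").read_text()
    )


def load_parameters(source: str = "turner2004-screen") -> EnergyParameters:
    """Load a named bundled profile or a parameter table from a file path.

    ``turner2004-screen`` (default) is the screening convention: the Turner
    2004 tables with zero duplex-initiation and terminal-AU terms.
    ``turner2004`` keeps the published 4.09 / 0.45 kcal/mol end terms for
    absolute duplex free energies.
    """
    if source in ("turner2004", "default-full"):
        return _parse_table(_bundled_text(), "turner2004")
    if source in ("turner2004-screen", "default", "screen"):
        params = _parse_table(_bundled_text(), "turner2004-screen")
        return replace(params, helix_init=0.0, au_end_penalty=0.0)
    path = Path(source)
    if not path.exists():
        raise ParameterError(f"unknown parameter source {source!r}")
    return _parse_table(path.read_text(), str(path))


_DEFAULT: Optional[EnergyParameters] = None


def default_parameters() -> EnergyParameters:
    """The cached default (screening-profile) parameter set."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = load_parameters()
    return _DEFAULT


def _step_centi(
    params_int,
    prev_pair_idx: int,
    cur_rev_idx: int,
    lt: int,
    lq: int,
) -> int:
    """Centi-kcal cost of extending from one pair to the next.

    ``lt``/``lq`` are the unpaired gap sizes on target and query.  Shared by
    the explicit-structure evaluator and the DP so the two cannot drift.
    """
    st, bulge, internal, _ends, ninio_c, ninio_m, _init = params_int
    if lt == 0 and lq == 0:
        return int(st[prev_pair_idx, cur_rev_idx])
    if lt == 0 or lq == 0:
        size = lt + lq
        if size >= len(bulge):
            return _BIG
        cost = int(bulge[size])
        if size == 1:
            cost += int(st[prev_pair_idx, cur_rev_idx])
        return cost
    total = lt + lq
    if total >= len(internal):
        return _BIG
    return int(internal[total]) + min(ninio_m, ninio_c * abs(lt - lq))


def duplex_energy_of_pairing(
    target: NucleotideSequence,
    query: NucleotideSequence,
    pairing: Sequence[Tuple[int, int]],
    params: Optional[EnergyParameters] = None,
    wobble: bool = True,
) -> float:
    """Free energy (kcal/mol) of an explicit antiparallel duplex structure.

    ``pairing`` lists (target_index, query_index) pairs, 0-based, with target
    indices strictly increasing and query indices strictly decreasing
    (antiparallel, non-crossing by construction).  This evaluator defines the
    model; the dynamic program is checked against it.
    """
    params = params or default_parameters()
    t = target.as_rna().residues
    q = query.as_rna().residues
    if not pairing:
        raise StructureError("empty pairing")
    for ti, qi in pairing:
        if not (0 <= ti < len(t)) or not (0 <= qi < len(q)):
            raise StructureError(f"pair ({ti}, {qi}) out of range")
        if not pair_allowed(t[ti], q[qi], wobble=wobble):
            raise StructureError(
                f"disallowed pair {t[ti]}-{q[qi]} at ({ti}, {qi})"
            )
    for (t1, q1), (t2, q2) in zip(pairing, pairing[1:]):
        if t2 <= t1 or q2 >= q1:
            raise StructureError(
                "pairing must be strictly increasing on target and strictly "
                f"decreasing on query; offending pairs ({t1},{q1}) -> ({t2},{q2})"
            )
    # large caps: the evaluator accepts any loop the extrapolation covers
    # (rounded up so repeated calls share one cached integer table)
    max_gap = 64 * (1 + max(len(t), len(q)) // 64)
    pint = params.int_tables(max_bulge=max_gap, max_internal=max_gap)
    _st, _bulge, _internal, ends, _nc, _nm, init = pint

    def pidx(a: str, b: str) -> int:
        return PAIR_INDEX[a + b]

    total = init
    first_t, first_q = pairing[0]
    last_t, last_q = pairing[-1]
    total += int(ends[pidx(t[first_t], q[first_q])])
    total += int(ends[pidx(t[last_t], q[last_q])])
    for (t1, q1), (t2, q2) in zip(pairing, pairing[1:]):
        lt = t2 - t1 - 1
        lq = q1 - q2 - 1
        total += _step_centi(pint, pidx(t[t1], q[q1]), pidx(q[q2], t[t2]), lt, lq)
    if total >= _BIG:
        raise StructureError("loop size exceeds the extrapolation range")
    return total / 100.0
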