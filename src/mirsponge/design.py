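"""miRNA sponge construct design: binding sites, spacers, repeats, oligos.

A sponge is a transcript carrying several miRNA-binding sites (MBS), each the
antisense of a mature miRNA, separated by short spacers.  A perfectly paired
MBS is sliced by Ago2 and degraded, so the preferred design carries a central
bulge: the four antisense bases opposite a chosen miRNA window (default
positions 10-13, 1-based from the miRNA 5' end) are replaced with bases that
can pair with none of them - G-U wobble included - and one of the replaced
bases is deleted, leaving 3 sponge nucleotides opposite 4 miRNA nucleotides.

The bulge-fill rule is calibrated: among all replacement candidates with zero
pairing potential, each position takes the weakest-stacking admissible base
(preference T, then C, then A, then G - pyrimidines stack more weakly than
purines, U weakest of all), and the 3'-most replaced position on the sponge
sense strand is the one deleted.  For hsa-miR-145-5p with window 10-13 this
reproduces the published two-site construct exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Optional, Sequence, Tuple, Union

from .sequences import (
    Alphabet,
    MiRNARecord,
    NucleotideSequence,
    ValidationError,
    dna,
    reverse_complement,
)
from .thermo import EnergyParameters, pair_allowed

__all__ = [
    "MBSMode",
    "MBSSpec",
    "SpongeConstruct",
    "OVERHANG_PRESETS",
    "perfect_mbs",
    "select_bulge_fill",
    "bulged_mbs",
    "build_construct",
    "emit_oligos",
    "construct_annotations",
    "write_oligos_fasta",
    "write_annotations_tsv",
]


class MBSMode(str, Enum):
    PERFECT = "PERFECT"
    BULGED = "BULGED"


#: Directional-cloning overhangs/tails used with the cumate-inducible pCDH
#: vector family: 5'-GTCCC on the sense strand, 5'-GACCC on the antisense
#: strand, and a GG tail on both.
OVERHANG_PRESETS: Dict[str, Dict[str, str]] = {
    "pcdh-cumate": {
        "sense_overhang": "GTCCC",
        "antisense_overhang": "GACCC",
        "sense_tail": "GG",
        "antisense_tail": "GG",
    },
    "none": {
        "sense_overhang": "",
        "antisense_overhang": "",
        "sense_tail": "",
        "antisense_tail": "",
    },
}

#: weakest-stacking-first preference used to break ties among non-pairing fills
_FILL_PREFERENCE = "TCAG"
_DNA_TO_RNA = {"A": "A", "C": "C", "G": "G", "T": "U"}


@dataclass(frozen=True)
class MBSSpec:
    """One designed miRNA-binding site (sense-strand DNA)."""

    source: MiRNARecord
    mode: MBSMode
    mbs_dna: NucleotideSequence
    bulge_window: Optional[Tuple[int, int]] = None

    def __post_init__(self) -> None:
        n = len(self.source)
        if self.mode is MBSMode.PERFECT:
            if len(self.mbs_dna) != n:
                raise ValidationError("perfect MBS must match the miRNA length")
            if self.bulge_window is not None:
                raise ValidationError("perfect MBS carries no bulge window")
        else:
            if len(self.mbs_dna) != n - 1:
                raise ValidationError(
                    "bulged MBS must be one nucleotide shorter than the miRNA"
                )
            if self.bulge_window is None:
                raise ValidationError("bulged MBS requires its bulge window")


def _dna_str(value: str, what: str) -> str:
    value = (value or "").upper()
    if value and set(value) - set("ACGT"):
        raise ValidationError(f"{what} must be DNA (ACGT), got {value!r}")
    return value


@dataclass(frozen=True)
class SpongeConstruct:
    """An assembled sponge: ordered MBS list, spacers, overhangs, oligos.

    ``sense_oligo`` = sense_overhang + core + sense_tail where core joins the
    MBS sense sequences with the spacer (no trailing spacer);
    ``antisense_oligo`` = antisense_overhang + reverse_complement(core) +
    antisense_tail.  ``transcript`` is the RNA of the core - the sequence the
    screen tests by default.
    """

    mbs_list: Tuple[MBSSpec, ...]
    spacer: str = "AATT"
    sense_overhang: str = ""
    antisense_overhang: str = ""
    sense_tail: str = ""
    antisense_tail: str = ""
    sense_oligo: NucleotideSequence = field(init=False)
    antisense_oligo: NucleotideSequence = field(init=False)
    transcript: NucleotideSequence = field(init=False)

    def __post_init__(self) -> None:
        if not self.mbs_list:
            raise ValidationError("a sponge needs at least one MBS")
        object.__setattr__(self, "spacer", _dna_str(self.spacer, "spacer"))
        for name in ("sense_overhang", "antisense_overhang",
                     "sense_tail", "antisense_tail"):
            object.__setattr__(self, name, _dna_str(getattr(self, name), name))
        if len(self.spacer) > 20:
            raise ValidationError("spacer longer than 20 nt")
        if self.spacer and not 4 <= len(self.spacer) <= 6:
            warnings.warn(
                f"spacer length {len(self.spacer)} nt is outside the usual 4-6 nt",
                stacklevel=2,
            )
        core = self.spacer.join(str(m.mbs_dna) for m in self.mbs_list)
        core_seq = dna(core)
        object.__setattr__(
            self, "sense_oligo", dna(self.sense_overhang + core + self.sense_tail)
        )
        object.__setattr__(
            self,
            "antisense_oligo",
            dna(
                self.antisense_overhang
                + str(reverse_complement(core_seq, Alphabet.DNA))
                + self.antisense_tail
            ),
        )
        object.__setattr__(self, "transcript", core_seq.as_rna())

    @property
    def core(self) -> str:
        return self.spacer.join(str(m.mbs_dna) for m in self.mbs_list)


def perfect_mbs(mirna: MiRNARecord) -> MBSSpec:
    """Perfect antisense MBS: the reverse complement of the miRNA, as DNA."""
    return MBSSpec(
        source=mirna,
        mode=MBSMode.PERFECT,
        mbs_dna=reverse_complement(mirna.sequence, Alphabet.DNA),
    )


def select_bulge_fill(
    mirna_window: Union[NucleotideSequence, str],
    params: Optional[EnergyParameters] = None,
) -> NucleotideSequence:
    """Choose the 3-nt sponge fill opposite a 4-nt miRNA window.

    All 256 4-nt sense-strand replacement candidates are scored for residual
    pairing potential against the window (Watson-Crick pair = 2, G-U wobble =
    1 per aligned position); minimal-score candidates are tie-broken by the
    weakest-stacking preference T > C > A > G at each position, and the
    3'-most replaced base is deleted.  A zero-score candidate always exists
    for the 4-letter alphabet; the warning branch is a guard only.

    The candidate is oriented 5'->3' on the sponge sense strand, so its first
    base sits opposite the *last* window base (antiparallel duplex).  ``params``
    is accepted for interface stability; the calibrated rule is parameter-free.
    """
    if isinstance(mirna_window, str):
        window = NucleotideSequence(
            mirna_window.upper().replace("T", "U"), Alphabet.RNA
        )
    else:
        window = mirna_window.as_rna()
    if len(window) != 4:
        raise ValidationError("bulge window must be exactly 4 nt")
    opposite = window.residues[::-1]  # window base facing each candidate position

    def score(cand: str) -> int:
        s = 0
        for c, w in zip(cand, opposite):
            r = _DNA_TO_RNA[c]
            if pair_allowed(r, w, wobble=False):
                s += 2
            elif pair_allowed(r, w, wobble=True):
                s += 1
        return s

    best: Optional[str] = None
    best_key: Optional[tuple] = None
    for i0 in _FILL_PREFERENCE:
        for i1 in _FILL_PREFERENCE:
            for i2 in _FILL_PREFERENCE:
                for i3 in _FILL_PREFERENCE:
                    cand = i0 + i1 + i2 + i3
                    key = (score(cand),) + tuple(
                        _FILL_PREFERENCE.index(c) for c in cand
                    )
                    if best_key is None or key < best_key:
                        best, best_key = cand, key
    assert best is not None and best_key is not None
    if best_key[0] > 0:  # pragma: no cover - unreachable with ACGT alphabet
        warnings.warn(
            "no zero-pairing bulge fill exists; using the minimal-scoring candidate"
        )
    return dna(best[:3])  # delete the 3'-most replaced sense-strand base


def bulged_mbs(
    mirna: MiRNARecord,
    bulge_window: Tuple[int, int] = (10, 13),
    params: Optional[EnergyParameters] = None,
) -> MBSSpec:
    """Centrally bulged MBS: perfect antisense with the window opposite replaced.

    ``bulge_window`` is 1-based inclusive on the miRNA (default 10-13).  The
    antisense bases opposite the window are swapped for the 3-nt fill from
    :func:`select_bulge_fill`; every position outside the window matches the
    perfect antisense unconditionally.
    """
    start, end = bulge_window
    n = len(mirna)
    if end - start != 3:
        raise ValidationError("bulge window must span exactly 4 miRNA positions")
    if start < 2 or end > n - 1:
        raise ValidationError(
            f"bulge window {start}-{end} must be internal (2 <= start, end <= {n - 1})"
        )
    perfect = str(reverse_complement(mirna.sequence, Alphabet.DNA))
    window = NucleotideSequence(mirna.sequence.residues[start - 1:end], Alphabet.RNA)
    fill = str(select_bulge_fill(window, params))
    # antisense indices opposite the window (0-based): n-end .. n-start
    edited = perfect[: n - end] + fill + perfect[n - start + 1:]
    return MBSSpec(
        source=mirna,
        mode=MBSMode.BULGED,
        mbs_dna=dna(edited),
        bulge_window=(start, end),
    )


def build_construct(
    mbs_specs: Union[MBSSpec, Sequence[MBSSpec]],
    repeats: int = 1,
    spacer: str = "AATT",
    sense_overhang: str = "",
    antisense_overhang: str = "",
    sense_tail: str = "",
    antisense_tail: str = "",
    preset: Optional[str] = None,
    interleave: str = "round-robin",
) -> SpongeConstruct:
    """Assemble a sponge from MBS specs with ``repeats`` copies of each.

    Multiple specs (a family or cluster design) are interleaved round-robin
    (A, B, A, B, ...) by default; ``interleave="block"`` keeps each spec's
    copies together.  ``preset`` selects named overhang/tail sets
    (e.g. ``"pcdh-cumate"``) and overrides the explicit overhang arguments.
    """
    if isinstance(mbs_specs, MBSSpec):
        mbs_specs = [mbs_specs]
    if not mbs_specs:
        raise ValidationError("need at least one MBS spec")
    if repeats < 1:
        raise ValidationError("repeats must be >= 1")
    if preset is not None:
        try:
            chosen = OVERHANG_PRESETS[preset]
        except KeyError:
            raise ValidationError(
                f"unknown preset {preset!r}; known: {', '.join(sorted(OVERHANG_PRESETS))}"
            ) from None
        sense_overhang = chosen["sense_overhang"]
        antisense_overhang = chosen["antisense_overhang"]
        sense_tail = chosen["sense_tail"]
        antisense_tail = chosen["antisense_tail"]
    if interleave == "round-robin":
        expanded = [spec for _ in range(repeats) for spec in mbs_specs]
    elif interleave == "block":
        expanded = [spec for spec in mbs_specs for _ in range(repeats)]
    else:
        raise ValidationError("interleave must be 'round-robin' or 'block'")
    return SpongeConstruct(
        mbs_list=tuple(expanded),
        spacer=spacer,
        sense_overhang=sense_overhang,
        antisense_overhang=antisense_overhang,
        sense_tail=sense_tail,
        antisense_tail=antisense_tail,
    )


def construct_annotations(construct: SpongeConstruct) -> List[Tuple[str, int, int, str]]:
    """(feature, start, end, strand) rows on the sense oligo, 0-based half-open."""
    rows: List[Tuple[str, int, int, str]] = []
    pos = 0
    if construct.sense_overhang:
        rows.append(("sense_overhang", 0, len(construct.sense_overhang), "+"))
        pos = len(construct.sense_overhang)
    for k, spec in enumerate(construct.mbs_list, 1):
        if k > 1 and construct.spacer:
            rows.append(("spacer_%d" % (k - 1), pos, pos + len(construct.spacer), "+"))
            pos += len(construct.spacer)
        elif k > 1:
            pass
        rows.append((
            f"MBS_{k}[{spec.source.name}|{spec.mode.value.lower()}]",
            pos,
            pos + len(spec.mbs_dna),
            "+",
        ))
        pos += len(spec.mbs_dna)
    if construct.sense_tail:
        rows.append(("sense_tail", pos, pos + len(construct.sense_tail), "+"))
    return rows


def emit_oligos(construct: SpongeConstruct) -> str:
    """Plain-text record of both cloning oligos with coordinate annotations.

    Both strands are emitted 5'->3' with a 5'-phosphate flag, ready for
    ordering; the annotation block locates every MBS and spacer on the sense
    oligo (0-based half-open intervals).
    """
    lines = [
        f"sense oligo     phos5'-{construct.sense_oligo}  ({len(construct.sense_oligo)} nt)",
        f"antisense oligo phos5'-{construct.antisense_oligo}  ({len(construct.antisense_oligo)} nt)",
        f"transcript (RNA, screened) {construct.transcript}",
        "",
        "feature\tstart\tend\tstrand",
    ]
    for feat, start, end, strand in construct_annotations(construct):
        lines.append(f"{feat}\t{start}\t{end}\t{strand}")
    return "\n".join(lines)


def write_oligos_fasta(construct: SpongeConstruct, path) -> None:
    """FASTA of sense oligo, antisense oligo and the screened transcript."""
    with open(path, "w") as fh:
        fh.write(f">sense_oligo phos5p\n{construct.sense_oligo}\n")
        fh.write(f">antisense_oligo phos5p\n{construct.antisense_oligo}\n")
        fh.write(f">transcript\n{construct.transcript}\n")


def write_annotations_tsv(construct: SpongeConstruct, path) -> None:
    with open(path, "w") as fh:
        fh.write("feature\tstart\tend\tstrand\n")
        for feat, start, end, strand in construct_annotations(construct):
            fh.write(f"{feat}\t{start}\t{end}\t{strand}\n")
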