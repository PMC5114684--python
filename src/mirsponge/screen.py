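"""Screen a sponge sequence against a mature-miRNA set.

Every miRNA in the set is scanned independently against the full sponge
transcript; sites failing the configured seed filter are dropped, miRNAs with
no surviving site below the energy cut-off are dropped, and the remainder are
ranked by the sum of their site free energies (most negative first).  The
seed filter demands *perfect* Watson-Crick pairing - wobble pairs and loops
inside the seed window disqualify a site - matching the canonical-seed
definition; a non-canonical screen (mode NONE) disables the filter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from typing import List, Optional, Sequence, Tuple, Union

from .design import SpongeConstruct
from .hybridize import DuplexSite, ScanLimits, scan_sites
from .sequences import MiRNARecord, NucleotideSequence, ValidationError
from .thermo import EnergyParameters, default_parameters

__all__ = [
    "SeedMode",
    "ScreenConfig",
    "MiRNAHit",
    "ScreenReport",
    "seed_match",
    "screen_construct",
    "rank_hits",
    "report_to_tsv",
    "report_to_json",
    "report_to_text",
]


class SeedMode(Enum):
    """Seed-region requirement: 1-based miRNA positions that must pair perfectly."""

    SIX_MER = (2, 7)
    SEVEN_MER = (2, 8)
    OFFSET_SIX_MER = (3, 8)
    NONE = None

    @classmethod
    def from_string(cls, text: str) -> "SeedMode":
        key = text.strip().lower().replace("_", "-")
        table = {
            "6mer": cls.SIX_MER,
            "7mer": cls.SEVEN_MER,
            "offset-6mer": cls.OFFSET_SIX_MER,
            "none": cls.NONE,
        }
        try:
            return table[key]
        except KeyError:
            raise ValidationError(
                f"unknown seed mode {text!r}; choose from {', '.join(table)}"
            ) from None

    @property
    def label(self) -> str:
        return {
            SeedMode.SIX_MER: "6mer",
            SeedMode.SEVEN_MER: "7mer",
            SeedMode.OFFSET_SIX_MER: "offset-6mer",
            SeedMode.NONE: "none",
        }[self]


_WC = frozenset(("AU", "UA", "GC", "CG"))
_WOBBLE = frozenset(("GU", "UG"))


@dataclass(frozen=True)
class ScreenConfig:
    """Screen settings; the defaults mirror the worked sponge example
    (-25 kcal/mol cut-off, canonical 6-mer seed)."""

    cutoff: float = -25.0
    seed_mode: SeedMode = SeedMode.SIX_MER
    limits: ScanLimits = field(default_factory=ScanLimits)
    params: Optional[EnergyParameters] = None
    allow_wobble_in_seed: bool = False

    def __post_init__(self) -> None:
        if self.cutoff >= 0:
            raise ValidationError("cutoff must be negative (dG, kcal/mol)")

    def resolved_params(self) -> EnergyParameters:
        return self.params or default_parameters()


@dataclass(frozen=True)
class MiRNAHit:
    """One interacting miRNA: its surviving sites and their energy sum."""

    mirna: MiRNARecord
    sites: Tuple[DuplexSite, ...]
    total_energy: float

    def __post_init__(self) -> None:
        if not self.sites:
            raise ValidationError("a hit requires at least one site")
        expected = round(sum(s.energy for s in self.sites), 6)
        if abs(expected - round(self.total_energy, 6)) > 1e-6:
            raise ValidationError("total_energy must equal the sum of site energies")


@dataclass(frozen=True)
class ScreenReport:
    """Ranked screen result (ascending total energy; ties by miRNA name)."""

    sponge: NucleotideSequence
    config: ScreenConfig
    hits: Tuple[MiRNAHit, ...]
    set_provenance: dict


def seed_match(
    site: DuplexSite,
    mirna: MiRNARecord,
    mode: SeedMode,
    allow_wobble: bool = False,
    target: Optional[NucleotideSequence] = None,
) -> bool:
    """True iff the site pairs the mode's seed window perfectly.

    Perfect means every miRNA position in the window is Watson-Crick paired
    (G-U counts only when ``allow_wobble``) with consecutive sponge bases:
    a bulge or internal loop inside the seed disqualifies the site.
    ``SeedMode.NONE`` accepts everything.

    ``target`` (the sponge) is needed to tell a Watson-Crick pair from a
    wobble when a seed position is G or U; miRNA positions A and C can only
    be Watson-Crick paired, so the check is target-free for them.
    """
    if mode is SeedMode.NONE:
        return True
    start, end = mode.value  # 1-based inclusive miRNA positions
    by_query = {qi: ti for ti, qi in site.pairing}
    q = mirna.sequence.residues
    prev_ti = None
    for pos in range(start, end + 1):
        qi = pos - 1
        ti = by_query.get(qi)
        if ti is None:
            return False  # unpaired seed position
        if prev_ti is not None and ti != prev_ti - 1:
            return False  # loop inside the seed
        prev_ti = ti
        if allow_wobble or q[qi] in "AC":
            continue  # any allowed pair with A or C is Watson-Crick
        if target is None:
            raise ValidationError(
                "seed position with G/U needs the sponge sequence to rule out "
                "a wobble pair; pass target="
            )
        if target.as_rna()[ti] + q[qi] in _WOBBLE:
            return False
    return True


def screen_construct(
    sponge: Union[NucleotideSequence, SpongeConstruct, str],
    mirna_set: Sequence[MiRNARecord],
    config: Optional[ScreenConfig] = None,
    provenance: str = "",
) -> ScreenReport:
    """Screen ``sponge`` against every miRNA in ``mirna_set``.

    Accepts a raw sequence (RNA or DNA; screened as RNA) or an assembled
    :class:`SpongeConstruct`, whose core transcript is screened.  The result
    is deterministic and independent of the order of ``mirna_set``.
    """
    config = config or ScreenConfig()
    if isinstance(sponge, SpongeConstruct):
        target = sponge.transcript
    elif isinstance(sponge, str):
        target = NucleotideSequence(
            sponge.upper().replace("T", "U"), "RNA"
        )
    else:
        target = sponge.as_rna()
    params = config.resolved_params()
    hits: List[MiRNAHit] = []
    for rec in mirna_set:
        sites = scan_sites(target, rec, config.cutoff, params, config.limits)
        kept = tuple(
            s for s in sites
            if seed_match(s, rec, config.seed_mode,
                          config.allow_wobble_in_seed, target)
        )
        if kept:
            hits.append(
                MiRNAHit(
                    mirna=rec,
                    sites=kept,
                    total_energy=round(sum(s.energy for s in kept), 10),
                )
            )
    return ScreenReport(
        sponge=target,
        config=config,
        hits=tuple(rank_hits(hits)),
        set_provenance={"source": provenance or "<in-memory>", "records": len(mirna_set)},
    )


def rank_hits(hits: Sequence[MiRNAHit]) -> List[MiRNAHit]:
    """Ascending by total energy (strongest binder first); ties by name; stable."""
    return sorted(hits, key=lambda h: (h.total_energy, h.mirna.name))


def report_to_tsv(report: ScreenReport) -> str:
    """One row per hit; intervals 0-based half-open, energies full precision."""
    lines = [
        "mirna\taccession\tn_sites\ttotal_energy\tsite_energies\tsite_intervals"
    ]
    for hit in report.hits:
        energies = ";".join(f"{s.energy:.2f}" for s in hit.sites)
        ivals = ";".join(f"{s.target_interval[0]}-{s.target_interval[1]}"
                         for s in hit.sites)
        lines.append(
            f"{hit.mirna.name}\t{hit.mirna.accession}\t{len(hit.sites)}\t"
            f"{hit.total_energy:.2f}\t{energies}\t{ivals}"
        )
    return "\n".join(lines) + "\n"


def report_to_json(report: ScreenReport) -> str:
    """Full nested report with the resolved configuration echoed."""
    payload = {
        "sponge": str(report.sponge),
        "config": {
            "cutoff": report.config.cutoff,
            "seed_mode": report.config.seed_mode.label,
            "max_bulge_loop": report.config.limits.max_bulge_loop,
            "max_internal_loop": report.config.limits.max_internal_loop,
            "wobble": report.config.limits.wobble,
            "allow_wobble_in_seed": report.config.allow_wobble_in_seed,
            "parameters": report.config.resolved_params().name,
        },
        "set_provenance": report.set_provenance,
        "hits": [
            {
                "mirna": hit.mirna.name,
                "accession": hit.mirna.accession,
                "total_energy": hit.total_energy,
                "sites": [
                    {
                        "target_interval": list(site.target_interval),
                        "energy": site.energy,
                        "pairing": [list(p) for p in site.pairing],
                    }
                    for site in hit.sites
                ],
            }
            for hit in report.hits
        ],
    }
    return json.dumps(payload, indent=2) + "\n"


def report_to_text(report: ScreenReport) -> str:
    """Human-readable report with one ASCII interaction diagram per site."""
    cfg = report.config
    out = [
        f"sponge ({len(report.sponge)} nt): {report.sponge}",
        f"settings: cutoff {cfg.cutoff:g} kcal/mol, seed {cfg.seed_mode.label}, "
        f"loops <= {cfg.limits.max_bulge_loop}/{cfg.limits.max_internal_loop} nt, "
        f"wobble {'on' if cfg.limits.wobble else 'off'}",
        f"miRNA set: {report.set_provenance['source']} "
        f"({report.set_provenance['records']} records)",
        f"hits: {len(report.hits)}",
        "",
    ]
    for rank, hit in enumerate(report.hits, 1):
        out.append(
            f"#{rank} {hit.mirna.name} "
            f"({hit.mirna.accession or 'no accession'}): "
            f"{len(hit.sites)} site(s), total dG = {hit.total_energy:.1f} kcal/mol"
        )
        for site in hit.sites:
            out.append(site.diagram)
            out.append("")
    return "\n".join(out)
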