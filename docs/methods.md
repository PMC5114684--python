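# Methods

## Scope and model

`mirsponge` designs miRNA sponge constructs and predicts their miRNA
interactions with a nearest-neighbour thermodynamic model of intermolecular
RNA–RNA hybridization.  The model deliberately excludes intramolecular
structure in either molecule (pure hybridization), target-site
accessibility, partition-function/ensemble effects, and any statistics over
hits (no p-values): a sponge screen is a deterministic energy ranking.

### Energy decomposition

A duplex is an antiparallel, non-crossing set of base pairs — Watson–Crick
plus the G–U wobble — between a *target* (the sponge, any length) and a
*query* (a mature miRNA, ≤ 35 nt).  Its free energy at 37 °C is

```
dG = helix_init + Σ stacks + Σ loops + end(first pair) + end(last pair)
```

* **Stacks** — Turner 2004 ΔG°₃₇ stacked-dinucleotide terms for adjacent
  pairs.  Watson–Crick/Watson–Crick stacks are bundled at the published
  0.01 kcal/mol precision (e.g. 5′AA3′/3′UU5′ = −0.93); wobble-containing
  stacks at the 0.1 kcal/mol precision of the distributed parameter sets.
* **Bulges** — initiation by size (1–30 nt tabulated); a single-nucleotide
  bulge retains the stack of its closing pairs, per the Turner rules.
* **Internal loops** — initiation by total size (2–30 nt tabulated) plus a
  Ninio asymmetry penalty `min(3.0, 0.6·|n1 − n2|)`.  Loops beyond the
  tables use the Jacobson–Stockmayer form
  `dG(n) = dG(30) + 1.75·R·T·ln(n/30)`.
* **Ends** — `helix_init` once per duplex and a terminal penalty for each
  helix-terminal AU/GU pair.

The parameter table is a sectioned plain-text file
(`src/mirsponge/data/turner2004_dg37.nn`, sections STACKS / BULGE /
INTERNAL / MISC) that `load_parameters` can replace wholesale; completeness
(all 36 allowed-pair stacks, all tabulated loop sizes), 180°-rotational
stack symmetry, and sign sanity are enforced at load time.

### The two bundled profiles

Screening tools in this domain report *hybridization* energies: sums of
stack and loop terms with no duplex-initiation or terminal-AU contribution.
Absolute duplex ΔG additionally carries `helix_init = 4.09` and
`au_end_penalty = 0.45` kcal/mol.  Both conventions are bundled:

| profile | helix_init | au_end | use |
|---|---|---|---|
| `turner2004-screen` (default) | 0 | 0 | sponge screening, site energies |
| `turner2004` | 4.09 | 0.45 | absolute duplex free energies |

Under the screening profile the worked miR-145 example (two bulged MBS,
`AATT` spacer) scores −34.11 kcal/mol per site, −68.22 total, within
1.3 kcal/mol of the value published for the same construct by the original
web tool; the absolute profile would shift each site by +4.5 kcal/mol.
Terminal-mismatch and dangling-end contributions are **not** modelled in
either profile: they would require the full mismatch/1×1/2×1/2×2 tables,
are absent from the screening convention this package reproduces, and would
perturb site energies by ≲ 1 kcal/mol per loop.  This is the main known
source of small offsets versus other Turner-2004 implementations.

Temperature is fixed at 37 °C; there is no enthalpy table, salt correction,
coaxial stacking, or support for modified nucleotides.

### Dynamic program

`hybridize_mfe` fills `B[i][j]` = best energy of a duplex whose last pair
is (target *i*, query *j*), extending from any previous pair across a
stack, bulge or internal loop with per-side caps (default 15 nt, matching
the conventional limits of hybridization scanners).  Unpaired flanks of
both molecules are free.  All arithmetic is integer centi-kcal/mol, so the
DP is *exactly* equal to the explicit-structure evaluator
`duplex_energy_of_pairing` — the test suite checks equality against
exhaustive enumeration of all antiparallel non-crossing pairings for short
sequences, and the evaluator re-scores every emitted site.

Tie-breaking is deterministic: end cells are scanned target-index-major and
kept only on strict improvement, and the traceback re-runs the kernel's
predecessor scan (stack before bulge before internal loop, smaller loops
first), which prefers densely paired structures.  A duplex is reported only
if its total energy is negative.

Multiple sites are extracted greedily: accept the global MFE site if it
meets the cut-off (`≤`, so a site exactly at the cut-off is reported), mask
exactly its target interval, and rescan the flanking segments.  Greedy
masking matches the intended use-case — distinct sites on distinct MBS
copies — and makes the site list deterministic; it does not enumerate
suboptimal overlapping structures.

## Sponge design

* **Perfect MBS** — the reverse complement of the miRNA (DNA on the oligo
  boundary, RNA internally).
* **Bulged MBS** — the four antisense bases opposite a 1-based miRNA window
  (default 10–13) are replaced so that *no* replacement base can pair —
  wobble included — with the window base it faces; the 3′-most replaced
  base on the sponge sense strand is then deleted, leaving a 4×3 internal
  loop in the duplex.  Among the zero-pairing candidates each position takes
  the weakest-stacking admissible base, preference T > C > A > G
  (pyrimidines stack more weakly than purines, U weakest).  The deletion
  choice and the preference order are calibrated jointly to the one
  published ground-truth construct (miR-145-5p, window 10–13 →
  MBS `AGGGATTCCTTTTAAACTGGAC`); the non-window positions always equal the
  perfect antisense, and the non-pairing guarantee holds for all 256
  possible windows by construction.
* **Assembly** — `core = MBS₁ + spacer + MBS₂ + …` (no trailing spacer);
  family/cluster designs interleave their MBS specs round-robin
  (A,B,A,B,…) by default, block order optionally.  The sense oligo is
  `overhang + core + tail`, the antisense oligo the reverse complement of
  the core with its own overhang/tail; the screened transcript is the RNA
  of the core (overhangs are cloning artifacts; a caller can screen the
  full oligo explicitly).  The `pcdh-cumate` preset carries the
  GTCCC/GACCC overhangs and GG tails used for directional cloning into a
  cumate-inducible pCDH vector.  Spacers warn outside the conventional
  4–6 nt and are capped at 20 nt.

## Screening

Each miRNA in the set is scanned independently against the full sponge
(sites of different miRNAs may overlap; masking applies only within one
miRNA's scan — sequestration competition between miRNAs is out of scope).
Sites must then pass the seed filter: every miRNA position in the seed
window (6-mer 2–7, 7-mer 2–8, offset 6-mer 3–8) must be Watson–Crick
paired — a wobble or any loop inside the seed disqualifies the site, since
a canonical seed is a perfect contiguous helix.  Wobble-tolerant seed
matching is available behind a flag for sensitivity analysis; mode `none`
disables the filter for non-canonical screens.  Each surviving miRNA is
scored by the sum of its site energies and ranked ascending (ties broken
by name), which makes reports independent of input order.  Defaults mirror
the worked example: cut-off −25 kcal/mol, 6-mer seed.

## Synthetic miRNA sets

`generate_synthetic_mirna_set` emulates a mature-miRNA database for
download-free testing: lengths uniform on [19, 25] nt (the bulk of real
mature miRNAs), i.i.d. bases with a configurable GC fraction (default 0.5),
fully determined by an integer seed, with optional *planted* sequences
appended under distinguishable names.  It reproduces none of the family
structure, shared seeds, or expression weighting of a real miRNome, so a
clean screen against it demonstrates specificity against random background
only — real off-target assessment must screen the actual species set
(miRBase `mature.fa`, read natively including gzip).

## Problem sizes and numerical choices

The test suite and the acceptance script use: exhaustive-enumeration
cross-checks on 200 random pairs of 4–8 nt (the largest size where
enumeration is comfortable and exact); planted-recovery screens of a 1/2/4/6
MBS construct against 500 random miRNAs per trial (25 seeded trials per
repeat count in the suite, 10 per count in the script); and 50 (suite) or
20 (script) random sponge/set pairs for filter monotonicity.  Energies are
exact to 0.01 kcal/mol by integer arithmetic; user-facing text rounds to
0.1 kcal/mol while TSV/JSON carry full precision.  Intervals are 0-based
half-open in data formats and 1-based inclusive in human-readable output,
labelled in both.

## Known limitations

* No terminal mismatches, dangles, coaxial stacks, or special small-loop
  tables (1×1/2×1/2×2); energies can differ from full Turner-2004
  implementations by a small per-loop constant.
* Greedy site extraction cannot report overlapping alternative sites.
* The seed filter is structural only; it does not model the biological
  asymmetry between seed-driven and compensatory 3′ pairing beyond the
  chosen window.
* Sponge design does not screen for restriction sites, promoter elements,
  or oligo Tm; vector biology ends at overhang-bearing oligos.
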