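# Methods

## Model

`disphscan` treats a protein chain as a set of independently titrating
groups embedded in a hydrophobicity landscape, and asks on which side of a
linear charge–hydrophobicity boundary the chain sits at each pH.

**Titration.** Every ionizable side chain is assumed to titrate
independently with a fixed, context-free pKa (no electrostatic coupling
between sites, no pKa shifts from burial or neighbors). The mean charge of
a group is the two-state Henderson–Hasselbalch ensemble average, so each
per-residue charge lies in [−1, +1] and is non-increasing in pH — which
makes NCPR itself non-increasing in pH, a property the test suite checks
on a thousand random sequences. NCPR divides the summed charge by chain
length; free terminal groups (N-term pKa 8.6, C-term 3.6) are excluded by
default because a length-normalized sum makes their contribution O(1/L),
and excluding them keeps homopolymer controls exactly neutral. A flag
turns them on.

**Lipophilicity.** Each residue's effective lipophilicity at a pH is the
protonation-weighted mix `f·h_neutral + (1−f)·h_charged`, with `f` the
neutral-species fraction (`f = 1 − |charge|`). Charged species are never
more lipophilic than neutral ones; the scale type enforces this. Local
hydrophobicity is a centered sliding-window mean (default 51 residues),
truncated at the chain ends — a sequence shorter than the window collapses
to whole-sequence averaging at every position, and global verdicts are
insensitive to the window choice, as expected for a windowed mean whose
own average is taken afterwards.

**Boundary.** The DispH score is `c1·⟨H⟩ − |NCPR| − c2` with defaults
c1 = 2.785, c2 = 1.151, the classic linear boundary separating compact
from natively unfolded sequences in the mean-hydrophobicity / mean-net-
charge plane. The score depends on NCPR only through its magnitude (a
strongly acidic and a strongly basic chain are equally disordered by this
criterion). A score of exactly 0 is labeled unfolded: ties break
conservatively toward disorder. Both coefficients live in the run config
so a recalibrated boundary can be substituted without code changes.

**Transition detection.** Over a pH grid (count =
`floor((pH_max − pH_min)/step) + 1`, default 0–14 at 0.5 → 29 points), a
transition requires the score's maximum to exceed +ci *and* its minimum to
fall below −ci (ci = 0.02 by default). Crossing counting is debounced:
scores inside the band inherit the previous definite sign (leading in-band
points inherit the first definite sign), so noise-scale wiggles around
zero cannot manufacture multitransitions. Each sign flip is located by
linear interpolation of the score's zero between the bracketing grid
points — a rule that is stable under step refinement (halving the step
moves the interpolated crossing by less than one coarse step on the
designed fixtures). Crossings class as acid (pH < 6), neutral (closed
interval [6, 8]) or basic (pH > 8); the closed neutral interval is this
package's reading of the conventional "6–8" range. Profiles failing the
gate are labeled folded/unfolded by the score's sign at the grid's middle
point, with a logged low-confidence warning when every score sits inside
the band. Dataset summaries attribute one direction per protein (its
first transition) and count every crossing in the acid/neutral/basic
split; percentage families over an empty denominator are reported as 0.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| pH range | 0–14 | pH | scanned interval |
| step | 0.5 | pH | grid spacing (29 points over 0–14) |
| window | 51 | residues | centered sliding window, odd required |
| ci | 0.02 | score | confidence half-width around score zero |
| c1, c2 | 2.785, 1.151 | — | boundary slope / intercept |
| pKa set | EMBOSS | pH | D 3.9, E 4.1, C 8.5, Y 10.1, H 6.5, K 10.8, R 12.5 |

Even windows are rejected rather than silently adjusted: a centered
window needs an odd width, and quiet rounding would make profiles
irreproducible across tools.

## The bundled lipophilicity scale is a stand-in

A measured pH-dependent implicit-solvation scale gives, for every
residue, distinct neutral- and charged-species lipophilicities. No such
per-residue table ships here; instead the package bundles a **synthetic
stand-in**: Kyte–Doolittle hydropathy min–max normalized to [0, 1] for
neutral species, with every charged species pinned to the scale minimum
(0.0). This preserves the method's structure — ionization always reduces
lipophilicity, mixing is protonation-weighted — but the absolute scores
and the exact crossing pHs it produces are scale-dependent. Users with a
measured scale should pass it via `--scale-file`
(CSV `residue,h_neutral,h_charged`). Scale and pKa files are the two
substitution points; everything downstream is unchanged.

## Synthetic data: what it emulates and what it does not

The fixtures module generates sequences whose titration behavior is known
by construction: homopolymer controls (poly-G is pH-inert; poly-K and
poly-E isolate one titrating group), alternating copolymers that dilute a
single ionizable residue into a hydrophobic valine background so that the
chain crosses the boundary near that group's pKa — (VK)₂₅ folds as pH
rises past the Lys pKa, (VE)₂₅ unfolds past the Glu pKa, (VH)₂₅ crosses
in the neutral window via histidine — and uniform-composition random
100-mers. The synthetic mini-proteome interleaves these, and its truth
table is computed at generation time with whatever scale/pKa/boundary are
in force, so swapping the stand-in scale regenerates a consistent truth
table instead of breaking tests.

Passing tests on these fixtures demonstrate that the machinery — the
titration math, mixing, windowing, boundary, debounced crossing logic and
serialization — behaves exactly as specified. They do **not** validate
predictive accuracy on real proteins: real proteomes have non-uniform
composition and length distributions, coupled titration, and disorder
that no two-feature linear boundary fully captures.

## Problem sizes

The default verification runs use a 200-sequence synthetic proteome
(lengths 50–100) over the 29-point grid, a thousand random sequences for
the titration/windowing properties and 10,000 fuzzed score series for the
crossing-parity invariant — sizes chosen so the entire suite re-derives
every property in seconds while exercising each code path at realistic
sequence lengths.

Reproducing published proteome-scale surveys (tens of thousands of
UniProt sequences per organism) is an optional large run: it needs the
reference proteome FASTA for a specific release, a measured pH-dependent
scale, and the recalibrated boundary coefficients of the original
predictor; with those in hand the same `disphscan scan` invocation
applies unchanged. Absent them, per-organism transition fractions are not
comparable number-for-number and are not asserted anywhere in this
package.

## Numerical choices and degenerate inputs

- Grid counts use `floor((max − min)/step + 1e-9)` to absorb binary
  floating-point representation of decimal steps.
- Window means use cumulative sums (exact up to ~1e-15 round-off; tests
  compare against brute-force slicing at 1e-12).
- A single-point profile (single-pH mode) can never transition; it is
  classified by its one score's sign.
- Ambiguity codes X/B/Z/U/O are tolerated: zero charge, scale-mean
  lipophilicity, one logged warning per sequence. Any other character
  rejects the record — but only that record; batch runs collect rejects
  in `skipped.tsv` and continue.
- Duplicate FASTA identifiers get numeric suffixes (`x`, `x_2`, ...) so
  output files never collide.
- All floats serialize with 6 decimals and fixed field order; with the
  timestamp disabled, re-running an identical configuration is
  byte-identical.

## Known limitations

- Independent-site titration with generic pKa values; no structural or
  environmental pKa shifts.
- A single global linear boundary; no per-pH recalibration, no quadratic
  or learned alternatives.
- Crossing pHs carry no uncertainty estimate beyond the confidence band
  gate, and no smoothing is applied to score-vs-pH curves.
- The stand-in scale makes absolute crossing pHs indicative, not
  quantitative, until a measured scale is supplied.
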