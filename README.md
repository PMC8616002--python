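# disphscan

Predicts **pH-dependent protein disorder** and detects pH-induced
order/disorder transitions for many sequences at once.

Intrinsically disordered proteins (IDPs) expose their side chains to the
solvent, so their conformational state responds to solution pH: titratable
groups (Asp, Glu, Cys, Tyr, His, Lys, Arg) charge and discharge as pH
moves across their pKa values, shifting both the chain's net charge and
its effective hydrophobicity. `disphscan` scans protein sequences over a
pH grid, scores each (sequence, pH) pair on a linear charge–hydrophobicity
boundary, and reports where — and in which direction — each sequence
crosses between predicted order and disorder. It is aimed at anyone
studying conditional disorder: proteome-scale surveys, mutant screens, or
buffer/formulation work where the pH is far from neutral.

## The model

At every pH of the grid, for each sequence:

1. **NCPR** (net charge per residue). Each ionizable group's mean charge
   follows the Henderson–Hasselbalch equation —
   acids: `q = -1 / (1 + 10^(pKa - pH))`,
   bases: `q = +1 / (1 + 10^(pH - pKa))` —
   summed over the chain and divided by its length. Default pKa values are
   the EMBOSS set (D 3.9, E 4.1, C 8.5, Y 10.1, H 6.5, K 10.8, R 12.5),
   overridable via CSV.
2. **Mean hydrophobicity** ⟨H⟩. Each residue's lipophilicity (normalized
   to [0, 1]) is a protonation-weighted mix of its neutral- and
   charged-species values, `h = f·h_neutral + (1-f)·h_charged` with `f`
   the neutral fraction at that pH; values are averaged in a centered
   sliding window (default 51, truncated at the ends) and then over the
   chain.
3. **DispH score.** The signed offset from the linear boundary separating
   compact and disordered sequences in the charge–hydrophobicity plane:

   `DispH = c1·⟨H⟩ − |NCPR| − c2`  (defaults c1 = 2.785, c2 = 1.151)

   Positive ⇒ predicted folded, negative ⇒ predicted disordered.
4. **Transitions.** A transition is reported only when the score's maximum
   exceeds +0.02 *and* its minimum falls below −0.02 (the confidence
   band); sign changes are counted on a debounced series in which in-band
   points inherit the last definite sign. Crossing pHs come from linear
   interpolation of the score's zero and are classed acid (< 6), neutral
   ([6, 8]) or basic (> 8). A disorder→order switch with rising pH is
   *conditional folding*; the reverse, *conditional unfolding*. Two or
   more crossings make a *multitransition*.

The bundled lipophilicity scale is a documented synthetic stand-in
(Kyte–Doolittle hydropathy min–max normalized, charged species at the
scale minimum); supply `--scale-file` to use a measured pH-dependent
scale. See `docs/methods.md` for assumptions and limitations.

## Worked example

```bash
cat > idp.fa <<'EOF'
>VE25 designed conditional-unfolding fixture
VEVEVEVEVEVEVEVEVEVEVEVEVEVEVEVEVEVEVEVEVEVEVEVEVE
>polyG50 pH-inert control
GGGGGGGGGGGGGGGGGGGGGGGGGGGGGGGGGGGGGGGGGGGGGGGGGG
EOF
disphscan scan --fasta idp.fa --out results --no-timestamp
```

`results/summary.csv`:

```
identifier,verdict,n_transitions,transition_phs,directions,ph_classes,max_score,max_score_ph,min_score,min_score_ph
VE25,transition,1,4.168020,conditional unfolding,acid,0.349754,0.000000,-0.304917,14.000000
polyG50,folded,0,,,,0.117722,0.000000,0.117722,0.000000
```

The (VE)₂₅ copolymer is folded at low pH (score +0.35 at pH 0, glutamates
protonated and neutral) and unfolds as its glutamates deprotonate: one
conditional-unfolding crossing at pH 4.17, right at the Glu pKa of 4.1,
classed acid. The glycine homopolymer has no titratable groups, so its
score never moves (+0.118 at every pH) and it is simply called folded.
`results/profiles/VE25.csv` holds the per-pH series (pH, ⟨H⟩, NCPR, score,
state) behind those verdicts, and `results/results.json` mirrors
everything with the full run configuration in its header.

Single-pH mode reports the score, ⟨H⟩ and NCPR per sequence plus a
per-residue score profile:

```bash
disphscan single --ph 7.0 --fasta idp.fa --out results_ph7
```

As a library:

```python
from disphscan import (PKaSet, LipophilicityScale, build_ph_grid,
                       scan_sequence, detect_transitions, ProteinRecord)

rec = ProteinRecord("VE25", "VE" * 25)
profile = scan_sequence(rec, build_ph_grid(0, 14, 0.5), 51,
                        LipophilicityScale.kyte_doolittle_normalized(),
                        PKaSet.emboss())
report = detect_transitions(profile, ci=0.02)
print(report.verdict, [(t.ph, t.direction) for t in report.transitions])
# transition [(4.168020..., 'conditional unfolding')]
```

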