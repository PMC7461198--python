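# disphred

**pH-dependent charge–hydropathy prediction of intrinsic protein disorder.**

Intrinsically disordered proteins (IDPs) stay unfolded because their
sequences combine high net charge with low hydrophobicity: on the
charge–hydropathy (C–H) plane, disordered and folded proteins occupy regions
separable by a straight line. Both coordinates, however, depend on solution
pH — ionizable side chains titrate, changing not only the net charge but
also the effective hydrophobicity of the residues that carry them. This
package scores protein sequences on a *pH-aware* C–H plane and predicts
pH-induced order/disorder transitions (conditional folding), for anyone
studying IDPs, designing disorder tags, or profiling how a sequence's
disorder responds to its environment.

## The score

For a sequence at pH *x* the package computes:

- **NCPR** — net charge per residue, from the Henderson–Hasselbalch partial
  charge of each ionizable group: `q = ±1 / (1 + 10^(±(pH − pKa)))`;
- **⟨H_pH⟩** — mean hydrophobicity from a two-state pH-dependent hydropathy
  scale in which each ionizable residue's value is the population-weighted
  average of its neutral- and charged-species hydropathies, normalized to
  [0, 1] over all residues and the full pH range;
- **Dis_pH** — the linear boundary score

  ```
  Dis_pH = 2.775 · ⟨H_pH⟩ − |NCPR| − 1.118
  ```

  Positive → predicted folded, negative → predicted disordered; a ±0.02
  band around zero is reported as low-confidence. The coefficients come
  from a linear-kernel SVM separation of literature order/disorder C–H
  datapoints; the classic Uversky boundary (2.785, 1.151) is available as
  a preset, and `fit_boundary` refits the SVM on any labeled dataset.

Scanning a pH grid with a sliding window classifies every position as
*always folded*, *always disordered*, or *conditionally disordered* (class
switches somewhere in the pH range).

## Worked example

The capped model peptide Ac-AKAAKAKAAKAKAAKA-NH2 (six lysines, no other
ionizable groups) is disordered at neutral pH but folds once its lysines
deprotonate:

```bash
disphred predict --seq "Ac-AKAAKAKAAKAKAAKA-NH2" \
    --ph-min 1 --ph-max 13 --ph-step 1 --window 7 --out out/
```

The JSON/TSV report contains, per pH, the mean hydrophobicity, NCPR and
Dis_pH score. Two rows of the scan:

```
pH  7: Dis_pH = -0.3011  (disordered)   |NCPR| = 0.3749, <H_pH> = 0.4295
pH 12: Dis_pH = +0.1869  (folded)       |NCPR| = 0.0115, <H_pH> = 0.4744
```

At pH 7 the six lysines are protonated (+0.9997 e each): the peptide
carries |NCPR| ≈ 0.375 and its charged lysines count as hydrophilic, so the
score is well below the boundary. By pH 12 the lysines are mostly neutral —
charge nearly vanishes and hydrophobicity rises — and the peptide crosses
to the folded side.

Library use:

```python
from disphred import scan_ph, PhGrid, parse_sequence

rec = parse_sequence("Ac-AKAAKAKAAKAKAAKA-NH2")
for row in scan_ph(rec.residues, PhGrid(1, 13, 1.0), window=7,
                   termini=rec.termini):
    print(f"pH {row.ph:4.1f}  Dis_pH {row.disph:+.3f}  {row.label}")
```

## What else is here

- `disphred scales corr` — residue-wise R² between hydropathy scales
  (packaged: `kyte_doolittle`, `guy`, `ph_default`, `ph_pro_corrected`, and
  a clearly-labelled synthetic stand-in for the IDP–Hydropathy scale).
- `disphred fit-boundary` / `evaluate` / `roc` — SVM boundary fitting and
  benchmarking (sensitivity, specificity, precision, FDR, accuracy, F1,
  MCC, ROC/AUC) on labeled CSV datasets
  (`id,sequence,ph,label[,h_override,ncpr_override]`).
- `disphred simulate` — deterministic synthetic fixtures: folded-like vs
  disordered-like benchmark sets, pH-switchable sequences with a chosen
  flip pH, and labeled C–H point clouds with known ground truth.
- A pH-frozen control mode (`freeze_h_at=7.0`) that keeps hydrophobicity at
  its neutral-pH value while charge titrates, demonstrating why pH-dependent
  hydrophobicity is essential for predicting conditional folding.

See `docs/methods.md` for the model, parameter defaults, numerical choices
and known limitations.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the package's main computations from scratch — packaged-scale
correlations, the model-peptide pH scan, synthetic benchmark generation
with ROC analysis at pH 7, an SVM boundary refit on synthetic labeled
points, and a pH-switchable fixture round trip — printing each result as it
is computed.
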