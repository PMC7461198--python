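# Methods

## Model

The package predicts protein disorder from the charge–hydropathy (C–H)
relationship, treating both coordinates as functions of solution pH.

**Partial charges.** Every ionizable group — side chains D, E, C, Y
(acids), K, R, H (bases), and the free termini — is an independent
two-state titrating site. Its fractional charge at pH *x* follows the
Henderson–Hasselbalch equation: `+1/(1+10^(pH−pKa))` for bases,
`−1/(1+10^(pKa−pH))` for acids. Site–site electrostatic coupling, ionic
strength and temperature effects are ignored. NCPR is the sum of partial
charges over a sequence (or window) divided by its length; N-acetylated /
C-amidated ends contribute no terminal charge, and window NCPR includes a
terminal charge only when the window touches a free terminus.

**pH-dependent hydrophobicity.** Each residue's hydropathy at pH *x* is the
population-weighted average of its neutral-species and charged-species
values, with the neutral fraction taken from the same titration model. The
packaged default (`ph_default`) uses Kyte–Doolittle values for the neutral
species and −5.0 (just below the Kyte–Doolittle minimum) for every ionized
species: ionization makes a side chain strongly hydrophilic. The reference
scale this emulates was derived from continuum-solvation calculations and
its constants are not public here, so the two-state table is a transparent,
replaceable approximation — any TSV with `residue  neutral  charged`
columns can be dropped in. Calibration: at pH 7 the default scale
correlates with the Guy scale at R² = 0.77 (the package requires ≥ 0.6; the
true reference scale is reported at 0.72).

Values are min-max normalized to [0, 1] with 1 = most hydrophobic.
**Normalization bounds for the pH-dependent scale are global** (the min/max
over both species tables, which bound every mixture attainable in pH 0–14),
so hydrophobicities at different pHs are mutually comparable — per-pH
renormalization would warp the boundary. Static scales whose raw convention
is "larger = more hydrophilic" (Guy) are flipped during normalization; the
orientation is declared in the scale file header.

**Score.** `Dis_pH = a·⟨H_pH⟩ − |NCPR| − b`, default (a, b) =
(2.775, 1.118) with a ±0.02 low-confidence margin in score units; the
Uversky boundary (2.785, 1.151) is a preset. ⟨H_pH⟩ is computed
windowed-then-averaged: the mean over all full-window sliding averages.
This matches assigning each window's average to its center residue; the
plain per-residue mean is available via `windowed=False` and differs only
by edge effects when the window is much shorter than the sequence.

**Windows and edges.** Default window 51 (whole-protein profiling); the
benchmark analyses in the tests use window 7. Windows must be odd (even
inputs are incremented with a warning). Only positions with a complete
window receive per-residue scores; the first and last (w−1)/2 positions are
unscored. Sequences shorter than the window fall back to the simple mean
for the global score, with a warning.

**Region classes.** Over a pH grid, a scored position is `always_folded`
(window score ≥ 0 at every pH), `always_disordered` (< 0 at every pH), or
`conditionally_disordered`. Within-margin scores count with their sign for
this purpose, so the three classes tile the scored positions exactly and a
margin of 0 never produces a within-margin label (ties at exactly 0 count
as folded, consistent with "disordered ⇔ score < 0" everywhere).

## Defaults that matter

| parameter | default | notes |
|---|---|---|
| pKa set | D 3.65, E 4.25, H 6.0, C 8.3, Y 10.1, K 10.5, R 12.5, N-term 9.0, C-term 2.0 | standard textbook values; lives in `data/pka_default.tsv`, swappable |
| titratable set | D, E, H, C, Y, K, R | `titratable="basic_acidic"` drops C and Y |
| supported pH | [0, 14] | outside raises `PhRangeError` |
| window | 51 (predict), 7 (benchmarks) | odd, center-assigned |
| margin | 0.02 score units | the SVM margin of the default boundary |
| pH grid | 1.0–13.0, step 0.5 | used when the caller gives none |
| SVM regularization | C = 10.0 | see below |
| termini | free for FASTA input | `Ac-`/`-NH2` affixes (sequence or record id) or the `--termini` flag override |
| non-canonical residues | hard error | permissive mode skips them from both H and NCPR averages |

## Boundary fitting and evaluation

`fit_boundary` trains a soft-margin linear-kernel SVM on (⟨H⟩, |NCPR|)
without feature standardization — the raw coefficients then live on the
same scale as the boundary equation — and divides the separating
hyperplane by minus its |NCPR| coefficient to reach the canonical form;
the reported margin is the SVM margin half-width in score units. C = 10.0
was fixed once against the parameter-recovery requirement (500 points at
±0.05 score offsets: < 1% coefficient error clean, < 4% with 5% mislabels)
and is not data-dependent; the fit is deterministic. If the data constrain
only the hydrophobicity axis (all points at |NCPR| = 0) the boundary is
vertical and is returned with unit H coefficient; if the fitted orientation
contradicts the C–H relationship (hydrophobicity not on the folded side)
the fit raises rather than returning a misleading model.

Binary metrics use *disordered* as the positive class. Undefined ratios
(zero denominators) are reported as NaN with the metric named in an
`undefined` set, never raised. ROC analysis ranks by a disorder score
(higher = more disordered, i.e. −Dis_pH); AUC equals the Mann–Whitney
pair-ranking probability with half credit for ties (verified in the tests
against an O(n²) pairwise oracle independent of the implementation).

The pH-frozen control (`freeze_h_at=7.0`) recomputes hydrophobicity at a
fixed pH while NCPR still titrates — the "hydrophobicity is
pH-independent" assumption the pH-dependent treatment is measured against.

## Synthetic data: what it emulates, what it does not

`gen_benchmark_sets` draws residues i.i.d. from two frozen composition
profiles (`data/composition_profiles.json`): folded-like
(hydrophobic-biased, charge-depleted; lengths U[100, 300]) and
disordered-like (E/K/S/P/Q-rich; lengths U[80, 250], the minimum chosen so
the default 51-window never triggers the short-sequence fallback). Default
sizes 150/111 mirror typical folded/disordered benchmark sets. The clouds
straddle the default boundary at pH 7 by construction, so a green
separation test establishes that the scoring pipeline is wired correctly —
not that the method would achieve the same AUC on real proteins, whose
compositions are correlated along the chain and far less polarized.

`gen_ph_switchable` engineers conditional folders: a hydrophobic I/L/A
filler with a titrating fraction of Glu (acid folders) or Lys (base
folders). The fraction is found by bisection against the package's own
predictor until the Dis_pH sign flip lands within 0.25 pH units of the
requested target — a self-consistency construction, so flip-location tests
validate internal coherence, not external truth. One genuine physical
consequence falls out of the model rather than the tuning: when the flip is
displaced from the side-chain pKa (acid folders flipping below ~3.9, base
folders above ~11), the transition is driven by the hydrophobicity gained
on neutralization rather than by charge loss, and the pH-frozen control
misclassifies the folded state — the regime used to demonstrate why
pH-dependent hydrophobicity matters. Closer to the pKa the charge term
alone can carry the transition and the frozen control limps through.

`gen_ch_points` places labeled points at known score offsets outside the
±margin band of a known boundary, the ground truth for parameter-recovery
tests; a mislabel fraction exercises the soft margin.

All generators are pure functions of (arguments, seed).

## Numerical choices

- Windowed means use `numpy` sliding windows; they agree with a pure-Python
  double loop to < 1e-12 (asserted over random sequences).
- NCPR sums per-residue-type contributions with `math.fsum`; sequence/
  window scores are plain float arithmetic.
- Flip-pH location uses Brent's method (xtol 1e-4) on the score, which is
  monotone in pH for single-titrating-residue compositions.
- JSON reports keep full double precision (bit-exact round trip); TSV
  output rounds to 6 significant digits.
- Coordinates in all outputs are 1-based inclusive.

## Design choices on open points

- **Guy scale transcription.** His is packaged as +0.50 (hydrophilic,
  consistent with the other ionizable residues); some electronic
  reproductions print −0.50. The +0.50 transcription reproduces the
  literature Guy-vs-Kyte–Doolittle residue correlation (R² 0.78).
- **IDP–Hydropathy stand-in.** The genuine constants of that scale are not
  redistributable here; `idp_hydropathy` resolves to a synthetic stand-in
  (mean of normalized Guy and Kyte–Doolittle with Pro forced to the unique
  minimum, its one documented property). Correlations computed against it
  do not reproduce the original scale's published values; supply the real
  constants as a scale file to get them.
- **Pro.** The default pH-dependent scale keeps Pro at its physical value;
  `ph_pro_corrected` (Pro := scale minimum) is a named option.
- **Global score.** Windowed-then-averaged ⟨H⟩ is the default (matches the
  center-assignment definition); the plain mean is a flag.
- **Within-margin points** count as their sign's class in confusion
  matrices and region calls; the low-confidence label appears in reports
  only.
- **UniProt retrieval** uses the standard library HTTP client with a disk
  cache and validates the accession format before any network call; it is
  never exercised by the tests.

## Known limitations

- Independent-site titration: no charge–charge coupling, no ionic-strength
  screening, no pKa shifts from local environment.
- The two-state hydropathy table approximates, not reproduces, the
  solvation-derived reference scale; absolute ⟨H_pH⟩ values (and hence
  scores near the boundary) shift if the real constants are substituted.
- The boundary was derived for global protein-scale C–H statistics;
  window-level scores inherit it unchanged.
- Synthetic benchmark sequences are compositionally idealized; published
  headline accuracies on curated folded/disordered databases are not
  reproducible from packaged data and require user-supplied datasets in the
  labeled-CSV schema.
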