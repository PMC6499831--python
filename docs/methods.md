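# Methods

This note documents the models, numerical choices, and known limitations
of `pihelix`, in the order data flows through the package.

## Backbone model and structure I/O

Structures (PDB/mmCIF, read via gemmi) are reduced to a backbone-only
model: per residue the N, Cα, C, O coordinates (Å), the one-letter code
(non-standard residues with a complete backbone are kept as `X` — the
annotation needs geometry, not identity), and φ/ψ in degrees. Alternate
locations resolve to the highest-occupancy atom (ties: first encountered).
Residues missing any backbone atom are dropped; a chain break is declared
wherever the C(i)–N(i+1) distance exceeds 2.5 Å, and dihedrals spanning a
break (or a terminus) are undefined. Residues are indexed 0-based and
contiguously per chain internally; author numbering is preserved for
output. Only the first model of multi-model files is used.

The classic `.dssp` text dialect is parsed with fixed column offsets;
hydrogen-bond partners, stored in the file as relative offsets against
DSSP's own sequential numbering, are converted to absolute indices (break
rows consume a sequence number but emit no residue). A writer for the same
dialect exists so the parser is pinned by write-then-read round-trips.

## Hydrogen bonds

Amide hydrogens are placed 1.0 Å from N along the reversed carbonyl C→O
direction of the preceding residue; prolines and chain-start residues get
no donor. Bonds are scored with the Kabsch–Sander electrostatic model,

    E = 0.084 · 332 · (1/r(O,N) + 1/r(C,H) − 1/r(O,H) − 1/r(C,N))  kcal/mol,

clamped at −9.9 kcal/mol; any pairwise distance < 0.5 Å is treated as a
clash error. Per donor, all acceptors at sequence separation ≥ 2 within a
9 Å Cα–Cα prefilter are evaluated and the two lowest-energy bonds with
E < −0.5 kcal/mol are stored. These are DSSP's conventions, adopted so
annotation can run identically with or without an external DSSP file; a
test asserts the prefiltered search equals exhaustive all-pairs evaluation.

## π-helix annotation

"Bond at i → i+5" means the carbonyl of residue *i* accepts from the amide
of residue *i+5*; the spanned range is *i* … *i*+5 inclusive. This makes
the length arithmetic exact: a run of *k* consecutive π bonds spans *k*+5
residues, so 2 bonds give the canonical 7-residue minimum and 9 bonds the
14-residue maximum seen in practice.

The algorithm erases all pre-existing `I` labels to `C` and re-marks a
range as `I` when (i) it holds ≥ 2 π-type bonds at consecutive acceptor
positions, each surviving the alternative-bond resolution for its donor
(lower energy wins; an exact tie resolves *toward* the π bond, since the
correction exists to recover π-helices masked by the α alternative);
(ii) at least one bond in the run has E ≤ −2.0 kcal/mol; and (iii) every
spanned residue's φ lies in (−180°, 0°) and ψ in (−120°, 45°). Residues
with undefined dihedrals (termini, breaks) pass the window test — the
alternative would categorically ban π-helices at chain ends. Re-marking
overwrites whatever 8-state label the range held. Runs must be strictly
consecutive; a gap splits the run. A run of exactly one qualifying bond
whose six spanned residues pass the windows is an α/π-bulge — bulges and
canonical π-helices are disjoint by construction.

Without a DSSP file the package computes bonds itself and reports
everything that is not a re-marked π-helix as coil; full 8-state labels
(H/G/E/B/S/T) are only available by supplying a `.dssp` file, because
re-implementing DSSP's complete assignment grammar is out of scope.

The production annotator is tested for exact agreement against a separate,
deliberately naive implementation that enumerates runs and checks the
three criteria literally, over hundreds of randomized bond/dihedral/label
instances, plus metamorphic properties (energy-gate monotonicity,
idempotence, segment-length arithmetic).

## Differential geometry

The Cα trace is interpolated by a natural cubic spline r(t) parametrized
by residue index. Curvature and torsion follow the standard space-curve
formulas κ = |r′×r″|/|r′|³ and τ = |(r′×r″)·r‴|/|r′×r″|² (units Å⁻¹,
invariant under rigid motion, scaling as 1/length). τ is reported as a
magnitude, with a signed variant available (positive for right-handed
helices).

Numerical details worth knowing:

- A cubic spline's third derivative is piecewise constant and represents
  r‴ best at interval midpoints; evaluating it naively at a knot leaves a
  half-interval phase error that does **not** vanish with knot density.
  The implementation therefore averages the left and right limits of r‴
  at interior knots, which restores second-order accuracy. With ~36 knots
  per turn, interior κ and τ agree with closed-form values on analytic
  helices to a few tenths of a percent.
- Natural boundary conditions leave a boundary layer of a few knots where
  third-derivative quantities are unreliable; the first and last two
  residues are flagged and excluded from segment averages (convergence
  tests use a wider interior margin of ~8 knots).
- Torsion is undefined where curvature vanishes (straight segments); the
  API raises rather than returning a junk value, and per-chain profiles
  carry NaN there.

Residues-per-turn uses the twist-angle method: for four consecutive Cα
positions the difference vectors of successive Cα–Cα steps point toward
the local helix axis, and the angle θ between consecutive difference
vectors is the per-residue twist, RPT = 360°/θ. Twists below 5° (near-
straight chains) are undefined. On parametric helices the estimate is
exact to within interpolation noise; on the ideal fixtures it gives 3.62
(α), 4.16 (π), 2.99 (3₁₀) residues/turn.

## Synthetic fixtures

`build_helix` places backbone atoms sequentially by internal coordinates
(natural-extension reference frame) from standard bond lengths and angles
(N–Cα 1.458 Å, Cα–C 1.525 Å, C–N 1.329 Å, C=O 1.231 Å; N–Cα–C 111.2°,
Cα–C–N 116.2°, C–N–Cα 121.7°; ω = 180°), the carbonyl O in the peptide
plane opposite the next N. The α (−57°, −47°) and 3₁₀ (−49°, −26°)
presets are the conventional ideals. Under *rigid* ideal bond geometry the
conventional π dihedrals (−76°, −41°) do not close the i → i+5
hydrogen-bond loop — real π-helices relax their bond angles — so the π
preset was calibrated once by grid search to (−62°, −62°), which yields
consecutive i → i+5 bonds at −2.6 kcal/mol (O···N 2.7 Å) dominating the
i → i+4 alternatives (−0.1 kcal/mol), RPT 4.16, and dihedrals inside the
helical windows; the value is frozen in code. The generated chains are
right-handed (positive signed torsion) and their φ/ψ round-trip through
coordinates to < 0.5°.

The sequence generator plants segment-structured 4-state labels (every
`I` run ≥ 7 residues; the I-start probability is solved from the target
π-residue fraction, valid up to 0.2) and emits integer PSSMs whose scores
carry class-conditional column biases (+4 on four class-specific columns,
Gaussian noise σ = 1.5) plus a mild compositional bias in the sequences
themselves, loosely mimicking real preferences (Asn/aromatics in π, small
residues in coil). This makes the planted signal strongly learnable by a
per-position classifier — deliberately so: passing the learnability test
demonstrates that the training loop, loss weighting, and model selection
work, **not** that real π-helices are predictable at this accuracy. Real
sequence–structure signal is far weaker, non-local, and entangled with
homology; none of that is emulated.

## Encoder

700×40 input frame: columns 0–19 one-hot amino acid (`X` → all-zero),
columns 20–39 the PSI-BLAST log-odds scores through a logistic sigmoid
(sigmoid of the raw integer scores, the convention of the architecture
family this model belongs to — sigmoid of probabilities would be nearly
constant). Sequences shorter than 700 are zero-padded entirely at one
end, the end drawn uniformly from the caller's seed, once per call;
sequences longer than 700 are rejected (the dataset rules discard them
upstream). A boolean mask records real rows; de-padding by the mask is
seed-independent.

## Network and training

The architecture is fixed by `ModelConfig`: three parallel length-
preserving 1-D convolutions (windows 3/5/7, 64 filters, tanh), per-branch
batch normalization (ε = 10⁻³, momentum 0.99, applied after activation),
concatenation to 192 features, position-wise dense 200 (ReLU), two
bidirectional LSTM layers of 200 units per direction (input and recurrent
dropout 0.5, gate order i/f/g/o, unit forget-gate bias, orthogonal
recurrent initialization, Glorot-uniform input weights), dense 200
(ReLU), and a 4-way softmax over (E, H, I, C). Ties in the argmax resolve
to the first class in that order.

The implementation is plain NumPy (float32) with hand-derived backward
passes, verified against central finite differences in float64 at every
parameter tensor. Training uses Adam (lr 3·10⁻⁴, β₁ 0.9, β₂ 0.999) on
weighted categorical cross-entropy: weight 0 on padding, 5 on true-π
positions, 1 elsewhere; batch size 16 (unspecified upstream, configurable).
Because all layers are length-agnostic and padded positions carry zero
loss, training batches are packed to their true sequence lengths rather
than the full 700-row frame — mathematically this only removes zero-loss
timesteps from the recurrences, and it is what makes CPU training of the
test-scale problems take ~1 minute instead of ~20.

Cross-validation builds 10 folds of equal size (±1) by greedy assignment
of sequences (largest π count first, seeded random tie-break) to the fold
with the smallest running π total. Each fold trains 50 epochs; the epoch
with the best validation π-F1 is kept. The ensemble averages member
probabilities — the simplest combination consistent with "10 models build
the final predictor"; selection-by-F1 and probability averaging are the
two places where the training protocol admits choices, and both are
documented here rather than hidden.

Checkpoints are `.npz` weight dictionaries written at run time; none are
shipped.

## Evaluation

Per-residue: 4×4 confusion over (E, H, I, C); for the π class, TP are
correctly predicted π residues, FN π residues predicted otherwise, FP
non-π predicted π; precision TP/(TP+FP), sensitivity TP/(TP+FN), F1 their
harmonic mean (0 when both vanish), Q the label-match fraction.

Per-segment: true and predicted π segments (maximal runs) are matched by
any ≥ 1-residue overlap. Matching is *not* one-to-one: one predicted
segment overlapping two true segments scores both as detected and itself
as matched once, because the definitions are phrased purely in terms of
non-overlap. Segment lists with internal overlaps are rejected as input
errors.

The PR curve evaluates precision and recall at every distinct score
threshold, anchors recall 0 at the precision of the most stringent
threshold, and integrates by trapezoid over recall (interpolated-precision
variants exist; this choice is pinned by an independent step-loop oracle
test). Constant scores collapse to precision = prevalence, which is also
reported as the random baseline. AUPRC is undefined without positive
residues.

The paired t-test on per-sequence F1 uses scipy's implementation with
explicit degenerate handling: all differences zero → p = 1; nonzero
constant differences → infinite statistic, p = 0, flagged. Callers are
expected to restrict input to sequences containing true π residues.

## Dataset rules

Filters: keep 30 ≤ length ≤ 700 (inclusive), resolution ≤ 2.5 Å
(inclusive; "lowest resolution" is read as numerically smallest Å, i.e.
best diffraction), X-ray only. Representative selection per cluster:
clusters with neither π-helices nor bulges take the best-resolution
member; π clusters choose among
bulge-free π members by resolution then longest π segment; clusters whose
π candidates all carry bulges yield none; ties break on id. The
train/test splitter swaps records greedily after a seeded random split
until the π-residue percentages agree within 0.02 percentage points
(configurable; infeasible tolerances return the best split with a
warning). Sequence clustering and sequence-to-structure matching are
consumed as precomputed tables — they require external search tools.

`relabel_dataset` applies the annotation algorithm to entries with
matched structures; by construction only `I` and `C` labels can change,
which a test asserts per position. Entries whose structure sequence
disagrees with the dataset sequence are skipped and reported.

## Test-scale choices

Test and acceptance runs use desk-scale problem sizes chosen once:
30–100 synthetic sequences of 60–120 residues, π-residue rate 0.08,
200 randomized instances for oracle-equivalence checks, 120-knot analytic
helices at 10°/knot for geometry convergence. One 50-epoch training fold
at the full hyperparameters on the 30-sequence set reaches training π-F1
0.92–0.97 across seeds in about a minute on one CPU.

## Known limitations

- Full-scale benchmark numbers (precision/sensitivity on PDB-derived test
  sets) require the real training corpus, database-searched PSSMs, and
  trained weights; nothing here claims them.
- 8-state annotation richness requires an external `.dssp` file; the
  internal path reports π-vs-coil only.
- The NumPy network is CPU-sized: it trains the test-scale problems
  comfortably but is not meant for the 20k-sequence regime.
- Bifurcated and side-chain hydrogen bonds, NMR ensembles beyond the
  first model, and sliding-window handling of > 700-residue sequences are
  unimplemented.
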