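# Methods

This note records the models, conventions and numerical choices behind
`fieldqsar`, in the order the pipeline applies them.

## Activities

Measured potencies (IC50/EC50/Ki) are converted to mol/L (accepted units:
M, mM, µM, nM, pM — anything else is rejected rather than guessed) and
transformed to p = −log₁₀(concentration), so larger p means more potent
and positive model coefficients mark activity-improving field changes.
The measure type is recorded but mixing measure types in one dataset is
not forbidden; that judgement is left to the user. A dataset whose
p-values span less than 2 log units draws a warning: differences that
small are hard to distinguish from experimental variability. Duplicate
molecule ids are a hard error, never silently de-duplicated.

## Alignment

The template may be the most active, least active, or most flexible
training molecule. Flexibility is measured as the count of rotatable
bonds, defined explicitly as single, acyclic bonds between heavy atoms
whose endpoints each have at least two heavy-atom neighbours; ties break
to the lexicographically first id. Superposition is rigid-body
least-squares (Kabsch, SVD with reflection correction) over a mapped atom
set — supplied as a CSV of index pairs or derived from the RDKit maximum
common substructure. At least three non-collinear pairs are required;
collinear mappings are rejected as degenerate. The full coordinate set of
each molecule is transformed; the template is untouched. Flexible
(torsional) alignment and field/shape-overlap scoring are out of scope.

## Grid

The lattice covers the bounding box of all aligned atoms expanded by the
grid extension GE on every side; points per axis = floor(span/GS) + 1,
with the lattice centered on the expanded box, so every atom keeps at
least GE − GS of margin on every face. Point order is x-fastest
(index = i + nx·(j + ny·l)) and frozen for reproducibility. The grid
origin is derived from the data, recorded in the GridSpec, and reused
verbatim for test-set fields — predictions are only defined on the
training lattice. Settings outside the usual scan ranges (GS 1–3 Å,
GE 5–10 Å, cutoff 20–40 kcal/mol, minimum sigma 0.05–2) warn but do not
refuse: published models do occasionally sit outside them.

## Fields

Steric: 12-6 Lennard-Jones with R_ij = R_probe + R_atom and
ε_ij = √(ε_probe·ε_atom). Parameters live in a bundled, versioned CSV in
Tripos/Sybyl style (per Sybyl atom type: vdW radius in Å, well depth in
kcal/mol) and can be edited without touching code. Electrostatic:
Coulomb with the constant 332.0716 kcal·Å·mol⁻¹·e⁻² and, by default, the
distance-dependent dielectric ε(r) = r; a constant dielectric is
available. The probe charge is +1 e for all six probe types,
configurable. Distances are floored at 1e-6 Å to guard the singularity
at coincident points.

Cutoff semantics follow classic CoMFA practice: steric energies are
truncated at +cutoff (implemented as a symmetric clamp — the attractive
branch cannot approach the cutoff in practice, so only the truncation is
ever active), electrostatic energies are clamped to ±cutoff, and at
lattice points buried inside a molecule (pre-truncation steric ≥ cutoff)
the electrostatic entry is replaced by the column mean over the
non-buried molecules, since the probe cannot physically occupy that
point; plain clamping is available as an option.

The minimum-sigma filter masks columns whose sample standard deviation
(ddof = 1) is strictly below MS; a column exactly at the threshold is
kept. The matrix retains all columns so maps and reports can still see
the full lattice; only modeling uses the mask. For combined
steric+electrostatic models, block scaling divides each field's columns
by the square root of the block's total column variance, so both fields
contribute equal total variance; scaling factors are recorded in the
model and reapplied to any new data.

## PLS

Single-response NIPALS with mean-centering of X and y and no per-column
autoscaling (all scaling lives in the block-scaling step — the CoMFA
convention, and the only way coefficients stay interpretable per lattice
point). The weight vector of each component is X′y of the deflated data,
so the algorithm is deterministic; the classic u→w→t→c→u loop is retained
with tolerance 1e-12 and a 500-iteration cap purely as a safety net
(single-y NIPALS converges in one pass). Components whose score variance
falls below 1e-12 of the first component's end extraction early. With as
many components as the centered matrix has rank, the fit equals ordinary
least squares, which the tests verify against the normal equations; a
scikit-learn cross-check on under-determined data guards the wide-matrix
regime. Models serialize to .npz and round-trip bit-exactly.

r² = 1 − SS_res/SS_tot. SDEC and SDEP are both √(Σ(y−ŷ)²/n) — n, not
n−1, a choice stated here openly since both conventions exist — differing
only in whether ŷ are fitted values or out-of-sample predictions.

## Validation

Cross-validation refits the entire preprocessing inside every fold:
centering and block re-scaling are recomputed from the fold's training
rows only, so no information leaks from held-out molecules. q² uses the
stricter denominator — deviations of the held-out responses from the
*training-fold* mean; the global-mean variant is available behind a flag.
LSO defaults to 5 groups × 20 seeded repeats, averaging q² and SDEP over
repeats; LSO with as many groups as molecules reproduces LOO exactly
(fold order is normalized so even the floating-point accumulation
matches). Y-scrambling (default 20 scrambles) permutes the response with
a seeded generator, rejecting the identity permutation, and records
r²_YS and q²_YS per scramble; both the mean and the maximum are reported
since either summary appears in the literature. The optimal component
count (ONPC) is the argmax of the q² profile, ties to fewer components.

External prediction computes the test molecules' fields on the training
grid with the training settings, selects exactly the model's retained
columns via its provenance, and reports SDEP_ext and r²_pred. Test
molecules extending beyond the lattice box draw a warning (their fields
are implicitly truncated at the box) but are still predicted; r²_pred is
undefined (NaN) for fewer than two test molecules.

## Contour maps

Map values are PLScoeff_i × statistic_i per retained lattice point. The
default statistic is the column standard deviation ("StDev*Coeff"): a
mean-based map is dominated by where field magnitude is large rather than
where it discriminates between molecules, so the mean statistic is
provided only as an alternative. With the negative-log activity
transform, positive steric values mark regions where added bulk raises
predicted potency; positive electrostatic values (probe +1 e) mark
regions favoring positive potential. Display isolevels default to the
80th percentile of positive values and the corresponding percentile of
negative values. Exports are Gaussian cube (coordinates ×1.8897259886
Å→Bohr, one placeholder atom for strict readers) and OpenDX, both with
z-fastest file order, masked points written as exact zeros, and 8
significant digits so round trips are faithful to 1e-6.

## Synthetic data generator

The generator emulates the congeneric series a field-based QSAR is built
from: a rigid benzene-like six-ring (C.ar, small negative charges) with
three substitution sites, each drawing from a palette of six single-atom
substituents (H, F, Cl, OH-oxygen, NH₂-nitrogen, CH₃-carbon) spanning
both steric bulk and partial charge (−0.5 to +0.1 e). All molecules
share identical core coordinates — the set is born aligned — so
alignment tests can corrupt copies with known rigid transforms and verify
recovery. Default conditions: 25 molecules, activity noise 0.1 log
units, probe C.3, GS 1 Å, GE 5 Å, cutoff 30 kcal/mol, MS 0.05 (mid-range
values of the usual scan grids).

Activities are planted as a linear function of the molecules' own field
values at chosen lattice points plus Gaussian noise. Planted points are
picked deterministically as the most discriminative (maximum column
standard deviation) lattice point near each substituent site — where a
real structure–activity signal would live; for electrostatic sites the
search avoids columns at the cutoff clamp. Because the lattice is mirror
symmetric about the molecular plane (and, for on-axis sites, about the
site axis), the chosen column can have mirror twins that are numerically
indistinguishable (1 − correlation < 1e-6); the weight is split over the
whole equivalent set, since no estimator could attribute the signal to
one twin over the other. Weights are normalized by the column's value
range so each site contributes on the order of one log unit, yielding
activity spans of 3–4 log units — comfortably above the 2-log guidance
and typical of a usable QSAR series.

What the generator does not emulate: conformational flexibility,
alignment uncertainty, correlated experimental error, activity cliffs
from binding-mode switches, and real charge models. Passing tests on
this fixture therefore demonstrate the correctness of the machinery —
fields, PLS, validation, maps — not the predictive power of 3D QSAR on
any real target.

## Problem sizes

The default study (25 molecules, ≈2 600 lattice points per field) was
chosen so the full pipeline — component selection, LOO and LSO
cross-validation, 20 Y-scrambles and contour export — completes in a few
seconds on one CPU, while remaining over-determined enough in columns
(≈100× more descriptors than molecules) to exercise the wide-matrix
regime PLS exists for.

## Known limitations

- No GRID-style directional or H-bond probes, desolvation, or QM
  charges; charges are taken from the input files as-is.
- One conformer per molecule; conformational search is delegated to
  external tools.
- SMILES input requires a separate 3D-coordinate source; there is no
  internal 2D→3D embedding.
- Region/variable selection beyond minimum sigma is not implemented.
- The sweep's best-model rule is highest q², tie-break by r²; other
  orderings exist in the literature.
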