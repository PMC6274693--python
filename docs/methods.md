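# Methods

## Problem and model

`mixtox` predicts the acute toxicity of binary chemical mixtures, expressed
as −log10(EC50mix) in mol/L, from the structures of the two pure components
and their toxic-unit ratio. The underlying assumption is concentration
addition: if each component contributes in proportion to its toxic-unit
fraction x_i (the fraction of the mixture's total toxic units carried by
component i, with Σx_i = 1), then any per-compound molecular descriptor D_i
can be aggregated into a *hypothetical* mixture descriptor

    D_mix = Σ_i x_i · D_i ,

a convex combination of the component values. Three descriptors of the pure
compounds drive the models:

- **NTB** — the number of triple bonds in the molecular graph (nitrile and
  alkyne groups). Weighted mixing makes it a real number; it is never
  re-rounded.
- **ACIC2** — the average complementary information content of order 2,
  `log2(n) − IC_2` bits, where n counts all atoms including hydrogens and
  IC_2 is the Shannon entropy of the distribution of atoms over order-2
  topological equivalence classes. Large, symmetric molecules score high;
  structurally diverse ones score low.
- **QMaxC** — the maximum partial charge over carbon atoms under a
  Sanderson electronegativity-equalization (Zefirov-type) scheme, a proxy
  for hydrogen-bond-acceptor strength and surface charge concentration.

Two regression models map the three mixture descriptors to toxicity: a
multiple linear regression selected by forward stepwise search, and a
radial basis function network (Gaussian hidden units, linear output layer).

## Descriptor computation

SMILES are parsed with RDKit and hydrogens are made explicit; all
descriptors operate on the hydrogen-complete graph. Equivalence classes for
IC_k start from element symbols (order 0) and are refined k times by the
multiset of (bond order, neighbor class) pairs; signatures are sorted
tuples, so partitions are independent of atom numbering, and order k always
refines order k−1. Aromatic bonds enter signatures as bond order 1.5, which
keeps classes independent of the Kekulé structure chosen; for NTB the graph
is kekulized first (aromatic rings contribute no triple bonds either way).

The charge scheme computes the molecular electronegativity S_mol as the
geometric mean of atomic Sanderson values and assigns each atom

    q_i = (S_mol − S_i) / (2.08 · sqrt(S_i)) .

This one-shot scheme does not conserve charge for general molecules, so a
uniform shift is applied to make the charges sum to the net formal charge
(exactly, to 1e−12). The Sanderson table ships as an editable JSON config
(`data/sanderson_electronegativity.json`, stability-ratio scale: H 3.55,
C 3.79, N 4.49, O 5.21, ...); elements outside the table raise a
configuration error rather than guessing.

The commercial descriptor package used to derive the published models does
not document its exact IC/CIC and charge parameterizations, and the
per-compound descriptor values were never printed; numeric descriptor
values computed here therefore differ from the originals, and nothing in
the reproduction suite compares descriptor values to published numbers.
Model *procedures* are validated instead on synthetic data of known
structure (below).

## Linear modeling

`OLSRegressor` fits least squares with an intercept and refuses degenerate
inputs (fewer than p+2 rows, constant columns, rank-deficient designs)
rather than pseudo-inverting. Fit statistics follow the conventions of the
source tables:

- R² is the squared Pearson correlation between fitted and observed values
  (equal to the coefficient of determination here).
- Two RMS forms are exposed: plain `sqrt(SSE/N)` and the standard error of
  estimate `sqrt(SSE/(N−p−1))`. The published linear-model statistics are
  reproduced exactly by the df-corrected form (0.599 and 1.042 on the
  bundled tables), while the published RBF-network training RMS matches the
  plain form; the reproduction module uses the matching convention per
  model family and says so explicitly.
- F = (R²/p)/((1−R²)/(N−p−1)); leave-one-out q² = 1 − PRESS/SS_tot, computed
  exactly through the hat matrix.

The heuristic pre-screen mirrors the classic descriptor-selection rules:
drop missing/constant columns, require a one-parameter regression F ≥ 1.0
and |t| ≥ 0.1, then greedily remove the later member of any pair with
|r| > 0.80. `ForwardStepwiseRegressor` adds descriptors greedily by fitted
R² and stops when the best gain drops below 0.02 (plain R², not adjusted —
the stopping rule's variant is configurable via `delta_r2_break` but the
plain form is the default). Ties break on the lowest column index; an
unreachable breakpoint yields the intercept-only model.

Three published reference models are bundled as constants (single-compound,
mixture training, and the mixture model refit after outlier removal), with
their printed coefficients bit-exact.

## RBF network

`RBFNetworkRegressor` uses Gaussian units h_j(x) = exp(−‖x−c_j‖²/r²) with a
single shared width, centers drawn from the training points by greedy
forward subset selection (each step adds the point that most reduces
training RMS; ties break to the lowest index, making training fully
deterministic), and a least-squares linear output layer with bias. The
width is either fixed or scanned over 0.1–4.0 in steps of 0.1; the scan
criterion is leave-one-out RMS of the output layer (computed through the
hat matrix), with plain training RMS available as an alternative. Ties go
to the smallest width.

Inputs are standardized by training mean and standard deviation before any
distance computation, and the transform is stored with the network. This is
a deliberate choice the original protocol is silent on: QMaxC (~0.01–0.05)
and ACIC2 (a few bits) live on very different scales, and a shared
Euclidean width on raw coordinates would make the 0.1–4.0 grid meaningless
for one of them. The module-level wrappers (`forward_center_selection`,
`width_scan`) skip standardization so widths keep the caller's units.

The published architecture is ambiguous about its input dimension (a
"2-14-1" layout next to three descriptors and a singular "hypothetical
descriptor"); the input dimension here is simply the number of descriptor
columns supplied (three for the bundled pipeline), and the preset
`reference` (14 hidden units, width 1.2) reproduces the published
hyperparameters.

## Validation toolkit

All statistics used to judge the models are implemented in
`mixtox.validation`: R², RMS, F, leave-one-out q², the external-validation
criteria (through-origin slopes k = Σyŷ/Σŷ², k′ = Σyŷ/Σy², coefficients
R0² and R0′², and the four pass/fail inequalities q² > 0.5, R² > 0.6,
(R²−R0²)/R² < 0.1, 0.85 ≤ k ≤ 1.15), VIF = 1/(1−r²), descriptor mean
effects MF_j = β_jΣ_i d_ij / Σ_j β_jΣ_i d_ij (an algebraic partition of
unity), Y-randomization (seeded response shuffling; failed inner fits are
recorded per repeat, not fatal), grouped leave-many-out cross-validation
over the A/B/C/D/T subset labels, and the leverage / Williams-plot
applicability domain.

Leverage is the hat-matrix quadratic form h = xᵀ(XᵀX)⁻¹x on the design
including the intercept column. The leverage limit defaults to h* = 3m/n
with m the descriptor count — the convention of the source protocol — with
the more common 3(m+1)/n available via `h_star_formula="standard"`.
Standardized cross-validated residuals are externally studentized
(leave-one-out) residuals for training samples and
prediction-variance-standardized residuals (√(1+h)) for external samples;
|residual| > 3 flags Y-outliers.

## Synthetic data generator

`generate_synthetic` emulates the two structure–activity shapes the models
assume. Linear mode draws descriptor-like columns (an integer triple-bond
count in 0–2, an information content in 1.5–4.5 bits, a partial charge in
0.02–0.12) and applies a stated linear combination; its default
coefficients are the published mixture-model values (−0.405, −0.688, 1.847,
63.611). RBF mode draws uniform points in the unit cube and evaluates a
known mixture of three Gaussian bumps (default width 1.2, matching the
published network). Gaussian noise with configurable SD (default 0.3,
roughly the magnitude of the published training residuals) is added; every
draw is governed by a single integer seed.

The generator emulates the *shape* of the relationships, not real
chemistry: its columns are independent, whereas real descriptors correlate
(the published pairwise correlations reach 0.74), and its noise is
homoscedastic Gaussian, whereas assay error is not. Passing recovery tests
therefore demonstrates that the estimators implement their procedures
correctly, not that the models would achieve any particular accuracy on new
chemicals.

## Reproduction of published statistics, and known discrepancies

The source tables print experimental and model-predicted activities for
all 55 compounds and 99 mixtures, so the headline statistics are
recomputed directly from those columns (`mixtox.reproduce`, CLI
`mixtox reproduce`, and `scripts/acceptance.py`). At the tolerances
absorbing the two-decimal rounding of the printed columns (±0.005 for R²,
±0.01 for RMS and k, three decimals for VIF), eleven of thirteen checks
pass. Two do not, under any standard RMS convention (plain, df-corrected,
or pooled over all 99 rows):

- the published external-test RMS of the linear model, 0.691 (best
  recomputation 0.703, df-corrected form);
- the published external-test RMS of the RBF network, 0.547 (best
  recomputation 0.591, plain form).

Both are reported as failures rather than silently re-toleranced; the
corresponding test cases are kept red deliberately. Statistics that depend
on the unprinted descriptor values (the stepwise selection outcome on the
original 614-descriptor pool, refit coefficients, the cross-validation
tables, the identity of the two applicability-domain outliers) are
validated by parameter recovery on synthetic data instead.

## Problem sizes and numerical choices

All bundled-data computations are desk-scale (55 compounds, 99 mixtures).
Synthetic checks use n = 50–200 samples; the RBF width-recovery check uses
n = 80 points and 6 hidden units, and the q²-versus-R² simulation uses 100
seeded repetitions at n = 25. Floating-point tie-breaks are deterministic
everywhere (lowest index for stepwise and center selection, smallest width
in the scan); charge conservation is enforced to 1e−12; descriptor
invariance under SMILES rewriting is exact to 1e−12.

## Known limitations

- Descriptor values are parameterization-dependent and not interchangeable
  with those of the original commercial software; models refit on this
  package's descriptors reach R² ≈ 0.75 on the bundled training mixtures
  (versus 0.869 published with the original descriptor values).
- Only binary mixtures are exercised by the bundled data; the weighted-sum
  descriptor generalizes to more components and is property-tested, but no
  higher-order fixture exists.
- The applicability-domain defaults follow the source protocol (h* = 3m/n),
  which is tighter than the common 3(m+1)/n; users comparing against other
  QSAR software should set the formula explicitly.
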