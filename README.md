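# mixtox

QSAR models for the toxicity of binary chemical mixtures.

Environmental pollutants act as mixtures, but toxicity data are mostly
measured on single chemicals. Under concentration addition, a mixture can
be described by *hypothetical descriptors*: toxic-unit-fraction-weighted
sums of per-compound molecular descriptors,

    D_mix = Σ_i x_i · D_i ,        Σ_i x_i = 1 ,

which slot directly into ordinary QSAR machinery. `mixtox` implements this
pipeline end to end for −log10(EC50) prediction (mol/L):

- **Descriptors** (`mixtox.chem_descriptors`): from SMILES, via RDKit —
  NTB (triple-bond count), ACIC2 (order-2 average complementary
  information content, `log2 n − IC_2` bits over the hydrogen-complete
  graph), and QMaxC (maximum Sanderson electronegativity-equalization
  partial charge on carbon).
- **Mixture descriptors** (`mixtox.mixture_descriptors`): the weighted sums
  above, from toxic-unit ratio strings like `"13396:1"`.
- **Models** (`mixtox.mlr`, `mixtox.rbfnn`): scikit-learn-style estimators —
  `OLSRegressor`, `ForwardStepwiseRegressor` (heuristic pre-screen +
  greedy R² selection with a 0.02 gain breakpoint), and
  `RBFNetworkRegressor` (Gaussian units, forward center selection,
  width grid scan 0.1–4.0, least-squares output layer). The published
  reference models ship as constants (`mixtox.mlr.REFERENCE_MODELS`).
- **Validation** (`mixtox.validation`): R², RMS, F, leave-one-out q²,
  external-validation criteria with through-origin slopes k/k′ and R0²,
  VIF, descriptor mean effects, Y-randomization, grouped leave-many-out
  cross-validation, and the leverage/Williams applicability domain.
- **Data** (`mixtox.dataset_io`): bundled tables of 55 pure compounds
  (with curated SMILES) and 99 binary mixtures with experimental and
  model-predicted activities, plus a seeded synthetic-data generator.

## Worked example

```python
from mixtox import compute_descriptors, hypothetical_descriptor, REFERENCE_MODELS
import pandas as pd

d_ald = compute_descriptors("CC=O")       # acetaldehyde
d_mal = compute_descriptors("N#CCC#N")    # malononitrile
mix = hypothetical_descriptor([d_ald, d_mal], [0.5, 0.5])   # 1:1 toxic units
print(mix)
X = pd.DataFrame([{"ntb": mix.ntb, "acic2": mix.acic2, "qmaxc": mix.qmaxc}])
print(REFERENCE_MODELS["mixture_training"].predict(X)[0])
```

prints

```
DescriptorVector(ntb=1.0, acic2=0.7682062501545337, qmaxc=0.018008403287766338)
1.4714094855735282
```

The mixture inherits one (weighted) triple bond from malononitrile's two,
and the reference linear model maps the descriptor triple to a predicted
mixture toxicity of −log10(EC50mix) ≈ 1.47, i.e. an EC50 of about 34 mmol/L.
Descriptor values are parameterization-dependent (see `docs/methods.md`):
they are internally consistent but not numerically interchangeable with
those of the commercial package behind the original reference models.

The same pipeline runs from the shell:

```
mixtox descriptors --output desc.csv          # 55 compounds -> 3 descriptors
mixtox mixture --descriptors desc.csv --output mix.csv   # 99 weighted rows
mixtox fit --input data.csv --model rbfnn --n-hidden 14 --width 1.2
```

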