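{
  "_comment": "Sanderson electronegativities (stability-ratio scale) used by the geometric-mean charge-equalization scheme. Editable configuration: values per element symbol.",
  "H": 3.55,
  "Li": 0.74,
  "Be": 1.99,
  "B": 2.93,
  "C": 3.79,
  "N": 4.49,
  "O": 5.21,
  "F": 5.75,
  "Na": 0.70,
  "Mg": 1.56,
  "Al": 2.22,
  "Si": 2.84,
  "P": 3.43,
  "S": 4.12,
  "Cl": 4.93,
  "K": 0.42,
  "Br": 4.53,
  "I": 4.00
}
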