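# Fixture errata

Corrections applied while transcribing the source data tables into
`compounds.csv` and `mixtures.csv`:

- Compound 25# (atrazine): residual printed as "0863"; stored as 0.863
  (consistent with predicted 7.543 − experimental 6.68).
- Compound 20# (acetonitrile): CAS printed as "1975-5-8"; stored as the
  registry number 75-05-8.
- Mixture table: the row printed with No. "67" immediately after row 56
  (pair 9#:19#) is a misprint for 57; rows are renumbered sequentially
  1..99 in `combo_id` and the printed label is kept in `printed_no`.
- Mixture row 58: pair printed "10#19#" (missing separator); stored as
  10#:19#.
- Toxic-unit fractions are recomputed at load time from the ratio string
  at full precision; the CSV stores the ratio string verbatim.
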