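# Reference signature tables

Three published intersected peptide signatures from the two-study murine
lupus immunosignaturing experiment, transcribed as TSV:

| file | signature | rows |
| --- | --- | --- |
| `diagnostic_lupus.tsv` | diagnostic peptides of lupus (Study 1 ∩ Study 2) | 58 |
| `behavior_diagnostic.tsv` | diagnostic peptides of altered forced-swim behavior | 39 |
| `predictive_lupus.tsv` | predictive peptides of lupus | 18 |

Columns: `sequence` (20-mer ending in the GSC linker), `ratio_study1` and
`ratio_study2` (case/control binding ratios that passed the mean + k·SD
cutoff in each study), and boolean `in_*` cross-membership flags (`x` =
flagged in the printed table). Peptide ids are the sequences themselves,
since the published tables carry no array ids.

## Known printed inconsistencies (quarantined)

The cross-membership check marks in the printed tables disagree with the
tables' own member lists in exactly two places; the TSVs transcribe the
marks as printed, and consistency tests must exclude these rows:

1. `behavior_diagnostic.tsv`, row `LAFAWKPDPWQSLVTKFGSC`: not flagged as
   shared with the diagnostic-lupus set, although the sequence appears in
   `diagnostic_lupus.tsv` (which does flag it in the other direction).
2. `predictive_lupus.tsv`, row `KIWAMRKPRYQYWNQPAGSC`: flagged as shared
   with the diagnostic-lupus set, but the sequence does not appear in
   `diagnostic_lupus.tsv`.

All other flags agree with the computed pairwise intersections
(58 ∩ 39 tables share 23 sequences, 58 ∩ 18 share 3, 39 ∩ 18 share 0).
Flags against the 96-peptide behavior-predictive set cannot be audited —
that set was never published.
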