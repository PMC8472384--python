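# lofburden

Rare loss-of-function (LOF) variant prioritization and domain-restricted
burden testing for case-control cohorts, with exact association statistics
against frozen reference-population allele counts.

The package implements a small, fully tested pipeline:

1. **variant annotation** — parse cDNA coding-change strings in two dialects
   (`c.C2014T` and `c.2014C>T`), classify consequences (stop-gain,
   frameshift, in-frame indel, missense, synonymous) on a transcript model,
   map changes to protein residues (`residue = (pos - 1) // 3 + 1`) and
   named domain intervals, and filter to deleterious variants (LOF always;
   missense at CADD >= 25 by default) with a genomic-position blocklist.
2. **cohort burden** — build cohort strata and combined sets from a config
   file (allele totals are always 2N), count carriers/carrier alleles per
   variant set and cohort, and produce a carrier census with per-domain
   carrier fractions.
3. **association statistics** — unconditional sample odds ratio
   `(a*d)/(b*c)` (with `inf`/`0` conventions for empty cells) and the
   two-sided exact p-value under the minimum-likelihood rule (sum of
   hypergeometric probabilities no larger than the observed one, with the
   `1 + 1e-7` relative guard), against internal cohorts or frozen reference
   populations.
4. **synthetic cohorts** — seeded genotype simulators emitting the same TSV
   dialect (and minimal VCF), plus Monte-Carlo type-I-error calibration and
   power estimation of the exact test.
5. **CLI / reports** — orchestration, deterministic TSV/Markdown/JSON
   reports with a machine-readable sidecar carrying every raw fraction,
   p-value and 2x2 table.

Bundled under `src/lofburden/data/` are plain-text fixtures for the RAD50
(NM_005732) familial-ESCC analysis: the per-variant carrier table, the
Henan cohort configuration, frozen gnomAD v2.1.1 allele counts (East Asian
and all populations), and the transcript/domain model (zinc-hook domain at
residues 635-734).

## CLI

```sh
lofburden annotate --out annotated.tsv                 # parse + classify
lofburden burden --variant-set all_lof --out b.tsv     # per-cohort burden
lofburden reproduce-tables --out-dir reports/          # discovery + combined grids
lofburden assoc --out-dir reports/                     # combined grid only
lofburden simulate --spec spec.json --out-dir sim/     # synthetic cohorts
lofburden calibrate --n1-alleles 2088 --n2-alleles 4490 \
    --frequency 0.001 --replicates 5000 --out cal.json # type-I error
```

All subcommands default to the bundled fixture inputs; pass `--variants`,
`--transcript`, `--cohorts` or a `--config` JSON/YAML to use your own.
Exit codes: 0 ok, 2 config error, 3 validation error, 4 enumeration guard.

## Layout

```
src/lofburden/
  coding.py       coding-change parsing / canonical form
  transcript.py   transcript model, codon arithmetic, domain mapping
  consequence.py  consequence classification
  variants.py     variant records, TSV + VCF input, deleterious filter
  cohorts.py      strata/sets, variant sets, burden counts, census
  stats.py        contingency tables, exact test, odds ratios, scans
  simulate.py     synthetic cohorts, calibration, power
  reports.py      run config, discovery/combined reports
  cli.py          click CLI
  datasets.py     bundled fixture accessors
  data/           plain-text fixture inputs
```
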