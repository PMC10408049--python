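# Template for reproducing the published plasma-caffeine cis-MR analysis.
#
# Fill in the paths below with the study's supplementary summary-statistic
# tables (exposure associations and per-outcome PGC/UKB + FinnGen
# associations, exported as TSV with the canonical columns
# rsid/chr/pos/ea/oa/eaf/beta/se/pval/n) and an LD correlation matrix for
# the instrument variants estimated from the 1000 Genomes European
# subsample. All thresholds and region definitions below are the analysis
# defaults and should not need editing.
#
# Run with:  cismr mr --config configs/real_data_template.yaml --out results/real

exposure:
  path: PATH/TO/plasma_caffeine.tsv   # SD-unit exposure GWAS (n = 9876)
  trait: plasma caffeine

ld: PATH/TO/instrument_ld_1kg_eur.tsv # signed r, TSV, rsids in header + first column

outcomes:
  - name: anorexia nervosa
    sources:
      - {path: PATH/TO/anorexia_pgc.tsv, label: pgc}
      - {path: PATH/TO/anorexia_finngen.tsv, label: finngen}
  - name: bipolar disorder
    sources:
      - {path: PATH/TO/bipolar_pgc_ukb.tsv, label: pgc_ukb}
      - {path: PATH/TO/bipolar_finngen.tsv, label: finngen}
  - name: major depressive disorder
    sources:
      - {path: PATH/TO/mdd_pgc_ukb.tsv, label: pgc_ukb}
      - {path: PATH/TO/mdd_finngen.tsv, label: finngen}
  - name: schizophrenia
    sources:
      - {path: PATH/TO/schizophrenia_pgc.tsv, label: pgc}
      - {path: PATH/TO/schizophrenia_finngen.tsv, label: finngen}

regions:                               # GRCh37, Ensembl gene bounds
  - {name: AHR,    chrom: 7,  start: 17338246, end: 17385776, flank: 100000}
  - {name: CYP1A2, chrom: 15, start: 75041185, end: 75048543, flank: 100000}

selection:
  p_threshold: 5.0e-5                  # region-wide Bonferroni-scale cutoff
  clump_r2: 0.3
  clump_window_kb: 10000
  m_total: 955                         # variants measured within the two regions

eaf_ambiguity_band: 0.08
fiqt: true
leads: [rs4410790, rs2472297]          # AHR and CYP1A2 lead variants
seed: 1
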