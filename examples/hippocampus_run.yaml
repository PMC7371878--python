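# Hippocampus neighborhood analysis at the published study settings:
# 80% frequency threshold for each single hippocampus, 90% for the union
# of the two neighbor sets; set sizes up to 4; chi-square at alpha = 0.01
# with Holm-Bonferroni correction; score cutoffs 17 (PMAT24) and 36 (IWRD),
# both the sample medians of the cohort the method was developed on.
#
# Point manifest/phenotype at your own cohort, or generate a synthetic one:
#   fnnm simulate --out cohort/ --seed 1
manifest: cohort/manifest.csv
nodes: cohort/nodes.txt
phenotype: cohort/phenotype.csv
output: results/hippocampus
analyses:
  - name: left_pmat
    targets: [Left-Hippocampus]
    test: PMAT24_A_CR
    cutoff: 17
    threshold: 0.8
    max_size: 4
    alpha: 0.01
  - name: right_pmat
    targets: [Right-Hippocampus]
    test: PMAT24_A_CR
    cutoff: 17
    threshold: 0.8
    max_size: 4
    alpha: 0.01
  - name: union_pmat
    targets: [Left-Hippocampus, Right-Hippocampus]
    test: PMAT24_A_CR
    cutoff: 17
    threshold: 0.9
    max_size: 4
    alpha: 0.01
  - name: left_iwrd
    targets: [Left-Hippocampus]
    test: IWRD_TOT
    cutoff: 36
    threshold: 0.8
    max_size: 4
    alpha: 0.01
  - name: right_iwrd
    targets: [Right-Hippocampus]
    test: IWRD_TOT
    cutoff: 36
    threshold: 0.8
    max_size: 4
    alpha: 0.01
  - name: union_iwrd
    targets: [Left-Hippocampus, Right-Hippocampus]
    test: IWRD_TOT
    cutoff: 36
    threshold: 0.9
    max_size: 4
    alpha: 0.01
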