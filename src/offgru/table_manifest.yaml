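# Published off-target benchmark datasets: positive/negative counts,
# printed imbalance ratios (negative/positive, one decimal) and category.
# Rows where the printed ratio or count is internally inconsistent with
# the stated sample counts are flagged; the printed values are stored
# verbatim either way.
datasets:
  - name: "Dhanjal et al."
    cell_type: "Human cell line"
    n_positive: 9214
    n_negative: 9917
    imbalance_ratio: 1.10
    ir_decimals: 2
    category: mismatch
    flagged: true   # 9917/9214 = 1.08, printed 1.10
  - name: "II1"
    cell_type: "A357, HT29, 293T"
    n_positive: 2273
    n_negative: 2580
    imbalance_ratio: 1.14
    ir_decimals: 2
    category: mismatch
    flagged: false
  - name: "CHANGE-seq"
    cell_type: "Human primary T cells"
    n_positive: 67476
    n_negative: 2806151
    imbalance_ratio: 41.6
    category: mismatch
    flagged: false
  - name: "I1"
    cell_type: "U2OS, HEK293t, K562, PGP1"
    n_positive: 7371
    n_negative: 577577
    imbalance_ratio: 78.4
    category: mismatch_and_indel
    flagged: false
  - name: "K562"
    cell_type: "K562"
    n_positive: 120
    n_negative: 20199
    imbalance_ratio: 168.3
    category: mismatch
    flagged: false
  - name: "HEK293t"
    cell_type: "HEK293t"
    n_positive: 536
    n_negative: 132378
    imbalance_ratio: 247.0
    category: mismatch
    flagged: false
  - name: "BE3"
    cell_type: "HEK293t"
    n_positive: 83
    n_negative: 93434
    imbalance_ratio: 1125.7
    category: mismatch
    flagged: false   # ratio consistent; positive count disputed elsewhere (79 vs 83)
  - name: "II5"
    cell_type: "EGFP, U2OS"
    n_positive: 54
    n_negative: 95775
    imbalance_ratio: 1773.6
    category: mismatch
    flagged: false
  - name: "I2"
    cell_type: "U2OS"
    n_positive: 50
    n_negative: 231883
    imbalance_ratio: 4277.7
    category: mismatch_and_indel
    flagged: true   # 231883/50 = 4637.7, printed 4277.7
  - name: "II6"
    cell_type: "HCT116, HEK293t, HL60, Kbm7, K562, U2OS"
    n_positive: 52
    n_negative: 383407
    imbalance_ratio: 6846.6
    category: mismatch
    flagged: true   # 383407/52 = 7373.2, printed 6846.6
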