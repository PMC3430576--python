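{
  "cohort_size": 483,
  "clinical": {
    "histology": {"ductal": 319, "lobular": 126, "other": 38},
    "grade": {"1": 89, "2": 169, "3": 219, "NA": 6},
    "size_class": {"<=2cm": 206, ">2-<=5cm": 219, ">5cm": 49, "NA": 9},
    "node_status": {"negative": 225, "positive": 232, "NA": 26},
    "age_mean": 60,
    "age_range": [28, 88]
  },
  "overall": {
    "comment": "per-marker [n_positive, n_negative, n_missing] of 483; CAIX negative corrected 414->412 so the row sums to 483 and matches the printed 85.3%",
    "counts": {
      "HER2": [50, 432, 1],
      "EGFR": [84, 395, 4],
      "MET": [43, 423, 17],
      "IGF1R": [62, 400, 21],
      "GLUT1": [98, 360, 25],
      "CAIX": [46, 412, 25],
      "TfR": [70, 402, 11],
      "CD44v6": [308, 160, 15],
      "CAXII": [42, 426, 15],
      "Mammaglobin": [81, 382, 20],
      "MUC1": [438, 26, 19]
    }
  },
  "by_histology": {
    "comment": "n_positive per histology stratum [ductal, lobular, other]; ductal MUC1 corrected 218->281 to match the printed 88.1% and the subtype subtotals",
    "sizes": {"ductal": 319, "lobular": 126, "other": 38},
    "positive": {
      "HER2": [43, 4, 3],
      "EGFR": [71, 4, 9],
      "MET": [34, 4, 5],
      "IGF1R": [48, 7, 7],
      "GLUT1": [85, 5, 8],
      "CAIX": [38, 2, 6],
      "TfR": [53, 10, 7],
      "CD44v6": [197, 82, 29],
      "CAXII": [30, 12, 1],
      "Mammaglobin": [44, 34, 3],
      "MUC1": [281, 119, 38]
    }
  },
  "by_subtype": {
    "comment": "n_positive per molecular subtype of ductal cancers [luminal, her2_driven, basal_tn]",
    "sizes": {"luminal": 242, "her2_driven": 20, "basal_tn": 57},
    "positive": {
      "HER2": [23, 20, 0],
      "EGFR": [25, 11, 35],
      "MET": [21, 4, 9],
      "IGF1R": [41, 2, 5],
      "GLUT1": [49, 6, 30],
      "CAIX": [11, 4, 23],
      "TfR": [33, 5, 40],
      "CD44v6": [148, 9, 15],
      "CAXII": [28, 1, 1],
      "Mammaglobin": [39, 4, 1],
      "MUC1": [213, 20, 48]
    }
  },
  "tn_ratios": {
    "comment": "tumor-to-normal ratios of less tumor-specific markers: immunofluorescence medians where detectable, IHC membrane quantification for TfR",
    "CD44v6": 3.93,
    "MUC1": 2.74,
    "Mammaglobin": 1.54,
    "CAXII": 1.66,
    "TfR": 2.4
  }
}
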