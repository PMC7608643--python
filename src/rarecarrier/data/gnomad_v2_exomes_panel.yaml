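# gnomAD v2.1.1 exome ancestry panel: six analysed groups plus the
# 'oth' catch-all (retained in files, excluded from analyses).
# Sex splits for 'oth' are not published; an even split is assumed.
groups:
  - {label: nfe, n: 67709, n_male: 37442, n_female: 30267}
  - {label: amr, n: 17296, n_male: 7161, n_female: 10135}
  - {label: sas, n: 15308, n_male: 11536, n_female: 3772}
  - {label: eas, n: 9197, n_male: 4533, n_female: 4664}
  - {label: afr, n: 8128, n_male: 3093, n_female: 5035}
  - {label: asj, n: 5040, n_male: 2590, n_female: 2450}
  - {label: oth, n: 3070, n_male: 1535, n_female: 1535}
other_label: oth
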