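# Synthetic stand-in diagnosis category table. The original dictionary this
# emulates maps 51 categories; this representative table covers the major
# malignant subtypes, the suspicious/benign/insufficient categories needed
# for the cohort tables, and the worked report examples.
kind: diagnosis
categories:
  - {category_id: adenocarcinoma,            display_name: Adenocarcinoma,                 exclusive_group: malignant,    group_rank: 0}
  - {category_id: squamous_cell_carcinoma,   display_name: Squamous cell carcinoma,        exclusive_group: malignant,    group_rank: 0}
  - {category_id: small_cell_carcinoma,      display_name: Small cell carcinoma,           exclusive_group: malignant,    group_rank: 0}
  - {category_id: non_small_cell_carcinoma,  display_name: Non-small cell carcinoma,       exclusive_group: malignant,    group_rank: 0}
  - {category_id: carcinoma_nos,             display_name: Carcinoma not otherwise specified, exclusive_group: malignant, group_rank: 0}
  - {category_id: metastasis,                display_name: Metastasis,                     exclusive_group: malignant,    group_rank: 0}
  - {category_id: lymphoma,                  display_name: Lymphoma,                       exclusive_group: malignant,    group_rank: 0}
  - {category_id: malignant_nos,             display_name: Malignant not further specified, exclusive_group: malignant,   group_rank: 0}
  - {category_id: suspicious_for_malignancy, display_name: Suspicious for malignancy,      exclusive_group: suspicious,   group_rank: 1}
  - {category_id: atypical,                  display_name: Atypical cells,                 exclusive_group: suspicious,   group_rank: 1}
  - {category_id: insufficient,              display_name: Insufficient for diagnosis,     exclusive_group: insufficient, group_rank: 2}
  - {category_id: benign_reactive,           display_name: Reactive lymphoid changes,      exclusive_group: benign,       group_rank: 3}
  - {category_id: granulomatous_inflammation, display_name: Granulomatous inflammation,    exclusive_group: benign,       group_rank: 3}
  - {category_id: benign_lymphocytes,        display_name: Benign lymphocytes,             exclusive_group: benign,       group_rank: 3}
  - {category_id: negative_for_malignancy,   display_name: Negative for malignancy,        exclusive_group: benign,       group_rank: 3}
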