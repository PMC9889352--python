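phrase	category_id
adenocarcinoma	adenocarcinoma
metastatic adenocarcinoma	adenocarcinoma
adenocarcinoma of pulmonary origin	adenocarcinoma
non-small cell carcinoma, favor adenocarcinoma	adenocarcinoma
non-small cell carcinoma favour adenocarcinoma	adenocarcinoma
squamous cell carcinoma	squamous_cell_carcinoma
squamous carcinoma	squamous_cell_carcinoma
keratinizing carcinoma	squamous_cell_carcinoma
non-small cell carcinoma, favor squamous cell carcinoma	squamous_cell_carcinoma
small cell carcinoma	small_cell_carcinoma
small cell lung carcinoma	small_cell_carcinoma
oat cell carcinoma	small_cell_carcinoma
small cell neuroendocrine carcinoma	small_cell_carcinoma
non-small cell carcinoma	non_small_cell_carcinoma
non-small cell lung carcinoma	non_small_cell_carcinoma
nsclc	non_small_cell_carcinoma
carcinoma not otherwise specified	carcinoma_nos
carcinoma nos	carcinoma_nos
poorly differentiated carcinoma	carcinoma_nos
metastasis	metastasis
metastatic malignancy	metastasis
metastatic tumour	metastasis
consistent with metastasis	metastasis
lymphoma	lymphoma
non-hodgkin lymphoma	lymphoma
hodgkin lymphoma	lymphoma
lymphoproliferative disorder	lymphoma
malignant cells	malignant_nos
malignant cells present	malignant_nos
positive for malignant cells	malignant_nos
malignant, not further specified	malignant_nos
suspicious for malignancy	suspicious_for_malignancy
suspicious for malignant cells	suspicious_for_malignancy
suspicious for carcinoma	suspicious_for_malignancy
suspicious for involvement by carcinoma	suspicious_for_malignancy
atypical cells present	atypical
atypical epithelial cells	atypical
atypical lymphoid population	atypical
insufficient for diagnosis	insufficient
insufficient cellularity	insufficient
non-diagnostic	insufficient
inadequate specimen	insufficient
unsatisfactory for evaluation	insufficient
insufficient material for diagnosis	insufficient
reactive lymphoid hyperplasia	benign_reactive
reactive changes	benign_reactive
benign reactive lymph node	benign_reactive
granulomatous inflammation	granulomatous_inflammation
non-necrotizing granulomatous inflammation	granulomatous_inflammation
necrotizing granulomatous inflammation	granulomatous_inflammation
granulomas	granulomatous_inflammation
benign lymphocytes	benign_lymphocytes
benign appearing lymphocytes	benign_lymphocytes
polymorphous lymphocytes	benign_lymphocytes
polymorphous population of lymphocytes	benign_lymphocytes
negative for malignant cells	negative_for_malignancy
no malignant cells identified	negative_for_malignancy
negative for malignancy	negative_for_malignancy
no evidence of malignancy	negative_for_malignancy
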