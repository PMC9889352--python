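# Versioned template bank for rendering synthetic free-text reports.
# Placeholders: {proc} = EBUS|EUS, {site} = station synonym phrase,
# {phrase} = diagnosis lexicon phrase of the latent category.
version: 1
source_templates:
  - "{proc} FNA lymph node, {site}."
  - "{proc}-TBNA of lymph node, {site}."
  - "Lymph node, {site}, {proc} guided FNA."
  - "Fine needle aspirate of lymph node ({site}), {proc}."
diagnosis_templates:
  - "{phrase}."
  - "Cytology: {phrase}."
  - "FNA smears show {phrase}."
  - "{phrase}. See comment."
addendum_templates:
  - "Addendum: immunohistochemical workup supports {phrase}."
  - "Addendum: further review favors {phrase}."
# Distractor prose must not itself contain any diagnosis-lexicon phrase,
# except the negation sentence, which is an intentional lexicon entry.
distractors_mild:
  - "Cell block prepared."
  - "See microscopic description."
  - "Adequacy assessed on site."
distractors_heavy:
  - "Immunostains are pending at the time of reporting."
  - "Scattered bronchial epithelial cells are noted in the background."
  - "Rare anthracotic pigment-laden macrophages are seen."
  - "Limited clinical history was provided."
negation_distractor: "Negative for malignant cells."
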