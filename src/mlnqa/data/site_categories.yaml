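# 24 IASLC/AJCC nodal-station site categories (category_id == station label).
kind: site
categories:
  - {category_id: "1R", station_label: "1R"}
  - {category_id: "1L", station_label: "1L"}
  - {category_id: "2R", station_label: "2R"}
  - {category_id: "2L", station_label: "2L"}
  - {category_id: "3A", station_label: "3A"}
  - {category_id: "3P", station_label: "3P"}
  - {category_id: "4R", station_label: "4R"}
  - {category_id: "4L", station_label: "4L"}
  - {category_id: "5",  station_label: "5"}
  - {category_id: "6",  station_label: "6"}
  - {category_id: "7",  station_label: "7"}
  - {category_id: "8",  station_label: "8"}
  - {category_id: "9",  station_label: "9"}
  - {category_id: "10R", station_label: "10R"}
  - {category_id: "10L", station_label: "10L"}
  - {category_id: "11R", station_label: "11R"}
  - {category_id: "11L", station_label: "11L"}
  - {category_id: "12R", station_label: "12R"}
  - {category_id: "12L", station_label: "12L"}
  - {category_id: "13R", station_label: "13R"}
  - {category_id: "13L", station_label: "13L"}
  - {category_id: "14R", station_label: "14R"}
  - {category_id: "14L", station_label: "14L"}
  - {category_id: "12",  station_label: "12"}
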