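{
  "table1.yaml": "5555382ce1f5610c0f1bee3424067a109e11472fc9d97cd5bd077d3107bc383f",
  "physiology_standard.yaml": "b061542f69c791b5f9785772d8205be5ab29170042196f65cb1cf170aaa24b45",
  "table2_demographics.csv": "b665eea112d7a0ecede000976ecb8a5b1308f8954d0ef1002449e9885a14a54d",
  "table3_observed.csv": "d84e7fbed9f7742121a90bc1f994434a8b1f9dcf4f6316fc8a3846acf3e8677a",
  "table4_ddi_observed.csv": "701abbc73a9ed8db99374a7f2be4396896bdef6f0c19acf475b2c46ac5f23c29",
  "perpetrators.yaml": "38f780a13ec818804f19ed39b1a65825b1ed5db6f35c427a5ddff790d0cb3450",
  "calibration_locked.yaml": "3cdc0463bbc6b1ec1e575e2f5c843edf60ac1645898f5318e20d993654545a39"
}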