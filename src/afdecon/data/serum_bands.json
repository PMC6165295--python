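{
  "tissue": "serum",
  "provenance": "Literature-informed default band shapes for 366 nm-excited rat serum autofluorescence. Centers follow the reported band positions (albumin blue band 455 nm; bilirubin bichromophore bands near 523 and 570 nm; porphyrin red bands spanning 600-770 nm); widths and skews are package defaults derived from typical solution emission profiles, not measured ground truth, and are fully configurable.",
  "fluorophores": [
    {
      "name": "blue_band",
      "report_group": "blue_band",
      "bands": [
        {"center_nm": 455.0, "sigma_g_cm1": 1100.0, "sigma_h_cm1": 1300.0, "skew": "red"}
      ]
    },
    {
      "name": "bilirubin_517_530",
      "report_group": "bilirubin_517_530",
      "bands": [
        {"center_nm": 523.0, "sigma_g_cm1": 800.0, "sigma_h_cm1": 900.0, "skew": "red"}
      ]
    },
    {
      "name": "bilirubin_570",
      "report_group": "bilirubin_570",
      "bands": [
        {"center_nm": 570.0, "sigma_g_cm1": 800.0, "sigma_h_cm1": 900.0, "skew": "red"}
      ]
    },
    {
      "name": "red_bands",
      "report_group": "red_bands",
      "bands": [
        {"center_nm": 635.0, "sigma_g_cm1": 350.0, "sigma_h_cm1": 400.0, "skew": "red"},
        {"center_nm": 700.0, "sigma_g_cm1": 600.0, "sigma_h_cm1": 700.0, "skew": "red"}
      ]
    }
  ]
}
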