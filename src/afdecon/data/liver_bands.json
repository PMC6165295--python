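{
  "tissue": "liver",
  "provenance": "Literature-informed default band shapes for 366 nm-excited rat liver autofluorescence (proteins, bound and free NAD(P)H, fatty acids, vitamin A, flavins, lipofuscin-like lipopigments). Centers follow typical emission maxima of the pure compounds; widths and skews are package defaults chosen so the fixed-shape unmixing problem is well conditioned, not measured ground truth, and are fully configurable.",
  "fluorophores": [
    {
      "name": "proteins",
      "report_group": "proteins",
      "bands": [
        {"center_nm": 426.0, "sigma_g_cm1": 550.0, "sigma_h_cm1": 650.0, "skew": "red"}
      ]
    },
    {
      "name": "nadph_bound",
      "report_group": "nadph_bound",
      "bands": [
        {"center_nm": 444.0, "sigma_g_cm1": 750.0, "sigma_h_cm1": 850.0, "skew": "red"}
      ]
    },
    {
      "name": "nadph_free",
      "report_group": "nadph_free",
      "bands": [
        {"center_nm": 468.0, "sigma_g_cm1": 850.0, "sigma_h_cm1": 1000.0, "skew": "red"}
      ]
    },
    {
      "name": "fatty_acids",
      "report_group": "fatty_acids",
      "bands": [
        {"center_nm": 476.0, "sigma_g_cm1": 450.0, "sigma_h_cm1": 500.0, "skew": "red"}
      ]
    },
    {
      "name": "vitamin_a",
      "report_group": "vitamin_a",
      "bands": [
        {"center_nm": 484.0, "sigma_g_cm1": 450.0, "sigma_h_cm1": 500.0, "skew": "red"},
        {"center_nm": 514.0, "sigma_g_cm1": 550.0, "sigma_h_cm1": 600.0, "skew": "red"}
      ]
    },
    {
      "name": "flavins",
      "report_group": "flavins",
      "bands": [
        {"center_nm": 532.0, "sigma_g_cm1": 800.0, "sigma_h_cm1": 950.0, "skew": "red"}
      ]
    },
    {
      "name": "lipopigments",
      "report_group": "lipopigments",
      "bands": [
        {"center_nm": 595.0, "sigma_g_cm1": 1300.0, "sigma_h_cm1": 1700.0, "skew": "red"}
      ]
    }
  ]
}
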