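"""Published cohort-level reference values for the rat bile-duct-ligation model.

Group means and standard errors (n = 5 animals per group) of the relative
fluorophore contributions to serum and liver autofluorescence at 366 nm
excitation, for sham-operated animals and 24, 48 and 72 h after bile duct
ligation (BDL).  These figures serve two roles:

* generating targets for :mod:`afdecon.simulate` (default cohort specs), and
* printed inputs for the derived cholestasis biomarkers (bilirubin band
  metrics, NAD(P)H free/bound ratio, optical redox ratio).

Each entry maps ``fluorophore -> (mean_pct, se_pct)``.
"""

from __future__ import annotations

GROUP_ORDER = ("sham", "bdl24", "bdl48", "bdl72")

N_PER_GROUP = 5

#: Serum relative contributions, % of the 400-750 nm emission area.
SERUM_CONTRIBUTIONS: dict[str, dict[str, tuple[float, float]]] = {
    "sham": {
        "blue_band": (98.56, 5.26),
        "bilirubin_517_530": (0.09, 0.02),
        "bilirubin_570": (0.06, 0.02),
        "red_bands": (1.76, 0.12),
    },
    "bdl24": {
        "blue_band": (69.05, 3.49),
        "bilirubin_517_530": (16.98, 1.45),
        "bilirubin_570": (4.67, 0.34),
        "red_bands": (7.12, 0.40),
    },
    "bdl48": {
        "blue_band": (70.22, 4.41),
        "bilirubin_517_530": (14.80, 0.76),
        "bilirubin_570": (3.68, 0.20),
        "red_bands": (8.71, 0.46),
    },
    "bdl72": {
        "blue_band": (67.31, 4.77),
        "bilirubin_517_530": (14.31, 0.92),
        "bilirubin_570": (3.56, 0.24),
        "red_bands": (13.60, 0.62),
    },
}

#: Liver relative contributions, % of the 400-750 nm emission area.
LIVER_CONTRIBUTIONS: dict[str, dict[str, tuple[float, float]]] = {
    "sham": {
        "proteins": (3.72, 0.26),
        "nadph_bound": (13.06, 0.81),
        "nadph_free": (39.23, 2.35),
        "flavins": (3.94, 0.20),
        "vitamin_a": (21.07, 1.07),
        "fatty_acids": (12.43, 0.71),
        "lipopigments": (6.01, 0.43),
    },
    "bdl24": {
        "proteins": (5.40, 0.44),
        "nadph_bound": (11.76, 0.83),
        "nadph_free": (38.19, 2.29),
        "flavins": (5.02, 0.25),
        "vitamin_a": (20.44, 1.22),
        "fatty_acids": (11.42, 0.78),
        "lipopigments": (6.69, 0.55),
    },
    "bdl48": {
        "proteins": (7.09, 0.49),
        "nadph_bound": (11.33, 0.68),
        "nadph_free": (37.88, 1.97),
        "flavins": (5.37, 0.26),
        "vitamin_a": (18.35, 0.91),
        "fatty_acids": (11.10, 0.59),
        "lipopigments": (6.98, 0.50),
    },
    "bdl72": {
        "proteins": (8.80, 0.52),
        "nadph_bound": (9.27, 0.46),
        "nadph_free": (37.15, 1.67),
        "flavins": (5.02, 0.27),
        "vitamin_a": (16.97, 0.69),
        "fatty_acids": (10.90, 0.46),
        "lipopigments": (8.78, 0.42),
    },
}

#: Integrated raw serum emission over 400-750 nm, a.u.: (mean, se) per group.
SERUM_TOTAL_AREAS: dict[str, tuple[float, float]] = {
    "sham": (4490.0, 251.0),
    "bdl24": (3720.0, 287.0),
    "bdl48": (4390.0, 219.0),
    "bdl72": (4650.0, 155.0),
}

#: Liver total emission areas are not published; a common nominal value keeps
#: the liver forward model on the same arbitrary-unit footing as serum.
LIVER_TOTAL_AREAS: dict[str, tuple[float, float]] = {
    g: (5000.0, 250.0) for g in GROUP_ORDER
}
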