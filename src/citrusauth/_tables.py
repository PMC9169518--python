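"""Reference data for the OHA compound library.

Two kinds of entries live here:

* ``KNOWN_CALIBRATIONS`` — the published calibration and quantitation
  parameters (linear range, through-origin slope, R², LOD, LOQ and the
  psoralen internal-standard correction factor, for UV and fluorescence
  detection) of the 39 known oxygenated heterocyclic aglycones (OHAs):
  10 methoxyflavones (MF), 13 coumarins and 16 furanocoumarins (FC).
* ``CANDIDATE_ROWS`` — the 13 tentatively screened OHA candidates with
  their retention times, retention indices, UV/emission spectral maxima,
  monitored fluorescence wavelength pairs and peak-height ratios.

Retention times, spectral maxima and fluorescence ratios of the 39 known
compounds are NOT part of the published tables; the library fills them with
SYNTHETIC values generated from the substitution-class spectral landmarks in
``CLASS_LANDMARKS`` (see :func:`citrusauth.catalog.build_default_catalog`).
They are self-consistent placeholders for round-trip testing, not measured
values.
"""

from __future__ import annotations

# (id, name, family, substitution_class,
#  uv: (range_low, range_high, slope, r2, lod, loq, cf),
#  fl: same tuple or None when the compound yields no usable emission signal)
KNOWN_CALIBRATIONS = [
    ("1", "scopoletin", "coumarin", "6-OR,7-OH C",
     (0.05, 500, 5.2828, 0.9992, 0.01, 0.04, 10),
     (0.0005, 25, 37.891, 0.9998, 0.0002, 0.0007, 12)),
    ("2", "umbelliferone", "coumarin", "7-OH C",
     (0.05, 500, 4.1033, 0.9998, 0.01, 0.04, 8.1),
     (0.001, 5.0, 84.201, 1.0000, 0.0001, 0.0004, 27)),
    ("3", "herniarin", "coumarin", "7-OR C",
     (0.5, 600, 3.9501, 0.9996, 0.31, 1.05, 7.8),
     (0.1, 300, 5.0011, 0.9995, 0.02, 0.08, 0.56)),
    ("4", "heraclenol", "FC", "8-OR FC",
     (0.2, 500, 3.4774, 1.0000, 0.15, 0.51, 18),
     (30, 1200, 0.0272, 1.0000, 10.5, 35, 0.0036)),
    ("5", "meranzin hydrate", "coumarin", "7-OR,8-R C",
     (0.5, 500, 2.7524, 0.9999, 0.16, 0.55, 5.4),
     (0.02, 100, 9.5500, 1.0000, 0.0074, 0.025, 1.1)),
    ("6", "bergaptol", "FC", "5-OH FC",
     (0.1, 500, 4.4802, 0.9997, 0.02, 0.08, 23),
     None),
    ("7", "oxypeucedanin hydrate", "FC", "5-OR FC",
     (0.5, 500, 3.1312, 1.0000, 0.16, 0.52, 6.1),
     (2.0, 2000, 0.0650, 0.9999, 0.83, 2.77, 0.0086)),
    ("8", "byakangelicin", "FC", "5,8-diOR FC",
     (0.5, 150, 2.7260, 0.9999, 0.02, 0.06, 3.8),
     (5.0, 500, 0.2071, 0.9998, 0.64, 2.13, 0.028)),
    ("9", "citropten", "coumarin", "5,7-diOR C",
     (0.1, 500, 6.2133, 1.0000, 0.02, 0.06, 12),
     (0.2, 500, 54.720, 0.9996, 0.0004, 0.0016, 17)),
    ("10", "bergapten", "FC", "5-OR FC",
     (0.3, 500, 3.8002, 0.9994, 0.03, 0.10, 20),
     (1.0, 500, 0.1364, 0.9999, 0.13, 0.43, 0.018)),
    ("11", "auraptenol", "coumarin", "7-OR,8-R C",
     (0.5, 300, 3.4638, 0.9999, 0.17, 0.56, 6.8),
     (0.03, 100, 8.7202, 1.0000, 0.01, 0.03, 0.97)),
    ("12", "heraclenin", "FC", "8-OR FC",
     (0.5, 1200, 3.1276, 1.0000, 0.22, 0.73, 16),
     (5.0, 1200, 0.0203, 1.0000, 2.60, 8.67, 0.0027)),
    ("13", "meranzin", "coumarin", "7-OR,8-R C",
     (0.2, 500, 4.1710, 0.9997, 0.04, 0.12, 8.2),
     (0.2, 500, 5.5027, 0.9996, 0.0012, 0.0050, 0.61)),
    ("14", "isomeranzin", "coumarin", "7-OR,8-R C",
     (0.05, 500, 4.3205, 0.9996, 0.04, 0.14, 8.5),
     (0.01, 50, 5.4720, 0.9986, 0.0023, 0.0075, 6.1)),
    ("15", "isosinensetin", "MF", "3',4'-diOMe MF",
     (2.0, 1000, 2.7304, 0.9995, 0.11, 0.36, 5.4),
     None),
    ("16", "byakangelicol", "FC", "5,8-diOR FC",
     (1.0, 4000, 3.0139, 1.0000, 0.20, 0.67, 4.2),
     None),
    ("17", "sinensetin", "MF", "3',4'-diOMe MF",
     (5.0, 500, 3.0462, 1.0000, 0.27, 0.92, 6.0),
     (5.0, 500, 0.8602, 0.9995, 0.13, 0.40, 0.27)),
    ("18", "oxypeucedanin", "FC", "5-OR FC",
     (1.0, 500, 4.6982, 0.9995, 0.04, 0.14, 25),
     (5.0, 500, 0.2071, 0.9998, 0.13, 0.43, 0.066)),
    ("19", "marmin", "coumarin", "7-OR C",
     (1.0, 500, 2.8562, 0.9998, 0.02, 0.07, 4.9),
     (0.2, 500, 3.9527, 0.9998, 0.01, 0.03, 0.30)),
    ("20", "hexamethyl-O-quercetagetin", "MF", "3',4'-diOMe MF",
     (1.0, 800, 1.7258, 0.9997, 0.08, 0.27, 3.4),
     (5.0, 800, 0.4830, 0.9992, 0.08, 0.25, 0.15)),
    ("21", "tetramethyl-O-isoscutellarein", "MF", "4'-OMe MF",
     (1.0, 1000, 2.8129, 0.9999, 0.04, 0.12, 5.5),
     None),
    ("22", "nobiletin", "MF", "3',4'-diOMe MF",
     (2.0, 500, 5.0870, 0.9998, 0.09, 0.30, 10),
     (5.0, 500, 0.2072, 0.9998, 0.15, 0.51, 0.066)),
    ("23", "tetramethyl-O-scutellarein", "MF", "4'-OMe MF",
     (1.0, 5000, 6.0807, 0.9998, 0.06, 0.19, 12),
     (5.0, 5000, 0.1875, 0.9996, 0.25, 0.85, 0.021)),
    ("24", "3,5,6,7,8,3',4'-heptamethoxyflavone", "MF", "3',4'-diOMe MF",
     (1.0, 500, 6.1161, 0.9998, 0.03, 0.11, 12),
     (10, 500, 0.0693, 0.9998, 0.41, 1.44, 0.022)),
    ("25", "6',7'-dihydroxybergamottin", "FC", "5-OR FC",
     (0.1, 1000, 2.1900, 0.9999, 0.01, 0.04, 11),
     (1.0, 600, 0.0910, 0.9990, 0.04, 0.15, 0.012)),
    ("26", "tangeretin", "MF", "4'-OMe MF",
     (0.5, 500, 6.7485, 0.9994, 0.02, 0.06, 13),
     None),
    ("27", "5-demethylnobiletin", "MF", "5-OH MF",
     (0.5, 1000, 3.1097, 0.9998, 0.04, 0.13, 6.1),
     None),
    ("28", "imperatorin", "FC", "8-OR FC",
     (0.2, 200, 2.5970, 0.9998, 0.02, 0.05, 14),
     (15, 1500, 0.0085, 0.999, 4.77, 15.9, 0.0011)),
    ("29", "phellopterin", "FC", "5,8-diOR FC",
     (0.2, 200, 3.3218, 0.9996, 0.01, 0.04, 4.6),
     None),
    ("30", "5-demethyltangeretin", "MF", "5-OH MF",
     (0.5, 500, 2.0667, 1.0000, 0.11, 0.38, 4.1),
     None),
    ("31", "osthole", "coumarin", "7-OR,8-R C",
     (0.5, 500, 4.4870, 0.9999, 0.02, 0.08, 8.8),
     (1.0, 500, 1.9800, 0.9998, 0.05, 0.15, 0.22)),
    ("32", "isoimperatorin", "FC", "5-OR FC",
     (0.2, 500, 4.0122, 0.9998, 0.01, 0.03, 21),
     (1.5, 3000, 0.0911, 1.0000, 0.27, 0.89, 0.012)),
    ("33", "6',7'-epoxybergamottin", "FC", "5-OR FC",
     (1.0, 500, 2.8260, 0.9998, 0.04, 0.13, 15),
     (2.0, 500, 0.1563, 1.0000, 0.11, 0.38, 0.050)),
    ("34", "8-geranyloxypsoralen", "FC", "8-OR FC",
     (0.2, 200, 1.9664, 0.9999, 0.01, 0.04, 10),
     (20, 500, 0.0028, 0.9994, 10.2, 24.0, 0.00040)),
    ("35", "auraptene", "coumarin", "7-OR C",
     (1.0, 500, 2.3146, 0.9999, 0.03, 0.11, 4.5),
     (0.2, 500, 2.6926, 0.9998, 0.01, 0.03, 0.30)),
    ("36", "bergamottin", "FC", "5-OR FC",
     (0.5, 500, 4.3068, 0.9997, 0.02, 0.06, 22),
     (0.5, 500, 0.5795, 0.9999, 0.02, 0.06, 0.18)),
    ("37", "5-geranoxy-7-methoxycoumarin", "coumarin", "5,7-diOR C",
     (0.5, 500, 2.7850, 1.0000, 0.12, 0.40, 5.5),
     (0.02, 50, 20.998, 0.9999, 0.005, 0.020, 6.7)),
    ("38", "6',7'-epoxyauraptene", "coumarin", "7-OR C",
     (3.2, 1600, 4.7086, 0.9999, 0.06, 0.25, 12),
     (0.6, 1600, 6.2310, 0.9998, 0.02, 0.06, 0.70)),
    ("39", "cnidicin", "FC", "5,8-diOR FC",
     (0.2, 300, 3.3762, 0.9999, 0.02, 0.07, 5.4),
     None),
]

# (id, rt_min, retention_index or None, uv_maxima, emission_max,
#  (fl_high_nm, fl_second_nm), fl_ratio, deduced substitution class)
CANDIDATE_ROWS = [
    ("I", 5.5, None, (230, 295, 347), 462, (450, 500), 2.3, "6-OR,7-OH C"),
    ("II", 15.0, 877, (262, 331), 467, (450, 500), 1.4, "5-OR,7-OH C"),
    ("III", 22.3, 958, (262, 330), 463, (450, 500), 1.6, "5-OR,7-OH C"),
    ("IV", 23.7, 973, (224, 248, 295, 330), 431, (450, 400), 1.6,
     "uncategorized C"),
    ("V", 26.8, 1006, (259, 328), 457, (450, 500), 2.1, "5-OR,7-OH C"),
    ("VI", 28.0, 1018, (252, 258, 326), 454, (450, 500), 2.2, "5,7-diOR C"),
    ("VII", 29.0, 1028, (230, 295, 344), 422, (450, 400), 1.1, "6,7-diOR C"),
    ("VIII", 31.1, 1049, (223, 251, 312), 476, (450, 400), 1.8, "5-OR FC"),
    ("IX", 33.0, 1067, (222, 251, 312), 488, (500, 450), 2.2, "5-OR FC"),
    ("X", 40.7, 1260, (222, 251, 309), 485, (500, 450), 1.6, "5-OR FC"),
    ("XI", 43.0, 1313, (227, 294, 343), 422, (450, 400), 1.1, "6,7-diOR C"),
    ("XII", 43.3, 1318, (221, 250, 308), 477, (450, 500), 1.4, "5-OR FC"),
    ("XIII", 43.9, 1331, (223, 242, 249, 268, 311), 496, (500, 450), 4.7,
     "5,8-diOR FC"),
]

# Candidate families (8 coumarins, 5 furanocoumarins).
CANDIDATE_FAMILIES = {
    "I": "coumarin", "II": "coumarin", "III": "coumarin", "IV": "coumarin",
    "V": "coumarin", "VI": "coumarin", "VII": "coumarin", "XI": "coumarin",
    "VIII": "FC", "IX": "FC", "X": "FC", "XII": "FC", "XIII": "FC",
}

# Synthetic spectral landmarks per substitution class: (uv_maxima tuple,
# emission_max or None). Chosen to sit inside the classification windows of
# citrusauth.spectra.classify_spectrum so the library is self-consistent.
CLASS_LANDMARKS = {
    "7-OH C": ((240, 323), 461),
    "7-OR C": ((240, 323), 395),
    "7-OR,8-R C": ((256, 323), 395),
    "5,7-diOR C": ((251, 259, 326), 437),
    "6,7-diOR C": ((228, 294, 343), 422),
    "6-OR,7-OH C": ((230, 298, 338), 460),
    "5-OR,7-OH C": ((260, 330), 462),
    "5-OR FC": ((222, 250, 311), 481),
    "8-OR FC": ((221, 249, 301), 478),
    "5,8-diOR FC": ((223, 268, 315), 490),
    "5-OH FC": ((250, 312), None),
    "4'-OMe MF": ((268, 327), 522),
    "3',4'-diOMe MF": ((245, 268, 330), 525),
    "5-OH MF": ((272, 355), None),
}

# Synthetic psoralen internal-standard settings: 5 mg/L nominal level,
# assumed UV-250 slope 3.0 area units per mg/L, early-eluting synthetic rt.
IS_NOMINAL_MG_L = 5.0
IS_SLOPE = 3.0
IS_NOMINAL_RESPONSE = IS_NOMINAL_MG_L * IS_SLOPE
IS_RT_MIN = 8.9
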