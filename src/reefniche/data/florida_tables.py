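"""Published Florida reef-tract survey summaries (2011-2015, 985 sites).

Printed summary tables for the 32 coral species surveyed along the Florida
reef tract: per-species presence at sites (%), hold-out AUC and percent
suitable habitat for the 23 modelled species, and per-subregion suitable
habitat areas (km^2) with the model extent per subregion. These serve as
reference inputs for the species-prevalence filter, the area accounting
arithmetic, and the site missing-data bookkeeping, all of which can be
checked end-to-end without the (unreleased) raw survey records.
"""

from __future__ import annotations

#: survey accounting: total sites and per-predictor missing-data counts.
#: 22 sites lacked SST, 20 lacked turbidity (K490), 7 lacked wave energy of
#: which 6 also lacked SST; no other overlap. 1028 - 43 = 985 analysed.
N_SURVEY_SITES = 1028
MISSING_SST = 22
MISSING_K490 = 20
MISSING_WAVE = 7
MISSING_WAVE_AND_SST = 6

#: presence at sites (%) for all 32 surveyed species
PRESENCE_PCT: dict[str, float] = {
    "Siderastrea radians": 47.67,
    "Siderastrea siderea": 89.4,
    "Stephanocoenia intersepta": 72.28,
    "Solenastrea bournoni": 30.06,
    "Millepora alcicornis": 88.52,
    "Porites astreoides": 80.93,
    "Pseudodiploria strigosa": 30.06,
    "Orbicella faveolata": 30.35,
    "Dichocoenia stokesii": 59.53,
    "Montastraea cavernosa": 64.49,
    "Porites porites": 54.96,
    "Undaria (Agaricia) agaricites": 48.15,
    "Diploria labyrinthiformis": 19.84,
    "Eusmilia fastigiata": 16.44,
    "Pseudodiploria clivosa": 16.05,
    "Colpophyllia natans": 26.65,
    "Porites furcata": 12.55,
    "Porites divaricata": 15.08,
    "Orbicella franksi": 12.26,
    "Mycetophyllia sp.": 10.31,
    "Acropora cervicornis": 7.78,
    "Meandrina meandrites": 31.52,
    "Madracis decactis": 11.28,
    "Agaricia fragilis": 1.75,
    "Agaricia lamarcki": 8.46,
    "Favia fragum": 4.28,
    "Isophyllia sinuosa": 0.88,
    "Millepora complanata": 2.72,
    "Orbicella annularis": 8.95,
    "Mussa angulosa": 3.5,
    "Oculina diffusa": 2.04,
    "Acropora palmata": 0.39,
}

#: hold-out AUC for the 23 modelled species
AUC: dict[str, float] = {
    "Siderastrea radians": 0.66,
    "Siderastrea siderea": 0.75,
    "Stephanocoenia intersepta": 0.62,
    "Solenastrea bournoni": 0.63,
    "Millepora alcicornis": 0.75,
    "Porites astreoides": 0.68,
    "Pseudodiploria strigosa": 0.64,
    "Orbicella faveolata": 0.62,
    "Dichocoenia stokesii": 0.69,
    "Montastraea cavernosa": 0.69,
    "Porites porites": 0.70,
    "Undaria (Agaricia) agaricites": 0.71,
    "Diploria labyrinthiformis": 0.61,
    "Eusmilia fastigiata": 0.59,
    "Pseudodiploria clivosa": 0.56,
    "Colpophyllia natans": 0.70,
    "Porites furcata": 0.65,
    "Porites divaricata": 0.57,
    "Orbicella franksi": 0.74,
    "Mycetophyllia sp.": 0.83,
    "Acropora cervicornis": 0.69,
    "Meandrina meandrites": 0.57,
    "Madracis decactis": 0.65,
}

#: printed percent suitable habitat area for the 23 modelled species
SUITABLE_PCT: dict[str, float] = {
    "Siderastrea radians": 80.5,
    "Siderastrea siderea": 75.57,
    "Stephanocoenia intersepta": 65.79,
    "Solenastrea bournoni": 61.54,
    "Millepora alcicornis": 58.34,
    "Porites astreoides": 58.09,
    "Pseudodiploria strigosa": 57.97,
    "Orbicella faveolata": 56.45,
    "Dichocoenia stokesii": 55.48,
    "Montastraea cavernosa": 55.45,
    "Porites porites": 54.86,
    "Undaria (Agaricia) agaricites": 51.36,
    "Diploria labyrinthiformis": 49.88,
    "Eusmilia fastigiata": 48.73,
    "Pseudodiploria clivosa": 46.77,
    "Colpophyllia natans": 46.33,
    "Porites furcata": 46.17,
    "Porites divaricata": 44.7,
    "Orbicella franksi": 36.34,
    "Mycetophyllia sp.": 32.65,
    "Acropora cervicornis": 24.2,
    "Meandrina meandrites": 24.12,
    "Madracis decactis": 22.87,
}

#: the ten reef-tract subregions, north to southwest
SUBREGIONS = [
    "North Palm Beach",
    "South Palm Beach",
    "Deerfield",
    "Broward-Miami",
    "Biscayne",
    "Upper Keys",
    "Middle Keys",
    "Lower Keys",
    "Marquesas",
    "Dry Tortugas",
]

#: suitable habitat area (km^2) per subregion for the 23 modelled species
SUBREGION_AREAS: dict[str, list[float]] = {
    "Siderastrea radians": [0, 0, 0, 0, 328, 407, 335, 404, 588, 270],
    "Siderastrea siderea": [13, 10, 8, 97, 256, 347, 286, 385, 536, 233],
    "Stephanocoenia intersepta": [25, 46, 17, 110, 130, 181, 255, 419, 494, 229],
    "Solenastrea bournoni": [1, 18, 11, 138, 240, 361, 301, 419, 277, 2],
    "Porites astreoides": [2, 0, 0, 23, 166, 163, 220, 328, 520, 261],
    "Pseudodiploria strigosa": [0, 0, 0, 0, 146, 207, 257, 382, 434, 254],
    "Millepora alcicornis": [17, 44, 15, 67, 220, 276, 222, 344, 201, 270],
    "Orbicella faveolata": [0, 0, 0, 0, 140, 258, 196, 369, 466, 207],
    "Dichocoenia stokesii": [0, 0, 0, 1, 204, 362, 283, 405, 339, 0],
    "Montastraea cavernosa": [31, 49, 17, 96, 105, 81, 178, 356, 427, 253],
    "Porites porites": [0, 0, 0, 0, 116, 268, 217, 284, 421, 270],
    "Undaria (Agaricia) agaricites": [0, 0, 0, 0, 158, 206, 213, 235, 454, 222],
    "Diploria labyrinthiformis": [0, 0, 0, 0, 118, 220, 200, 297, 369, 241],
    "Eusmilia fastigiata": [0, 0, 0, 0, 110, 172, 225, 324, 367, 202],
    "Pseudodiploria clivosa": [0, 4, 4, 17, 198, 264, 193, 285, 246, 144],
    "Porites furcata": [0, 0, 0, 0, 210, 208, 245, 160, 312, 203],
    "Colpophyllia natans": [0, 0, 0, 0, 48, 108, 187, 337, 425, 226],
    "Porites divaricata": [0, 0, 0, 0, 188, 265, 306, 346, 110, 80],
    "Orbicella franksi": [0, 0, 0, 0, 105, 147, 35, 54, 456, 256],
    "Mycetophyllia sp.": [0, 5, 5, 4, 2, 6, 100, 226, 367, 237],
    "Acropora cervicornis": [0, 9, 8, 91, 49, 112, 22, 195, 59, 156],
    "Meandrina meandrites": [30, 52, 19, 76, 27, 18, 63, 123, 122, 163],
    "Madracis decactis": [29, 47, 16, 44, 2, 8, 2, 33, 298, 188],
}

#: model extent (km^2) per subregion — the clipped 1-km reef-buffer area
MODEL_EXTENT: list[float] = [33, 84, 43, 203, 349, 433, 372, 522, 588, 270]

#: the species exempted from the 10 %-prevalence filter
PREVALENCE_FILTER_EXCEPTIONS = ["Acropora cervicornis"]
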