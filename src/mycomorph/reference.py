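"""Published reference values for the three M. alpina macro-morphologies.

Kinetic parameters fitted to batch shake-flask fermentations of
*Mortierella alpina* grown as hollow pellets, fluffy pellets and dispersed
mycelia, together with the reported day-by-day growth (Q_X) and lipid
accumulation (Q_L) rates and the morphometric characteristics of each form.
These constants are the inputs to the table-reproduction pipeline and to
the acceptance checks; nothing in the package tunes them.

Units: mu_max 1/day; x_m (maximum DCW) g/L; alpha g lipid/g biomass;
beta g lipid/g biomass/day; rates g/L/day; diameters mm.
"""

from __future__ import annotations

MORPHOLOGIES = ("hollow_pellet", "fluffy_pellet", "dispersed")

#: Fitted kinetic parameters per morphology: mu_max, x_m, alpha, beta.
KINETIC_PARAMS: dict[str, dict[str, float]] = {
    "hollow_pellet": {"mu_max": 0.4373, "x_m": 16.19, "alpha": 0.5594, "beta": 0.0037},
    "fluffy_pellet": {"mu_max": 0.6584, "x_m": 28.44, "alpha": 0.3531, "beta": 0.0204},
    "dispersed": {"mu_max": 1.153, "x_m": 30.68, "alpha": 0.2289, "beta": 0.0127},
}

#: Reported grid maxima of the daily rates (Q_X_max, Q_L_max), g/L/day.
RATE_MAXIMA: dict[str, dict[str, float]] = {
    "hollow_pellet": {"q_x_max": 1.7678, "q_l_max": 1.0198},
    "fluffy_pellet": {"q_x_max": 4.6488, "q_l_max": 1.9557},
    "dispersed": {"q_x_max": 8.6831, "q_l_max": 2.1567},
}

#: Reported daily rates, day 1..8: rows of (Q_X, Q_L) in g/L/day.
DAILY_RATES: dict[str, list[tuple[float, float]]] = {
    "hollow_pellet": [
        (1.5115, 0.8640), (1.7115, 0.9818), (1.7678, 1.0198), (1.6610, 0.9663),
        (1.4275, 0.8414), (1.1361, 0.6831), (0.8503, 0.5269), (0.6077, 0.3939),
    ],
    "fluffy_pellet": [
        (3.4200, 1.3471), (4.4093, 1.7771), (4.6488, 1.9557), (3.9668, 1.8041),
        (2.8220, 1.4694), (1.7610, 1.1410), (1.0116, 0.9041), (0.5539, 0.7580),
    ],
    "dispersed": [
        (5.5319, 1.3421), (8.6831, 2.1567), (7.3244, 1.9530), (3.6159, 1.1734),
        (1.3460, 0.6835), (0.4489, 0.4886), (0.1442, 0.4223), (0.0458, 0.4008),
    ],
}

#: Day-1 growth rate per morphology — the anchor that pins the unreported
#: inoculum biomass x_0 (see kinetics.anchor_trajectory).
DAY1_GROWTH_RATE: dict[str, float] = {
    m: DAILY_RATES[m][0][0] for m in MORPHOLOGIES
}

#: Reported morphometric characteristics: fluffy degree (A_pc/A_m) and
#: pellet-core equivalent diameter (mm). The dispersed form has no core.
MORPHOMETRICS: dict[str, dict[str, float]] = {
    "hollow_pellet": {"fluffy_degree": 0.811, "core_diameter_mm": 3.88,
                      "colony_diameter_mm": 4.31},
    "fluffy_pellet": {"fluffy_degree": 0.438, "core_diameter_mm": 2.91,
                      "colony_diameter_mm": 4.41},
    "dispersed": {"fluffy_degree": 0.0, "core_diameter_mm": 0.0,
                  "colony_diameter_mm": 6.01},
}
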