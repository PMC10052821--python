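"""Published adjusted mean final germination proportions for the five
sexual Dilatata-group *Paspalum* species, one value per treatment level of
the two glasshouse germination designs (11 levels total).

Level order: stratification design (none, cold, warm), then the alternating
temperature x solution design in water (10/20, 15/25, 20/30, 25/35 C) and
in 0.2% KNO3 (same temperature order). These species-level means are the
worked-example inputs for the germination ability / evenness indices.
"""

TREATMENT_LEVELS = [
    "strat_none", "strat_cold", "strat_warm",
    "10/20_water", "15/25_water", "20/30_water", "25/35_water",
    "10/20_nitrate", "15/25_nitrate", "20/30_nitrate", "25/35_nitrate",
]

ADJUSTED_FGP = {
    "P. dasypleurum": [0.04, 0.08, 0.04, 0.00, 0.00, 0.11, 0.19,
                       0.00, 0.12, 0.39, 0.54],
    "P. flavescens":  [0.04, 0.49, 0.13, 0.00, 0.03, 0.31, 0.37,
                       0.01, 0.10, 0.96, 0.98],
    "P. plurinerve":  [0.54, 0.96, 0.83, 0.00, 0.21, 0.48, 0.39,
                       0.10, 0.98, 0.99, 0.99],
    "P. vacarianum":  [0.38, 0.86, 0.50, 0.00, 0.05, 0.89, 0.91,
                       0.02, 0.41, 0.98, 0.98],
    "P. urvillei":    [0.86, 0.97, 0.96, 0.04, 0.75, 0.83, 0.78,
                       0.81, 0.98, 0.99, 0.99],
}
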