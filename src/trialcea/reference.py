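"""Published summary values from the three-arm internet-therapy trial.

The analysis re-implements the economic evaluation of a Dutch randomized
trial comparing internet-based cognitive behavioural therapy (CBT),
internet-based problem-solving therapy (PST) and a waiting list (WL) for
adults with depressive symptoms. The raw participant-level data were never
deposited, but the publication prints enough summary arithmetic (unit
costs, per-arm cost means, clinically-significant-change counts) to anchor
the implementation. This module holds those printed values; they are used
as default unit costs, as inputs to the arithmetic verification, and as
calibration targets for the synthetic cohort generator.

All monetary values are Euros at 2007 price levels.
"""

from __future__ import annotations

ARMS = ("CBT", "PST", "WL")

#: Randomized sample sizes per arm.
ARM_N = {"CBT": 88, "PST": 88, "WL": 87}

#: Baseline CES-D depression score distribution (0-60 scale, inclusion >= 16).
CESD_BASELINE_MEAN = 31.7
CESD_BASELINE_SD = 7.5
CESD_CUTOFF = 16

#: Baseline EQ-5D utility (Dutch tariff).
UTILITY_BASELINE_MEAN = 0.61
UTILITY_BASELINE_SD = 0.22

#: Per-participant intervention costs (EUR), waiting list costs nothing.
INTERVENTION_COST = {"CBT": 501.0, "PST": 338.0, "WL": 0.0}

#: Rate constants used to value direct nonmedical costs (EUR, 2007).
KM_RATE = 0.17          # per kilometre travelled
PARKING_RATE = 2.64     # per hour of parking (one hour assumed per visit)
TIME_RATE = 8.83        # per hour of patient time / domestic help

# Unit-cost table for health services: service slug ->
# (printed name, unit, direct medical unit cost EUR,
#  travel distance km, patient time hours, printed direct nonmedical EUR).
UNIT_COSTS = {
    "gp": ("General practitioner", "Consultation", 21.36, 1.8, 1.0, 11.80),
    "mental_health": ("Regional mental health service", "Contact",
                      131.14, 10.0, 3.0, 30.84),
    "psychotherapist": ("Private practice psychotherapist", "Session",
                        80.38, 5.0, 2.0, 21.16),
    "psychotherapist_hospital": ("Psychotherapist hospital", "Consultation",
                                 76.08, 7.0, 3.0, 30.31),
    "company_doctor": ("Company doctor", "Consultation",
                       22.47, 0.0, 1.0, 8.83),
    "company_social_worker": ("Social worker in company", "Contact",
                              50.62, 7.0, 3.0, 30.31),
    "specialist": ("Medical specialist", "Consultation",
                   103.64, 7.0, 2.0, 21.48),
    "physiotherapist": ("Physiotherapist", "Contact",
                        24.06, 1.8, 2.0, 20.63),
    "social_worker": ("Social worker", "Contact", 50.62, 7.0, 3.0, 30.31),
    "alcohol_drugs": ("Consultation alcohol/drugs", "Contact",
                      131.14, 10.0, 3.0, 30.84),
    "home_care": ("Home care", "Hour", 32.47, 0.0, 0.0, 0.00),
    "alternative_care": ("Alternative care", "Contact",
                         47.00, 7.0, 3.0, 30.31),
    "self_help": ("Self-help group", "Session", 8.83, 7.0, 3.0, 30.31),
}

SERVICES = tuple(UNIT_COSTS)

#: Per-arm estimated per-capita costs over the 12-week horizon (Table 3
#: layout): mean (sd) by category, EM-imputed data.
COST_TABLE = {
    "CBT": {"intervention": 501.0, "health_care": (441.0, 452.0),
            "medication": (17.0, 25.0), "direct_medical": (958.0, 462.0),
            "direct_nonmedical": (156.0, 156.0), "indirect": (1701.0, 2562.0),
            "total": (2814.0, 2683.0)},
    "PST": {"intervention": 338.0, "health_care": (513.0, 453.0),
            "medication": (15.0, 26.0), "direct_medical": (888.0, 461.0),
            "direct_nonmedical": (175.0, 162.0), "indirect": (1642.0, 2669.0),
            "total": (2705.0, 2851.0)},
    "WL": {"intervention": 0.0, "health_care": (472.0, 538.0),
           "medication": (18.0, 30.0), "direct_medical": (490.0, 544.0),
           "direct_nonmedical": (168.0, 203.0), "indirect": (1900.0, 3544.0),
           "total": (2558.0, 3691.0)},
}

#: Reported counts of participants with reliable and clinically significant
#: change at 12 weeks (numerator) out of the randomized arm size.
RCSC_COUNTS = {"CBT": (25, 88), "PST": (23, 88), "WL": (13, 87)}

#: Reported chi-square test on those counts.
RCSC_CHI2 = 5.10
RCSC_CHI2_DF = 2
RCSC_CHI2_P = 0.08

#: Participants returning cost data at the 12-week follow-up, by arm.
COST_DATA_RETURNED = {"CBT": 45, "PST": 40, "WL": 62}
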