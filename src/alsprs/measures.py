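"""Registry of the 11 longitudinal clinical instruments.

Eight Edinburgh Cognitive and Behavioural ALS Screen (ECAS) scores cover
overall cognition and its domains; the ALSFRS-R and clinician-rated upper /
lower motor-neuron (UMN/LMN) burden scores cover motor function.  Instrument
bounds are the published score ranges; baseline means and SDs are
cohort-realistic values for an ALS natural-history population, and monthly
slope scales are typical decline rates for such cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class MeasureSpec:
    """Static description of one clinical instrument.

    ``baseline_mean``/``baseline_sd`` describe the between-subject
    distribution of true baseline scores; ``slope_mean``/``slope_sd`` the
    distribution of true monthly rates of change (points/month).
    ``noise_sd`` is the within-visit measurement error.  ``kind`` separates
    cognitive measures (driven by the planted genetic composite in the
    simulator) from motor measures (independent of it by construction).
    """

    name: str
    lo: float
    hi: float
    baseline_mean: float
    baseline_sd: float
    slope_mean: float
    slope_sd: float
    noise_sd: float
    kind: str  # "cognitive" | "motor"


MEASURES: dict[str, MeasureSpec] = {
    m.name: m
    for m in [
        MeasureSpec("ecas_total", 0, 136, 106.0, 15.0, -0.25, 0.50, 3.5, "cognitive"),
        MeasureSpec("ecas_als_specific", 0, 100, 79.0, 11.0, -0.20, 0.40, 2.8, "cognitive"),
        MeasureSpec("ecas_als_nonspecific", 0, 36, 27.5, 4.2, -0.08, 0.15, 1.1, "cognitive"),
        MeasureSpec("ecas_executive", 0, 48, 37.0, 6.5, -0.10, 0.22, 1.7, "cognitive"),
        MeasureSpec("ecas_language", 0, 28, 25.3, 2.6, -0.06, 0.10, 0.7, "cognitive"),
        MeasureSpec("ecas_fluency", 0, 24, 16.5, 5.2, -0.07, 0.18, 1.3, "cognitive"),
        MeasureSpec("ecas_memory", 0, 24, 16.0, 4.0, -0.06, 0.14, 1.1, "cognitive"),
        MeasureSpec("ecas_visuospatial", 0, 12, 11.3, 0.8, -0.02, 0.03, 0.25, "cognitive"),
        MeasureSpec("alsfrs_r", 0, 48, 35.0, 6.8, -0.70, 0.50, 2.0, "motor"),
        MeasureSpec("umn_burden", 0, 10, 2.7, 1.7, 0.04, 0.06, 0.5, "motor"),
        MeasureSpec("lmn_burden", 0, 10, 2.5, 1.6, 0.05, 0.06, 0.5, "motor"),
    ]
}

MEASURE_NAMES: tuple[str, ...] = tuple(MEASURES)
COGNITIVE_MEASURES: tuple[str, ...] = tuple(m for m, s in MEASURES.items() if s.kind == "cognitive")
MOTOR_MEASURES: tuple[str, ...] = tuple(m for m, s in MEASURES.items() if s.kind == "motor")

# Covariates recorded once per subject and entered as fixed effects in every
# mixed model: age at baseline (years), lag from symptom onset to baseline
# (years), college education (0/1), bulbar onset (0/1).
BASELINE_COVARIATES: tuple[str, ...] = ("age_at_baseline", "onset_lag", "college", "bulbar_onset")
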