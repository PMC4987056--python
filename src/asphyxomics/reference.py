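"""Published summary statistics of the newborn-pig asphyxia/resuscitation study.

These constants parameterize the synthetic cohort generator:

* the six resuscitation protocol groups with their sample sizes and the
  median (IQR) times to asystole and to return of spontaneous circulation
  (ROSC),
* per-group sample availability for plasma and urine at the three sampling
  time points t1 (baseline), t2 (2 h after ROSC) and t3 (4 h after ROSC),
* the plasma and urine metabolite panels: signal position (ppm),
  multiplicity, protons per signal, median (IQR) concentration at each time
  point, and the signed pairwise fold changes t1->t2 and t2->t3.

Concentrations are in mM for identified metabolites; "unknown" signals are
in arbitrary units (unresolved proton counts) and are rendered with a
nominal single proton.

Time-to-asystole values are stored as printed; their unit is configurable
in the generator (the asphyxiation protocol ran over tens of minutes, so
the default interpretation is minutes, while ROSC times are seconds).
"""

from __future__ import annotations

import math

from scipy.stats import norm

#: standard-normal 75% quantile used in median/IQR <-> lognormal conversion
Z75 = float(norm.ppf(0.75))


def fit_lognormal_from_median_iqr(median: float, q1: float, q3: float) -> tuple[float, float]:
    """Moment-match a log-normal to a printed median and interquartile range.

    Returns ``(mu, sigma)`` such that ``exp(mu) == median`` and the
    distribution's quartiles are ``(q1, q3)``:
    ``sigma = ln(q3/q1) / (2 * z_0.75)``.

    If ``q1 == 0`` (quartiles truncated at zero in the published tables)
    the scale is estimated from the upper half only,
    ``sigma = ln(q3/median) / z_0.75``; if additionally ``q3 == median``
    the distribution degenerates to a point mass (``sigma = 0``).
    """
    if median <= 0:
        raise ValueError(f"median must be positive, got {median}")
    if q1 < 0 or q3 <= 0:
        raise ValueError(f"quartiles must be non-negative with q3 > 0, got ({q1}, {q3})")
    if not (q1 <= median <= q3):
        raise ValueError(f"quartiles must bracket the median: q1={q1} median={median} q3={q3}")
    mu = math.log(median)
    if q1 == q3:
        return mu, 0.0
    if q1 == 0.0:
        sigma = math.log(q3 / median) / Z75
    else:
        sigma = math.log(q3 / q1) / (2.0 * Z75)
    return mu, sigma


# --------------------------------------------------------------------------
# Resuscitation protocol groups.
# fields: group id, n animals, initial ventilation [s], FiO2, C:V ratio,
#         time to asystole median (q1, q3), time to ROSC median (q1, q3) [s]
RESUSCITATION_GROUPS = [
    (1, 21, 30, 1.00, "3:1", (28.0, 24.0, 35.0), (135.0, 121.0, 168.0)),
    (2, 32, 30, 0.21, "3:1", (32.5, 27.8, 35.5), (146.0, 125.0, 173.0)),
    (3, 21, 60, 0.21, "3:1", (32.0, 29.0, 35.0), (170.0, 146.0, 184.0)),
    (4, 8, 90, 0.21, "3:1", (33.0, 30.3, 36.0), (250.0, 202.5, 330.0)),
    (5, 16, 30, 0.21, "9:3", (35.0, 30.8, 40.3), (145.0, 118.0, 173.0)),
    (6, 12, 30, 0.21, "15:2", (37.0, 33.5, 39.0), (195.0, 155.0, 315.0)),
]

# Available samples per group, material and time point (groups 1-6).
# {group: {(material, timepoint): n_available}}
SAMPLE_AVAILABILITY = {
    1: {("plasma", "t1"): 20, ("urine", "t1"): 18, ("plasma", "t2"): 21,
        ("urine", "t2"): 16, ("plasma", "t3"): 17, ("urine", "t3"): 7},
    2: {("plasma", "t1"): 32, ("urine", "t1"): 29, ("plasma", "t2"): 28,
        ("urine", "t2"): 24, ("plasma", "t3"): 25, ("urine", "t3"): 12},
    3: {("plasma", "t1"): 21, ("urine", "t1"): 17, ("plasma", "t2"): 20,
        ("urine", "t2"): 13, ("plasma", "t3"): 15, ("urine", "t3"): 9},
    4: {("plasma", "t1"): 8, ("urine", "t1"): 7, ("plasma", "t2"): 8,
        ("urine", "t2"): 5, ("plasma", "t3"): 7, ("urine", "t3"): 4},
    5: {("plasma", "t1"): 16, ("urine", "t1"): 16, ("plasma", "t2"): 16,
        ("urine", "t2"): 15, ("plasma", "t3"): 15, ("urine", "t3"): 7},
    6: {("plasma", "t1"): 11, ("urine", "t1"): 11, ("plasma", "t2"): 8,
        ("urine", "t2"): 8, ("plasma", "t3"): 9, ("urine", "t3"): 8},
}

TIMEPOINTS = ("t1", "t2", "t3")


# --------------------------------------------------------------------------
# Metabolite panels.
#
# Row layout:
#   (name, ppm, multiplicity, protons, identified,
#    (t1 median, q1, q3), (t2 median, q1, q3), (t3 median, q1, q3),
#    fc_t1_t2, fc_t2_t3)
#
# Fold changes use the signed convention: the geometric-mean ratio when
# >= 1, its negative reciprocal when < 1 (e.g. -1.38 means a factor 1/1.38).
# Proton counts for identified metabolites are the standard assignments of
# the quantified signal (e.g. lactate CH3 doublet at 1.33 ppm -> 3 protons,
# the glucose alpha-anomeric doublet at 5.24 ppm -> 1 proton); unknown
# signals are carried with a nominal 1 proton and arbitrary units.

PLASMA_PANEL = [
    ("Acetate",          1.91, "s", 3, True,  (0.0053, 0.000061, 0.018), (0.014, 0.00023, 0.087), (0.014, 0.0028, 0.1),   2.82, 1.6),
    ("Alanine",          1.48, "d", 3, True,  (0.64, 0.37, 1.0),        (1.5, 0.64, 2.6),        (1.2, 0.43, 2.6),       2.21, -1.38),
    ("Choline",          3.19, "s", 9, True,  (0.013, 0.0, 0.049),      (0.061, 0.012, 0.14),    (0.077, 0.021, 0.22),   4.85, 1.22),
    ("Creatinine",       4.05, "s", 2, True,  (0.034, 0.023, 0.05),     (0.045, 0.022, 0.063),   (0.061, 0.038, 0.082),  1.29, 1.27),
    ("DMA",              2.72, "s", 6, True,  (0.0078, 0.0042, 0.012),  (0.0088, 0.0048, 0.012), (0.0099, 0.0058, 0.013), 1.15, 1.09),
    ("Formate",          8.45, "s", 1, True,  (0.0083, 0.0, 0.043),     (0.012, 0.0, 0.054),     (0.018, 0.0, 0.035),    1.4, 1.81),
    ("Fumarate",         6.51, "s", 2, True,  (0.0056, 0.0017, 0.013),  (0.033, 0.0047, 0.083),  (0.019, 0.0012, 0.085), 4.85, -1.56),
    ("Glucose",          5.24, "d", 1, True,  (6.0, 4.1, 8.6),          (11.0, 5.5, 20.0),       (6.6, 2.7, 16.0),       1.77, -1.53),
    ("Glutamine",        2.45, "m", 2, True,  (0.27, 0.19, 0.4),        (0.45, 0.25, 0.76),      (0.51, 0.25, 1.0),      1.65, 1.06),
    ("Glycerol",         3.57, "m", 2, True,  (0.18, 0.0041, 0.39),     (0.35, 0.045, 1.0),      (0.2, 0.018, 2.2),      1.8, -1.2),
    ("Glycine",          3.55, "s", 2, True,  (0.61, 0.39, 1.0),        (0.95, 0.39, 1.5),       (0.89, 0.43, 1.7),      1.44, 1.03),
    ("Hypoxanthine",     8.20, "s", 1, True,  (0.041, 0.023, 0.068),    (0.12, 0.036, 0.26),     (0.06, 0.017, 0.27),    2.63, -1.6),
    ("Isoleucine",       1.00, "d", 3, True,  (0.097, 0.061, 0.16),     (0.1, 0.055, 0.2),       (0.065, 0.044, 0.18),   1.06, -1.39),
    ("Lactate",          1.33, "d", 3, True,  (2.9, 1.5, 5.3),          (10.0, 3.7, 16.0),       (5.3, 1.3, 16.0),       3.07, -1.75),
    ("Leucine",          0.95, "d", 6, True,  (0.11, 0.074, 0.17),      (0.14, 0.054, 0.32),     (0.089, 0.053, 0.29),   1.23, -1.37),
    ("Malate",           2.65, "m", 1, True,  (0.013, 0.0, 0.062),      (0.13, 0.013, 0.28),     (0.088, 0.02, 0.29),    6.69, -1.07),
    ("Methionine",       2.63, "t", 2, True,  (0.032, 0.0019, 0.077),   (0.032, 0.0045, 0.087),  (0.03, 0.0, 0.088),     1.02, -1.22),
    ("Myo-inositol",     4.06, "t", 1, True,  (0.064, 0.0, 0.39),       (0.2, 0.045, 0.6),       (0.23, 0.037, 0.6),     2.26, 1.02),
    ("Phenylalanine",    7.33, "m", 3, True,  (0.051, 0.026, 0.079),    (0.064, 0.018, 0.14),    (0.046, 0.018, 0.13),   1.22, -1.27),
    ("Proline",          4.14, "m", 1, True,  (0.49, 0.32, 0.84),       (0.57, 0.34, 0.92),      (0.57, 0.32, 0.94),     1.08, -1.09),
    ("Pyruvate",         2.37, "s", 3, True,  (0.1, 0.059, 0.21),       (0.21, 0.11, 0.34),      (0.2, 0.058, 0.33),     2.0, -1.22),
    ("Succinate",        2.40, "s", 4, True,  (0.015, 0.0054, 0.035),   (0.17, 0.0095, 0.62),    (0.072, 0.0035, 0.44),  7.67, -1.54),
    ("Trimethylamine",   2.88, "s", 9, True,  (0.0011, 0.0, 0.0033),    (0.0046, 0.00083, 0.016), (0.0054, 0.00092, 0.019), 4.43, 1.26),
    ("Tyrosine",         7.20, "d", 2, True,  (0.11, 0.059, 0.2),       (0.13, 0.066, 0.22),     (0.11, 0.047, 0.19),    1.21, -1.22),
    ("Valine",           1.03, "d", 3, True,  (0.19, 0.11, 0.34),       (0.22, 0.082, 0.45),     (0.16, 0.069, 0.36),    1.08, -1.36),
    ("Unknown doublet 1.06",   1.06, "d", 1, False, (1.6, 0.094, 4.5),  (2.1, 0.0015, 5.1),      (1.9, 0.7, 4.6),        1.34, -1.04),
    ("Unknown doublet 1.11",   1.11, "d", 1, False, (2.7, 1.8, 3.8),    (2.2, 0.33, 3.7),        (2.4, 1.1, 3.9),        -1.59, 1.09),
    ("Unknown doublet 1.14",   1.14, "d", 1, False, (0.19, 0.12, 0.47), (0.14, 0.083, 0.43),     (0.14, 0.063, 0.28),    -1.27, -1.07),
    ("Unknown multiplet 1.40", 1.40, "m", 1, False, (40.0, 24.0, 63.0), (23.0, 9.1, 43.0),       (25.0, 9.4, 43.0),      -1.92, -1.06),
    ("Unknown singlet 3.92",   3.92, "s", 1, False, (2.7, 1.3, 7.7),    (3.3, 0.8, 14.0),        (3.4, 1.4, 25.0),       1.14, 1.3),
    ("Unknown singlet 5.39",   5.39, "s", 1, False, (1.1, 0.24, 2.8),   (1.9, 0.25, 6.0),        (2.6, 0.34, 8.0),       1.78, 1.16),
]

#: TSP full width at half maximum [ppm] in plasma (lipoprotein proxy):
#: median (q1, q3) at t1/t2/t3 and its pairwise signed fold changes.
PLASMA_TSP_FWHM = {
    "t1": (0.0047, 0.003, 0.007),
    "t2": (0.004, 0.0026, 0.0052),
    "t3": (0.0038, 0.0027, 0.0051),
    "fc_t1_t2": -1.24,
    "fc_t2_t3": -1.02,
}

URINE_PANEL = [
    ("1-Methylnicotinamide", 8.95, "s", 1, True, (0.14, 0.042, 0.93),   (0.15, 0.055, 0.7),     (0.19, 0.055, 0.6),     1.14, 1.16),
    ("3-Hydroxyisovalerate", 1.27, "s", 6, True, (0.035, 0.025, 0.078), (0.03, 0.022, 0.068),   (0.028, 0.02, 0.06),    -1.18, -1.1),
    ("Alanine",          1.48, "d", 3, True,  (0.42, 0.17, 1.5),        (1.1, 0.4, 2.9),        (1.3, 0.54, 4.5),       2.29, 1.25),
    ("Ascorbate",        4.52, "d", 1, True,  (0.83, 0.11, 3.9),        (0.9, 0.17, 3.4),       (0.86, 0.15, 3.2),      1.21, -1.04),
    ("Choline",          3.21, "s", 9, True,  (0.12, 0.041, 0.67),      (0.29, 0.051, 1.1),     (0.32, 0.076, 1.9),     1.91, 1.12),
    ("Creatinine",       4.05, "s", 2, True,  (3.0, 1.5, 8.6),          (2.5, 0.92, 7.4),       (2.0, 0.76, 5.1),       -1.27, -1.17),
    ("Formate",          8.47, "s", 1, True,  (0.49, 0.16, 1.2),        (0.31, 0.12, 0.92),     (0.26, 0.11, 0.86),     -1.32, -1.25),
    ("Fumarate",         6.52, "s", 2, True,  (0.22, 0.077, 1.2),       (0.29, 0.11, 0.98),     (0.25, 0.1, 0.55),      1.24, -1.09),
    ("Glucose",          5.24, "d", 1, True,  (2.0, 0.5, 7.9),          (10.0, 2.3, 50.0),      (13.0, 2.3, 70.0),      5.2, 1.2),
    ("Glycine",          3.57, "s", 2, True,  (2.4, 0.56, 9.8),         (2.8, 1.0, 7.2),        (2.9, 0.99, 11.0),      1.39, 1.04),
    ("Hippurate",        7.55, "t", 1, True,  (0.71, 0.099, 5.4),       (0.75, 0.18, 4.3),      (0.57, 0.067, 4.0),     1.28, -1.19),
    ("Hypoxanthine",     8.21, "s", 1, True,  (0.13, 0.0, 0.79),        (0.41, 0.065, 1.4),     (0.38, 0.07, 1.7),      3.44, 1.1),
    ("Lactate",          1.33, "d", 3, True,  (1.2, 0.81, 3.7),         (9.7, 1.6, 28.0),       (12.0, 1.8, 32.0),      6.17, 1.14),
    ("Leucine",          0.97, "d", 6, True,  (0.058, 0.039, 0.1),      (0.089, 0.051, 0.26),   (0.1, 0.053, 0.21),     1.59, 1.1),
    ("Lysine",           1.72, "m", 2, True,  (0.14, 0.0, 2.3),         (0.16, 0.0, 0.89),      (0.16, 0.035, 0.89),    -1.11, 1.04),
    ("N,N-Dimethylglycine", 2.93, "s", 6, True, (1.0, 0.21, 3.1),       (0.63, 0.16, 2.4),      (0.53, 0.071, 2.0),     -1.45, -1.23),
    ("N-phenylacetylglycine", 7.43, "m", 2, True, (1.3, 0.45, 6.8),     (0.92, 0.2, 4.7),       (0.84, 0.18, 3.3),      -1.38, -1.17),
    ("Succinate",        2.41, "s", 4, True,  (0.28, 0.088, 1.0),       (0.6, 0.18, 1.3),       (0.48, 0.17, 1.2),      1.92, 1.0),
    ("Trimethylamine",   2.88, "s", 9, True,  (0.15, 0.0, 1.2),         (0.16, 0.0, 0.72),      (0.17, 0.0, 1.5),       1.09, 1.2),
    ("Trimethylamine-N-Oxide", 3.27, "s", 9, True, (1.5, 0.0, 6.0),     (1.3, 0.0, 4.0),        (1.2, 0.0, 3.8),        -1.03, 1.01),
    ("Valine",           1.05, "d", 3, True,  (0.039, 0.016, 0.093),    (0.12, 0.03, 0.35),     (0.14, 0.042, 0.35),    2.81, 1.42),
    ("Unknown doublet 1.08",   1.08, "d", 1, False, (0.059, 0.038, 0.24), (0.062, 0.042, 0.15), (0.062, 0.04, 0.21),    -1.02, -1.06),
    ("Unknown doublet 1.11",   1.11, "d", 1, False, (0.089, 0.069, 0.17), (0.085, 0.067, 0.16), (0.081, 0.065, 0.12),   -1.06, -1.03),
    ("Unknown doublet 1.15",   1.15, "d", 1, False, (0.16, 0.05, 0.48),  (0.3, 0.12, 0.74),     (0.3, 0.15, 0.71),      2.06, 1.06),
    ("Unknown doublet 1.25",   1.25, "d", 1, False, (0.18, 0.11, 0.37),  (0.12, 0.061, 0.29),   (0.11, 0.052, 0.2),     -1.46, -1.19),
    ("Unknown doublet 1.38",   1.38, "d", 1, False, (0.069, 0.033, 0.21), (0.062, 0.029, 0.19), (0.057, 0.026, 0.15),   -1.16, -1.02),
    ("Unknown doublet 5.10",   5.10, "d", 1, False, (0.0038, 0.0, 0.0057), (0.0059, 0.0015, 0.022), (0.007, 0.0027, 0.03), 1.99, 1.16),
    ("Unknown doublet 5.48",   5.48, "d", 1, False, (0.00074, 0.0, 0.0054), (0.00056, 0.0, 0.0038), (0.00062, 0.0002, 0.0031), -1.31, -1.08),
    ("Unknown doublet 5.70",   5.70, "d", 1, False, (0.12, 0.019, 0.54), (0.098, 0.0061, 0.45), (0.082, 0.013, 0.39),   -1.38, -1.16),
    ("Unknown multiplet 6.65", 6.65, "m", 1, False, (0.0072, 0.0025, 0.028), (0.0044, 0.0014, 0.028), (0.0042, 0.0, 0.015), -1.42, -1.17),
    ("Unknown multiplet 6.76", 6.76, "m", 1, False, (0.011, 0.0054, 0.037), (0.0081, 0.003, 0.034), (0.008, 0.0012, 0.018), -1.33, -1.26),
    ("Unknown multiplet 6.79", 6.79, "m", 1, False, (0.0081, 0.0034, 0.027), (0.0057, 0.0011, 0.026), (0.0041, 0.00045, 0.014), -1.53, -1.45),
    ("Unknown multiplet 7.68", 7.68, "m", 1, False, (0.18, 0.083, 0.53), (0.14, 0.047, 0.46),   (0.12, 0.029, 0.29),    -1.32, -1.24),
    ("Unknown singlet 6.78",   6.78, "s", 1, False, (0.0034, 0.0, 0.017), (0.0016, 0.0, 0.011), (0.0013, 0.0, 0.0095),  -2.12, -1.06),
    ("Unknown triplet 6.29",   6.29, "t", 1, False, (0.0062, 0.0, 0.067), (0.003, 0.0, 0.039),  (0.0032, 0.0, 0.031),   -1.4, -1.1),
]

#: baseline endpoint correlations used by the generator defaults:
#: Pearson r between log concentration at t1 and the duration of hypoxia
#: (time to asystole); lower hypoxanthine <-> longer endurance.
ENDPOINT_CORRELATIONS = {"Hypoxanthine": -0.23}

#: Pearson r between the (log) TSP broadening factor, a lipoprotein proxy,
#: and the duration of hypoxia: broader TSP <-> shorter endurance.
TSP_BROADENING_ASYSTOLE_R = -0.26


def panel_rows(material: str) -> list:
    """Return the raw panel rows for ``'plasma'`` or ``'urine'``."""
    if material == "plasma":
        return PLASMA_PANEL
    if material == "urine":
        return URINE_PANEL
    raise ValueError(f"unknown material {material!r}; expected 'plasma' or 'urine'")
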