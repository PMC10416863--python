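"""Published group-mean estimates for Ross 308 AP broiler flocks.

Group-mean growth-curve parameters, 35-d feed conversion ratios, FCR
trajectories and coefficients of variation reported for male and female
Ross 308 AP broiler flocks reared to 35 d under commercial tropical
conditions with controlled feeding, split into high-efficiency (HE) and
low-efficiency (LE) groups by 35-d FCR.  These serve two roles: the worked
examples for the closed-form inflection traits, and the default generating
conditions of the synthetic flock simulator.

Keys are ``(sex, efficiency)`` with sex in {male, female} and efficiency in
{HE, LE}; HE flocks have the *lower* FCR (less feed per unit body weight).
"""

from __future__ import annotations

from .models import GompertzLairdParams, LogisticParams, VonBertalanffyParams

#: Logistic group means: asymptote W_A (g), growth rate K (1/d), inflection age t_i (d).
LOGISTIC_GROUP_MEANS: dict[tuple[str, str], LogisticParams] = {
    ("male", "LE"): LogisticParams(w_a=2934.0, k=0.122, t_i=30.0),
    ("male", "HE"): LogisticParams(w_a=3655.0, k=0.114, t_i=34.0),
    ("female", "LE"): LogisticParams(w_a=2657.0, k=0.119, t_i=30.0),
    ("female", "HE"): LogisticParams(w_a=3020.0, k=0.117, t_i=32.0),
}

#: Gompertz–Laird group means: hatch weight W_0 (g), initial growth rate L, decay K (1/d).
GOMPERTZ_LAIRD_GROUP_MEANS: dict[tuple[str, str], GompertzLairdParams] = {
    ("male", "LE"): GompertzLairdParams(w_0=50.0, l=0.188, k=0.038),
    ("male", "HE"): GompertzLairdParams(w_0=57.0, l=0.163, k=0.029),
    ("female", "LE"): GompertzLairdParams(w_0=51.0, l=0.182, k=0.038),
    ("female", "HE"): GompertzLairdParams(w_0=52.0, l=0.172, k=0.033),
}

#: von Bertalanffy group means: asymptote W_A (g), integration constant B, rate K (1/d).
VON_BERTALANFFY_GROUP_MEANS: dict[tuple[str, str], VonBertalanffyParams] = {
    ("male", "LE"): VonBertalanffyParams(w_a=143570.0, b=0.911, k=0.010),
    ("male", "HE"): VonBertalanffyParams(w_a=678172.0, b=0.940, k=0.006),
    ("female", "LE"): VonBertalanffyParams(w_a=92429.0, b=0.899, k=0.010),
    ("female", "HE"): VonBertalanffyParams(w_a=370448.0, b=0.930, k=0.006),
}

#: Group-mean cumulative FCR at 35 d (g feed : g BW); HE < LE within each sex.
FCR35_GROUP_MEANS: dict[tuple[str, str], float] = {
    ("male", "LE"): 1.527,
    ("male", "HE"): 1.371,
    ("female", "LE"): 1.526,
    ("female", "HE"): 1.426,
}

#: Group-mean cumulative FCR trajectory by age (d); used as the shape template
#: the simulator rescales to each flock's drawn 35-d FCR.
FCR_TRAJECTORIES: dict[tuple[str, str], dict[int, float]] = {
    ("male", "LE"): {7: 0.882, 14: 1.179, 21: 1.327, 28: 1.424, 35: 1.527},
    ("male", "HE"): {7: 0.841, 14: 1.131, 21: 1.251, 28: 1.322, 35: 1.371},
    ("female", "LE"): {7: 0.883, 14: 1.172, 21: 1.317, 28: 1.419, 35: 1.526},
    ("female", "HE"): {7: 0.846, 14: 1.126, 21: 1.265, 28: 1.350, 35: 1.426},
}

#: Between-flock coefficient of variation (%) of body weight by age (d):
#: roughly 6% in early life shrinking to ~3.5% at 35 d.
BW_CV_BY_AGE: dict[int, float] = {0: 6.1, 7: 6.5, 14: 5.9, 21: 5.5, 28: 4.7, 35: 3.4}

#: Mean within-week mortality (%), on the 0.4–1.0% scale typical of these flocks.
MORT_WEEKLY_MEAN: float = 0.55
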