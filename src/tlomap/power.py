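"""Monte-Carlo power analysis under a nested linear mixed model.

The study design has two patient groups, replicate tissue sections per
patient, and replicate spatially annotated niches (spots) per section.
The outcome follows

    y = beta * group + u_patient + v_section + eps,

with independent Gaussian random effects ``u ~ N(0, var_patient)``,
``v ~ N(0, var_section)`` and residual ``eps ~ N(0, var_resid)``; the
group effect ``beta`` is specified in residual-SD units. The default
test is a pooled two-sample t on patient means — exact for this nested
model (group variances are equal by construction) and cheap enough for
dense design grids. Power is the Monte-Carlo rejection fraction at level alpha, with
a target of 80% ("saturation").
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError

POWER_TARGET = 0.8


@dataclass
class PowerDesign:
    n_patients_per_group: int = 3
    n_sections_per_patient: int = 4
    n_spots_per_condition: int = 80
    effect_size: float = 1.0  # in residual-SD units
    var_patient: float = 0.5
    var_section: float = 0.25
    var_resid: float = 1.0
    alpha: float = 0.05
    n_sim: int = 2000
    seed: int = 0
    test: str = "patient_t"  # or "lmm_wald"

    def __post_init__(self) -> None:
        for name in ("n_patients_per_group", "n_sections_per_patient",
                     "n_spots_per_condition", "n_sim"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.n_patients_per_group < 2:
            raise ParameterError("need at least 2 patients per group for a t test")
        for name in ("var_patient", "var_section", "var_resid"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")
        if not 0.0 < self.alpha < 1.0:
            raise ParameterError("alpha must be in (0, 1)")
        if self.test not in ("patient_t", "lmm_wald"):
            raise ParameterError(f"unknown test {self.test!r}")


@dataclass
class PowerResult:
    power: float
    monte_carlo_se: float
    reached_target: bool
    design: PowerDesign
    target: float = POWER_TARGET


def _patient_mean_sd(d: PowerDesign) -> float:
    """SD of a patient's mean over its sections x spots under the model."""
    S, K = d.n_sections_per_patient, d.n_spots_per_condition
    return float(np.sqrt(d.var_patient + d.var_section / S + d.var_resid / (S * K)))


def _pooled_t(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorized two-sided pooled-variance t p-values (samples last axis).

    Group variances are equal by construction under the simulated
    model, so the pooled test is exact; a Welch correction would be
    conservative at the small per-group sizes typical of these designs
    (3-5 patients) and visibly undershoot the nominal size.
    """
    na, nb = a.shape[-1], b.shape[-1]
    sp2 = ((na - 1) * a.var(axis=-1, ddof=1) + (nb - 1) * b.var(axis=-1, ddof=1)) / (
        na + nb - 2
    )
    t = (a.mean(axis=-1) - b.mean(axis=-1)) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    return 2.0 * stats.t.sf(np.abs(t), na + nb - 2)


def simulate_power(d: PowerDesign) -> PowerResult:
    """Monte-Carlo power of the group test under the nested design."""
    if d.n_sim < 100:
        warnings.warn("n_sim < 100: Monte-Carlo SE too large for 0.8 decisions")
    beta = d.effect_size * np.sqrt(d.var_resid)
    rng = np.random.default_rng(d.seed)
    P = d.n_patients_per_group
    if d.test == "patient_t":
        # patient means are sufficient; simulate them directly
        sd = _patient_mean_sd(d)
        a = beta + sd * rng.standard_normal((d.n_sim, P))
        b = sd * rng.standard_normal((d.n_sim, P))
        pvals = _pooled_t(a, b)
    else:
        pvals = np.array([_lmm_wald_once(d, beta, rng) for _ in range(d.n_sim)])
    power = float(np.mean(pvals < d.alpha))
    se = float(np.sqrt(power * (1.0 - power) / d.n_sim))
    return PowerResult(power, se, power >= POWER_TARGET, d)


def _lmm_wald_once(d: PowerDesign, beta: float, rng: np.random.Generator) -> float:
    """One replicate: fit a random-intercept LMM, Wald test on group."""
    import statsmodels.api as sm

    P, S, K = d.n_patients_per_group, d.n_sections_per_patient, d.n_spots_per_condition
    rows = []
    for g in (0, 1):
        for p in range(P):
            u = rng.normal(0.0, np.sqrt(d.var_patient))
            for s in range(S):
                v = rng.normal(0.0, np.sqrt(d.var_section))
                eps = rng.normal(0.0, np.sqrt(d.var_resid), K)
                y = beta * g + u + v + eps
                rows.append((g, f"g{g}p{p}", y))
    y = np.concatenate([r[2] for r in rows])
    group = np.concatenate([np.full(K, r[0]) for r in rows])
    patient = np.concatenate([np.full(K, r[1]) for r in rows])
    X = np.column_stack([np.ones_like(y), group])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.MixedLM(y, X, groups=patient).fit(reml=True, method="lbfgs")
        p = float(fit.pvalues[1])
        if np.isfinite(p):
            return p
    except Exception:  # noqa: BLE001 - boundary variance estimates
        pass
    # degenerate fit (variance at boundary): fall back to patient means
    frame = pd.DataFrame({"y": y, "g": group, "p": patient})
    means = frame.groupby(["p", "g"])["y"].mean().reset_index()
    a = means.loc[means.g == 1, "y"].to_numpy()[None, :]
    b = means.loc[means.g == 0, "y"].to_numpy()[None, :]
    return float(_pooled_t(a, b)[0])


def closed_form_power(d: PowerDesign) -> float:
    """Analytic two-sample t power on patient means (oracle check).

    Exact for the patient-mean test when the group variances are equal
    (they always are under this model).
    """
    sd = _patient_mean_sd(d)
    beta = d.effect_size * np.sqrt(d.var_resid)
    P = d.n_patients_per_group
    df = 2 * P - 2
    nc = beta / (sd * np.sqrt(2.0 / P))
    crit = stats.t.ppf(1.0 - d.alpha / 2.0, df)
    return float(stats.nct.sf(crit, df, nc) + stats.nct.cdf(-crit, df, nc))


def design_search(
    base: PowerDesign,
    n_patients: list[int],
    n_sections: list[int],
    n_spots: list[int],
    target: float = POWER_TARGET,
) -> pd.DataFrame:
    """Evaluate a design grid and mark the minimal designs meeting target.

    All designs share the base seed (common random numbers), so
    comparisons along the grid are low-variance. Returns one row per
    design with power, Monte-Carlo SE, ``reached_target``, and
    ``frontier`` — passing designs not dominated component-wise by a
    cheaper passing design.
    """
    rows = []
    for p, s, k in itertools.product(
        sorted(n_patients), sorted(n_sections), sorted(n_spots)
    ):
        d = replace(
            base,
            n_patients_per_group=p,
            n_sections_per_patient=s,
            n_spots_per_condition=k,
        )
        res = simulate_power(d)
        rows.append((p, s, k, res.power, res.monte_carlo_se, res.power >= target))
    frame = pd.DataFrame(
        rows,
        columns=["n_patients_per_group", "n_sections_per_patient",
                 "n_spots_per_condition", "power", "se", "reached_target"],
    )
    passing = frame[frame["reached_target"]]
    frontier = []
    dims = ["n_patients_per_group", "n_sections_per_patient", "n_spots_per_condition"]
    for i, row in passing.iterrows():
        dominated = (
            (passing[dims] <= row[dims]).all(axis=1)
            & (passing[dims] < row[dims]).any(axis=1)
        ).any()
        frontier.append((i, not dominated))
    frame["frontier"] = False
    for i, flag in frontier:
        frame.loc[i, "frontier"] = flag
    return frame
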