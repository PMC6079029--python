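"""Power and type-I-error simulation for the neighbour-corrected trans test.

The simulated system has four observed variables: two genetic instruments
correlated at r_gi (standing in for LD/local pleiotropy), the index gene's
expression (correlated r_gi_index with its GI), the nearby gene's
expression (correlated r_gi_nearby with its GI), and a target gene driven
either by the index gene (alternative scenario) or by the nearby gene
(null scenario for the index GI). For each draw the index-GI coefficient
is tested in two models — corrected (GI_nearby included as a covariate)
and uncorrected — and power is the fraction of replicates with p < alpha.
Under the null scenario the corrected model should reject at the nominal
rate while the uncorrected one rejects in excess whenever r_gi > 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._lm import add_intercept, ols, t_pvalue
from .core_io import DataError

SCENARIOS = ("index_drives", "nearby_drives")
MODELS = ("corrected", "uncorrected")


@dataclass(frozen=True)
class SimulationSetting:
    r_gi: float
    r_gi_index: float
    r_gi_nearby: float
    r_index_target: float
    r_nearby_target: float
    n: int = 3072
    scenario: str = "index_drives"
    model: str = "corrected"

    def __post_init__(self):
        for name in ("r_gi", "r_gi_index", "r_gi_nearby", "r_index_target",
                     "r_nearby_target"):
            r = getattr(self, name)
            if not -1.0 <= r <= 1.0:
                raise DataError(f"{name}={r} outside [-1, 1]")
        if self.n < 10:
            raise DataError("n must be >= 10")
        if self.scenario not in SCENARIOS:
            raise DataError(f"unknown scenario {self.scenario}")
        if self.model not in MODELS:
            raise DataError(f"unknown model {self.model}")


@dataclass(frozen=True)
class PowerEstimate:
    setting: SimulationSetting
    reps: int
    alpha: float
    power: float
    mc_se: float


@dataclass(frozen=True)
class SimulatedSystem:
    gi_index: np.ndarray
    gi_nearby: np.ndarray
    expr_index: np.ndarray
    expr_nearby: np.ndarray
    target: np.ndarray


def correlated_normal(
    x: np.ndarray, r: float, rng: np.random.Generator
) -> np.ndarray:
    """y = r*x + sqrt(1 - r^2)*eps for standardized x; corr(x, y) = r."""
    if not -1.0 <= r <= 1.0:
        raise DataError(f"correlation {r} outside [-1, 1]")
    x = np.asarray(x, dtype=float)
    return r * x + np.sqrt(1.0 - r * r) * rng.standard_normal(len(x))


def simulate_system(
    setting: SimulationSetting, rng: np.random.Generator
) -> SimulatedSystem:
    """One draw of the four-variable system under the setting's scenario."""
    gi_index = rng.standard_normal(setting.n)
    gi_nearby = correlated_normal(gi_index, setting.r_gi, rng)
    expr_index = correlated_normal(gi_index, setting.r_gi_index, rng)
    expr_nearby = correlated_normal(gi_nearby, setting.r_gi_nearby, rng)
    if setting.scenario == "index_drives":
        target = correlated_normal(expr_index, setting.r_index_target, rng)
    else:
        target = correlated_normal(expr_nearby, setting.r_nearby_target, rng)
    return SimulatedSystem(gi_index, gi_nearby, expr_index, expr_nearby, target)


def fit_sim_models(system: SimulatedSystem) -> tuple[float, float]:
    """Two-sided t-test p for the index-GI coefficient in both models.

    Corrected: target ~ GI_index + GI_nearby; uncorrected: target ~ GI_index.
    An intercept is included in both fits.
    """
    y = system.target
    Xc = add_intercept(system.gi_index, system.gi_nearby)
    Xu = add_intercept(system.gi_index)
    fc = ols(Xc, y, check_rank=False)
    fu = ols(Xu, y, check_rank=False)
    p_corr = float(t_pvalue(fc.coef[1], fc.se[1], fc.dof))
    p_unc = float(t_pvalue(fu.coef[1], fu.se[1], fu.dof))
    return p_corr, p_unc


def rejection_rate(p_values: np.ndarray, alpha: float = 0.05) -> float:
    """Fraction of replicates rejected at level alpha."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise DataError("no p-values")
    return float(np.mean(p < alpha))


def simulate_pvalues(
    setting: SimulationSetting, reps: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """(corrected, uncorrected) p-values over ``reps`` shared realizations."""
    rng = np.random.default_rng(seed)
    pc = np.empty(reps)
    pu = np.empty(reps)
    for i in range(reps):
        pc[i], pu[i] = fit_sim_models(simulate_system(setting, rng))
    return pc, pu


def estimate_power(
    setting: SimulationSetting,
    reps: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
) -> PowerEstimate:
    """Monte-Carlo rejection rate for the setting's model."""
    if reps < 1:
        raise DataError("reps must be >= 1")
    pc, pu = simulate_pvalues(setting, reps, seed)
    p = pc if setting.model == "corrected" else pu
    power = rejection_rate(p, alpha)
    return PowerEstimate(
        setting=setting,
        reps=reps,
        alpha=alpha,
        power=power,
        mc_se=float(np.sqrt(power * (1 - power) / reps)),
    )


def run_grid(
    correlations: list[dict] | list[tuple],
    n: int = 3072,
    reps: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Power for all four scenario x model combinations per correlation tuple.

    ``correlations`` is a list of dicts (r_gi, r_gi_index, r_gi_nearby,
    r_index_target, r_nearby_target) or 5-tuples in that order. Both models
    are evaluated on the same data realizations within a scenario, so the
    corrected/uncorrected columns are paired.
    """
    rows = []
    for i, cors in enumerate(correlations):
        if not isinstance(cors, dict):
            keys = ("r_gi", "r_gi_index", "r_gi_nearby", "r_index_target",
                    "r_nearby_target")
            cors = dict(zip(keys, cors))
        for scenario in SCENARIOS:
            setting = SimulationSetting(n=n, scenario=scenario, model="corrected",
                                        **cors)
            pc, pu = simulate_pvalues(setting, reps, seed + i)
            for model, p in (("corrected", pc), ("uncorrected", pu)):
                power = rejection_rate(p, alpha)
                rows.append(
                    {
                        **cors,
                        "n": n,
                        "scenario": scenario,
                        "model": model,
                        "reps": reps,
                        "alpha": alpha,
                        "power": power,
                        "mc_se": float(np.sqrt(power * (1 - power) / reps)),
                    }
                )
    return pd.DataFrame(rows)


DEFAULT_GRID = [
    {
        "r_gi": r,
        "r_gi_index": 0.3,
        "r_gi_nearby": 0.3,
        "r_index_target": 0.3,
        "r_nearby_target": 0.3,
    }
    for r in (0.1, 0.25, 0.4, 0.6, 0.8)
]
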