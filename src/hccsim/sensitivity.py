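"""One-way sensitivity sweeps, break-even finding, scenario grids and PSA.

All sweeps reuse a single frozen random substrate (common random numbers
across grid points and arms), so response curves are smooth in the swept
parameter and break-even (threshold) finding by bisection is well-posed.
The Monte Carlo half-width of the response at the crossing is always
reported alongside.

Beyond the literal model fields, three composite parameters can be swept:

* ``outreach_cost_annual`` -- one annual per-patient program cost applied to
  first and later years alike (the published program-cost axis);
* ``adherence_gain`` -- outreach-arm adherence expressed as percentage-point
  gain over the usual-care arm (the published effectiveness axis);
* ``early_survival_gain_years`` -- early-stage mean survival expressed as
  gain over late-stage survival (the published treatment-efficacy axis).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Optional

import numpy as np
import pandas as pd

from .cea import compare_arms, relative_early_increase
from .engine import draw_substrate, simulate_arm
from .parameters import (
    ModelParams,
    SimulationConfig,
    UnprintedParams,
    ValidationError,
)
from .parameters import draw_psa_params

__all__ = [
    "SweepSpec",
    "BreakevenResult",
    "apply_parameter",
    "one_way_sweep",
    "find_breakeven",
    "scenario_grid",
    "run_psa",
]

_COMPOSITES = ("outreach_cost_annual", "adherence_gain", "early_survival_gain_years")


def apply_parameter(params: ModelParams, unprinted: UnprintedParams,
                    name: str, value: float) -> tuple[ModelParams, UnprintedParams]:
    """Return copies of the parameter sets with one (possibly composite) field set."""
    if name == "outreach_cost_annual":
        return replace(params, outreach_cost_y1=value, outreach_cost_later=value), unprinted
    if name == "adherence_gain":
        return replace(params, adherence_outreach=params.adherence_usual + value), unprinted
    if name == "early_survival_gain_years":
        return replace(params, surv_early_hcc=params.surv_late_hcc + value), unprinted
    if name in {f.name for f in fields(ModelParams)}:
        return replace(params, **{name: value}), unprinted
    if name in {f.name for f in fields(UnprintedParams)}:
        return params, replace(unprinted, **{name: value})
    raise ValidationError(f"sweep parameter {name!r} is not a model field")


@dataclass
class SweepSpec:
    """One-way sweep definition."""

    parameter: str
    grid: list
    response: str = "delta_cost"        # delta_cost | delta_qaly | icer
    common_random_numbers: bool = True

    def validate(self) -> "SweepSpec":
        g = list(self.grid)
        if len(g) == 0:
            raise ValidationError("grid: must be non-empty")
        diffs = np.diff(g)
        if len(g) > 1 and not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise ValidationError("grid: must be strictly monotone")
        if self.response not in ("delta_cost", "delta_qaly", "icer"):
            raise ValidationError(f"response: unknown response {self.response!r}")
        known = ({f.name for f in fields(ModelParams)}
                 | {f.name for f in fields(UnprintedParams)} | set(_COMPOSITES))
        if self.parameter not in known:
            raise ValidationError(f"parameter {self.parameter!r} is not a model field")
        return self


def _paired(config, params, unprinted, substrate, substrate2):
    out = simulate_arm("outreach", config, params, unprinted, substrate)
    usual = simulate_arm("usual_care", config, params, unprinted, substrate2)
    return out, usual


def _delta_se(out, usual) -> tuple[float, float]:
    """Monte Carlo SEs of (delta total cost, delta total qaly) for paired arms."""
    n = out.n_patients
    dc = out.cost - usual.cost
    dq = out.qaly - usual.qaly
    return (float(dc.std(ddof=1) * np.sqrt(n)), float(dq.std(ddof=1) * np.sqrt(n)))


def one_way_sweep(spec: SweepSpec, params: ModelParams, unprinted: UnprintedParams,
                  config: SimulationConfig, seed: Optional[int] = None) -> pd.DataFrame:
    """Simulate both arms at each grid value, everything else at base case.

    Returns one row per grid point with the incremental responses, the
    comparison verdict and Monte Carlo SEs of the deltas.
    """
    spec.validate(); config.validate()
    base_seed = config.seed if seed is None else seed
    sub = draw_substrate(config, seed=base_seed)
    sub2 = sub if (spec.common_random_numbers and config.use_common_random_numbers) \
        else draw_substrate(config, seed=base_seed + 1)
    rows = []
    for value in spec.grid:
        p, u = apply_parameter(params, unprinted, spec.parameter, value)
        out, usual = _paired(config, p, u, sub, sub2)
        cmp = compare_arms(out, usual)
        se_c, se_q = _delta_se(out, usual)
        rows.append({
            "value": value,
            "delta_cost": cmp.delta_cost,
            "delta_qaly": cmp.delta_qaly,
            "icer": cmp.icer,
            "verdict": cmp.verdict,
            "delta_cost_se": se_c,
            "delta_qaly_se": se_q,
            "early_outreach": out.n_early_detected,
            "early_usual": usual.n_early_detected,
            "relative_early_increase": relative_early_increase(out, usual),
        })
    return pd.DataFrame(rows)


@dataclass
class BreakevenResult:
    parameter: str
    value: float                     # crossing point
    response: str
    response_low: float              # response at final bracket ends
    response_high: float
    mc_halfwidth: float              # 1.96 x MC SE of the response at the crossing
    bracket: tuple
    n_iterations: int


def find_breakeven(parameter: str, params: ModelParams, unprinted: UnprintedParams,
                   config: SimulationConfig, bracket: tuple,
                   response: str = "delta_cost", target: float = 0.0,
                   tolerance: float = 1e-3, seed: Optional[int] = None,
                   max_iter: int = 60) -> BreakevenResult:
    """Bisection for the parameter value where the response crosses ``target``.

    The response is evaluated on a frozen common-random-numbers substrate, so
    it is a deterministic function of the parameter and bisection converges;
    the Monte Carlo half-width reported reflects sampling noise of the
    substrate itself.
    """
    config.validate()
    base_seed = config.seed if seed is None else seed
    sub = draw_substrate(config, seed=base_seed)

    def evaluate(value: float) -> tuple[float, float]:
        p, u = apply_parameter(params, unprinted, parameter, value)
        out, usual = _paired(config, p, u, sub, sub)
        cmp = compare_arms(out, usual)
        resp = getattr(cmp, response) if response != "icer" else (cmp.icer or np.nan)
        se_c, se_q = _delta_se(out, usual)
        se = se_c if response == "delta_cost" else se_q
        return float(resp) - target, se

    lo, hi = float(bracket[0]), float(bracket[1])
    f_lo, _ = evaluate(lo)
    f_hi, se = evaluate(hi)
    if np.sign(f_lo) == np.sign(f_hi):
        raise ValidationError(
            f"find_breakeven: response does not change sign over bracket "
            f"({f_lo + target:.4g} .. {f_hi + target:.4g})")
    n_it = 0
    while (hi - lo) > tolerance * max(1.0, abs(hi) + abs(lo)) and n_it < max_iter:
        mid = 0.5 * (lo + hi)
        f_mid, se = evaluate(mid)
        if np.sign(f_mid) == np.sign(f_lo):
            lo, f_lo = mid, f_mid
        else:
            hi, f_hi = mid, f_mid
        n_it += 1
    return BreakevenResult(
        parameter=parameter, value=0.5 * (lo + hi), response=response,
        response_low=f_lo + target, response_high=f_hi + target,
        mc_halfwidth=1.96 * se, bracket=(lo, hi), n_iterations=n_it,
    )


def scenario_grid(horizons: list, cohort_sizes: list, params: ModelParams,
                  unprinted: UnprintedParams, config: SimulationConfig,
                  seed: Optional[int] = None) -> pd.DataFrame:
    """Paired comparison for every (horizon, cohort size) scenario.

    Emits the published table's row structure: arm totals, per-patient
    values and differences.
    """
    config.validate()
    base_seed = config.seed if seed is None else seed
    rows = []
    for horizon in horizons:
        for n in cohort_sizes:
            conf = replace(config, horizon_years=float(horizon), n_patients=int(n))
            conf.validate()
            sub = draw_substrate(conf, seed=base_seed)
            out, usual = _paired(conf, params, unprinted, sub, sub)
            cmp = compare_arms(out, usual)
            rows.append({
                "horizon_years": horizon,
                "n_patients": n,
                "cost_outreach": out.total_cost,
                "cost_usual": usual.total_cost,
                "qaly_outreach": out.total_qaly,
                "qaly_usual": usual.total_qaly,
                "per_patient_cost_outreach": out.per_patient_cost,
                "per_patient_cost_usual": usual.per_patient_cost,
                "per_patient_qaly_outreach": out.per_patient_qaly,
                "per_patient_qaly_usual": usual.per_patient_qaly,
                "delta_cost": cmp.delta_cost,
                "delta_qaly": cmp.delta_qaly,
                "delta_cost_per_patient": cmp.delta_cost / int(n),
                "delta_qaly_per_patient": cmp.delta_qaly / int(n),
                "verdict": cmp.verdict,
            })
    return pd.DataFrame(rows)


def run_psa(n_draws: int, params: ModelParams, unprinted: UnprintedParams,
            config: SimulationConfig, seed: Optional[int] = None) -> pd.DataFrame:
    """Probabilistic sensitivity analysis: incremental scatter over PSA draws.

    Each draw samples the published parameter distributions, then runs the
    paired comparison under common random numbers (one fresh substrate per
    draw).  Returns the (delta_cost, delta_qaly) scatter with verdicts; the
    fraction of dominant draws is ``(df.verdict == 'dominant').mean()``.
    """
    if n_draws < 1:
        raise ValidationError("n_draws: must be >= 1")
    config.validate()
    base_seed = config.seed if seed is None else seed
    rng = np.random.default_rng(base_seed)
    rows = []
    for k in range(n_draws):
        drawn = draw_psa_params(params, rng)
        sub = draw_substrate(config, seed=base_seed + 1 + k)
        out, usual = _paired(config, drawn, unprinted, sub, sub)
        cmp = compare_arms(out, usual)
        rows.append({
            "draw": k,
            "delta_cost": cmp.delta_cost,
            "delta_qaly": cmp.delta_qaly,
            "icer": cmp.icer,
            "verdict": cmp.verdict,
        })
    return pd.DataFrame(rows)
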