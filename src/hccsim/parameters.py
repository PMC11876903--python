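"""Model parameters for the HCC screening-outreach microsimulation.

Every printed model input lives here: the base-case value, the distribution
used for probabilistic sensitivity analysis (PSA), validation of invariants,
and round-tripping to a human-editable YAML config file.

Three parameter groups:

* :class:`ModelParams` -- the published base-case inputs (transition
  probabilities, utilities, mean survivals, treatment costs, outreach costs,
  discount rates), each paired with an optional :class:`DistributionSpec`.
* :class:`UnprintedParams` -- mechanistic detection and background-cost
  values that the published model left unreported; they are recovered by the
  :mod:`hccsim.calibration` module and shipped as calibrated defaults.
* :class:`SimulationConfig` -- cohort size, horizon, cycle length, seed and
  engine switches.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

__all__ = [
    "ValidationError",
    "DistributionSpec",
    "ModelParams",
    "UnprintedParams",
    "SimulationConfig",
    "TABLE1_DISTRIBUTIONS",
    "load_config",
    "save_config",
    "draw_psa_params",
    "default_params",
    "calibrated_defaults",
]

CONFIG_SCHEMA_VERSION = 1


class ValidationError(ValueError):
    """A parameter violated its invariant; the message names the field."""


# ---------------------------------------------------------------------------
# distributions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistributionSpec:
    """PSA distribution for one parameter.

    ``kind`` is one of ``beta``, ``triangle``, ``gamma``, ``fixed``.
    Beta and gamma are parameterized by method of moments from
    ``(center, spread)`` where ``spread`` is a standard deviation; triangle
    uses ``(low, center, high)`` with the base case as mode.
    """

    kind: str
    center: float
    spread: Optional[float] = None
    low: Optional[float] = None
    high: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in ("beta", "triangle", "gamma", "fixed"):
            raise ValidationError(f"DistributionSpec.kind: unknown kind {self.kind!r}")
        if self.kind == "triangle":
            if self.low is None or self.high is None:
                raise ValidationError("DistributionSpec: triangle requires low/high")
            if not (self.low <= self.center <= self.high):
                raise ValidationError(
                    f"DistributionSpec: triangle requires low <= center <= high, "
                    f"got ({self.low}, {self.center}, {self.high})"
                )
        elif self.kind in ("beta", "gamma"):
            if self.spread is None or self.spread <= 0:
                raise ValidationError(f"DistributionSpec: {self.kind} requires spread > 0")
            if self.kind == "beta" and not (0.0 < self.center < 1.0):
                raise ValidationError("DistributionSpec: beta center must lie in (0, 1)")
            if self.kind == "gamma" and self.center <= 0:
                raise ValidationError("DistributionSpec: gamma center must be > 0")

    def moments(self) -> tuple[float, float]:
        """Method-of-moments shape parameters.

        Returns ``(a, b)`` for beta, ``(shape, scale)`` for gamma.
        Raises :class:`ValidationError` when the printed spread is impossible
        for the distribution family (e.g. beta variance >= m(1-m)).
        """
        m, s = self.center, self.spread
        if self.kind == "beta":
            v = s * s
            if v >= m * (1.0 - m):
                raise ValidationError(
                    f"DistributionSpec: beta sd {s} impossible for mean {m}"
                )
            k = m * (1.0 - m) / v - 1.0
            return m * k, (1.0 - m) * k
        if self.kind == "gamma":
            return (m / s) ** 2, s * s / m
        raise ValidationError(f"moments() undefined for kind {self.kind!r}")

    def sample(self, rng: np.random.Generator, size=None):
        if self.kind == "fixed":
            return np.full(size, self.center) if size is not None else self.center
        if self.kind == "triangle":
            if self.low == self.high:  # degenerate
                return np.full(size, self.center) if size is not None else self.center
            return rng.triangular(self.low, self.center, self.high, size=size)
        if self.kind == "beta":
            a, b = self.moments()
            return rng.beta(a, b, size=size)
        a, scale = self.moments()  # gamma
        return rng.gamma(a, scale, size=size)


# Table-1 distribution assignments (Dist. / Range-or-Std.Dev. columns).
TABLE1_DISTRIBUTIONS: dict[str, DistributionSpec] = {
    "prop_compensated": DistributionSpec("beta", 0.58, spread=0.05),
    "p_decomp_annual": DistributionSpec("beta", 0.06, spread=0.02),
    "p_hcc_comp_annual": DistributionSpec("beta", 0.02, spread=0.02),
    "p_hcc_decomp_annual": DistributionSpec("beta", 0.04, spread=0.02),
    "p_early_with_screen": DistributionSpec("triangle", 0.67, low=0.62, high=0.72),
    "p_early_without_screen": DistributionSpec("triangle", 0.33, low=0.28, high=0.38),
    "adherence_usual": DistributionSpec("triangle", 0.23, low=0.20, high=0.27),
    "adherence_outreach": DistributionSpec("triangle", 0.35, low=0.32, high=0.37),
    "utility_comp": DistributionSpec("triangle", 0.80, low=0.70, high=0.90),
    "utility_decomp": DistributionSpec("triangle", 0.65, low=0.60, high=0.72),
    "utility_early_hcc": DistributionSpec("triangle", 0.67, low=0.55, high=0.72),
    "utility_late_hcc": DistributionSpec("triangle", 0.52, low=0.47, high=0.57),
    "surv_comp": DistributionSpec("triangle", 9.8, low=7.2, high=13.0),
    "surv_decomp": DistributionSpec("triangle", 2.5, low=0.5, high=5.0),
    "surv_early_hcc": DistributionSpec("triangle", 6.5, low=1.0, high=13.0),
    "surv_late_hcc": DistributionSpec("triangle", 2.0, low=0.0, high=5.5),
    # Printed std devs for the SEER-Medicare episode costs are implausibly
    # tight for gamma scale parameters but are honored as published.
    "cost_treat_early": DistributionSpec("gamma", 174_981.0, spread=418.0),
    "cost_treat_late": DistributionSpec("gamma", 203_708.0, spread=451.0),
    "outreach_cost_y1": DistributionSpec("gamma", 32.45, spread=5.7),
    "outreach_cost_later": DistributionSpec("gamma", 21.90, spread=4.7),
}


# ---------------------------------------------------------------------------
# parameter groups
# ---------------------------------------------------------------------------

@dataclass
class ModelParams:
    """Published base-case model inputs (2021 US dollars, annual rates)."""

    prop_compensated: float = 0.58
    p_decomp_annual: float = 0.06
    p_hcc_comp_annual: float = 0.02
    p_hcc_decomp_annual: float = 0.04
    p_early_with_screen: float = 0.67
    p_early_without_screen: float = 0.33
    adherence_usual: float = 0.23
    adherence_outreach: float = 0.35
    utility_comp: float = 0.80
    utility_decomp: float = 0.65
    utility_early_hcc: float = 0.67
    utility_late_hcc: float = 0.52
    surv_comp: float = 9.8
    surv_decomp: float = 2.5
    surv_early_hcc: float = 6.5
    surv_late_hcc: float = 2.0
    cost_treat_early: float = 174_981.0
    cost_treat_late: float = 203_708.0
    outreach_cost_y1: float = 32.45
    outreach_cost_later: float = 21.90
    discount_cost: float = 0.03
    discount_qaly: float = 0.03
    distributions: dict = field(default_factory=lambda: dict(TABLE1_DISTRIBUTIONS))

    _PROBABILITIES = (
        "prop_compensated", "p_decomp_annual", "p_hcc_comp_annual",
        "p_hcc_decomp_annual", "p_early_with_screen", "p_early_without_screen",
        "adherence_usual", "adherence_outreach",
    )
    _UTILITIES = ("utility_comp", "utility_decomp", "utility_early_hcc", "utility_late_hcc")
    _SURVIVALS = ("surv_comp", "surv_decomp", "surv_early_hcc", "surv_late_hcc")
    _COSTS = ("cost_treat_early", "cost_treat_late", "outreach_cost_y1", "outreach_cost_later")

    def validate(self) -> "ModelParams":
        for name in self._PROBABILITIES:
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name}: probability {v} outside [0, 1]")
        for name in self._UTILITIES:
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name}: utility {v} outside [0, 1]")
        for name in self._SURVIVALS:
            if getattr(self, name) <= 0.0:
                raise ValidationError(f"{name}: survival must be > 0 years")
        for name in self._COSTS:
            if getattr(self, name) < 0.0:
                raise ValidationError(f"{name}: cost must be >= 0")
        for name in ("discount_cost", "discount_qaly"):
            if getattr(self, name) < 0.0:
                raise ValidationError(f"{name}: discount rate must be >= 0")
        if self.utility_early_hcc < self.utility_late_hcc:
            raise ValidationError("utility_early_hcc: must be >= utility_late_hcc")
        if self.surv_early_hcc < self.surv_late_hcc:
            raise ValidationError("surv_early_hcc: must be >= surv_late_hcc")
        return self

    def check(self) -> bool:
        try:
            self.validate()
            return True
        except ValidationError:
            return False


@dataclass
class UnprintedParams:
    """Mechanistic detection and background-cost parameters.

    The published appendix withheld these values; the defaults below are the
    shipped calibration output (see ``data/calibrated_defaults.yaml`` and the
    methods note).  ``early_dwell_cycles`` is the number of semi-annual cycles
    a tumor remains early-stage (and screen-detectable) before progressing.
    """

    early_dwell_cycles: int = 1
    screen_sensitivity_early: float = 0.97604
    p_incidental_early_percycle: float = 0.002
    p_symptomatic_detect_percycle: float = 1.0
    cost_care_comp_annual: float = 1236.010191
    cost_care_decomp_annual: float = 3830.836718
    cost_diagnostic_workup: float = 1000.0
    cpi_adjust: float = 1.0
    p_false_positive: float = 0.0

    def validate(self) -> "UnprintedParams":
        if int(self.early_dwell_cycles) != self.early_dwell_cycles or self.early_dwell_cycles < 1:
            raise ValidationError("early_dwell_cycles: must be a positive integer")
        for name in ("screen_sensitivity_early", "p_incidental_early_percycle",
                     "p_symptomatic_detect_percycle", "p_false_positive"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name}: probability {v} outside [0, 1]")
        for name in ("cost_care_comp_annual", "cost_care_decomp_annual",
                     "cost_diagnostic_workup"):
            if getattr(self, name) < 0.0:
                raise ValidationError(f"{name}: cost must be >= 0")
        if self.cpi_adjust <= 0.0:
            raise ValidationError("cpi_adjust: must be > 0")
        return self


@dataclass
class SimulationConfig:
    """Cohort size, horizon and engine switches.

    ``accrual`` selects how post-diagnosis outcomes are credited:

    * ``"lifetime"`` (default): at diagnosis the patient is credited the
      stage-specific expected discounted QALYs (utility / (1/survival + rho))
      and the stage-specific episode treatment cost as lump sums; only
      pre-diagnosis person-time is simulated cycle by cycle.
    * ``"horizon"``: diagnosed patients continue to be simulated cycle by
      cycle and all accrual is truncated at the horizon.

    ``detection_mode`` selects the detection model: ``"mechanistic"``
    (dwell time + screening + incidental/symptomatic detection; default) or
    ``"reduced_form"`` (stage assigned at onset from the published 0.67/0.33
    conditional on that cycle's screening status).

    ``terminal_diagnosis``: death in an undetected HCC state is a terminal
    presentation -- the late-stage treatment episode cost is charged and the
    case counts as a late-stage diagnosis (no post-diagnosis QALY credit).

    ``resolve_horizon`` (lifetime accrual only): tumors still undiagnosed at
    the horizon are resolved analytically with the expected discounted
    continuation of the detection cascade (incidental/symptomatic detection
    only, arm-independent), so the intervention-affected HCC pathway runs to
    completion in both arms while background cirrhosis person-time truncates
    at the horizon identically.
    """

    n_patients: int = 10_000
    horizon_years: float = 10.0
    cycle_length: float = 0.5
    seed: int = 2021
    use_common_random_numbers: bool = True
    detection_mode: str = "mechanistic"
    accrual: str = "lifetime"
    terminal_diagnosis: bool = True
    resolve_horizon: bool = True

    def validate(self) -> "SimulationConfig":
        if self.n_patients < 1:
            raise ValidationError("n_patients: must be >= 1")
        if self.cycle_length <= 0:
            raise ValidationError("cycle_length: must be > 0")
        n = self.horizon_years / self.cycle_length
        if abs(n - round(n)) > 1e-9:
            raise ValidationError(
                f"horizon_years: {self.horizon_years} is not a whole number of "
                f"{self.cycle_length}-year cycles"
            )
        if self.detection_mode not in ("mechanistic", "reduced_form"):
            raise ValidationError(f"detection_mode: unknown mode {self.detection_mode!r}")
        if self.accrual not in ("lifetime", "horizon"):
            raise ValidationError(f"accrual: unknown mode {self.accrual!r}")
        return self

    @property
    def n_cycles(self) -> int:
        return int(round(self.horizon_years / self.cycle_length))


def default_params() -> tuple[ModelParams, UnprintedParams, SimulationConfig]:
    """Base-case parameter set: published values plus calibrated defaults."""
    return ModelParams().validate(), calibrated_defaults(), SimulationConfig().validate()


def calibrated_defaults() -> UnprintedParams:
    """The shipped calibrated :class:`UnprintedParams` (versioned defaults file)."""
    path = Path(__file__).parent / "data" / "calibrated_defaults.yaml"
    if path.exists():
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return _build(UnprintedParams, doc.get("unprinted", {}), "unprinted").validate()
    return UnprintedParams().validate()


# ---------------------------------------------------------------------------
# PSA draws
# ---------------------------------------------------------------------------

def draw_psa_params(params: ModelParams, rng: np.random.Generator,
                    max_redraws: int = 1000) -> ModelParams:
    """Draw one PSA replicate of ``params`` from its distribution table.

    Cross-field invariants of :class:`ModelParams` (e.g. early-stage utility
    and survival at least the late-stage values) are enforced by redrawing the
    offending fields.
    """
    drawn = {name: float(spec.sample(rng)) for name, spec in params.distributions.items()}
    candidate = replace(params, **drawn)
    for _ in range(max_redraws):
        if candidate.check():
            return candidate
        redraw = {}
        if candidate.utility_early_hcc < candidate.utility_late_hcc:
            for name in ("utility_early_hcc", "utility_late_hcc"):
                if name in params.distributions:
                    redraw[name] = float(params.distributions[name].sample(rng))
        if candidate.surv_early_hcc < candidate.surv_late_hcc or candidate.surv_late_hcc <= 0:
            for name in ("surv_early_hcc", "surv_late_hcc"):
                if name in params.distributions:
                    redraw[name] = float(params.distributions[name].sample(rng))
        if not redraw:  # some single-field invariant failed; redraw everything
            redraw = {name: float(spec.sample(rng))
                      for name, spec in params.distributions.items()}
        candidate = replace(candidate, **redraw)
    raise ValidationError("draw_psa_params: could not satisfy invariants after redraws")


# ---------------------------------------------------------------------------
# YAML config round-trip
# ---------------------------------------------------------------------------

_SKIP_FIELDS = {"distributions"}


def _scalar_fields(cls) -> list[str]:
    return [f.name for f in fields(cls) if f.name not in _SKIP_FIELDS]


def _build(cls, mapping: dict, section: str):
    known = set(_scalar_fields(cls))
    unknown = set(mapping) - known
    if unknown:
        raise ValidationError(f"{section}: unknown field(s) {sorted(unknown)}")
    kwargs = {}
    for key, value in mapping.items():
        f = {f.name: f for f in fields(cls)}[key]
        if f.type in ("int", int):
            kwargs[key] = int(value)
        elif f.type in ("bool", bool):
            kwargs[key] = bool(value)
        elif f.type in ("str", str):
            kwargs[key] = str(value)
        else:
            kwargs[key] = float(value)
    return cls(**kwargs)


def load_config(path) -> tuple[ModelParams, UnprintedParams, SimulationConfig]:
    """Load a YAML config; missing fields take the package defaults.

    An empty file therefore yields the published base case together with the
    shipped calibrated detection/cost defaults.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ValidationError("config: top level must be a mapping")
    version = doc.pop("schema_version", CONFIG_SCHEMA_VERSION)
    if version != CONFIG_SCHEMA_VERSION:
        raise ValidationError(f"schema_version: unsupported version {version}")
    unknown = set(doc) - {"model", "unprinted", "simulation"}
    if unknown:
        raise ValidationError(f"config: unknown section(s) {sorted(unknown)}")

    mp_doc = dict(doc.get("model") or {})
    up_doc = dict(doc.get("unprinted") or {})
    sc_doc = dict(doc.get("simulation") or {})

    mp = _build(ModelParams, mp_doc, "model")
    # fields absent from the file keep the default distribution table entries;
    # overridden fields keep their Table-1 distribution around the new center.
    up_defaults = dataclasses.asdict(calibrated_defaults())
    up_defaults.update(up_doc)
    up = _build(UnprintedParams, up_defaults, "unprinted")
    sc = _build(SimulationConfig, sc_doc, "simulation")
    return mp.validate(), up.validate(), sc.validate()


def save_config(path, params: ModelParams, unprinted: UnprintedParams,
                config: SimulationConfig) -> None:
    """Write the full parameter set to YAML (inverse of :func:`load_config`)."""
    doc = {
        "schema_version": CONFIG_SCHEMA_VERSION,
        "model": {k: getattr(params, k) for k in _scalar_fields(ModelParams)},
        "unprinted": {k: getattr(unprinted, k) for k in _scalar_fields(UnprintedParams)},
        "simulation": {k: getattr(config, k) for k in _scalar_fields(SimulationConfig)},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
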