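"""Core demand engine: policy price changes propagated through a conditional
price-elasticity (PE) matrix, with expenditure-preserving rescaling (step 1)
and reallocation of the total-expenditure change via expenditure elasticities
and the total food expenditure elasticity, TFEe (step 2).

Conventions
-----------
* Prices are currency units per 100 g; quantities are g/person/day (ml for
  beverages, carried in the same column).
* Expenditure is therefore ``sum(q / 100 * p)``.
* All percent-change quantities are stored as *fractions* internally
  (0.05, not 5%); they are rendered on the percent scale only at I/O
  boundaries (``ScenarioResult.to_dict`` and the ``*_pct`` fields).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "FoodSystem",
    "PEMatrix",
    "PolicySpec",
    "ExpenditureVector",
    "ScenarioResult",
    "total_expenditure",
    "apply_policy",
    "fpi_change",
    "fpi_percent_change",
    "conditional_step",
    "expenditure_step",
    "run_policy_scenario",
    "revealed_tfee",
    "expenditure_change_pct",
    "revealed_tfee_from_pct",
]

MODES = ("conventional", "tfee_adjusted")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class FoodSystem:
    """A food system: what is eaten, at what price, with what composition.

    Parameters
    ----------
    food_id : list of str
        Unique food labels.
    q_b : array-like
        Baseline consumption, g/person/day (>= 0).
    p_b : array-like
        Baseline price, currency per 100 g (> 0).
    energy_density : array-like
        kJ per 100 g (>= 0).
    nutrient_content : dict of str -> array-like
        g of nutrient per 100 g of food, each value in [0, 100].
    group_id : list of str, optional
        Elasticity food-group label per food (defaults to ``food_id``).
    """

    food_id: list[str]
    q_b: np.ndarray
    p_b: np.ndarray
    energy_density: np.ndarray
    nutrient_content: dict[str, np.ndarray] = field(default_factory=dict)
    group_id: list[str] | None = None

    def __post_init__(self) -> None:
        self.q_b = np.asarray(self.q_b, dtype=float)
        self.p_b = np.asarray(self.p_b, dtype=float)
        self.energy_density = np.asarray(self.energy_density, dtype=float)
        self.nutrient_content = {
            k: np.asarray(v, dtype=float) for k, v in self.nutrient_content.items()
        }
        n = len(self.food_id)
        if len(set(self.food_id)) != n:
            raise ValueError("duplicate food_id")
        for name, arr in [("q_b", self.q_b), ("p_b", self.p_b),
                          ("energy_density", self.energy_density)]:
            if arr.shape != (n,):
                raise ValueError(f"{name} must have length {n}, got {arr.shape}")
        if np.any(self.q_b < 0):
            raise ValueError("negative quantity")
        if np.any(self.p_b <= 0):
            raise ValueError("non-positive price")
        if np.any(self.energy_density < 0):
            raise ValueError("negative energy density")
        for nut, arr in self.nutrient_content.items():
            if arr.shape != (n,):
                raise ValueError(f"nutrient {nut!r} must have length {n}")
            if np.any((arr < 0) | (arr > 100)):
                raise ValueError(f"nutrient {nut!r} content outside [0, 100] g/100 g")
        if self.group_id is None:
            self.group_id = list(self.food_id)
        elif len(self.group_id) != n:
            raise ValueError("group_id length mismatch")

    @property
    def n(self) -> int:
        return len(self.food_id)

    @property
    def expenditure(self) -> np.ndarray:
        """Per-food baseline expenditure, currency/day."""
        return self.q_b / 100.0 * self.p_b

    @property
    def shares(self) -> np.ndarray:
        """Baseline expenditure shares w_i (sum to 1)."""
        e = self.expenditure
        total = e.sum()
        if total <= 0:
            raise ValueError("zero baseline expenditure; shares undefined")
        return e / total

    @property
    def x_b(self) -> float:
        """Baseline total food expenditure, currency/day."""
        return float(self.expenditure.sum())


@dataclass
class PEMatrix:
    """Marshallian conditional own/cross price-elasticity matrix.

    ``epsilon[i, j]`` is the % change in quantity of food *i* per 1% change
    in the price of food *j*.  Own-PEs (the diagonal) are expected to be
    non-positive; positive diagonals warn by default and raise when
    ``strict=True``.
    """

    epsilon: np.ndarray
    sd: np.ndarray | None = None
    food_id: list[str] | None = None
    strict: bool = False

    def __post_init__(self) -> None:
        self.epsilon = np.asarray(self.epsilon, dtype=float)
        if self.epsilon.ndim != 2 or self.epsilon.shape[0] != self.epsilon.shape[1]:
            raise ValueError("PE matrix must be square")
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
            if self.sd.shape != self.epsilon.shape:
                raise ValueError("sd shape must match epsilon")
            if np.any(self.sd < 0):
                raise ValueError("negative sd")
        if self.food_id is not None and len(self.food_id) != self.epsilon.shape[0]:
            raise ValueError("food_id length must match matrix dimension")
        diag = np.diag(self.epsilon)
        if np.any(diag > 0):
            bad = np.where(diag > 0)[0]
            msg = f"positive own-price elasticities at indices {bad.tolist()}"
            if self.strict:
                raise ValueError(msg)
            warnings.warn(msg, stacklevel=2)

    @property
    def n(self) -> int:
        return self.epsilon.shape[0]

    def check_alignment(self, system: FoodSystem) -> None:
        if self.n != system.n:
            raise ValueError(
                f"PE matrix dimension {self.n} != number of foods {system.n}"
            )
        if self.food_id is not None and list(self.food_id) != list(system.food_id):
            raise ValueError("PE matrix food_id ordering differs from food system")


@dataclass
class PolicySpec:
    """A price intervention: per-nutrient specific taxes plus ad valorem rates.

    ``nutrient_taxes`` maps nutrient name -> currency per 100 g of nutrient
    (applied in proportion to each food's nutrient content, 100% pass-through).
    ``ad_valorem`` maps food_id -> proportional price change as a fraction
    (e.g. -0.20 for a 20% subsidy); entries must exceed -1.
    """

    nutrient_taxes: dict[str, float] = field(default_factory=dict)
    ad_valorem: dict[str, float] = field(default_factory=dict)
    name: str = "policy"

    def __post_init__(self) -> None:
        for food, rate in self.ad_valorem.items():
            if rate <= -1:
                raise ValueError(
                    f"ad valorem rate for {food!r} must be > -1, got {rate}"
                )

    @property
    def is_null(self) -> bool:
        return not self.nutrient_taxes and not any(
            v != 0 for v in self.ad_valorem.values()
        )


@dataclass
class ExpenditureVector:
    """Per-food expenditure elasticities eta_i.

    When ``normalized`` is True the vector claims Engel aggregation
    (share-weighted mean of 1); ``check_engel`` verifies it against a share
    vector.
    """

    eta: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.eta = np.asarray(self.eta, dtype=float)
        if self.eta.ndim != 1:
            raise ValueError("eta must be 1-D")

    def check_engel(self, w: np.ndarray, tol: float = 1e-6) -> None:
        if not self.normalized:
            return
        total = float(np.asarray(w, dtype=float) @ self.eta)
        if abs(total - 1.0) > tol:
            raise ValueError(
                f"Engel aggregation violated: share-weighted mean eta = {total}"
            )


@dataclass
class ScenarioResult:
    """Outcome of applying one policy to one food system."""

    food_id: list[str]
    q_b: np.ndarray
    q_a: np.ndarray
    p_b: np.ndarray
    p_a: np.ndarray
    x_b: float
    x_a: float
    delta_x: float | None
    fpi_pct: float
    dq_pes: np.ndarray          # step-1 scaled fractional quantity changes
    summaries: dict
    mode: str
    tfee: float | None = None
    policy_name: str = "policy"

    @property
    def pct_dq_pes(self) -> np.ndarray:
        return 100.0 * self.dq_pes

    @property
    def expenditure_pct_change(self) -> float:
        return 100.0 * (self.x_a / self.x_b - 1.0)

    def to_dict(self) -> dict:
        """JSON-ready representation; percent-scale fields carry units."""
        return {
            "policy": self.policy_name,
            "mode": self.mode,
            "tfee": self.tfee,
            "food_id": list(self.food_id),
            "q_b_g_per_day": self.q_b.tolist(),
            "q_a_g_per_day": self.q_a.tolist(),
            "p_b_per_100g": self.p_b.tolist(),
            "p_a_per_100g": self.p_a.tolist(),
            "x_b": self.x_b,
            "x_a": self.x_a,
            "delta_x": self.delta_x,
            "fpi_change": {"value": self.fpi_pct, "units": "%"},
            "expenditure_change": {"value": self.expenditure_pct_change, "units": "%"},
            "step1_quantity_change": {
                "value": self.pct_dq_pes.tolist(), "units": "%"},
            "summaries": self.summaries,
        }


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def total_expenditure(q: np.ndarray, p: np.ndarray) -> float:
    """Total expenditure ``sum(q/100 * p)`` in currency/day.

    ``q`` in g/day, ``p`` per 100 g.
    """
    q = np.asarray(q, dtype=float)
    p = np.asarray(p, dtype=float)
    if q.shape != p.shape:
        raise ValueError(f"length mismatch: q {q.shape} vs p {p.shape}")
    if np.any(p < 0):
        raise ValueError("negative price")
    if np.any(q < 0):
        raise ValueError("negative quantity")
    return float((q / 100.0 * p).sum())


def apply_policy(system: FoodSystem, policy: PolicySpec) -> np.ndarray:
    """Post-policy prices per 100 g.

    Specific nutrient taxes add ``rate * content/100`` to the price (100%
    pass-through onto fixed producer prices); any ad valorem rate is then
    applied multiplicatively.
    """
    p_a = system.p_b.copy()
    for nutrient, rate in policy.nutrient_taxes.items():
        if nutrient not in system.nutrient_content:
            raise KeyError(
                f"policy taxes nutrient {nutrient!r} not present in food system"
            )
        p_a = p_a + rate * system.nutrient_content[nutrient] / 100.0
    if policy.ad_valorem:
        idx = {f: i for i, f in enumerate(system.food_id)}
        for food, rate in policy.ad_valorem.items():
            if food not in idx:
                raise KeyError(f"ad valorem rate for unknown food {food!r}")
            p_a[idx[food]] *= 1.0 + rate
    if np.any(p_a <= 0):
        bad = [system.food_id[i] for i in np.where(p_a <= 0)[0]]
        raise ValueError(f"policy drives price non-positive for {bad}")
    return p_a


def fpi_change(system: FoodSystem, p_a: np.ndarray) -> float:
    """Fractional change in the food price index.

    Base-quantity-weighted (Laspeyres-type): ``sum(q_b*p_a)/x_b - 1``.
    """
    p_a = np.asarray(p_a, dtype=float)
    if np.any(p_a <= 0):
        raise ValueError("non-positive post-policy price")
    x_b = system.x_b
    if x_b <= 0:
        raise ValueError("zero baseline expenditure")
    return total_expenditure(system.q_b, p_a) / x_b - 1.0


def fpi_percent_change(system: FoodSystem, p_a: np.ndarray) -> float:
    """Percent change in the food price index (percent scale)."""
    return 100.0 * fpi_change(system, p_a)


def conditional_step(
    system: FoodSystem, p_a: np.ndarray, pe: PEMatrix
) -> np.ndarray:
    """Step 1: propagate price changes through the PE matrix, then rescale so
    total food expenditure is unchanged (the conditional-matrix assumption).

    Returns the scaled fractional quantity changes ``dq_pes`` satisfying
    ``sum((1 + dq_pes) * q_b/100 * p_a) == x_b`` to machine precision.
    Quantity factors driven below zero by extreme elasticities are clamped
    to zero (with a warning) before the rescale.
    """
    pe.check_alignment(system)
    p_a = np.asarray(p_a, dtype=float)
    dp = p_a / system.p_b - 1.0
    dq_pe = pe.epsilon @ dp
    factor = 1.0 + dq_pe
    if np.any(factor < 0):
        bad = [system.food_id[i] for i in np.where(factor < 0)[0]]
        logger.warning(
            "raw PE application drives quantity below zero for %s; clamping", bad
        )
        warnings.warn(f"quantity clamped to zero for {bad}", stacklevel=2)
        factor = np.clip(factor, 0.0, None)
    x_b = system.x_b
    x_pe = float((factor * system.q_b / 100.0 * p_a).sum())
    if x_pe <= 0:
        raise ValueError("implied post-PE expenditure is non-positive")
    return x_b / x_pe * factor - 1.0


def expenditure_step(
    system: FoodSystem,
    p_a: np.ndarray,
    dq_pes: np.ndarray,
    ee: ExpenditureVector,
    tfee: float,
    policy_name: str = "policy",
) -> ScenarioResult:
    """Step 2: allocate the TFEe-implied change in total expenditure across
    foods via per-food expenditure elasticities, with a closing scalar so the
    final expenditure hits the target exactly.
    """
    if not np.isfinite(tfee):
        raise ValueError("tfee must be finite")
    p_a = np.asarray(p_a, dtype=float)
    dq_pes = np.asarray(dq_pes, dtype=float)
    if ee.eta.shape != (system.n,):
        raise ValueError("expenditure-elasticity vector length mismatch")
    ee.check_engel(system.shares)

    x_b = system.x_b
    fpi = fpi_change(system, p_a)
    delta_x = fpi * tfee * x_b
    # preliminary EE-driven change, stacked multiplicatively on the step-1 result
    dq_ee = fpi * tfee * ee.eta
    delta_q_ee = dq_ee * (1.0 + dq_pes) * system.q_b
    delta_x_ee = float((delta_q_ee / 100.0 * p_a).sum())
    if delta_x == 0.0:
        scalar = 0.0
    elif delta_x_ee == 0.0:
        raise ValueError(
            "degenerate expenditure-elasticity vector: target expenditure "
            "change is nonzero but the preliminary EE change is zero"
        )
    else:
        scalar = delta_x / delta_x_ee
    q_a = scalar * delta_q_ee + dq_pes * system.q_b + system.q_b
    if np.any(q_a < 0):
        bad = [system.food_id[i] for i in np.where(q_a < 0)[0]]
        logger.warning("post-policy quantity below zero for %s; clamping", bad)
        warnings.warn(f"post-policy quantity clamped to zero for {bad}",
                      stacklevel=2)
        q_a = np.clip(q_a, 0.0, None)
    x_a = total_expenditure(q_a, p_a)
    return ScenarioResult(
        food_id=list(system.food_id),
        q_b=system.q_b.copy(),
        q_a=q_a,
        p_b=system.p_b.copy(),
        p_a=p_a.copy(),
        x_b=x_b,
        x_a=x_a,
        delta_x=delta_x,
        fpi_pct=100.0 * fpi,
        dq_pes=dq_pes.copy(),
        summaries=_summaries(system, q_a),
        mode="tfee_adjusted",
        tfee=float(tfee),
        policy_name=policy_name,
    )


def run_policy_scenario(
    system: FoodSystem,
    policy: PolicySpec,
    pe: PEMatrix,
    ee: ExpenditureVector | None = None,
    tfee: float | None = None,
    mode: str = "tfee_adjusted",
) -> ScenarioResult:
    """Run the full policy simulation.

    ``mode="conventional"`` applies the PE matrix directly with neither the
    step-1 expenditure-preserving rescale nor step 2 (so total expenditure is
    free to drift — the behaviour the TFEe adjustment exists to repair).
    ``mode="tfee_adjusted"`` runs both steps and requires ``ee`` and ``tfee``.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    p_a = apply_policy(system, policy)
    if mode == "conventional":
        pe.check_alignment(system)
        dp = p_a / system.p_b - 1.0
        factor = 1.0 + pe.epsilon @ dp
        if np.any(factor < 0):
            bad = [system.food_id[i] for i in np.where(factor < 0)[0]]
            warnings.warn(f"quantity clamped to zero for {bad}", stacklevel=2)
            factor = np.clip(factor, 0.0, None)
        q_a = factor * system.q_b
        return ScenarioResult(
            food_id=list(system.food_id),
            q_b=system.q_b.copy(),
            q_a=q_a,
            p_b=system.p_b.copy(),
            p_a=p_a,
            x_b=system.x_b,
            x_a=total_expenditure(q_a, p_a),
            delta_x=None,
            fpi_pct=fpi_percent_change(system, p_a),
            dq_pes=factor - 1.0,
            summaries=_summaries(system, q_a),
            mode="conventional",
            tfee=None,
            policy_name=policy.name,
        )
    if ee is None or tfee is None:
        raise ValueError("tfee_adjusted mode requires an EE vector and a TFEe")
    dq_pes = conditional_step(system, p_a, pe)
    result = expenditure_step(system, p_a, dq_pes, ee, tfee,
                              policy_name=policy.name)
    return result


def revealed_tfee(result: ScenarioResult) -> float:
    """Post-hoc TFEe implied by a model run: (% expenditure change)/(% FPI change).

    For a ``tfee_adjusted`` run this recovers the input TFEe exactly; for a
    conventional run it diagnoses the plausibility of the expenditure drift.
    """
    if result.fpi_pct == 0.0:
        raise ValueError("revealed TFEe undefined: zero FPI change")
    return result.expenditure_pct_change / result.fpi_pct


# -- percent-scale arithmetic helpers (diagnostics on reported figures) -----

def expenditure_change_pct(fpi_pct: float, tfee: float) -> float:
    """TFEe-adjusted % change in total food expenditure for a given % FPI change."""
    return fpi_pct * tfee


def revealed_tfee_from_pct(expenditure_pct: float, fpi_pct: float) -> float:
    """Revealed TFEe from reported percent changes."""
    if fpi_pct == 0.0:
        raise ValueError("revealed TFEe undefined: zero FPI change")
    return expenditure_pct / fpi_pct


def _summaries(system: FoodSystem, q_a: np.ndarray) -> dict:
    """Diet summaries pre/post: total g/day, kJ/day and nutrient g/day."""
    out = {
        "grams_per_day": {"pre": float(system.q_b.sum()),
                          "post": float(q_a.sum())},
        "kj_per_day": {
            "pre": float((system.q_b * system.energy_density / 100.0).sum()),
            "post": float((q_a * system.energy_density / 100.0).sum()),
        },
    }
    for nut, content in system.nutrient_content.items():
        out[f"{nut}_g_per_day"] = {
            "pre": float((system.q_b * content / 100.0).sum()),
            "post": float((q_a * content / 100.0).sum()),
        }
    return out
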