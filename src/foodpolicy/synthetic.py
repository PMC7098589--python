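"""Synthetic food systems, elasticity matrices, expenditure-elasticity
vectors, disaggregation schemes and health fixtures.

Everything is generated from a seeded :class:`numpy.random.Generator`, so
the whole pipeline is testable without external data.  Generated PE
matrices satisfy full-budget Cournot aggregation (share-weighted column sums
equal to minus the column share); EE vectors satisfy Engel aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .demand import ExpenditureVector, FoodSystem, PEMatrix
from .disaggregation import DisaggregationScheme
from .health import Cohort, DiseaseSpec, PopulationLifetable

__all__ = [
    "SyntheticConfig",
    "make_food_system",
    "make_pe_matrix",
    "make_ee_vector",
    "make_scheme",
    "make_health_inputs",
]

# plausibility floor: kJ per g of carbohydrate-like and fat-like mass
KJ_PER_G_SUGAR = 17.0
KJ_PER_G_FAT = 37.0


@dataclass
class SyntheticConfig:
    n_groups: int = 5
    subfoods_per_group: int = 1
    price_range: tuple[float, float] = (0.3, 5.0)       # per 100 g
    quantity_range: tuple[float, float] = (5.0, 400.0)  # g/day
    energy_range: tuple[float, float] = (80.0, 1800.0)  # kJ/100 g
    nutrient_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"satfat": (0.0, 30.0), "sugar": (0.0, 50.0)}
    )
    own_pe_range: tuple[float, float] = (-1.5, -0.2)
    cross_pe_scale: float = 0.05
    pe_sd_frac: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("price_range", "quantity_range", "energy_range",
                     "own_pe_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} is not well-ordered")
        if self.own_pe_range[1] >= 0:
            raise ValueError("own-PE range must be strictly negative")
        if self.n_groups < 1 or self.subfoods_per_group < 1:
            raise ValueError("need at least one group and one sub-food")

    @property
    def n_foods(self) -> int:
        return self.n_groups * self.subfoods_per_group

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def make_food_system(cfg: SyntheticConfig,
                     rng: np.random.Generator | None = None) -> FoodSystem:
    """Random food system with positive prices and an energy-density floor
    consistent with macronutrient content."""
    rng = cfg.rng() if rng is None else rng
    n = cfg.n_foods
    food_id = [f"g{g:02d}f{s:02d}"
               for g in range(cfg.n_groups)
               for s in range(cfg.subfoods_per_group)]
    group_id = [f"g{g:02d}"
                for g in range(cfg.n_groups)
                for _ in range(cfg.subfoods_per_group)]
    q = rng.uniform(*cfg.quantity_range, size=n)
    p = rng.uniform(*cfg.price_range, size=n)
    nutrients = {
        nut: rng.uniform(lo, hi, size=n)
        for nut, (lo, hi) in cfg.nutrient_ranges.items()
    }
    energy = rng.uniform(*cfg.energy_range, size=n)
    floor = np.zeros(n)
    if "sugar" in nutrients:
        floor = floor + KJ_PER_G_SUGAR * nutrients["sugar"]
    if "satfat" in nutrients:
        floor = floor + KJ_PER_G_FAT * nutrients["satfat"]
    energy = np.maximum(energy, floor)
    return FoodSystem(
        food_id=food_id, q_b=q, p_b=p, energy_density=energy,
        nutrient_content=nutrients, group_id=group_id,
    )


def make_pe_matrix(w: np.ndarray, cfg: SyntheticConfig,
                   rng: np.random.Generator | None = None,
                   max_retries: int = 20) -> PEMatrix:
    """Random conditional PE matrix satisfying Cournot aggregation.

    Diagonal drawn from ``own_pe_range``; off-diagonal entries drawn small,
    then each column's off-diagonal entries shifted uniformly so the
    share-weighted column sum equals ``-w_j`` to 1e-9.
    """
    rng = cfg.rng() if rng is None else rng
    w = np.asarray(w, dtype=float)
    n = w.size
    if abs(w.sum() - 1.0) > 1e-9 or np.any(w <= 0):
        raise ValueError("shares must be positive and sum to 1")
    if n == 1:
        eps = np.array([[-float(w[0])]])
        return PEMatrix(epsilon=eps, sd=cfg.pe_sd_frac * np.abs(eps))
    for _ in range(max_retries):
        eps = rng.normal(0.0, cfg.cross_pe_scale, size=(n, n))
        np.fill_diagonal(eps, rng.uniform(*cfg.own_pe_range, size=n))
        ok = True
        for j in range(n):
            off = np.arange(n) != j
            deficit = -w[j] - float(w @ eps[:, j])
            shift = deficit / w[off].sum()
            eps[off, j] += shift
            if not np.isfinite(shift):
                ok = False
                break
        if ok and np.all(np.diag(eps) < 0):
            sd = cfg.pe_sd_frac * np.abs(eps)
            return PEMatrix(epsilon=eps, sd=sd)
    raise RuntimeError("could not draw a feasible PE matrix")


def make_ee_vector(w: np.ndarray, cfg: SyntheticConfig,
                   rng: np.random.Generator | None = None) -> ExpenditureVector:
    """Positive expenditure elasticities normalized to Engel aggregation
    (share-weighted mean exactly 1)."""
    rng = cfg.rng() if rng is None else rng
    w = np.asarray(w, dtype=float)
    eta = rng.uniform(0.2, 1.8, size=w.size)
    eta = eta / float(w @ eta)
    return ExpenditureVector(eta=eta, normalized=True)


def make_scheme(cfg: SyntheticConfig,
                rng: np.random.Generator | None = None,
                group_ids: list[str] | None = None,
                subfoods: list[int] | None = None) -> DisaggregationScheme:
    """Random disaggregation scheme with Dirichlet within-group shares."""
    rng = cfg.rng() if rng is None else rng
    if group_ids is None:
        group_ids = [f"g{g:02d}" for g in range(cfg.n_groups)]
    if subfoods is None:
        subfoods = [cfg.subfoods_per_group] * len(group_ids)
    groups: dict[str, list[tuple[str, float]]] = {}
    for gid, k in zip(group_ids, subfoods):
        shares = rng.dirichlet(np.full(k, 5.0)) if k > 1 else np.array([1.0])
        groups[gid] = [(f"{gid}s{i:02d}", float(sh))
                       for i, sh in enumerate(shares)]
        # re-normalize away float drift so scheme validation is exact
        total = sum(sh for _, sh in groups[gid])
        groups[gid] = [(sid, sh / total) for sid, sh in groups[gid]]
    return DisaggregationScheme(groups=groups)


def make_health_inputs(
    cfg: SyntheticConfig,
    rng: np.random.Generator | None = None,
    n_ages: int = 3,
    n_diseases: int = 3,
    max_age: int = 110,
) -> tuple[PopulationLifetable, list[DiseaseSpec]]:
    """Small random population (n_ages x 2 sexes) and a few diseases with
    rates in plausible annual ranges and harmful relative risks > 1."""
    rng = cfg.rng() if rng is None else rng
    sexes = ("female", "male")
    ages = np.linspace(20, 70, n_ages).astype(int)
    cohorts = [
        Cohort(age=int(a), sex=s, count=float(rng.uniform(500, 5000)))
        for a in ages for s in sexes
    ]
    grid = np.arange(max_age + 1)
    mortality = {
        s: np.clip(0.0003 * np.exp(0.085 * grid) * rng.uniform(0.8, 1.2),
                   0.0, 1.0)
        for s in sexes
    }
    morbidity = {
        s: np.clip(0.01 + 0.002 * grid / 10.0 * rng.uniform(0.5, 1.5), 0.0, 0.5)
        for s in sexes
    }
    pop = PopulationLifetable(cohorts=cohorts, mortality=mortality,
                              morbidity=morbidity, discount_rate=0.0)
    diseases = []
    for d in range(n_diseases):
        inc = np.clip(rng.uniform(0.001, 0.02) * (1 + grid / 50.0), 0.0, 0.5)
        cf = np.full(max_age + 1, rng.uniform(0.01, 0.2))
        rem = np.full(max_age + 1, rng.uniform(0.0, 0.1))
        diseases.append(DiseaseSpec(
            name=f"disease{d}",
            incidence={s: inc for s in sexes},
            case_fatality={s: cf for s in sexes},
            remission={s: rem for s in sexes},
            disability_weight=float(rng.uniform(0.05, 0.3)),
            rr_per_unit={"bmi": float(rng.uniform(1.05, 1.4))},
            lag_years=int(rng.integers(0, 5)),
        ))
    return pop, diseases
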