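"""Central composite design, response-surface fitting, and desirability optimization.

The batch chemistry screen behind the flow process was a rotatable two-factor
central composite design (CCD) in reaction temperature (factor A, coded about
140 degC with a 10 degC step) and chlorosulfonic-acid equivalents (factor B,
coded about 7.5 eq with a 2.5 eq step).  Three responses were modelled in
coded units by ordinary least squares with p-value term elimination:

* R1, product LCAP (cubic model, maximized),
* R2, starting-material LCAP (quadratic, minimized),
* R3, sulfonic-acid impurity LCAP (quadratic on 1/R3, held in range).

LCAP is HPLC area percent.  The published model coefficients are shipped
verbatim as fixtures (:data:`PRODUCT_MODEL`, :data:`STARTING_MATERIAL_MODEL`,
:data:`SULFONIC_ACID_MODEL`) so that prediction and optimization do not
depend on refitting.  The executed run list (:data:`BATCH_DESIGN`) is also a
fixture: its axial points sit at coded +/-1.5 in A and about +/-1.4 in B and
its centers at B = +0.2, i.e. the executed design deviates slightly from the
textbook rotatable alpha = sqrt(2); both are supported.

Multivariate optimization uses Derringer-Suich desirability ramps combined by
geometric mean, searched by coarse grid plus Nelder-Mead polish.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize

__all__ = [
    "FactorCoding",
    "TEMPERATURE_CODING",
    "EQUIVALENTS_CODING",
    "CCDDesign",
    "build_rotatable_ccd",
    "BATCH_DESIGN",
    "ResponseSurfaceModel",
    "PRODUCT_MODEL",
    "STARTING_MATERIAL_MODEL",
    "SULFONIC_ACID_MODEL",
    "PRINTED_MODELS",
    "fit_response_surface",
    "simulate_responses",
    "Goal",
    "batch_range_criteria",
    "desirability",
    "overall_desirability",
    "desirability_optimize",
    "OptimizationResult",
    "save_models",
    "load_models",
]


# ---------------------------------------------------------------------------
# factor coding
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FactorCoding:
    """Affine map between physical factor levels and coded units.

    coded = (physical - center) / step.  ``axial_level`` records the coded
    magnitude of the design's axial (star) points.
    """

    name: str
    center: float
    step: float
    axial_level: float = math.sqrt(2.0)

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("coding step must be positive")

    def code(self, physical: float | np.ndarray) -> float | np.ndarray:
        return (np.asarray(physical, dtype=float) - self.center) / self.step

    def decode(self, coded: float | np.ndarray) -> float | np.ndarray:
        return np.asarray(coded, dtype=float) * self.step + self.center


#: Factor A: reaction temperature, degC (levels 130 / 140 / 150).
TEMPERATURE_CODING = FactorCoding("temperature_C", 140.0, 10.0)
#: Factor B: ClSO3H molar equivalents (levels 5 / 7.5 / 10).
EQUIVALENTS_CODING = FactorCoding("eq_clso3h", 7.5, 2.5)


@dataclass(frozen=True)
class CCDDesign:
    """A two-factor central composite design with coded and physical levels."""

    factors: tuple[FactorCoding, FactorCoding]
    runs: pd.DataFrame  # columns: run, coded_A, coded_B, <factor names>
    center_replicates: int

    @property
    def n_runs(self) -> int:
        return len(self.runs)


def build_rotatable_ccd(
    factor_a: FactorCoding = TEMPERATURE_CODING,
    factor_b: FactorCoding = EQUIVALENTS_CODING,
    center_replicates: int = 3,
) -> CCDDesign:
    """Construct a rotatable CCD: 4 factorial + 4 axial + center replicates.

    Axial points sit at the coded magnitude each factor's ``axial_level``
    records (sqrt(2) by default, giving direction-independent prediction
    variance for two factors).
    """
    if center_replicates < 0:
        raise ValueError("center_replicates must be >= 0")
    coded: list[tuple[float, float]] = []
    coded.extend(itertools.product((-1.0, 1.0), (-1.0, 1.0)))
    coded.extend([(-factor_a.axial_level, 0.0), (factor_a.axial_level, 0.0)])
    coded.extend([(0.0, -factor_b.axial_level), (0.0, factor_b.axial_level)])
    coded.extend([(0.0, 0.0)] * center_replicates)
    a = np.array([c[0] for c in coded])
    b = np.array([c[1] for c in coded])
    runs = pd.DataFrame(
        {
            "run": np.arange(1, len(coded) + 1),
            "coded_A": a,
            "coded_B": b,
            factor_a.name: factor_a.decode(a),
            factor_b.name: factor_b.decode(b),
        }
    )
    return CCDDesign((factor_a, factor_b), runs, center_replicates)


def _executed_batch_design() -> CCDDesign:
    # The 11 batch conditions as executed (temperature degC, ClSO3H eq).
    # Centers ran at 8 eq rather than the coded center 7.5, and the axial
    # levels were rounded to practical settings (155/125 degC, 11/4 eq).
    physical = [
        (130.0, 10.0),
        (140.0, 8.0),
        (155.0, 8.0),
        (140.0, 8.0),
        (130.0, 5.0),
        (140.0, 11.0),
        (140.0, 8.0),
        (150.0, 5.0),
        (125.0, 8.0),
        (140.0, 4.0),
        (150.0, 10.0),
    ]
    t = np.array([p[0] for p in physical])
    e = np.array([p[1] for p in physical])
    runs = pd.DataFrame(
        {
            "run": np.arange(1, 12),
            "coded_A": TEMPERATURE_CODING.code(t),
            "coded_B": EQUIVALENTS_CODING.code(e),
            TEMPERATURE_CODING.name: t,
            EQUIVALENTS_CODING.name: e,
        }
    )
    return CCDDesign((TEMPERATURE_CODING, EQUIVALENTS_CODING), runs, 3)


#: The 11-run batch screen as executed (fixture; see module docstring).
BATCH_DESIGN = _executed_batch_design()


# ---------------------------------------------------------------------------
# response-surface models
# ---------------------------------------------------------------------------


def _term_name(powers: tuple[int, int]) -> str:
    i, j = powers
    if i == j == 0:
        return "1"
    parts = []
    if i:
        parts.append("A" if i == 1 else f"A^{i}")
    if j:
        parts.append("B" if j == 1 else f"B^{j}")
    return "*".join(parts)


def _parse_term(name: str) -> tuple[int, int]:
    name = name.strip()
    if name in ("1", "", "intercept"):
        return (0, 0)
    i = j = 0
    for part in name.split("*"):
        part = part.strip()
        base, _, exp = part.partition("^")
        power = int(exp) if exp else 1
        if base == "A":
            i += power
        elif base == "B":
            j += power
        else:
            raise ValueError(f"unknown factor in term {name!r}")
    return (i, j)


@dataclass(frozen=True)
class ResponseSurfaceModel:
    """Polynomial response model in coded units, with optional 1/y transform.

    ``terms`` maps monomial powers ``(i, j)`` (for ``A**i * B**j``) to
    coefficients.  For ``transform == "reciprocal"`` the polynomial models
    ``1/y`` and predictions are inverted last.
    """

    response: str
    terms: dict[tuple[int, int], float]
    transform: str = "identity"
    coding: tuple[FactorCoding, FactorCoding] = (
        TEMPERATURE_CODING,
        EQUIVALENTS_CODING,
    )

    def __post_init__(self) -> None:
        if self.transform not in ("identity", "reciprocal"):
            raise ValueError("transform must be 'identity' or 'reciprocal'")

    def evaluate_coded(self, a, b):
        """Evaluate the (transformed-scale) polynomial at coded (a, b)."""
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        out = np.zeros(np.broadcast(a, b).shape)
        for (i, j), coef in self.terms.items():
            out = out + coef * a**i * b**j
        return out if out.shape else float(out)

    def predict_coded(self, a, b):
        """Predict the response (original scale) at coded (a, b)."""
        y = self.evaluate_coded(a, b)
        if self.transform == "reciprocal":
            y = 1.0 / np.asarray(y, dtype=float)
            return y if y.shape else float(y)
        return y

    def predict(self, temperature_c, equivalents):
        """Predict the response at physical factor levels."""
        a = self.coding[0].code(temperature_c)
        b = self.coding[1].code(equivalents)
        return self.predict_coded(a, b)


# Published coded-unit model coefficients (fixtures).
PRODUCT_MODEL = ResponseSurfaceModel(
    "R1",
    {
        (0, 0): 58.02,
        (1, 0): 14.24,
        (0, 1): 8.13,
        (1, 1): -3.64,
        (2, 0): 2.84,
        (0, 2): -4.55,
        (2, 1): -7.92,
        (1, 2): -0.7728,
    },
)

STARTING_MATERIAL_MODEL = ResponseSurfaceModel(
    "R2",
    {
        (0, 0): 14.81,
        (1, 0): -16.22,
        (0, 1): 2.18,
        (1, 1): 1.45,
        (2, 0): 4.84,
        (0, 2): 2.03,
    },
)

SULFONIC_ACID_MODEL = ResponseSurfaceModel(
    "R3",
    {
        (0, 0): 0.0376,
        (1, 0): -0.0101,
        (0, 1): 0.0108,
        (1, 1): -0.0104,
        (2, 0): 0.0168,
    },
    transform="reciprocal",
)

PRINTED_MODELS: dict[str, ResponseSurfaceModel] = {
    "R1": PRODUCT_MODEL,
    "R2": STARTING_MATERIAL_MODEL,
    "R3": SULFONIC_ACID_MODEL,
}


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _candidate_terms(max_order: int) -> list[tuple[int, int]]:
    terms = [
        (i, j)
        for i in range(max_order + 1)
        for j in range(max_order + 1)
        if i + j <= max_order
    ]
    # intercept first, then by total degree; within a degree, mixed terms
    # before pure powers: on a CCD the pure cubes are exactly aliased with
    # {A, A*B^2} / {B, A^2*B}, and the mixed cubics are the estimable choice
    terms.sort(key=lambda ij: (ij[0] + ij[1], -(ij[0] * ij[1]), ij[1]))
    return terms


def _design_matrix(a: np.ndarray, b: np.ndarray, terms: list[tuple[int, int]]) -> np.ndarray:
    return np.column_stack([a**i * b**j for i, j in terms])


def _drop_aliased(a, b, terms):
    """Greedily keep candidate terms while the design matrix stays full rank.

    On saturated or collapsed designs higher-order monomials can be exact
    linear combinations of lower ones (e.g. A^3 on a 9-distinct-point CCD);
    those aliased terms cannot be estimated and are dropped, lowest degree
    retained first.
    """
    kept: list[tuple[int, int]] = []
    for term in terms:
        trial = kept + [term]
        x = _design_matrix(a, b, trial)
        if np.linalg.matrix_rank(x) == len(trial):
            kept.append(term)
    return kept


def _has_dependent_child(term, terms):
    i, j = term
    for (ci, cj) in terms:
        if (ci, cj) != (i, j) and ci >= i and cj >= j:
            return True
    return False


def fit_response_surface(
    design: pd.DataFrame,
    response: str,
    max_order: int = 2,
    alpha: float = 0.05,
    transform: str = "identity",
    preserve_hierarchy: bool = True,
    coding: tuple[FactorCoding, FactorCoding] = (TEMPERATURE_CODING, EQUIVALENTS_CODING),
) -> tuple[ResponseSurfaceModel, pd.DataFrame]:
    """OLS response-surface fit with backward p-value elimination.

    ``design`` needs columns ``coded_A``, ``coded_B`` and the response.  The
    candidate model holds all monomials ``A**i B**j`` with ``i + j <=
    max_order`` (aliased ones dropped, see :func:`_drop_aliased`).  Terms are
    removed one at a time, largest p-value first, while ``p >= alpha``;
    with ``preserve_hierarchy`` a term is only removable while no retained
    higher-order term contains it.  Returns the reduced model and a per-term
    ANOVA table (coefficient, standard error, F, p) from the final fit.
    """
    import statsmodels.api as sm

    if max_order not in (2, 3):
        raise ValueError("max_order must be 2 or 3")
    a = design["coded_A"].to_numpy(dtype=float)
    b = design["coded_B"].to_numpy(dtype=float)
    y = design[response].to_numpy(dtype=float)
    if transform == "reciprocal":
        y = 1.0 / y
    elif transform != "identity":
        raise ValueError("transform must be 'identity' or 'reciprocal'")

    terms = _drop_aliased(a, b, _candidate_terms(max_order))
    if len(terms) > len(y):
        raise ValueError("more candidate terms than runs")

    def _ols(current):
        x = _design_matrix(a, b, current)
        return sm.OLS(y, x).fit()

    current = list(terms)
    fit = _ols(current)
    while True:
        pvals = np.asarray(fit.pvalues, dtype=float)
        candidates = []
        for idx, term in enumerate(current):
            if term == (0, 0):
                continue  # intercept always retained
            if preserve_hierarchy and _has_dependent_child(term, current):
                continue
            p = pvals[idx]
            if np.isnan(p) or p >= alpha:
                candidates.append((1.0 if np.isnan(p) else p, idx))
        if not candidates:
            break
        _, drop_idx = max(candidates)
        current.pop(drop_idx)
        fit = _ols(current)

    coefs = np.asarray(fit.params, dtype=float)
    se = np.asarray(fit.bse, dtype=float)
    tvals = np.asarray(fit.tvalues, dtype=float)
    pvals = np.asarray(fit.pvalues, dtype=float)
    anova = pd.DataFrame(
        {
            "term": [_term_name(t) for t in current],
            "coef": coefs,
            "stderr": se,
            "F": tvals**2,
            "p": pvals,
        }
    )
    model = ResponseSurfaceModel(
        response,
        {term: float(c) for term, c in zip(current, coefs)},
        transform=transform,
        coding=coding,
    )
    return model, anova


def simulate_responses(
    design: CCDDesign | pd.DataFrame = BATCH_DESIGN,
    models: dict[str, ResponseSurfaceModel] = PRINTED_MODELS,
    noise_sd: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Synthetic response table: model predictions at the design points.

    Emulates the 60-minute HPLC response table of a batch screen: each
    response is the model prediction at the run's coded levels plus i.i.d.
    Gaussian noise of standard deviation ``noise_sd`` (LCAP units, applied on
    the original response scale).  With ``noise_sd = 0`` the table is exact,
    which is the fixture used by the OLS-exactness tests.
    """
    runs = design.runs if isinstance(design, CCDDesign) else design
    rng = np.random.default_rng(rng)
    out = runs.copy()
    a = out["coded_A"].to_numpy(dtype=float)
    b = out["coded_B"].to_numpy(dtype=float)
    for name, model in models.items():
        y = np.asarray(model.predict_coded(a, b), dtype=float)
        if noise_sd > 0:
            y = y + rng.normal(0.0, noise_sd, size=y.shape)
        out[name] = y
    return out


# ---------------------------------------------------------------------------
# desirability
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Goal:
    """Derringer-Suich desirability goal for one response.

    ``maximize``: d = 0 below ``low``, ramps to 1 at ``high``.
    ``minimize``: d = 1 below ``low``, ramps to 0 at ``high``.
    ``in_range``: d = 1 inside [low, high], 0 outside.
    """

    kind: str
    low: float
    high: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("maximize", "minimize", "in_range"):
            raise ValueError("goal kind must be maximize, minimize or in_range")
        if not self.low <= self.high:
            raise ValueError("goal anchors must satisfy low <= high")
        if self.weight <= 0:
            raise ValueError("goal weight must be positive")


def desirability(value: float, goal: Goal) -> float:
    """Per-response desirability in [0, 1]."""
    lo, hi, w = goal.low, goal.high, goal.weight
    if goal.kind == "in_range":
        return 1.0 if lo <= value <= hi else 0.0
    if goal.kind == "maximize":
        if hi == lo:
            ramp = 1.0 if value >= hi else 0.0
        else:
            ramp = min(1.0, max(0.0, (value - lo) / (hi - lo)))
    else:  # minimize
        if hi == lo:
            ramp = 1.0 if value <= lo else 0.0
        else:
            ramp = min(1.0, max(0.0, (hi - value) / (hi - lo)))
    return ramp**w


def overall_desirability(values: dict[str, float], criteria: dict[str, Goal]) -> float:
    """Weighted geometric mean of per-response desirabilities."""
    if not criteria:
        raise ValueError("no criteria given")
    total_w = sum(g.weight for g in criteria.values())
    log_sum = 0.0
    for name, goal in criteria.items():
        d = desirability(values[name], replace(goal, weight=1.0))
        if d <= 0.0:
            return 0.0
        log_sum += goal.weight * math.log(d)
    return math.exp(log_sum / total_w)


def batch_range_criteria(
    models: dict[str, ResponseSurfaceModel] = PRINTED_MODELS,
    design: CCDDesign | pd.DataFrame = BATCH_DESIGN,
    r3_range: tuple[float, float] | None = None,
) -> dict[str, Goal]:
    """Optimization criteria anchored to the batch screen's response ranges.

    Product (R1) is maximized and starting material (R2) minimized between
    the minimum and maximum predicted over the executed design; the sulfonic
    acid impurity (R3) is held in range.  ``r3_range`` overrides the R3
    anchors when the observed impurity range is known.
    """
    table = simulate_responses(design, models, noise_sd=0.0)
    crit: dict[str, Goal] = {}
    if "R1" in models:
        crit["R1"] = Goal("maximize", float(table["R1"].min()), float(table["R1"].max()))
    if "R2" in models:
        crit["R2"] = Goal("minimize", float(table["R2"].min()), float(table["R2"].max()))
    if "R3" in models:
        lo, hi = r3_range if r3_range is not None else (
            float(table["R3"].min()),
            float(table["R3"].max()),
        )
        crit["R3"] = Goal("in_range", lo, hi)
    return crit


@dataclass(frozen=True)
class OptimizationResult:
    """Best desirability point(s): coded and physical levels plus responses."""

    points: pd.DataFrame  # coded_A, coded_B, physical cols, responses, desirability
    desirability: float

    @property
    def best(self) -> pd.Series:
        return self.points.iloc[0]


#: Coded search region spanned by the executed batch design.
DEFAULT_CODED_BOUNDS = ((-1.5, 1.5), (-1.4, 1.4))


def desirability_optimize(
    models: dict[str, ResponseSurfaceModel] = PRINTED_MODELS,
    criteria: dict[str, Goal] | None = None,
    coded_bounds: tuple[tuple[float, float], tuple[float, float]] = DEFAULT_CODED_BOUNDS,
    coarse_grid: int = 41,
    n_polish: int = 8,
    tie_tol: float = 1e-9,
) -> OptimizationResult:
    """Maximize the geometric-mean desirability over the coded design region.

    A coarse grid scan seeds Nelder-Mead polish from the ``n_polish`` best
    cells (multi-start; the desirability surface is piecewise smooth with
    plateaus, so gradient-free polish is used).  All evaluated points tying
    the optimum within ``tie_tol`` are returned, deduplicated.
    """
    if criteria is None:
        criteria = batch_range_criteria(models)
    (a_lo, a_hi), (b_lo, b_hi) = coded_bounds

    def objective(point) -> float:
        a, b = point
        if not (a_lo <= a <= a_hi and b_lo <= b <= b_hi):
            return 0.0
        values = {name: float(m.predict_coded(a, b)) for name, m in models.items()}
        return overall_desirability(values, criteria)

    aa, bb = np.meshgrid(
        np.linspace(a_lo, a_hi, coarse_grid), np.linspace(b_lo, b_hi, coarse_grid)
    )
    grid_pts = np.column_stack([aa.ravel(), bb.ravel()])
    grid_d = np.array([objective(p) for p in grid_pts])

    order = np.argsort(grid_d)[::-1]
    seeds = grid_pts[order[:n_polish]]
    candidates = [(grid_d[i], grid_pts[i]) for i in order[:n_polish]]
    for seed in seeds:
        res = minimize(
            lambda p: -objective(p),
            seed,
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-12, "maxiter": 400},
        )
        candidates.append((-res.fun, np.clip(res.x, (a_lo, b_lo), (a_hi, b_hi))))

    best_d = max(d for d, _ in candidates)
    ties = [p for d, p in candidates if best_d - d <= tie_tol]
    # deduplicate points closer than 1e-3 coded units
    unique: list[np.ndarray] = []
    for p in ties:
        if not any(np.linalg.norm(p - q) < 1e-3 for q in unique):
            unique.append(p)

    coding = next(iter(models.values())).coding
    rows = []
    for p in unique:
        a, b = float(p[0]), float(p[1])
        row = {
            "coded_A": a,
            "coded_B": b,
            coding[0].name: float(coding[0].decode(a)),
            coding[1].name: float(coding[1].decode(b)),
        }
        for name, m in models.items():
            row[name] = float(m.predict_coded(a, b))
        row["desirability"] = objective(p)
        rows.append(row)
    points = pd.DataFrame(rows).sort_values("desirability", ascending=False)
    return OptimizationResult(points.reset_index(drop=True), float(best_d))


# ---------------------------------------------------------------------------
# plain-text model serialization
# ---------------------------------------------------------------------------


def save_models(models: dict[str, ResponseSurfaceModel], path) -> None:
    """Write models as plain-text ``term: coefficient`` listings."""
    with open(path, "w") as fh:
        for name, model in models.items():
            fh.write(f"[{name}]\n")
            fh.write(f"transform: {model.transform}\n")
            for term, coef in sorted(model.terms.items()):
                fh.write(f"{_term_name(term)}: {coef!r}\n")
            fh.write("\n")


def load_models(path) -> dict[str, ResponseSurfaceModel]:
    """Read models written by :func:`save_models`."""
    models: dict[str, ResponseSurfaceModel] = {}
    name = None
    terms: dict[tuple[int, int], float] = {}
    transform = "identity"

    def _flush():
        if name is not None:
            models[name] = ResponseSurfaceModel(name, dict(terms), transform=transform)

    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("[") and line.endswith("]"):
                _flush()
                name = line[1:-1]
                terms = {}
                transform = "identity"
            else:
                key, _, value = line.partition(":")
                if key.strip() == "transform":
                    transform = value.strip()
                else:
                    terms[_parse_term(key)] = float(value)
    _flush()
    return models
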