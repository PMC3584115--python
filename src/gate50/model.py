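"""The multivariable logistic diagnostic model.

Covers four concerns:

* scoring subjects with a frozen, published coefficient set (shipped as JSON
  under ``gate50/models/``);
* maximum-likelihood fitting of a logistic model to a cohort table;
* stepwise covariate selection with a score (Lagrange-multiplier) test for
  entry and a Wald test for removal, both at configurable significance
  levels (0.15 by default);
* LOESS-based exploration of disease risk as a function of the continuous
  gating ratio, returning the ratio at which the smoothed log-odds first
  crosses the cohort-prevalence log-odds (the dichotomization cutoff).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import special, stats as sps
import statsmodels.api as sm
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.tools.sm_exceptions import (
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from .errors import (
    ConfigurationError,
    NoCutoffError,
    ScoringError,
    SeparationError,
    SingularDesignError,
)
from .peaks import dichotomize_gating

__all__ = [
    "Term",
    "ModelCoefficients",
    "FittedModel",
    "load_published_model",
    "score_probability",
    "score_table",
    "fit_logistic",
    "stepwise_select",
    "estimate_cutoff",
    "odds_ratios",
]

PUBLISHED_MODEL_RESOURCE = "published_diagnostic_model.json"


@dataclass(frozen=True)
class Term:
    name: str
    coef: float
    se: float | None = None

    def __post_init__(self) -> None:
        if self.se is not None and self.se <= 0:
            raise ConfigurationError(f"standard error for {self.name} must be > 0")


@dataclass
class ModelCoefficients:
    """Named logistic-regression terms (log-odds scale) with standard errors."""

    terms: list[Term]
    outcome: str = "schizophrenia"
    gating_cutoff: float = 0.4
    notes: dict = field(default_factory=dict)

    @property
    def names(self) -> list[str]:
        return [t.name for t in self.terms]

    def covariate_names(self) -> list[str]:
        return [t.name for t in self.terms if t.name.lower() != "intercept"]

    def get(self, name: str) -> Term:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelCoefficients":
        terms = [Term(t["name"], float(t["coef"]), t.get("se")) for t in d["terms"]]
        return cls(terms, d.get("outcome", "schizophrenia"),
                   float(d.get("gating_cutoff", 0.4)), d.get("notes", {}))

    def to_dict(self) -> dict:
        return {
            "terms": [{"name": t.name, "coef": t.coef, "se": t.se}
                      for t in self.terms],
            "outcome": self.outcome,
            "gating_cutoff": self.gating_cutoff,
            "notes": self.notes,
        }

    @classmethod
    def from_json(cls, path) -> "ModelCoefficients":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


@dataclass
class FittedModel:
    """A maximum-likelihood logistic fit with its uncertainty."""

    coefficients: ModelCoefficients
    cov: np.ndarray
    llf: float
    converged: bool
    n: int
    audit_trail: list = field(default_factory=list)

    def wald_p(self) -> dict:
        """Two-sided Wald p-value per term."""
        out = {}
        for t in self.coefficients.terms:
            z = t.coef / t.se
            out[t.name] = 2 * sps.norm.sf(abs(z))
        return out


def load_published_model() -> ModelCoefficients:
    """The published six-covariate diagnostic coefficient set."""
    ref = resources.files("gate50") / "models" / PUBLISHED_MODEL_RESOURCE
    return ModelCoefficients.from_dict(json.loads(ref.read_text()))


def score_probability(record, coefs: ModelCoefficients) -> float:
    """Predicted probability of disease for one subject.

    ``record`` is any mapping covariate-name -> value.  Raises ScoringError
    naming the first covariate the model needs but the record lacks.
    """
    eta = 0.0
    for t in coefs.terms:
        if t.name.lower() == "intercept":
            eta += t.coef
            continue
        try:
            value = record[t.name]
        except (KeyError, IndexError):
            raise ScoringError(f"record lacks covariate {t.name!r}") from None
        if value is None or (isinstance(value, float) and np.isnan(value)):
            raise ScoringError(f"record lacks covariate {t.name!r}")
        eta += t.coef * float(value)
    return float(special.expit(eta))


def score_table(table: pd.DataFrame, coefs: ModelCoefficients) -> np.ndarray:
    """Vectorized scoring of a cohort table.

    If the model names a ``gating`` column absent from the table, it is
    derived from the continuous ``ratio`` column at the model's cutoff.
    """
    table = table.copy()
    if "gating" in coefs.covariate_names() and "gating" not in table.columns:
        if "ratio" not in table.columns:
            raise ScoringError("record lacks covariate 'gating'")
        table["gating"] = [
            dichotomize_gating(r, coefs.gating_cutoff) for r in table["ratio"]
        ]
    eta = np.zeros(len(table))
    for t in coefs.terms:
        if t.name.lower() == "intercept":
            eta += t.coef
            continue
        if t.name not in table.columns:
            raise ScoringError(f"record lacks covariate {t.name!r}")
        eta += t.coef * table[t.name].to_numpy(dtype=float)
    return special.expit(eta)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

_SEPARATION_COEF_LIMIT = 25.0


def _design(table: pd.DataFrame, terms: list[str]) -> tuple[np.ndarray, np.ndarray, list[str]]:
    y = table["group"].to_numpy(dtype=float)
    X = np.column_stack(
        [np.ones(len(table))] + [table[t].to_numpy(dtype=float) for t in terms]
    )
    names = ["Intercept"] + list(terms)
    return y, X, names


def _check_design(X: np.ndarray, names: list[str]) -> None:
    for j, name in enumerate(names[1:], start=1):
        if np.ptp(X[:, j]) == 0:
            raise SingularDesignError([name])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # identify columns involved in the collinearity via QR
        _, R = np.linalg.qr(X)
        bad = [names[j] for j in range(X.shape[1])
               if abs(R[j, j]) < 1e-8 * max(1.0, abs(R[0, 0]))]
        raise SingularDesignError(bad or names[1:])


def fit_logistic(table: pd.DataFrame, terms: list[str]) -> FittedModel:
    """Maximum-likelihood logistic regression of ``group`` on ``terms``.

    Fitting is by iteratively reweighted least squares; standard errors come
    from the inverse observed information.  Complete separation and singular
    designs raise dedicated errors.
    """
    y, X, names = _design(table, terms)
    if y.min() == y.max():
        raise ConfigurationError("need at least one event and one non-event")
    _check_design(X, names)
    model = sm.GLM(y, X, family=sm.families.Binomial())
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=PerfectSeparationWarning)
            try:
                res = model.fit(maxiter=100, tol=1e-8)
            except PerfectSeparationWarning:
                raise SeparationError("separation") from None
    except PerfectSeparationError:
        raise SeparationError("separation") from None
    params = np.asarray(res.params, dtype=float)
    scale = np.concatenate([[1.0], X[:, 1:].std(axis=0)]) if X.shape[1] > 1 else np.ones(1)
    if np.any(np.abs(params * scale) > _SEPARATION_COEF_LIMIT):
        raise SeparationError("separation")
    cov = np.asarray(res.cov_params(), dtype=float)
    ses = np.sqrt(np.diag(cov))
    coefs = ModelCoefficients(
        [Term(nm, float(b), float(se)) for nm, b, se in zip(names, params, ses)]
    )
    return FittedModel(coefs, cov, float(res.llf), bool(res.converged), len(y))


def _score_test(y: np.ndarray, Z: np.ndarray, p_hat: np.ndarray,
                x: np.ndarray) -> float:
    """1-df score-test p-value for adding covariate ``x`` to a fitted
    logistic model with design ``Z`` and fitted probabilities ``p_hat``."""
    w = p_hat * (1 - p_hat)
    u = x @ (y - p_hat)
    A = Z.T @ (Z * w[:, None])
    c = Z.T @ (w * x)
    var = (x * w) @ x - c @ np.linalg.solve(A, c)
    if var <= 0:
        return 1.0
    stat = u * u / var
    return float(sps.chi2.sf(stat, df=1))


def stepwise_select(
    table: pd.DataFrame,
    candidates: list[str],
    sle: float = 0.15,
    sls: float = 0.15,
) -> FittedModel:
    """Stepwise covariate selection (score test to enter, Wald test to stay).

    At each step the excluded candidate with the smallest score-test p-value
    enters if p < ``sle``; then the included term with the largest Wald
    p-value leaves if p > ``sls``.  Iteration stops when no change occurs or
    a previously visited model recurs.  The returned fit carries an audit
    trail of every entry/removal with its p-value.
    """
    if not candidates:
        raise ConfigurationError("candidates must be non-empty")
    current: list[str] = []
    trail: list[dict] = []
    visited = {frozenset()}
    while True:
        fit = fit_logistic(table, current)
        y, Z, _ = _design(table, current)
        p_hat = special.expit(Z @ np.array([t.coef for t in fit.coefficients.terms]))
        # entry
        entry_p = {
            c: _score_test(y, Z, p_hat, table[c].to_numpy(dtype=float))
            for c in candidates if c not in current
        }
        changed = False
        if entry_p:
            best = min(entry_p, key=entry_p.get)
            if entry_p[best] < sle:
                current.append(best)
                trail.append({"action": "enter", "term": best, "p": entry_p[best]})
                changed = True
        # removal
        if current:
            fit = fit_logistic(table, current)
            wald = {k: v for k, v in fit.wald_p().items() if k != "Intercept"}
            worst = max(wald, key=wald.get)
            if wald[worst] > sls:
                current.remove(worst)
                trail.append({"action": "remove", "term": worst, "p": wald[worst]})
                changed = True
        state = frozenset(current)
        if not changed or state in visited:
            break
        visited.add(state)
    final = fit_logistic(table, current)
    final.audit_trail = trail
    return final


# ---------------------------------------------------------------------------
# LOESS cutoff exploration
# ---------------------------------------------------------------------------

def estimate_cutoff(
    table: pd.DataFrame,
    variable: str = "ratio",
    span: float = 0.75,
) -> tuple[float, pd.DataFrame]:
    """Locate where LOESS-smoothed disease risk crosses cohort prevalence.

    A locally weighted linear smooth of the binary outcome on ``variable``
    is converted to log-odds; the smallest value of ``variable`` at which
    the smooth crosses the prevalence log-odds is returned together with the
    full curve.  Raises NoCutoffError (carrying the curve) when the smooth
    never crosses the prevalence line.
    """
    if len(table) < 50:
        raise ConfigurationError("cutoff estimation requires >= 50 observations")
    x = table[variable].to_numpy(dtype=float)
    y = table["group"].to_numpy(dtype=float)
    sm_xy = lowess(y, x, frac=span, it=0, return_sorted=True)
    xs, ps = sm_xy[:, 0], np.clip(sm_xy[:, 1], 1e-6, 1 - 1e-6)
    # collapse duplicate x (lowess returns one row per input point)
    _, first = np.unique(xs, return_index=True)
    xs, ps = xs[first], ps[first]
    logits = special.logit(ps)
    prevalence = y.mean()
    target = special.logit(np.clip(prevalence, 1e-6, 1 - 1e-6))
    curve = pd.DataFrame({variable: xs, "risk": ps, "log_odds": logits,
                          "prevalence_log_odds": target})
    d = logits - target
    if np.all(np.abs(d) < 1e-9):
        # flat curve sitting on the prevalence line: no informative crossing
        raise NoCutoffError(curve)
    for i in range(len(d) - 1):
        if abs(d[i]) < 1e-12:
            return float(xs[i]), curve
        if d[i] * d[i + 1] < 0:
            x0, x1, d0, d1 = xs[i], xs[i + 1], d[i], d[i + 1]
            return float(x0 - d0 * (x1 - x0) / (d1 - d0)), curve
    if abs(d[-1]) < 1e-12:
        return float(xs[-1]), curve
    raise NoCutoffError(curve)


def odds_ratios(model: FittedModel | ModelCoefficients, z: float = 1.96) -> pd.DataFrame:
    """Per-term odds ratios with 95 % Wald confidence intervals."""
    coefs = model.coefficients if isinstance(model, FittedModel) else model
    rows = []
    for t in coefs.terms:
        if t.name.lower() == "intercept":
            continue
        if t.se is None:
            raise ConfigurationError(f"term {t.name} has no standard error")
        rows.append({
            "term": t.name,
            "odds_ratio": np.exp(t.coef),
            "ci_low": np.exp(t.coef - z * t.se),
            "ci_high": np.exp(t.coef + z * t.se),
        })
    return pd.DataFrame(rows).set_index("term")
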