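"""Discrimination, calibration, bootstrap validation and group comparisons.

* ``concordance`` — the c statistic by explicit case-control pair counting
  (equals the area under the ROC curve).
* ``hosmer_lemeshow`` — goodness-of-fit chi-square over deciles of risk,
  df = groups - 2.
* ``bootstrap_validate`` — internal validation: refit on resamples drawn
  with replacement at the original n, record each refit's c statistic on its
  own resample.
* ``group_compare`` — pooled-variance two-sample t and Pearson chi-square
  (no continuity correction), from raw columns or printed summaries.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    ConfigurationError,
    DegenerateLabelsError,
    SeparationError,
    UnstableBootstrapError,
)
from . import model as _model

__all__ = [
    "ValidationReport",
    "concordance",
    "hosmer_lemeshow",
    "bootstrap_validate",
    "group_compare",
    "group_compare_summary",
    "validate_model",
]

log = logging.getLogger("gate50.validate")


@dataclass
class ValidationReport:
    c_statistic: float
    pct_concordant: float
    pct_discordant: float
    pct_tied: float
    hl_statistic: float
    hl_df: int
    hl_p: float
    n: int
    bootstrap_mean_c: float | None = None
    bootstrap_sd_c: float | None = None
    n_bootstrap: int | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    def summary(self) -> str:
        lines = [
            f"n = {self.n}",
            f"concordant {self.pct_concordant:.1f}% / discordant "
            f"{self.pct_discordant:.1f}% / tied {self.pct_tied:.1f}%",
            f"c statistic = {self.c_statistic:.4f}",
            f"Hosmer-Lemeshow chi2 = {self.hl_statistic:.3f} "
            f"(df = {self.hl_df}), p = {self.hl_p:.3f}",
        ]
        if self.n_bootstrap:
            lines.append(
                f"bootstrap c = {self.bootstrap_mean_c:.3f} "
                f"± {self.bootstrap_sd_c:.3f} ({self.n_bootstrap} resamples)"
            )
        return "\n".join(lines)


def concordance(
    probs: np.ndarray, labels: np.ndarray
) -> tuple[float, float, float, float]:
    """Count concordant/discordant/tied case-control pairs.

    Returns (c, pct_concordant, pct_discordant, pct_tied) where
    c = (concordant + tied/2) / total over all case-control pairs.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels)
    cases = np.sort(probs[labels == 1])
    controls = np.sort(probs[labels == 0])
    if cases.size == 0 or controls.size == 0:
        raise DegenerateLabelsError("degenerate_labels")
    # for each case, count controls strictly below / equal via binary search
    lo = np.searchsorted(controls, cases, side="left")
    hi = np.searchsorted(controls, cases, side="right")
    concordant = float(lo.sum())
    tied = float((hi - lo).sum())
    total = float(cases.size * controls.size)
    discordant = total - concordant - tied
    c = (concordant + 0.5 * tied) / total
    return (
        c,
        100.0 * concordant / total,
        100.0 * discordant / total,
        100.0 * tied / total,
    )


def hosmer_lemeshow(
    probs: np.ndarray, labels: np.ndarray, groups: int = 10
) -> tuple[float, int, float]:
    """Hosmer-Lemeshow goodness-of-fit over deciles of risk.

    Subjects are sorted by predicted probability and split into ``groups``
    near-equal bins, keeping tied probabilities in the same bin.  The
    statistic is sum (O - E)^2 / (E (1 - E/n_g)); df = bins - 2.  Degenerate
    bins (expected events 0 or n_g) are merged with their neighbour and the
    df reduced accordingly.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=float)
    n = probs.size
    if n < groups:
        raise ConfigurationError("need at least one subject per risk group")
    order = np.argsort(probs, kind="stable")
    p, y = probs[order], labels[order]
    edges = [int(round(n * k / groups)) for k in range(groups + 1)]
    bins: list[tuple[int, int]] = []
    for a, b in zip(edges[:-1], edges[1:]):
        if a >= b:
            continue
        # keep ties together: extend the bin while the boundary value repeats
        while b < n and p[b] == p[b - 1]:
            b += 1
        if bins and bins[-1][1] > a:
            a = bins[-1][1]
        if a < b:
            bins.append((a, b))
    cells = [[y[a:b].sum(), p[a:b].sum(), b - a] for a, b in bins]

    # merge bins with degenerate expectation (E == 0 or E == n_g) into a
    # neighbour, reducing the df; logged so calibration output is auditable
    def degenerate(cell):
        return cell[1] <= 0 or cell[1] >= cell[2]

    while len(cells) > 1 and any(degenerate(c) for c in cells):
        i = next(j for j, c in enumerate(cells) if degenerate(c))
        j = i - 1 if i > 0 else i + 1
        cells[j] = [cells[j][0] + cells[i][0], cells[j][1] + cells[i][1],
                    cells[j][2] + cells[i][2]]
        del cells[i]
        log.info("Hosmer-Lemeshow: merged a degenerate risk bin")
    stat = 0.0
    for O, E, n_g in cells:
        denom = E * (1 - E / n_g)
        if denom <= 0:
            continue
        stat += (O - E) ** 2 / denom
    df = max(len(cells) - 2, 1)
    return float(stat), int(df), float(sps.chi2.sf(stat, df))


def bootstrap_validate(
    table: pd.DataFrame,
    terms: list[str],
    B: int = 1000,
    seed: int = 0,
    optimism_corrected: bool = False,
) -> tuple[float, float, int]:
    """Bootstrap internal validation of model discrimination.

    For each of ``B`` resamples drawn with replacement at the original n,
    the model is refit and its c statistic recorded — on the resample itself
    by default, or on the original data when ``optimism_corrected`` is set.
    Resamples with a single outcome class or non-convergent fits are redrawn
    (counted; more than 10 % redraws raises UnstableBootstrapError).

    Returns (mean_c, sd_c, n_redrawn).
    """
    if B < 2:
        raise ConfigurationError("B must be >= 2")
    rng = np.random.default_rng(seed)
    n = len(table)
    cs = []
    redrawn = 0
    while len(cs) < B:
        idx = rng.integers(0, n, size=n)
        boot = table.iloc[idx]
        y = boot["group"].to_numpy()
        if y.min() == y.max():
            redrawn += 1
            _check_redraws(redrawn, B)
            continue
        try:
            fit = _model.fit_logistic(boot.reset_index(drop=True), terms)
        except SeparationError:
            redrawn += 1
            _check_redraws(redrawn, B)
            continue
        eval_table = table if optimism_corrected else boot
        probs = _model.score_table(eval_table, fit.coefficients)
        c, *_ = concordance(probs, eval_table["group"].to_numpy())
        cs.append(c)
    cs = np.asarray(cs)
    if redrawn:
        log.info("bootstrap: %d replicates redrawn", redrawn)
    return float(cs.mean()), float(cs.std(ddof=1)), redrawn


def _check_redraws(redrawn: int, B: int) -> None:
    if redrawn > 0.1 * B + 5:
        raise UnstableBootstrapError("unstable_bootstrap")


def group_compare(
    table: pd.DataFrame, variable: str, kind: str = "t"
) -> tuple[float, float]:
    """Two-group comparison of one cohort variable.

    ``kind='t'``: pooled-variance two-sample t (patients vs controls),
    two-sided p.  ``kind='chisq'``: Pearson chi-square on the group-by-level
    contingency table, no continuity correction.
    """
    groups = table["group"].unique()
    if len(groups) != 2:
        raise ConfigurationError("exactly two groups required")
    a = table.loc[table["group"] == groups[0], variable]
    b = table.loc[table["group"] == groups[1], variable]
    if kind == "t":
        if np.concatenate([a, b]).std() == 0:
            raise ConfigurationError("zero pooled variance")
        stat, p = sps.ttest_ind(a, b, equal_var=True)
        return float(stat), float(p)
    if kind == "chisq":
        contingency = pd.crosstab(table["group"], table[variable]).to_numpy()
        stat, p, _, _ = sps.chi2_contingency(contingency, correction=False)
        return float(stat), float(p)
    raise ConfigurationError(f"unknown comparison kind {kind!r}")


def group_compare_summary(
    mean1: float, sd1: float, n1: int,
    mean2: float, sd2: float, n2: int,
    welch: bool = False,
) -> tuple[float, float]:
    """Pooled-variance (default) or Welch t test from printed summaries."""
    if welch:
        se = np.sqrt(sd1**2 / n1 + sd2**2 / n2)
        df = se**4 / ((sd1**2 / n1) ** 2 / (n1 - 1) + (sd2**2 / n2) ** 2 / (n2 - 1))
    else:
        sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
        if sp2 == 0:
            raise ConfigurationError("zero pooled variance")
        se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = n1 + n2 - 2
    t = (mean2 - mean1) / se
    return float(t), float(2 * sps.t.sf(abs(t), df))


def validate_model(
    table: pd.DataFrame,
    coefs: _model.ModelCoefficients,
    bootstrap_B: int = 0,
    bootstrap_terms: list[str] | None = None,
    seed: int = 0,
    hl_groups: int = 10,
) -> ValidationReport:
    """Score a cohort with a coefficient set and report discrimination and
    calibration (optionally with bootstrap internal validation)."""
    probs = _model.score_table(table, coefs)
    labels = table["group"].to_numpy()
    c, pc, pdisc, pt = concordance(probs, labels)
    hl_stat, hl_df, hl_p = hosmer_lemeshow(probs, labels, hl_groups)
    report = ValidationReport(c, pc, pdisc, pt, hl_stat, hl_df, hl_p, len(table))
    if bootstrap_B:
        terms = bootstrap_terms or coefs.covariate_names()
        work = table.copy()
        if "gating" in terms and "gating" not in work.columns:
            from .peaks import dichotomize_gating
            work["gating"] = [dichotomize_gating(r, coefs.gating_cutoff)
                              for r in work["ratio"]]
        mean_c, sd_c, _ = bootstrap_validate(work, terms, bootstrap_B, seed)
        report.bootstrap_mean_c = mean_c
        report.bootstrap_sd_c = sd_c
        report.n_bootstrap = bootstrap_B
    return report
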