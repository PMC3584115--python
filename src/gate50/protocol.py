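"""Domain types for the paired-click paradigm and the cohort generator.

The paired-click (conditioning/test) paradigm presents two identical auditory
clicks (S1, S2) separated by a short inter-stimulus interval, with a long gap
between pairs.  Sensory gating is quantified at electrode Cz as the ratio of
the P50 response amplitude to the second click over the first.

``GroupParams`` carries the marginal means/SDs (and binary prevalences) of
every covariate the cohort generator draws, separately for patients and
controls, together with per-variable truncation bounds and the Gaussian-copula
correlation structure used to couple the neuropsychological indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "ClickProtocol",
    "SubjectTruth",
    "VariableSpec",
    "GroupParams",
    "default_group_params",
    "COHORT_COLUMNS",
]


@dataclass(frozen=True)
class ClickProtocol:
    """Timing of a paired-click session.

    Parameters
    ----------
    sampling_rate : float
        EEG digitization rate in Hz.
    isi_ms : float
        Interval between the two clicks of a pair (S1 -> S2), in ms.
    inter_pair_s : tuple of float
        Uniform range (low, high) of the interval between pair onsets, seconds.
    click_duration_ms : float
        Duration of each click, ms (metadata; clicks are modelled by their
        evoked response, not their acoustic waveform).
    n_pairs : int
        Number of click pairs in the session.
    level_db : float
        Nominal click intensity in dB (metadata only).
    """

    sampling_rate: float = 1000.0
    isi_ms: float = 500.0
    inter_pair_s: tuple[float, float] = (8.0, 12.0)
    click_duration_ms: float = 1.0
    n_pairs: int = 120
    level_db: float = 85.0

    def __post_init__(self) -> None:
        if self.isi_ms <= 0:
            raise ConfigurationError("isi_ms must be positive")
        lo, hi = self.inter_pair_s
        if not (0 < lo <= hi):
            raise ConfigurationError("inter_pair_s must satisfy 0 < low <= high")
        if lo <= self.isi_ms / 1000.0:
            raise ConfigurationError(
                "inter-pair interval must exceed the within-pair ISI"
            )
        if self.n_pairs < 1:
            raise ConfigurationError("n_pairs must be >= 1")
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be positive")


@dataclass(frozen=True)
class SubjectTruth:
    """Ground-truth generative parameters for one simulated subject."""

    group: str = "control"
    true_s1_amp: float = 2.3
    true_s2_amp: float = 0.8
    true_s1_latency: float = 60.0
    noise_sd: float = 5.0
    blink_rate: float = 2.0  # events / minute on the EOG channel
    artifact_rate: float = 0.0  # high-amplitude segments / minute
    eog_bleed: float = 0.2  # fraction of EOG amplitude contaminating Cz

    def __post_init__(self) -> None:
        if self.group not in ("patient", "control"):
            raise ConfigurationError("group must be 'patient' or 'control'")
        if self.true_s1_amp < 0 or self.true_s2_amp < 0:
            raise ConfigurationError("amplitudes must be >= 0")
        if not (45.0 <= self.true_s1_latency <= 75.0):
            raise ConfigurationError("true_s1_latency must lie in [45, 75] ms")
        if min(self.noise_sd, self.blink_rate, self.artifact_rate) < 0:
            raise ConfigurationError("noise/blink/artifact rates must be >= 0")


@dataclass(frozen=True)
class VariableSpec:
    """Marginal target for one continuous cohort covariate in one group."""

    mean: float
    sd: float
    lower: float = -np.inf
    upper: float = np.inf

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ConfigurationError("sd must be >= 0")
        if not self.lower < self.upper:
            raise ConfigurationError("lower bound must be < upper bound")


# Order of columns in the interchange cohort CSV.
COHORT_COLUMNS = [
    "group", "age", "sex", "education_years", "smoker", "ppd",
    "s1_latency_ms", "s1_uv", "s2_uv", "diff_uv", "ratio",
    "cpt_d", "cpt_md",
    "wcst_pe", "wcst_cat", "wcst_t1c", "wcst_clr",
    "arithmetic", "digit_span", "information", "digit_symbol", "block_design",
    "wmi", "viq", "piq", "fiq",
]

# Continuous covariates drawn through the Gaussian copula, in a fixed order.
CONTINUOUS_VARS = [
    "age", "education_years",
    "s1_latency_ms", "s1_uv", "s2_uv", "diff_uv", "ratio",
    "cpt_d", "cpt_md",
    "wcst_pe", "wcst_cat", "wcst_t1c", "wcst_clr",
    "arithmetic", "digit_span", "information", "digit_symbol", "block_design",
    "wmi", "viq", "piq", "fiq",
]

CPT_VARS = ["cpt_d", "cpt_md"]
WAIS_VARS = [
    "arithmetic", "digit_span", "information", "digit_symbol", "block_design",
    "wmi", "viq", "piq", "fiq",
]


@dataclass(frozen=True)
class GroupParams:
    """Per-group marginal targets plus the copula correlation structure.

    ``variables`` maps group name -> {covariate -> VariableSpec}.
    ``smoking_prevalence`` / ``male_fraction`` are per-group Bernoulli rates;
    ``ppd`` targets are the *overall* (zeros included) mean/SD of packs per
    day, from which the generator derives a conditional distribution among
    smokers.
    """

    variables: dict = field(default_factory=dict)
    smoking_prevalence: dict = field(default_factory=dict)
    male_fraction: dict = field(default_factory=dict)
    ppd_overall: dict = field(default_factory=dict)  # group -> (mean, sd)
    rho_wais: float = 0.6
    rho_cpt_wais: float = 0.3

    def __post_init__(self) -> None:
        for rho in (self.rho_wais, self.rho_cpt_wais):
            if not -1.0 <= rho <= 1.0:
                raise ConfigurationError("correlations must lie in [-1, 1]")
        for group, prev in self.smoking_prevalence.items():
            if not 0.0 <= prev <= 1.0:
                raise ConfigurationError(f"smoking prevalence for {group} not in [0,1]")
        for group, frac in self.male_fraction.items():
            if not 0.0 <= frac <= 1.0:
                raise ConfigurationError(f"male fraction for {group} not in [0,1]")
        # the copula correlation matrix must be positive semidefinite
        R = self.correlation_matrix()
        if np.linalg.eigvalsh(R).min() < -1e-10:
            raise ConfigurationError(
                "copula correlation matrix is not positive semidefinite"
            )

    def correlation_matrix(self) -> np.ndarray:
        """Copula correlation over CONTINUOUS_VARS (identity off the
        CPT/WAIS blocks)."""
        k = len(CONTINUOUS_VARS)
        idx = {v: i for i, v in enumerate(CONTINUOUS_VARS)}
        R = np.eye(k)
        for i, a in enumerate(WAIS_VARS):
            for b in WAIS_VARS[i + 1:]:
                R[idx[a], idx[b]] = R[idx[b], idx[a]] = self.rho_wais
        for a in CPT_VARS:
            for b in WAIS_VARS:
                R[idx[a], idx[b]] = R[idx[b], idx[a]] = self.rho_cpt_wais
        return R

    def with_zero_sds(self) -> "GroupParams":
        """Degenerate copy with every marginal SD set to 0 (testing aid)."""
        new_vars = {
            g: {v: replace(s, sd=0.0) for v, s in group_vars.items()}
            for g, group_vars in self.variables.items()
        }
        return replace(self, variables=new_vars)


def default_group_params() -> GroupParams:
    """Group marginals calibrated to the published case–control cohort
    (106 schizophrenia outpatients, 74 healthy controls).

    Truncation bounds: gating ratio in [0, 2] (methodological cap), S1
    latency in the [45, 75] ms scoring window, amplitudes and WAIS scores
    positive, z-scored indices unbounded, age within the 18–65 recruitment
    range.
    """

    def v(cm, cs, pm, ps, lo=-np.inf, hi=np.inf):
        return {
            "control": VariableSpec(cm, cs, lo, hi),
            "patient": VariableSpec(pm, ps, lo, hi),
        }

    tbl = {
        "age": v(36.2, 11.5, 37.2, 10.0, 18.0, 65.0),
        "education_years": v(15.3, 3.6, 13.8, 2.7, 0.0, np.inf),
        "s1_latency_ms": v(60.62, 7.06, 60.94, 8.74, 45.0, 75.0),
        "s1_uv": v(2.29, 0.87, 2.38, 1.17, 0.0, np.inf),
        "s2_uv": v(0.79, 0.65, 1.10, 0.93, 0.0, np.inf),
        "diff_uv": v(1.50, 0.98, 1.28, 1.17),
        "ratio": v(0.37, 0.37, 0.52, 0.46, 0.0, 2.0),
        "cpt_d": v(-0.03, 1.07, -0.71, 1.21),
        "cpt_md": v(0.00, 0.95, -0.91, 1.36),
        "wcst_pe": v(-0.16, 0.93, 0.75, 1.44),
        "wcst_cat": v(0.41, 1.02, -0.48, 1.09),
        "wcst_t1c": v(0.06, 0.92, 0.46, 1.19),
        "wcst_clr": v(0.30, 1.02, -0.57, 1.18),
        "arithmetic": v(12.06, 3.11, 8.38, 3.30, 0.0, np.inf),
        "digit_span": v(12.40, 3.18, 9.90, 4.22, 0.0, np.inf),
        "information": v(12.03, 2.94, 10.26, 3.27, 0.0, np.inf),
        # the patient SDs for digit_symbol (12.06) and block_design (6.40)
        # are used as printed even though they are large relative to controls
        "digit_symbol": v(11.91, 2.95, 9.96, 12.06, 0.0, np.inf),
        "block_design": v(11.99, 2.81, 9.93, 6.40, 0.0, np.inf),
        "wmi": v(112.5, 15.34, 93.14, 17.66, 0.0, np.inf),
        "viq": v(113.0, 16.28, 95.74, 16.76, 0.0, np.inf),
        "piq": v(113.5, 16.53, 90.58, 18.05, 0.0, np.inf),
        "fiq": v(114.1, 15.64, 93.21, 16.15, 0.0, np.inf),
    }
    variables = {
        "control": {k: specs["control"] for k, specs in tbl.items()},
        "patient": {k: specs["patient"] for k, specs in tbl.items()},
    }
    return GroupParams(
        variables=variables,
        smoking_prevalence={"control": 5 / 74, "patient": 18 / 106},
        male_fraction={"control": 31 / 74, "patient": 52 / 106},
        ppd_overall={"control": (0.05, 0.21), "patient": (0.16, 0.40)},
    )
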