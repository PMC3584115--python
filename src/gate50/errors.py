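"""Exception hierarchy shared across the pipeline stages."""


class Gate50Error(Exception):
    """Base class for all package errors."""


class ConfigurationError(Gate50Error):
    """A parameter or configuration value is outside its documented domain."""


class FormatError(Gate50Error):
    """An input file could not be parsed or is missing required content."""


class PipelineError(Gate50Error):
    """A preprocessing stage cannot proceed (e.g. no usable trials)."""


class MeasurementError(Gate50Error):
    """Peak scoring failed (e.g. search window outside the waveform)."""


class ScoringError(Gate50Error):
    """Model scoring failed, e.g. a covariate named by the model is absent."""


class SeparationError(Gate50Error):
    """Logistic likelihood is monotone (complete/quasi-complete separation)."""


class SingularDesignError(Gate50Error):
    """Design matrix is rank deficient; names the collinear terms."""

    def __init__(self, terms):
        self.terms = list(terms)
        super().__init__(f"singular design; collinear terms: {', '.join(self.terms)}")


class NoCutoffError(Gate50Error):
    """LOESS risk curve never crosses the prevalence line; carries the curve."""

    def __init__(self, curve):
        self.curve = curve
        super().__init__("no_cutoff_found")


class DegenerateLabelsError(Gate50Error):
    """Concordance requires at least one case and one control."""


class UnstableBootstrapError(Gate50Error):
    """Too many bootstrap replicates had to be redrawn."""
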