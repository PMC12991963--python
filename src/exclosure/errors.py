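"""Exception hierarchy for the exclosure package."""


class ExclosureError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(ExclosureError):
    """Invalid simulation or pipeline configuration; message names the field."""


class SurveyValidationError(ExclosureError):
    """A survey table violates the long-format schema.

    Carries a ``report`` attribute: list of human-readable problem strings,
    each referencing offending row numbers or labels where applicable.
    """

    def __init__(self, report):
        if isinstance(report, str):
            report = [report]
        self.report = list(report)
        super().__init__("; ".join(self.report))


class UndefinedDissimilarityError(ExclosureError):
    """Dissimilarity requested between communities that are all empty."""


class InsufficientPlotsError(ExclosureError):
    """Fewer than two usable (non-empty) plots in a multiple-site computation."""

    def __init__(self, message, site=None, month=None, treatment=None):
        self.site = site
        self.month = month
        self.treatment = treatment
        super().__init__(message)


class JackknifeError(ExclosureError):
    """Leave-one-out resampling failed (too few plots, or statistic failure)."""


class ModelError(ExclosureError):
    """A trend model cannot be specified on the data provided."""
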