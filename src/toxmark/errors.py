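"""Exception hierarchy shared across the pipeline."""


class ToxmarkError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ToxmarkError, ValueError):
    """A file does not conform to its declared tabular format."""


class ValidationError(ToxmarkError, ValueError):
    """A domain-type invariant is violated."""


class LookupError_(ToxmarkError, KeyError):
    """A referenced identifier (sample, symptom, gene) does not exist."""


class DegenerateLabelsError(ToxmarkError, ValueError):
    """Fewer usable label groups than the statistic requires."""


class DegenerateDatasetError(ToxmarkError, ValueError):
    """A dataset is unusable for modelling (e.g. no case samples)."""


class FeatureMismatchError(ToxmarkError, KeyError):
    """A required marker gene is absent from the query expression matrix."""


class UndefinedMetricError(ToxmarkError, ValueError):
    """A metric has no defined value for the given inputs."""


class ConfigError(ToxmarkError, ValueError):
    """A run configuration is invalid or incomplete."""
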