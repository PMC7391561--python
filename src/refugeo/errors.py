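"""Exception types shared across the package."""


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class UndefinedIndexError(ValueError):
    """A genetic index is undefined for the given sample (e.g. n < 2)."""


class GridError(ValueError):
    """Invalid analysis-grid geometry."""


class SeparationWarning(UserWarning):
    """Perfect or quasi-perfect separation detected in a binomial GLM."""
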