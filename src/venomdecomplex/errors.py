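"""Exception hierarchy for the decomplexing-venomics pipeline.

Every reader/stage error derives from :class:`VenomdecomplexError` so callers
can catch pipeline failures without masking programming errors.
"""


class VenomdecomplexError(Exception):
    """Base class for all pipeline errors."""


class MalformedTrace(VenomdecomplexError):
    """Chromatogram input violates a trace invariant (non-monotone time, <2 rows)."""


class MalformedRecord(VenomdecomplexError):
    """A PSM/ELISA row violates a field invariant; message carries the row number."""


class SchemaError(VenomdecomplexError):
    """An input table is missing required columns or is empty."""


class VocabularyError(VenomdecomplexError):
    """A family label is outside the controlled toxin-family vocabulary."""


class NoSignal(VenomdecomplexError):
    """Chromatogram has zero total integrated area over the collected fractions."""


class BoundsError(VenomdecomplexError):
    """A fraction boundary lies outside the chromatogram time range."""


class FdrUnattainable(VenomdecomplexError):
    """No peptide-score cutoff achieves the requested FDR."""


class EmptyFraction(VenomdecomplexError):
    """A fraction has zero total spectral intensity."""


class MissingShare(VenomdecomplexError):
    """A fraction with identified PSMs has no chromatographic share."""


class UnassignedFraction(VenomdecomplexError):
    """A fraction carries a share but has neither PSMs nor an 'unidentified' flag."""


class NoBlank(VenomdecomplexError):
    """ELISA plate contains no blank well."""


class ContractViolation(VenomdecomplexError):
    """A value violates a documented pre-condition (e.g. negative corrected absorbance)."""


class AlignmentError(VenomdecomplexError):
    """Two immunoprofiles do not cover the same fraction set."""


class ConfigError(VenomdecomplexError):
    """Pipeline configuration is missing a required key or names a bad mode."""
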