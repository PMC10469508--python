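"""Exception hierarchy for mrkit.

Every fatal condition in the pipeline maps to one subclass so callers can
distinguish configuration mistakes from data problems (empty inputs, no
instrument overlap, all SNPs removed during harmonization, ...).
"""


class MrKitError(Exception):
    """Base class for all mrkit errors."""


class ConfigurationError(MrKitError):
    """Invalid option value or missing mapped column."""


class EmptyInputError(MrKitError):
    """A summary-statistics file yielded zero valid rows."""


class NoOverlapError(MrKitError):
    """Exposure and outcome tables share no rsids."""


class NoInstrumentsError(MrKitError):
    """Instrument selection retained zero SNPs for an exposure."""


class InsufficientInstrumentsError(MrKitError):
    """An estimator or diagnostic needs more SNPs than are available."""


class HarmonizationEmptiedError(MrKitError):
    """Harmonization dropped every SNP pair."""


class NoDataError(MrKitError):
    """An estimator was handed an empty harmonized set."""


class UndefinedRatioError(MrKitError):
    """Wald ratio requested for a SNP with zero exposure effect."""


class StrengthUnavailableError(MrKitError):
    """Instrument strength cannot be computed (missing allele frequency)."""
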