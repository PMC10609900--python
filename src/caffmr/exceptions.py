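"""Exception hierarchy for the caffmr pipeline."""


class CaffMRError(Exception):
    """Base class for all caffmr errors."""


class ValidationError(CaffMRError):
    """A record or configuration violates a domain invariant."""


class ConfigurationError(CaffMRError):
    """A file, column map, or option is malformed or missing."""


class HarmonizationError(CaffMRError):
    """Exposure/outcome records cannot be combined (e.g. rsid mismatch)."""


class NoInstrumentsError(CaffMRError):
    """Instrument selection or harmonization left zero usable variants."""


class UndefinedRatioError(CaffMRError):
    """Wald ratio undefined because the variant-exposure effect is zero."""


class AmbiguousLocusError(CaffMRError):
    """A variant falls inside two overlapping gene-region windows."""


class WeakInstrumentWarning(UserWarning):
    """Variant-exposure association too weak for a stable ratio estimate."""
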