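"""Exception hierarchy for lncsurv."""


class LncsurvError(Exception):
    """Base class for all lncsurv errors."""


class ConfigurationError(LncsurvError):
    """An invalid configuration value (violated invariant, unknown schedule, ...)."""


class InputError(LncsurvError):
    """Malformed or inconsistent input data (tables, clinical records, ...)."""


class EvaluationError(LncsurvError):
    """An evaluation procedure cannot be carried out (single-class labels, ...)."""


class DegenerateRangeError(LncsurvError):
    """A variation range is empty after intersection with the index domain."""
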