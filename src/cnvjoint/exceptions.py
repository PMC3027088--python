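"""Exception hierarchy for cnvjoint."""


class CnvJointError(ValueError):
    """Base class for all cnvjoint errors."""


class FormatError(CnvJointError):
    """A file violates the documented on-disk format."""


class ValidationError(CnvJointError):
    """In-memory data violate a domain invariant."""


class FitError(CnvJointError):
    """A model fit cannot proceed (rank deficiency, bad domain, ...)."""
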