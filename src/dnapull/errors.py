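"""Exception hierarchy.

All errors raised deliberately by the toolkit derive from :class:`DnapullError`
so that callers (and the CLI) can distinguish data problems from bugs.
"""


class DnapullError(Exception):
    """Base class for all toolkit errors."""


class StructureError(DnapullError):
    """Malformed or inconsistent structure/trajectory input."""


class ContactMapError(DnapullError):
    """Invalid contact-map specification or evaluation request."""


class SteeringError(DnapullError):
    """Invalid steering schedule, CV series or start-frame request."""


class AnalysisError(DnapullError):
    """Invalid work-curve ensemble or estimator request."""


class ToySimError(DnapullError):
    """Toy-simulator instability or invalid parameters."""
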