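"""Exception hierarchy."""


class FframError(Exception):
    """Base class for all package errors."""


class TreeFormatError(FframError):
    """A geometry file does not conform to the CTREE-JSON dialect."""


class TreeValidationError(FframError):
    """A tree or branch violates a structural invariant."""


class TreeLookupError(FframError, LookupError):
    """A branch id or location cannot be resolved on the tree."""


class OccludedBranchError(FframError):
    """Flow or pressure was requested through a fully occluded branch."""


class LesionError(FframError):
    """Lesion detection or parameterization failed on the given extent."""
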