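"""Exception hierarchy shared across the package."""


class HippofuseError(Exception):
    """Base class for all package errors."""


class FormatError(HippofuseError, ValueError):
    """A file or header violates the expected on-disk format."""


class DomainError(HippofuseError, ValueError):
    """Inputs are structurally valid but outside an operation's domain
    (disjoint extents, empty prior, mismatched grids, ...)."""


class ValidationError(HippofuseError, ValueError):
    """A configuration or specification object violates its invariants."""


class PipelineError(HippofuseError, RuntimeError):
    """An unrecoverable failure inside the segmentation pipeline
    (e.g. fewer surviving templates than the fusion rank requires)."""
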