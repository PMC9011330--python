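"""Exception types shared across the package.

The CLI maps :class:`ValidationError` (and subclasses) to exit code 2 and any
other failure to exit code 3.
"""


class ValidationError(ValueError):
    """Invalid user input: bad shapes, unknown names, out-of-range parameters."""


class ConflictError(RuntimeError):
    """An on-disk resource already exists and overwrite was not requested."""


class CapacityError(RuntimeError):
    """A phantom specification cannot be satisfied (object placement failed)."""
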