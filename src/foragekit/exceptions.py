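"""Exception hierarchy for foragekit."""


class ForagingError(Exception):
    """Base class for all foragekit errors."""


class InvalidArgumentError(ForagingError, ValueError):
    """An argument is outside its documented domain."""


class DegenerateGeometryError(InvalidArgumentError):
    """Coincident positions make a direction of travel undefined."""


class EmptyChoiceSetError(InvalidArgumentError):
    """A selection step was requested with no remaining items."""


class SequenceMismatchError(InvalidArgumentError):
    """A selection sequence is inconsistent with its display."""


class InsufficientDataError(ForagingError, ValueError):
    """Not enough observations to fit or split."""


class NonConvergenceError(ForagingError, RuntimeError):
    """All optimizer starts failed."""


class DegenerateComponentError(ForagingError, RuntimeError):
    """A mixture component lost all responsibility mass."""


class NotFittedError(ForagingError, RuntimeError):
    """A model was used before fitting."""


class PackingInfeasibleError(ForagingError, RuntimeError):
    """Display placement failed under the minimum-spacing constraint."""


class DatasetValidationError(ForagingError, ValueError):
    """A tidy foraging table violated the schema."""
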