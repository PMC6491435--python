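"""Exception hierarchy shared across the pipeline stages."""


class SeqmateError(Exception):
    """Base class for all package errors."""


class ParameterError(SeqmateError, ValueError):
    """An argument violates a documented precondition."""


class DepthError(SeqmateError, ValueError):
    """A subsampling target exceeds the available read depth."""


class IntegrityError(SeqmateError, ValueError):
    """Inputs that should agree (ids, schemas, state flags) do not."""


class DesignError(SeqmateError, ValueError):
    """The sample design is unusable (missing groups or replicates)."""


class UndefinedStatisticError(SeqmateError, ValueError):
    """A mating statistic is undefined on the given table.

    Carries ``cell`` naming the offending coefficient cell when applicable.
    """

    def __init__(self, message: str, cell=None):
        super().__init__(message)
        self.cell = cell


class UnstableStatisticError(SeqmateError, RuntimeError):
    """Too many bootstrap resamples left the statistic undefined."""
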