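"""Exception hierarchy for modgen.

Every failure mode raised by the library derives from :class:`ModgenError`
so callers (and the CLI) can distinguish bad input from bad luck.
"""


class ModgenError(Exception):
    """Base class for all modgen errors."""


class InputError(ModgenError, ValueError):
    """Malformed or inconsistent user input (bad partition, bad sequence, ...)."""


class FeasibilityError(InputError):
    """A requested specification is provably unachievable (e.g. Q >= Q_max)."""


class SamplingError(ModgenError, RuntimeError):
    """A rejection-sampling loop exhausted its attempt budget.

    The message names the condition that kept failing.
    """


class WiringError(ModgenError, RuntimeError):
    """Edge construction stalled and could not be completed after restarts."""


class GenerationError(ModgenError, RuntimeError):
    """The full generation pipeline exhausted its retry budget.

    Carries diagnostics about the last failing stage.
    """

    def __init__(self, message, *, last_q=None, stage=None):
        super().__init__(message)
        self.last_q = last_q
        self.stage = stage
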