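"""Exception hierarchy for stepcmh."""


class StepCMHError(Exception):
    """Base class for all stepcmh errors."""


class ValidationError(StepCMHError, ValueError):
    """Invalid input data (bad genotype codes, malformed tables, ...)."""


class EmptyStratumError(StepCMHError, ValueError):
    """A stratum slice with zero total was passed where counts are required."""


class DegenerateStratumError(StepCMHError, ValueError):
    """A stratum with fewer than two subjects; its variance is undefined."""


class UntestableError(StepCMHError, ValueError):
    """No stratum carries information: the CMH statistic cannot be formed."""


class ParseError(StepCMHError, ValueError):
    """A genotype/phenotype file could not be parsed."""
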