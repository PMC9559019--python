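"""Exception types shared across the pipeline."""


class HidmedError(Exception):
    """Base class for all package-specific errors."""


class RankDeficiencyError(HidmedError):
    """A regression design matrix is singular (e.g. more SNPs than samples)."""


class DegenerateFitError(HidmedError):
    """An EM run collapsed (component variance below the floor) in every attempt."""


class IllPosedError(HidmedError):
    """The posterior for b_H is unidentifiable (mu_a = 0)."""


class ParseError(HidmedError):
    """A dosage or phenotype file could not be parsed; message names the position."""
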