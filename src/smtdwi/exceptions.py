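"""Exception hierarchy used across the package.

The CLI maps these onto distinct process exit codes, so computational code
should raise the most specific class that applies.
"""


class SMTError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SMTError):
    """Malformed or inconsistent input files (NIfTI / bval / bvec)."""


class EstimationError(SMTError):
    """The estimation problem is ill-posed or failed everywhere."""


class SimulationError(SMTError):
    """A simulation sanity check failed (e.g. quadrature normalization)."""
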