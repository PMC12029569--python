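"""Exception hierarchy shared across the pipeline.

The CLI maps these onto exit codes (input problems -> 2, fit failures -> 3)
so shell pipelines can branch on what went wrong.
"""


class G4ProbeError(Exception):
    """Base class for all g4probe errors."""


class InputError(G4ProbeError):
    """Malformed or inconsistent user input (sequences, files, configs)."""


class FitError(G4ProbeError):
    """A nonlinear fit failed to converge or its input admits no fit."""
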