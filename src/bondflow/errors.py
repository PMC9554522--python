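"""Exception types shared across the package."""


class BondflowError(Exception):
    """Base class for package errors."""


class ModelValidationError(BondflowError):
    """A model document or assembled network failed validation."""


class SimulationError(BondflowError):
    """The integrator failed or produced an inadmissible trajectory."""
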