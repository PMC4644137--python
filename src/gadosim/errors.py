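"""Exception hierarchy for gadosim."""


class GadosimError(Exception):
    """Base class for all gadosim errors."""


class InvalidParameterError(GadosimError, ValueError):
    """A model parameter violates its physical constraints."""


class InfeasibleCalibrationError(GadosimError, ValueError):
    """The requested macro constants admit no positive micro solution."""


class GridError(GadosimError, ValueError):
    """A time grid is non-monotone, mismatched, or a query lies outside it."""


class FitError(GadosimError, RuntimeError):
    """A regression / nonlinear fit failed or is degenerate."""


class ConfigError(GadosimError, ValueError):
    """A study configuration file is malformed or contains unknown keys."""


class ParseError(GadosimError, ValueError):
    """A tabular input file does not match the documented dialect."""
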