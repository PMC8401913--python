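"""Exception hierarchy shared across the pipeline."""


class PKQuantError(Exception):
    """Base class for all pkquant errors."""


class ConfigurationError(PKQuantError):
    """Invalid configuration value or combination."""


class InsufficientDataError(PKQuantError):
    """Too few points/replicates for the requested computation."""


class WindowError(PKQuantError):
    """Integration or noise window outside the trace, or degenerate."""


class ZeroNoiseError(PKQuantError):
    """Noise estimate below the configured floor; S/N undefined."""


class NoLLOQError(PKQuantError):
    """No standard reached the signal-to-noise threshold."""


class NoEliminationPhaseError(PKQuantError):
    """Terminal regression produced a non-negative slope."""


class NotApplicableError(PKQuantError):
    """Operation does not apply to this route or input."""


class UndefinedStatisticError(PKQuantError):
    """Statistic undefined for the given input (e.g. zero mean CV)."""
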