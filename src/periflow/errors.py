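"""Exception hierarchy shared across the package."""


class PeriflowError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(PeriflowError):
    """Invalid or self-intersecting implant/domain geometry."""


class ResolutionError(PeriflowError):
    """Grid or sample spacing too coarse for the requested feature scale."""


class ConfigError(PeriflowError):
    """Invalid, unknown, or physically inadmissible configuration value."""


class ZoneError(PeriflowError):
    """Zone assignment or zone reduction applied to inconsistent inputs."""


class SolverError(PeriflowError):
    """Flow or transport solver failure (carries diagnostics in args)."""


class BenchmarkError(PeriflowError):
    """Unknown benchmark case or benchmark harness misuse."""
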