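"""Exception hierarchy.

Every error raised by the package derives from :class:`ScenithError` so callers
(and the CLI) can distinguish configuration problems (exit code 2) from data
problems (exit code 3).
"""


class ScenithError(Exception):
    """Base class for all package errors."""


class ConfigError(ScenithError):
    """Invalid configuration: bad schema, unknown keys, unresolvable references."""


class FormatError(ScenithError):
    """Unreadable or unsupported input file format."""


class ValidationError(ScenithError):
    """Structurally invalid data (duplicate channels, empty tables, ...)."""


class DemuxError(ScenithError):
    """Barcode demultiplexing failed (no hi/lo structure, starved condition, ...)."""


class MetricError(ScenithError):
    """MFI / dependence-metric computation failed (too few events, bad inputs)."""


class LowResolutionError(MetricError):
    """The assay's dynamic range collapsed: MFI(control) − MFI(double inhibition) ≤ 0.

    The dependence formulas divide by this difference; when translation under
    full ATP-synthesis block is as high as under control, the denominator
    vanishes and the profile is undefined.  We report, never divide.
    """


class StatsError(ScenithError):
    """Statistical procedure preconditions violated (too few pairs, missing cells)."""
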