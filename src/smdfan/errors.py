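"""Exception hierarchy with stable process exit codes for the CLI."""


class SmdFanError(Exception):
    """Base class for all toolkit errors."""

    exit_code = 1


class InputError(SmdFanError):
    """Missing files, empty selections, out-of-range indices."""

    exit_code = 2


class FormatError(SmdFanError):
    """Malformed PDB / log / xvg content."""

    exit_code = 3


class ConfigurationError(SmdFanError):
    """Invalid plan parameters, angle grids, or group definitions."""

    exit_code = 4


class SelectionError(SmdFanError):
    """Selection grammar or resolution failures."""

    exit_code = 5


class DegenerateAxisError(SmdFanError):
    """Fixed and pulled centers of mass coincide (no pulling axis)."""

    exit_code = 6


class StabilityError(SmdFanError):
    """Toy integrator produced non-finite coordinates."""

    exit_code = 7


class AlignmentError(SmdFanError):
    """Series that must be paired 1:1 have different lengths or no overlap."""

    exit_code = 8
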