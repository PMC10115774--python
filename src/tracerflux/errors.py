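"""Exception hierarchy for tracerflux.

All library errors derive from :class:`TracerFluxError` so callers can catch
one base class; QC conditions that are recoverable are reported as row flags
in output tables instead of exceptions (see the lab and field modules).
"""


class TracerFluxError(Exception):
    """Base class for all tracerflux errors."""


class InvalidCompositionError(TracerFluxError, ValueError):
    """An isotope composition outside its physical domain (delta <= -1000 permil
    or atom fraction outside [0, 1))."""


class UndefinedMixtureError(TracerFluxError, ValueError):
    """A mass-weighted mixture with zero total mass."""


class EndMemberSeparationError(TracerFluxError, ValueError):
    """Two-source end members closer than the configured separation threshold;
    the source fraction is unidentifiable."""


class PairingError(TracerFluxError, ValueError):
    """A treatment jar has no paired measurement (e.g. no control jar and no
    site-level fallback)."""


class SchemaError(TracerFluxError, ValueError):
    """An input table is missing required columns or contains invalid values.

    Carries the offending file, column, and (1-based data) row when known.
    """

    def __init__(self, message, *, path=None, column=None, row=None):
        detail = message
        loc = []
        if path is not None:
            loc.append(f"file={path}")
        if column is not None:
            loc.append(f"column={column}")
        if row is not None:
            loc.append(f"row={row}")
        if loc:
            detail = f"{message} ({', '.join(loc)})"
        super().__init__(detail)
        self.path = path
        self.column = column
        self.row = row


class InsufficientDataError(TracerFluxError, ValueError):
    """Too few observations for a statistical operation."""


class ReferenceUnavailableError(TracerFluxError, ValueError):
    """No unlabeled reference bag retrieved at a site."""


class SimulationConfigError(TracerFluxError, ValueError):
    """A simulator configuration that produces unphysical state (e.g. negative
    remaining pool masses)."""
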