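"""Exception hierarchy for the nanobody profiler.

Exit-code mapping used by the CLI: :class:`InputError` subclasses map to
exit code 2, :class:`ConfigurationError` to 3.
"""


class TnpError(Exception):
    """Base class for all profiler errors."""


class InputError(TnpError):
    """A problem with user-supplied input (structure, reference, value)."""


class ParseError(InputError):
    """Unreadable or malformed structure file."""


class AmbiguityError(ParseError):
    """More than one polypeptide chain in the input file."""


class EmptyStructureError(ParseError):
    """No polymer residues found in the input file."""


class AnchorError(InputError):
    """A CDR3 anchor residue (IMGT 104 or 118) or its CA atom is missing."""


class EmptyLoopError(InputError):
    """CDR3 span contains no residues."""


class AngleError(InputError):
    """A CA atom required for the kink pseudo-angles is missing."""


class SuperpositionError(InputError):
    """Too few shared framework CA atoms for a least-squares superposition."""


class PairingError(InputError):
    """Bound/unbound structures share no CDR3 residues."""


class GeometryError(InputError):
    """Degenerate geometry (e.g. coincident atoms at zero distance)."""


class CalibrationError(InputError):
    """Reference set too small or unusable for calibration."""


class InfeasibleSpecError(InputError):
    """A fixture specification that no chain geometry can satisfy."""


class ConfigurationError(TnpError):
    """Missing or inconsistent configuration (e.g. reference lacks a metric)."""
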