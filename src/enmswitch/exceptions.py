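"""Exception hierarchy shared across the package.

Input/contract problems and numerical failures are kept distinct so the
command-line layer can map them to different exit codes.
"""


class EnmSwitchError(Exception):
    """Base class for all errors raised by enmswitch."""


class InputError(EnmSwitchError):
    """A file, selection or configuration value is unusable."""


class PDBParseError(InputError):
    """A structure file could not be reduced to C-alpha conformers."""


class EmptySelectionError(InputError):
    """A chain or region filter matched nothing."""


class ContractError(EnmSwitchError):
    """Arguments violate a documented precondition."""


class NumericalError(EnmSwitchError):
    """A numerical step failed (singular normalization, bad decomposition)."""


class DisconnectedStructureError(NumericalError):
    """The contact graph has more than one component where one is required."""
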