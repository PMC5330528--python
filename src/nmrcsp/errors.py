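"""Exception hierarchy for the pipeline."""


class NmrCspError(Exception):
    """Base class for all package errors."""


class CifParseError(NmrCspError):
    """A CIF document is missing required items or is malformed."""


class SymmetryError(NmrCspError):
    """A symmetry operator string could not be parsed."""


class DisorderError(NmrCspError):
    """A structure contains partial occupancies; only ordered structures are handled."""


class TopologyError(NmrCspError):
    """Bond perception or molecule/methyl identification failed."""


class TrajectoryError(NmrCspError):
    """Frames are inconsistent (atom counts, ordering) or unreadable."""


class ShiftDataError(NmrCspError):
    """Shielding/shift tables and assignments do not match up."""


class CampaignError(NmrCspError):
    """Synthetic campaign generation failed (collisions, bad config, existing output)."""
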