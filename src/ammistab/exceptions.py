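"""Exception hierarchy for ammistab."""


class AmmistabError(Exception):
    """Base class for all ammistab errors."""


class TrialFormatError(AmmistabError):
    """A trial file or table does not have the expected shape or types."""


class DuplicateRecordError(TrialFormatError):
    """The same (genotype, environment, block) plot appears more than once."""


class IncompleteTrialError(AmmistabError):
    """One or more genotype x environment cells have no observations."""

    def __init__(self, missing_pairs, message=None):
        self.missing_pairs = list(missing_pairs)
        if message is None:
            shown = ", ".join(f"({g}, {e})" for g, e in self.missing_pairs[:10])
            more = "" if len(self.missing_pairs) <= 10 else f" and {len(self.missing_pairs) - 10} more"
            message = f"missing genotype x environment cells: {shown}{more}"
        super().__init__(message)


class UnbalancedTrialError(AmmistabError):
    """Replicate counts differ between cells; a common r is required."""


class DesignError(AmmistabError):
    """The experimental design cannot support the requested partition."""


class DegenerateFitError(AmmistabError):
    """The AMMI fit lacks the interaction structure a statistic requires."""
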