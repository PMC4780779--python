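"""Exception hierarchy shared across the package."""


class NicheLimitsError(Exception):
    """Base class for all package errors."""


class ConfigurationError(NicheLimitsError):
    """Invalid or inconsistent run configuration (missing columns, files, variables)."""


class GridParseError(NicheLimitsError):
    """Malformed ESRI ASCII grid."""


class TreeError(NicheLimitsError):
    """Malformed newick input or structurally invalid phylogeny."""


class MonophylyError(TreeError):
    """A backbone clade's sampled members are not monophyletic in the source tree."""

    def __init__(self, clade_name: str, intruders):
        self.clade_name = clade_name
        self.intruders = sorted(intruders)
        super().__init__(
            f"clade {clade_name!r} is not monophyletic: "
            f"intruding taxa {', '.join(self.intruders)}"
        )


class SingularCovarianceError(NicheLimitsError):
    """The (transformed) phylogenetic covariance matrix is numerically singular."""


class ReconciliationError(NicheLimitsError):
    """Species sets of the climate summaries and the working phylogeny do not match."""
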