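"""Exception types shared across the package."""


class MdscError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MdscError, ValueError):
    """An invalid configuration value (probability vector, threshold, ...)."""


class CohortValidationError(MdscError, ValueError):
    """One or more cohort rows violate the data-model invariants.

    Parameters
    ----------
    problems : list of str
        One human-readable message per offending row, each naming the row.
    """

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__(
            "cohort validation failed:\n" + "\n".join(f"  - {p}" for p in self.problems)
        )
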