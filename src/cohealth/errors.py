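"""Exception hierarchy shared across the pipeline."""


class CohealthError(Exception):
    """Base class for all package errors."""


class InclusionRuleError(CohealthError):
    """An experiment violates the >6-samples inclusion rule."""


class ExperimentExcluded(CohealthError):
    """An experiment must be excluded from the meta-study (not a crash).

    Carries a machine-readable reason so the pipeline can emit an
    exclusion record instead of failing.
    """

    def __init__(self, reason: str, detail: str = ""):
        self.reason = reason
        self.detail = detail
        super().__init__(f"{reason}: {detail}" if detail else reason)


class ScoreCardError(CohealthError):
    """Scorecard refers to metadata that does not exist, or is malformed."""


class ConstantPhenotypeError(CohealthError):
    """All health phenotype scores are identical; correlation is undefined."""
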