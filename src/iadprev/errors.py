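"""Exception and warning types shared across the package."""


class IadPrevError(Exception):
    """Base class for all package-specific errors."""


class UnknownDrug(IadPrevError, LookupError):
    """Drug name absent from the formulary."""

    def __init__(self, drug_name, dose_mg=None):
        self.drug_name = drug_name
        self.dose_mg = dose_mg
        super().__init__(f"drug {drug_name!r} is not in the formulary")


class UnknownDose(IadPrevError, LookupError):
    """Drug is known but the dose has no formulary entry."""

    def __init__(self, drug_name, dose_mg):
        self.drug_name = drug_name
        self.dose_mg = dose_mg
        super().__init__(
            f"no formulary entry for {drug_name!r} at dose {dose_mg} mg"
        )


class UnclassifiedDrug(IadPrevError, ValueError):
    """ATC code outside the LHRH-analogue and antiandrogen families."""

    def __init__(self, atc_code, context=None):
        self.atc_code = atc_code
        self.context = context
        msg = f"ATC code {atc_code!r} is neither an LHRH analogue nor an antiandrogen"
        if context:
            msg += f" ({context})"
        super().__init__(msg)


class InvalidDuration(IadPrevError, ValueError):
    """Negative or otherwise impossible treatment duration."""


class SchemaError(IadPrevError, ValueError):
    """Dispensation file violates the expected schema.

    ``rows`` lists 1-based file line numbers of the offending rows (the
    header is line 1), or is empty for file-level problems such as a
    missing column.
    """

    def __init__(self, message, rows=()):
        self.rows = list(rows)
        if self.rows:
            message = f"{message} (lines {self.rows})"
        super().__init__(message)


class InfeasibleSimulation(IadPrevError, ValueError):
    """Simulation configuration cannot produce a valid cohort."""


class UndefinedPrevalence(IadPrevError, ZeroDivisionError):
    """Prevalence requested for a stratum with an empty denominator."""


class UndefinedPercent(IadPrevError, ZeroDivisionError):
    """Percentage of time off treatment with a zero-day denominator."""


class FirstYearExcluded(IadPrevError, ValueError):
    """Annual prevalence requested for the first observation year.

    The first calendar year of a dispensation window systematically
    understates intermittency: a patient already off treatment when the
    window opens cannot be recognised until a later gap.  The estimate is
    therefore refused unless explicitly overridden.
    """


class DegenerateTable(IadPrevError, ValueError):
    """Contingency table with a zero marginal or wrong shape."""


class InvalidCost(IadPrevError, ValueError):
    """Negative cost encountered in the input records."""

    def __init__(self, message, rows=()):
        self.rows = list(rows)
        super().__init__(message)


class IOFailure(IadPrevError, OSError):
    """Missing or unwritable file in a command-line run."""


class EmptyStratumWarning(UserWarning):
    """A requested stratum contains no data; the result is empty, not an error."""
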