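"""Exception hierarchy for input validation and degenerate statistics."""


class CCIError(ValueError):
    """Base class for all validation and computation errors in this package."""


class DimensionError(CCIError):
    """Matrix too small for the requested statistic (n < 2 or N < 3)."""


class DegenerateGeneError(CCIError):
    """A gene (row) has zero variance, so it cannot be standardized."""

    def __init__(self, genes, message=None):
        self.genes = list(genes)
        if message is None:
            shown = ", ".join(map(str, self.genes[:5]))
            more = "" if len(self.genes) <= 5 else f" (+{len(self.genes) - 5} more)"
            message = (
                f"constant (zero-variance) row(s) cannot be standardized: "
                f"{shown}{more}; drop them or pass on_constant='drop'"
            )
        super().__init__(message)


class UndefinedStatisticError(CCIError):
    """The statistic is undefined for this input (e.g. all-zero matrix, zero null spread)."""


class TableFormatError(CCIError):
    """A delimited input table or gene-set file failed to parse."""
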