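"""Exception hierarchy shared across the package."""


class MstScanError(Exception):
    """Base class for all package-specific errors."""


class DataError(MstScanError):
    """Malformed or inconsistent input data (fatal for the affected file)."""


class UntestableSNPError(MstScanError):
    """SNP monomorphic in the analysed samples (L = 1); scan skips it."""


class DegenerateTraitSetError(MstScanError):
    """Reduced-model SSCP matrix is singular (e.g. duplicated trait)."""


class CollinearityError(MstScanError):
    """Rank-deficient design matrix; names the offending column."""

    def __init__(self, column: str):
        self.column = column
        super().__init__(f"design matrix is rank deficient: column {column!r} "
                         f"is collinear with earlier columns")
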