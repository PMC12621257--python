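"""Exception hierarchy for benchkit."""


class BenchkitError(Exception):
    """Base class for all benchkit errors."""


class SpectrumParseError(BenchkitError):
    """A spectrum file could not be parsed (carries the offending line number)."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class InputError(BenchkitError):
    """Input data violates a precondition (too few points, bad values...)."""


class WindowError(BenchkitError):
    """Requested energy window lies outside the available data range."""


class DegenerateSpectrumError(BenchkitError):
    """A spectrum is identically zero and cannot be normalized or compared."""


class XYZFormatError(BenchkitError):
    """An XYZ file violates the count-line/atom-lines layout."""


class MetalAmbiguityError(BenchkitError):
    """Zero or multiple metal-centre candidates and no explicit override."""


class GridMismatchError(BenchkitError):
    """Two spectra are not defined on the identical energy grid."""


class CorrespondenceError(BenchkitError):
    """Atom sequences of two structures do not match index-by-index."""


class IllPosedSuperpositionError(BenchkitError):
    """Fewer than three non-collinear atoms; the optimal rotation is not unique."""


class BondDetectionError(BenchkitError):
    """No metal-ligand bonds found within the distance cutoff."""
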