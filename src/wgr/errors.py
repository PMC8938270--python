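"""Typed exceptions raised across the package."""


class WgrError(Exception):
    """Base class for all package errors."""


class FormatError(WgrError):
    """A file violates the documented dialect (malformed record, bad header...)."""


class MissingSampleError(FormatError):
    """A requested sample is absent from a VCF."""


class MapError(FormatError):
    """Genetic map violates monotonicity or coverage requirements."""


class UnidentifiableError(WgrError):
    """The requested inference is not identifiable from the given data
    (e.g. parental phasing from a single embryo)."""


class UninformativeChromosomeError(WgrError):
    """No site on the chromosome is heterozygous in either parent, so the
    transmitted haplotype cannot be inferred."""


class CoverageError(WgrError):
    """Too few genotyped sites to run a projection or comparison."""


class DegenerateInputError(WgrError):
    """Input is structurally valid but degenerate for the requested statistic
    (zero variance, empty mask, empty decile...)."""


class PhaseConflictWarning(UserWarning):
    """Scaffold and external phase disagree systematically (possible sample swap)."""
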