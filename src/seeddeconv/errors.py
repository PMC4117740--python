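"""Exception hierarchy for seeddeconv.

All package-specific errors derive from :class:`SeedDeconvError` so callers
can catch one base class at pipeline boundaries (the CLI maps these to
categorized exit messages).
"""


class SeedDeconvError(Exception):
    """Base class for all seeddeconv errors."""


class InvalidAlphabet(SeedDeconvError):
    """A sequence contains characters outside {A, C, G, U} after
    normalization — usually a malformed library file."""


class SequenceTooShort(SeedDeconvError):
    """An oligo sequence is too short to carry the requested seed window."""


class EmptyLibrary(SeedDeconvError):
    """No valid oligo records were supplied."""


class MissingColumn(SeedDeconvError):
    """A required column is absent from an input table."""


class EmptyTable(SeedDeconvError):
    """An input table has no usable rows."""


class DegenerateMAD(SeedDeconvError):
    """Median absolute deviation is zero — a constant batch cannot be
    converted to robust Z scores."""


class DegenerateSplit(SeedDeconvError):
    """A KS comparison was requested with an empty family or an empty
    complement."""


class NonFiniteInput(SeedDeconvError):
    """A numeric input contains NaN or infinity."""


class ConfigInvalid(SeedDeconvError):
    """A simulation configuration violates its invariants."""


class MissingTruth(SeedDeconvError):
    """A pool needed for evaluation has no retest truth annotation."""


class UnreadableFile(SeedDeconvError):
    """A file could not be parsed in any supported format."""
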