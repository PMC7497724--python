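"""Exception hierarchy for the converter."""


class Gen2VcfError(Exception):
    """Base class for all gen2vcf errors."""


class MalformedLine(Gen2VcfError):
    """A GEN data line that cannot be parsed under the active dialect.

    Carries the 1-based line number so pipeline errors are actionable.
    """

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class MalformedSampleFile(Gen2VcfError):
    """An Oxford .sample file missing its two header lines or with short rows."""


class DegenerateTriple(Gen2VcfError):
    """Renormalization requested for a triple whose sum is effectively zero."""


class DuplicateSampleId(Gen2VcfError):
    """Two samples would share the same VCF header column name."""


class UnresolvedChromosome(Gen2VcfError):
    """A record reached the VCF writer without a chromosome label."""


class UnsortedInput(Gen2VcfError):
    """Indexing was requested but records are not coordinate-sorted.

    The VCF file itself has been written in full when this is raised;
    only the index step is refused.
    """
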