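"""Run configuration and counters shared across the conversion pipeline."""

from dataclasses import dataclass, field


#: Tolerance on the [0, 1] probability bounds; IMPUTE prints 3-decimal
#: probabilities, so values such as 1.0000001 arise only from rounding noise.
PROB_EPS = 1e-6

ID_POLICIES = ("auto", "rsid", "varid")


@dataclass
class ConversionConfig:
    """Options controlling per-genotype computation and rendering.

    Parameters
    ----------
    precision
        Decimal places for GP and DS in the output (1-10). Default 3,
        matching the precision IMPUTE itself prints.
    gt_threshold
        Minimum posterior probability required to emit a hard call. With
        the default 0 a GT is always called; when the maximum probability
        falls below the threshold GT is "./." while GP and DS are kept.
    renormalize
        Divide each non-missing triple by its sum before computing GP/DS.
        Off by default: raw file values are passed through and the dosage
        is clamped into [0, 2] if rounding pushed it outside.
    missing_eps
        A triple whose components sum below this is a missing genotype
        (the GEN convention writes missing as "0 0 0").
    strict
        Strict mode rejects malformed lines and out-of-range probabilities;
        lenient mode clamps probabilities, skips bad lines, and counts both.
    id_policy
        VCF ID column source: "rsid", "varid", or "auto" (rsid unless it is
        "." or empty, then varid, then "chrom:pos_ref_alt").
    """

    precision: int = 3
    gt_threshold: float = 0.0
    renormalize: bool = False
    missing_eps: float = 1e-6
    strict: bool = True
    id_policy: str = "auto"

    def __post_init__(self) -> None:
        if not 1 <= self.precision <= 10:
            raise ValueError(f"precision must be in [1, 10], got {self.precision}")
        if not 0.0 <= self.gt_threshold <= 1.0:
            raise ValueError(
                f"gt_threshold must be in [0, 1], got {self.gt_threshold}"
            )
        if self.missing_eps <= 0:
            raise ValueError(f"missing_eps must be > 0, got {self.missing_eps}")
        if self.id_policy not in ID_POLICIES:
            raise ValueError(
                f"id_policy must be one of {ID_POLICIES}, got {self.id_policy!r}"
            )


@dataclass
class ConversionStats:
    """Counters accumulated over one conversion run."""

    records: int = 0
    samples: int = 0
    missing_genotypes: int = 0
    clamped_dosages: int = 0
    clamped_probabilities: int = 0
    malformed_lines: int = 0
    blank_lines: int = 0
    index_written: bool = False

    def summary(self) -> str:
        return (
            f"records={self.records} samples={self.samples} "
            f"missing_genotypes={self.missing_genotypes} "
            f"clamped_dosages={self.clamped_dosages} "
            f"clamped_probabilities={self.clamped_probabilities} "
            f"malformed_lines={self.malformed_lines} "
            f"blank_lines={self.blank_lines} "
            f"index_written={self.index_written}"
        )
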