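"""Reading and validating GEN files and Oxford .sample companions.

GEN is the whitespace-delimited text format emitted by the IMPUTE family
of imputation tools: per line, 5 or 6 variant metadata columns followed
by three genotype posterior probabilities P(AA), P(AB), P(BB) for every
diploid sample. Two metadata layouts circulate:

* 6 leading columns: ``chrom varid rsid pos allele_a allele_b``
* 5 leading columns: ``varid rsid pos allele_a allele_b`` (no chromosome)

The dialect is detected from the token count of the first data line and
enforced thereafter. Everything here is streaming: one line is held in
memory at a time.
"""

from __future__ import annotations

import gzip
import io
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, NamedTuple, Optional, Union

import numpy as np

from gen2vcf.config import PROB_EPS, ConversionStats
from gen2vcf.errors import MalformedLine, MalformedSampleFile


class GenotypeProbTriple(NamedTuple):
    """Posterior probabilities of the three diploid genotypes of one sample."""

    p_aa: float
    p_ab: float
    p_bb: float


@dataclass(frozen=True)
class GenDialect:
    """Which of the two GEN metadata layouts a file uses."""

    leading_columns: int

    def __post_init__(self) -> None:
        if self.leading_columns not in (5, 6):
            raise ValueError(
                f"leading_columns must be 5 or 6, got {self.leading_columns}"
            )

    @property
    def has_chrom_column(self) -> bool:
        return self.leading_columns == 6


FIVE_COLUMN = GenDialect(5)
SIX_COLUMN = GenDialect(6)


@dataclass
class GenRecord:
    """One parsed GEN line: variant metadata plus an (N, 3) probability array."""

    varid: str
    rsid: str
    pos: int
    allele_a: str
    allele_b: str
    probs: np.ndarray  # shape (n_samples, 3), float64
    line_number: int
    chrom: Optional[str] = None

    @property
    def n_samples(self) -> int:
        return self.probs.shape[0]

    def triple(self, i: int) -> GenotypeProbTriple:
        """Probability triple of sample ``i`` as a named tuple."""
        row = self.probs[i]
        return GenotypeProbTriple(float(row[0]), float(row[1]), float(row[2]))


@dataclass
class SampleInfo:
    """One data row of an Oxford .sample file; columns pass through unparsed."""

    id_1: str
    id_2: str
    missing: str
    extra_columns: list[str] = field(default_factory=list)


def detect_dialect(
    token_count: int, declared_samples: Optional[int] = None
) -> GenDialect:
    """Resolve the 5- vs 6-leading-column layout from a line's token count.

    The layouts are distinguishable because token counts are congruent to
    2 (5-column) or 0 (6-column) modulo 3; a count congruent to 1 fits
    neither. With ``declared_samples`` the count must match exactly.
    """
    if token_count < 8:
        raise MalformedLine(
            f"too few columns ({token_count}); a GEN line needs at least "
            "5 metadata columns plus 3 probabilities for one sample"
        )
    rem = token_count % 3
    if rem == 2:
        dialect = FIVE_COLUMN
    elif rem == 0:
        dialect = SIX_COLUMN
    else:
        raise MalformedLine(
            f"token count {token_count} fits neither the 5- nor the "
            "6-leading-column GEN layout"
        )
    if declared_samples is not None:
        expected = dialect.leading_columns + 3 * declared_samples
        if token_count != expected:
            raise MalformedLine(
                f"token count {token_count} does not match "
                f"{declared_samples} declared samples "
                f"(expected {expected} with {dialect.leading_columns} "
                "leading columns)"
            )
    return dialect


def parse_gen_line(
    line: str,
    dialect: GenDialect,
    expected_samples: int,
    line_number: int,
    strict: bool = True,
    stats: Optional[ConversionStats] = None,
) -> GenRecord:
    """Parse one GEN data line into a :class:`GenRecord`.

    Metadata columns map positionally according to the dialect. The
    remaining 3N tokens are parsed as decimal probabilities. Strict mode
    rejects negative probabilities and values above ``1 + 1e-6``; lenient
    mode clamps them into [0, 1] and counts each clamp.
    """
    tokens = line.split()
    expected_tokens = dialect.leading_columns + 3 * expected_samples
    if len(tokens) != expected_tokens:
        raise MalformedLine(
            f"expected {expected_tokens} columns "
            f"({dialect.leading_columns} metadata + 3 x {expected_samples} "
            f"probabilities), found {len(tokens)}",
            line_number,
        )

    meta = tokens[: dialect.leading_columns]
    if dialect.has_chrom_column:
        chrom, varid, rsid, pos_str, allele_a, allele_b = meta
    else:
        chrom = None
        varid, rsid, pos_str, allele_a, allele_b = meta

    try:
        pos = int(pos_str)
    except ValueError:
        raise MalformedLine(
            f"position {pos_str!r} is not an integer", line_number
        ) from None
    if pos < 1:
        raise MalformedLine(f"position must be >= 1, got {pos}", line_number)
    if not allele_a or not allele_b:
        raise MalformedLine("empty allele column", line_number)

    try:
        probs = np.array(tokens[dialect.leading_columns :], dtype=np.float64)
    except ValueError:
        bad = next(
            t
            for t in tokens[dialect.leading_columns :]
            if not _is_number(t)
        )
        raise MalformedLine(
            f"non-numeric probability token {bad!r}", line_number
        ) from None
    if not np.all(np.isfinite(probs)):
        raise MalformedLine("non-finite probability value", line_number)

    out_of_range = (probs < 0.0) | (probs > 1.0 + PROB_EPS)
    within_eps = (probs > 1.0) & (probs <= 1.0 + PROB_EPS)
    if strict and out_of_range.any():
        bad_val = float(probs[out_of_range][0])
        raise MalformedLine(
            f"probability {bad_val} outside [0, 1] in strict mode", line_number
        )
    n_clamped = int(out_of_range.sum()) + int(within_eps.sum())
    if n_clamped:
        np.clip(probs, 0.0, 1.0, out=probs)
        if stats is not None:
            stats.clamped_probabilities += n_clamped

    return GenRecord(
        chrom=chrom,
        varid=varid,
        rsid=rsid,
        pos=pos,
        allele_a=allele_a,
        allele_b=allele_b,
        probs=probs.reshape(expected_samples, 3),
        line_number=line_number,
    )


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


Source = Union[str, Path, IO[str], IO[bytes], Iterable[str]]


def _open_source(source: Source) -> Iterator[str]:
    """Yield text lines from a path, '-', a file object, or any line iterable.

    Paths ending in .gz (or whose first two bytes are the gzip magic) are
    decompressed on the fly; BGZF is a gzip variant, so bgzipped GEN input
    works too.
    """
    if isinstance(source, (str, Path)):
        if str(source) == "-":
            yield from sys.stdin
            return
        path = Path(source)
        with open(path, "rb") as raw:
            magic = raw.read(2)
            raw.seek(0)
            if magic == b"\x1f\x8b":
                with gzip.open(raw, "rt") as fh:
                    yield from fh
            else:
                yield from io.TextIOWrapper(raw)
        return
    if isinstance(source, io.TextIOBase):
        yield from source
        return
    first = True
    for line in source:
        if isinstance(line, bytes):
            line = line.decode()
        first = False
        yield line
    if first:
        return


def stream_gen(
    source: Source,
    expected_samples: Optional[int] = None,
    strict: bool = True,
    stats: Optional[ConversionStats] = None,
) -> Iterator[GenRecord]:
    """Yield :class:`GenRecord` objects from a GEN stream, one at a time.

    The dialect is detected from the first non-empty line (cross-checked
    against ``expected_samples`` when given, e.g. from a .sample file) and
    enforced for every subsequent line. Memory held at any time is one
    line plus one record. Blank lines are skipped and counted. An empty
    stream yields nothing and is not an error.

    In strict mode a malformed line aborts the stream; in lenient mode it
    is skipped and counted in ``stats.malformed_lines``.
    """
    if stats is None:
        stats = ConversionStats()
    dialect: Optional[GenDialect] = None
    n_samples = expected_samples

    for line_number, line in enumerate(_open_source(source), start=1):
        if not line.strip():
            stats.blank_lines += 1
            continue
        if dialect is None:
            token_count = len(line.split())
            dialect = detect_dialect(token_count, declared_samples=n_samples)
            if n_samples is None:
                n_samples = (token_count - dialect.leading_columns) // 3
            stats.samples = n_samples
        try:
            record = parse_gen_line(
                line, dialect, n_samples, line_number, strict=strict, stats=stats
            )
        except MalformedLine:
            if strict:
                raise
            stats.malformed_lines += 1
            continue
        yield record


def read_sample_file(path: Union[str, Path]) -> list[SampleInfo]:
    """Read an Oxford .sample file and return its data rows in order.

    The format has a header line (conventionally ``ID_1 ID_2 missing ...``),
    a column-type line (``0 0 0 ...``), then one row per sample. The number
    of returned rows defines the sample count N of the companion GEN file.
    """
    lines = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                lines.append(line.split())
    if len(lines) < 2:
        raise MalformedSampleFile(
            f"{path}: a .sample file needs a header line and a type line, "
            f"found {len(lines)} non-empty line(s)"
        )
    samples = []
    for row_number, tokens in enumerate(lines[2:], start=3):
        if len(tokens) < 3:
            raise MalformedSampleFile(
                f"{path}: row {row_number} has {len(tokens)} columns, "
                "expected at least ID_1, ID_2 and missing"
            )
        if not tokens[0] or not tokens[1]:
            raise MalformedSampleFile(
                f"{path}: row {row_number} has an empty sample identifier"
            )
        samples.append(
            SampleInfo(
                id_1=tokens[0],
                id_2=tokens[1],
                missing=tokens[2],
                extra_columns=tokens[3:],
            )
        )
    return samples
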