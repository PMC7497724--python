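"""Rendering and writing VCF 4.2 with FORMAT GT:GP:DS.

The writer is record-at-a-time: lines are emitted as they arrive, plain
or BGZF-compressed (via pysam), and a tabix index is built afterwards
when the output is a coordinate-sorted compressed file. GP is emitted as
linear probabilities in genotype order P(0/0), P(0/1), P(1/1); QUAL,
FILTER and INFO are "." because GEN carries no such data.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Optional, Sequence, Union

import pysam

from gen2vcf.config import ConversionConfig, ConversionStats
from gen2vcf.errors import (
    DuplicateSampleId,
    UnresolvedChromosome,
    UnsortedInput,
)
from gen2vcf.gen_io import GenRecord
from gen2vcf.genotype_compute import ComputedGenotype

FIXED_COLUMNS = (
    "#CHROM",
    "POS",
    "ID",
    "REF",
    "ALT",
    "QUAL",
    "FILTER",
    "INFO",
    "FORMAT",
)

FORMAT_DECLARATIONS = (
    '##FORMAT=<ID=GT,Number=1,Type=String,'
    'Description="Best-guess genotype (maximum posterior probability)">',
    '##FORMAT=<ID=GP,Number=G,Type=Float,'
    'Description="Genotype posterior probabilities P(0/0), P(0/1), P(1/1)">',
    '##FORMAT=<ID=DS,Number=1,Type=Float,'
    'Description="Imputed ALT-allele dosage: P(0/1) + 2*P(1/1)">',
)


def format_float(x: float, precision: int) -> str:
    """Fixed-point decimal with exactly ``precision`` digits after the point.

    Round-half-to-even, never exponent notation, trailing zeros kept, so
    a value re-parsed at the stated precision round-trips bit-exactly.
    """
    return f"{x:.{precision}f}"


@dataclass
class VcfHeaderSpec:
    """Everything needed to emit the VCF meta lines and column header."""

    sample_ids: Sequence[str]
    source: str = "gen2vcf"
    file_date: Optional[str] = None
    contigs: Sequence[str] = field(default_factory=tuple)
    file_format_version: str = "VCFv4.2"


def build_header(spec: VcfHeaderSpec, allow_empty: bool = False) -> str:
    """Render the full VCF header, ending with a newline.

    ``##fileformat`` comes first, then the three FORMAT declarations for
    GT, GP and DS, the ``##source`` line, any ``##contig`` lines, and the
    ``#CHROM`` column line carrying the sample IDs in input order.
    """
    if not spec.sample_ids and not allow_empty:
        raise ValueError("a VCF header needs at least one sample")
    seen = set()
    for sid in spec.sample_ids:
        if sid in seen:
            raise DuplicateSampleId(f"duplicate sample ID {sid!r}")
        seen.add(sid)

    lines = [f"##fileformat={spec.file_format_version}"]
    if spec.file_date is not None:
        lines.append(f"##fileDate={spec.file_date}")
    lines.extend(FORMAT_DECLARATIONS)
    lines.append(f"##source={spec.source}")
    for contig in spec.contigs:
        lines.append(f"##contig=<ID={contig}>")
    lines.append("\t".join([*FIXED_COLUMNS, *spec.sample_ids]))
    return "\n".join(lines) + "\n"


def _variant_id(rec: GenRecord, chrom: str, policy: str) -> str:
    if policy == "rsid":
        return rec.rsid or "."
    if policy == "varid":
        return rec.varid or "."
    # auto: rsid unless "." or empty, else varid, else a synthetic key
    if rec.rsid and rec.rsid != ".":
        return rec.rsid
    if rec.varid and rec.varid != ".":
        return rec.varid
    return f"{chrom}:{rec.pos}_{rec.allele_a}_{rec.allele_b}"


def render_record(
    rec: GenRecord,
    genotypes: Sequence[ComputedGenotype],
    config: ConversionConfig,
) -> str:
    """Render one VCF data line (no trailing newline).

    Allele A of the GEN line is REF, allele B is ALT. Missing samples are
    "./.:.:."; a GT blanked by the hard-call threshold keeps its GP and DS.
    """
    if rec.chrom is None:
        raise UnresolvedChromosome(
            f"line {rec.line_number}: no chromosome column in the input and "
            "no override given"
        )
    if len(genotypes) != rec.n_samples:
        raise ValueError(
            f"line {rec.line_number}: {len(genotypes)} computed genotypes "
            f"for {rec.n_samples} samples"
        )
    p = config.precision
    fields = [
        rec.chrom,
        str(rec.pos),
        _variant_id(rec, rec.chrom, config.id_policy),
        rec.allele_a,
        rec.allele_b,
        ".",
        ".",
        ".",
        "GT:GP:DS",
    ]
    for g in genotypes:
        if g.gp is None:
            fields.append("./.:.:.")
        else:
            fields.append(
                f"{g.gt.vcf}:"
                f"{g.gp.p_aa:.{p}f},{g.gp.p_ab:.{p}f},{g.gp.p_bb:.{p}f}:"
                f"{g.ds:.{p}f}"
            )
    return "\t".join(fields)


Destination = Union[str, Path, IO[str]]


def write_vcf(
    header: str,
    record_stream: Iterable[str],
    destination: Destination,
    compress: Optional[bool] = None,
    index: bool = False,
    stats: Optional[ConversionStats] = None,
) -> ConversionStats:
    """Write header + records to a path, "-" (stdout) or a text handle.

    ``compress=None`` infers BGZF from a ".gz" suffix; standard output is
    plain text unless compression is explicitly requested. Records are
    written one at a time (bounded memory). Indexing happens only for
    compressed file output; if the records turn out not to be
    coordinate-sorted the file is still written in full and
    :class:`UnsortedInput` is raised for the index step alone.
    """
    if stats is None:
        stats = ConversionStats()

    path: Optional[Path] = None
    handle: Optional[IO[str]] = None
    if isinstance(destination, (str, Path)) and str(destination) != "-":
        path = Path(destination)
        if compress is None:
            compress = path.suffix == ".gz"
    else:
        handle = sys.stdout if str(destination) == "-" else destination  # type: ignore[assignment]
        if compress is None:
            compress = False

    sorted_so_far = True
    last_chrom: Optional[str] = None
    last_pos = -1
    finished_chroms: set[str] = set()

    def _record_lines() -> Iterable[str]:
        nonlocal sorted_so_far, last_chrom, last_pos
        for line in record_stream:
            chrom, pos_str, _ = line.split("\t", 2)
            pos = int(pos_str)
            if chrom != last_chrom:
                if last_chrom is not None:
                    finished_chroms.add(last_chrom)
                if chrom in finished_chroms:
                    sorted_so_far = False
                last_chrom, last_pos = chrom, pos
            elif pos < last_pos:
                sorted_so_far = False
            else:
                last_pos = pos
            stats.records += 1
            yield line if line.endswith("\n") else line + "\n"

    if path is not None and compress:
        with pysam.BGZFile(str(path), "wb") as bgzf:
            bgzf.write(header.encode())
            for line in _record_lines():
                bgzf.write(line.encode())
        if index:
            if not sorted_so_far:
                raise UnsortedInput(
                    f"{path}: records are not coordinate-sorted; the VCF was "
                    "written but the index step is refused"
                )
            pysam.tabix_index(str(path), preset="vcf", force=True)
            stats.index_written = True
    elif path is not None:
        with open(path, "w") as fh:
            fh.write(header)
            for line in _record_lines():
                fh.write(line)
    else:
        assert handle is not None
        handle.write(header)
        for line in _record_lines():
            handle.write(line)
        handle.flush()
    return stats
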