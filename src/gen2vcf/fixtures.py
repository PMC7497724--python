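"""Seeded GEN/.sample fixture generation and a naive reference converter.

``generate_fixture`` emulates IMPUTE output: per sample, a genotype
probability triple drawn from a flat Dirichlet over the 2-simplex and
printed with 3 decimals — so, as in real files, the printed triple may
not sum to exactly 1. A machine-readable truth table accompanies every
fixture, computed from the rounded, as-written values (the converter can
only see the file). ``oracle_convert`` is a deliberately naive
whole-file-in-memory re-implementation of the conversion, kept
independent of the streaming path, for use as a test oracle.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np

from gen2vcf.config import ConversionConfig
from gen2vcf.gen_io import SIX_COLUMN, GenDialect
from gen2vcf.vcf_out import VcfHeaderSpec, build_header

_ALLELES = ("A", "C", "G", "T")

TRUTH_COLUMNS = (
    "variant_index",
    "sample_index",
    "p_aa",
    "p_ab",
    "p_bb",
    "ds",
    "gt",
    "missing",
)


@dataclass
class FixtureSpec:
    """Shape and randomness of one synthetic GEN + .sample fixture."""

    n_variants: int
    n_samples: int
    seed: int
    missing_rate: float = 0.0
    dialect: GenDialect = SIX_COLUMN
    prob_decimals: int = 3
    chrom: str = "1"

    def __post_init__(self) -> None:
        if self.n_variants < 0:
            raise ValueError("n_variants must be >= 0")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must be in [0, 1]")


@dataclass
class TruthRow:
    """Expected conversion output for one sample at one variant."""

    variant_index: int
    sample_index: int
    p_aa: float
    p_ab: float
    p_bb: float
    ds: Optional[float]  # None when missing
    gt: str  # "0/0", "0/1", "1/1" or "./."
    missing: bool


@dataclass
class Fixture:
    """Paths of one generated fixture; the truth table stays on disk."""

    spec: FixtureSpec
    gen_path: Path
    sample_path: Path
    truth_path: Optional[Path]

    def load_truth(self) -> list[TruthRow]:
        if self.truth_path is None:
            raise ValueError("fixture was generated with write_truth=False")
        return load_truth(self.truth_path)


def _expected_call(p_aa: float, p_ab: float, p_bb: float) -> str:
    probs = (p_aa, p_ab, p_bb)
    return ("0/0", "0/1", "1/1")[probs.index(max(probs))]


def generate_fixture(
    spec: FixtureSpec,
    directory: Union[str, Path],
    write_truth: bool = True,
) -> Fixture:
    """Write <stem>.gen, <stem>.sample and <stem>.truth.tsv under ``directory``.

    Positions are strictly increasing; a ``missing_rate`` fraction of
    sample-genotypes is written as "0 0 0". The same spec (seed included)
    always yields byte-identical files. Truth rows are streamed straight
    to disk; ``write_truth=False`` skips them for very large fixtures.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = f"fixture_s{spec.seed}_v{spec.n_variants}_n{spec.n_samples}"
    gen_path = directory / f"{stem}.gen"
    sample_path = directory / f"{stem}.sample"
    truth_path = directory / f"{stem}.truth.tsv" if write_truth else None

    rng = np.random.default_rng(spec.seed)
    v, n = spec.n_variants, spec.n_samples
    positions = 1000 + np.cumsum(rng.integers(1, 300, size=max(v, 1)))[:v]
    ref_idx = rng.integers(0, 4, size=max(v, 1))[:v]
    alt_shift = rng.integers(1, 4, size=max(v, 1))[:v]
    probs = rng.dirichlet((1.0, 1.0, 1.0), size=(max(v, 1), n))[:v]
    missing = rng.random(size=(max(v, 1), n))[:v] < spec.missing_rate

    probs = np.round(probs, spec.prob_decimals)
    probs[missing] = 0.0

    dec = spec.prob_decimals
    truth_fh = open(truth_path, "w") if truth_path is not None else None
    if truth_fh is not None:
        truth_fh.write("\t".join(TRUTH_COLUMNS) + "\n")
    try:
        with open(gen_path, "w") as gen:
            for i in range(v):
                ref = _ALLELES[ref_idx[i]]
                alt = _ALLELES[(ref_idx[i] + alt_shift[i]) % 4]
                meta = [f"snp{i + 1}", f"rs{i + 1}", str(positions[i]), ref, alt]
                if spec.dialect.has_chrom_column:
                    meta.insert(0, spec.chrom)
                cells = []
                for j in range(n):
                    p_aa, p_ab, p_bb = (float(x) for x in probs[i, j])
                    cells.append(f"{p_aa:.{dec}f} {p_ab:.{dec}f} {p_bb:.{dec}f}")
                    if truth_fh is None:
                        continue
                    if p_aa + p_ab + p_bb < 1e-6:
                        ds_str, gt, miss = "", "./.", 1
                    else:
                        ds = min(2.0, max(0.0, p_ab + 2.0 * p_bb))
                        ds_str = format(ds, ".10g")
                        gt, miss = _expected_call(p_aa, p_ab, p_bb), 0
                    truth_fh.write(
                        f"{i}\t{j}\t{p_aa:.{dec}f}\t{p_ab:.{dec}f}\t"
                        f"{p_bb:.{dec}f}\t{ds_str}\t{gt}\t{miss}\n"
                    )
                gen.write(" ".join(meta) + " " + " ".join(cells) + "\n")
    finally:
        if truth_fh is not None:
            truth_fh.close()

    with open(sample_path, "w") as fh:
        fh.write("ID_1 ID_2 missing\n0 0 0\n")
        for j in range(n):
            fh.write(f"fam{j + 1} ind{j + 1} 0\n")

    return Fixture(spec, gen_path, sample_path, truth_path)


def load_truth(truth_path: Union[str, Path]) -> list[TruthRow]:
    """Read a truth table written by :func:`generate_fixture`."""
    rows: list[TruthRow] = []
    with open(truth_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        assert tuple(header) == TRUTH_COLUMNS
        for line in fh:
            vi, si, paa, pab, pbb, ds, gt, miss = line.rstrip("\n").split("\t")
            rows.append(
                TruthRow(
                    int(vi), int(si),
                    float(paa), float(pab), float(pbb),
                    None if ds == "" else float(ds),
                    gt, bool(int(miss)),
                )
            )
    return rows


def oracle_convert(
    gen_path: Union[str, Path],
    sample_path: Optional[Union[str, Path]] = None,
    config: Optional[ConversionConfig] = None,
    chrom_override: Optional[str] = None,
    sample_id_col: str = "id_2",
    source: Optional[str] = None,
) -> str:
    """Naive whole-file-in-memory GEN -> VCF conversion (test oracle only).

    Re-derives dosage, hard call, missingness, ID policy and rendering
    from first principles, independently of the streaming modules. Output
    carries no ##fileDate line, so it is directly comparable with CLI
    output produced under ``--no-date``.
    """
    if config is None:
        config = ConversionConfig()
    if source is None:
        from gen2vcf import __version__

        source = f"gen2vcf {__version__}"

    opener = gzip.open if str(gen_path).endswith(".gz") else open
    with opener(gen_path, "rt") as fh:  # type: ignore[operator]
        raw_lines = [ln for ln in fh.read().splitlines() if ln.strip()]

    sample_ids: Optional[list[str]] = None
    if sample_path is not None:
        with open(sample_path) as fh:
            rows = [ln.split() for ln in fh if ln.strip()]
        data = rows[2:]
        if sample_id_col == "id_1":
            sample_ids = [r[0] for r in data]
        elif sample_id_col == "id_2":
            sample_ids = [r[1] for r in data]
        else:
            sample_ids = [f"{r[0]}_{r[1]}" for r in data]

    body_lines: list[str] = []
    p = config.precision
    for raw in raw_lines:
        tokens = raw.split()
        lead = 6 if len(tokens) % 3 == 0 else 5
        if lead == 6:
            chrom, varid, rsid, pos, ref, alt = tokens[:6]
        else:
            varid, rsid, pos, ref, alt = tokens[:5]
            chrom = None
        if chrom_override is not None:
            chrom = chrom_override
        values = [float(t) for t in tokens[lead:]]
        if sample_ids is None:
            sample_ids = [
                f"sample_{k + 1}" for k in range(len(values) // 3)
            ]

        if config.id_policy == "rsid":
            vid = rsid or "."
        elif config.id_policy == "varid":
            vid = varid or "."
        elif rsid not in ("", "."):
            vid = rsid
        elif varid not in ("", "."):
            vid = varid
        else:
            vid = f"{chrom}:{pos}_{ref}_{alt}"

        cells = []
        for k in range(0, len(values), 3):
            t = [min(1.0, max(0.0, x)) for x in values[k : k + 3]]
            total = t[0] + t[1] + t[2]
            if total < config.missing_eps:
                cells.append("./.:.:.")
                continue
            if config.renormalize:
                t = [x / total for x in t]
            ds = min(2.0, max(0.0, t[1] + 2.0 * t[2]))
            peak = max(t)
            if peak < config.gt_threshold:
                call = "./."
            else:
                call = ("0/0", "0/1", "1/1")[t.index(peak)]
            cells.append(
                f"{call}:{t[0]:.{p}f},{t[1]:.{p}f},{t[2]:.{p}f}:{ds:.{p}f}"
            )
        body_lines.append(
            "\t".join(
                [chrom, pos, vid, ref, alt, ".", ".", ".", "GT:GP:DS", *cells]
            )
        )

    header = build_header(
        VcfHeaderSpec(sample_ids=sample_ids or [], source=source),
        allow_empty=sample_ids is None or not sample_ids,
    )
    return header + "".join(line + "\n" for line in body_lines)
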