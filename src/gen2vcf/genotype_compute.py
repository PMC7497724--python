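"""Deriving GT, GP and DS from a genotype-probability triple.

With allele A as the reference and allele B as the coded (alternate)
allele, the imputed dosage is the expected ALT-allele count

    DS = 0 * P(AA) + 1 * P(AB) + 2 * P(BB),

which lies in [0, 2] for a biallelic diploid genotype, and the best-guess
genotype GT is the genotype with maximum posterior probability. An
all-zero triple is the GEN convention for a missing genotype: GT, GP and
DS are all emitted as missing.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

from gen2vcf.config import ConversionConfig, ConversionStats
from gen2vcf.errors import DegenerateTriple
from gen2vcf.gen_io import GenotypeProbTriple

Triple = Sequence[float]


class GtCall(enum.Enum):
    """Hard-call genotype, rendered in VCF GT notation."""

    HOM_REF = "0/0"
    HET = "0/1"
    HOM_ALT = "1/1"
    MISSING = "./."

    @property
    def vcf(self) -> str:
        return self.value


@dataclass
class ComputedGenotype:
    """GT call plus (unless the input was missing) the GP triple and DS.

    ``gp`` and ``ds`` are None exactly when the input triple was classified
    missing. A GT blanked by the hard-call threshold keeps gp and ds.
    """

    gt: GtCall
    gp: Optional[GenotypeProbTriple]
    ds: Optional[float]


def dosage(triple: Triple, stats: Optional[ConversionStats] = None) -> float:
    """Expected ALT-allele count P(AB) + 2*P(BB), clamped into [0, 2].

    Clamping only fires when an unnormalized triple sums above 1 (3-decimal
    rounding in the input can do this); each clamp is counted.
    """
    ds = triple[1] + 2.0 * triple[2]
    if ds < 0.0:
        if stats is not None:
            stats.clamped_dosages += 1
        return 0.0
    if ds > 2.0:
        if stats is not None:
            stats.clamped_dosages += 1
        return 2.0
    return ds


def classify_missing(triple: Triple, missing_eps: float = 1e-6) -> bool:
    """True iff the triple denotes a missing genotype (component sum ~ 0)."""
    return triple[0] + triple[1] + triple[2] < missing_eps


_CALL_BY_INDEX = (GtCall.HOM_REF, GtCall.HET, GtCall.HOM_ALT)


def best_guess(triple: Triple, gt_threshold: float = 0.0) -> GtCall:
    """Genotype with maximum posterior probability.

    Exact ties break toward the lowest genotype index
    (HOM_REF < HET < HOM_ALT). If the maximum probability is below
    ``gt_threshold`` the call is MISSING (GP and DS are unaffected).
    """
    p_aa, p_ab, p_bb = triple[0], triple[1], triple[2]
    if p_aa >= p_ab:
        idx, best = (0, p_aa) if p_aa >= p_bb else (2, p_bb)
    else:
        idx, best = (1, p_ab) if p_ab >= p_bb else (2, p_bb)
    if best < gt_threshold:
        return GtCall.MISSING
    return _CALL_BY_INDEX[idx]


def renormalize(
    triple: Triple, missing_eps: float = 1e-6
) -> GenotypeProbTriple:
    """Divide each component by the component sum so they sum to 1."""
    total = triple[0] + triple[1] + triple[2]
    if total < missing_eps:
        raise DegenerateTriple(
            f"cannot renormalize triple with sum {total}; it should have "
            "been classified missing"
        )
    return GenotypeProbTriple(
        triple[0] / total, triple[1] / total, triple[2] / total
    )


def compute_genotype(
    triple: Triple,
    config: ConversionConfig,
    stats: Optional[ConversionStats] = None,
) -> ComputedGenotype:
    """Full per-sample derivation: missingness, optional renormalization,
    dosage, and the hard call."""
    if classify_missing(triple, config.missing_eps):
        if stats is not None:
            stats.missing_genotypes += 1
        return ComputedGenotype(gt=GtCall.MISSING, gp=None, ds=None)
    if config.renormalize:
        gp = renormalize(triple, config.missing_eps)
    elif isinstance(triple, GenotypeProbTriple):
        gp = triple
    else:
        gp = GenotypeProbTriple(float(triple[0]), float(triple[1]), float(triple[2]))
    ds = dosage(gp, stats)
    gt = best_guess(gp, config.gt_threshold)
    return ComputedGenotype(gt=gt, gp=gp, ds=ds)
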