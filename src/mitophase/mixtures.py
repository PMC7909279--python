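"""In silico two-person mtDNA mixtures with exact, noise-free read counts.

A mixture is specified by an ordered (major, minor) haplotype pair, an
integer ratio p:q and a total per-site depth D.  Idealized ratios are
normalized into read counts — e.g. a 1:9 mixture at D = 100 yields 10:90
counts at a site where only the 9-part contributor carries the alternative
allele — so that downstream phasing accuracy reflects the algorithm rather
than sequencing noise.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .empop import Haplotype, SiteCountTable, SiteLocus


@dataclass
class MixtureSpec:
    """Ordered contributor pair plus ratio (major:minor) and total depth."""

    major: Haplotype
    minor: Haplotype
    ratio: tuple[int, int] = (1, 1)
    total_depth: int = 100

    def __post_init__(self) -> None:
        p, q = self.ratio
        if p <= 0 or q <= 0:
            raise ValueError("ratio parts must be positive integers")
        if self.total_depth < 1:
            raise ValueError("total depth must be >= 1")
        if len(self.major) != len(self.minor):
            raise ValueError("contributors must share one site universe")

    @property
    def proportions(self) -> tuple[float, float]:
        p, q = self.ratio
        return p / (p + q), q / (p + q)

    @property
    def minor_proportion(self) -> float:
        return self.proportions[1]


@dataclass
class MixtureTruth:
    """A generated mixture bundled with its ground truth for evaluation."""

    spec: MixtureSpec
    counts: SiteCountTable
    true_major: Haplotype
    true_minor: Haplotype


def _round_half_up(x: np.ndarray) -> np.ndarray:
    # round-half-away-from-zero; x is non-negative here
    return np.floor(x + 0.5).astype(np.int64)


def make_mixture(spec: MixtureSpec, loci: Sequence[SiteLocus]) -> SiteCountTable:
    """Normalize a haplotype pair at a given ratio into exact per-site counts.

    Per site j, ``alt = round(D * (w_maj * h_maj[j] + w_min * h_min[j]))`` and
    ``ref = D - alt``, so depth is conserved exactly; sites where both
    contributors agree are homozygous at full depth.
    """
    if len(spec.major) != len(loci):
        raise ValueError("haplotypes not aligned to the provided site list")
    w_major, w_minor = spec.proportions
    q = w_major * spec.major.alleles + w_minor * spec.minor.alleles
    alt = _round_half_up(spec.total_depth * q)
    ref = spec.total_depth - alt
    return SiteCountTable(list(loci), ref, alt)


def make_truth(spec: MixtureSpec, loci: Sequence[SiteLocus]) -> MixtureTruth:
    return MixtureTruth(spec, make_mixture(spec, loci), spec.major, spec.minor)


def enumerate_pairs(
    db: Sequence[Haplotype],
    ratios: Sequence[tuple[int, int]],
    total_depth: int = 100,
) -> list[MixtureSpec]:
    """All unordered contributor pairs crossed with all ratios.

    Pairs are ordered by sample ID, the first member taking the major role;
    for a 1:1 ratio the major/minor labels are therefore a tie-break by ID,
    mirroring how subequal in vitro mixtures are dichotomized in practice.
    With n haplotypes and r ratios the output has C(n, 2) * r specs.
    """
    if len(db) < 2:
        raise ValueError("need at least two haplotypes to form mixtures")
    ordered = sorted(db, key=lambda h: h.sample_id)
    return [
        MixtureSpec(a, b, ratio, total_depth)
        for a, b in itertools.combinations(ordered, 2)
        for ratio in ratios
    ]


def restrict_to_mixture_sites(
    counts: SiteCountTable,
    haplotypes: Sequence[Haplotype] = (),
    drop_invariant: bool = True,
) -> tuple[SiteCountTable, np.ndarray]:
    """Drop sites with no alternative-allele evidence anywhere.

    A site is retained when the mixture shows alternative reads or any of the
    supplied haplotypes (database and/or panel) carries the alternative
    allele; all-reference sites carry no phasing signal.  Returns the reduced
    table plus the integer index map into the original site list, so full
    mitotypes can be reconstituted after phasing.  With ``drop_invariant``
    off this is the identity with a trivial map.
    """
    m = len(counts)
    if not drop_invariant:
        return counts, np.arange(m)
    keep = counts.alt_counts > 0
    for hap in haplotypes:
        if len(hap) != m:
            raise ValueError("haplotype not aligned to count table")
        keep |= hap.alleles == 1
    idx = np.flatnonzero(keep)
    reduced = SiteCountTable(
        [counts.loci[j] for j in idx],
        counts.ref_counts[idx],
        counts.alt_counts[idx],
    )
    return reduced, idx
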