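"""Minor-contributor interpolation and the phasing-error taxonomy.

In a two-person mixture, once the major contributor's alleles are known with
confidence, the remaining observed alleles necessarily belong to the minor
contributor: at heterozygous (He) sites the minor takes the complement of
the major, at homozygous (HoR/HoA) sites it copies the single observed
allele, and zero-depth sites yield no call.  This post-pass rescues minor
mitotypes from imbalanced mixtures where the sampler, starved of minor-read
signal, tends to coerce the minor onto its major homologue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .empop import HE, HOA, MISSING, Haplotype, SiteCountTable, classify_sites

MINOR_MISSING = -1  # sentinel allele for no-call sites

HE_TO_HO = "He->Ho"          # heterozygous site coerced homozygous
HO_TO_HE = "Ho->He"          # homozygous site coerced heterozygous
POINT_SWITCH = "point-switch"  # He site with both contributors swapped
OTHER_ERROR = "other"        # e.g. both contributors wrong the same way


class InterpolationError(ValueError):
    """The asserted major haplotype contradicts the observed counts."""


@dataclass
class InterpolationResult:
    """Interpolated minor haplotype plus the per-site rule that produced it."""

    alleles: np.ndarray      # int8, MINOR_MISSING at no-call sites
    source: list[str]        # "He-complement" | "Ho-copy" | "missing"

    def as_haplotype(self, sample_id: str = "interpolated_minor") -> Haplotype:
        """Strict conversion; fails if any site is uncalled."""
        if (self.alleles == MINOR_MISSING).any():
            raise ValueError("cannot convert: interpolation left uncalled sites")
        return Haplotype(sample_id, self.alleles)


def interpolate_minor(major: Haplotype, counts: SiteCountTable) -> InterpolationResult:
    """Reconstruct the minor contributor from a trusted major haplotype.

    Raises :class:`InterpolationError` when the major carries an allele with
    zero supporting reads at an observed site — the premise that the major
    is correct cannot hold there.
    """
    if len(major) != len(counts):
        raise ValueError("major haplotype not aligned to count table")
    classes = classify_sites(counts)
    alleles = np.full(len(counts), MINOR_MISSING, dtype=np.int8)
    source: list[str] = []
    for j, cls in enumerate(classes):
        a = int(major.alleles[j])
        if cls == MISSING:
            source.append("missing")
            continue
        observed_alt = counts.alt_counts[j] > 0
        observed_ref = counts.ref_counts[j] > 0
        if (a == 1 and not observed_alt) or (a == 0 and not observed_ref):
            raise InterpolationError(
                f"site {counts.loci[j].position}: major allele {a} has zero reads"
            )
        if cls == HE:
            alleles[j] = 1 - a
            source.append("He-complement")
        else:
            alleles[j] = 1 if cls == HOA else 0
            source.append("Ho-copy")
    return InterpolationResult(alleles, source)


def error_taxonomy(
    truth: tuple[Haplotype, Haplotype],
    estimate: tuple[Haplotype, Haplotype],
    counts: SiteCountTable | None = None,
) -> list[tuple[int, str]]:
    """Label every mismatched site of an (already matched) haplotype pair.

    The pairs must be in matched order (truth major with estimated major,
    as produced by the optimal-matching evaluation).  Labels: He->Ho when a
    truly heterozygous site is estimated homozygous, Ho->He for the
    converse, point-switch when both contributors are wrong at a He site in
    complementary fashion, and "other" for residual patterns.
    """
    ta, tb = truth[0].alleles, truth[1].alleles
    ea, eb = estimate[0].alleles, estimate[1].alleles
    if not (ta.size == tb.size == ea.size == eb.size):
        raise ValueError("all four haplotypes must share one site universe")
    labels: list[tuple[int, str]] = []
    for j in range(ta.size):
        if ta[j] == ea[j] and tb[j] == eb[j]:
            continue
        truth_he = ta[j] != tb[j]
        est_he = ea[j] != eb[j]
        if truth_he and not est_he:
            labels.append((j, HE_TO_HO))
        elif not truth_he and est_he:
            labels.append((j, HO_TO_HE))
        elif truth_he and est_he:
            labels.append((j, POINT_SWITCH))
        else:
            labels.append((j, OTHER_ERROR))
    return labels
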