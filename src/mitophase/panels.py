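"""Reference-panel construction.

Two families of panel are provided.  The four *experimental* designs probe
how panel composition limits phasing accuracy: (1) an idealized panel
containing both contributors, (2) hold-two-out cross-validation with both
contributors removed, (3) a one-SNP "derived" contributor in the mixture
whose "ancestral" sequence stays in the panel, and (4) the converse, a
one-SNP-mutated copy in the panel.  The *production* builder filters a large
haplotype database by graph edit distance to the observed mixture — the
number of allele changes a candidate needs to be compatible with the mixed
genotypes (heterozygous sites accept either allele) — and caps the panel at
the nearest haplotypes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .empop import Haplotype, SiteCountTable
from .mixtures import MixtureTruth, make_mixture

logger = logging.getLogger(__name__)


@dataclass
class ReferencePanel:
    """An ordered haplotype set supplying the copying prior."""

    haplotypes: list[Haplotype]
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        if not self.haplotypes:
            raise ValueError("a reference panel needs at least one haplotype")
        lengths = {len(h) for h in self.haplotypes}
        if len(lengths) != 1:
            raise ValueError("panel haplotypes must share one site universe")
        ids = [h.sample_id for h in self.haplotypes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample IDs in panel")

    @property
    def matrix(self) -> np.ndarray:
        """N_p x M binary allele matrix."""
        return np.vstack([h.alleles for h in self.haplotypes])

    def __len__(self) -> int:
        return len(self.haplotypes)


@dataclass
class PanelConfig:
    """Edit-distance filter settings: threshold d and panel-size cap."""

    edit_distance: int = 4
    max_panel: int = 25

    def __post_init__(self) -> None:
        if self.edit_distance < 0:
            raise ValueError("edit distance must be non-negative")
        if self.max_panel < 1:
            raise ValueError("max_panel must be >= 1")


def mixture_edit_distance(candidate: Haplotype, counts: SiteCountTable) -> int:
    """Allele changes needed for a candidate to be compatible with the mixture.

    Per site, the mixture's observed allele set is {ref if ref reads > 0} ∪
    {alt if alt reads > 0}; the candidate pays 1 wherever its allele is not
    in that set.  Heterozygous sites accept either allele and zero-depth
    sites contribute nothing.
    """
    if len(candidate) != len(counts):
        raise ValueError("candidate and count table not on one site universe")
    a = candidate.alleles
    ref_seen = counts.ref_counts > 0
    alt_seen = counts.alt_counts > 0
    incompatible = ((a == 0) & ~ref_seen & alt_seen) | ((a == 1) & ~alt_seen & ref_seen)
    return int(incompatible.sum())


def build_edit_distance_panel(
    db: Sequence[Haplotype],
    counts: SiteCountTable,
    cfg: PanelConfig = PanelConfig(),
) -> ReferencePanel:
    """Keep database haplotypes within edit distance d of the mixture.

    If more than ``max_panel`` survive, the smallest distances win, ties
    broken lexicographically by sample ID for reproducibility.  If no
    candidate passes the filter the single globally nearest haplotype is
    returned instead (the engine requires a non-empty panel) with a warning.
    """
    if not db:
        raise ValueError("empty haplotype database")
    scored = sorted(
        ((mixture_edit_distance(h, counts), h.sample_id, h) for h in db),
        key=lambda t: (t[0], t[1]),
    )
    kept = [t for t in scored if t[0] <= cfg.edit_distance]
    if not kept:
        warnings.warn(
            "no database haplotype within edit distance "
            f"{cfg.edit_distance}; falling back to the nearest haplotype",
            stacklevel=2,
        )
        kept = scored[:1]
    kept = kept[: cfg.max_panel]
    return ReferencePanel(
        [t[2] for t in kept], provenance=f"edit_distance({cfg.edit_distance})"
    )


def build_experimental_panel(
    truth: MixtureTruth,
    db: Sequence[Haplotype],
    panel_type: int,
    seed: int = 0,
) -> tuple[ReferencePanel, MixtureTruth]:
    """Build one of the four experimental panel designs.

    Returns the panel and a possibly modified truth record: design 3 flips a
    single random allele in the *mixture* copy of one contributor (the panel
    keeps the original "ancestral" haplotype; the other contributor leaves
    the panel), so the returned truth has regenerated counts and true
    haplotypes; design 4 flips the allele in the *panel* copy instead and
    leaves the mixture untouched.
    """
    ids = {h.sample_id for h in db}
    for contrib in (truth.true_major, truth.true_minor):
        if contrib.sample_id not in ids:
            raise ValueError(f"contributor {contrib.sample_id} absent from database")
    major_id, minor_id = truth.true_major.sample_id, truth.true_minor.sample_id

    if panel_type == 1:
        return ReferencePanel(list(db), provenance="panel1"), truth

    if panel_type == 2:
        members = [h for h in db if h.sample_id not in (major_id, minor_id)]
        return ReferencePanel(members, provenance="panel2"), truth

    if panel_type not in (3, 4):
        raise ValueError("panel_type must be 1, 2, 3 or 4")

    rng = np.random.default_rng(seed)
    flip_major = bool(rng.integers(2))
    target_id = major_id if flip_major else minor_id
    other_id = minor_id if flip_major else major_id
    target = truth.true_major if flip_major else truth.true_minor
    site = int(rng.integers(len(target)))

    mutated = Haplotype(target.sample_id, target.alleles.copy())
    mutated.alleles[site] ^= 1

    if panel_type == 3:
        # derived haplotype enters the mixture; its ancestor stays in the panel
        members = [h for h in db if h.sample_id != other_id]
        panel = ReferencePanel(members, provenance="panel3")
        new_major = mutated if flip_major else truth.true_major
        new_minor = truth.true_minor if flip_major else mutated
        spec = replace(truth.spec, major=new_major, minor=new_minor)
        new_truth = MixtureTruth(
            spec, make_mixture(spec, truth.counts.loci), new_major, new_minor
        )
        return panel, new_truth

    # panel_type == 4: mutated copy goes into the panel, mixture unchanged
    members = [mutated if h.sample_id == target_id else h for h in db]
    members = [h for h in members if h.sample_id != other_id]
    return ReferencePanel(members, provenance="panel4"), truth


def private_site_report(
    mismatch_sites: Sequence[tuple[int, int]],
    panel: ReferencePanel,
) -> tuple[int, int]:
    """Count phasing errors at sites private to the mixture.

    ``mismatch_sites`` lists (site index, true allele) for every erroneously
    phased site of a deconvolution.  An error is *private* when no panel
    haplotype carries the true allele at that site, i.e. the panel could not
    have supplied it.  Returns (private errors, total errors) for pooling
    into an equality-of-proportions test.
    """
    mat = panel.matrix
    private = sum(
        1 for j, allele in mismatch_sites if not (mat[:, j] == allele).any()
    )
    return private, len(mismatch_sites)
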