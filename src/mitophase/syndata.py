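"""Synthetic haplogroup-structured mtDNA haplotype databases.

Emulates a large curated mitogenome database well enough to exercise the
whole deconvolution pipeline without any download: haplotypes fall into
haplogroups radiating from an rCRS-like root (a star phylogeny), each group
defined by a Poisson number of shared substitutions and each sample adding
Poisson-many private substitutions.  Defaults are calibrated so pairwise
Hamming distances span roughly 1-56 with a mean near 38.6, the distance
regime of real population mitogenome panels: with branch mean 17 and
private mean 4 over 8 groups of 4, mean pairwise distance is
``2*lambda_p + (between-group fraction) * 2*lambda_b ~ 38.7``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import empop
from .empop import Haplotype, SiteLocus, VariantToken, reference_base
from .mixtures import MixtureTruth, enumerate_pairs, make_truth

DEFAULT_RATIOS: tuple[tuple[int, int], ...] = (
    (50, 1), (19, 1), (9, 1), (4, 1), (2, 1), (1, 1),
)

_BASES = "ACGT"


@dataclass
class SynDBConfig:
    """Generator settings for one synthetic database.

    ``lambda_branch`` is the Poisson mean of haplogroup-defining variants,
    ``lambda_private`` the Poisson mean of per-sample private variants;
    positions are drawn without replacement within each lineage from the
    rCRS coordinate range.
    """

    n_haplogroups: int = 8
    samples_per_group: int = 4
    lambda_branch: float = 17.0
    lambda_private: float = 4.0
    site_pool: int = empop.RCRS_LENGTH
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda_branch <= 0 or self.lambda_private < 0:
            raise ValueError("Poisson means must be positive (private may be 0)")
        if self.n_haplogroups < 1 or self.samples_per_group < 1:
            raise ValueError("need at least one haplogroup and one sample per group")


def generate_db(cfg: SynDBConfig) -> list[tuple[str, list[VariantToken]]]:
    """Draw a synthetic database as EMPOP-style records, deterministic per seed.

    Each haplogroup g receives Poisson(lambda_branch) defining substitutions
    at fresh positions; each sample carries its group's variants plus
    Poisson(lambda_private) private ones.  Alternative bases are uniform
    over the three non-reference bases, so recurrent mutation across
    lineages (and hence multi-allelic filtering) is rare but possible, as in
    real databases.
    """
    rng = np.random.default_rng(cfg.seed)
    n_samples = cfg.n_haplogroups * cfg.samples_per_group
    budget = cfg.n_haplogroups * cfg.lambda_branch + n_samples * cfg.lambda_private
    if budget > cfg.site_pool / 2:
        raise ValueError("expected variant count exhausts the site pool")

    def draw_positions(n: int, used: set[int]) -> list[int]:
        out: list[int] = []
        while len(out) < n:
            pos = int(rng.integers(1, cfg.site_pool + 1))
            if pos not in used:
                used.add(pos)
                out.append(pos)
        return out

    def token(pos: int) -> VariantToken:
        ref = reference_base(pos)
        alt = rng.choice([b for b in _BASES if b != ref])
        return VariantToken(pos, "substitution", str(alt))

    records: list[tuple[str, list[VariantToken]]] = []
    for g in range(cfg.n_haplogroups):
        lineage_used: set[int] = set()
        n_branch = int(rng.poisson(cfg.lambda_branch))
        branch = [token(p) for p in draw_positions(n_branch, lineage_used)]
        for s in range(cfg.samples_per_group):
            n_priv = int(rng.poisson(cfg.lambda_private))
            used = set(lineage_used)
            private = [token(p) for p in draw_positions(n_priv, used)]
            tokens = sorted(branch + private, key=lambda t: t.position)
            records.append((f"HG{g + 1:02d}S{s + 1:02d}", tokens))
    return records


@dataclass
class FixtureSuite:
    """A bundled synthetic study: database, site universe, mixtures, panels.

    Panels are materialized on demand — eagerly building the four
    experimental designs plus every edit-distance panel for all 270
    mixtures would mostly be thrown away.
    """

    records: list[tuple[str, list[VariantToken]]]
    loci: list[SiteLocus]
    haplotypes: list[Haplotype]      # all database members on the universe
    sources: list[Haplotype]         # mixture-source subset
    background: list[Haplotype]      # the rest
    mixtures: list[MixtureTruth]

    def experimental_panel(self, truth: MixtureTruth, panel_type: int, seed: int = 0):
        """Panel design 1-4 for one mixture (returns panel, possibly new truth)."""
        from .panels import build_experimental_panel

        return build_experimental_panel(truth, self.haplotypes, panel_type, seed)

    def edit_distance_panel(self, truth: MixtureTruth, d: int, max_panel: int = 25):
        """Edit-distance-filtered panel for one mixture."""
        from .panels import PanelConfig, build_edit_distance_panel

        return build_edit_distance_panel(
            self.haplotypes, truth.counts, PanelConfig(d, max_panel)
        )


def make_fixture_suite(
    cfg: SynDBConfig | None = None,
    ratios: Sequence[tuple[int, int]] = DEFAULT_RATIOS,
    n_sources: int = 10,
    total_depth: int = 100,
) -> FixtureSuite:
    """Generate the standard study layout: sources + background + mixtures.

    With the default 32-member database, 10 mixture sources (spread across
    haplogroups, chosen round-robin) and 6 ratios, this yields
    C(10,2) * 6 = 270 mixtures; the remaining 22 members serve as panel
    background.
    """
    cfg = cfg or SynDBConfig()
    records = generate_db(cfg)
    loci, haplotypes = empop.build_site_universe(records)
    if n_sources > len(haplotypes):
        raise ValueError("more sources requested than database members")
    # round-robin across groups so sources span the haplogroup structure
    by_group: dict[str, list[Haplotype]] = {}
    for h in haplotypes:
        by_group.setdefault(h.sample_id[:4], []).append(h)
    sources: list[Haplotype] = []
    depth = 0
    while len(sources) < n_sources:
        for group in sorted(by_group):
            members = by_group[group]
            if depth < len(members) and len(sources) < n_sources:
                sources.append(members[depth])
        depth += 1
    source_ids = {h.sample_id for h in sources}
    background = [h for h in haplotypes if h.sample_id not in source_ids]
    specs = enumerate_pairs(sources, list(ratios), total_depth)
    mixtures = [make_truth(spec, loci) for spec in specs]
    return FixtureSuite(records, loci, haplotypes, sources, background, mixtures)
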