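"""End-to-end orchestration: the parameter grid and summary reports.

A grid run crosses every contributor pair and ratio with read depth, MCMC
step count and panel edit distance, executing
simulate -> panel -> deconvolve -> interpolate -> evaluate for each cell
and emitting one tidy row per run.  Per-run seeds are derived by hashing
the master seed with the run's identifying parameters, so any subset of the
grid reproduces independently.
"""

from __future__ import annotations

import hashlib
import itertools
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .empop import Haplotype, SiteLocus
from .engine import EngineConfig, run_mcmc
from .interpolate import InterpolationError, interpolate_minor
from .metrics import paired_distance, proportion_fit
from .mixtures import MixtureSpec, make_truth
from .panels import PanelConfig, ReferencePanel, build_edit_distance_panel

logger = logging.getLogger(__name__)


@dataclass
class GridSpec:
    """The experiment grid: depths x MCMC steps x panel edit distances."""

    depths: tuple[int, ...] = (50, 75, 100)
    steps: tuple[int, ...] = (3000, 6000, 9000)
    edit_distances: tuple[int, ...] = (1, 2, 4)
    ratios: tuple[tuple[int, int], ...] = ((50, 1), (19, 1), (9, 1), (4, 1), (2, 1), (1, 1))
    max_panel: int = 25

    def cells(self) -> list[tuple[tuple[int, int], int, int, int]]:
        """Deterministic enumeration of (ratio, depth, steps, d) cells."""
        return list(itertools.product(self.ratios, self.depths, self.steps, self.edit_distances))


def derive_seed(master_seed: int, *parts) -> int:
    """Stable per-run seed below 2^31 from the master seed and identifiers."""
    key = ":".join([str(master_seed), *map(str, parts)]).encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") % (2**31)


def run_one(
    spec: MixtureSpec,
    loci: Sequence[SiteLocus],
    panel: ReferencePanel,
    n_steps: int,
    seed: int,
    engine_kwargs: dict | None = None,
) -> dict:
    """Simulate one mixture, deconvolve it, interpolate, and evaluate."""
    truth = make_truth(spec, loci)
    cfg = EngineConfig(n_steps=n_steps, seed=seed, **(engine_kwargs or {}))
    result = run_mcmc(truth.counts, panel, cfg)

    est_major = Haplotype("est_major", result.haplotypes[0])
    est_minor = Haplotype("est_minor", result.haplotypes[1])
    raw = paired_distance(
        (truth.true_major, truth.true_minor),
        (est_major, est_minor),
        true_minor_proportion=spec.minor_proportion,
        est_minor_proportion=float(result.proportions[-1]),
    )
    try:
        interp = interpolate_minor(est_major, truth.counts)
        interp_minor = Haplotype("interp_minor", interp.alleles)
    except InterpolationError:
        interp_minor = est_minor  # major contradicted the counts; keep raw call
    interpolated = paired_distance(
        (truth.true_major, truth.true_minor),
        (est_major, interp_minor),
        true_minor_proportion=spec.minor_proportion,
        est_minor_proportion=float(result.proportions[-1]),
    )
    return {
        "major_id": spec.major.sample_id,
        "minor_id": spec.minor.sample_id,
        "ratio": f"{spec.ratio[0]}:{spec.ratio[1]}",
        "depth": spec.total_depth,
        "steps": n_steps,
        "seed": seed,
        "raw_total": raw.total,
        "raw_major_correct": raw.major_correct,
        "raw_minor_correct": raw.minor_correct,
        "interp_total": interpolated.total,
        "interp_major_correct": interpolated.major_correct,
        "interp_minor_correct": interpolated.minor_correct,
        "uncalled": interpolated.uncalled,
        "expected_minor": spec.minor_proportion,
        "observed_minor": float(result.proportions[-1]),
        "geweke_z": result.geweke_z,
        "converged": result.converged,
        "acceptance_rate": result.acceptance_rate,
    }


def run_grid(
    db: Sequence[Haplotype],
    sources: Sequence[Haplotype],
    loci: Sequence[SiteLocus],
    grid: GridSpec,
    master_seed: int = 0,
    engine_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Execute the full grid over all source pairs; one row per run.

    Per-run failures are logged and the grid continues; the output is a pure
    function of (database, grid, master seed).
    """
    pairs = [
        (a, b)
        for a, b in itertools.combinations(sorted(sources, key=lambda h: h.sample_id), 2)
    ]
    rows = []
    for ratio, depth, steps, d in grid.cells():
        for a, b in pairs:
            seed = derive_seed(
                master_seed, a.sample_id, b.sample_id, ratio, depth, steps, d
            )
            spec = MixtureSpec(a, b, ratio, depth)
            try:
                truth = make_truth(spec, loci)
                panel = build_edit_distance_panel(
                    db, truth.counts, PanelConfig(d, grid.max_panel)
                )
                row = run_one(spec, loci, panel, steps, seed, engine_kwargs)
            except Exception:  # noqa: BLE001 - resumable grid
                logger.exception(
                    "grid cell failed: %s+%s ratio=%s depth=%d steps=%d d=%d",
                    a.sample_id, b.sample_id, ratio, depth, steps, d,
                )
                continue
            row["edit_distance"] = d
            row["panel_size"] = len(panel)
            rows.append(row)
    return pd.DataFrame(rows)


def reference_panel_study(
    ratio: tuple[int, int],
    master_seed: int = 0,
    db_config=None,
    n_steps: int = 3000,
    total_depth: int = 100,
) -> list:
    """Deconvolve all 45 source-pair mixtures at one ratio, idealized panel.

    The panel contains the entire synthetic database — both contributors
    plus background haplotypes — the design that isolates the engine's
    ceiling accuracy from panel-composition effects.  Returns one
    :class:`~mitophase.metrics.AccuracyRecord` per mixture.
    """
    from .syndata import SynDBConfig, make_fixture_suite

    cfg = db_config or SynDBConfig(seed=derive_seed(master_seed, "db"))
    suite = make_fixture_suite(cfg, ratios=(ratio,), total_depth=total_depth)
    panel = ReferencePanel(suite.haplotypes, provenance="panel1")
    records = []
    for truth in suite.mixtures:
        seed = derive_seed(
            master_seed, "panel1", truth.spec.major.sample_id,
            truth.spec.minor.sample_id, ratio,
        )
        result = run_mcmc(
            truth.counts, panel, EngineConfig(n_steps=n_steps, seed=seed)
        )
        records.append(
            paired_distance(
                (truth.true_major, truth.true_minor),
                (
                    Haplotype("est_major", result.haplotypes[0]),
                    Haplotype("est_minor", result.haplotypes[1]),
                ),
                true_minor_proportion=truth.spec.minor_proportion,
                est_minor_proportion=float(result.proportions[-1]),
            )
        )
    return records


def tuned_panel_study(
    master_seed: int = 0,
    ratios: Sequence[tuple[int, int]] = ((50, 1), (19, 1), (9, 1), (4, 1), (2, 1)),
    n_per_ratio: int = 20,
    edit_distance: int = 4,
    max_panel: int = 25,
    n_steps: int = 3000,
    db_config=None,
) -> pd.DataFrame:
    """The production configuration: edit-distance panels + minor interpolation.

    For each (non-subequal) ratio a seeded subsample of the 45 source pairs
    is deconvolved against an edit-distance-filtered panel capped at the
    nearest ``max_panel`` database haplotypes, and the minor contributor is
    re-derived from the estimated major.  Returns one tidy row per run with
    raw and interpolated accuracies and minor-proportion estimates.
    """
    from .syndata import SynDBConfig, make_fixture_suite

    cfg = db_config or SynDBConfig(seed=derive_seed(master_seed, "db"))
    suite = make_fixture_suite(cfg, ratios=tuple(ratios))
    by_ratio: dict[tuple[int, int], list] = {}
    for truth in suite.mixtures:
        by_ratio.setdefault(truth.spec.ratio, []).append(truth)
    rows = []
    for ratio in ratios:
        pool = by_ratio[ratio]
        rng = np.random.default_rng(derive_seed(master_seed, "subsample", ratio))
        chosen = rng.choice(len(pool), size=min(n_per_ratio, len(pool)), replace=False)
        for i in sorted(chosen):
            truth = pool[i]
            panel = build_edit_distance_panel(
                suite.haplotypes, truth.counts, PanelConfig(edit_distance, max_panel)
            )
            seed = derive_seed(
                master_seed, "tuned", truth.spec.major.sample_id,
                truth.spec.minor.sample_id, ratio, edit_distance,
            )
            row = run_one(truth.spec, suite.loci, panel, n_steps, seed)
            row["edit_distance"] = edit_distance
            row["panel_size"] = len(panel)
            rows.append(row)
    return pd.DataFrame(rows)


def report(results: pd.DataFrame, plot_dir=None) -> dict[str, pd.DataFrame]:
    """Summarize a grid-results table into the study's standard views.

    Returns per-ratio deconvolution accuracy (raw and after interpolation)
    with 95% binomial CIs, the observed-vs-expected proportion R^2 per
    parameter value, and the per-ratio variance/SD of the estimated minor
    proportions.  When ``plot_dir`` is given, accuracy-by-ratio and
    estimated-vs-expected figures are written there as PNG.
    """
    if results.empty:
        raise ValueError("empty results table")
    from statsmodels.stats.proportion import proportion_confint

    acc_rows = []
    for ratio, sub in results.groupby("ratio", sort=False):
        n = len(sub)
        for label, col in (("raw", "raw_total"), ("interpolated", "interp_total")):
            k = int((sub[col] == 0).sum())
            lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
            acc_rows.append(
                {
                    "ratio": ratio,
                    "mode": label,
                    "n": n,
                    "accuracy_pct": 100.0 * k / n,
                    "ci_low_pct": 100.0 * lo,
                    "ci_high_pct": 100.0 * hi,
                }
            )
    accuracy = pd.DataFrame(acc_rows)

    r2_rows = []
    for param in ("depth", "steps", "edit_distance"):
        if param not in results:
            continue
        for value, sub in results.groupby(param):
            if sub["expected_minor"].nunique() < 2:
                logger.warning("skipping %s=%s: single expected ratio", param, value)
                continue
            fit = proportion_fit(sub["expected_minor"], sub["observed_minor"])
            r2_rows.append({"parameter": param, "value": value, "r_squared": fit.r_squared})
    r_squared = pd.DataFrame(r2_rows)

    spread = (
        results.groupby("ratio", sort=False)["observed_minor"]
        .agg(variance=lambda s: s.var(ddof=1), sd=lambda s: s.std(ddof=1))
        .reset_index()
    )

    if plot_dir is not None:
        _write_plots(results, accuracy, plot_dir)
    return {"accuracy": accuracy, "r_squared": r_squared, "proportion_spread": spread}


def _write_plots(results: pd.DataFrame, accuracy: pd.DataFrame, plot_dir) -> None:
    import pathlib

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plot_dir = pathlib.Path(plot_dir)
    plot_dir.mkdir(parents=True, exist_ok=True)

    fig, ax = plt.subplots(figsize=(7, 4))
    for mode, sub in accuracy.groupby("mode"):
        acc = sub["accuracy_pct"].to_numpy()
        err = [
            acc - sub["ci_low_pct"].to_numpy(),
            sub["ci_high_pct"].to_numpy() - acc,
        ]
        ax.errorbar(sub["ratio"].to_numpy(), acc, yerr=err, marker="o", label=mode)
    ax.set_xlabel("mixture ratio")
    ax.set_ylabel("deconvolution accuracy (%)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(plot_dir / "accuracy_by_ratio.png", dpi=150)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(results["expected_minor"], results["observed_minor"], s=12, alpha=0.6)
    lim = max(results["expected_minor"].max(), results["observed_minor"].max()) * 1.05
    ax.plot([0, lim], [0, lim], ls="--", c="grey")
    ax.set_xlabel("expected minor proportion")
    ax.set_ylabel("observed minor proportion")
    fig.tight_layout()
    fig.savefig(plot_dir / "observed_vs_expected.png", dpi=150)
    plt.close(fig)
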