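"""Scenario orchestration: replicate simulation, test execution and
type-I-error / power summarization.

A replicate is one simulated gene with one case/control sampling; the
scenario grid varies the migration rate between the demes, the share of
controls ascertained from deme B, and the hypothesis (no association vs a
logistic disease model on rare variants).  Empirical rejection rates at a
chosen significance level are reported with the binomial null-consistency
band used to judge type-I-error calibration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .inference import PermutationPlan, SeparationError, run_test
from .popsim import (
    DemographyConfig,
    EffectModel,
    SimulationError,
    sample_case_control,
    simulate_two_pop,
)
from .structure import ld_prune, pca_genotypes

__all__ = [
    "Scenario",
    "BackgroundPanel",
    "run_scenario",
    "rejection_rate",
    "summarize",
    "compare_scenarios",
]

log = logging.getLogger(__name__)

DEFAULT_METHODS = ("cast", "sum", "skat")


@dataclass(frozen=True)
class Scenario:
    """One cell of the simulation grid.

    ``pct_controls_b`` is the fraction of controls drawn from deme B
    (0, 0.25, 0.5, 0.75 or 1.0 in the study grid).  Corrections are
    disabled at 100% controls from B: there the ancestry covariates fully
    explain the phenotype and the null fit separates.
    """

    migration_rate: float
    pct_controls_b: float = 0.0
    hypothesis: str = "H0"
    n_cases: int = 1_000
    n_controls: int = 1_000
    methods: tuple[str, ...] = DEFAULT_METHODS
    corrections: tuple[str, ...] = ("none",)
    n_pcs: int = 2
    replicates: int = 100

    def __post_init__(self) -> None:
        if self.hypothesis not in ("H0", "H1"):
            raise ValueError("hypothesis must be 'H0' or 'H1'")
        if not 0.0 <= self.pct_controls_b <= 1.0:
            raise ValueError("pct_controls_b must lie in [0, 1]")
        bad = set(self.corrections) - {"none", "pca_model", "pca_perm"}
        if bad:
            raise ValueError(f"unknown corrections: {sorted(bad)}")
        if self.pct_controls_b == 1.0 and set(self.corrections) != {"none"}:
            raise ValueError(
                "corrections are disabled when all controls come from deme B "
                "(covariates would fully explain the phenotype)"
            )
        if self.replicates < 1:
            raise ValueError("replicates must be positive")


@dataclass
class BackgroundPanel:
    """Pruned common-variant haplotypes from a pool of background genes.

    Rows are panel haplotypes (deme A first, then deme B); columns are the
    common variants (deme-A MAF >= 5%) surviving LD pruning, concatenated
    over the gene pool.  Sampled individuals keep their panel haplotype
    indices across genes, so their genome-wide genotypes — and hence
    ancestry PCs — can be reconstructed for any case/control sampling.
    """

    haplotypes: np.ndarray  # (2 * deme_haplotypes, C) uint8
    n_deme_a: int

    @classmethod
    def from_demography(
        cls,
        demography: DemographyConfig,
        n_genes: int,
        seed: int,
        maf_min: float = 0.05,
        r2_max: float = 0.2,
    ) -> "BackgroundPanel":
        dem = replace(demography, n_genes=n_genes)
        panels = simulate_two_pop(dem, seed=seed, demes=("A", "B"), on_empty="skip")
        blocks = []
        nh = demography.deme_haplotypes
        for panel in panels:
            if panel.n_sites == 0:
                continue
            maf_a = panel.maf_a()
            # genotype matrix of deme-A panel diploids, for the r^2 stage
            ga = panel.haplotypes_a[0::2] + panel.haplotypes_a[1::2]
            kept = ld_prune(ga, ref_maf=maf_a, maf_min=maf_min, r2_max=r2_max)
            if kept.size == 0:
                continue
            h = np.vstack([panel.haplotypes_a[:, kept], panel.haplotypes_b[:, kept]])
            blocks.append(h.astype(np.uint8))
        if not blocks:
            raise SimulationError("background pool produced no common variants")
        return cls(haplotypes=np.concatenate(blocks, axis=1), n_deme_a=nh)

    @property
    def n_variants(self) -> int:
        return int(self.haplotypes.shape[1])

    def genotypes_for(self, haplotype_indices: np.ndarray) -> np.ndarray:
        """Background genotypes for individuals given (N, 2) global
        haplotype indices (deme-B ids offset by the deme-A panel size)."""
        idx = np.asarray(haplotype_indices)
        return (
            self.haplotypes[idx[:, 0]].astype(np.int16)
            + self.haplotypes[idx[:, 1]]
        )

    def principal_components(self, haplotype_indices: np.ndarray, K: int) -> np.ndarray:
        G = self.genotypes_for(haplotype_indices)
        return pca_genotypes(G, K=K).coordinates


def run_scenario(
    scenario: Scenario,
    demography: DemographyConfig,
    master_seed: int,
    background: BackgroundPanel | None = None,
    effects: EffectModel | None = None,
    plan: PermutationPlan | None = None,
    rare_threshold: float = 0.01,
    use_permutation: bool | None = None,
) -> pd.DataFrame:
    """Simulate and test ``scenario.replicates`` independent genes.

    Returns a tidy table with one row per (replicate, method, correction);
    per-replicate failures (no analyzable variants, separation) are logged,
    excluded and counted in ``df.attrs["failures"]``.
    """
    needs_pcs = any(c != "none" for c in scenario.corrections)
    if needs_pcs and background is None:
        raise ValueError("corrections require a BackgroundPanel for the PCs")
    if scenario.hypothesis == "H1" and effects is None:
        effects = EffectModel()
    if scenario.hypothesis == "H0":
        effects = None
    dem = replace(demography, migration_rate=scenario.migration_rate, n_genes=1)
    demes = ("A", "B") if scenario.pct_controls_b > 0 else ("A",)

    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(scenario.replicates)
    rows: list[dict] = []
    failures: list[tuple[int, str]] = []
    for rep, child in enumerate(children):
        rng = np.random.default_rng(child)
        try:
            panel = simulate_two_pop(
                dem, seed=int(rng.integers(1, 2**31 - 1)), demes=demes
            )[0]
            gmx, phen = sample_case_control(
                panel,
                n_cases=scenario.n_cases,
                n_controls=scenario.n_controls,
                pct_controls_b=scenario.pct_controls_b,
                effects=effects,
                seed=rng,
                rare_threshold=rare_threshold,
            )
        except SimulationError as exc:
            failures.append((rep, str(exc)))
            continue
        view = gmx.analysis_view()
        if view.n_variants == 0:
            failures.append((rep, "no analyzable rare variants"))
            continue
        Z = None
        if needs_pcs:
            Z = background.principal_components(
                gmx.haplotype_indices, K=scenario.n_pcs
            )
        for correction in scenario.corrections:
            for method in scenario.methods:
                try:
                    res = run_test(
                        method,
                        view.genotypes,
                        phen.y,
                        positions=view.positions,
                        gene_length=float(gmx.region_length_bp),
                        Z=Z if correction != "none" else None,
                        correction=correction,
                        plan=plan,
                        rng=rng,
                        use_permutation=use_permutation,
                    )
                except SeparationError as exc:
                    failures.append((rep, f"{method}/{correction}: {exc}"))
                    continue
                rows.append(
                    {
                        "replicate": rep,
                        "migration_rate": scenario.migration_rate,
                        "pct_controls_b": scenario.pct_controls_b,
                        "hypothesis": scenario.hypothesis,
                        "method": method,
                        "correction": correction,
                        "statistic": res.statistic,
                        "p": res.p,
                        "permutations": res.permutations,
                        "n_variants": view.n_variants,
                    }
                )
    if failures:
        log.warning("run_scenario: %d replicate failures", len(failures))
    df = pd.DataFrame(rows)
    df.attrs["failures"] = failures
    df.attrs["master_seed"] = master_seed
    return df


def rejection_rate(
    p_values: np.ndarray, alpha: float = 0.05
) -> tuple[float, float, float]:
    """Empirical rejection rate with the binomial null-consistency band.

    The band is the 95% normal-approximation interval of a
    Binomial(n, alpha) proportion, centered at alpha: rates inside it are
    consistent with a calibrated test at level alpha.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("rejection_rate requires at least one p-value")
    rate = float((p <= alpha).mean())
    half = 1.96 * np.sqrt(alpha * (1.0 - alpha) / p.size)
    return rate, alpha - half, alpha + half


def _wilson_ci(k: int, n: int, z: float = 1.96) -> tuple[float, float]:
    if n == 0:
        return (0.0, 1.0)
    phat = k / n
    denom = 1.0 + z * z / n
    center = (phat + z * z / (2 * n)) / denom
    half = z * np.sqrt(phat * (1 - phat) / n + z * z / (4 * n * n)) / denom
    return center - half, center + half


def summarize(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-(scenario, method, correction) rejection rates at ``alpha``.

    Columns include the null-consistency band (centered at alpha) and a
    rate-centered Wilson 95% CI.
    """
    if results.empty:
        raise ValueError("no results to summarize")
    keys = [
        c
        for c in ("migration_rate", "pct_controls_b", "hypothesis", "method", "correction")
        if c in results.columns
    ]
    out = []
    for key_vals, grp in results.groupby(keys, sort=True):
        rate, lo, hi = rejection_rate(grp["p"].to_numpy(), alpha)
        k = int((grp["p"] <= alpha).sum())
        n = len(grp)
        wlo, whi = _wilson_ci(k, n)
        rec = dict(zip(keys, key_vals if isinstance(key_vals, tuple) else (key_vals,)))
        rec.update(
            rejection_rate=rate,
            n_replicates=n,
            null_band_low=lo,
            null_band_high=hi,
            ci_low=wlo,
            ci_high=whi,
            alpha=alpha,
        )
        out.append(rec)
    return pd.DataFrame(out)


def compare_scenarios(*tables: pd.DataFrame) -> pd.DataFrame:
    """Stack per-scenario summaries into one tidy long-format table."""
    if not tables:
        raise ValueError("no tables given")
    methods = {tuple(sorted(t["method"].unique())) for t in tables}
    if len(methods) > 1:
        raise ValueError("summaries do not share a common method set")
    return pd.concat(tables, ignore_index=True)


def plot_rejection_rates(summary: pd.DataFrame, path: str | None = None):
    """Bar chart of rejection rates by method, one panel per scenario."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    keys = [k for k in ("migration_rate", "pct_controls_b") if k in summary.columns]
    groups = list(summary.groupby(keys)) if keys else [((), summary)]
    fig, axes = plt.subplots(
        1, len(groups), figsize=(4 * len(groups), 3.2), squeeze=False, sharey=True
    )
    for ax, (key, grp) in zip(axes[0], groups):
        labels = grp["method"] + np.where(
            grp["correction"].ne("none"), "+" + grp["correction"], ""
        )
        ax.bar(labels, grp["rejection_rate"])
        ax.axhline(grp["alpha"].iloc[0], color="red", lw=1)
        ax.axhline(grp["null_band_low"].iloc[0], color="blue", lw=0.8, ls="--")
        ax.axhline(grp["null_band_high"].iloc[0], color="blue", lw=0.8, ls="--")
        ax.set_title(str(key))
        ax.tick_params(axis="x", rotation=70)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
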