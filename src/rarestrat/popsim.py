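"""Coalescent simulation of a two-deme demography and case/control sampling.

The demographic model is a single ancestral lineage that splits, a configurable
number of generations before present, into two demes A and B connected by
symmetric migration.  Per-gene haplotype panels are simulated with msprime;
diploid genotypes are built by pairing panel haplotypes, and case/control
samples are drawn either blindly (null hypothesis) or through a logistic
disease model on the rare variants of the gene (alternative hypothesis).

Variants are classified as rare or common according to their minor allele
frequency in the *full* deme-A panel, not in the drawn sample: cases always
originate from deme A, so deme A is the frequency reference population.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import msprime
import numpy as np

__all__ = [
    "DemographyConfig",
    "HaplotypePanel",
    "GenotypeMatrix",
    "PhenotypePanel",
    "EffectModel",
    "simulate_two_pop",
    "haplotypes_to_genotypes",
    "classify_variants",
    "draw_effect_sizes",
    "sample_case_control",
]

#: Minor-allele-frequency floor above which a variant counts as common
#: for structure analyses (LD pruning, PCA, F_ST).
COMMON_MAF_MIN = 0.05


class SimulationError(RuntimeError):
    """Raised when a simulation request cannot be satisfied."""


@dataclass(frozen=True)
class DemographyConfig:
    """Parameters of the two-deme split demography.

    Parameters
    ----------
    split_time_generations:
        Generations before present at which demes A and B split from the
        ancestral population.
    deme_haplotypes:
        Number of haplotypes sampled per deme to form the panel from which
        individuals are drawn (the census panel).
    deme_effective_diploids:
        Coalescent (effective) size of each deme, in diploid individuals.
        The default of 10,000 diploids per deme is a calibration choice: it
        reproduces the between-deme differentiation regime this package
        targets (multi-locus Weir-Cockerham F_ST near 1.2e-3 at migration
        rate 0.01 for an 80-generation split; see docs/methods.md).
    ancestral_diploids:
        Effective size of the ancestral population (diploids).
    expansion:
        Optional ``(time_generations, size_before_diploids)`` step change:
        before ``time_generations`` ago the ancestral population had size
        ``size_before_diploids``.  ``None`` keeps a constant ancestral size.
    migration_rate:
        Symmetric per-haplotype per-generation migration probability between
        A and B, applied from the split to the present.
    region_length_bp:
        Length of the simulated gene region in base pairs.  The 10 kb default
        yields on the order of 31 analyzed rare variants per gene for a
        2,000-individual sample under the default mutation rate.
    mutation_rate, recombination_rate:
        Per-bp per-generation rates.
    n_genes:
        Number of independent gene panels produced per call.
    """

    split_time_generations: int = 80
    deme_haplotypes: int = 10_000
    deme_effective_diploids: int = 10_000
    ancestral_diploids: int = 10_000
    expansion: tuple[float, float] | None = None
    migration_rate: float = 0.0
    region_length_bp: int = 10_000
    mutation_rate: float = 1.5e-8
    recombination_rate: float = 1.0e-8
    n_genes: int = 1

    def __post_init__(self) -> None:
        if self.split_time_generations <= 0:
            raise ValueError("split_time_generations must be positive")
        if not 0.0 <= self.migration_rate <= 0.5:
            raise ValueError("migration_rate must lie in [0, 0.5]")
        if self.deme_haplotypes % 2:
            raise ValueError("deme_haplotypes must be even")
        if self.region_length_bp <= 0 or self.n_genes <= 0:
            raise ValueError("region_length_bp and n_genes must be positive")

    def to_msprime(self) -> msprime.Demography:
        dem = msprime.Demography()
        dem.add_population(name="A", initial_size=self.deme_effective_diploids)
        dem.add_population(name="B", initial_size=self.deme_effective_diploids)
        dem.add_population(name="ANC", initial_size=self.ancestral_diploids)
        if self.migration_rate > 0:
            dem.set_symmetric_migration_rate(["A", "B"], self.migration_rate)
        dem.add_population_split(
            time=self.split_time_generations, derived=["A", "B"], ancestral="ANC"
        )
        if self.expansion is not None:
            t_exp, size_before = self.expansion
            if t_exp <= self.split_time_generations:
                raise ValueError("expansion time must predate the split")
            dem.add_population_parameters_change(
                time=t_exp, population="ANC", initial_size=size_before
            )
        dem.sort_events()
        return dem


@dataclass
class HaplotypePanel:
    """Binary haplotype panels for one simulated gene.

    ``haplotypes_a``/``haplotypes_b`` are (haplotypes x sites) 0/1 arrays of
    derived-allele indicators; ``positions`` are 1-based bp coordinates,
    strictly increasing.  ``haplotypes_b`` may be ``None`` when only deme A
    was sampled.
    """

    haplotypes_a: np.ndarray
    haplotypes_b: np.ndarray | None
    positions: np.ndarray
    region_length_bp: int

    def __post_init__(self) -> None:
        if self.haplotypes_a.shape[1] != self.positions.shape[0]:
            raise ValueError("positions length must match site count")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")

    @property
    def n_sites(self) -> int:
        return int(self.positions.shape[0])

    def frequency_a(self) -> np.ndarray:
        """Derived-allele frequency per site in the full deme-A panel."""
        return self.haplotypes_a.mean(axis=0)

    def maf_a(self) -> np.ndarray:
        """Minor-allele frequency per site in the full deme-A panel."""
        f = self.frequency_a()
        return np.minimum(f, 1.0 - f)


@dataclass
class GenotypeMatrix:
    """Diploid minor-allele counts for N individuals at P variants.

    The minor allele is defined relative to the full deme-A panel: columns
    whose derived allele exceeds 50% frequency in deme A are flipped, so
    ``genotypes`` counts copies of the allele that is minor in deme A.
    """

    genotypes: np.ndarray  # (N, P) int8
    positions: np.ndarray  # (P,) 1-based bp
    maf_a: np.ndarray  # (P,) panel-A minor allele frequency
    region_length_bp: int
    rare_threshold: float = 0.01
    origin: np.ndarray | None = None  # per-individual deme label "A"/"B"
    haplotype_indices: np.ndarray | None = None  # (N, 2) panel haplotype ids

    def __post_init__(self) -> None:
        g = np.asarray(self.genotypes)
        if g.size and (g.min() < 0 or g.max() > 2):
            raise ValueError("genotype entries must lie in {0, 1, 2}")

    @property
    def n_individuals(self) -> int:
        return int(self.genotypes.shape[0])

    @property
    def n_variants(self) -> int:
        return int(self.genotypes.shape[1])

    @property
    def rare_mask(self) -> np.ndarray:
        rare, _ = classify_variants(self.maf_a, self.rare_threshold)
        return rare

    @property
    def common_mask(self) -> np.ndarray:
        _, common = classify_variants(self.maf_a, self.rare_threshold)
        return common

    def analysis_mask(self) -> np.ndarray:
        """Rare variants that are polymorphic in the drawn sample."""
        counts = self.genotypes.sum(axis=0)
        poly = (counts > 0) & (counts < 2 * self.n_individuals)
        return self.rare_mask & poly

    def analysis_view(self) -> "GenotypeMatrix":
        """Submatrix of analyzed (rare, sample-polymorphic) variants."""
        keep = self.analysis_mask()
        return GenotypeMatrix(
            genotypes=self.genotypes[:, keep],
            positions=self.positions[keep],
            maf_a=self.maf_a[keep],
            region_length_bp=self.region_length_bp,
            rare_threshold=self.rare_threshold,
            origin=self.origin,
            haplotype_indices=self.haplotype_indices,
        )


@dataclass
class PhenotypePanel:
    """Case/control labels with population of origin."""

    y: np.ndarray  # (N,) 0/1
    origin: np.ndarray  # (N,) "A"/"B"

    def __post_init__(self) -> None:
        if self.y.shape != self.origin.shape:
            raise ValueError("y and origin must have equal length")
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("phenotypes must be 0/1")

    @property
    def n_cases(self) -> int:
        return int(self.y.sum())

    @property
    def n_controls(self) -> int:
        return int(self.y.size - self.y.sum())


@dataclass(frozen=True)
class EffectModel:
    """Logistic disease model acting on the rare variants of a gene.

    Half of the rare variants (by default) are deleterious with a common
    odds ratio; the remainder have no effect.  ``alpha0`` is the baseline
    log-odds of disease for a carrier of no risk alleles; it controls
    sampling efficiency, not the estimands, because case/control quotas are
    fixed.
    """

    prop_deleterious: float = 0.5
    odds_ratio: float = 1.5
    alpha0: float = math.log(0.1 / 0.9)  # logit of 10% baseline prevalence

    def __post_init__(self) -> None:
        if not 0.0 <= self.prop_deleterious <= 1.0:
            raise ValueError("prop_deleterious must lie in [0, 1]")
        if self.odds_ratio <= 0:
            raise ValueError("odds_ratio must be positive")


def _seeds(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(1, 2**31 - 1, size=n)


def simulate_two_pop(
    demography: DemographyConfig,
    seed: int,
    demes: Sequence[str] = ("A", "B"),
    on_empty: str = "resimulate",
    max_retries: int = 100,
) -> list[HaplotypePanel]:
    """Simulate independent per-gene haplotype panels under the two-deme model.

    Parameters
    ----------
    demography:
        Model parameters; ``demography.n_genes`` panels are returned.
    seed:
        Master seed; identical seeds give bit-identical panels.
    demes:
        Which demes to sample panels for.  Sampling only ``("A",)`` halves
        the work for scenarios without deme-B individuals.
    on_empty:
        Policy when a gene has zero segregating sites: ``"resimulate"``
        draws a fresh gene, ``"skip"`` omits it, ``"keep"`` returns an
        empty panel.
    """
    if on_empty not in ("resimulate", "skip", "keep"):
        raise ValueError("on_empty must be 'resimulate', 'skip' or 'keep'")
    rng = np.random.default_rng(seed)
    dem = demography.to_msprime()
    sample_sets = {d: demography.deme_haplotypes // 2 for d in demes}
    panels: list[HaplotypePanel] = []
    produced = 0
    retries = 0
    while produced < demography.n_genes:
        anc_seed, mut_seed = _seeds(rng, 2)
        ts = msprime.sim_ancestry(
            samples=sample_sets,
            demography=dem,
            sequence_length=demography.region_length_bp,
            recombination_rate=demography.recombination_rate,
            random_seed=anc_seed,
        )
        ts = msprime.sim_mutations(
            ts,
            rate=demography.mutation_rate,
            random_seed=mut_seed,
            model=msprime.BinaryMutationModel(),
        )
        panel = _panel_from_ts(ts, demography, demes)
        if panel.n_sites == 0:
            if on_empty == "resimulate":
                retries += 1
                if retries > max_retries:
                    raise SimulationError(
                        "exceeded retry budget while resimulating empty genes"
                    )
                continue
            if on_empty == "skip":
                produced += 1
                continue
        panels.append(panel)
        produced += 1
    return panels


def _panel_from_ts(
    ts, demography: DemographyConfig, demes: Sequence[str]
) -> HaplotypePanel:
    G = ts.genotype_matrix()  # (sites, haplotypes), 0/1 under the binary model
    positions = np.array([int(s.position) + 1 for s in ts.sites()], dtype=np.int64)
    # Collapse duplicate discrete positions (possible with recurrent mutation)
    # by keeping the first site at each coordinate.
    _, first = np.unique(positions, return_index=True)
    G = G[first]
    positions = positions[first]
    # Drop non-segregating sites (union of sampled demes).
    seg = (G.sum(axis=1) > 0) & (G.sum(axis=1) < G.shape[1])
    G = G[seg]
    positions = positions[seg]
    nh = demography.deme_haplotypes
    ha = G[:, :nh].T.astype(np.uint8)
    hb = None
    if len(demes) > 1:
        hb = G[:, nh : 2 * nh].T.astype(np.uint8)
    return HaplotypePanel(
        haplotypes_a=np.ascontiguousarray(ha),
        haplotypes_b=None if hb is None else np.ascontiguousarray(hb),
        positions=positions,
        region_length_bp=demography.region_length_bp,
    )


def classify_variants(
    reference_maf_a: np.ndarray, rare_threshold: float = 0.01
) -> tuple[np.ndarray, np.ndarray]:
    """Rare/common masks from deme-A panel minor allele frequencies.

    Rare: segregating in deme A with MAF at or below the threshold.
    Common: MAF at or above 5% (the structure-analysis set).
    Sites monomorphic in deme A are neither.
    """
    maf = np.asarray(reference_maf_a, dtype=float)
    rare = (maf > 0.0) & (maf <= rare_threshold)
    common = maf >= COMMON_MAF_MIN
    return rare, common


def _genotypes_from_pairs(
    panel: HaplotypePanel, pairs_a: np.ndarray | None, pairs_b: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sum haplotype pairs into genotypes; recode to deme-A minor allele."""
    freq_a = panel.frequency_a()
    flip = freq_a > 0.5
    blocks = []
    origins = []
    index_blocks = []
    if pairs_a is not None and len(pairs_a):
        g = panel.haplotypes_a[pairs_a[:, 0]] + panel.haplotypes_a[pairs_a[:, 1]]
        blocks.append(g)
        origins.append(np.full(len(pairs_a), "A"))
        index_blocks.append(pairs_a)
    if pairs_b is not None and len(pairs_b):
        if panel.haplotypes_b is None:
            raise ValueError("panel has no deme-B haplotypes")
        g = panel.haplotypes_b[pairs_b[:, 0]] + panel.haplotypes_b[pairs_b[:, 1]]
        blocks.append(g)
        origins.append(np.full(len(pairs_b), "B"))
        # Deme-B haplotype ids are offset so indices are globally unique.
        index_blocks.append(pairs_b + panel.haplotypes_a.shape[0])
    G = np.concatenate(blocks).astype(np.int8)
    G[:, flip] = 2 - G[:, flip]
    origin = np.concatenate(origins)
    idx = np.concatenate(index_blocks)
    return G, origin, idx


def haplotypes_to_genotypes(
    panel: HaplotypePanel,
    n_a: int,
    n_b: int = 0,
    seed: int | np.random.Generator = 0,
    rare_threshold: float = 0.01,
) -> GenotypeMatrix:
    """Pair disjoint random panel haplotypes into diploid individuals.

    ``n_a`` (``n_b``) individuals are formed from deme A (B); each haplotype
    is used at most once, so at most ``deme_haplotypes/2`` individuals per
    deme are available.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    nh = panel.haplotypes_a.shape[0]
    if 2 * n_a > nh:
        raise ValueError(f"requested {n_a} deme-A diploids but only {nh // 2} available")
    pairs_a = rng.permutation(nh)[: 2 * n_a].reshape(-1, 2) if n_a else None
    pairs_b = None
    if n_b:
        if panel.haplotypes_b is None:
            raise ValueError("panel has no deme-B haplotypes")
        nhb = panel.haplotypes_b.shape[0]
        if 2 * n_b > nhb:
            raise ValueError(f"requested {n_b} deme-B diploids but only {nhb // 2} available")
        pairs_b = rng.permutation(nhb)[: 2 * n_b].reshape(-1, 2)
    G, origin, idx = _genotypes_from_pairs(panel, pairs_a, pairs_b)
    return GenotypeMatrix(
        genotypes=G,
        positions=panel.positions.copy(),
        maf_a=panel.maf_a(),
        region_length_bp=panel.region_length_bp,
        rare_threshold=rare_threshold,
        origin=origin,
        haplotype_indices=idx,
    )


def draw_effect_sizes(
    rare_count: int, model: EffectModel, seed: int | np.random.Generator
) -> np.ndarray:
    """Per-rare-variant log odds ratios under the disease model.

    Exactly ``round(prop_deleterious * rare_count)`` variants (round half
    up), chosen uniformly at random, receive ``log(odds_ratio)``; the rest 0.
    """
    if rare_count < 1:
        raise ValueError("need at least one rare variant under H1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n_del = int(math.floor(model.prop_deleterious * rare_count + 0.5))
    beta = np.zeros(rare_count)
    chosen = rng.choice(rare_count, size=n_del, replace=False)
    beta[chosen] = math.log(model.odds_ratio)
    return beta


def _expit(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def sample_case_control(
    panel: HaplotypePanel,
    n_cases: int = 1_000,
    n_controls: int = 1_000,
    pct_controls_b: float = 0.0,
    effects: EffectModel | None = None,
    seed: int | np.random.Generator = 0,
    rare_threshold: float = 0.01,
    max_batches: int = 500,
) -> tuple[GenotypeMatrix, PhenotypePanel]:
    """Draw a case/control sample from the two-deme panels.

    Cases always come from deme A.  ``pct_controls_b`` (0, 25, 50, 75 or 100,
    as a fraction in [0, 1]) of the controls come from deme B, the rest from
    deme A; the deme-B quota is met exactly.  Without an effect model (H0)
    individuals are labeled independently of genotype.  With an effect model
    (H1), candidate deme-A individuals are formed by random mating (random
    haplotype pairing) and accepted as cases/controls with probability given
    by the logistic model on their rare-variant genotypes, repeating until
    the quotas are filled.
    """
    if not 0.0 <= pct_controls_b <= 1.0:
        raise ValueError("pct_controls_b must lie in [0, 1]")
    n_b = int(round(pct_controls_b * n_controls))
    n_ctrl_a = n_controls - n_b
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    nh = panel.haplotypes_a.shape[0]
    if effects is None:
        n_a = n_cases + n_ctrl_a
        if 2 * n_a > nh:
            raise ValueError("deme-A panel too small for the requested sample")
        perm = rng.permutation(nh)
        pairs_a = perm[: 2 * n_a].reshape(-1, 2)
        pairs_case = pairs_a[:n_cases]
        pairs_ctrl_a = pairs_a[n_cases:]
    else:
        pairs_case, pairs_ctrl_a = _sample_h1_from_a(
            panel, n_cases, n_ctrl_a, effects, rng, rare_threshold, max_batches
        )
    pairs_b = None
    if n_b:
        if panel.haplotypes_b is None:
            raise ValueError("scenario requires deme-B controls but panel lacks deme B")
        nhb = panel.haplotypes_b.shape[0]
        pairs_b = rng.permutation(nhb)[: 2 * n_b].reshape(-1, 2)

    pairs_a_all = np.concatenate([pairs_case, pairs_ctrl_a]) if n_ctrl_a else pairs_case
    G, origin, idx = _genotypes_from_pairs(panel, pairs_a_all, pairs_b)
    y = np.zeros(G.shape[0], dtype=np.int8)
    y[:n_cases] = 1
    gmx = GenotypeMatrix(
        genotypes=G,
        positions=panel.positions.copy(),
        maf_a=panel.maf_a(),
        region_length_bp=panel.region_length_bp,
        rare_threshold=rare_threshold,
        origin=origin,
        haplotype_indices=idx,
    )
    return gmx, PhenotypePanel(y=y, origin=origin)


def _sample_h1_from_a(
    panel: HaplotypePanel,
    n_cases: int,
    n_ctrl_a: int,
    effects: EffectModel,
    rng: np.random.Generator,
    rare_threshold: float,
    max_batches: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Rejection-sample deme-A cases and controls under the logistic model."""
    rare, _ = classify_variants(panel.maf_a(), rare_threshold)
    rare_idx = np.flatnonzero(rare)
    if rare_idx.size == 0:
        raise SimulationError("no rare variants in deme A: H1 model undefined")
    beta = draw_effect_sizes(rare_idx.size, effects, rng)
    freq_a = panel.frequency_a()[rare_idx]
    flip = freq_a > 0.5
    hap_rare = panel.haplotypes_a[:, rare_idx].astype(np.float64)

    nh = panel.haplotypes_a.shape[0]
    batch = max(256, 2 * (n_cases + n_ctrl_a))
    cases: list[np.ndarray] = []
    ctrls: list[np.ndarray] = []
    n_case_have = n_ctrl_have = 0
    for _ in range(max_batches):
        cand = rng.integers(0, nh, size=(batch, 2))
        same = cand[:, 0] == cand[:, 1]
        cand[same, 1] = (cand[same, 1] + 1) % nh
        g = hap_rare[cand[:, 0]] + hap_rare[cand[:, 1]]
        g[:, flip] = 2.0 - g[:, flip]
        p = _expit(effects.alpha0 + g @ beta)
        is_case = rng.random(batch) < p
        if n_case_have < n_cases:
            take = cand[is_case][: n_cases - n_case_have]
            cases.append(take)
            n_case_have += len(take)
        if n_ctrl_have < n_ctrl_a:
            take = cand[~is_case][: n_ctrl_a - n_ctrl_have]
            ctrls.append(take)
            n_ctrl_have += len(take)
        if n_case_have >= n_cases and n_ctrl_have >= n_ctrl_a:
            break
    else:
        raise SimulationError(
            "case/control quotas not reached within the iteration cap; "
            "check alpha0 and the effect model"
        )
    pairs_case = np.concatenate(cases) if cases else np.empty((0, 2), dtype=np.int64)
    pairs_ctrl = np.concatenate(ctrls) if ctrls else np.empty((0, 2), dtype=np.int64)
    return pairs_case, pairs_ctrl
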