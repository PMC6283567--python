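"""Readers, writers and run configuration.

Genotypes travel as VCF (one file per gene, phased GT, INFO field ``MAFA``
carrying the deme-A panel minor allele frequency), phenotypes/covariates as
tab-separated tables, results as CSV, and run configuration as YAML.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
import yaml

from .popsim import DemographyConfig, GenotypeMatrix, PhenotypePanel

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_phenotypes",
    "read_phenotypes",
    "write_results",
    "read_results",
    "RunConfig",
]


class VcfFormatError(ValueError):
    """Malformed or unsupported VCF content."""


def write_vcf(gmx: GenotypeMatrix, path: str | Path, contig: str = "gene1") -> None:
    """Write simulated genotypes as an uncompressed VCF.

    Genotype counts are emitted as phased GT pairs (0|0, 0|1, 1|1; the
    phase itself carries no information here) with REF=A, ALT=C
    placeholder alleles and the deme-A panel MAF in INFO/MAFA.
    """
    path = Path(path)
    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={contig},length={gmx.region_length_bp}>")
    header.add_line(
        '##INFO=<ID=MAFA,Number=1,Type=Float,Description='
        '"Minor allele frequency in the full deme-A panel">'
    )
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    n = gmx.n_individuals
    for i in range(n):
        header.add_sample(f"ind{i}")
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for j in range(gmx.n_variants):
            rec = vf.new_record(
                contig=contig,
                start=int(gmx.positions[j]) - 1,
                stop=int(gmx.positions[j]),
                alleles=("A", "C"),
            )
            rec.info["MAFA"] = float(gmx.maf_a[j])
            col = gmx.genotypes[:, j]
            for i in range(n):
                g = int(col[i])
                rec.samples[i]["GT"] = (0, 0) if g == 0 else ((0, 1) if g == 1 else (1, 1))
                rec.samples[i].phased = True
            vf.write(rec)


def read_vcf(path: str | Path, rare_threshold: float = 0.01) -> GenotypeMatrix:
    """Read bi-allelic SNVs with GT into a genotype matrix.

    Counts are of the allele that is minor according to INFO/MAFA when
    present, else minor in the sample.  Multi-allelic records and records
    without GT are rejected with the record position in the message.
    """
    path = Path(path)
    positions: list[int] = []
    maf: list[float] = []
    cols: list[np.ndarray] = []
    region_length = 0
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for contig in vf.header.contigs.values():
            region_length = max(region_length, contig.length or 0)
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                raise VcfFormatError(
                    f"multi-allelic or ALT-less record at position {rec.pos}"
                )
            counts = np.empty(len(samples), dtype=np.int8)
            for i, s in enumerate(samples):
                gt = rec.samples[s].get("GT")
                if gt is None or any(a is None for a in gt):
                    raise VcfFormatError(f"missing GT at position {rec.pos}")
                counts[i] = sum(gt)
            f_alt = counts.sum() / (2.0 * len(samples))
            info_maf = rec.info.get("MAFA")
            if info_maf is not None:
                m = float(info_maf)
            else:
                m = min(f_alt, 1.0 - f_alt)
                if f_alt > 0.5:
                    counts = 2 - counts
            positions.append(rec.pos)
            maf.append(m)
            cols.append(counts)
    if not cols:
        raise VcfFormatError(f"no variant records in {path}")
    G = np.column_stack(cols)
    return GenotypeMatrix(
        genotypes=G,
        positions=np.asarray(positions, dtype=np.int64),
        maf_a=np.asarray(maf, dtype=float),
        region_length_bp=int(region_length or max(positions)),
        rare_threshold=rare_threshold,
    )


def write_phenotypes(
    phen: PhenotypePanel, path: str | Path, pcs: np.ndarray | None = None
) -> None:
    """Tab-separated phenotype/origin (and optional PC covariate) table."""
    df = pd.DataFrame(
        {
            "id": [f"ind{i}" for i in range(phen.y.size)],
            "phenotype": phen.y.astype(int),
            "origin": phen.origin,
        }
    )
    if pcs is not None:
        pcs = np.atleast_2d(np.asarray(pcs, dtype=float))
        for k in range(pcs.shape[1]):
            df[f"PC{k + 1}"] = pcs[:, k]
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_phenotypes(path: str | Path) -> tuple[PhenotypePanel, np.ndarray | None]:
    df = pd.read_csv(path, sep="\t")
    phen = PhenotypePanel(
        y=df["phenotype"].to_numpy(dtype=np.int8),
        origin=df["origin"].to_numpy(dtype=object),
    )
    pc_cols = [c for c in df.columns if c.startswith("PC")]
    pcs = df[pc_cols].to_numpy(dtype=float) if pc_cols else None
    return phen, pcs


RESULT_COLUMNS = [
    "replicate",
    "migration_rate",
    "pct_controls_b",
    "hypothesis",
    "method",
    "correction",
    "statistic",
    "p",
    "permutations",
    "n_variants",
]


def write_results(results: pd.DataFrame, path: str | Path) -> None:
    """Per-gene test results as CSV with a deterministic column order and
    full float precision."""
    if results.empty:
        raise ValueError("refusing to write an empty results table")
    ordered = [c for c in RESULT_COLUMNS if c in results.columns]
    ordered += [c for c in results.columns if c not in ordered]
    results[ordered].to_csv(path, index=False, float_format="%.17g")


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


@dataclass
class RunConfig:
    """Structured run configuration: demography, scenario grid and seeds.

    Round-trips losslessly through YAML; unknown keys are rejected so a
    typo in a config file fails loudly instead of silently using defaults.
    """

    demography: dict = field(default_factory=dict)
    migration_rates: list = field(default_factory=lambda: [0.0, 0.001, 0.01, 0.025, 0.05, 0.1])
    pct_controls_b: list = field(default_factory=lambda: [0.0, 0.25, 0.5, 0.75, 1.0])
    hypotheses: list = field(default_factory=lambda: ["H0"])
    methods: list = field(default_factory=lambda: list(DEFAULTS_METHODS))
    corrections: list = field(default_factory=lambda: ["none"])
    n_pcs: int = 2
    replicates: int = 100
    n_cases: int = 1_000
    n_controls: int = 1_000
    rare_threshold: float = 0.01
    seed: int = 1
    output_dir: str = "results"

    def demography_config(self) -> DemographyConfig:
        return DemographyConfig(**self.demography)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        demo_known = {f.name for f in fields(DemographyConfig)}
        demo_unknown = set(cfg.demography) - demo_known
        if demo_unknown:
            raise ValueError(f"unknown demography keys: {sorted(demo_unknown)}")
        return cfg


DEFAULTS_METHODS = ("cast", "sum", "skat")
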