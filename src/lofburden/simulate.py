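"""Synthetic cohort genotype tables with known per-allele carrier
frequencies, plus Monte-Carlo calibration of the exact test.

Each individual draws two alleles independently at the stratum's per-allele
frequency, so carrier-allele counts are Binomial(2N, f) and homozygous
carriers occur with probability f^2 (counted as one carrier, two alleles).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .coding import CodingChange, canonical, parse_coding_change
from .stats import ContingencyTable, fisher_two_sided
from .transcript import DomainInterval, TranscriptModel


@dataclass(frozen=True)
class VariantTemplate:
    """A coding change to place on the synthetic transcript."""

    coding_change: str
    protein_change: str | None = None
    pos: int | None = None
    chrom: str = "chrS"

    @property
    def parsed(self) -> CodingChange:
        return parse_coding_change(self.coding_change)

    @property
    def key(self) -> str:
        return canonical(self.parsed)


def default_transcript_model() -> TranscriptModel:
    """Synthetic 3939-nt transcript with a hook-like domain at residues 635-734.

    The CDS is poly-GCT (alanine) except codon 672 (CAA) and codon 1264
    (CTT), so the default templates translate to a stop gain inside the
    domain and a missense outside it.
    """
    codons = ["GCT"] * 1313
    codons[671] = "CAA"   # codon 672: CAA -> TAA under C>T at its first base
    codons[1263] = "CTT"  # codon 1264: CTT -> TTT (Leu -> Phe)
    codons[1312] = "TAA"
    seq = "".join(codons)
    return TranscriptModel(
        transcript_id="SYNTH-1",
        cds_length=len(seq),
        domains=(DomainInterval("zinc_hook", 635, 734),),
        cds_sequence=seq,
    )


def default_templates() -> tuple[VariantTemplate, ...]:
    """One in-domain stop gain, one in-domain frameshift, one missense outside."""
    return (
        VariantTemplate("c.C2014T", pos=1_002_014),
        VariantTemplate("c.2165_2166insT", protein_change="p.K722fs", pos=1_002_165),
        VariantTemplate("c.C3790T", pos=1_003_790),
    )


@dataclass(frozen=True)
class SimulationSpec:
    strata: tuple[tuple[str, int, float], ...]
    templates: tuple[VariantTemplate, ...] = field(default_factory=default_templates)
    n_replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        for name, n, freq in self.strata:
            if n < 1:
                raise ValueError(f"stratum {name!r} needs n_individuals >= 1")
            if not 0.0 <= freq <= 1.0:
                raise ValueError(
                    f"stratum {name!r}: carrier frequency {freq} outside [0, 1]"
                )
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not self.templates:
            raise ValueError("at least one variant template is required")


@dataclass(frozen=True)
class SyntheticCohort:
    """One simulated replicate: allele counts (0/1/2) per individual x variant."""

    spec: SimulationSpec
    replicate: int
    genotypes: Mapping[str, np.ndarray]

    def carrier_counts(self, stratum: str) -> np.ndarray:
        return (self.genotypes[stratum] > 0).sum(axis=0)

    def carrier_allele_counts(self, stratum: str) -> np.ndarray:
        return self.genotypes[stratum].sum(axis=0)

    def to_variant_table(self) -> pd.DataFrame:
        """The TSV dialect consumed by the annotation/burden pipeline.

        Carrier counts are per individual (a rare homozygote counts once).
        """
        rows = []
        for j, template in enumerate(self.spec.templates):
            row = {
                "chrom": template.chrom,
                "pos": template.pos,
                "exon": None,
                "coding_change": template.coding_change,
                "protein_change": template.protein_change,
                "cadd": None,
            }
            for name, _, _ in self.spec.strata:
                row[name] = int(self.carrier_counts(name)[j])
            rows.append(row)
        return pd.DataFrame(rows)

    def write_variant_table(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# seed={self.spec.seed} replicate={self.replicate}\n")
            self.to_variant_table().to_csv(fh, sep="\t", index=False)

    def to_vcf(self, path: str | Path) -> None:
        """Minimal uncompressed VCF v4.2 with per-individual GT columns."""
        samples = [
            f"{name}_{i + 1}"
            for name, n, _ in self.spec.strata
            for i in range(n)
        ]
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write(f"##source=lofburden simulate seed={self.spec.seed} "
                     f"replicate={self.replicate}\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            for template in self.spec.templates:
                fh.write(f"##contig=<ID={template.chrom}>\n")
                break
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
            fh.write("\t".join(samples) + "\n")
            for j, template in enumerate(self.spec.templates):
                gts = []
                for name, _, _ in self.spec.strata:
                    for g in self.genotypes[name][:, j]:
                        gts.append(["0/0", "0/1", "1/1"][int(g)])
                pos = template.pos or (j + 1)
                fh.write(
                    f"{template.chrom}\t{pos}\t{template.key}\tN\t<ALT>\t.\tPASS\t"
                    f".\tGT\t" + "\t".join(gts) + "\n"
                )


def simulate_cohort(spec: SimulationSpec) -> list[SyntheticCohort]:
    """All replicates of the spec; deterministic under the spec seed."""
    rng = np.random.default_rng(spec.seed)
    replicates = []
    for r in range(spec.n_replicates):
        genotypes = {}
        for name, n, freq in spec.strata:
            # two independent allele draws per individual per variant
            genotypes[name] = rng.binomial(
                2, freq, size=(n, len(spec.templates))
            ).astype(np.int8)
        replicates.append(SyntheticCohort(spec=spec, replicate=r, genotypes=genotypes))
    return replicates


@dataclass(frozen=True)
class CalibrationResult:
    nominal_alpha: float
    empirical_rejection_rate: float
    monte_carlo_se: float
    n_replicates: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.empirical_rejection_rate <= 1.0:
            raise ValueError("rejection rate outside [0, 1]")


def _rejection_rate(
    n1_alleles: int,
    n2_alleles: int,
    freq1: float,
    freq2: float,
    alpha: float,
    n_replicates: int,
    seed: int,
) -> CalibrationResult:
    rng = np.random.default_rng(seed)
    x1 = rng.binomial(n1_alleles, freq1, size=n_replicates)
    x2 = rng.binomial(n2_alleles, freq2, size=n_replicates)
    cache: dict[tuple[int, int], float] = {}
    rejections = 0
    for a, c in zip(x1.tolist(), x2.tolist()):
        p = cache.get((a, c))
        if p is None:
            p = fisher_two_sided(
                ContingencyTable(a, n1_alleles - a, c, n2_alleles - c)
            )
            cache[(a, c)] = p
        # reject at p <= alpha so alpha = 1 rejects the whole discrete support
        if p <= alpha:
            rejections += 1
    rate = rejections / n_replicates
    se = math.sqrt(rate * (1.0 - rate) / n_replicates)
    return CalibrationResult(
        nominal_alpha=alpha,
        empirical_rejection_rate=rate,
        monte_carlo_se=se,
        n_replicates=n_replicates,
    )


def calibrate_type1(
    n1_alleles: int,
    n2_alleles: int,
    null_frequency: float,
    alpha: float = 0.05,
    n_replicates: int = 5000,
    seed: int = 0,
) -> CalibrationResult:
    """Empirical type-I error of the two-sided exact test under a shared null
    frequency; expected to be at most alpha (discreteness makes it conservative)."""
    if not 0.0 <= null_frequency <= 1.0:
        raise ValueError("null frequency outside [0, 1]")
    return _rejection_rate(
        n1_alleles, n2_alleles, null_frequency, null_frequency,
        alpha, n_replicates, seed,
    )


def estimate_power(
    n1_alleles: int,
    n2_alleles: int,
    freq1: float,
    freq2: float,
    alpha: float = 0.05,
    n_replicates: int = 5000,
    seed: int = 0,
) -> CalibrationResult:
    """Empirical rejection rate under unequal group frequencies."""
    for f in (freq1, freq2):
        if not 0.0 <= f <= 1.0:
            raise ValueError("frequency outside [0, 1]")
    return _rejection_rate(
        n1_alleles, n2_alleles, freq1, freq2, alpha, n_replicates, seed
    )
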