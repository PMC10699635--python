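"""Founder-age estimation from Y-STR diversity: modal ancestor, rho, TMRCA.

The rho statistic is the mean number of single-step mutations separating
each sampled haplotype from a designated ancestral haplotype (here the
per-locus modal haplotype). Under a star-like expansion rho estimates
L * mu * T, so dividing by the panel-wide mutation rate converts it to an
age: TMRCA_years = rho / (n_loci * mu) * generation_years. The standard
deviation uses the star-genealogy approximation sigma = sqrt(rho / n).

The evolutionary calibration ("EMR", 6.9e-4 per locus per 25-year
generation) ships as a preset; the genealogical/observed calibrations
(OMRS, OMRB, OMRG) are named but carry no numeric default — their sources
print none — and must be configured explicitly.
"""

from __future__ import annotations

import warnings
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genotypes import SNPGenotypeTable
from .profiles import STRProfile, active_loci


@dataclass(frozen=True)
class RateConfig:
    """A named mutation-rate calibration for TMRCA conversion."""

    name: str
    mu_per_locus_per_gen: float
    generation_years: float = 25.0
    n_loci: int = 15

    def __post_init__(self) -> None:
        if self.mu_per_locus_per_gen <= 0:
            raise ValueError("mutation rate must be positive")
        if self.generation_years <= 0 or self.n_loci <= 0:
            raise ValueError("generation_years and n_loci must be positive")

    def years_per_step(self) -> float:
        return self.generation_years / (self.n_loci * self.mu_per_locus_per_gen)


#: Evolutionary mutation rate: 6.9e-4 / locus / 25-year generation, 15 loci.
EMR = RateConfig(name="EMR", mu_per_locus_per_gen=6.9e-4, generation_years=25.0, n_loci=15)


@dataclass
class RhoResult:
    """rho, its star-approximation SD and per-rate TMRCA conversions."""

    rho: float
    sigma: float
    n: int
    tmrca_years: dict[str, tuple[float, float]] = field(default_factory=dict)
    low_confidence: bool = False


def modal_ancestral(
    profiles: Sequence[STRProfile], loci: Sequence[str] | None = None
) -> dict[str, int]:
    """Per-locus modal allele; ties break to the smallest allele."""
    if not profiles:
        raise ValueError("empty profile collection")
    loci = tuple(loci) if loci is not None else active_loci(profiles)
    ancestral = {}
    for l in loci:
        values, counts = np.unique([p.alleles[l] for p in profiles], return_counts=True)
        ancestral[l] = int(values[counts == counts.max()].min())
    return ancestral


def rho_statistic(
    profiles: Sequence[STRProfile], ancestral: Mapping[str, int]
) -> tuple[float, float]:
    """Mean unweighted step count to the ancestral haplotype, and its SD.

    rho = (1/n) * sum_samples sum_loci |allele - ancestral allele|;
    sigma = sqrt(rho / n) (star-genealogy approximation). Profiles missing
    any required locus are excluded with a warning and n adjusted.
    """
    if not profiles:
        raise ValueError("empty profile collection")
    loci = [l for l in ancestral if l not in profiles[0].excluded_loci]
    usable, dropped = [], []
    for p in profiles:
        if all(l in p.alleles for l in loci):
            usable.append(p)
        else:
            dropped.append(p.sample_id)
    if dropped:
        warnings.warn(f"profiles missing loci excluded from rho: {dropped}", stacklevel=2)
    if not usable:
        raise ValueError("no profile covers all ancestral loci")
    n = len(usable)
    total = sum(
        abs(int(p.alleles[l]) - int(ancestral[l])) for p in usable for l in loci
    )
    rho = total / n
    return rho, float(np.sqrt(rho / n))


def tmrca(rho_result: RhoResult, rates: Sequence[RateConfig]) -> RhoResult:
    """Fill TMRCA (years) and SD under every configured rate.

    TMRCA is linear in rho: estimate = rho * generation_years /
    (n_loci * mu); the SD scales sigma by the same factor.
    """
    if not rates:
        raise ValueError("rates must be non-empty")
    filled = dict(rho_result.tmrca_years)
    for rate in rates:
        k = rate.years_per_step()
        filled[rate.name] = (rho_result.rho * k, rho_result.sigma * k)
    return replace(rho_result, tmrca_years=filled)


def date_haplotypes(
    profiles: Sequence[STRProfile], rates: Sequence[RateConfig]
) -> RhoResult:
    """Modal-ancestral rho dating of one haplotype set under every rate."""
    ancestral = modal_ancestral(profiles)
    rho, sigma = rho_statistic(profiles, ancestral)
    result = RhoResult(rho=rho, sigma=sigma, n=len(profiles), low_confidence=len(profiles) < 2)
    return tmrca(result, rates)


def date_sublineage(
    profiles: Sequence[STRProfile],
    carriers: Mapping[str, Sequence[str]] | SNPGenotypeTable,
    rates: Sequence[RateConfig],
    markers: Sequence[str] | None = None,
) -> dict[str, RhoResult]:
    """Per-SNP rho/TMRCA over each marker's derived carriers.

    `carriers` maps marker -> derived sample ids, or is a genotype table
    from which carrier sets are read. For each marker the profiles are
    restricted to carriers, the modal ancestral haplotype is re-inferred
    within them, and rho is converted to years under every rate. A single
    carrier yields rho = 0 flagged low-confidence.
    """
    if isinstance(carriers, SNPGenotypeTable):
        names = markers if markers is not None else carriers.markers
        carrier_map = {m: carriers.carriers(m) for m in names}
    else:
        carrier_map = {m: list(s) for m, s in carriers.items()}
    by_id = {p.sample_id: p for p in profiles}
    results: dict[str, RhoResult] = {}
    for marker, ids in carrier_map.items():
        subset = [by_id[s] for s in ids if s in by_id]
        if not subset:
            raise ValueError(f"marker {marker!r} has no carriers with STR profiles")
        ancestral = modal_ancestral(subset)
        rho, sigma = rho_statistic(subset, ancestral)
        result = RhoResult(
            rho=rho, sigma=sigma, n=len(subset), low_confidence=len(subset) < 2
        )
        results[marker] = tmrca(result, rates)
    return results


def tmrca_table(results: Mapping[str, RhoResult]) -> pd.DataFrame:
    """Flatten per-SNP results into a report table (one row per SNP)."""
    rows = []
    for marker, res in results.items():
        row: dict = {"snp": marker, "n": res.n, "rho": res.rho, "sigma": res.sigma}
        for rate, (est, sd) in res.tmrca_years.items():
            row[f"tmrca_{rate}"] = est
            row[f"sd_{rate}"] = sd
        row["low_confidence"] = res.low_confidence
        rows.append(row)
    return pd.DataFrame(rows)
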