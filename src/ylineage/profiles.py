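"""Core Y-STR profile container and helpers shared across modules."""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np

#: Duplicated multi-copy loci excluded by default from distances, networks and dating.
DEFAULT_EXCLUDED_LOCI = frozenset({"DYS385a", "DYS385b"})

#: The 17-locus Y-filer panel (DYS385a/b are typed but excluded from arithmetic).
YFILER_LOCI = (
    "DYS456", "DYS389I", "DYS390", "DYS389II", "DYS458", "DYS19",
    "DYS385a", "DYS385b", "DYS393", "DYS391", "DYS439", "DYS635",
    "DYS392", "GATA-H4", "DYS437", "DYS438", "DYS448",
)


@dataclass(frozen=True)
class STRProfile:
    """One sample's repeat counts across named Y-STR loci.

    Parameters
    ----------
    sample_id
        Unique sample identifier.
    alleles
        Mapping locus name -> integer repeat count (all counts >= 1).
    population, group
        Hierarchical labels used by AMOVA/MCA (population nested in group).
    excluded_loci
        Loci never entering distance, network or dating computations;
        defaults to the duplicated DYS385a/b pair.
    """

    sample_id: str
    alleles: Mapping[str, int]
    population: str = "pop1"
    group: str = "group1"
    excluded_loci: frozenset = DEFAULT_EXCLUDED_LOCI

    def __post_init__(self) -> None:
        for locus, rep in self.alleles.items():
            if rep != int(rep) or int(rep) < 1:
                raise ValueError(
                    f"repeat count for locus {locus!r} must be a positive "
                    f"integer, got {rep!r}"
                )

    def active_loci(self) -> tuple[str, ...]:
        return tuple(l for l in self.alleles if l not in self.excluded_loci)

    def vector(self, loci: Sequence[str]) -> tuple[int, ...]:
        return tuple(int(self.alleles[l]) for l in loci)


def active_loci(profiles: Sequence[STRProfile]) -> tuple[str, ...]:
    """Ordered loci present in every profile, minus every profile's exclusions.

    Order follows the first profile so tables and haplotype vectors are stable.
    """
    if not profiles:
        raise ValueError("empty profile collection")
    excluded: set[str] = set()
    common = set(profiles[0].alleles)
    for p in profiles:
        excluded |= set(p.excluded_loci)
        common &= set(p.alleles)
    return tuple(l for l in profiles[0].alleles if l in common and l not in excluded)


def allele_matrix(
    profiles: Sequence[STRProfile], loci: Sequence[str] | None = None
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Integer allele matrix (n_samples x n_loci) plus the locus order used."""
    loci = tuple(loci) if loci is not None else active_loci(profiles)
    mat = np.array([[p.alleles[l] for l in loci] for p in profiles], dtype=np.int64)
    return mat, loci
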