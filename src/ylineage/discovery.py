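"""Candidate Y-SNP selection filters.

Selects novel candidate SNPs from a variant list the way a discovery screen
on non-recombining Y data does: keep single-nucleotide variants that are not
already catalogued, do not fall in masked repeat regions, have no neighbouring
variant inside a fixed field of view, and are transversions (transversions
being far less prone to recurrent mutation than transitions).
"""

from __future__ import annotations

import bisect
import warnings
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

from intervaltree import IntervalTree

_PURINES = frozenset({"A", "G"})
_BASES = frozenset({"A", "C", "G", "T"})

#: Rejection reasons, in the order the rules are applied.
REASON_NOT_SNV = "not_snv"
REASON_KNOWN = "known_variant"
REASON_REPEAT = "in_repeat_region"
REASON_PROXIMITY = "neighbour_within_window"
REASON_TRANSITION = "not_transversion"


def is_transversion(ref_base: str, alt_base: str) -> bool:
    """True iff the substitution swaps a purine for a pyrimidine.

    Raises ValueError on non-ACGT input or a non-substitution (ref == alt).
    """
    ref, alt = ref_base.upper(), alt_base.upper()
    if ref not in _BASES or alt not in _BASES:
        raise ValueError(f"bases must be in A/C/G/T, got {ref_base!r}>{alt_base!r}")
    if ref == alt:
        raise ValueError(f"not a substitution: {ref_base!r}>{alt_base!r}")
    return (ref in _PURINES) != (alt in _PURINES)


@dataclass(frozen=True, order=True)
class VariantRecord:
    """A single variant call: 1-based position, ref and alt alleles."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref/alt must be non-empty")

    @property
    def vtype(self) -> str:
        return "snv" if len(self.ref) == 1 and len(self.alt) == 1 else "indel"


@dataclass
class FilterConfig:
    """Candidate-selection switches.

    window_nt is the TOTAL width of the field of view centred on each
    variant: a neighbour within window_nt/2 on either side disqualifies it.
    """

    window_nt: int = 3000
    require_transversion: bool = True
    exclude_known: bool = True
    exclude_repeats: bool = True
    allele_aware_known: bool = False

    def __post_init__(self) -> None:
        if self.window_nt < 0:
            raise ValueError("window_nt must be >= 0")


@dataclass
class FilterResult:
    kept: list[VariantRecord]
    audit: list[dict] = field(default_factory=list)

    def reasons(self) -> dict[VariantRecord, str]:
        return {entry["variant"]: entry["reason"] for entry in self.audit}


def _mask_trees(repeat_mask) -> Mapping[str, IntervalTree]:
    """Normalise a repeat mask into per-chromosome interval trees.

    Accepts {chrom: IntervalTree} or {chrom: iterable of (start, end)}
    with 0-based half-open coordinates.
    """
    trees: dict[str, IntervalTree] = {}
    for chrom, intervals in (repeat_mask or {}).items():
        if isinstance(intervals, IntervalTree):
            trees[chrom] = intervals
        else:
            trees[chrom] = IntervalTree.from_tuples(
                (int(s), int(e)) for s, e in intervals
            )
    return trees


def filter_candidate_snps(
    variants: Sequence[VariantRecord],
    known_catalog: Iterable = (),
    repeat_mask=None,
    cfg: FilterConfig | None = None,
) -> FilterResult:
    """Apply the candidate-SNP filters and return survivors plus an audit.

    Rules, in order (the audit records the first failing rule per variant):
      i.   the variant is a single-nucleotide substitution;
      ii.  it is absent from the known-variant catalog;
      iii. it does not intersect the repeat mask (0-based half-open BED);
      iv.  no other input variant lies within window_nt/2 on the same
           chromosome (proximity is judged against the FULL input list,
           including variants other rules reject);
      v.   it is a transversion.

    Survivors are returned in (chrom, pos) order. Duplicate positions with
    conflicting alleles are warned about and evaluated independently (they
    reject each other via rule iv whenever a proximity window is active).
    """
    cfg = cfg or FilterConfig()
    known = set()
    for entry in known_catalog or ():
        if isinstance(entry, VariantRecord):
            key = (entry.chrom, entry.pos, entry.ref, entry.alt)
        else:
            key = tuple(entry)
        known.add(key if cfg.allele_aware_known else key[:2])
    trees = _mask_trees(repeat_mask)

    seen_pos: dict[tuple[str, int], VariantRecord] = {}
    for v in variants:
        prev = seen_pos.get((v.chrom, v.pos))
        if prev is not None and (prev.ref, prev.alt) != (v.ref, v.alt):
            warnings.warn(
                f"conflicting alleles at {v.chrom}:{v.pos}; evaluating both",
                stacklevel=2,
            )
        seen_pos.setdefault((v.chrom, v.pos), v)

    half = cfg.window_nt // 2
    by_chrom: dict[str, list[int]] = {}
    for v in variants:
        by_chrom.setdefault(v.chrom, []).append(v.pos)
    for positions in by_chrom.values():
        positions.sort()

    def has_neighbour(v: VariantRecord) -> bool:
        if half == 0:
            # only a second record at the exact same position conflicts
            return sum(1 for p in by_chrom[v.chrom] if p == v.pos) > 1
        positions = by_chrom[v.chrom]
        lo = bisect.bisect_left(positions, v.pos - half)
        hi = bisect.bisect_right(positions, v.pos + half)
        return (hi - lo) > 1  # more than the variant itself

    def first_failure(v: VariantRecord) -> str | None:
        if v.vtype != "snv":
            return REASON_NOT_SNV
        if cfg.exclude_known:
            key = (v.chrom, v.pos, v.ref, v.alt) if cfg.allele_aware_known else (v.chrom, v.pos)
            if key in known:
                return REASON_KNOWN
        if cfg.exclude_repeats and v.chrom in trees and trees[v.chrom].overlaps(v.pos - 1):
            return REASON_REPEAT
        if cfg.window_nt > 0 and has_neighbour(v):
            return REASON_PROXIMITY
        if cfg.require_transversion and not is_transversion(v.ref, v.alt):
            return REASON_TRANSITION
        return None

    kept, audit = [], []
    for v in sorted(variants):
        reason = first_failure(v)
        if reason is None:
            kept.append(v)
        else:
            audit.append({"variant": v, "reason": reason})
    return FilterResult(kept=kept, audit=audit)
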