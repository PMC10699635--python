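"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from ylineage import STRProfile, SNPGenotypeTable


def make_profile(sample_id, alleles, population="pop1", group="group1"):
    return STRProfile(sample_id=sample_id, alleles=dict(alleles),
                      population=population, group=group)


@pytest.fixture
def three_locus_profiles():
    """Small 3-locus table with hand-computable variances."""
    rows = [
        ("s1", {"DYS19": 13, "DYS390": 24, "DYS391": 10}),
        ("s2", {"DYS19": 13, "DYS390": 24, "DYS391": 11}),
        ("s3", {"DYS19": 15, "DYS390": 24, "DYS391": 10}),
        ("s4", {"DYS19": 13, "DYS390": 25, "DYS391": 11}),
    ]
    return [make_profile(s, a) for s, a in rows]


@pytest.fixture
def toy_tree_dict():
    """Four-node chain with one side branch, for classification tests."""
    return {
        "root": "R",
        "nodes": [
            {"name": "R", "markers": ["r1"], "parent": None},
            {"name": "A", "markers": ["a1", "a2"], "parent": "R"},
            {"name": "B", "markers": ["b1"], "parent": "A"},
            {"name": "C", "markers": ["c1"], "parent": "R"},
        ],
    }


def genotype_table(records, markers, populations=None, groups=None):
    """records: {sample: {marker: state}}; unmentioned markers default ancestral."""
    data = {
        m: [records[s].get(m, "A") for s in records] for m in markers
    }
    df = pd.DataFrame(data, index=list(records))
    pops = pd.Series(populations) if populations else None
    grps = pd.Series(groups) if groups else None
    return SNPGenotypeTable(df, populations=pops, groups=grps)


# ---- independent closed-form oracles -------------------------------------

def expected_abs_net_steps(lam: float, nmax: int = 40) -> float:
    """E|net displacement| of a +/-1 walk with Poisson(lam) steps.

    Exact truncated sum: E[|D| given N] enumerated from the binomial law,
    weighted by Poisson probabilities. Independent of the simulator.
    """
    total = 0.0
    for n in range(1, nmax + 1):
        pn = math.exp(-lam) * lam ** n / math.factorial(n)
        e_abs = sum(
            abs(2 * k - n) * math.comb(n, k) * 0.5 ** n for k in range(n + 1)
        )
        total += pn * e_abs
    return total


def net_step_pmf(lam: float, nmax: int = 40) -> dict[int, float]:
    """Exact pmf of the net displacement under the Poisson-compound +/-1 law."""
    pmf: dict[int, float] = {}
    for n in range(0, nmax + 1):
        pn = math.exp(-lam) * lam ** n / math.factorial(n)
        for k in range(n + 1):
            d = 2 * k - n
            pmf[d] = pmf.get(d, 0.0) + pn * math.comb(n, k) * 0.5 ** n
    return pmf
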