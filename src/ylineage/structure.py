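"""Population structure: hierarchical AMOVA and multiple correspondence analysis.

AMOVA partitions the total molecular variance of haplotypes into among-group
(Va), among-population-within-group (Vb) and within-population (Vc)
components from a matrix of pairwise squared distances, using the standard
sums-of-squared-deviations identities and unbalanced-design expected-mean-
square coefficients. Significance is assessed by label permutation, each
level permuting the exchangeable units for its component. Negative
components are reported unmodified.

MCA is indicator-matrix correspondence analysis of SNP states: samples x
(marker x state) categories, with missing as its own category; an origin
label can ride along as a supplementary (projected, non-influential)
variable.
"""

from __future__ import annotations

import warnings
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

from .genotypes import MISSING, SNPGenotypeTable
from .profiles import STRProfile, allele_matrix

METRICS = ("pairwise_difference", "sum_squared_size_difference")


def pairwise_distance_matrix(
    profiles: Sequence[STRProfile], metric: str = "pairwise_difference"
) -> np.ndarray:
    """Squared molecular distances between all profile pairs.

    pairwise_difference: number of differing loci (FST-like);
    sum_squared_size_difference: sum of squared repeat-count differences
    (RST-like). Both enter AMOVA directly as squared distances.
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    mat, _ = allele_matrix(profiles)
    diff = mat[:, None, :] - mat[None, :, :]
    if metric == "pairwise_difference":
        return (diff != 0).sum(axis=2).astype(float)
    return (diff ** 2).sum(axis=2).astype(float)


@dataclass
class AmovaLevel:
    source: str
    df: int
    ss: float
    variance: float
    percent: float


@dataclass
class AmovaResult:
    levels: list[AmovaLevel]
    phi: dict[str, float]
    p_values: dict[str, float]
    n_permutations: int
    metric: str
    degenerate: bool = False

    def percent_total(self) -> float:
        return sum(l.percent for l in self.levels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (l.source, l.df, l.ss, l.variance, l.percent)
                for l in self.levels
            ],
            columns=["source", "df", "sum_of_squares", "variance_component", "percent"],
        )


def _ss_within(D: np.ndarray, idx: np.ndarray) -> float:
    """Sum over i<j in idx of D_ij / |idx| (squared deviations from centroid)."""
    sub = D[np.ix_(idx, idx)]
    return float(sub.sum() / (2 * len(idx)))


def _components(
    D: np.ndarray, pop_idx: list[np.ndarray], group_of_pop: np.ndarray
) -> tuple[float, float, float, tuple[float, float, float]]:
    """(SSD_ag, SSD_ap, SSD_wp) and (Va, Vb, Vc) for the given partition."""
    N = D.shape[0]
    P = len(pop_idx)
    groups = np.unique(group_of_pop)
    G = len(groups)
    ss_total = D.sum() / (2 * N)
    ss_wp = sum(_ss_within(D, idx) for idx in pop_idx)
    ss_group = 0.0
    for g in groups:
        idx = np.concatenate([pop_idx[p] for p in range(P) if group_of_pop[p] == g])
        ss_group += _ss_within(D, idx)
    ssd_ag = ss_total - ss_group
    ssd_ap = ss_group - ss_wp
    ssd_wp = ss_wp

    n_p = np.array([len(idx) for idx in pop_idx], dtype=float)
    n_g = np.array(
        [n_p[group_of_pop == g].sum() for g in groups], dtype=float
    )
    df_ag, df_ap, df_wp = G - 1, P - G, N - P
    Vc = ssd_wp / df_wp if df_wp > 0 else 0.0
    sum_np2_over_ng = sum(
        (n_p[group_of_pop == g] ** 2).sum() / n_g[i] for i, g in enumerate(groups)
    )
    if df_ap > 0:
        n1 = (N - sum_np2_over_ng) / df_ap
        Vb = (ssd_ap / df_ap - Vc) / n1
    else:
        Vb = 0.0
    if df_ag > 0:
        n2 = (sum_np2_over_ng - (n_p ** 2).sum() / N) / df_ag
        n3 = (N - (n_g ** 2).sum() / N) / df_ag
        Va = (ssd_ag / df_ag - Vc - n2 * Vb) / n3
    else:
        Va = 0.0
    return ssd_ag, ssd_ap, ssd_wp, (Va, Vb, Vc)


def _phi(Va: float, Vb: float, Vc: float) -> dict[str, float]:
    total = Va + Vb + Vc
    return {
        "Phi_CT": Va / total if total else float("nan"),
        "Phi_SC": Vb / (Vb + Vc) if (Vb + Vc) else float("nan"),
        "Phi_ST": (Va + Vb) / total if total else float("nan"),
    }


def amova_two_level(
    profiles: Sequence[STRProfile],
    group_of: Mapping[str, str] | None = None,
    metric: str = "pairwise_difference",
    n_permutations: int = 9999,
    seed: int | None = None,
) -> AmovaResult:
    """Two-level hierarchical AMOVA with permutation p-values.

    `group_of` maps population name -> group name; by default each
    profile's own group label is used. With a single group the analysis
    collapses to a one-level AMOVA (Va undefined, reported as 0 with the
    among-group row omitted). Populations of size 0 cannot occur here
    (populations are read off the profiles); p-values use (1 + #{perm >=
    obs}) / (B + 1) on the Phi statistic of each level.
    """
    pops = sorted({p.population for p in profiles})
    if len(pops) < 2:
        raise ValueError("AMOVA needs at least two populations")
    if group_of is None:
        group_of = {}
        for p in profiles:
            prev = group_of.setdefault(p.population, p.group)
            if prev != p.group:
                raise ValueError(f"population {p.population!r} spans multiple groups")
    missing = [q for q in pops if q not in group_of]
    if missing:
        raise ValueError(f"populations without a group assignment: {missing}")

    D = pairwise_distance_matrix(profiles, metric)
    pop_label = np.array([pops.index(p.population) for p in profiles])
    pop_idx = [np.flatnonzero(pop_label == i) for i in range(len(pops))]
    group_names = sorted({group_of[q] for q in pops})
    group_of_pop = np.array([group_names.index(group_of[q]) for q in pops])
    N, P, G = len(profiles), len(pops), len(group_names)

    ssd_ag, ssd_ap, ssd_wp, (Va, Vb, Vc) = _components(D, pop_idx, group_of_pop)
    total_var = Va + Vb + Vc
    degenerate = total_var == 0
    if degenerate:
        warnings.warn("all haplotypes identical: variance components degenerate", stacklevel=2)
    pct = (
        lambda v: 100.0 * v / total_var if total_var else float("nan")
    )
    phi = _phi(Va, Vb, Vc)

    rng = np.random.default_rng(seed)
    p_values: dict[str, float] = {}
    if n_permutations > 0 and not degenerate:
        # Phi_ST: permute samples among populations (and hence groups)
        count_st = 0
        obs_st = phi["Phi_ST"]
        for _ in range(n_permutations):
            perm = rng.permutation(N)
            idx = [perm[pi] for pi in pop_idx]
            _, _, _, (va, vb, vc) = _components(D, idx, group_of_pop)
            if _phi(va, vb, vc)["Phi_ST"] >= obs_st - 1e-12:
                count_st += 1
        p_values["Phi_ST"] = (1 + count_st) / (n_permutations + 1)

        if G > 1:
            # Phi_CT: permute whole populations among groups
            count_ct = 0
            obs_ct = phi["Phi_CT"]
            for _ in range(n_permutations):
                g_perm = group_of_pop[rng.permutation(P)]
                _, _, _, (va, vb, vc) = _components(D, pop_idx, g_perm)
                if _phi(va, vb, vc)["Phi_CT"] >= obs_ct - 1e-12:
                    count_ct += 1
            p_values["Phi_CT"] = (1 + count_ct) / (n_permutations + 1)

            # Phi_SC: permute samples among populations within their group
            count_sc = 0
            obs_sc = phi["Phi_SC"]
            sample_group = np.array([group_of_pop[pop_label[i]] for i in range(N)])
            for _ in range(n_permutations):
                perm = np.arange(N)
                for g in range(G):
                    sel = np.flatnonzero(sample_group == g)
                    perm[sel] = sel[rng.permutation(len(sel))]
                idx = [perm[pi] for pi in pop_idx]
                _, _, _, (va, vb, vc) = _components(D, idx, group_of_pop)
                if _phi(va, vb, vc)["Phi_SC"] >= obs_sc - 1e-12:
                    count_sc += 1
            p_values["Phi_SC"] = (1 + count_sc) / (n_permutations + 1)

    levels = []
    if G > 1:
        levels.append(AmovaLevel("Among groups", G - 1, ssd_ag, Va, pct(Va)))
        levels.append(
            AmovaLevel("Among populations within groups", P - G, ssd_ap, Vb, pct(Vb))
        )
    else:
        levels.append(AmovaLevel("Among populations", P - 1, ssd_ap + ssd_ag, Vb, pct(Vb)))
    levels.append(AmovaLevel("Within populations", N - P, ssd_wp, Vc, pct(Vc)))
    return AmovaResult(
        levels=levels,
        phi=phi,
        p_values=p_values,
        n_permutations=n_permutations,
        metric=metric,
        degenerate=degenerate,
    )


@dataclass
class McaResult:
    eigenvalues: np.ndarray
    percent_inertia: np.ndarray
    total_inertia: float
    row_coords: pd.DataFrame
    col_coords: pd.DataFrame
    supp_coords: pd.DataFrame | None = None
    excluded_markers: list[str] = field(default_factory=list)

    @property
    def cumulative_percent_dims12(self) -> float:
        return float(self.percent_inertia[: min(2, len(self.percent_inertia))].sum())


def _indicator(states: pd.DataFrame) -> pd.DataFrame:
    """0/1 indicator over (marker, observed state) categories."""
    blocks = []
    for marker in states.columns:
        dummies = pd.get_dummies(states[marker], prefix=marker, prefix_sep="=")
        blocks.append(dummies.astype(float))
    return pd.concat(blocks, axis=1)


def mca(
    snp_table: SNPGenotypeTable,
    active_markers: Sequence[str] | None = None,
    supplementary: str | None = None,
    n_dims: int = 5,
    benzecri: bool = False,
) -> McaResult:
    """Indicator-matrix multiple correspondence analysis of SNP states.

    Constant markers (a single observed state) are excluded with a warning.
    `supplementary` names a sample label ("population" or "group") whose
    categories are projected onto the axes without influencing them.
    `benzecri` applies the Benzecri eigenvalue correction to the reported
    inertia percentages (raw by default).
    """
    markers = list(active_markers) if active_markers is not None else snp_table.markers
    states = snp_table.states[markers]
    keep, excluded = [], []
    for m in markers:
        if states[m].nunique() >= 2:
            keep.append(m)
        else:
            excluded.append(m)
    if excluded:
        warnings.warn(f"constant markers excluded from MCA: {excluded}", stacklevel=2)
    if len(keep) < 2:
        # fully (or nearly) constant table: no non-trivial inertia to analyse
        warnings.warn("fewer than two variable markers: degenerate MCA", stacklevel=2)
        dims = ["dim1"]
        zero = pd.DataFrame(
            np.zeros((len(states), 1)), index=states.index, columns=dims
        )
        return McaResult(
            eigenvalues=np.zeros(0),
            percent_inertia=np.zeros(0),
            total_inertia=0.0,
            row_coords=zero,
            col_coords=pd.DataFrame(columns=dims),
            supp_coords=None,
            excluded_markers=excluded,
        )
    X = _indicator(states[keep])
    Q = len(keep)

    total = X.values.sum()
    Pm = X.values / total
    r = Pm.sum(axis=1)
    c = Pm.sum(axis=0)
    S = (Pm - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sig, Vt = scipy.linalg.svd(S, full_matrices=False)
    eig = sig ** 2
    keep_dims = eig > 1e-12
    eig, U, sig, Vt = eig[keep_dims], U[:, keep_dims], sig[keep_dims], Vt[keep_dims, :]
    total_inertia = float((S ** 2).sum())
    k = min(n_dims, len(eig))

    if benzecri:
        adj = np.array(
            [((Q / (Q - 1)) * (l - 1.0 / Q)) ** 2 if l > 1.0 / Q else 0.0 for l in eig]
        )
        percent = 100 * adj / adj.sum() if adj.sum() else np.zeros_like(adj)
    else:
        percent = 100 * eig / total_inertia if total_inertia else np.zeros_like(eig)

    dims = [f"dim{i + 1}" for i in range(k)]
    row_std = U / np.sqrt(r)[:, None]  # standard coordinates
    row_principal = row_std * sig[None, :]
    col_principal = (Vt.T / np.sqrt(c)[:, None]) * sig[None, :]
    row_coords = pd.DataFrame(row_principal[:, :k], index=X.index, columns=dims)
    col_coords = pd.DataFrame(col_principal[:, :k], index=X.columns, columns=dims)

    supp_coords = None
    if supplementary is not None:
        label = snp_table.label(supplementary)
        Xs = pd.get_dummies(label, prefix=supplementary, prefix_sep="=").astype(float)
        profile = Xs.values / Xs.values.sum(axis=0, keepdims=True)
        supp = profile.T @ row_std  # transition formula: principal coords of supp cats
        supp_coords = pd.DataFrame(supp[:, :k], index=Xs.columns, columns=dims)

    return McaResult(
        eigenvalues=eig,
        percent_inertia=percent,
        total_inertia=total_inertia,
        row_coords=row_coords,
        col_coords=col_coords,
        supp_coords=supp_coords,
        excluded_markers=excluded,
    )
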