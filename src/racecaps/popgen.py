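"""Hybridization and structure inference from single-locus genotype counts.

The three race-diagnostic SNPs are in complete linkage (identical genotype
calls across markers in the field data), so by default they are treated as one
effective biallelic locus with alleles *e* and *z*.  A site sample is then just
the genotype-count triple (n_zz, n_ez, n_ee); observed heterozygosity H_O =
n_ez/n doubles as the per-site hybridization-frequency estimate.

Implemented here:

* Nei's unbiased expected heterozygosity H_E = 2n/(2n-1) * 2pq;
* the exact conditional Hardy-Weinberg test by full enumeration over
  heterozygote counts compatible with the observed allele counts, plus a
  Metropolis Markov-chain estimator of the same p-value;
* Weir-Cockerham theta for pairs of populations and a three-level hierarchical
  AMOVA (among groups / among populations within groups / among individuals /
  within individuals) with permutation tests;
* the Benjamini-Yekutieli multiple-testing threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "PopulationSample",
    "HWEResult",
    "FStatResult",
    "observed_heterozygosity",
    "unbiased_expected_heterozygosity",
    "hwe_exact",
    "hwe_markov_chain",
    "reconstruct_counts",
    "hierarchical_fstats",
    "pairwise_fst",
    "by_threshold",
    "site_summary",
]


@dataclass(frozen=True)
class PopulationSample:
    """Genotype counts for one collection site at the effective pgfar locus."""

    site_id: str
    n_zz: int
    n_ez: int
    n_ee: int
    region: str | None = None  # e.g. "Midwest" / "EastCoast"

    def __post_init__(self) -> None:
        if min(self.n_zz, self.n_ez, self.n_ee) < 0:
            raise ValueError("negative genotype count")
        if self.n < 1:
            raise ValueError("empty sample")

    @property
    def n(self) -> int:
        return self.n_zz + self.n_ez + self.n_ee

    @property
    def n_z(self) -> int:
        return 2 * self.n_zz + self.n_ez

    @property
    def n_e(self) -> int:
        return 2 * self.n_ee + self.n_ez

    @property
    def p_e(self) -> float:
        return self.n_e / (2 * self.n)

    @property
    def monomorphic(self) -> bool:
        return self.n_e == 0 or self.n_z == 0


def observed_heterozygosity(pop: PopulationSample) -> float:
    """H_O = heterozygote fraction (doubles as the hybridization frequency)."""
    return pop.n_ez / pop.n


def unbiased_expected_heterozygosity(pop: PopulationSample) -> float:
    """Nei's unbiased H_E = 2n/(2n-1) * 2 p q for a biallelic locus."""
    if pop.n < 2:
        raise ValueError("need n >= 2 for the unbiased estimator")
    p = pop.p_e
    return (2 * pop.n) / (2 * pop.n - 1) * 2 * p * (1 - p)


# --- exact conditional HWE test -------------------------------------------

def _log_config_prob(n: int, n_ez: int, n_e: int) -> float:
    """log P(n_ez | n, allele counts) under the exact conditional distribution."""
    n_z = 2 * n - n_e
    n_ee = (n_e - n_ez) // 2
    n_zz = (n_z - n_ez) // 2
    return (
        gammaln(n + 1)
        - gammaln(n_zz + 1)
        - gammaln(n_ez + 1)
        - gammaln(n_ee + 1)
        + n_ez * math.log(2)
        + gammaln(n_e + 1)
        + gammaln(n_z + 1)
        - gammaln(2 * n + 1)
    )


def _het_support(n: int, n_e: int) -> list[int]:
    n_minor = min(n_e, 2 * n - n_e)
    return list(range(n_minor % 2, n_minor + 1, 2))


@dataclass(frozen=True)
class HWEResult:
    p_exact: float
    method: str  # "enumeration" or "markov_chain"
    observed_config: tuple[int, int, int]  # (n_zz, n_ez, n_ee)


_TIE_REL = 1e-12  # probabilities within this relative slack count as ties


def hwe_exact(pop: PopulationSample) -> HWEResult:
    """Exact conditional Hardy-Weinberg test by full enumeration.

    p = sum of probabilities of all heterozygote counts no more probable than
    the observed one (ties included), conditional on the allele counts.
    Monomorphic samples admit a single configuration and return p = 1.
    """
    n, n_e = pop.n, pop.n_e
    support = _het_support(n, n_e)
    logps = {h: _log_config_prob(n, h, n_e) for h in support}
    # guard: enumeration must account for all probability mass
    total = math.fsum(math.exp(lp) for lp in logps.values())
    if abs(total - 1.0) > 1e-9:
        raise AssertionError(f"enumeration mass {total} != 1")
    obs = logps[pop.n_ez]
    p = math.fsum(
        math.exp(lp) for lp in logps.values() if lp <= obs + _TIE_REL
    )
    return HWEResult(min(p, 1.0), "enumeration", (pop.n_zz, pop.n_ez, pop.n_ee))


def hwe_markov_chain(
    pop: PopulationSample,
    steps: int = 100_000,
    burnin: int = 1_000,
    seed: int | np.random.Generator = 0,
) -> HWEResult:
    """Markov-chain estimate of the exact conditional HWE p-value.

    A Metropolis walk over heterozygote counts (proposals +/-2) whose
    stationary law is the conditional distribution; the p-value is the
    fraction of post-burnin states no more probable than the observed
    configuration.  Converges to :func:`hwe_exact` as steps grow.
    """
    if steps <= burnin:
        raise ValueError("steps must exceed burnin")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n, n_e = pop.n, pop.n_e
    support = _het_support(n, n_e)
    if len(support) == 1:
        return HWEResult(1.0, "markov_chain", (pop.n_zz, pop.n_ez, pop.n_ee))
    logp = {h: _log_config_prob(n, h, n_e) for h in support}
    obs = logp[pop.n_ez]
    lo, hi = support[0], support[-1]
    state = pop.n_ez
    hits = 0
    kept = 0
    deltas = rng.integers(0, 2, size=steps) * 4 - 2  # +/-2
    us = rng.random(steps)
    for t in range(steps):
        prop = state + int(deltas[t])
        if lo <= prop <= hi and math.log(us[t]) < logp[prop] - logp[state]:
            state = prop
        if t >= burnin:
            kept += 1
            if logp[state] <= obs + _TIE_REL:
                hits += 1
    return HWEResult(hits / kept, "markov_chain", (pop.n_zz, pop.n_ez, pop.n_ee))


def reconstruct_counts(
    n: int, h_o: float, h_e: float | None, tol: float = 1e-3
) -> tuple[int, int, int]:
    """Invert printed (n, H_O, H_E) back to genotype counts (n_zz, n_ez, n_ee).

    n_ez = round(H_O * n); the homozygote split is the one whose unbiased H_E
    matches the printed 3-decimal value within ``tol``.  The solution is
    returned with the z-allele as the major allele (counts are unique only up
    to an allele-label swap).  Monomorphic sites (H_E absent) return (n,0,0).
    """
    n_ez = round(h_o * n)
    if abs(n_ez / n - h_o) > 5e-3 + 1e-9:
        raise ValueError(f"no integer heterozygote count matches H_O={h_o} at n={n}")
    if h_e is None:
        if n_ez != 0:
            raise ValueError("monomorphic site with nonzero H_O")
        return (n, 0, 0)
    matches = []
    for n_ee in range(0, n - n_ez + 1):
        n_zz = n - n_ez - n_ee
        if n_zz < n_ee:
            continue  # canonical orientation: z major; swap-equivalents skipped
        pop = PopulationSample("probe", n_zz, n_ez, n_ee)
        if abs(unbiased_expected_heterozygosity(pop) - h_e) <= tol:
            matches.append((n_zz, n_ez, n_ee))
    if not matches:
        raise ValueError(f"no consistent counts for n={n}, H_O={h_o}, H_E={h_e}")
    if len(matches) > 1:
        raise ValueError(f"ambiguous counts for n={n}, H_O={h_o}, H_E={h_e}: {matches}")
    return matches[0]


# --- Weir-Cockerham theta for two populations ------------------------------

def _wc_theta_components(pops: Sequence[PopulationSample]) -> tuple[float, float, float]:
    """Weir & Cockerham (1984) a, b, c variance components for one biallelic locus."""
    r = len(pops)
    ns = np.array([p.n for p in pops], dtype=float)
    ps = np.array([p.p_e for p in pops])
    hs = np.array([p.n_ez / p.n for p in pops])
    nbar = ns.mean()
    nc = (r * nbar - (ns**2).sum() / (r * nbar)) / (r - 1)
    pbar = (ns * ps).sum() / (r * nbar)
    s2 = (ns * (ps - pbar) ** 2).sum() / ((r - 1) * nbar)
    hbar = (ns * hs).sum() / (r * nbar)
    if nbar <= 1 or nc == 0:
        raise ValueError("samples too small for the theta estimator")
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
    )
    c = hbar / 2
    return float(a), float(b), float(c)


def _theta(pops: Sequence[PopulationSample]) -> float | None:
    a, b, c = _wc_theta_components(pops)
    denom = a + b + c
    if denom == 0:
        return None
    return a / denom


def _counts_to_genotypes(pop: PopulationSample) -> np.ndarray:
    """Individuals as z-allele dosage codes 0/1/2 (ee=0, ez=1, zz=2)."""
    return np.repeat([2, 1, 0], [pop.n_zz, pop.n_ez, pop.n_ee])


def _genotypes_to_counts(site_id: str, g: np.ndarray, region: str | None = None) -> PopulationSample:
    return PopulationSample(
        site_id,
        n_zz=int((g == 2).sum()),
        n_ez=int((g == 1).sum()),
        n_ee=int((g == 0).sum()),
        region=region,
    )


def pairwise_fst(
    a: PopulationSample,
    b: PopulationSample,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> tuple[float | None, float | None]:
    """Weir-Cockerham theta between two samples with a permutation p-value.

    Significance is assessed by permuting individuals (genotypes) between the
    two samples; p = (#{theta_perm >= theta_obs} + 1) / (n_perm + 1).  Both
    samples monomorphic for the same allele leave theta undefined (None).
    """
    if a.n < 2 or b.n < 2:
        raise ValueError("need n >= 2 in both samples")
    if a.monomorphic and b.monomorphic and a.p_e == b.p_e:
        return None, None
    theta = _theta([a, b])
    if theta is None or n_perm <= 0:
        return theta, None
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    combined = np.concatenate([_counts_to_genotypes(a), _counts_to_genotypes(b)])
    hits = 0
    for _ in range(n_perm):
        rng.shuffle(combined)
        pa = _genotypes_to_counts("a", combined[: a.n])
        pb = _genotypes_to_counts("b", combined[a.n :])
        t = _theta([pa, pb])
        if t is not None and t >= theta - 1e-12:
            hits += 1
    return theta, (hits + 1) / (n_perm + 1)


# --- hierarchical AMOVA -----------------------------------------------------

@dataclass(frozen=True)
class FStatResult:
    F_IS: float | None
    F_SC: float | None
    F_CT: float | None
    F_ST: float | None
    F_IT: float | None
    sigma2_among_groups: float
    sigma2_among_pops: float
    sigma2_among_individuals: float
    sigma2_within_individuals: float
    p_CT: float | None = None
    p_SC: float | None = None
    p_IS: float | None = None


def _amova_components(
    groups: Sequence[Sequence[PopulationSample]],
) -> tuple[float, float, float, float]:
    """Variance components (sigma2_a, sigma2_b, sigma2_c, sigma2_d) of the
    four-level nested ANOVA on allele indicator values: among groups, among
    populations within groups, among individuals within populations, within
    individuals.  Unbalanced-design coefficients follow the standard AMOVA
    moment estimators; each individual contributes exactly two alleles, so the
    intra-individual coefficients are exactly 2.
    """
    pops = [p for g in groups for p in g]
    G = len(groups)
    P = len(pops)
    if G < 2 or P < 2:
        raise ValueError("need >= 2 groups and >= 2 populations")
    m_gp = {}  # alleles per pop
    for gi, g in enumerate(groups):
        for p in g:
            m_gp[(gi, p.site_id)] = 2 * p.n
    M = sum(m_gp.values())
    m_g = [sum(2 * p.n for p in g) for g in groups]

    # allele-frequency means at each level (allele value = z-dosage per allele)
    p_pop = {(gi, p.site_id): 1 - p.p_e for gi, g in enumerate(groups) for p in g}
    p_group = [
        sum(2 * p.n * (1 - p.p_e) for p in g) / mg for g, mg in zip(groups, m_g)
    ]
    p_tot = sum(2 * p.n * (1 - p.p_e) for g in groups for p in g) / M

    # sums of squares on z-allele indicators
    ss_wi = 0.0  # within individuals
    ss_ai = 0.0  # among individuals within pops
    ss_ap = 0.0  # among pops within groups
    ss_ag = 0.0  # among groups
    for gi, g in enumerate(groups):
        for pop in g:
            pz = p_pop[(gi, pop.site_id)]
            ss_wi += 0.5 * pop.n_ez  # each het: two alleles deviating 0.5 from 0.5
            ss_ai += 2 * (
                pop.n_zz * (1 - pz) ** 2
                + pop.n_ez * (0.5 - pz) ** 2
                + pop.n_ee * (0.0 - pz) ** 2
            )
            ss_ap += 2 * pop.n * (pz - p_group[gi]) ** 2
        ss_ag += m_g[gi] * (p_group[gi] - p_tot) ** 2

    N_ind = M // 2
    df_wi = N_ind
    df_ai = N_ind - P
    df_ap = P - G  # zero when every group holds a single population
    df_ag = G - 1
    ms_wi = ss_wi / df_wi
    ms_ai = ss_ai / df_ai if df_ai > 0 else 0.0
    ms_ag = ss_ag / df_ag

    # unbalanced coefficients (allele units)
    sum_mgp2_over_mg = sum(
        sum((2 * p.n) ** 2 for p in g) / mg for g, mg in zip(groups, m_g)
    )
    sum_mgp2_over_M = sum((2 * p.n) ** 2 for g in groups for p in g) / M
    n_prime = (sum_mgp2_over_mg - sum_mgp2_over_M) / df_ag
    n_dprime = (M - sum(mg**2 for mg in m_g) / M) / df_ag

    sigma2_d = ms_wi
    sigma2_c = (ms_ai - ms_wi) / 2 if df_ai > 0 else 0.0
    if df_ap > 0:
        ms_ap = ss_ap / df_ap
        n_coef = (M - sum_mgp2_over_mg) / df_ap
        sigma2_b = (ms_ap - ms_ai) / n_coef
    else:
        sigma2_b = 0.0  # the among-populations-within-groups level is absent
    sigma2_a = (ms_ag - ms_ai - n_prime * sigma2_b) / n_dprime
    return sigma2_a, sigma2_b, sigma2_c, sigma2_d


def _fstats_from_components(
    comps: tuple[float, float, float, float]
) -> tuple[float | None, ...]:
    a, b, c, d = comps
    tot = a + b + c + d
    if tot == 0:
        return (None,) * 5
    F_CT = a / tot
    F_ST = (a + b) / tot
    F_IT = (a + b + c) / tot
    F_SC = b / (b + c + d) if (b + c + d) != 0 else None
    F_IS = c / (c + d) if (c + d) != 0 else None
    return F_IS, F_SC, F_CT, F_ST, F_IT


def hierarchical_fstats(
    pops: Sequence[PopulationSample],
    grouping: Mapping[str, str],
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> FStatResult:
    """Three-level AMOVA F-statistics with permutation significance.

    ``grouping`` maps site_id -> group label (e.g. Midwest / EastCoast).
    Permutation schemes: whole populations among groups for F_CT; individuals
    among populations within groups for F_SC; alleles among individuals within
    populations for F_IS.  All-monomorphic data leave the Fs undefined.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = sorted({grouping[p.site_id] for p in pops})
    groups = [[p for p in pops if grouping[p.site_id] == lab] for lab in labels]
    comps = _amova_components(groups)
    F_IS, F_SC, F_CT, F_ST, F_IT = _fstats_from_components(comps)
    result = FStatResult(F_IS, F_SC, F_CT, F_ST, F_IT, *comps)
    if n_perm <= 0 or F_CT is None:
        return result

    sizes = [len(g) for g in groups]

    def perm_p(observed: float | None, stat_index: int, permute) -> float | None:
        if observed is None:
            return None
        hits = 0
        for _ in range(n_perm):
            t = _fstats_from_components(_amova_components(permute()))[stat_index]
            if t is not None and t >= observed - 1e-12:
                hits += 1
        return (hits + 1) / (n_perm + 1)

    flat = [p for g in groups for p in g]

    def permute_pops():
        order = rng.permutation(len(flat))
        shuffled = [flat[i] for i in order]
        out, i = [], 0
        for s in sizes:
            out.append(shuffled[i : i + s])
            i += s
        return out

    def permute_individuals_within_groups():
        out = []
        for g in groups:
            genos = np.concatenate([_counts_to_genotypes(p) for p in g])
            rng.shuffle(genos)
            i, newg = 0, []
            for p in g:
                newg.append(_genotypes_to_counts(p.site_id, genos[i : i + p.n], p.region))
                i += p.n
            out.append(newg)
        return out

    def permute_alleles_within_pops():
        out = []
        for g in groups:
            newg = []
            for p in g:
                alleles = np.repeat([1, 0], [p.n_z, p.n_e])  # 1 = z allele
                rng.shuffle(alleles)
                pairs = alleles.reshape(-1, 2).sum(axis=1)  # z-dosage per individual
                newg.append(_genotypes_to_counts(p.site_id, pairs, p.region))
            out.append(newg)
        return out

    return replace(
        result,
        p_CT=perm_p(F_CT, 2, permute_pops),
        p_SC=perm_p(F_SC, 1, permute_individuals_within_groups),
        p_IS=perm_p(F_IS, 0, permute_alleles_within_pops),
    )


def by_threshold(alpha: float, m: int) -> float:
    """Benjamini-Yekutieli adjusted significance threshold alpha / H(m)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / sum(1.0 / i for i in range(1, m + 1))


def site_summary(
    pops: Sequence[PopulationSample],
    site_sets: Mapping[str, Sequence[str]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-site H_O / H_E / exact HWE p plus mean +/- SD over requested site sets.

    Monomorphic sites are reported with H_E and p empty ("Monomorphic" in the
    printed table) but still contribute their H_O = 0 to regional means.
    """
    rows = []
    for pop in pops:
        mono = pop.monomorphic
        rows.append(
            {
                "site_id": pop.site_id,
                "region": pop.region,
                "n": pop.n,
                "H_O": observed_heterozygosity(pop),
                "H_E": None if mono else unbiased_expected_heterozygosity(pop),
                "hwe_p": None if mono else hwe_exact(pop).p_exact,
                "monomorphic": mono,
            }
        )
    per_site = pd.DataFrame(rows)
    summaries = []
    site_sets = site_sets or {}
    for label, ids in site_sets.items():
        sub = per_site[per_site.site_id.isin(list(ids))]
        ho = sub["H_O"].astype(float)
        summaries.append(
            {
                "set": label,
                "n_sites": len(sub),
                "mean_H_O": float(ho.mean()) if len(sub) else None,
                "sd_H_O": float(ho.std(ddof=1)) if len(sub) > 1 else None,
            }
        )
    return per_site, pd.DataFrame(summaries)
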