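"""Microsatellite population genetics: diversity indices, HWE and linkage tests,
EM null-allele estimation with ENA-corrected Weir–Cockerham FST, hierarchical
AMOVA, and Mantel isolation-by-distance.

Genotypes are unordered diploid allele pairs (positive integer identifiers,
0 = missing) for individuals labelled with a population, populations labelled
with a group (subspecies).  Missing data are handled pairwise-complete per
locus.  All permutation p-values use the (#extreme + 1)/(n + 1) estimator.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GenotypeMatrix",
    "LocusSummary",
    "NullAlleleEstimate",
    "PairwiseFstMatrix",
    "AmovaResult",
    "MantelResult",
    "summarize_loci",
    "hwe_exact_test",
    "linkage_permutation_test",
    "bonferroni",
    "estimate_null_alleles_em",
    "wc_fst",
    "compare_fst_paired_t",
    "amova_three_level",
    "mantel_ibd",
    "haversine_km",
]

MISSING = 0


@dataclass
class GenotypeMatrix:
    """Diploid genotype calls with population/group labels and site coordinates.

    calls : int array (n_individuals, n_loci, 2); allele ids > 0, 0 = missing.
    A call is missing as a whole (both entries 0) or present as a whole.
    """

    individuals: list
    loci: list
    calls: np.ndarray
    population: list  # per individual
    group: dict  # population -> group label
    site_coords: dict = field(default_factory=dict)  # population -> (lon, lat)

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=int)
        n, L = len(self.individuals), len(self.loci)
        if self.calls.shape != (n, L, 2):
            raise ValueError(f"calls must have shape ({n}, {L}, 2)")
        if len(self.population) != n:
            raise ValueError("population label required for every individual")
        for p in set(self.population):
            if p not in self.group:
                raise ValueError(f"population {p!r} has no group label")
        if np.any(self.calls < 0):
            raise ValueError("allele identifiers must be positive (0 = missing)")
        half = (self.calls == MISSING).sum(axis=2)
        if np.any(half == 1):
            raise ValueError("half-missing calls not allowed")
        self.population = list(self.population)

    @property
    def populations(self) -> list:
        seen = []
        for p in self.population:
            if p not in seen:
                seen.append(p)
        return seen

    @property
    def groups(self) -> list:
        seen = []
        for p in self.populations:
            g = self.group[p]
            if g not in seen:
                seen.append(g)
        return seen

    def pop_indices(self, pop) -> np.ndarray:
        return np.array([i for i, p in enumerate(self.population) if p == pop])

    def locus_index(self, locus) -> int:
        return self.loci.index(locus)

    def genotyped_mask(self, l: int) -> np.ndarray:
        return self.calls[:, l, 0] != MISSING

    def missing_rate_per_individual(self) -> np.ndarray:
        return (self.calls[:, :, 0] == MISSING).mean(axis=1)

    def drop_high_missing(self, threshold: float = 0.2) -> "GenotypeMatrix":
        """Keep individuals with missing rate below the threshold (QC filter)."""
        keep = self.missing_rate_per_individual() < threshold
        return self.subset(np.nonzero(keep)[0])

    def subset(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            individuals=[self.individuals[i] for i in idx],
            loci=list(self.loci),
            calls=self.calls[idx],
            population=[self.population[i] for i in idx],
            group=dict(self.group),
            site_coords=dict(self.site_coords),
        )


@dataclass
class LocusSummary:
    locus: str
    population: str  # population label or "All"
    n_genotyped: int
    na: int
    ho: float
    he: float
    ar: float
    pic: float
    hwe_p: float | None = None


@dataclass
class NullAlleleEstimate:
    locus: str
    population: str
    null_freq: float
    visible_freqs: dict  # allele -> adjusted frequency; sums with null_freq to 1
    converged: bool = True
    n_iter: int = 0


@dataclass
class PairwiseFstMatrix:
    populations: list
    theta: np.ndarray
    theta_ena: np.ndarray | None = None
    bootstrap_ci: np.ndarray | None = None  # (n_pop, n_pop, 2)
    n_boot: int = 0

    def as_frame(self, ena: bool = False) -> pd.DataFrame:
        m = self.theta_ena if ena else self.theta
        return pd.DataFrame(m, index=self.populations, columns=self.populations)


@dataclass
class AmovaResult:
    df: dict  # level -> degrees of freedom
    ss: dict  # level -> sum of squares
    sigma2: dict  # level -> variance component
    pct_variation: dict
    fixation: dict  # {"F_CT", "F_SC", "F_ST"}
    p_values: dict | None = None

    def as_frame(self) -> pd.DataFrame:
        levels = ["among_groups", "among_pops_within_groups", "within_pops"]
        return pd.DataFrame(
            {
                "df": [self.df[l] for l in levels],
                "sum_of_squares": [self.ss[l] for l in levels],
                "variance_component": [self.sigma2[l] for l in levels],
                "pct_variation": [self.pct_variation[l] for l in levels],
            },
            index=levels,
        )


@dataclass
class MantelResult:
    r: float
    r_squared: float
    p: float
    n_perm: int
    transform: str = "fst/(1-fst) vs km"


# ---------------------------------------------------------------------------
# allele bookkeeping


def _allele_counts(calls_l: np.ndarray) -> dict:
    """Allele -> count of gene copies among non-missing calls at one locus."""
    flat = calls_l.ravel()
    flat = flat[flat != MISSING]
    alleles, counts = np.unique(flat, return_counts=True)
    return dict(zip(alleles.tolist(), counts.tolist()))


def _freqs(counts: dict) -> dict:
    tot = sum(counts.values())
    return {a: c / tot for a, c in counts.items()}


# ---------------------------------------------------------------------------
# diversity indices


def _rarefied_ar(counts: dict, rarefaction_n: int) -> float:
    """Expected allele count in a sample of ``rarefaction_n`` gene copies
    (hypergeometric rarefaction)."""
    N = sum(counts.values())
    if rarefaction_n > N:
        raise ValueError("rarefaction_n exceeds available gene copies")
    total = 0.0
    for c in counts.values():
        # 1 - C(N - c, n) / C(N, n), computed in log space for stability
        if N - c < rarefaction_n:
            total += 1.0
        else:
            logp = (
                math.lgamma(N - c + 1) - math.lgamma(N - c - rarefaction_n + 1)
                - math.lgamma(N + 1) + math.lgamma(N - rarefaction_n + 1)
            )
            total += 1.0 - math.exp(logp)
    return total


def _locus_pop_summary(calls_l: np.ndarray, rarefaction_n: int | None):
    ok = calls_l[:, 0] != MISSING
    sub = calls_l[ok]
    n = sub.shape[0]
    if n == 0:
        raise ValueError("locus has zero genotyped individuals in a population")
    counts = _allele_counts(sub)
    freqs = _freqs(counts)
    p = np.array(list(freqs.values()))
    na = len(counts)
    ho = float(np.mean(sub[:, 0] != sub[:, 1]))
    sum_p2 = float(np.sum(p**2))
    he = (2 * n / (2 * n - 1)) * (1.0 - sum_p2) if n > 0 else 0.0
    pic = 1.0 - sum_p2 - (np.sum(np.outer(p**2, p**2)) - np.sum(p**4))
    # second term above is sum_{i != j} p_i^2 p_j^2 = sum_{i<j} 2 p_i^2 p_j^2
    if rarefaction_n is None:
        ar = float(na)
    else:
        ar = _rarefied_ar(counts, rarefaction_n)
    return n, na, ho, he, float(pic), ar


def summarize_loci(
    g: GenotypeMatrix,
    rarefaction_n: int | None = None,
    hwe_reps: int = 0,
    seed: int = 0,
) -> list[LocusSummary]:
    """Per-locus, per-population diversity indices plus a pooled "All" row.

    He is Nei's unbiased expected heterozygosity (2n/(2n-1))(1 - Σp²); AR is
    hypergeometric rarefaction to ``rarefaction_n`` gene copies (default: twice
    the smallest per-population genotyped count at each locus); PIC is
    1 - Σp² - Σ_{i<j} 2 p_i² p_j².  If ``hwe_reps`` > 0, a Monte-Carlo HWE exact
    test is run per population x locus.
    """
    out = []
    pops = g.populations
    for l, locus in enumerate(g.loci):
        per_pop_n = []
        for pop in pops:
            idx = g.pop_indices(pop)
            ok = g.calls[idx, l, 0] != MISSING
            per_pop_n.append(int(ok.sum()))
        if min(per_pop_n) == 0:
            raise ValueError(
                f"locus {locus!r} has zero genotyped individuals in a population"
            )
        rn = rarefaction_n if rarefaction_n is not None else 2 * min(per_pop_n)
        for pop in pops + ["All"]:
            if pop == "All":
                calls_l = g.calls[:, l, :]
            else:
                calls_l = g.calls[g.pop_indices(pop), l, :]
            n, na, ho, he, pic, ar = _locus_pop_summary(calls_l, rn)
            hwe_p = None
            if hwe_reps > 0 and pop != "All" and na >= 2 and n >= 5:
                hwe_p = hwe_exact_test(g, locus, pop, n_reps=hwe_reps, seed=seed)
            out.append(
                LocusSummary(
                    locus=locus, population=pop, n_genotyped=n, na=na,
                    ho=ho, he=he, ar=ar, pic=pic, hwe_p=hwe_p,
                )
            )
    return out


def summary_table(summaries: list[LocusSummary]) -> pd.DataFrame:
    """Population-level means over loci (the familiar N / Na / Ho / He / AR table)."""
    df = pd.DataFrame([s.__dict__ for s in summaries])
    agg = df.groupby("population").agg(
        n=("n_genotyped", "max"),
        na=("na", "mean"),
        ho=("ho", "mean"),
        he=("he", "mean"),
        ar=("ar", "mean"),
    )
    return agg


# ---------------------------------------------------------------------------
# HWE exact test (Monte-Carlo, Guo & Thompson flavour)


def _log_cond_prob(genotype_counts: dict, allele_counts: dict, n: int) -> float:
    """log P(genotype array | allele counts) under HWE (multi-allelic exact)."""
    twon = 2 * n
    h = sum(c for (a, b), c in genotype_counts.items() if a != b)
    lp = math.lgamma(n + 1) + h * math.log(2.0)
    for c in genotype_counts.values():
        lp -= math.lgamma(c + 1)
    for m in allele_counts.values():
        lp += math.lgamma(m + 1)
    lp -= math.lgamma(twon + 1)
    return lp


def _genotype_counts(pairs: np.ndarray) -> dict:
    out: dict = {}
    for a, b in pairs:
        key = (min(a, b), max(a, b))
        out[key] = out.get(key, 0) + 1
    return out


def hwe_exact_test(
    g: GenotypeMatrix, locus, population, n_reps: int = 10000, seed: int = 0
) -> float:
    """Monte-Carlo exact test for Hardy–Weinberg proportions at one locus.

    Gene copies are shuffled and re-paired; the p-value is the fraction of
    arrangements whose conditional probability given the allele counts is <=
    that of the observed array ((#<= + 1)/(n_reps + 1)).
    """
    l = g.locus_index(locus)
    idx = g.pop_indices(population)
    calls = g.calls[idx, l, :]
    calls = calls[calls[:, 0] != MISSING]
    n = calls.shape[0]
    if n < 5:
        raise ValueError("need >= 5 genotyped individuals")
    ac = _allele_counts(calls)
    if len(ac) < 2:
        raise ValueError("monomorphic locus: HWE test undefined")
    obs_lp = _log_cond_prob(_genotype_counts(calls), ac, n)
    rng = np.random.default_rng(seed)
    copies = calls.ravel().copy()
    count = 0
    tol = 1e-12
    for _ in range(n_reps):
        rng.shuffle(copies)
        perm = copies.reshape(n, 2)
        lp = _log_cond_prob(_genotype_counts(perm), ac, n)
        if lp <= obs_lp + tol:
            count += 1
    return (count + 1) / (n_reps + 1)


def hwe_exact_enumeration(genotype_pairs: np.ndarray) -> float:
    """Exact HWE p-value by exhaustive enumeration of pairings (oracle, tiny n).

    Enumerates all distinct perfect matchings of the 2n gene copies via
    recursive pairing; feasible for n <= ~8.
    """
    calls = np.asarray(genotype_pairs)
    n = calls.shape[0]
    ac = _allele_counts(calls)
    obs_lp = _log_cond_prob(_genotype_counts(calls), ac, n)

    # enumerate genotype-count tables with the given allele counts by recursion
    alleles = sorted(ac)
    results: dict = {}

    def rec(remaining: tuple, partial: dict):
        total_left = sum(remaining)
        if total_left == 0:
            key = tuple(sorted(partial.items()))
            if key not in results:
                results[key] = _log_cond_prob(dict(partial), ac, n)
            return
        # pick the first allele with copies left, pair one copy with any allele
        i = next(k for k, c in enumerate(remaining) if c > 0)
        for j in range(i, len(alleles)):
            need = 2 if j == i else 1
            if remaining[j] < (need if j == i else 1) or (j == i and remaining[i] < 2):
                if j == i:
                    continue
            if j != i and remaining[j] < 1:
                continue
            new = list(remaining)
            new[i] -= 1
            new[j] -= 1
            if new[i] < 0 or new[j] < 0:
                continue
            key = (alleles[i], alleles[j])
            partial[key] = partial.get(key, 0) + 1
            rec(tuple(new), partial)
            partial[key] -= 1
            if partial[key] == 0:
                del partial[key]

    rec(tuple(ac[a] for a in alleles), {})
    lps = np.array(list(results.values()))
    probs = np.exp(lps - lps.max())
    probs /= probs.sum()
    return float(probs[lps <= obs_lp + 1e-12].sum())


# ---------------------------------------------------------------------------
# linkage (genotypic association) permutation test


def _g_statistic(table: np.ndarray) -> float:
    """Log-likelihood-ratio statistic of a two-way contingency table."""
    table = np.asarray(table, dtype=float)
    rowsum = table.sum(axis=1, keepdims=True)
    colsum = table.sum(axis=0, keepdims=True)
    total = table.sum()
    if total == 0:
        return 0.0
    expected = rowsum * colsum / total
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(table > 0, table * np.log(table / expected), 0.0)
    return float(2.0 * terms.sum())


def _genotype_codes(calls_l: np.ndarray) -> np.ndarray:
    """Integer code per individual for its unordered genotype (-1 = missing)."""
    lo = np.minimum(calls_l[:, 0], calls_l[:, 1])
    hi = np.maximum(calls_l[:, 0], calls_l[:, 1])
    key = lo.astype(np.int64) * 100000 + hi
    key[lo == MISSING] = -1
    _, codes = np.unique(key, return_inverse=True)
    codes[key == -1] = -1
    return codes


def linkage_permutation_test(
    g: GenotypeMatrix, locus_a, locus_b, n_reps: int = 10000, seed: int = 0
) -> float:
    """Permutation test of genotypic linkage disequilibrium between two loci.

    Statistic: summed G (log-likelihood-ratio) over per-population genotype x
    genotype contingency tables; the null is built by permuting locus-b
    genotypes across individuals within populations.
    """
    la, lb = g.locus_index(locus_a), g.locus_index(locus_b)
    for l in (la, lb):
        if len(_allele_counts(g.calls[:, l, :])) < 2:
            raise ValueError("both loci must be polymorphic")
    codes_a = _genotype_codes(g.calls[:, la, :])
    codes_b = _genotype_codes(g.calls[:, lb, :])
    pops = g.populations
    pop_idx = [g.pop_indices(p) for p in pops]

    def stat(cb: np.ndarray) -> float:
        total = 0.0
        for idx in pop_idx:
            a, b = codes_a[idx], cb[idx]
            ok = (a >= 0) & (b >= 0)
            if ok.sum() < 2:
                continue
            au, ai = np.unique(a[ok], return_inverse=True)
            bu, bi = np.unique(b[ok], return_inverse=True)
            table = np.zeros((au.size, bu.size))
            np.add.at(table, (ai, bi), 1)
            total += _g_statistic(table)
        return total

    obs = stat(codes_b)
    rng = np.random.default_rng(seed)
    count = 0
    cb = codes_b.copy()
    for _ in range(n_reps):
        for idx in pop_idx:
            cb[idx] = cb[idx][rng.permutation(idx.size)]
        if stat(cb) >= obs - 1e-12:
            count += 1
    return (count + 1) / (n_reps + 1)


def bonferroni(p_values, alpha: float = 0.05) -> np.ndarray:
    """Bonferroni significance flags: p < alpha / k (statsmodels-backed)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    reject, _, _, _ = multipletests(p, alpha=alpha, method="bonferroni")
    return reject


# ---------------------------------------------------------------------------
# EM null-allele estimation (FreeNA-style gene counting)


def estimate_null_alleles_em(
    g: GenotypeMatrix,
    locus,
    population,
    tol: float = 1e-8,
    max_iter: int = 10000,
    missing_as_null: bool = True,
) -> NullAlleleEstimate:
    """EM estimate of the null-allele frequency at one locus in one population.

    Model: genotypes follow HWE over visible alleles plus one null allele;
    null/visible heterozygotes are observed as visible homozygotes and
    null/null homozygotes as missing data.  ``missing_as_null`` controls
    whether observed missing genotypes enter the likelihood as putative null
    homozygotes (default) or are excluded as true missing.
    """
    l = g.locus_index(locus)
    idx = g.pop_indices(population)
    calls = g.calls[idx, l, :]
    present = calls[calls[:, 0] != MISSING]
    if present.shape[0] < 5:
        raise ValueError("need >= 5 genotyped individuals")
    n_missing = int((calls[:, 0] == MISSING).sum())

    het_counts: dict = {}
    hom_counts: dict = {}
    for a, b in present:
        if a == b:
            hom_counts[a] = hom_counts.get(a, 0) + 1
        else:
            het_counts[(min(a, b), max(a, b))] = het_counts.get((min(a, b), max(a, b)), 0) + 1
    alleles = sorted(_allele_counts(present))
    k = len(alleles)
    n_eff = present.shape[0] + (n_missing if missing_as_null else 0)

    # init: observed frequencies, small null
    freqs = np.array(
        [_freqs(_allele_counts(present)).get(a, 0.0) for a in alleles]
    )
    p_null = 0.05
    freqs = freqs * (1 - p_null)

    a_index = {a: i for i, a in enumerate(alleles)}
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        copy_counts = np.zeros(k)
        null_copies = 0.0
        for (a, b), c in het_counts.items():
            copy_counts[a_index[a]] += c
            copy_counts[a_index[b]] += c
        for a, c in hom_counts.items():
            i = a_index[a]
            pa = freqs[i]
            denom = pa * pa + 2 * pa * p_null
            w_hom = 1.0 if denom <= 0 else (pa * pa) / denom
            copy_counts[i] += c * (2 * w_hom + (1 - w_hom))
            null_copies += c * (1 - w_hom)
        if missing_as_null:
            null_copies += 2.0 * n_missing
        total = 2.0 * n_eff
        new_freqs = copy_counts / total
        new_null = null_copies / total
        delta = max(abs(new_null - p_null), float(np.max(np.abs(new_freqs - freqs))))
        freqs, p_null = new_freqs, new_null
        if delta < tol:
            converged = True
            break

    return NullAlleleEstimate(
        locus=locus,
        population=population,
        null_freq=float(p_null),
        visible_freqs={a: float(freqs[a_index[a]]) for a in alleles},
        converged=converged,
        n_iter=it,
    )


# ---------------------------------------------------------------------------
# Weir–Cockerham theta


def _wc_components_locus(
    calls_by_pop: list[np.ndarray],
    freq_override: list[dict] | None = None,
) -> tuple[float, float, float]:
    """Sum of Weir–Cockerham a, b, c variance components over alleles at one locus.

    ``calls_by_pop`` holds the non-missing (n_i, 2) call arrays per population.
    If ``freq_override`` is given (EM-adjusted visible-allele frequencies per
    population), those frequencies replace the observed ones and the null class
    is excluded (the ENA computation); observed heterozygote proportions are
    retained.
    """
    r = len(calls_by_pop)
    n_i = np.array([c.shape[0] for c in calls_by_pop], dtype=float)
    if np.any(n_i == 0) or r < 2:
        return 0.0, 0.0, 0.0
    nbar = n_i.mean()
    nc = (r * nbar - np.sum(n_i**2) / (r * nbar)) / (r - 1)

    alleles = sorted(set().union(*[_allele_counts(c) for c in calls_by_pop]))
    if freq_override is not None:
        # renormalize the visible-class frequencies to sum to 1 (null excluded)
        pops_freqs = []
        for f in freq_override:
            tot = sum(f.values())
            pops_freqs.append({a: v / tot for a, v in f.items()} if tot > 0 else {})
    else:
        pops_freqs = [_freqs(_allele_counts(c)) for c in calls_by_pop]

    A = B = C = 0.0
    for allele in alleles:
        p_i = np.array([pf.get(allele, 0.0) for pf in pops_freqs])
        h_i = np.array(
            [
                np.mean((c[:, 0] != c[:, 1]) & ((c[:, 0] == allele) | (c[:, 1] == allele)))
                for c in calls_by_pop
            ]
        )
        pbar = np.sum(n_i * p_i) / (r * nbar)
        s2 = np.sum(n_i * (p_i - pbar) ** 2) / ((r - 1) * nbar)
        hbar = np.sum(n_i * h_i) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4.0) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2.0
        A += a
        B += b
        C += c
    return A, B, C


def _theta_from_components(comps: list[tuple[float, float, float]]) -> float:
    """Multi-locus ratio-of-sums estimator."""
    A = sum(c[0] for c in comps)
    denom = sum(c[0] + c[1] + c[2] for c in comps)
    return A / denom if denom != 0 else 0.0


def _pop_calls(g: GenotypeMatrix, pops: list, l: int) -> list[np.ndarray]:
    out = []
    for pop in pops:
        idx = g.pop_indices(pop)
        calls = g.calls[idx, l, :]
        out.append(calls[calls[:, 0] != MISSING])
    return out


def _ena_freqs(g: GenotypeMatrix, pops: list, l: int,
               missing_as_null: bool = True) -> list[dict]:
    freqs = []
    for pop in pops:
        try:
            est = estimate_null_alleles_em(
                g, g.loci[l], pop, missing_as_null=missing_as_null
            )
            freqs.append(est.visible_freqs)
        except ValueError:
            idx = g.pop_indices(pop)
            calls = g.calls[idx, l, :]
            calls = calls[calls[:, 0] != MISSING]
            freqs.append(_freqs(_allele_counts(calls)))
    return freqs


def wc_fst(
    g: GenotypeMatrix,
    scope: str = "pairwise",
    ena: bool = False,
    n_boot: int = 1000,
    seed: int = 0,
    missing_as_null: bool = True,
) -> PairwiseFstMatrix:
    """Weir–Cockerham θ (global or pairwise) with bootstrap-over-loci CIs.

    With ``ena=True`` the matrix is additionally computed from EM-adjusted
    visible-allele frequencies with the null-allele class excluded (the
    "excluding null alleles" correction).
    """
    pops = g.populations
    if len(pops) < 2:
        raise ValueError("need >= 2 populations")
    L = len(g.loci)
    rng = np.random.default_rng(seed)

    def matrix_for(pair_pops: list, use_ena: bool):
        comps = []
        for l in range(L):
            calls_by_pop = _pop_calls(g, pair_pops, l)
            if any(c.shape[0] == 0 for c in calls_by_pop):
                continue
            alleles = set().union(*[_allele_counts(c) for c in calls_by_pop])
            if len(alleles) < 2:
                continue
            fo = _ena_freqs(g, pair_pops, l, missing_as_null) if use_ena else None
            comps.append(_wc_components_locus(calls_by_pop, fo))
        if not comps:
            raise ValueError(f"populations {pair_pops} share no usable loci")
        return comps

    if scope == "global":
        comps = matrix_for(pops, False)
        theta = np.array([[_theta_from_components(comps)]])
        theta_ena = None
        if ena:
            comps_e = matrix_for(pops, True)
            theta_ena = np.array([[_theta_from_components(comps_e)]])
        ci = None
        if n_boot > 0:
            vals = []
            for _ in range(n_boot):
                pick = rng.integers(0, len(comps), len(comps))
                vals.append(_theta_from_components([comps[i] for i in pick]))
            ci = np.percentile(vals, [2.5, 97.5]).reshape(1, 1, 2)
        return PairwiseFstMatrix(
            populations=["global"], theta=theta, theta_ena=theta_ena,
            bootstrap_ci=ci, n_boot=n_boot,
        )

    if scope != "pairwise":
        raise ValueError("scope must be 'global' or 'pairwise'")

    P = len(pops)
    theta = np.zeros((P, P))
    theta_ena = np.zeros((P, P)) if ena else None
    ci = np.zeros((P, P, 2)) if n_boot > 0 else None
    for i, j in combinations(range(P), 2):
        comps = matrix_for([pops[i], pops[j]], False)
        t = _theta_from_components(comps)
        theta[i, j] = theta[j, i] = t
        if ena:
            comps_e = matrix_for([pops[i], pops[j]], True)
            te = _theta_from_components(comps_e)
            theta_ena[i, j] = theta_ena[j, i] = te
        if n_boot > 0:
            vals = []
            for _ in range(n_boot):
                pick = rng.integers(0, len(comps), len(comps))
                vals.append(_theta_from_components([comps[k] for k in pick]))
            lo, hi = np.percentile(vals, [2.5, 97.5])
            ci[i, j] = ci[j, i] = (lo, hi)
    return PairwiseFstMatrix(
        populations=pops, theta=theta, theta_ena=theta_ena,
        bootstrap_ci=ci, n_boot=n_boot,
    )


def compare_fst_paired_t(theta: np.ndarray, theta_ena: np.ndarray) -> tuple[float, float]:
    """Two-sided paired t-test over the off-diagonal pairs of two θ matrices.

    Identical matrices give (t = 0, p = 1); a zero-variance nonzero difference
    gives p = 0 by convention (the difference is deterministic).
    """
    theta = np.asarray(theta, dtype=float)
    theta_ena = np.asarray(theta_ena, dtype=float)
    if theta.shape != theta_ena.shape:
        raise ValueError("matrices must be aligned")
    iu = np.triu_indices_from(theta, k=1)
    x, y = theta[iu], theta_ena[iu]
    if x.size < 2:
        raise ValueError("need >= 2 pairs")
    d = x - y
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            return 0.0, 1.0
        return float(np.inf * np.sign(d.mean())), 0.0
    t, p = stats.ttest_rel(x, y)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# hierarchical AMOVA on gene copies, allele-identity distances


def _amova_ss_locus(copies_by_pop: list[np.ndarray], group_of_pop: np.ndarray):
    """Sums of squares per level at one locus, allele-identity distances.

    For gene copies with d² = 1 when alleles differ, SS within a set of N
    copies equals (1/N) Σ_{i<j} d²_ij = (N - Σ_a m_a²/N) / 2.
    """
    def ss_within(counts: np.ndarray) -> float:
        N = counts.sum()
        if N == 0:
            return 0.0
        return (N - np.sum(counts.astype(float) ** 2) / N) / 2.0

    alleles = sorted(set().union(*[set(np.unique(c)) for c in copies_by_pop if c.size]))
    a_index = {a: i for i, a in enumerate(alleles)}
    K = len(alleles)
    pop_counts = np.zeros((len(copies_by_pop), K))
    for p, c in enumerate(copies_by_pop):
        for a in c:
            pop_counts[p, a_index[a]] += 1

    groups = sorted(set(group_of_pop.tolist()))
    grp_counts = np.zeros((len(groups), K))
    for gi, grp in enumerate(groups):
        grp_counts[gi] = pop_counts[group_of_pop == grp].sum(axis=0)
    tot_counts = pop_counts.sum(axis=0)

    ss_wp = sum(ss_within(pop_counts[p]) for p in range(len(copies_by_pop)))
    ss_wg = sum(ss_within(grp_counts[gi]) for gi in range(len(groups)))
    ss_total = ss_within(tot_counts)
    return {
        "within_pops": ss_wp,
        "among_pops_within_groups": ss_wg - ss_wp,
        "among_groups": ss_total - ss_wg,
    }


def _amova_components(g: GenotypeMatrix, pop_of_ind: list, group_of_pop_map: dict):
    """Variance components summed over loci (per-locus coefficients)."""
    pops = []
    for p in pop_of_ind:
        if p not in pops:
            pops.append(p)
    grp_labels = np.array([group_of_pop_map[p] for p in pops])
    sig_a = sig_b = sig_c = 0.0
    ss_tot = {"among_groups": 0.0, "among_pops_within_groups": 0.0, "within_pops": 0.0}
    pop_arr = np.array(pop_of_ind)
    for l in range(len(g.loci)):
        copies_by_pop = []
        for pop in pops:
            idx = np.nonzero(pop_arr == pop)[0]
            calls = g.calls[idx, l, :]
            calls = calls[calls[:, 0] != MISSING]
            copies_by_pop.append(calls.ravel())
        N_p = np.array([c.size for c in copies_by_pop], dtype=float)
        if np.sum(N_p > 0) < 2:
            continue
        ss = _amova_ss_locus(copies_by_pop, grp_labels)
        for k in ss_tot:
            ss_tot[k] += ss[k]

        groups = sorted(set(grp_labels.tolist()))
        G, P = len(groups), len(pops)
        N = N_p.sum()
        N_g = np.array([N_p[grp_labels == grp].sum() for grp in groups])
        S_g = np.array(
            [np.sum(N_p[grp_labels == grp] ** 2) / N_g[gi] if N_g[gi] > 0 else 0.0
             for gi, grp in enumerate(groups)]
        )
        df_wp = N - P
        df_ap = P - G
        df_ag = G - 1
        if df_wp <= 0 or df_ap <= 0 or df_ag <= 0:
            raise ValueError("AMOVA needs >= 2 groups, nested pops, and copies")
        n1 = (N - S_g.sum()) / df_ap
        n2 = (S_g.sum() - np.sum(N_p**2) / N) / df_ag
        n3 = (N - np.sum(N_g**2) / N) / df_ag

        msd_wp = ss["within_pops"] / df_wp
        msd_ap = ss["among_pops_within_groups"] / df_ap
        msd_ag = ss["among_groups"] / df_ag
        c_l = msd_wp
        b_l = (msd_ap - c_l) / n1
        a_l = (msd_ag - c_l - n2 * b_l) / n3
        sig_a += a_l
        sig_b += b_l
        sig_c += c_l
    return sig_a, sig_b, sig_c, ss_tot


def amova_three_level(
    g: GenotypeMatrix,
    grouping: dict | None = None,
    distance: str = "allele_identity",
    n_perm: int = 10000,
    seed: int = 0,
) -> AmovaResult:
    """Three-level AMOVA (among groups / among populations within groups /
    within populations) on gene copies with allele-identity distances.

    Permutation tests: F_CT permutes whole populations among groups, F_SC
    permutes individuals among populations within groups, F_ST permutes
    individuals among populations across the whole sample.
    """
    if distance != "allele_identity":
        raise ValueError("only allele_identity distances are implemented")
    group_map = dict(g.group) if grouping is None else dict(grouping)
    pops = g.populations
    groups = sorted({group_map[p] for p in pops})
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")

    sig_a, sig_b, sig_c, ss = _amova_components(g, g.population, group_map)
    total = sig_a + sig_b + sig_c
    pct = {
        "among_groups": 100.0 * sig_a / total,
        "among_pops_within_groups": 100.0 * sig_b / total,
        "within_pops": 100.0 * sig_c / total,
    }
    fix = {
        "F_CT": sig_a / total,
        "F_SC": sig_b / (sig_b + sig_c),
        "F_ST": (sig_a + sig_b) / total,
    }
    # df reported on the full-sample gene-copy convention (2N - P etc.)
    n_copies = 2 * len(g.individuals)
    df = {
        "among_groups": len(groups) - 1,
        "among_pops_within_groups": len(pops) - len(groups),
        "within_pops": n_copies - len(pops),
    }

    rng = np.random.default_rng(seed)
    p_values = None
    if n_perm > 0:
        pop_arr = list(g.population)
        cnt = {"F_CT": 0, "F_SC": 0, "F_ST": 0}
        pops_list = list(pops)
        grp_of_pop = [group_map[p] for p in pops_list]
        ind_by_group: dict = {}
        for i, p in enumerate(pop_arr):
            ind_by_group.setdefault(group_map[p], []).append(i)
        for _ in range(n_perm):
            # F_CT: permute population labels' group assignment
            perm_groups = list(grp_of_pop)
            rng.shuffle(perm_groups)
            gm = dict(zip(pops_list, perm_groups))
            a, b, c, _ = _amova_components(g, pop_arr, gm)
            if (a / (a + b + c)) >= fix["F_CT"] - 1e-12:
                cnt["F_CT"] += 1
            # F_SC: permute individuals among pops within their group
            perm_pop = list(pop_arr)
            for grp, idxs in ind_by_group.items():
                labels = [pop_arr[i] for i in idxs]
                rng.shuffle(labels)
                for i, lab in zip(idxs, labels):
                    perm_pop[i] = lab
            a, b, c, _ = _amova_components(g, perm_pop, group_map)
            if (b / (b + c)) >= fix["F_SC"] - 1e-12:
                cnt["F_SC"] += 1
            # F_ST: permute individuals among pops over the whole sample
            perm_pop2 = list(pop_arr)
            rng.shuffle(perm_pop2)
            a, b, c, _ = _amova_components(g, perm_pop2, group_map)
            if ((a + b) / (a + b + c)) >= fix["F_ST"] - 1e-12:
                cnt["F_ST"] += 1
        p_values = {k: (v + 1) / (n_perm + 1) for k, v in cnt.items()}

    return AmovaResult(
        df=df, ss=ss, sigma2={
            "among_groups": sig_a,
            "among_pops_within_groups": sig_b,
            "within_pops": sig_c,
        },
        pct_variation=pct, fixation=fix, p_values=p_values,
    )


# ---------------------------------------------------------------------------
# Mantel isolation-by-distance


def haversine_km(lon1, lat1, lon2, lat2, radius_km: float = 6371.0) -> float:
    """Great-circle distance in km."""
    rad = np.pi / 180.0
    dlat = (lat2 - lat1) * rad
    dlon = (lon2 - lon1) * rad
    a = (
        np.sin(dlat / 2) ** 2
        + np.cos(lat1 * rad) * np.cos(lat2 * rad) * np.sin(dlon / 2) ** 2
    )
    return float(2 * radius_km * np.arcsin(np.sqrt(a)))


def _mantel_r(x: np.ndarray, y: np.ndarray) -> float:
    iu = np.triu_indices_from(x, k=1)
    a, b = x[iu], y[iu]
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        raise ValueError("constant distance matrix")
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def mantel_ibd(
    fst: PairwiseFstMatrix | np.ndarray,
    coords: dict | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    geo: np.ndarray | None = None,
) -> MantelResult:
    """Mantel test of FST/(1 - FST) against great-circle distance (km).

    Negative θ values are clamped to 0 before the transform.  The permutation
    null shuffles population labels (simultaneous row/column permutation);
    the p-value is one-sided for positive association.
    """
    if isinstance(fst, PairwiseFstMatrix):
        theta = fst.theta
        pops = fst.populations
    else:
        theta = np.asarray(fst, dtype=float)
        pops = list(range(theta.shape[0]))
    P = theta.shape[0]
    if P < 4:
        raise ValueError("need >= 4 populations")
    t = np.clip(theta, 0.0, None)
    gen = t / (1.0 - t)
    if geo is None:
        if coords is None:
            raise ValueError("need coords or a geographic distance matrix")
        geo = np.zeros((P, P))
        for i, j in combinations(range(P), 2):
            lon1, lat1 = coords[pops[i]]
            lon2, lat2 = coords[pops[j]]
            geo[i, j] = geo[j, i] = haversine_km(lon1, lat1, lon2, lat2)
        if np.all(geo == 0):
            raise ValueError("all site coordinates coincide")

    r_obs = _mantel_r(gen, geo)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(P)
        if _mantel_r(gen[np.ix_(perm, perm)], geo) >= r_obs - 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return MantelResult(r=r_obs, r_squared=r_obs**2, p=p, n_perm=n_perm)
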