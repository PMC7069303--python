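"""Microsatellite population genetics.

Diversity (allele counts, observed/unbiased expected heterozygosity, F_IS,
rarefied allelic richness), permutation tests for Hardy-Weinberg equilibrium
and pairwise linkage disequilibrium, and the Weir & Cockerham (1984)
theta estimator of F_ST with a percentile bootstrap over loci.

Genotypes travel as a :class:`GenotypeTable`: an n x L x 2 integer array of
allele codes with 0 as the missing sentinel, read from / written to GENEPOP
text files (2- or 3-digit diploid codes).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import gammaln

MISSING = 0


@dataclass
class GenotypeTable:
    individuals: List[str]
    pops: np.ndarray            # population label per individual
    loci: List[str]
    calls: np.ndarray           # n x L x 2 allele codes, 0 = missing

    def __post_init__(self) -> None:
        self.pops = np.asarray(self.pops)
        self.calls = np.asarray(self.calls, dtype=int)
        n, L = len(self.individuals), len(self.loci)
        if self.calls.shape != (n, L, 2):
            raise ValueError(f"calls must be {n} x {L} x 2, got {self.calls.shape}")
        half = (self.calls == MISSING).sum(axis=2) == 1
        if half.any():
            raise ValueError("half-missing calls found: each call needs 2 alleles "
                             "or both missing")

    @property
    def n(self) -> int:
        return len(self.individuals)

    def subset(self, mask: np.ndarray) -> "GenotypeTable":
        idx = np.flatnonzero(mask)
        return GenotypeTable([self.individuals[i] for i in idx],
                             self.pops[idx], self.loci, self.calls[idx])

    def pop_table(self, pop: str) -> "GenotypeTable":
        return self.subset(self.pops == pop)


@dataclass
class FstEstimate:
    theta_global: float
    theta_by_locus: np.ndarray
    ci95: Tuple[float, float]
    n_boot: int
    seed: int
    grouping: str = "habitat_paired"

    @property
    def theta_reported(self) -> float:
        """Point estimate truncated at 0 (reporting convention)."""
        return max(0.0, self.theta_global)


# ---------------------------------------------------------------------------
# GENEPOP I/O
# ---------------------------------------------------------------------------

def read_genepop(path) -> GenotypeTable:
    """Parse a GENEPOP file: title line, locus names, ``Pop`` blocks.

    Allele codes may be 2- or 3-digit; code 0 (``00``/``000``) is missing.
    Population labels follow the GENEPOP convention of naming each block by
    its last individual's identifier.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines:
        raise ValueError(f"{path}: empty file")
    loci: List[str] = []
    i = 1
    while i < len(lines):
        line = lines[i].strip()
        if line.lower() == "pop":
            break
        if line:
            loci.extend(s.strip() for s in line.split(",") if s.strip())
        i += 1
    if not loci:
        raise ValueError(f"{path}: no locus names before first 'Pop'")

    individuals: List[str] = []
    pop_of: List[int] = []
    calls: List[List[Tuple[int, int]]] = []
    block_last_id: List[str] = []
    n_pops = 0
    for lineno in range(i, len(lines)):
        line = lines[lineno].strip()
        if not line:
            continue
        if line.lower() == "pop":
            n_pops += 1
            block_last_id.append("")
            continue
        if "," not in line:
            raise ValueError(f"{path}: line {lineno + 1}: expected 'id , genotypes'")
        ind_id, geno = line.split(",", 1)
        ind_id = ind_id.strip()
        tokens = geno.split()
        if len(tokens) != len(loci):
            raise ValueError(
                f"{path}: line {lineno + 1}: {len(tokens)} genotypes for "
                f"{len(loci)} loci")
        row = []
        for tok in tokens:
            if len(tok) not in (4, 6) or not tok.isdigit():
                raise ValueError(
                    f"{path}: line {lineno + 1}: bad genotype code {tok!r} "
                    "(need 4 or 6 digits)")
            half = len(tok) // 2
            row.append((int(tok[:half]), int(tok[half:])))
        individuals.append(ind_id)
        pop_of.append(n_pops - 1)
        calls.append(row)
        block_last_id[-1] = ind_id
    if not individuals:
        raise ValueError(f"{path}: no individuals")
    pop_labels = np.array([block_last_id[p] for p in pop_of])
    return GenotypeTable(individuals, pop_labels, loci,
                         np.array(calls, dtype=int))


def write_genepop(table: GenotypeTable, path, title: str = "synthetic genotypes",
                  digits: int = 3) -> None:
    fmt = f"{{:0{digits}d}}"
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for locus in table.loci:
            fh.write(locus + "\n")
        seen: List[str] = []
        for p in table.pops:
            if p not in seen:
                seen.append(p)
        for pop in seen:
            fh.write("Pop\n")
            for i in np.flatnonzero(table.pops == pop):
                codes = " ".join(
                    fmt.format(a) + fmt.format(b) for a, b in table.calls[i])
                fh.write(f"{table.individuals[i]} ,  {codes}\n")


# ---------------------------------------------------------------------------
# Diversity
# ---------------------------------------------------------------------------

def _allele_counts(calls_1locus: np.ndarray) -> Dict[int, int]:
    alleles = calls_1locus[calls_1locus != MISSING]
    vals, counts = np.unique(alleles, return_counts=True)
    return dict(zip(vals.tolist(), counts.tolist()))


def rarefied_richness(allele_counts: Dict[int, int], g: int) -> float:
    """Expected allele count in a subsample of ``g`` gene copies.

    A_R = sum_a [1 - C(2N - N_a, g) / C(2N, g)]; at g = 2N this equals the
    observed allele number; it is nondecreasing in g.
    """
    total = sum(allele_counts.values())
    if g > total:
        raise ValueError(f"rarefaction size g={g} exceeds gene copies {total}")
    def log_comb(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    ar = 0.0
    for na in allele_counts.values():
        if total - na < g:
            ar += 1.0
        else:
            ar += 1.0 - math.exp(log_comb(total - na, g) - log_comb(total, g))
    return ar


def diversity(table: GenotypeTable, rarefaction_g: Optional[int] = None) -> pd.DataFrame:
    """Per-population x locus diversity statistics.

    Columns: N (individuals genotyped), NA (allele count), Ho (observed
    heterozygosity), He (Nei unbiased expected heterozygosity,
    ``2n/(2n-1) * (1 - sum p^2)``), F_IS (= 1 - Ho/He, NaN when He = 0), and
    A_R (allelic richness rarefied to ``g`` gene copies, where ``g`` defaults
    to twice the global minimum per-cell sample size). Population means are in
    ``result.attrs["pop_means"]``.
    """
    pops = [p for p in pd.unique(table.pops)]
    cells = []
    min_n = None
    for pop in pops:
        sub = table.pop_table(pop)
        for li, locus in enumerate(table.loci):
            calls = sub.calls[:, li, :]
            present = calls[:, 0] != MISSING
            n = int(present.sum())
            if n == 0:
                warnings.warn(f"pop {pop!r}, locus {locus!r}: no data; "
                              "cell statistics undefined")
            cells.append((pop, locus, calls[present]))
            if n > 0:
                min_n = n if min_n is None else min(min_n, n)
    if min_n is None:
        raise ValueError("no genotyped individuals in any population")
    g = rarefaction_g if rarefaction_g is not None else 2 * min_n

    rows = []
    for pop, locus, calls in cells:
        n = calls.shape[0]
        if n == 0:
            rows.append({"pop": pop, "locus": locus, "N": 0, "NA": np.nan,
                         "Ho": np.nan, "He": np.nan, "F_IS": np.nan, "A_R": np.nan})
            continue
        counts = _allele_counts(calls.reshape(-1))
        na = len(counts)
        ho = float((calls[:, 0] != calls[:, 1]).mean())
        p = np.array(list(counts.values()), float)
        p = p / p.sum()
        he = (2 * n / (2 * n - 1)) * (1 - float((p**2).sum()))
        fis = 1 - ho / he if he > 0 else np.nan
        ar = rarefied_richness(counts, min(g, 2 * n))
        rows.append({"pop": pop, "locus": locus, "N": n, "NA": na,
                     "Ho": ho, "He": he, "F_IS": fis, "A_R": ar})
    out = pd.DataFrame(rows)
    out.attrs["rarefaction_g"] = g
    out.attrs["pop_means"] = (
        out.groupby("pop", sort=False)[["NA", "A_R", "He", "Ho", "F_IS"]]
        .mean().reset_index())
    return out


# ---------------------------------------------------------------------------
# Permutation tests
# ---------------------------------------------------------------------------

def _fis_from_alleles(a1: np.ndarray, a2: np.ndarray) -> float:
    n = a1.shape[0]
    ho = float((a1 != a2).mean())
    alleles = np.concatenate([a1, a2])
    _, counts = np.unique(alleles, return_counts=True)
    p = counts / counts.sum()
    he = (2 * n / (2 * n - 1)) * (1 - float((p**2).sum()))
    if he == 0:
        return np.nan
    return 1 - ho / he


def hwe_test(table: GenotypeTable, locus: str, population: str,
             n_perm: int = 10_000, seed: int = 0) -> Dict[str, float]:
    """Permutation test of Hardy-Weinberg equilibrium in one sample.

    The statistic is the sample F_IS; the null distribution is obtained by
    shuffling the 2n allele copies among individuals (which preserves allele
    frequencies, hence He, so the test is equivalently on Ho). Returns the
    two-sided p and the one-sided heterozygote-deficit p.
    """
    li = table.loci.index(locus)
    sub = table.pop_table(population)
    calls = sub.calls[:, li, :]
    calls = calls[calls[:, 0] != MISSING]
    n = calls.shape[0]
    if n < 5:
        raise ValueError(f"need >= 5 genotyped individuals, got {n}")
    if len(np.unique(calls)) < 2:
        return {"f_is": np.nan, "p_two_sided": np.nan, "p_deficit": np.nan, "n": n}
    f_obs = _fis_from_alleles(calls[:, 0], calls[:, 1])

    alleles = calls.reshape(-1)
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(alleles, (n_perm, 1)), axis=1)
    a1, a2 = perms[:, :n], perms[:, n:]
    ho_perm = (a1 != a2).mean(axis=1)
    # He is permutation-invariant; compare via Ho (F_IS decreasing in Ho).
    # Ho is heavily tied (multiples of 1/n), so ties enter with half weight
    # (mid-p); a plain >= rule is markedly conservative here.
    ho_obs = float((calls[:, 0] != calls[:, 1]).mean())
    eps = 0.5 / n
    n_below = np.sum(ho_perm < ho_obs - eps)
    n_above = np.sum(ho_perm > ho_obs + eps)
    n_tied = n_perm - n_below - n_above
    p_deficit = (n_below + 0.5 * n_tied + 1) / (n_perm + 1)
    p_excess = (n_above + 0.5 * n_tied + 1) / (n_perm + 1)
    p_two = min(1.0, 2 * min(p_deficit, p_excess))
    return {"f_is": f_obs, "p_two_sided": p_two, "p_deficit": p_deficit, "n": n}


def hwe_scan(table: GenotypeTable, n_perm: int = 2000, seed: int = 0,
             alpha: float = 0.05) -> pd.DataFrame:
    """HWE deficit test over all population x locus cells, Bonferroni-flagged.

    A significant heterozygote deficit after Bonferroni correction also raises
    the ``null_allele_suspect`` flag for that cell (heterozygote-deficit
    screen standing in for dedicated null-allele inference).
    """
    rows = []
    pops = list(pd.unique(table.pops))
    rng = np.random.default_rng(seed)
    for pop in pops:
        for locus in table.loci:
            try:
                res = hwe_test(table, locus, pop, n_perm=n_perm,
                               seed=int(rng.integers(2**31)))
            except ValueError:
                res = {"f_is": np.nan, "p_two_sided": np.nan,
                       "p_deficit": np.nan, "n": 0}
            rows.append({"pop": pop, "locus": locus, **res})
    out = pd.DataFrame(rows)
    m = out["p_deficit"].notna().sum()
    out["bonferroni_sig"] = out["p_deficit"] < alpha / max(m, 1)
    out["null_allele_suspect"] = out["bonferroni_sig"]
    return out


def ld_test(table: GenotypeTable, locus_pair: Tuple[str, str], population: str,
            n_perm: int = 10_000, seed: int = 0) -> Dict[str, float]:
    """Permutation G-test of genotypic linkage disequilibrium.

    The statistic is the log-likelihood-ratio G on the two-locus genotype
    contingency table; the null is generated by permuting one locus's
    genotypes among individuals, breaking between-locus association while
    preserving single-locus genotype frequencies.
    """
    la, lb = (table.loci.index(l) for l in locus_pair)
    sub = table.pop_table(population)
    ca, cb = sub.calls[:, la, :], sub.calls[:, lb, :]
    ok = (ca[:, 0] != MISSING) & (cb[:, 0] != MISSING)
    ca, cb = ca[ok], cb[ok]
    n = ca.shape[0]
    ga = np.array([f"{min(a)}/{max(a)}" for a in ca])
    gb = np.array([f"{min(b)}/{max(b)}" for b in cb])
    if len(np.unique(ga)) < 2 or len(np.unique(gb)) < 2:
        return {"g": np.nan, "p": np.nan, "n": n}

    ua, ia = np.unique(ga, return_inverse=True)
    ub, ib = np.unique(gb, return_inverse=True)

    def g_stat(ia_, ib_):
        obs = np.zeros((len(ua), len(ub)))
        np.add.at(obs, (ia_, ib_), 1)
        rowsum = obs.sum(axis=1, keepdims=True)
        colsum = obs.sum(axis=0, keepdims=True)
        exp = rowsum * colsum / n
        mask = obs > 0
        return 2.0 * float((obs[mask] * np.log(obs[mask] / exp[mask])).sum())

    g_obs = g_stat(ia, ib)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        count += g_stat(ia, rng.permutation(ib)) >= g_obs - 1e-12
    p = (count + 1) / (n_perm + 1)
    return {"g": g_obs, "p": p, "n": n}


# ---------------------------------------------------------------------------
# Weir-Cockerham theta
# ---------------------------------------------------------------------------

def _wc_components_locus(samples: Sequence[np.ndarray]) -> Tuple[float, float]:
    """Sum of a and a+b+c over alleles for one locus, r >= 2 samples.

    ``samples`` holds each sample's non-missing n x 2 calls. Implements the
    per-allele variance components: a (among samples), b (among individuals
    within samples), c (within individuals).
    """
    samples = [s for s in samples if s.shape[0] > 0]
    r = len(samples)
    if r < 2:
        return 0.0, 0.0
    ns = np.array([s.shape[0] for s in samples], float)
    nbar = ns.mean()
    nsum = ns.sum()
    if nbar <= 1:
        return 0.0, 0.0
    nc = (nsum - (ns**2).sum() / nsum) / (r - 1)
    alleles = np.unique(np.concatenate([s.reshape(-1) for s in samples]))
    if len(alleles) < 2:
        return 0.0, 0.0
    a_sum = abc_sum = 0.0
    for al in alleles:
        p_i = np.array([ (s == al).mean() for s in samples ])
        h_i = np.array([ ((s[:, 0] == al) ^ (s[:, 1] == al)).mean() for s in samples ])
        pbar = float((ns * p_i).sum() / nsum)
        s2 = float((ns * (p_i - pbar)**2).sum() / ((r - 1) * nbar))
        hbar = float((ns * h_i).sum() / nsum)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
                           / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                   - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        a_sum += a
        abc_sum += a + b + c
    return a_sum, abc_sum


def _habitat_of(pop: str) -> str:
    return pop.rsplit("-", 1)[-1]


def _lake_of(pop: str) -> str:
    return pop.rsplit("-", 1)[0]


def wc_fst(table: GenotypeTable, grouping: str = "habitat_paired",
           n_boot: int = 10_000, seed: int = 0) -> FstEstimate:
    """Multilocus Weir-Cockerham theta with a percentile bootstrap over loci.

    Population labels must be ``"<lake>-<habitat>"``. Groupings:

    - ``habitat_paired`` (default): within each lake, contrast the littoral
      and pelagic samples; variance components are summed over alleles, loci
      and lakes before the ratio is taken (global littoral-pelagic estimate
      over lake pairs).
    - ``habitat_pooled``: pool all littoral vs. all pelagic individuals into
      two samples.
    - ``lake``: contrast the lakes (habitats pooled within lake).
    - ``pop``: contrast the raw population labels.

    Theta is the ratio of sums Sigma(a) / Sigma(a+b+c); negative estimates are
    reported as computed (``theta_reported`` truncates at 0). The 95% CI is a
    percentile bootstrap resampling loci; for a ratio-of-sums estimator the
    point estimate is not guaranteed to lie inside the CI.
    """
    L = len(table.loci)
    pops = table.pops

    def sample_masks() -> List[List[np.ndarray]]:
        if grouping == "habitat_pooled":
            habs = np.array([_habitat_of(p) for p in pops])
            return [[habs == h for h in np.unique(habs)]]
        if grouping == "lake":
            lakes = np.array([_lake_of(p) for p in pops])
            return [[lakes == l for l in np.unique(lakes)]]
        if grouping == "pop":
            return [[pops == p for p in np.unique(pops)]]
        if grouping == "habitat_paired":
            lakes = np.array([_lake_of(p) for p in pops])
            habs = np.array([_habitat_of(p) for p in pops])
            groups = []
            for lake in np.unique(lakes):
                masks = [(lakes == lake) & (habs == h) for h in np.unique(habs)]
                masks = [m for m in masks if m.any()]
                if len(masks) >= 2:
                    groups.append(masks)
            return groups
        raise ValueError(f"unknown grouping {grouping!r}")

    groups = sample_masks()
    if not groups:
        raise ValueError("no contrastable sample groups under this grouping")

    a_loc = np.zeros(L)
    abc_loc = np.zeros(L)
    for li in range(L):
        for masks in groups:
            samples = []
            for m in masks:
                calls = table.calls[m, li, :]
                samples.append(calls[calls[:, 0] != MISSING])
            a, abc = _wc_components_locus(samples)
            a_loc[li] += a
            abc_loc[li] += abc
    if abc_loc.sum() == 0:
        raise ValueError("all loci monomorphic: theta undefined")
    theta = float(a_loc.sum() / abc_loc.sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        theta_by_locus = np.where(abc_loc > 0, a_loc / abc_loc, np.nan)

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, L, size=(n_boot, L))
    a_b = a_loc[idx].sum(axis=1)
    abc_b = abc_loc[idx].sum(axis=1)
    ok = abc_b != 0
    boot = a_b[ok] / abc_b[ok]
    lo, hi = (float(np.percentile(boot, 2.5)), float(np.percentile(boot, 97.5))) \
        if boot.size else (np.nan, np.nan)
    return FstEstimate(theta, theta_by_locus, (lo, hi), n_boot, seed, grouping)
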