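"""Bayesian genetic stock identification against a colony baseline.

The model is the standard conditional GSI setup: colony allele counts with
a Dirichlet prior (alpha = 1/A per allele, A = alleles observed at the
locus) give a posterior-predictive probability for each multilocus
genotype; self-assignment uses leave-one-out counts; mixture (bycatch)
analysis runs a conditional Gibbs sampler over mixing proportions pi and
per-individual colony allocations z (pi ~ Dirichlet(1/K), z_i | pi
categorical, genotype likelihoods fixed from the baseline).  z-scores
standardize an individual's log-likelihood against its assigned colony's
own genotype distribution to flag birds from unsampled populations.

For an unordered genotype (a, b) at a locus with colony counts y and total
n, theta = sum(alpha):

    P(a,a) = (y_a + alpha_a) (y_a + alpha_a + 1) / ((n + theta)(n + 1 + theta))
    P(a,b) = 2 (y_a + alpha_a) (y_b + alpha_b) / ((n + theta)(n + 1 + theta))

which sums to 1 over all unordered genotypes.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import GenotypeTable, MISSING_ALLELE

logger = logging.getLogger("fulmargsi")


# ---------------------------------------------------------------------------
# baseline
# ---------------------------------------------------------------------------

@dataclass
class BaselineCounts:
    """Per colony x locus x allele counts plus the Dirichlet prior.

    The allele universe at each locus is fixed up front from the reference
    and (optionally) the mixture jointly, so novel mixture alleles receive
    prior mass instead of zero probability.
    """

    colonies: list                  # colony names, fixed order
    loci: list                      # locus ids, fixed order
    alleles: list                   # per locus: list of allele strings
    y: list                         # per locus: (K, A_l) count matrix
    n: np.ndarray                   # (K, L) total allele copies
    alpha: list                     # per locus: (A_l,) prior, each 1/A_l
    # encoded reference (for LOO): genotype allele indices, -1 = missing
    ref_samples: list = field(default_factory=list)
    ref_labels: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    ref_geno: np.ndarray = field(default_factory=lambda: np.empty((0, 0, 2), int))

    @property
    def K(self) -> int:
        return len(self.colonies)

    @property
    def L(self) -> int:
        return len(self.loci)


def _encode_table(table: GenotypeTable, loci: Sequence[str],
                  allele_index: Sequence[Mapping[str, int]]) -> tuple:
    """Encode a genotype table as (samples, geno[i, l, 2] allele indices).

    Missing calls and loci absent for a sample encode as -1.  Raises on an
    allele outside the locus's universe.
    """
    samples = sorted(table.calls["sample_id"].unique())
    s_index = {s: i for i, s in enumerate(samples)}
    l_index = {l: i for i, l in enumerate(loci)}
    geno = np.full((len(samples), len(loci), 2), -1, dtype=np.int32)
    df = table.calls
    for row in df.itertuples(index=False):
        l = l_index.get(row.locus_id)
        if l is None:
            continue
        if row.allele_1 == MISSING_ALLELE:
            continue
        ai = allele_index[l]
        try:
            geno[s_index[row.sample_id], l, 0] = ai[row.allele_1]
            geno[s_index[row.sample_id], l, 1] = ai[row.allele_2]
        except KeyError as exc:
            raise KeyError(
                f"allele {exc} at locus {row.locus_id} not in the allele "
                "universe; build the baseline with the mixture included") from None
    return samples, geno


def build_baseline(reference: GenotypeTable, labels: Mapping[str, str] | pd.Series,
                   mixture: GenotypeTable | None = None) -> BaselineCounts:
    """Count reference allele copies per colony and set the 1/A prior.

    ``mixture`` only contributes alleles to the locus allele universes
    (so they get prior mass); its genotypes are never counted into y.
    """
    labels = pd.Series(labels)
    ref = reference.calls
    ref = ref[ref["sample_id"].isin(labels.index)]
    if ref[ref["allele_1"] != MISSING_ALLELE].empty:
        raise ValueError("empty reference: no non-missing calls")
    loci = sorted(ref["locus_id"].unique())
    universe: dict[str, set] = {l: set() for l in loci}
    for frame in ([ref] if mixture is None else [ref, mixture.calls]):
        called = frame[frame["allele_1"] != MISSING_ALLELE]
        for locus, sub in called.groupby("locus_id"):
            if locus in universe:
                universe[locus] |= set(sub["allele_1"]) | set(sub["allele_2"])
    alleles = [sorted(universe[l]) for l in loci]
    allele_index = [{a: i for i, a in enumerate(al)} for al in alleles]

    colonies = sorted(labels.unique())
    c_index = {c: k for k, c in enumerate(colonies)}
    samples, geno = _encode_table(GenotypeTable(ref), loci, allele_index)
    ref_labels = np.array([c_index[labels[s]] for s in samples], dtype=np.int32)

    K, L = len(colonies), len(loci)
    y = [np.zeros((K, len(al))) for al in alleles]
    n = np.zeros((K, L))
    for l in range(L):
        called = geno[:, l, 0] >= 0
        for copy in (0, 1):
            np.add.at(y[l], (ref_labels[called], geno[called, l, copy]), 1.0)
        n[:, l] = y[l].sum(axis=1)
    alpha = [np.full(len(al), 1.0 / len(al)) for al in alleles]
    return BaselineCounts(colonies=colonies, loci=loci, alleles=alleles,
                          y=y, n=n, alpha=alpha, ref_samples=samples,
                          ref_labels=ref_labels, ref_geno=geno)


# ---------------------------------------------------------------------------
# posterior-predictive genotype likelihood
# ---------------------------------------------------------------------------

def genotype_log_likelihood(a: int, b: int, y: np.ndarray, alpha: np.ndarray,
                            n: float) -> float:
    """Log posterior-predictive probability of unordered genotype (a, b)
    given colony counts ``y`` (one locus) and prior ``alpha``."""
    theta = alpha.sum()
    denom = (n + theta) * (n + 1.0 + theta)
    if a == b:
        num = (y[a] + alpha[a]) * (y[a] + alpha[a] + 1.0)
    else:
        num = 2.0 * (y[a] + alpha[a]) * (y[b] + alpha[b])
    return math.log(num / denom)


def _locus_loglik_matrix(geno_l: np.ndarray, y_l: np.ndarray,
                         alpha_l: np.ndarray, n_l: np.ndarray) -> np.ndarray:
    """Vectorized per-locus log-likelihoods: (n_individuals, K).

    geno_l: (N, 2) allele indices (-1 missing, contributes 0);
    y_l: (K, A); n_l: (K,).
    """
    N = geno_l.shape[0]
    K = y_l.shape[0]
    out = np.zeros((N, K))
    called = geno_l[:, 0] >= 0
    if not called.any():
        return out
    a = geno_l[called, 0]
    b = geno_l[called, 1]
    theta = alpha_l.sum()
    post = y_l + alpha_l[None, :]           # (K, A)
    denom = (n_l + theta) * (n_l + 1.0 + theta)   # (K,)
    pa = post[:, a]                          # (K, m)
    pb = post[:, b]
    hom = (a == b)
    num = np.where(hom[None, :], pa * (pa + 1.0), 2.0 * pa * pb)
    out[called] = (np.log(num) - np.log(denom)[:, None]).T
    return out


def likelihood_matrix(baseline: BaselineCounts, geno: np.ndarray) -> np.ndarray:
    """Multilocus log-likelihood logL[i, k] for encoded genotypes."""
    N = geno.shape[0]
    logL = np.zeros((N, baseline.K))
    for l in range(baseline.L):
        logL += _locus_loglik_matrix(geno[:, l, :], baseline.y[l],
                                     baseline.alpha[l], baseline.n[:, l])
    return logL


def encode_mixture(baseline: BaselineCounts, mixture: GenotypeTable) -> tuple:
    allele_index = [{a: i for i, a in enumerate(al)} for al in baseline.alleles]
    return _encode_table(mixture, baseline.loci, allele_index)


# ---------------------------------------------------------------------------
# self-assignment (leave-one-out)
# ---------------------------------------------------------------------------

@dataclass
class SelfAssignResult:
    assignments: pd.DataFrame      # per reference bird
    confusion: pd.DataFrame        # true colony x assigned colony (assigned only)
    accuracy_assigned: float       # accuracy among birds passing the threshold
    accuracy_all: float            # MAP accuracy over everyone
    fraction_assigned: float


def self_assign_loo(baseline: BaselineCounts, threshold: float = 0.9
                    ) -> SelfAssignResult:
    """Leave-one-out self-assignment of every reference bird.

    Each bird's own allele copies are subtracted from its colony's counts
    before scoring, then posterior[k] ∝ L_ik with a flat 1/K colony prior.
    """
    geno = baseline.ref_geno
    N = geno.shape[0]
    logL = likelihood_matrix(baseline, geno)
    # correct own-colony column by recomputing with LOO counts per locus
    for l in range(baseline.L):
        y_l = baseline.y[l]
        alpha_l = baseline.alpha[l]
        called = geno[:, l, 0] >= 0
        if not called.any():
            continue
        idx = np.where(called)[0]
        a = geno[idx, l, 0]
        b = geno[idx, l, 1]
        k = baseline.ref_labels[idx]
        ya = y_l[k, a] - (1 + (a == b))
        yb = y_l[k, b] - (1 + (a == b))
        if (ya < 0).any():
            raise RuntimeError("LOO subtraction below zero: counts inconsistent")
        n_loo = baseline.n[k, l] - 2.0
        theta = alpha_l.sum()
        denom = (n_loo + theta) * (n_loo + 1.0 + theta)
        hom = a == b
        num = np.where(hom, (ya + alpha_l[a]) * (ya + alpha_l[a] + 1.0),
                       2.0 * (ya + alpha_l[a]) * (yb + alpha_l[b]))
        # replace this locus's own-colony contribution
        full = _locus_loglik_matrix(geno[idx, l, :], y_l, alpha_l,
                                    baseline.n[:, l])
        logL[idx, k] += np.log(num / denom) - full[np.arange(len(idx)), k]
    post = _normalize_rows(logL)
    return _summarize_assignments(baseline, post, threshold)


def _normalize_rows(logL: np.ndarray) -> np.ndarray:
    m = logL.max(axis=1, keepdims=True)
    w = np.exp(logL - m)
    return w / w.sum(axis=1, keepdims=True)


def _summarize_assignments(baseline: BaselineCounts, post: np.ndarray,
                           threshold: float) -> SelfAssignResult:
    colonies = baseline.colonies
    map_idx = post.argmax(axis=1)
    max_post = post.max(axis=1)
    assigned = max_post >= threshold
    true_names = [colonies[k] for k in baseline.ref_labels]
    df = pd.DataFrame({"sample_id": baseline.ref_samples,
                       "true_colony": true_names})
    for k, c in enumerate(colonies):
        df[f"posterior_{c}"] = post[:, k]
    df["map_colony"] = [colonies[k] for k in map_idx]
    df["max_posterior"] = max_post
    df["assigned"] = assigned
    correct = map_idx == baseline.ref_labels
    acc_all = float(correct.mean()) if len(correct) else float("nan")
    acc_assigned = (float(correct[assigned].mean()) if assigned.any()
                    else float("nan"))
    confusion = pd.crosstab(
        pd.Series(np.array(true_names)[assigned], name="true"),
        pd.Series(np.array([colonies[k] for k in map_idx])[assigned],
                  name="assigned")).reindex(index=colonies, columns=colonies,
                                            fill_value=0)
    return SelfAssignResult(assignments=df, confusion=confusion,
                            accuracy_assigned=acc_assigned,
                            accuracy_all=acc_all,
                            fraction_assigned=float(assigned.mean()))


# ---------------------------------------------------------------------------
# mixture (Gibbs)
# ---------------------------------------------------------------------------

@dataclass
class MixtureResult:
    assignments: pd.DataFrame      # per bycatch bird posteriors + z-score
    pi_mean: np.ndarray            # posterior mean mixing proportions
    pi_summary: pd.DataFrame       # mean + 90% credible interval per colony
    membership: np.ndarray         # (N, K) posterior membership probabilities
    samples: list


def infer_mixture(baseline: BaselineCounts, mixture: GenotypeTable,
                  sweeps: int = 2000, burn_in: int = 100, seed: int = 0,
                  threshold: float = 0.9) -> MixtureResult:
    """Conditional Gibbs sampler for mixing proportions and memberships.

    One sweep: draw z_i | pi ~ Categorical(pi_k L_ik) for every bird, then
    pi | z ~ Dirichlet(1/K + n_k).  Post-burn-in means of pi and of the
    membership indicators are reported.  Deterministic given the seed.
    """
    if sweeps <= burn_in:
        raise ValueError(f"need sweeps > burn_in, got {sweeps} <= {burn_in}")
    samples, geno = encode_mixture(baseline, mixture)
    logL = likelihood_matrix(baseline, geno)
    N, K = logL.shape
    rng = np.random.default_rng(seed)
    L_scaled = np.exp(logL - logL.max(axis=1, keepdims=True))  # (N, K)

    pi = np.full(K, 1.0 / K)
    z_mean = np.zeros((N, K))
    pi_draws = np.zeros((sweeps - burn_in, K))
    for sweep in range(sweeps):
        w = L_scaled * pi[None, :]
        w /= w.sum(axis=1, keepdims=True)
        u = rng.random((N, 1))
        z = (u > w.cumsum(axis=1)).sum(axis=1)
        counts = np.bincount(z, minlength=K)
        pi = rng.dirichlet(1.0 / K + counts)
        if sweep >= burn_in:
            pi_draws[sweep - burn_in] = pi
            z_mean[np.arange(N), z] += 1.0
    z_mean /= sweeps - burn_in
    pi_mean = pi_draws.mean(axis=0)
    lo, hi = np.percentile(pi_draws, [5, 95], axis=0)
    pi_summary = pd.DataFrame({"colony": baseline.colonies, "pi_mean": pi_mean,
                               "ci_5": lo, "ci_95": hi})

    map_idx = z_mean.argmax(axis=1)
    max_post = z_mean.max(axis=1)
    assigned = max_post >= threshold
    zs = z_scores(baseline, geno, map_idx, logL)
    df = pd.DataFrame({"sample_id": samples})
    for k, c in enumerate(baseline.colonies):
        df[f"posterior_{c}"] = z_mean[:, k]
    df["map_colony"] = [baseline.colonies[k] for k in map_idx]
    df["max_posterior"] = max_post
    df["z_score"] = zs
    df["assigned"] = assigned
    logger.info("infer_mixture: %d birds, %.1f%% assigned at %.2f",
                N, 100 * assigned.mean(), threshold)
    return MixtureResult(assignments=df, pi_mean=pi_mean,
                         pi_summary=pi_summary, membership=z_mean,
                         samples=samples)


# ---------------------------------------------------------------------------
# z-scores
# ---------------------------------------------------------------------------

def _locus_moments(baseline: BaselineCounts) -> tuple:
    """Per colony x locus mean and variance of log P(genotype) under the
    colony's own posterior-predictive genotype distribution."""
    K, L = baseline.K, baseline.L
    mu = np.zeros((K, L))
    var = np.zeros((K, L))
    for l in range(L):
        y_l, alpha_l = baseline.y[l], baseline.alpha[l]
        A = len(alpha_l)
        theta = alpha_l.sum()
        post = y_l + alpha_l[None, :]                   # (K, A)
        denom = ((baseline.n[:, l] + theta)
                 * (baseline.n[:, l] + 1.0 + theta))    # (K,)
        ii, jj = np.triu_indices(A)
        hom = ii == jj
        num = np.where(hom, post[:, ii] * (post[:, ii] + 1.0),
                       2.0 * post[:, ii] * post[:, jj])  # (K, G)
        p = num / denom[:, None]
        logp = np.log(p)
        mu[:, l] = (p * logp).sum(axis=1)
        var[:, l] = (p * logp ** 2).sum(axis=1) - mu[:, l] ** 2
    return mu, var


def z_scores(baseline: BaselineCounts, geno: np.ndarray,
             map_idx: np.ndarray, logL: np.ndarray | None = None) -> np.ndarray:
    """Standardized log-likelihood of each bird under its MAP colony.

    z = (logL_obs - sum_l mu_l) / sqrt(sum_l var_l) over the bird's
    non-missing loci; birds with no scorable loci (or zero variance) get NaN.
    """
    if logL is None:
        logL = likelihood_matrix(baseline, geno)
    mu, var = _locus_moments(baseline)
    called = geno[:, :, 0] >= 0                        # (N, L)
    mu_i = (called * mu[map_idx, :]).sum(axis=1)
    var_i = (called * var[map_idx, :]).sum(axis=1)
    obs = logL[np.arange(len(map_idx)), map_idx]
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (obs - mu_i) / np.sqrt(var_i)
    z[~called.any(axis=1)] = np.nan
    z[var_i <= 0] = np.nan
    return z


# ---------------------------------------------------------------------------
# downsampling
# ---------------------------------------------------------------------------

def downsample_reference(reference: GenotypeTable,
                         labels: Mapping[str, str] | pd.Series,
                         target_n: int, seed: int = 0) -> tuple:
    """Reduce colonies larger than ``target_n`` by seeded uniform sampling
    without replacement; smaller colonies pass through untouched."""
    if target_n < 1:
        raise ValueError("target_n must be >= 1")
    labels = pd.Series(labels)
    rng = np.random.default_rng(seed)
    keep: list[str] = []
    for colony in sorted(labels.unique()):
        members = sorted(labels[labels == colony].index)
        if len(members) > target_n:
            members = sorted(rng.choice(members, size=target_n, replace=False))
        keep.extend(members)
    return reference.subset_samples(keep), labels.loc[keep]


# ---------------------------------------------------------------------------
# independent oracles (used by the test suite; kept here so they share the
# encoded-genotype plumbing but never the sampler's code path)
# ---------------------------------------------------------------------------

def em_mixing_proportions(logL: np.ndarray, tol: float = 1e-10,
                          max_iter: int = 10_000) -> np.ndarray:
    """Maximum-likelihood mixing proportions by EM on a fixed logL matrix."""
    N, K = logL.shape
    L = np.exp(logL - logL.max(axis=1, keepdims=True))
    pi = np.full(K, 1.0 / K)
    for _ in range(max_iter):
        w = L * pi[None, :]
        w /= w.sum(axis=1, keepdims=True)
        new = w.mean(axis=0)
        if np.abs(new - pi).max() < tol:
            return new
        pi = new
    return pi


def enumerate_mixture_posterior(logL: np.ndarray, prior: float | None = None
                                ) -> tuple:
    """Exact posterior membership and E[pi] by enumerating allocations.

    Integrates pi analytically (Dirichlet-multinomial) over all K^N
    allocations; only feasible for tiny mixtures.  Returns
    (membership (N, K), E[pi] (K,)).
    """
    N, K = logL.shape
    a0 = 1.0 / K if prior is None else prior
    logw_geno = logL - logL.max(axis=1, keepdims=True)
    membership = np.zeros((N, K))
    e_pi = np.zeros(K)
    total = 0.0
    from scipy.special import gammaln
    for alloc in itertools.product(range(K), repeat=N):
        counts = np.bincount(alloc, minlength=K)
        logw = (gammaln(K * a0) - gammaln(K * a0 + N)
                + (gammaln(a0 + counts) - gammaln(a0)).sum())
        logw += sum(logw_geno[i, alloc[i]] for i in range(N))
        w = math.exp(logw)
        total += w
        for i, k in enumerate(alloc):
            membership[i, k] += w
        e_pi += w * (a0 + counts) / (K * a0 + N)
    return membership / total, e_pi / total
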