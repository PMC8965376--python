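"""Genotype calling and the QC cascade for amplicon microhaplotype data.

Raw per-haplotype read depths become diploid calls via the depth and
allelic-ratio rules (>= 20 reads; second allele kept when its depth is at
least 0.4 of the first), then sample- and locus-level filters run in a
fixed, logged order: call-level filters -> duplicate-sample removal ->
per-sample missingness (> 20% removed) -> Hardy-Weinberg screen (locus
dropped when out of HWE at p < alpha in >= 3 colonies).  Later stages'
denominators depend on earlier removals, so the order matters and re-running
on filtered output is a no-op.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .io_formats import (GENOTYPE_COLUMNS, GenotypeTable, MISSING_ALLELE,
                         PipelineConfig)

logger = logging.getLogger("fulmargsi")


# ---------------------------------------------------------------------------
# genotype calling from depths
# ---------------------------------------------------------------------------

def call_genotype(depths: Mapping[str, float], min_depth: int = 20,
                  min_ratio: float = 0.4) -> tuple:
    """Call one diploid genotype from per-haplotype read depths.

    Haplotypes are ranked by depth (ties by allele string); a call with
    total depth below ``min_depth`` is missing; otherwise the second-ranked
    haplotype is kept (heterozygote) iff depth2/depth1 >= ``min_ratio``,
    else the call is homozygous for the top haplotype.  Haplotypes beyond
    the top two are treated as sequencing error and ignored.

    Returns a canonical ``(allele_a, allele_b)`` pair or ``(MISSING_ALLELE,
    MISSING_ALLELE)``.
    """
    ranked = sorted(depths.items(), key=lambda kv: (-kv[1], kv[0]))
    total = sum(d for _, d in ranked[:2])
    if total < min_depth or not ranked or ranked[0][1] <= 0:
        return (MISSING_ALLELE, MISSING_ALLELE)
    top, d1 = ranked[0]
    if len(ranked) > 1 and ranked[1][1] / d1 >= min_ratio:
        second = ranked[1][0]
        return tuple(sorted((top, second)))
    return (top, top)


def call_genotypes(raw: GenotypeTable, min_depth: int = 20,
                   min_ratio: float = 0.4) -> GenotypeTable:
    """Vectorized genotype calling over a raw depth-bearing table.

    Each row carries the two deepest haplotypes for a call; rows without
    depth information pass through unchanged.
    """
    df = raw.calls.copy()
    has_depth = df["depth_1"].notna() & df["depth_2"].notna()
    sub = df[has_depth]
    d1 = sub["depth_1"].to_numpy(dtype=float)
    d2 = sub["depth_2"].to_numpy(dtype=float)
    a1 = sub["allele_1"].to_numpy()
    a2 = sub["allele_2"].to_numpy()
    # rank by depth, ties by allele string (canonical order = allele order)
    swap = (d2 > d1)
    top = np.where(swap, a2, a1)
    second = np.where(swap, a1, a2)
    dtop = np.where(swap, d2, d1)
    dsec = np.where(swap, d1, d2)
    total = dtop + dsec
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(dtop > 0, dsec / dtop, 0.0)
    missing = (total < min_depth) | (dtop <= 0)
    het = ~missing & (ratio >= min_ratio) & (second != top)
    out_a = np.where(missing, MISSING_ALLELE, np.where(het, top, top))
    out_b = np.where(missing, MISSING_ALLELE, np.where(het, second, top))
    df.loc[has_depth, "allele_1"] = out_a
    df.loc[has_depth, "allele_2"] = out_b
    df.loc[has_depth & pd.Series(missing, index=sub.index),
           ["depth_1", "depth_2"]] = np.nan
    return GenotypeTable(df)


# ---------------------------------------------------------------------------
# sample-level filters
# ---------------------------------------------------------------------------

def filter_missingness(table: GenotypeTable,
                       max_missing_fraction: float = 0.2) -> tuple:
    """Drop samples missing strictly more than ``max_missing_fraction`` of
    the locus universe.  Returns (filtered table, removed sample -> fraction)."""
    n_loci = len(table.loci)
    df = table.calls
    missing = df["allele_1"] == MISSING_ALLELE
    called = df[~missing].groupby("sample_id").size()
    all_samples = pd.Index(sorted(df["sample_id"].unique()))
    frac = 1.0 - called.reindex(all_samples, fill_value=0) / n_loci
    removed = frac[frac > max_missing_fraction]
    kept = table.subset_samples(frac[frac <= max_missing_fraction].index)
    return kept, removed.to_dict()


def find_duplicates(table: GenotypeTable, min_shared_loci: int = 30,
                    match_fraction: float = 0.95) -> list:
    """Flag near-identical genotype pairs (likely resampled birds).

    For each sample pair the match fraction is computed over loci called in
    both; a pair is flagged when it shares >= ``min_shared_loci`` loci and
    matches at >= ``match_fraction`` of them.  Returns a list of
    ``(keep, remove, shared, fraction)`` tuples where ``remove`` is the
    member with more missing data.
    """
    df = table.calls
    called = df[df["allele_1"] != MISSING_ALLELE].copy()
    called["geno"] = called["allele_1"] + "/" + called["allele_2"]
    wide = called.pivot(index="sample_id", columns="locus_id", values="geno")
    samples = list(wide.index)
    codes = wide.apply(lambda col: col.astype("category").cat.codes)
    mat = codes.to_numpy()  # -1 where missing
    present = mat >= 0
    n_missing = (~present).sum(axis=1)
    pairs = []
    for i, j in itertools.combinations(range(len(samples)), 2):
        both = present[i] & present[j]
        shared = int(both.sum())
        if shared < min_shared_loci:
            continue
        frac = float((mat[i, both] == mat[j, both]).mean())
        if frac >= match_fraction:
            keep, remove = ((samples[i], samples[j])
                            if n_missing[i] <= n_missing[j]
                            else (samples[j], samples[i]))
            pairs.append((keep, remove, shared, frac))
    return pairs


# ---------------------------------------------------------------------------
# Hardy-Weinberg screen
# ---------------------------------------------------------------------------

def _hwe_chi2_stat(genotype_counts: Mapping[tuple, int]) -> tuple:
    """Chi-square-style HWE statistic for arbitrary allele numbers.

    Returns (statistic, allele_counts, n_diploids).  Expected genotype
    counts come from the sample allele frequencies under random mating.
    """
    allele_counts: dict[str, int] = {}
    n = 0
    for (a, b), cnt in genotype_counts.items():
        allele_counts[a] = allele_counts.get(a, 0) + cnt
        allele_counts[b] = allele_counts.get(b, 0) + cnt
        n += cnt
    alleles = sorted(allele_counts)
    total = 2 * n
    stat = 0.0
    for i, a in enumerate(alleles):
        pa = allele_counts[a] / total
        for b in alleles[i:]:
            pb = allele_counts[b] / total
            expected = n * (pa * pa if a == b else 2 * pa * pb)
            if expected > 0:
                observed = genotype_counts.get((a, b), 0)
                stat += (observed - expected) ** 2 / expected
    return stat, allele_counts, n


def hwe_mc_pvalue(genotype_counts: Mapping[tuple, int], mc_reps: int = 10_000,
                  rng: np.random.Generator | None = None,
                  randomized: bool = False) -> float:
    """Monte-Carlo exact-style HWE p-value for one locus x population.

    Alleles are permuted into diploids ``mc_reps`` times; the p-value is the
    standard conservative (1 + #{stat_perm >= stat_obs}) / (reps + 1).  With
    ``randomized=True`` ties are broken uniformly, giving a p-value exactly
    uniform on [0, 1] under the null for any discrete statistic (used for
    calibration diagnostics, not for screening).  Monomorphic data give
    p = 1 by convention.

    The permutation is vectorized: allele counts are invariant under
    permutation, so the expected genotype counts are computed once and every
    replicate only needs a shuffle + bincount.
    """
    rng = np.random.default_rng() if rng is None else rng
    allele_counts: dict[str, int] = {}
    n = 0
    for (a, b), cnt in genotype_counts.items():
        allele_counts[a] = allele_counts.get(a, 0) + cnt
        allele_counts[b] = allele_counts.get(b, 0) + cnt
        n += cnt
    if len(allele_counts) < 2 or n < 2:
        return 1.0
    alleles = sorted(allele_counts)
    A = len(alleles)
    a_index = {a: i for i, a in enumerate(alleles)}
    counts_vec = np.array([allele_counts[a] for a in alleles], dtype=float)
    p = counts_vec / counts_vec.sum()
    # expected counts on the (lo, hi) genotype grid, fixed across replicates
    expected = np.zeros((A, A))
    for i in range(A):
        for j in range(i, A):
            expected[i, j] = n * (p[i] ** 2 if i == j else 2 * p[i] * p[j])
    exp_flat = expected.ravel()
    mask = exp_flat > 0

    def stat_from_counts(cnt_flat: np.ndarray) -> np.ndarray:
        return ((cnt_flat[..., mask] - exp_flat[mask]) ** 2
                / exp_flat[mask]).sum(axis=-1)

    obs_flat = np.zeros(A * A)
    for (a, b), cnt in genotype_counts.items():
        i, j = sorted((a_index[a], a_index[b]))
        obs_flat[i * A + j] += cnt
    stat_obs = float(stat_from_counts(obs_flat))

    pool = np.repeat(np.arange(A, dtype=np.int64),
                     counts_vec.astype(int))
    perms = np.tile(pool, (mc_reps, 1))
    perms = rng.permuted(perms, axis=1)
    pairs = perms.reshape(mc_reps, n, 2)
    lo = pairs.min(axis=2)
    hi = pairs.max(axis=2)
    code = lo * A + hi
    G = A * A
    flat = (np.arange(mc_reps)[:, None] * G + code).ravel()
    cnt = np.bincount(flat, minlength=mc_reps * G).reshape(mc_reps, G)
    stats = stat_from_counts(cnt.astype(float))
    greater = int((stats > stat_obs + 1e-9).sum())
    equal = int((np.abs(stats - stat_obs) <= 1e-9).sum())
    if randomized:
        u = rng.random()
        return float((greater + u * (equal + 1)) / (mc_reps + 1))
    return float((1 + greater + equal) / (mc_reps + 1))


def hwe_screen(table: GenotypeTable, labels: Mapping[str, str] | pd.Series,
               alpha: float = 0.05, min_pop_failures: int = 3,
               mc_reps: int = 10_000, seed: int = 0) -> tuple:
    """Drop loci out of HWE (p < alpha) in >= ``min_pop_failures`` colonies.

    Returns (loci_to_remove, per-locus-per-colony p-value DataFrame)."""
    labels = pd.Series(labels)
    df = table.calls
    df = df[df["allele_1"] != MISSING_ALLELE].copy()
    df["colony"] = df["sample_id"].map(labels)
    df = df[df["colony"].notna()]
    rng = np.random.default_rng(seed)
    rows = []
    for (locus, colony), sub in df.groupby(["locus_id", "colony"], sort=True):
        counts = (sub.groupby(["allele_1", "allele_2"]).size()).to_dict()
        p = hwe_mc_pvalue(counts, mc_reps=mc_reps, rng=rng)
        rows.append({"locus_id": locus, "colony": colony, "p_value": p})
    pvals = pd.DataFrame(rows, columns=["locus_id", "colony", "p_value"])
    if pvals.empty:
        return [], pvals
    failures = (pvals[pvals["p_value"] < alpha]
                .groupby("locus_id").size())
    remove = sorted(failures[failures >= min_pop_failures].index)
    return remove, pvals


# ---------------------------------------------------------------------------
# heterozygosity
# ---------------------------------------------------------------------------

def heterozygosity(table: GenotypeTable,
                   labels: Mapping[str, str] | pd.Series | None = None
                   ) -> pd.DataFrame:
    """Observed (fraction heterozygous calls) and expected (1 - sum p^2)
    heterozygosity per locus, per colony and pooled (sample-size weighted)."""
    df = table.calls
    df = df[df["allele_1"] != MISSING_ALLELE].copy()
    if labels is not None:
        df["colony"] = df["sample_id"].map(pd.Series(labels))
        df = df[df["colony"].notna()]
    else:
        df["colony"] = "pooled"
    rows = []
    for (locus, colony), sub in df.groupby(["locus_id", "colony"], sort=True):
        n = len(sub)
        ho = float((sub["allele_1"] != sub["allele_2"]).mean())
        counts = pd.concat([sub["allele_1"], sub["allele_2"]]).value_counts()
        p = counts / counts.sum()
        he = float(1.0 - (p ** 2).sum())
        rows.append({"locus_id": locus, "colony": colony, "n": n,
                     "Ho": ho, "He": he})
    per_colony = pd.DataFrame(rows)
    if labels is not None and not per_colony.empty:
        pooled = (per_colony.groupby("locus_id")
                  .apply(lambda g: pd.Series({
                      "colony": "pooled",
                      "n": g["n"].sum(),
                      "Ho": np.average(g["Ho"], weights=g["n"]),
                      "He": np.average(g["He"], weights=g["n"])}),
                      include_groups=False)
                  .reset_index())
        per_colony = pd.concat([per_colony, pooled], ignore_index=True)
    return per_colony


# ---------------------------------------------------------------------------
# full cascade
# ---------------------------------------------------------------------------

def qc_pipeline(raw: GenotypeTable, labels: pd.Series | None,
                config: PipelineConfig) -> tuple:
    """Run the full QC cascade; returns (filtered table, report DataFrame).

    HWE screening needs colony labels and is skipped (with a log line) for
    unlabeled tables such as the bycatch mixture.
    """
    report_rows = []
    called = call_genotypes(raw, min_depth=config.min_depth,
                            min_ratio=config.min_allelic_ratio)

    dupes = find_duplicates(called,
                            min_shared_loci=config.duplicate_min_shared_loci,
                            match_fraction=config.duplicate_match_fraction)
    to_drop = {remove for _, remove, _, _ in dupes}
    for keep, remove, shared, frac in dupes:
        report_rows.append({"stage": "duplicates", "item": remove,
                            "detail": f"matches {keep} at {frac:.3f} over {shared} loci"})
    called = called.subset_samples(set(called.samples) - to_drop)

    called, removed_missing = filter_missingness(
        called, max_missing_fraction=config.max_missing_fraction)
    for sample, frac in removed_missing.items():
        report_rows.append({"stage": "missingness", "item": sample,
                            "detail": f"missing fraction {frac:.3f}"})

    if labels is not None:
        labels = pd.Series(labels)
        remove_loci, pvals = hwe_screen(
            called, labels, alpha=config.hwe_alpha,
            min_pop_failures=config.hwe_pop_fail_min,
            mc_reps=config.hwe_mc_reps, seed=config.stage_seed("hwe"))
        for locus in remove_loci:
            detail = pvals[(pvals["locus_id"] == locus)
                           & (pvals["p_value"] < config.hwe_alpha)]
            report_rows.append({
                "stage": "hwe", "item": locus,
                "detail": "p<alpha in " + ",".join(detail["colony"])})
        called = called.subset_loci(set(called.loci) - set(remove_loci))
    else:
        logger.info("qc_pipeline: no labels, HWE screen skipped")

    report = pd.DataFrame(report_rows, columns=["stage", "item", "detail"])
    logger.info("qc_pipeline: %d samples, %d loci retained (%d removals)",
                len(called.samples), len(called.loci), len(report))
    return called, report
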