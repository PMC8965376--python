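"""Panel design: colony allele frequencies, LD pruning, Weir-Cockerham
F_ST, divergent-SNP ranking, and grouping of nearby SNPs into candidate
microhaplotype amplicons.

The F_ST estimator is Weir & Cockerham's (1984) theta, computed from
per-locus/per-allele variance components a (among populations), b (among
individuals within populations) and c (within individuals), combined across
loci as a ratio of sums.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import MISSING_ALLELE, GenotypeTable

logger = logging.getLogger("fulmargsi")


@dataclass(frozen=True)
class SNPRecord:
    """A SNP: scaffold, 1-based position, and its alleles."""

    scaffold: str
    position: int
    alleles: tuple = ()

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")


@dataclass(frozen=True)
class MicrohapLocus:
    """A candidate microhaplotype amplicon: a cluster of nearby SNPs plus
    flanking sequence for primer design."""

    locus_id: str
    scaffold: str
    start: int            # 1-based inclusive
    end: int              # 1-based inclusive
    snp_positions: tuple
    flank: int
    flank_truncated: bool = False

    def __post_init__(self) -> None:
        if not all(self.start <= p <= self.end for p in self.snp_positions):
            raise ValueError("snp_positions must lie within [start, end]")

    def bed_interval(self) -> tuple:
        """0-based half-open interval including flanks."""
        return (max(self.start - 1 - self.flank, 0), self.end + self.flank)


@dataclass
class FstResult:
    """Weir-Cockerham variance components and theta estimates."""

    per_locus: pd.DataFrame        # locus_id, a, b, c, theta
    theta: float                   # multi-locus ratio of sums
    pairwise: pd.DataFrame | None  # colony x colony theta matrix
    theta_se: float | None = None  # delete-one-locus jackknife SE


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------

def colony_allele_freqs(table: GenotypeTable, labels: Mapping[str, str] | pd.Series
                        ) -> pd.DataFrame:
    """Per colony x locus allele frequencies from non-missing diploid calls.

    Returns a long DataFrame (colony, locus_id, allele, frequency, n_calls);
    a colony with zero calls at a locus is simply absent there (undefined).
    """
    labels = pd.Series(labels)
    df = table.calls.copy()
    df = df[df["allele_1"] != MISSING_ALLELE]
    df["colony"] = df["sample_id"].map(labels)
    df = df[df["colony"].notna()]
    long = pd.concat([
        df[["colony", "locus_id", "allele_1"]].rename(columns={"allele_1": "allele"}),
        df[["colony", "locus_id", "allele_2"]].rename(columns={"allele_2": "allele"}),
    ])
    counts = (long.groupby(["colony", "locus_id", "allele"], sort=True)
              .size().rename("count").reset_index())
    totals = counts.groupby(["colony", "locus_id"])["count"].transform("sum")
    counts["frequency"] = counts["count"] / totals
    counts["n_calls"] = totals // 2
    return counts


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def ld_prune(snps: Sequence[SNPRecord], min_dist: int = 100_000) -> list:
    """Greedy positional pruning: keep the first SNP on each scaffold, then
    each next SNP only if strictly more than ``min_dist`` bp from the last
    kept SNP on that scaffold."""
    ordered = sorted(snps, key=lambda s: (s.scaffold, s.position))
    kept: list[SNPRecord] = []
    last_by_scaffold: dict[str, int] = {}
    for snp in ordered:
        last = last_by_scaffold.get(snp.scaffold)
        if last is None or snp.position - last > min_dist:
            kept.append(snp)
            last_by_scaffold[snp.scaffold] = snp.position
    return kept


# ---------------------------------------------------------------------------
# Weir & Cockerham theta
# ---------------------------------------------------------------------------

def _wc_components_locus(freqs: np.ndarray, het: np.ndarray,
                         sizes: np.ndarray) -> tuple:
    """W&C (1984) variance components for one locus, summed over alleles.

    freqs: (r, A) per-population allele frequencies; het: (r, A) observed
    frequency of heterozygotes carrying each allele; sizes: (r,) diploid
    sample sizes.  Populations with no data must be excluded beforehand.
    """
    r = len(sizes)
    if r < 2:
        return 0.0, 0.0, 0.0
    n_bar = sizes.mean()
    if n_bar <= 1:
        return 0.0, 0.0, 0.0
    n_c = (r * n_bar - (sizes**2).sum() / (r * n_bar)) / (r - 1)
    a_sum = b_sum = c_sum = 0.0
    for col in range(freqs.shape[1]):
        p = freqs[:, col]
        h = het[:, col]
        p_bar = (sizes * p).sum() / (r * n_bar)
        s2 = (sizes * (p - p_bar) ** 2).sum() / ((r - 1) * n_bar)
        h_bar = (sizes * h).sum() / (r * n_bar)
        inner = p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4.0
        a = n_bar / n_c * (s2 - inner / (n_bar - 1))
        b = n_bar / (n_bar - 1) * (p_bar * (1 - p_bar) - (r - 1) / r * s2
                                   - (2 * n_bar - 1) / (4 * n_bar) * h_bar)
        c = h_bar / 2.0
        a_sum, b_sum, c_sum = a_sum + a, b_sum + b, c_sum + c
    return a_sum, b_sum, c_sum


def _locus_arrays(table: GenotypeTable, labels: pd.Series):
    """Yield (locus_id, freqs, het, sizes) per locus over colonies with data."""
    labels = pd.Series(labels)
    df = table.calls
    df = df[df["allele_1"] != MISSING_ALLELE].copy()
    df["colony"] = df["sample_id"].map(labels)
    df = df[df["colony"].notna()]
    if df.empty:
        return
    df["is_het"] = df["allele_1"] != df["allele_2"]
    long = pd.concat([
        df[["locus_id", "colony", "allele_1", "is_het"]]
        .rename(columns={"allele_1": "allele"}),
        df[["locus_id", "colony", "allele_2", "is_het"]]
        .rename(columns={"allele_2": "allele"}),
    ], ignore_index=True)
    allele_counts = long.groupby(["locus_id", "colony", "allele"]).size()
    het_counts = (long[long["is_het"]]
                  .groupby(["locus_id", "colony", "allele"]).size())
    sizes_all = df.groupby(["locus_id", "colony"]).size()
    for locus in sorted(df["locus_id"].unique()):
        ac = allele_counts.xs(locus, level="locus_id").unstack(fill_value=0)
        sizes = sizes_all.xs(locus)  # per present colony
        ac = ac.reindex(index=sizes.index, fill_value=0)
        try:
            hc = het_counts.xs(locus, level="locus_id").unstack(fill_value=0)
        except KeyError:
            hc = pd.DataFrame(0, index=ac.index, columns=ac.columns)
        hc = hc.reindex(index=ac.index, columns=ac.columns, fill_value=0)
        n = sizes.to_numpy(dtype=float)
        freqs = ac.to_numpy(dtype=float) / (2.0 * n[:, None])
        het = hc.to_numpy(dtype=float) / n[:, None]
        yield locus, freqs, het, n


def weir_cockerham_fst(table: GenotypeTable, labels: Mapping[str, str] | pd.Series,
                       loci: Iterable[str] | None = None,
                       pairwise: bool = True,
                       max_missing_fraction: float | None = 0.2) -> FstResult:
    """Multi-locus Weir-Cockerham theta with optional pairwise colony matrix.

    Samples with more than ``max_missing_fraction`` missing genotypes are
    excluded first (pass None to keep everyone).  Loci with zero total
    variance contribute nothing to the ratio of sums.
    """
    labels = pd.Series(labels)
    if max_missing_fraction is not None:
        miss = missingness_by_sample(table)
        keep = miss[miss <= max_missing_fraction].index
        table = table.subset_samples(keep)
    if loci is not None:
        table = table.subset_loci(loci)

    rows = []
    for locus, freqs, het, sizes in _locus_arrays(table, labels):
        a, b, c = _wc_components_locus(freqs, het, sizes)
        denom = a + b + c
        rows.append({"locus_id": locus, "a": a, "b": b, "c": c,
                     "theta": a / denom if denom > 0 else np.nan})
    per_locus = pd.DataFrame(rows, columns=["locus_id", "a", "b", "c", "theta"])
    tot = per_locus[["a", "b", "c"]].sum()
    denom = tot["a"] + tot["b"] + tot["c"]
    theta = float(tot["a"] / denom) if denom > 0 else float("nan")

    # delete-one-locus jackknife on the ratio of sums
    theta_se = None
    ok = per_locus.dropna(subset=["theta"])
    L = len(ok)
    if L > 1:
        a_i = ok["a"].to_numpy()
        d_i = (ok["a"] + ok["b"] + ok["c"]).to_numpy()
        loo = (tot["a"] - a_i) / (denom - d_i)
        theta_se = float(np.sqrt((L - 1) / L * ((loo - loo.mean()) ** 2).sum()))

    pw = None
    if pairwise:
        colonies = sorted(labels.unique())
        pw = pd.DataFrame(0.0, index=colonies, columns=colonies)
        for i, ci in enumerate(colonies):
            for cj in colonies[i + 1:]:
                pair_samples = labels[labels.isin([ci, cj])].index
                sub = table.subset_samples(pair_samples)
                res = weir_cockerham_fst(sub, labels.loc[pair_samples],
                                         pairwise=False,
                                         max_missing_fraction=None)
                pw.loc[ci, cj] = pw.loc[cj, ci] = res.theta
    return FstResult(per_locus=per_locus, theta=theta, pairwise=pw,
                     theta_se=theta_se)


def missingness_by_sample(table: GenotypeTable) -> pd.Series:
    """Fraction of the locus universe missing per sample."""
    n_loci = len(table.loci)
    df = table.calls
    missing = df["allele_1"] == MISSING_ALLELE
    called = df[~missing].groupby("sample_id").size()
    called = called.reindex(sorted(df["sample_id"].unique()), fill_value=0)
    return 1.0 - called / n_loci


# ---------------------------------------------------------------------------
# divergent-SNP ranking
# ---------------------------------------------------------------------------

def rank_divergent_snps(freqs: pd.DataFrame, colony_a: str, colony_b: str,
                        snp_positions: Mapping[str, tuple] | None = None,
                        top_k: int = 40) -> pd.DataFrame:
    """Rank SNPs by the maximum absolute per-allele frequency difference
    between two colonies; ties break by (scaffold, position) then locus id.

    ``freqs`` is the long table from :func:`colony_allele_freqs`;
    ``snp_positions`` optionally maps locus_id -> (scaffold, position) for
    positional tie-breaking.  Returns the top_k loci with their scores.
    """
    sub = freqs[freqs["colony"].isin([colony_a, colony_b])]
    wide = sub.pivot_table(index=["locus_id", "allele"], columns="colony",
                           values="frequency", fill_value=0.0)
    if colony_a not in wide.columns or colony_b not in wide.columns:
        raise ValueError(f"no frequency data for pair ({colony_a}, {colony_b})")
    defined_a = set(sub[sub["colony"] == colony_a]["locus_id"])
    defined_b = set(sub[sub["colony"] == colony_b]["locus_id"])
    wide = wide[wide.index.get_level_values("locus_id")
                .isin(defined_a & defined_b)]
    diff = (wide[colony_a] - wide[colony_b]).abs()
    score = diff.groupby(level="locus_id").max().rename("score").reset_index()

    def sort_key(locus: str):
        if snp_positions and locus in snp_positions:
            return snp_positions[locus]
        return ("", 0)

    score["_pos"] = score["locus_id"].map(sort_key)
    score = score.sort_values(["score", "_pos", "locus_id"],
                              ascending=[False, True, True],
                              kind="mergesort").drop(columns="_pos")
    if top_k > len(score):
        logger.warning("rank_divergent_snps: top_k=%d > %d available SNPs",
                       top_k, len(score))
    return score.head(top_k).reset_index(drop=True)


def select_panel(freqs: pd.DataFrame, colonies: Sequence[str],
                 snp_positions: Mapping[str, tuple] | None = None,
                 top_k: int = 40) -> list:
    """Union of the top_k most divergent SNPs over all colony pairs,
    de-duplicated, in deterministic order."""
    selected: dict[str, float] = {}
    for i, ca in enumerate(sorted(colonies)):
        for cb in sorted(colonies)[i + 1:]:
            ranked = rank_divergent_snps(freqs, ca, cb, snp_positions, top_k)
            for row in ranked.itertuples():
                selected[row.locus_id] = max(selected.get(row.locus_id, 0.0),
                                             row.score)
    return sorted(selected)


# ---------------------------------------------------------------------------
# microhaplotype grouping
# ---------------------------------------------------------------------------

def group_microhaps(snps: Sequence[SNPRecord], window: int = 150,
                    flank: int = 75,
                    scaffold_lengths: Mapping[str, int] | None = None) -> list:
    """Greedily cluster SNPs on a scaffold into candidate amplicons.

    A SNP joins the current cluster while the cluster span (max - min
    position) stays strictly below ``window``; each cluster becomes one
    MicrohapLocus carrying ``flank`` bases each side.  Flanks running off
    the scaffold (when lengths are known) are truncated and flagged.
    """
    loci: list[MicrohapLocus] = []
    by_scaffold: dict[str, list[SNPRecord]] = {}
    for snp in sorted(snps, key=lambda s: (s.scaffold, s.position)):
        by_scaffold.setdefault(snp.scaffold, []).append(snp)
    idx = 0
    for scaffold in sorted(by_scaffold):
        cluster: list[int] = []
        for snp in by_scaffold[scaffold]:
            if cluster and snp.position - cluster[0] < window:
                cluster.append(snp.position)
            else:
                if cluster:
                    loci.append(_make_locus(idx, scaffold, cluster, flank,
                                            scaffold_lengths))
                    idx += 1
                cluster = [snp.position]
        if cluster:
            loci.append(_make_locus(idx, scaffold, cluster, flank,
                                    scaffold_lengths))
            idx += 1
    return loci


def _make_locus(idx: int, scaffold: str, positions: list, flank: int,
                scaffold_lengths: Mapping[str, int] | None) -> MicrohapLocus:
    start, end = positions[0], positions[-1]
    truncated = False
    if start - flank < 1:
        truncated = True
    if scaffold_lengths and end + flank > scaffold_lengths.get(scaffold, np.inf):
        truncated = True
    return MicrohapLocus(locus_id=f"amp_{idx:04d}", scaffold=scaffold,
                         start=start, end=end, snp_positions=tuple(positions),
                         flank=flank, flank_truncated=truncated)


def write_bed(loci: Sequence[MicrohapLocus], path: str | Path) -> None:
    """Candidate amplicons as BED (0-based half-open)."""
    with open(path, "w", encoding="utf-8") as fh:
        for locus in loci:
            b0, b1 = locus.bed_interval()
            fh.write(f"{locus.scaffold}\t{b0}\t{b1}\t{locus.locus_id}\n")


def write_fasta(loci: Sequence[MicrohapLocus], reference_fasta: str | Path,
                path: str | Path) -> None:
    """Extract amplicon sequences (with flanks) from a reference FASTA."""
    from Bio import SeqIO

    seqs = {rec.id: rec.seq for rec in SeqIO.parse(str(reference_fasta), "fasta")}
    with open(path, "w", encoding="utf-8") as fh:
        for locus in loci:
            if locus.scaffold not in seqs:
                logger.warning("write_fasta: scaffold %s absent from reference",
                               locus.scaffold)
                continue
            b0, b1 = locus.bed_interval()
            seq = seqs[locus.scaffold][b0:b1]
            fh.write(f">{locus.locus_id} {locus.scaffold}:{b0}-{b1}\n{seq}\n")
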