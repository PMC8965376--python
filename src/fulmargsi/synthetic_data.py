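"""Colony-structured synthetic data with known truth.

Emulates the study system end to end: K weakly differentiated breeding
colonies (Balding-Nichols drift around ancestral allele frequencies, F on
the 0.003-0.01 scale), a ~140-locus microhaplotype panel averaging ~3.9
alleles per locus, reference samples of known colony origin, a bycatch
mixture with known mixing proportions, amplicon read depths with realistic
noise, colony-clustered breeding-season locations (central-place foraging)
versus a shared nonbreeding field, and a gridded longline-effort field.
Every generator is a pure function of its config and seed.
"""

from __future__ import annotations

import calendar
import datetime as _dt
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import (GENOTYPE_COLUMNS, EffortRecord, GenotypeTable,
                         MISSING_ALLELE, ObserverRecord, season_of_month,
                         write_effort_records, write_genotype_table,
                         write_observer_records)

KM_PER_DEG_LAT = 111.19

# Default colony layout: the four largest Alaska fulmar colonies, ordered to
# match the census/bycatch tables (Semidis, Pribilofs, St. Matthew, Chagulak).
DEFAULT_COLONIES = ("Semidis", "Pribilofs", "StMatthew", "Chagulak")
DEFAULT_CENTROIDS = ((56.1, -156.7), (57.2, -170.3), (60.4, -172.7), (52.6, -171.2))
DEFAULT_CENSUS = (440_000, 79_700, 450_000, 500_000)
DEFAULT_CENSUS_PCT = (30, 6, 30, 34)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic bundle.

    Defaults mirror the study scale: K = 4 colonies at F_ST = 0.005 (middle
    of the observed 0.003-0.01 range), 140 microhaplotype loci with a mean
    of ~3.9 alleles/locus (truncated shifted Poisson, max 10), a reference
    of 517 birds split evenly across colonies, and a 1000-bird bycatch
    mixture with proportions matching the observed bycatch split.
    """

    n_colonies: int = 4
    fst: float = 0.005
    n_loci: int = 140
    allele_poisson_lambda: float = 2.9   # alleles/locus = 1 + min(Pois(lam), 9)
    max_alleles: int = 10
    ref_sizes: tuple = (130, 129, 129, 129)
    mixture_size: int = 1000
    mixture_proportions: tuple = (0.36, 0.23, 0.27, 0.14)
    # read-depth noise
    depth_mean: float = 80.0
    depth_dispersion: float = 5.0        # negative-binomial size parameter
    ratio_beta: float = 40.0             # het read split q ~ Beta(b, b)
    error_read_prob: float = 0.05        # homozygote picks up stray reads
    error_read_mean: float = 1.5
    # space and season
    colony_names: tuple = DEFAULT_COLONIES
    colony_centroids: tuple = DEFAULT_CENTROIDS
    census_sizes: tuple = DEFAULT_CENSUS
    census_percents: tuple = DEFAULT_CENSUS_PCT
    breeding_dispersion_km: float = 250.0
    nonbreeding_dispersion_km: float = 600.0
    nonbreeding_colony_weight: float = 0.3   # gamma: colony-specific share
    common_field_center: tuple = (57.0, -168.0)
    breeding_fraction: float = 0.5
    year: int = 2012
    # effort field
    effort_extent: tuple = (50.0, 62.0, -180.0, -150.0)  # lat0, lat1, lon0, lon1
    effort_cell_deg: float = 0.5
    effort_log_mean: float = 10.0
    effort_log_sd: float = 1.0
    effort_nonbreeding_multiplier: float = 1.4  # per-month intensity ratio
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fst < 1.0:
            raise ValueError(f"fst must be in [0, 1), got {self.fst}")
        if len(self.ref_sizes) != self.n_colonies:
            raise ValueError("ref_sizes length must equal n_colonies")
        if len(self.mixture_proportions) != self.n_colonies:
            raise ValueError("mixture_proportions length must equal n_colonies")
        if abs(sum(self.mixture_proportions) - 1.0) > 1e-9:
            raise ValueError("mixture_proportions must sum to 1")
        if any(n <= 0 for n in self.ref_sizes):
            raise ValueError("ref_sizes must be positive")
        if not 0.0 <= self.nonbreeding_colony_weight <= 1.0:
            raise ValueError("nonbreeding_colony_weight must be in [0, 1]")


@dataclass
class TruthBundle:
    """Everything a recovery test needs: generated data plus its truth."""

    config: SimulationConfig
    colony_freqs: list            # per locus: (K, A_l) frequency matrix
    locus_ids: list
    allele_names: list            # per locus: list of allele strings
    reference: GenotypeTable
    reference_raw: GenotypeTable  # with read-depth noise applied
    reference_labels: pd.Series   # sample_id -> colony
    mixture: GenotypeTable
    mixture_raw: GenotypeTable
    mixture_labels: pd.Series
    observers: list               # ObserverRecord per mixture bird
    effort: list                  # EffortRecord set


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------

def draw_allele_numbers(n_loci: int, lam: float, max_alleles: int,
                        rng: np.random.Generator) -> np.ndarray:
    """Alleles per locus: 1 + Poisson(lam) truncated at max_alleles.

    lam = 2.9 gives a mean of ~3.9 alleles/locus over a 1..10 range;
    monomorphic loci (1 allele) occur naturally.
    """
    return 1 + np.minimum(rng.poisson(lam, size=n_loci), max_alleles - 1)


def draw_colony_freqs(p: np.ndarray, F: float, K: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Balding-Nichols colony frequencies around ancestral simplex ``p``.

    Each colony's frequency vector is Dirichlet(p * (1 - F) / F), so
    E[freq] = p and the among-colony correlation of allele copies is F.
    F = 0 is the degenerate no-drift limit (all colonies get exactly p).
    """
    p = np.asarray(p, dtype=float)
    if not 0.0 <= F < 1.0:
        raise ValueError(f"F must be in [0, 1), got {F}")
    if p.ndim != 1 or abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
        raise ValueError("p must be a simplex")
    if F == 0.0 or len(p) == 1:
        return np.tile(p, (K, 1))
    conc = p * (1.0 - F) / F
    # Dirichlet via gammas so zero-probability ancestral alleles stay zero
    g = rng.gamma(shape=np.tile(conc, (K, 1)), scale=1.0)
    g = np.where(np.tile(conc, (K, 1)) > 0, g, 0.0)
    return g / g.sum(axis=1, keepdims=True)


def draw_panel_freqs(config: SimulationConfig, rng: np.random.Generator):
    """Ancestral + colony frequencies for a whole panel.

    Ancestral per-locus frequencies are symmetric Dirichlet(1) over the
    locus's alleles.  Returns (locus_ids, allele_names, colony_freqs).
    """
    n_alleles = draw_allele_numbers(config.n_loci, config.allele_poisson_lambda,
                                    config.max_alleles, rng)
    locus_ids, allele_names, colony_freqs = [], [], []
    for l, A in enumerate(n_alleles):
        locus_ids.append(f"mhap_{l:04d}")
        allele_names.append([f"H{a}" for a in range(A)])
        p = rng.dirichlet(np.ones(A)) if A > 1 else np.ones(1)
        colony_freqs.append(draw_colony_freqs(p, config.fst,
                                              config.n_colonies, rng))
    return locus_ids, allele_names, colony_freqs


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(colony_freqs: Sequence[np.ndarray], locus_ids: Sequence[str],
                       allele_names: Sequence[Sequence[str]],
                       labels: Sequence[int], sample_ids: Sequence[str],
                       rng: np.random.Generator) -> GenotypeTable:
    """HWE genotypes: two independent allele draws per locus from the
    individual's colony frequencies."""
    rows = []
    labels = np.asarray(labels, dtype=int)
    for l, locus in enumerate(locus_ids):
        freqs = colony_freqs[l]
        A = freqs.shape[1]
        cum = freqs.cumsum(axis=1)[labels]          # (n, A)
        u = rng.random((len(labels), 2))
        drawn = (u[:, :, None] >= cum[:, None, :]).sum(axis=2)  # (n, 2)
        names = allele_names[l]
        for i, sid in enumerate(sample_ids):
            a, b = sorted((names[drawn[i, 0]], names[drawn[i, 1]]))
            rows.append((sid, locus, a, b))
    df = pd.DataFrame(rows, columns=GENOTYPE_COLUMNS[:4])
    return GenotypeTable(df)


def overlay_read_depths(genotypes: GenotypeTable, config: SimulationConfig,
                        rng: np.random.Generator) -> GenotypeTable:
    """Add amplicon read-depth noise to clean genotypes.

    Total depth per call is negative binomial (mean ``depth_mean``, size
    ``depth_dispersion``); the negative-binomial left tail produces calls
    below the 20-read threshold and hence downstream missingness.
    Heterozygote reads split Binomial(total, q) with q ~ Beta(b, b), so a
    noisy split occasionally fails the allelic-ratio filter.  Homozygotes
    pick up a few stray reads on a random other allele with probability
    ``error_read_prob``.
    """
    df = genotypes.calls.copy()
    n = len(df)
    size = config.depth_dispersion
    p_nb = size / (size + config.depth_mean)
    total = rng.negative_binomial(size, p_nb, size=n)
    is_het = (df["allele_1"] != df["allele_2"]).to_numpy()

    d1 = np.zeros(n, dtype=int)
    d2 = np.zeros(n, dtype=int)
    q = rng.beta(config.ratio_beta, config.ratio_beta, size=n)
    het_d1 = rng.binomial(total, q)
    d1[is_het] = het_d1[is_het]
    d2[is_het] = (total - het_d1)[is_het]

    hom = ~is_het
    err = hom & (rng.random(n) < config.error_read_prob) & (total > 0)
    n_err = np.minimum(rng.poisson(config.error_read_mean, size=n) + 1, total)
    d1[hom] = total[hom]
    d1[err] -= n_err[err]
    d2[err] = n_err[err]
    err_allele = np.where(df["allele_1"].to_numpy() == "H0", "H1", "H0")
    a2 = df["allele_2"].to_numpy().copy()
    a2[err] = err_allele[err]
    df["allele_2"] = a2
    df["depth_1"], df["depth_2"] = d1, d2
    return GenotypeTable(df)


def simulate_reference(config: SimulationConfig, colony_freqs, locus_ids,
                       allele_names, rng: np.random.Generator):
    labels_idx = np.repeat(np.arange(config.n_colonies), config.ref_sizes)
    sample_ids = [f"ref_{i:04d}" for i in range(len(labels_idx))]
    table = simulate_genotypes(colony_freqs, locus_ids, allele_names,
                               labels_idx, sample_ids, rng)
    labels = pd.Series([config.colony_names[k] for k in labels_idx],
                       index=pd.Index(sample_ids, name="sample_id"), name="colony")
    return table, labels


def simulate_mixture(config: SimulationConfig, colony_freqs, locus_ids,
                     allele_names, rng: np.random.Generator):
    """Bycatch mixture: colony of origin ~ Categorical(rho), genotype from
    that colony's frequencies; true labels returned for recovery tests."""
    rho = np.asarray(config.mixture_proportions)
    labels_idx = rng.choice(config.n_colonies, size=config.mixture_size, p=rho)
    sample_ids = [f"byc_{i:04d}" for i in range(config.mixture_size)]
    table = simulate_genotypes(colony_freqs, locus_ids, allele_names,
                               labels_idx, sample_ids, rng)
    labels = pd.Series([config.colony_names[k] for k in labels_idx],
                       index=pd.Index(sample_ids, name="sample_id"), name="colony")
    return table, labels


# ---------------------------------------------------------------------------
# space, season, effort
# ---------------------------------------------------------------------------

def _random_date_in_months(months: Sequence[int], year: int,
                           rng: np.random.Generator) -> _dt.date:
    month = int(rng.choice(list(months)))
    day = int(rng.integers(1, calendar.monthrange(year, month)[1] + 1))
    return _dt.date(year, month, day)


def simulate_spatial(labels: pd.Series, config: SimulationConfig,
                     rng: np.random.Generator) -> list:
    """Observer records for the mixture birds.

    Breeding-season birds sit in a bivariate normal around their own colony
    (central-place foraging, ``breeding_dispersion_km``).  Nonbreeding birds
    come from a shared wintering field with probability 1 - gamma and from a
    colony-centred cloud (wider, ``nonbreeding_dispersion_km``) with
    probability gamma.
    """
    centroids = {name: c for name, c in zip(config.colony_names,
                                            config.colony_centroids)}
    records = []
    for sid, colony in labels.items():
        breeding = rng.random() < config.breeding_fraction
        if breeding:
            center = centroids[colony]
            disp = config.breeding_dispersion_km
            months = sorted(m for m in range(1, 13)
                            if season_of_month(m) == "breeding")
        else:
            disp = config.nonbreeding_dispersion_km
            if rng.random() < config.nonbreeding_colony_weight:
                center = centroids[colony]
            else:
                center = config.common_field_center
            months = sorted(m for m in range(1, 13)
                            if season_of_month(m) == "nonbreeding")
        dlat = rng.normal(0.0, disp) / KM_PER_DEG_LAT
        lat = float(np.clip(center[0] + dlat, -89.0, 89.0))
        dlon = rng.normal(0.0, disp) / (KM_PER_DEG_LAT * math.cos(math.radians(lat)))
        lon = center[1] + dlon
        lon = (lon + 180.0) % 360.0 - 180.0  # wrap across the antimeridian
        date = _random_date_in_months(months, config.year, rng)
        records.append(ObserverRecord(sample_id=sid, latitude=lat, longitude=lon,
                                      date=date,
                                      season="breeding" if breeding else "nonbreeding"))
    return records


def simulate_effort(config: SimulationConfig, rng: np.random.Generator) -> list:
    """Longline effort: one record per 0.5-degree cell per month, hooks drawn
    from a log-normal field; nonbreeding months get a per-month intensity
    multiplier."""
    lat0, lat1, lon0, lon1 = config.effort_extent
    step = config.effort_cell_deg
    lats = np.arange(lat0 + step / 2, lat1, step)
    lons = np.arange(lon0 + step / 2, lon1, step)
    if len(lats) == 0 or len(lons) == 0:
        raise ValueError("effort extent is empty")
    records = []
    for month in range(1, 13):
        mult = (config.effort_nonbreeding_multiplier
                if season_of_month(month) == "nonbreeding" else 1.0)
        field = rng.lognormal(config.effort_log_mean, config.effort_log_sd,
                              size=(len(lats), len(lons)))
        hooks = np.round(field * mult).astype(int)
        date = _dt.date(config.year, month, 15)
        for i, la in enumerate(lats):
            for j, lo in enumerate(lons):
                if hooks[i, j] > 0:
                    records.append(EffortRecord(latitude=float(la),
                                                longitude=float(lo),
                                                date=date,
                                                hooks=int(hooks[i, j])))
    return records


# ---------------------------------------------------------------------------
# bundle
# ---------------------------------------------------------------------------

def simulate_bundle(config: SimulationConfig) -> TruthBundle:
    """Generate the full study bundle from one config + seed."""
    root = np.random.SeedSequence(config.seed)
    (s_freq, s_ref, s_mix, s_depth_r, s_depth_m,
     s_space, s_effort) = [np.random.default_rng(s) for s in root.spawn(7)]
    locus_ids, allele_names, colony_freqs = draw_panel_freqs(config, s_freq)
    reference, ref_labels = simulate_reference(config, colony_freqs, locus_ids,
                                               allele_names, s_ref)
    mixture, mix_labels = simulate_mixture(config, colony_freqs, locus_ids,
                                           allele_names, s_mix)
    reference_raw = overlay_read_depths(reference, config, s_depth_r)
    mixture_raw = overlay_read_depths(mixture, config, s_depth_m)
    observers = simulate_spatial(mix_labels, config, s_space)
    effort = simulate_effort(config, s_effort)
    return TruthBundle(config=config, colony_freqs=colony_freqs,
                       locus_ids=locus_ids, allele_names=allele_names,
                       reference=reference, reference_raw=reference_raw,
                       reference_labels=ref_labels,
                       mixture=mixture, mixture_raw=mixture_raw,
                       mixture_labels=mix_labels,
                       observers=observers, effort=effort)


def write_bundle(bundle: TruthBundle, outdir: str | Path) -> None:
    """Write the bundle in the formats the pipeline stages read."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = bundle.config
    write_genotype_table(bundle.reference_raw, outdir / "reference_raw.csv")
    write_genotype_table(bundle.mixture_raw, outdir / "mixture_raw.csv")
    bundle.reference_labels.reset_index().to_csv(
        outdir / "reference_labels.csv", index=False)
    bundle.mixture_labels.reset_index().to_csv(
        outdir / "mixture_truth.csv", index=False)
    write_observer_records(bundle.observers, outdir / "observer.csv")
    write_effort_records(bundle.effort, outdir / "effort.csv")
    pd.DataFrame({"colony": cfg.colony_names,
                  "population_estimate": cfg.census_sizes,
                  "percent_of_total": cfg.census_percents,
                  }).to_csv(outdir / "census.csv", index=False)
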