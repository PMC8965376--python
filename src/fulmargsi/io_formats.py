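"""File formats, configuration and orchestration for the bycatch-GSI pipeline.

The pipeline moves between a small set of plain-text formats: VCF for
candidate SNPs, CSV for genotype tables (one row per sample x locus call,
with per-haplotype read depths), CSV for fishery-observer metadata and
longline effort, and YAML/JSON for configuration.  Everything here is
deliberately boring: fixed CSV dialect (comma, header, UTF-8), signed
decimal degrees for coordinates, opaque string identifiers for samples,
loci and alleles.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("fulmargsi")

MISSING_ALLELE = ""  # sentinel for a missing call in genotype tables

BREEDING_MONTHS = frozenset({5, 6, 7, 8, 9})  # May-September
NONBREEDING_MONTHS = frozenset({10, 11, 12, 1, 2, 3, 4})  # October-April


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds, MCMC settings and season definitions for a full run.

    Defaults implement the standard amplicon-GSI protocol for this panel:
    calls need >= 20 reads, a heterozygote needs an allelic ratio >= 0.4,
    samples with > 20% missing loci are dropped, loci out of HWE (p < 0.05)
    in >= 3 colonies are dropped, and a bycatch bird counts as assigned only
    when its posterior for one colony reaches 0.9.
    """

    seed: int = 1
    # genotype-QC thresholds
    min_depth: int = 20
    min_allelic_ratio: float = 0.4
    max_missing_fraction: float = 0.2
    hwe_alpha: float = 0.05
    hwe_pop_fail_min: int = 3
    hwe_mc_reps: int = 10_000
    duplicate_min_shared_loci: int = 30
    duplicate_match_fraction: float = 0.95
    # assignment
    posterior_threshold: float = 0.9
    sweeps: int = 2000
    burn_in: int = 100
    # spatial grids
    cell_size_deg: float = 0.25
    effort_cell_size_deg: float = 0.5
    kde_bandwidth_method: str = "href"
    isopleth_level: float = 0.5
    # seasons
    breeding_months: frozenset = BREEDING_MONTHS
    nonbreeding_months: frozenset = NONBREEDING_MONTHS

    def __post_init__(self) -> None:
        for name in ("min_allelic_ratio", "max_missing_fraction", "hwe_alpha",
                     "posterior_threshold", "isopleth_level"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.burn_in < 0 or self.sweeps <= self.burn_in:
            raise ValueError(
                f"need sweeps > burn_in >= 0, got sweeps={self.sweeps} "
                f"burn_in={self.burn_in}")
        breeding = frozenset(self.breeding_months)
        nonbreeding = frozenset(self.nonbreeding_months)
        if breeding & nonbreeding or breeding | nonbreeding != frozenset(range(1, 13)):
            raise ValueError("breeding and nonbreeding months must partition 1..12")
        object.__setattr__(self, "breeding_months", breeding)
        object.__setattr__(self, "nonbreeding_months", nonbreeding)
        if self.min_depth < 0 or self.hwe_pop_fail_min < 0:
            raise ValueError("counts must be non-negative")
        if self.cell_size_deg <= 0 or self.effort_cell_size_deg <= 0:
            raise ValueError("grid cell sizes must be positive")

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the global seed."""
        h = zlib.crc32(stage.encode("utf-8"))
        return int(np.random.SeedSequence([self.seed, h]).generate_state(1)[0] % (2**31 - 1))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["breeding_months"] = sorted(self.breeding_months)
        d["nonbreeding_months"] = sorted(self.nonbreeding_months)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        d = dict(d)
        for key in ("breeding_months", "nonbreeding_months"):
            if key in d:
                d[key] = frozenset(int(m) for m in d[key])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text(encoding="utf-8")
        data = yaml.safe_load(text)  # YAML parses JSON too
        return cls.from_dict(data or {})

    def to_file(self, path: str | Path) -> None:
        p = Path(path)
        if p.suffix == ".json":
            p.write_text(json.dumps(self.to_dict(), indent=2), encoding="utf-8")
        else:
            p.write_text(yaml.safe_dump(self.to_dict()), encoding="utf-8")


# ---------------------------------------------------------------------------
# records
# ---------------------------------------------------------------------------

def season_of_month(month: int | None,
                    breeding_months: frozenset = BREEDING_MONTHS) -> str:
    """Map a calendar month to 'breeding'/'nonbreeding'; None -> 'unknown'."""
    if month is None:
        return "unknown"
    if not 1 <= int(month) <= 12:
        raise ValueError(f"month out of range: {month}")
    return "breeding" if int(month) in breeding_months else "nonbreeding"


@dataclass(frozen=True)
class ObserverRecord:
    """Where and when a bycatch bird was collected by a fishery observer."""

    sample_id: str
    latitude: float
    longitude: float
    date: _dt.date | None
    season: str = "unknown"

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude out of range: {self.latitude}")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude out of range: {self.longitude}")
        if self.season == "unknown" and self.date is not None:
            # default May-September breeding window; readers with a custom
            # season config pass season explicitly
            object.__setattr__(self, "season",
                               season_of_month(self.date.month))


@dataclass(frozen=True)
class EffortRecord:
    """A longline set: location, date, and number of hooks deployed."""

    latitude: float
    longitude: float
    date: _dt.date | None
    hooks: int

    def __post_init__(self) -> None:
        if self.hooks < 0:
            raise ValueError(f"hooks must be >= 0, got {self.hooks}")


# ---------------------------------------------------------------------------
# genotype tables
# ---------------------------------------------------------------------------

GENOTYPE_COLUMNS = ["sample_id", "locus_id", "allele_1", "allele_2",
                    "depth_1", "depth_2"]


@dataclass
class GenotypeTable:
    """Unordered diploid calls per sample x locus, with optional read depths.

    ``calls`` has columns sample_id, locus_id, allele_1, allele_2, depth_1,
    depth_2.  Allele pairs are canonicalized lexicographically so that
    ('B','A') and ('A','B') are the same genotype.  A missing call stores the
    empty string in both allele columns.  Alleles are opaque strings — SNP
    bases and multi-SNP haplotype strings are treated identically.
    """

    calls: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.calls.copy()
        missing = [c for c in GENOTYPE_COLUMNS[:4] if c not in df.columns]
        if missing:
            raise ValueError(f"genotype table missing columns: {missing}")
        for c in ("depth_1", "depth_2"):
            if c not in df.columns:
                df[c] = np.nan
            df[c] = pd.to_numeric(df[c], errors="coerce").astype(float)
        df["allele_1"] = df["allele_1"].fillna(MISSING_ALLELE).astype(str)
        df["allele_2"] = df["allele_2"].fillna(MISSING_ALLELE).astype(str)
        depths = df[["depth_1", "depth_2"]].to_numpy(dtype=float)
        if np.nanmin(depths, initial=0.0) < 0:
            bad = df[(df["depth_1"] < 0) | (df["depth_2"] < 0)]
            raise ValueError(f"negative read depths in rows: {bad.index.tolist()}")
        # canonical unordered pair: allele_1 <= allele_2, depths follow alleles
        swap = (df["allele_1"] > df["allele_2"]).to_numpy()
        if swap.any():
            a1 = df["allele_1"].to_numpy().copy()
            a2 = df["allele_2"].to_numpy().copy()
            d1 = df["depth_1"].to_numpy(dtype=float).copy()
            d2 = df["depth_2"].to_numpy(dtype=float).copy()
            a1[swap], a2[swap] = a2[swap], a1[swap].copy()
            d1[swap], d2[swap] = d2[swap], d1[swap].copy()
            df["allele_1"], df["allele_2"] = a1, a2
            df["depth_1"], df["depth_2"] = d1, d2
        dup = df.duplicated(subset=["sample_id", "locus_id"], keep=False)
        if dup.any():
            offending = df.loc[dup, ["sample_id", "locus_id"]].drop_duplicates()
            raise ValueError(
                "duplicate (sample, locus) rows: "
                + "; ".join(f"({r.sample_id}, {r.locus_id})"
                            for r in offending.itertuples()))
        self.calls = df[GENOTYPE_COLUMNS].reset_index(drop=True)

    # -- accessors ----------------------------------------------------------

    @property
    def samples(self) -> list[str]:
        return sorted(self.calls["sample_id"].unique())

    @property
    def loci(self) -> list[str]:
        return sorted(self.calls["locus_id"].unique())

    def is_missing(self) -> pd.Series:
        return (self.calls["allele_1"] == MISSING_ALLELE) & \
               (self.calls["allele_2"] == MISSING_ALLELE)

    def subset_samples(self, keep: Iterable[str]) -> "GenotypeTable":
        keep = set(keep)
        return GenotypeTable(self.calls[self.calls["sample_id"].isin(keep)])

    def subset_loci(self, keep: Iterable[str]) -> "GenotypeTable":
        keep = set(keep)
        return GenotypeTable(self.calls[self.calls["locus_id"].isin(keep)])

    def __len__(self) -> int:
        return len(self.calls)


def read_genotype_table(path: str | Path) -> GenotypeTable:
    """Read a genotype CSV (sample_id, locus_id, allele_1, allele_2, depth_1, depth_2)."""
    df = pd.read_csv(path, dtype={"sample_id": str, "locus_id": str,
                                  "allele_1": str, "allele_2": str},
                     keep_default_na=False, na_values=[])
    for c in ("depth_1", "depth_2"):
        if c in df.columns:
            df[c] = pd.to_numeric(df[c], errors="coerce")
    return GenotypeTable(df)


def write_genotype_table(table: GenotypeTable, path: str | Path) -> None:
    table.calls.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# observer / effort CSV
# ---------------------------------------------------------------------------

def _parse_date(value) -> _dt.date | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip()
    if not s or s.lower() in ("na", "nan", "none"):
        return None
    return _dt.date.fromisoformat(s)


def read_observer_records(path: str | Path,
                          config: PipelineConfig | None = None) -> list[ObserverRecord]:
    """Read observer metadata CSV; season is derived from the date's month."""
    breeding = (config.breeding_months if config is not None else BREEDING_MONTHS)
    df = pd.read_csv(path, dtype={"sample_id": str})
    records = []
    for row in df.itertuples(index=False):
        date = _parse_date(getattr(row, "date", None))
        season = season_of_month(date.month if date else None, breeding)
        records.append(ObserverRecord(sample_id=row.sample_id,
                                      latitude=float(row.latitude),
                                      longitude=float(row.longitude),
                                      date=date, season=season))
    return records


def write_observer_records(records: Sequence[ObserverRecord], path: str | Path) -> None:
    pd.DataFrame([{
        "sample_id": r.sample_id, "latitude": r.latitude,
        "longitude": r.longitude,
        "date": r.date.isoformat() if r.date else "",
    } for r in records]).to_csv(path, index=False)


def read_effort_records(path: str | Path) -> list[EffortRecord]:
    df = pd.read_csv(path)
    return [EffortRecord(latitude=float(r.latitude), longitude=float(r.longitude),
                         date=_parse_date(getattr(r, "date", None)),
                         hooks=int(r.hooks))
            for r in df.itertuples(index=False)]


def write_effort_records(records: Sequence[EffortRecord], path: str | Path) -> None:
    pd.DataFrame([{
        "latitude": r.latitude, "longitude": r.longitude,
        "date": r.date.isoformat() if r.date else "", "hooks": r.hooks,
    } for r in records]).to_csv(path, index=False)


def read_census(path: str | Path) -> pd.DataFrame:
    """Colony census CSV: colony, population_estimate[, percent_of_total]."""
    df = pd.read_csv(path, dtype={"colony": str})
    if "percent_of_total" not in df.columns:
        total = df["population_estimate"].sum()
        df["percent_of_total"] = 100.0 * df["population_estimate"] / total
    return df


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path):
    """Read SNP genotypes from a VCF.

    Returns ``(genotypes, snps, samples, n_skipped_indels)`` where
    ``genotypes`` is an int array of shape (n_samples, n_snps, 2) holding
    allele indices (-1 for missing) and ``snps`` is a list of
    :class:`~fulmargsi.marker_panel.SNPRecord` in file order.  Indel records
    are skipped and counted; multiallelic SNPs are kept.
    """
    from cyvcf2 import VCF  # deferred: cyvcf2 import is slow

    from .marker_panel import SNPRecord

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    snps: list = []
    geno_cols: list[np.ndarray] = []
    n_skipped = 0
    for variant in vcf:
        alleles = [variant.REF] + list(variant.ALT)
        if any(len(a) != 1 for a in alleles if a not in (".",)):
            n_skipped += 1  # indel or MNP
            continue
        gt = np.asarray(variant.genotype.array())[:, :2].astype(int)
        snps.append(SNPRecord(scaffold=variant.CHROM, position=int(variant.POS),
                              alleles=tuple(alleles)))
        geno_cols.append(gt)
    vcf.close()
    if n_skipped:
        logger.warning("read_vcf: skipped %d indel/MNP records", n_skipped)
    if geno_cols:
        genotypes = np.stack(geno_cols, axis=1)  # (n_samples, n_snps, 2)
    else:
        genotypes = np.empty((len(samples), 0, 2), dtype=int)
    return genotypes, snps, samples, n_skipped


def vcf_genotypes_to_table(genotypes: np.ndarray, snps, samples) -> GenotypeTable:
    """Flatten VCF-derived genotypes into the pipeline's long genotype table."""
    rows = []
    for j, snp in enumerate(snps):
        locus = f"{snp.scaffold}:{snp.position}"
        for i, sample in enumerate(samples):
            a, b = genotypes[i, j]
            if a < 0 or b < 0:
                rows.append((sample, locus, MISSING_ALLELE, MISSING_ALLELE))
            else:
                rows.append((sample, locus, snp.alleles[a], snp.alleles[b]))
    df = pd.DataFrame(rows, columns=GENOTYPE_COLUMNS[:4])
    return GenotypeTable(df)


# ---------------------------------------------------------------------------
# pipeline orchestration
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig, workdir: str | Path,
                 stages: Sequence[str] = ("simulate", "qc", "assign",
                                          "impact", "overlap"),
                 sim_config=None) -> dict:
    """Run the requested stages in order inside ``workdir``.

    ``simulate`` writes a synthetic bundle (reference + mixture genotype
    tables, labels, census, observer and effort CSVs) with known truth;
    the remaining stages read their inputs from ``workdir`` and write their
    outputs next to them.  Identical config + inputs give identical outputs.
    Returns a report dict keyed by stage.
    """
    from . import colony_impact, genotype_qc, gsi_core, spatial_overlap, synthetic_data

    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    order = ["simulate", "qc", "assign", "impact", "overlap"]
    stages = sorted(set(stages), key=order.index)
    report: dict = {"config": config.to_dict()}
    logger.info("pipeline start: seed=%d stages=%s", config.seed, stages)

    def require(name: str, stage: str) -> Path:
        p = workdir / name
        if not p.exists():
            raise FileNotFoundError(f"stage '{stage}' needs missing input {p}")
        return p

    if "simulate" in stages:
        sim = sim_config or synthetic_data.SimulationConfig(
            seed=config.stage_seed("simulate"))
        bundle = synthetic_data.simulate_bundle(sim)
        synthetic_data.write_bundle(bundle, workdir)
        report["simulate"] = {"n_reference": len(bundle.reference_labels),
                              "n_mixture": len(bundle.mixture_labels)}

    if "qc" in stages:
        raw = read_genotype_table(require("mixture_raw.csv", "qc"))
        ref = read_genotype_table(require("reference_raw.csv", "qc"))
        labels = pd.read_csv(require("reference_labels.csv", "qc"),
                             dtype=str).set_index("sample_id")["colony"]
        ref_qc, ref_report = genotype_qc.qc_pipeline(
            ref, labels=labels, config=config)
        mix_qc, mix_report = genotype_qc.qc_pipeline(
            raw, labels=None, config=config)
        write_genotype_table(ref_qc, workdir / "reference_qc.csv")
        write_genotype_table(mix_qc, workdir / "mixture_qc.csv")
        ref_report.to_csv(workdir / "qc_report_reference.csv")
        mix_report.to_csv(workdir / "qc_report_mixture.csv")
        report["qc"] = {"reference_samples": len(ref_qc.samples),
                        "mixture_samples": len(mix_qc.samples)}

    if "assign" in stages:
        ref = read_genotype_table(require("reference_qc.csv", "assign"))
        mix = read_genotype_table(require("mixture_qc.csv", "assign"))
        labels = pd.read_csv(require("reference_labels.csv", "assign"),
                             dtype=str).set_index("sample_id")["colony"]
        labels = labels.loc[[s for s in ref.samples if s in labels.index]]
        baseline = gsi_core.build_baseline(ref, labels, mixture=mix)
        self_assign = gsi_core.self_assign_loo(
            baseline, threshold=config.posterior_threshold)
        result = gsi_core.infer_mixture(
            baseline, mix, sweeps=config.sweeps, burn_in=config.burn_in,
            seed=config.stage_seed("assign"),
            threshold=config.posterior_threshold)
        self_assign.assignments.to_csv(workdir / "self_assignment.csv", index=False)
        result.assignments.to_csv(workdir / "assignments.csv", index=False)
        result.pi_summary.to_csv(workdir / "mixing_proportions.csv", index=False)
        report["assign"] = {
            "self_assignment_accuracy": self_assign.accuracy_assigned,
            "fraction_assigned": float(result.assignments["assigned"].mean()),
        }

    if "impact" in stages:
        census = read_census(require("census.csv", "impact"))
        assignments = pd.read_csv(require("assignments.csv", "impact"),
                                  dtype={"sample_id": str})
        observers = read_observer_records(require("observer.csv", "impact"), config)
        impact = colony_impact.impact_report(census, assignments,
                                             observers=observers,
                                             alpha=config.hwe_alpha)
        impact.tests.to_csv(workdir / "impact_tests.csv", index=False)
        impact.seasonal.to_csv(workdir / "impact_seasonal.csv", index=False)
        report["impact"] = {"n_significant": int(impact.tests["significant"].sum())}

    if "overlap" in stages:
        assignments = pd.read_csv(require("assignments.csv", "overlap"),
                                  dtype={"sample_id": str})
        observers = read_observer_records(require("observer.csv", "overlap"), config)
        effort = read_effort_records(require("effort.csv", "overlap"))
        overlap = spatial_overlap.overlap_report(
            assignments, observers, effort, config=config)
        overlap.overlaps.to_csv(workdir / "overlap.csv", index=False)
        overlap.effort_grid.to_csv(workdir / "effort_grid.csv", index=False)
        (workdir / "effort_ratio.json").write_text(
            json.dumps(overlap.effort_ratio_summary, indent=2), encoding="utf-8")
        report["overlap"] = {"n_comparisons": len(overlap.overlaps)}

    (workdir / "pipeline_report.json").write_text(
        json.dumps(report, indent=2, default=float), encoding="utf-8")
    logger.info("pipeline done")
    return report
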