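"""Synthetic community datasets and on-disk formats.

This module owns the package's data containers (sample metadata, haplotype
alignments), all file I/O (FASTA + metadata TSV, Newick genealogies, ESRI
ASCII grids), and the generator that emulates the Joshua-tree/yucca-moth
study design: five co-distributed species (four moths with a mitochondrial
and a nuclear locus each, one plant with a chloroplast locus), locus-specific
substitution models and mutation rates, haploid effective sizes derived from
Θ estimates, a single instantaneous size change at 13 KYA, and — for the
plant — a stepping-stone arrangement of demes producing strong structure and
isolation by distance.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .coalsim import (
    DemographicScenario,
    simulate_genealogy,
    simulate_stepping_stone_genealogy,
)
from .seqsim import SubstitutionModel, evolve_sequences

__all__ = [
    "SampleMeta",
    "HaplotypeAlignment",
    "SpeciesConfig",
    "LocusConfig",
    "CommunityConfig",
    "default_community_config",
    "generate_community",
    "read_alignment",
    "write_alignment",
    "read_grid",
    "write_grid",
    "AsciiGrid",
    "generate_sdm_fixture",
]

VALID_CHARS = set("ACGT-N")
META_COLUMNS = ["sample_id", "population", "region", "latitude", "longitude"]


class FormatError(ValueError):
    """Malformed on-disk data (sequence lengths, characters, grid headers)."""


class MetadataError(ValueError):
    """Sample metadata inconsistent with sequence records."""


class ConfigurationError(ValueError):
    """Invalid generator or pipeline configuration."""


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    population: str
    region: str
    latitude: float
    longitude: float

    def __post_init__(self) -> None:
        if not self.population:
            raise MetadataError("population must be nonempty")
        if not -90.0 <= self.latitude <= 90.0:
            raise MetadataError(f"latitude out of range: {self.latitude}")
        if not -180.0 <= self.longitude <= 180.0:
            raise MetadataError(f"longitude out of range: {self.longitude}")


class HaplotypeAlignment:
    """Aligned haplotypes for one locus plus per-sample metadata.

    Sequences are equal-length strings over ``A C G T - N``; metadata rows are
    aligned one-to-one with sequences.  ``genome`` (mtDNA/nuclear/cpDNA)
    records the inheritance class, which determines the default generation
    scaling downstream.
    """

    def __init__(
        self,
        locus_name: str,
        sequences: list[str],
        sample_meta: list[SampleMeta],
        genome: str = "mtDNA",
        provenance: dict | None = None,
    ):
        if len(sequences) < 2:
            raise FormatError("an alignment needs at least 2 sequences")
        lengths = {len(s) for s in sequences}
        if len(lengths) != 1:
            raise FormatError(
                f"sequences have unequal lengths: {sorted(lengths)}"
            )
        for s in sequences:
            bad = set(s.upper()) - VALID_CHARS
            if bad:
                raise FormatError(f"invalid characters in sequence: {bad}")
        if len(sample_meta) != len(sequences):
            raise MetadataError(
                f"{len(sample_meta)} metadata rows for {len(sequences)} sequences"
            )
        if genome not in ("mtDNA", "nuclear", "cpDNA"):
            raise ValueError(f"unknown genome class: {genome!r}")
        pop_region: dict[str, str] = {}
        for m in sample_meta:
            if pop_region.setdefault(m.population, m.region) != m.region:
                raise MetadataError(
                    f"population {m.population!r} mapped to multiple regions"
                )
        self.locus_name = locus_name
        self.sequences = [s.upper() for s in sequences]
        self.sample_meta = list(sample_meta)
        self.genome = genome
        self.provenance = dict(provenance or {})

    @property
    def n(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    @property
    def populations(self) -> list[str]:
        return [m.population for m in self.sample_meta]

    @property
    def regions(self) -> list[str]:
        return [m.region for m in self.sample_meta]

    def as_matrix(self) -> np.ndarray:
        """(n, length) byte matrix for vectorized statistics."""
        return np.frombuffer(
            "".join(self.sequences).encode(), dtype="S1"
        ).reshape(self.n, self.length)

    def with_meta(self, sample_meta: list[SampleMeta]) -> "HaplotypeAlignment":
        return HaplotypeAlignment(
            self.locus_name, self.sequences, sample_meta, self.genome,
            self.provenance,
        )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, HaplotypeAlignment)
            and self.locus_name == other.locus_name
            and self.sequences == other.sequences
            and self.sample_meta == other.sample_meta
            and self.genome == other.genome
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"HaplotypeAlignment({self.locus_name!r}, n={self.n}, "
            f"length={self.length}, genome={self.genome!r})"
        )


# ---------------------------------------------------------------------------
# FASTA + TSV I/O

def write_alignment(aln: HaplotypeAlignment, path, meta_path) -> None:
    records = [
        SeqRecord(Seq(s), id=m.sample_id, description="")
        for s, m in zip(aln.sequences, aln.sample_meta)
    ]
    SeqIO.write(records, path, "fasta")
    df = pd.DataFrame(
        [
            {
                "sample_id": m.sample_id,
                "population": m.population,
                "region": m.region,
                "latitude": m.latitude,
                "longitude": m.longitude,
            }
            for m in aln.sample_meta
        ]
    )
    df.to_csv(meta_path, sep="\t", index=False)


def read_alignment(
    path, meta_path, locus_name: str | None = None, genome: str = "mtDNA"
) -> HaplotypeAlignment:
    """Read a FASTA alignment and its sample-metadata TSV.

    FASTA record ids must match the TSV's ``sample_id`` column exactly (same
    set; row order follows the FASTA).
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    df = pd.read_csv(meta_path, sep="\t", dtype={"sample_id": str})
    missing_cols = set(META_COLUMNS) - set(df.columns)
    if missing_cols:
        raise MetadataError(f"metadata TSV missing columns: {sorted(missing_cols)}")
    meta_by_id = {}
    for row in df.itertuples(index=False):
        meta_by_id[row.sample_id] = SampleMeta(
            sample_id=row.sample_id,
            population=str(row.population),
            region=str(row.region),
            latitude=float(row.latitude),
            longitude=float(row.longitude),
        )
    seqs, metas = [], []
    for rec in records:
        if rec.id not in meta_by_id:
            raise MetadataError(f"unknown sample_id in FASTA: {rec.id!r}")
        seqs.append(str(rec.seq))
        metas.append(meta_by_id[rec.id])
    name = locus_name if locus_name is not None else "locus"
    return HaplotypeAlignment(name, seqs, metas, genome=genome)


# ---------------------------------------------------------------------------
# ESRI ASCII grids

@dataclass
class AsciiGrid:
    """An ESRI ASCII raster: row-major values from the north-west corner."""

    values: np.ndarray  # (nrows, ncols), NODATA as np.nan
    xllcorner: float = 0.0
    yllcorner: float = 0.0
    cellsize: float = 1.0
    nodata_value: float = -9999.0

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    def same_geometry(self, other: "AsciiGrid") -> bool:
        return (
            self.values.shape == other.values.shape
            and math.isclose(self.xllcorner, other.xllcorner)
            and math.isclose(self.yllcorner, other.yllcorner)
            and math.isclose(self.cellsize, other.cellsize)
        )


def write_grid(grid: AsciiGrid, path) -> None:
    vals = np.where(np.isnan(grid.values), grid.nodata_value, grid.values)
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.ncols}\n")
        fh.write(f"nrows {grid.nrows}\n")
        fh.write(f"xllcorner {grid.xllcorner:.10g}\n")
        fh.write(f"yllcorner {grid.yllcorner:.10g}\n")
        fh.write(f"cellsize {grid.cellsize:.10g}\n")
        fh.write(f"NODATA_value {grid.nodata_value:.10g}\n")
        for row in vals:
            fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")


def read_grid(path) -> AsciiGrid:
    with open(path) as fh:
        header = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        body = fh.read().split()
    try:
        ncols = int(header["ncols"])
        nrows = int(header["nrows"])
        nodata = header["nodata_value"]
    except KeyError as e:
        raise FormatError(f"ASCII grid header missing {e}") from None
    vals = np.array(body, dtype=float)
    if vals.size != nrows * ncols:
        raise FormatError(
            f"expected {nrows * ncols} cells, found {vals.size}"
        )
    vals = vals.reshape(nrows, ncols)
    vals[vals == nodata] = np.nan
    return AsciiGrid(
        values=vals,
        xllcorner=header["xllcorner"],
        yllcorner=header["yllcorner"],
        cellsize=header["cellsize"],
        nodata_value=nodata,
    )


# ---------------------------------------------------------------------------
# Community generator

@dataclass(frozen=True)
class LocusConfig:
    name: str
    genome: str  # mtDNA | nuclear | cpDNA
    n_sites: int
    mu: float  # per site per generation
    model: SubstitutionModel
    n_samples: int

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ConfigurationError(f"locus {self.name!r}: mu must be > 0")
        if self.n_sites < 1:
            raise ConfigurationError(f"locus {self.name!r}: n_sites must be >= 1")
        if self.n_samples < 2:
            raise ConfigurationError(
                f"locus {self.name!r}: n_samples must be >= 2"
            )


@dataclass(frozen=True)
class SpeciesConfig:
    name: str
    loci: tuple[LocusConfig, ...]
    scenario: DemographicScenario
    # population name -> (region, latitude, longitude)
    populations: tuple[tuple[str, str, float, float], ...]
    structure: str = "panmictic"  # or "stepping-stone"
    migration_rate: float | None = None

    def __post_init__(self) -> None:
        if self.structure not in ("panmictic", "stepping-stone"):
            raise ConfigurationError(
                f"species {self.name!r}: unknown structure {self.structure!r}"
            )
        if self.structure == "stepping-stone":
            if len(self.populations) < 2:
                raise ConfigurationError(
                    f"species {self.name!r}: stepping-stone needs >= 2 populations"
                )
            if self.migration_rate is None or self.migration_rate <= 0:
                raise ConfigurationError(
                    f"species {self.name!r}: stepping-stone needs migration_rate > 0"
                )
        if not self.populations:
            raise ConfigurationError(f"species {self.name!r}: no populations")


@dataclass(frozen=True)
class CommunityConfig:
    species: tuple[SpeciesConfig, ...]
    seed: int = 0


# Substitution models and Γ shapes fitted to the real loci; mutation rates in
# substitutions/site/generation; haploid Ne = Θ/(2µ).
_MOTH_POPS_5 = (
    ("site02", "Southwest", 34.2, -116.5),
    ("site13", "Central", 35.3, -115.9),
    ("site27", "Northeast", 36.6, -114.9),
    ("site33", "Northwest", 36.0, -117.8),
    ("site37", "Southeast", 34.9, -114.2),
)
_PLANT_POPS = tuple(
    (f"yb{i + 1:02d}", reg, 33.9 + 0.18 * i, -118.0 + 0.15 * i)
    for i, reg in enumerate(
        ["South"] * 4 + ["Central"] * 4 + ["North"] * 4
    )
)


def _moth(name, mt_model, mt_theta, ef_model, ef_theta, n_mt, n_ef,
          ratio=1.0) -> SpeciesConfig:
    mt_mu, ef_mu = 1.5e-8, 2.2e-9
    scen_mt = DemographicScenario(
        ne_present=mt_theta / (2 * mt_mu), ratio_ancestral=ratio,
        t_change_years=13_000.0, generations_per_year=1.0,
    )
    # per-species scenario keyed on the mtDNA Ne; locus-specific Ne enters
    # through theta when the power engine rebuilds scenarios per locus
    return SpeciesConfig(
        name=name,
        loci=(
            LocusConfig(name="mtDNA", genome="mtDNA", n_sites=1800, mu=mt_mu,
                        model=mt_model, n_samples=n_mt),
            LocusConfig(name="EF1a", genome="nuclear", n_sites=490, mu=ef_mu,
                        model=ef_model, n_samples=n_ef),
        ),
        scenario=scen_mt,
        populations=_MOTH_POPS_5,
    )


def default_community_config(seed: int = 0, ratio: float = 1.0) -> CommunityConfig:
    """The study community: 4 moth species x 2 loci + 1 plant x 1 locus.

    Sample sizes, substitution models, Γ shapes, mutation rates and haploid
    effective sizes follow the study's fitted values; the plant is generated
    under a 1-D stepping-stone chain of 12 demes with low migration, which
    yields the strong chloroplast structure and isolation by distance seen in
    the real data.  ``ratio`` sets the ancestral:present size ratio for every
    species (1 = constant history).
    """
    g = 0.04
    species = (
        _moth("P_sordidus",
              SubstitutionModel("TrN", rate_AG=65.95, rate_CT=24.28, alpha=g),
              0.03,
              SubstitutionModel("K81", kappa=2.01, alpha=g),
              0.09, n_mt=25, n_ef=54, ratio=ratio),
        _moth("P_weethumpi",
              SubstitutionModel("HKY", kappa=25.90, alpha=g),
              0.04,
              SubstitutionModel("K81", kappa=1.49),
              0.01, n_mt=32, n_ef=58, ratio=ratio),
        _moth("T_antithetica",
              SubstitutionModel("TrN", rate_AG=25.38, rate_CT=14.72, alpha=g),
              0.03,
              SubstitutionModel("HKY", kappa=35.16),
              0.05, n_mt=24, n_ef=43, ratio=ratio),
        _moth("T_synthetica",
              SubstitutionModel("HKY", kappa=43.26, alpha=g),
              0.03,
              SubstitutionModel("HKY", kappa=39.72, alpha=g),
              0.04, n_mt=31, n_ef=49, ratio=ratio),
        SpeciesConfig(
            name="Y_brevifolia",
            loci=(
                LocusConfig(
                    name="cpDNA", genome="cpDNA", n_sites=2000, mu=2.42e-8,
                    model=SubstitutionModel("K81", kappa=2.81, alpha=1.55),
                    n_samples=79,
                ),
            ),
            scenario=DemographicScenario(
                ne_present=1.1 / (2 * 2.42e-8), ratio_ancestral=ratio,
                t_change_years=13_000.0, generations_per_year=1.0 / 30.0,
            ),
            populations=_PLANT_POPS,
            structure="stepping-stone",
            # per-lineage per-generation rate; with per-deme Ne ~ 1.9e6 this
            # gives Nm ~ 0.06, the strong-structure regime (F_ST near 0.9)
            migration_rate=3e-8,
        ),
    )
    return CommunityConfig(species=species, seed=seed)


def _spread_samples(n: int, n_pops: int) -> list[int]:
    base = n // n_pops
    counts = [base] * n_pops
    for i in range(n - base * n_pops):
        counts[i] += 1
    return counts


def generate_community(
    config: CommunityConfig,
) -> dict[str, list[HaplotypeAlignment]]:
    """Generate one alignment per species x locus, all from the master seed.

    Panmictic species draw a single-population coalescent genealogy; the
    stepping-stone mode places each population on a deme of a 1-D chain with
    symmetric nearest-neighbour migration.  Every alignment carries a
    provenance record (seed, scenario, substitution-model family).
    """
    master = np.random.default_rng(config.seed)
    out: dict[str, list[HaplotypeAlignment]] = {}
    for sp in config.species:
        alns = []
        for locus in sp.loci:
            rng = np.random.default_rng(master.integers(2**63))
            counts = _spread_samples(locus.n_samples, len(sp.populations))
            if sp.structure == "stepping-stone":
                # For the plant, deme size is the per-deme share of the total
                # Ne so the metapopulation size matches the scenario.
                deme_scen = DemographicScenario(
                    ne_present=sp.scenario.ne_present / len(sp.populations),
                    ratio_ancestral=sp.scenario.ratio_ancestral,
                    t_change_years=sp.scenario.t_change_years,
                    generations_per_year=sp.scenario.generations_per_year,
                )
                gen, tip_demes = simulate_stepping_stone_genealogy(
                    counts, deme_scen, sp.migration_rate, seed=rng
                )
                pop_of_tip = [sp.populations[d] for d in tip_demes]
            else:
                gen = simulate_genealogy(locus.n_samples, sp.scenario, seed=rng)
                pop_of_tip = []
                for p, c in zip(sp.populations, counts):
                    pop_of_tip.extend([p] * c)
            labels = [
                f"{sp.name}_{locus.name}_{i + 1:03d}"
                for i in range(locus.n_samples)
            ]
            aln = evolve_sequences(
                gen, locus.model, locus.mu, locus.n_sites, seed=rng,
                labels=labels,
            )
            meta = [
                SampleMeta(
                    sample_id=labels[i],
                    population=pop_of_tip[i][0],
                    region=pop_of_tip[i][1],
                    latitude=pop_of_tip[i][2],
                    longitude=pop_of_tip[i][3],
                )
                for i in range(locus.n_samples)
            ]
            aln = HaplotypeAlignment(
                locus_name=locus.name,
                sequences=aln.sequences,
                sample_meta=meta,
                genome=locus.genome,
                provenance={
                    "seed": config.seed,
                    "species": sp.name,
                    "scenario_ratio": sp.scenario.ratio_ancestral,
                    "model": locus.model.family,
                    "structure": sp.structure,
                },
            )
            alns.append(aln)
        out[sp.name] = alns
    return out


# ---------------------------------------------------------------------------
# SDM fixtures

def generate_sdm_fixture(
    n_cells: int,
    n_variables: int,
    seed=None,
    n_presence: int = 30,
    n_background: int = 30,
    past_shift: float = 0.0,
):
    """Synthetic habitat-suitability surface plus climate stacks.

    Returns ``(surface, presence_rc, background_rc, current_stack, past_stack)``
    where the surface is an :class:`AsciiGrid` of probabilities, the point
    sets are lists of (row, col) cells, and the stacks are lists of
    :class:`AsciiGrid` (one per climate variable) sharing the surface's
    geometry.  Presence cells are drawn preferentially from high-probability
    cells so a correct evaluator scores AUC > 0.5 in expectation.
    ``past_shift`` displaces the first past variable by that many standard
    deviations, creating non-analog cells when large.
    """
    if n_cells < 4:
        raise ConfigurationError("n_cells must be >= 4")
    if n_variables < 1:
        raise ConfigurationError("n_variables must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    side = int(math.floor(math.sqrt(n_cells)))
    ncols = side
    nrows = int(math.ceil(n_cells / side))
    total = nrows * ncols

    # smooth suitability: logistic of a distance-to-centre field plus noise
    rr, cc = np.meshgrid(np.arange(nrows), np.arange(ncols), indexing="ij")
    cy, cx = rng.uniform(0, nrows), rng.uniform(0, ncols)
    d = np.sqrt((rr - cy) ** 2 + (cc - cx) ** 2)
    z = 2.0 - 4.0 * d / max(d.max(), 1e-9) + rng.normal(0, 0.3, size=d.shape)
    prob = 1.0 / (1.0 + np.exp(-z))
    surface = AsciiGrid(values=prob.astype(float))

    flat = prob.ravel()
    weights = flat**3
    weights = weights / weights.sum()
    pres_idx = rng.choice(total, size=min(n_presence, total), replace=False,
                          p=weights)
    bg_idx = rng.choice(total, size=min(n_background, total), replace=False)
    presence = [(int(i // ncols), int(i % ncols)) for i in pres_idx]
    background = [(int(i // ncols), int(i % ncols)) for i in bg_idx]

    current, past = [], []
    for v in range(n_variables):
        cur = rng.normal(0, 1, size=(nrows, ncols)) + 0.5 * z
        pst = rng.normal(0, 1, size=(nrows, ncols)) + 0.5 * z
        if v == 0 and past_shift != 0.0:
            pst = pst + past_shift
        current.append(AsciiGrid(values=cur))
        past.append(AsciiGrid(values=pst))
    return surface, presence, background, current, past
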