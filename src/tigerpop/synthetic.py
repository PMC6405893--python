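"""Seeded synthetic datasets with the structure the analysis assumes.

Emulates a two-population noninvasive survey along an international
border: two demes with Balding-Nichols differentiation and a small
migrant fraction, microsatellite genotypes amplified in replicate with
fecal-DNA error (allelic dropout, false alleles, missing loci), sex
marker outcomes, and occurrence records whose spatial mean drifts along
the east-west axis at a configurable speed.

All randomness flows from a single seeded :class:`numpy.random.Generator`,
so a fixed seed yields byte-identical fixtures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .genotyping import ReplicateGenotype, GenepopTable, write_genepop

EARTH_RADIUS_KM = 6371.0088
KM_PER_DEG = EARTH_RADIUS_KM * np.pi / 180.0  # 111.1949... km per degree

POPULATIONS = ("China", "Russia")
EVIDENCE_TYPES = ("camera", "dna", "track", "kill", "other")
EVIDENCE_PROBS = (0.26, 0.10, 0.30, 0.09, 0.25)

_PROB_FIELDS = (
    "f_st",
    "migrant_fraction",
    "dropout_rate",
    "false_allele_rate",
    "missing_rate",
)


@dataclass
class SyntheticConfig:
    """Study-design parameters for the generator.

    Defaults mirror the survey conditions the analysis targets: 8 loci
    with 5 alleles each, modest differentiation (F = 0.15), 12
    individuals per population, a ~13% migrant fraction, four PCR
    replicates with fecal-DNA error rates, and occurrence records
    2003-2016 drifting westward at ~12.8 km per 3-year interval
    (negative drift = decreasing longitude).
    """

    n_loci: int = 8
    alleles_per_locus: int = 5
    f_st: float = 0.15
    n_per_pop: int = 12
    migrant_fraction: float = 0.13
    dropout_rate: float = 0.2
    false_allele_rate: float = 0.05
    missing_rate: float = 0.05
    n_replicates: int = 4
    extra_replicates: int = 3
    drift_km_per_3yr: float = -12.83
    years: tuple[int, int] = (2003, 2016)
    records_per_year: int = 77
    scatter_km: float = 5.0
    center_lon: float = 130.0
    center_lat: float = 43.5
    pop_offset_deg: float = 0.6
    coord_scatter_deg: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        for name in _PROB_FIELDS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1], got {v}")
        if self.f_st >= 1.0:
            raise ValueError(f"f_st must be < 1, got {self.f_st}")
        if self.n_per_pop < 4:
            raise ValueError("n_per_pop must be >= 4 (unbiased P_ID needs n >= 4)")
        for name in ("n_loci", "alleles_per_locus", "n_replicates", "records_per_year"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        y0, y1 = self.years
        if y1 < y0:
            raise ValueError(f"years range is empty: {self.years}")


@dataclass
class SyntheticTruth:
    """Ground truth behind a synthetic dataset.

    ``freqs`` has shape (2 populations, n_loci, alleles_per_locus) and
    sums to one per population x locus; ``genotypes`` has shape
    (N, n_loci, 2) and stores allele sizes; ``individuals`` records the
    sampling population, true origin, migrant flag, sex and coordinates.
    """

    loci: list[str]
    allele_sizes: list[int]
    freqs: np.ndarray
    individuals: pd.DataFrame
    genotypes: np.ndarray
    boundary: list[tuple[float, float]] = field(default_factory=list)
    config: SyntheticConfig | None = None


def _boundary_polyline(config: SyntheticConfig) -> list[tuple[float, float]]:
    # north-south polyline between the two population centers, with a
    # gentle fixed zigzag so it is a genuine polyline and not a meridian
    lon0 = config.center_lon
    lats = np.linspace(config.center_lat - 2.0, config.center_lat + 2.0, 9)
    wiggle = 0.05 * np.sin(np.arange(lats.size))
    return [(float(lon0 + w), float(la)) for w, la in zip(wiggle, lats)]


def simulate_populations(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> SyntheticTruth:
    """Draw two differentiated populations and their sampled individuals.

    Ancestral allele frequencies come from a symmetric Dirichlet; each
    population's frequencies from the Balding-Nichols construction
    ``Dirichlet(p * (1 - F) / F)`` (F = 0 copies the ancestral vector).
    Genotypes are drawn under Hardy-Weinberg from the individual's origin
    population; a ``migrant_fraction`` of individuals carry genotypes
    from the opposite population while labelled with the sampling
    population.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    L, A = config.n_loci, config.alleles_per_locus
    loci = [f"L{i + 1}" for i in range(L)]
    # allele ladder spaced 4 units so a +/-2 false allele never collides
    # with a true allele
    allele_sizes = [100 + 4 * a for a in range(A)]

    ancestral = rng.dirichlet(np.ones(A), size=L)  # (L, A)
    freqs = np.empty((2, L, A))
    if config.f_st == 0.0:
        freqs[0] = ancestral
        freqs[1] = ancestral
    else:
        scale = (1.0 - config.f_st) / config.f_st
        for p in range(2):
            for l in range(L):
                freqs[p, l] = rng.dirichlet(ancestral[l] * scale)

    n = config.n_per_pop
    N = 2 * n
    sampling_pop = np.repeat([0, 1], n)
    migrant = rng.random(N) < config.migrant_fraction
    origin = np.where(migrant, 1 - sampling_pop, sampling_pop)

    genotypes = np.empty((N, L, 2), dtype=int)
    sizes = np.asarray(allele_sizes)
    for i in range(N):
        for l in range(L):
            idx = rng.choice(A, size=2, p=freqs[origin[i], l])
            genotypes[i, l] = np.sort(sizes[idx])

    # coordinates: China west of the boundary, Russia east of it
    centers = {
        0: (config.center_lon - config.pop_offset_deg, config.center_lat),
        1: (config.center_lon + config.pop_offset_deg, config.center_lat),
    }
    lons = np.empty(N)
    lats = np.empty(N)
    for i in range(N):
        clon, clat = centers[sampling_pop[i]]
        lons[i] = clon + rng.normal(0.0, config.coord_scatter_deg)
        lats[i] = clat + rng.normal(0.0, config.coord_scatter_deg)
    sex = rng.choice(["male", "female"], size=N)

    individuals = pd.DataFrame(
        {
            "individual_id": [f"T{i + 1:03d}" for i in range(N)],
            "sample_id": [f"S{i + 1:03d}" for i in range(N)],
            "population": [POPULATIONS[p] for p in sampling_pop],
            "origin": [POPULATIONS[p] for p in origin],
            "is_migrant": migrant,
            "sex": sex,
            "lon": lons,
            "lat": lats,
        }
    )
    return SyntheticTruth(
        loci=loci,
        allele_sizes=allele_sizes,
        freqs=freqs,
        individuals=individuals,
        genotypes=genotypes,
        boundary=_boundary_polyline(config),
        config=config,
    )


def simulate_replicate_amplifications(
    truth: SyntheticTruth,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> list[ReplicateGenotype]:
    """Apply the fecal-DNA error model independently to each replicate.

    Per replicate and locus: the locus fails entirely with
    ``missing_rate``; at a heterozygous locus each allele drops out with
    ``dropout_rate`` — any dropout event yields an apparent homozygote
    (when both copies drop, severe amplification imbalance leaves one of
    the two true alleles, chosen at random); finally each reported allele
    copy is replaced with ``false_allele_rate`` by a stepwise artifact
    two size units away from the true allele.

    Mirroring the laboratory protocol, a sample whose initial
    ``n_replicates`` amplifications leave any locus without a confirmed
    consensus call receives ``extra_replicates`` additional
    amplifications.
    """
    from .genotyping import call_consensus, CONFIRMED

    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    d, f, m = config.dropout_rate, config.false_allele_rate, config.missing_rate

    def one_replicate(i: int) -> dict[str, tuple[int, int] | None]:
        calls: dict[str, tuple[int, int] | None] = {}
        for l, loc in enumerate(truth.loci):
            if rng.random() < m:
                calls[loc] = None
                continue
            a, b = truth.genotypes[i, l]
            if a != b:
                drop_a = rng.random() < d
                drop_b = rng.random() < d
                if drop_a and drop_b:
                    keep = a if rng.random() < 0.5 else b
                    a = b = keep
                elif drop_a:
                    a = b
                elif drop_b:
                    b = a
            pair = []
            for allele in (a, b):
                if rng.random() < f:
                    allele = allele + (2 if rng.random() < 0.5 else -2)
                pair.append(int(allele))
            calls[loc] = tuple(sorted(pair))
        return calls

    out: list[ReplicateGenotype] = []
    for i, sample_id in enumerate(truth.individuals["sample_id"]):
        reps = [
            ReplicateGenotype(str(sample_id), r + 1, one_replicate(i))
            for r in range(config.n_replicates)
        ]
        if config.extra_replicates > 0:
            consensus = call_consensus(reps, loci=truth.loci)
            if any(s != CONFIRMED for s in consensus.locus_status.values()):
                reps.extend(
                    ReplicateGenotype(
                        str(sample_id),
                        config.n_replicates + r + 1,
                        one_replicate(i),
                    )
                    for r in range(config.extra_replicates)
                )
        out.extend(reps)
    return out


def simulate_sex_markers(
    truth: SyntheticTruth,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
    zfx_success: float = 0.98,
    dby7_success: float = 0.9,
) -> pd.DataFrame:
    """Replicate ZFX/DBY7 amplification outcomes per sample.

    ZFX (X-linked) can amplify in either sex; DBY7 (Y-linked) only in
    males, with the given per-replicate success rates.
    """
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    rows = []
    for _, ind in truth.individuals.iterrows():
        male = ind["sex"] == "male"
        for r in range(config.n_replicates):
            rows.append(
                {
                    "sample_id": ind["sample_id"],
                    "replicate": r + 1,
                    "zfx": bool(rng.random() < zfx_success),
                    "dby7": bool(male and rng.random() < dby7_success),
                    "positive_control_ok": True,
                    "negative_control_clean": True,
                }
            )
    return pd.DataFrame(rows)


def simulate_occurrences(
    truth: SyntheticTruth,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Occurrence records whose yearly spatial mean drifts east-west.

    The mean longitude translates by ``drift_km_per_3yr / 3`` km per year
    (negative = westward); records scatter isotropically around the mean
    with standard deviation ``scatter_km``.
    """
    rng = np.random.default_rng(config.seed + 3) if rng is None else rng
    y0, y1 = config.years
    if y1 < y0:
        raise ValueError(f"empty year range {config.years}")
    lat0 = config.center_lat
    km_per_deg_lon = KM_PER_DEG * np.cos(np.radians(lat0))
    start_lon = config.center_lon - 0.3
    rows = []
    rid = 0
    for year in range(y0, y1 + 1):
        mean_lon = start_lon + (year - y0) * (config.drift_km_per_3yr / 3.0) / km_per_deg_lon
        for _ in range(config.records_per_year):
            rid += 1
            rows.append(
                {
                    "record_id": f"O{rid:05d}",
                    "lon": mean_lon + rng.normal(0.0, config.scatter_km) / km_per_deg_lon,
                    "lat": lat0 + rng.normal(0.0, config.scatter_km) / KM_PER_DEG,
                    "year": year,
                    "evidence_type": str(
                        rng.choice(EVIDENCE_TYPES, p=EVIDENCE_PROBS)
                    ),
                }
            )
    return pd.DataFrame(rows)


def simulate_dataset(config: SyntheticConfig):
    """Convenience wrapper: one seeded generator drives every stage."""
    rng = np.random.default_rng(config.seed)
    truth = simulate_populations(config, rng)
    replicates = simulate_replicate_amplifications(truth, config, rng)
    sex_markers = simulate_sex_markers(truth, config, rng)
    occurrences = simulate_occurrences(truth, config, rng)
    return truth, replicates, sex_markers, occurrences


# ---------------------------------------------------------------------------
# fixture serialization


def replicates_to_frame(replicates, loci) -> pd.DataFrame:
    rows = []
    for rep in replicates:
        for loc in loci:
            call = rep.calls.get(loc)
            rows.append(
                {
                    "sample_id": rep.sample_id,
                    "replicate": rep.replicate_index,
                    "locus": loc,
                    "allele1": "" if call is None else call[0],
                    "allele2": "" if call is None else call[1],
                }
            )
    return pd.DataFrame(rows)


def frame_to_replicates(df: pd.DataFrame) -> list[ReplicateGenotype]:
    out = []
    for (sid, rep), grp in df.groupby(["sample_id", "replicate"], sort=True):
        calls = {}
        for _, row in grp.iterrows():
            a1, a2 = row["allele1"], row["allele2"]
            if pd.isna(a1) or a1 == "" or pd.isna(a2) or a2 == "":
                calls[row["locus"]] = None
            else:
                calls[row["locus"]] = (int(a1), int(a2))
        out.append(
            ReplicateGenotype(sample_id=str(sid), replicate_index=int(rep), calls=calls)
        )
    return out


def write_fixture(
    truth: SyntheticTruth,
    replicates,
    occurrences: pd.DataFrame,
    directory,
    sex_markers: pd.DataFrame | None = None,
) -> dict[str, Path]:
    """Write the full plain-text fixture for the pipeline.

    Emits replicates.csv, samples.csv, sex_markers.csv, occurrences.csv,
    boundary.geojson, genotypes.gen (Genepop of the true consensus
    genotypes) and truth.json (generator ground truth for tests).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    rep_df = replicates_to_frame(replicates, truth.loci)
    paths["replicates"] = directory / "replicates.csv"
    rep_df.to_csv(paths["replicates"], index=False)

    samples = truth.individuals[["sample_id", "population", "lon", "lat"]]
    paths["samples"] = directory / "samples.csv"
    samples.to_csv(paths["samples"], index=False, float_format="%.6f")

    if sex_markers is not None:
        paths["sex_markers"] = directory / "sex_markers.csv"
        sex_markers.to_csv(paths["sex_markers"], index=False)

    paths["occurrences"] = directory / "occurrences.csv"
    occurrences.to_csv(paths["occurrences"], index=False, float_format="%.6f")

    paths["boundary"] = directory / "boundary.geojson"
    geojson = {
        "type": "Feature",
        "geometry": {
            "type": "LineString",
            "coordinates": [[round(x, 6), round(y, 6)] for x, y in truth.boundary],
        },
        "properties": {"name": "border"},
    }
    with open(paths["boundary"], "w") as fh:
        json.dump(geojson, fh, sort_keys=True, indent=1)
        fh.write("\n")

    # true consensus genotypes, grouped by sampling population
    pops = []
    for pop in POPULATIONS:
        block = []
        for i, ind in truth.individuals.iterrows():
            if ind["population"] != pop:
                continue
            calls = {
                loc: (int(truth.genotypes[i, l, 0]), int(truth.genotypes[i, l, 1]))
                for l, loc in enumerate(truth.loci)
            }
            block.append((ind["sample_id"], calls))
        pops.append(block)
    table = GenepopTable(
        title="synthetic two-population microsatellite dataset",
        loci=list(truth.loci),
        populations=pops,
    )
    paths["genepop"] = directory / "genotypes.gen"
    write_genepop(table, paths["genepop"])

    paths["truth"] = directory / "truth.json"
    records = []
    for _, ind in truth.individuals.iterrows():
        records.append(
            {
                "individual_id": str(ind["individual_id"]),
                "sample_id": str(ind["sample_id"]),
                "population": str(ind["population"]),
                "origin": str(ind["origin"]),
                "is_migrant": bool(ind["is_migrant"]),
                "sex": str(ind["sex"]),
                "lon": round(float(ind["lon"]), 6),
                "lat": round(float(ind["lat"]), 6),
            }
        )
    truth_doc = {
        "loci": truth.loci,
        "allele_sizes": [int(a) for a in truth.allele_sizes],
        "freqs": np.round(truth.freqs, 10).tolist(),
        "individuals": records,
        "genotypes": truth.genotypes.tolist(),
        "config": None if truth.config is None else asdict(truth.config),
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth_doc, fh, sort_keys=True, indent=1)
        fh.write("\n")
    return paths
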