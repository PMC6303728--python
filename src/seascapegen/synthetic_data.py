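"""Seeded synthetic-data generators: hierarchically structured microsatellite
genotypes (Balding–Nichols), latitude-correlated environmental covariates, and
a coherent end-to-end fixture world (coastline, boundary current, release
sites) so the whole pipeline runs without any download.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lagrangian import CoastMask, ReleaseSpec
from .ocean_fields import GridSpec, VectorGridField, make_synthetic_field
from .popgen import MISSING, GenotypeMatrix
from .seascape_rda import PredictorTable

__all__ = [
    "GenotypeSimConfig",
    "EnvSimConfig",
    "simulate_genotypes",
    "simulate_environment",
    "make_fixture_suite",
    "FixtureBundle",
]


@dataclass
class GenotypeSimConfig:
    """Hierarchical island-model genotype simulation.

    Ancestral allele frequencies are flat-Dirichlet; group frequencies follow a
    Balding–Nichols draw Dirichlet(p·(1-F)/F) with F = ``fst_between_groups``;
    population frequencies nest likewise within groups with
    ``fst_within_groups``.  One population may be an admixed contact zone:
    each of its gene copies is drawn from the first donor group with
    probability ``alpha`` and from the second otherwise.  Null alleles then
    mask genotypes (null heterozygote -> apparent homozygote, null homozygote
    -> missing), and extra missingness is applied.

    Defaults mirror the study system: 3 groups (subspecies), 21 loci with
    2–14 alleles, and a single admixed contact-zone population.
    """

    n_groups: int = 3
    pops_per_group: int = 2
    individuals_per_pop: int = 30
    n_loci: int = 21
    alleles_per_locus: tuple[int, int] = (2, 14)  # inclusive uniform range
    fst_between_groups: float = 0.05
    fst_within_groups: float = 0.01
    contact_zone: tuple | None = None  # (pop_label, alpha, (donor_g1, donor_g2))
    null_allele_freq: float | dict = 0.0  # scalar or {locus_index: freq}
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for f in (self.fst_between_groups, self.fst_within_groups):
            if not (0.0 < f < 1.0):
                raise ValueError("target F must lie strictly in (0, 1)")
        if not (0.0 <= self.missing_rate <= 1.0):
            raise ValueError("missing_rate must be in [0, 1]")


@dataclass
class EnvSimConfig:
    n_sites: int = 15
    lat_range: tuple[float, float] = (-34.0, 22.0)
    sst_gradient: float = 0.35  # °C per degree latitude (poleward cooling)
    sst_intercept: float = 24.0  # °C at the equator
    noise_sd: float = 0.5
    recruit_effect: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _bn_dirichlet(rng, base: np.ndarray, F: float) -> np.ndarray:
    """Balding–Nichols draw: Dirichlet(base * (1-F)/F)."""
    conc = np.clip(base, 1e-9, None) * (1.0 - F) / F
    return rng.dirichlet(conc)


def simulate_genotypes(config: GenotypeSimConfig) -> GenotypeMatrix:
    """Draw a structured diploid genotype matrix under the hierarchical model."""
    rng = np.random.default_rng(config.seed)
    G, PPG, N, L = (
        config.n_groups,
        config.pops_per_group,
        config.individuals_per_pop,
        config.n_loci,
    )
    lo, hi = config.alleles_per_locus
    n_alleles = rng.integers(lo, hi + 1, size=L)

    anc = [rng.dirichlet(np.ones(k)) for k in n_alleles]
    group_freqs = [
        [_bn_dirichlet(rng, anc[l], config.fst_between_groups) for l in range(L)]
        for _ in range(G)
    ]
    pop_freqs = {}
    pop_names, group_of = [], {}
    for gi in range(G):
        for pi in range(PPG):
            name = f"G{gi + 1}P{pi + 1}"
            pop_names.append(name)
            group_of[name] = f"group{gi + 1}"
            pop_freqs[name] = [
                _bn_dirichlet(rng, group_freqs[gi][l], config.fst_within_groups)
                for l in range(L)
            ]

    contact_pop, alpha, donors = (None, None, None)
    if config.contact_zone is not None:
        contact_pop, alpha, donors = config.contact_zone
        donor_idx = []
        for d in donors:
            names = [f"group{i + 1}" for i in range(G)]
            if d not in names:
                raise ValueError(f"donor group {d!r} does not exist")
            donor_idx.append(names.index(d))

    if isinstance(config.null_allele_freq, dict):
        null_freq = np.array(
            [config.null_allele_freq.get(l, 0.0) for l in range(L)]
        )
    else:
        null_freq = np.full(L, float(config.null_allele_freq))

    individuals, population = [], []
    calls = np.zeros((len(pop_names) * N, L, 2), dtype=int)
    row = 0
    for pop in pop_names:
        for i in range(N):
            individuals.append(f"{pop}_ind{i + 1}")
            population.append(pop)
            for l in range(L):
                if pop == contact_pop:
                    pair = []
                    for _ in range(2):
                        gi = donor_idx[0] if rng.random() < alpha else donor_idx[1]
                        pair.append(rng.choice(n_alleles[l], p=group_freqs[gi][l]) + 1)
                    calls[row, l] = pair
                else:
                    p = pop_freqs[pop][l]
                    calls[row, l] = rng.choice(n_alleles[l], size=2, p=p) + 1
            row += 1

    # null alleles: each gene copy independently becomes null with prob kappa
    for l in range(L):
        k = null_freq[l]
        if k <= 0:
            continue
        nulls = rng.random((calls.shape[0], 2)) < k
        for i in range(calls.shape[0]):
            a_null, b_null = nulls[i]
            if a_null and b_null:
                calls[i, l] = (MISSING, MISSING)
            elif a_null:
                calls[i, l, 0] = calls[i, l, 1]  # apparent homozygote
            elif b_null:
                calls[i, l, 1] = calls[i, l, 0]

    if config.missing_rate > 0:
        drop = rng.random((calls.shape[0], L)) < config.missing_rate
        calls[drop] = (MISSING, MISSING)

    return GenotypeMatrix(
        individuals=individuals,
        loci=[f"locus{l + 1}" for l in range(L)],
        calls=calls,
        population=population,
        group=group_of,
    )


def simulate_environment(
    config: EnvSimConfig, sites: pd.DataFrame | None = None
) -> PredictorTable:
    """Latitude-driven environmental covariates per site.

    min SST is exactly linear in latitude plus Gaussian noise (poleward
    cooling); mean/max SST track it with offsets; chl a and KD490 are
    independent positive noise.  ``sites`` needs columns site/lon/lat; by
    default sites are placed evenly across ``lat_range``.
    """
    rng = np.random.default_rng(config.seed)
    if sites is None:
        lats = np.linspace(*config.lat_range, config.n_sites)
        sites = pd.DataFrame(
            {
                "site": [f"S{i + 1}" for i in range(config.n_sites)],
                "lon": np.full(config.n_sites, 35.0),
                "lat": lats,
            }
        )
    lat = sites["lat"].to_numpy(dtype=float)
    n = len(sites)
    sst_min = (
        config.sst_intercept
        - config.sst_gradient * np.abs(lat)
        + rng.normal(0, config.noise_sd, n)
    )
    sst_mean = sst_min + 2.0 + rng.normal(0, config.noise_sd, n)
    sst_max = sst_mean + 2.5 + rng.normal(0, config.noise_sd, n)
    chl = np.exp(rng.normal(-1.0, 0.4, n))
    kd490 = 0.05 + np.exp(rng.normal(-3.3, 0.3, n))
    df = pd.DataFrame(
        {
            "sst_min": sst_min,
            "sst_mean": sst_mean,
            "sst_max": sst_max,
            "chl_a": chl,
            "kd490": kd490,
        },
        index=pd.Index(sites["site"], name="site"),
    )
    return PredictorTable(data=df)


@dataclass
class FixtureBundle:
    genotypes: GenotypeMatrix
    predictors: PredictorTable
    field: VectorGridField
    releases: list[ReleaseSpec]
    coast: CoastMask
    sites: pd.DataFrame = field(default=None)


def make_fixture_suite(seed: int = 0, n_days: float = 30.0) -> FixtureBundle:
    """A coherent 15-site synthetic world for end-to-end runs.

    Coastline along the western grid edge, a southwestward boundary current
    with stationary eddies offshore, release sites strung along the coast, and
    genotypes with a 3-group hierarchy plus one admixed contact-zone
    population; environmental covariates follow the latitude gradient.
    """
    # --- spatial world: 30-50E, 35S-10N at 0.25°, land strip on the west edge
    dt_field = 6 * 3600.0
    t_nodes = np.arange(0.0, n_days * 86400.0 + dt_field, dt_field)
    grid = GridSpec(
        lon_nodes=np.arange(30.0, 50.0 + 0.25, 0.25),
        lat_nodes=np.arange(-35.0, 10.0 + 0.25, 0.25),
        time_nodes=t_nodes,
    )
    land2d = np.zeros((grid.lat_nodes.size, grid.lon_nodes.size), dtype=bool)
    land2d[:, :2] = True  # coastline: two land columns on the western edge
    rng = np.random.default_rng(seed)
    eddies = [
        (38.0, -25.0, 1.5, 0.6),
        (42.0, -15.0, 2.0, -0.5),
        (45.0, 0.0, 2.0, 0.4),
    ]
    fld = make_synthetic_field(
        "boundary_current_with_eddies",
        {
            "jet_speed": 0.6,
            "jet_width": 2.0,
            "coast_lon": grid.lon_nodes[1],
            "onshore_frac": 0.05,
            "eddies": eddies,
        },
        grid,
        mask=land2d,
    )

    # --- 15 sites along the coast at varying offshore distance (0.5–2.5°,
    # cycling within each regional group of 5: variable shelf width drives a
    # site-to-site settlement gradient)
    site_lats = np.linspace(-33.0, 8.0, 15)
    coast_lon = float(grid.lon_nodes[1])
    offsets = 0.5 + 2.0 * (np.arange(15) % 5) / 4.0
    site_lons = coast_lon + offsets
    sites = pd.DataFrame(
        {
            "site": [f"S{i + 1}" for i in range(15)],
            "lon": site_lons,
            "lat": site_lats,
        }
    )
    releases = [
        ReleaseSpec(
            site_id=r.site, lon=r.lon, lat=r.lat, n_particles=100,
            release_time=0.0, duration_days=n_days, jitter_radius=0.1,
        )
        for r in sites.itertuples()
    ]
    coast = CoastMask.from_field(fld)
    coast.assign_sites(
        {r.site: (r.lon, r.lat) for r in sites.itertuples()}, radius=1.5
    )

    # --- genotypes: 3 groups x 5 pops, S6 is the admixed contact population
    gcfg = GenotypeSimConfig(
        n_groups=3,
        pops_per_group=5,
        individuals_per_pop=18,
        n_loci=21,
        fst_between_groups=0.05,
        fst_within_groups=0.01,
        contact_zone=("G2P1", 0.5, ("group1", "group2")),
        null_allele_freq=0.05,
        missing_rate=0.02,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    genotypes = simulate_genotypes(gcfg)
    # rename simulated populations onto the site labels (G1P1..G3P5 -> S1..S15)
    sim_pops = genotypes.populations
    pop_map = {sp: f"S{i + 1}" for i, sp in enumerate(sim_pops)}
    genotypes = GenotypeMatrix(
        individuals=genotypes.individuals,
        loci=genotypes.loci,
        calls=genotypes.calls,
        population=[pop_map[p] for p in genotypes.population],
        group={pop_map[p]: g for p, g in genotypes.group.items()},
        site_coords={
            pop_map[sp]: (float(site_lons[i]), float(site_lats[i]))
            for i, sp in enumerate(sim_pops)
        },
    )

    env = simulate_environment(
        EnvSimConfig(
            n_sites=15,
            lat_range=(float(site_lats[0]), float(site_lats[-1])),
            seed=int(rng.integers(0, 2**31 - 1)),
        ),
        sites,
    )
    return FixtureBundle(
        genotypes=genotypes, predictors=env, field=fld,
        releases=releases, coast=coast, sites=sites,
    )
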