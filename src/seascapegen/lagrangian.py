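"""Passive Lagrangian particle tracking over gridded surface currents.

Virtual larvae are advected in 2-D (the mixed upper layer) through a
``VectorGridField`` with X(t+dt) = X(t) + ∫ v(x, t) dt, approximated by Euler
or classical RK4 steps.  Settlement is first entry into a coastal cell (an
ocean cell adjacent to land) after a configurable minimum drift age;
trajectories are summarized as per-release arrival fractions and 1°x1°
sample-density grids.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .ocean_fields import DEG, GridSpec, PhysicalConstants, ScalarGridField, VectorGridField

__all__ = [
    "Status",
    "ReleaseSpec",
    "ParticleState",
    "TrajectoryEnsemble",
    "CoastMask",
    "sample_velocity",
    "advect_step",
    "run_dispersal",
    "coastal_arrival_fraction",
    "density_grid",
]

_R_EARTH = PhysicalConstants().earth_radius


class Status(str, Enum):
    DRIFTING = "drifting"
    SETTLED = "settled"
    OUT_OF_DOMAIN = "out_of_domain"


@dataclass(frozen=True)
class ReleaseSpec:
    site_id: str
    lon: float
    lat: float
    n_particles: int = 1000
    release_time: float = 0.0  # seconds on the field's time axis
    duration_days: float = 120.0
    jitter_radius: float = 0.1  # degrees, uniform disc

    def __post_init__(self):
        if self.n_particles < 1:
            raise ValueError("n_particles must be >= 1")
        if self.duration_days <= 0:
            raise ValueError("duration must be positive")


@dataclass
class ParticleState:
    particle_id: int
    lon: float
    lat: float
    time: float
    status: Status = Status.DRIFTING
    settle_time: float | None = None


@dataclass
class TrajectoryEnsemble:
    release: ReleaseSpec
    times: np.ndarray  # (n_steps+1,)
    lons: np.ndarray  # (n_particles, n_steps+1); nan after stop
    lats: np.ndarray
    final_states: list[ParticleState]
    integrator_config: dict = field(default_factory=dict)

    @property
    def n_particles(self) -> int:
        return self.lons.shape[0]

    def settled_fraction(self) -> float:
        return float(
            np.mean([s.status == Status.SETTLED for s in self.final_states])
        )


@dataclass
class CoastMask:
    """Spatial land/coast classification on a lon/lat grid.

    ``coastal`` cells are ocean cells with at least one land cell among their
    4-neighbours.  ``site_assignment`` optionally labels each coastal cell with
    the nearest release site within ``assign_radius`` degrees.
    """

    lon_nodes: np.ndarray
    lat_nodes: np.ndarray
    land: np.ndarray  # (lat, lon) bool
    site_assignment: dict | None = None  # (ilat, ilon) -> site_id

    def __post_init__(self):
        self.lon_nodes = np.asarray(self.lon_nodes, dtype=float)
        self.lat_nodes = np.asarray(self.lat_nodes, dtype=float)
        self.land = np.asarray(self.land, dtype=bool)
        if self.land.shape != (self.lat_nodes.size, self.lon_nodes.size):
            raise ValueError("land mask shape must be (lat, lon)")
        coastal = np.zeros_like(self.land)
        land = self.land
        coastal[:-1, :] |= land[1:, :]
        coastal[1:, :] |= land[:-1, :]
        coastal[:, :-1] |= land[:, 1:]
        coastal[:, 1:] |= land[:, :-1]
        self.coastal = coastal & ~land

    @classmethod
    def from_field(cls, fld: VectorGridField, site_coords: dict | None = None,
                   assign_radius: float = 1.0) -> "CoastMask":
        land = fld.mask[0] if fld.mask.ndim == 3 else fld.mask
        cm = cls(fld.grid.lon_nodes, fld.grid.lat_nodes, land)
        if site_coords:
            cm.assign_sites(site_coords, assign_radius)
        return cm

    def assign_sites(self, site_coords: dict, radius: float = 1.0):
        """Label coastal cells with the nearest site (great-circle) within radius°."""
        assignment = {}
        ii, jj = np.nonzero(self.coastal)
        for i, j in zip(ii, jj):
            clat, clon = self.lat_nodes[i], self.lon_nodes[j]
            best, best_d = None, np.inf
            for site, (slon, slat) in site_coords.items():
                d = np.hypot((slon - clon) * np.cos(clat * DEG), slat - clat)
                if d < best_d:
                    best, best_d = site, d
            if best is not None and best_d <= radius:
                assignment[(int(i), int(j))] = best
        self.site_assignment = assignment

    def cell_index(self, lon, lat):
        i = np.clip(
            np.rint((np.asarray(lat) - self.lat_nodes[0])
                    / (self.lat_nodes[1] - self.lat_nodes[0])).astype(int),
            0, self.lat_nodes.size - 1,
        )
        j = np.clip(
            np.rint((np.asarray(lon) - self.lon_nodes[0])
                    / (self.lon_nodes[1] - self.lon_nodes[0])).astype(int),
            0, self.lon_nodes.size - 1,
        )
        return i, j

    def is_land(self, lon, lat):
        i, j = self.cell_index(lon, lat)
        return self.land[i, j]

    def is_coastal(self, lon, lat):
        i, j = self.cell_index(lon, lat)
        return self.coastal[i, j]


# ---------------------------------------------------------------------------
# velocity sampling


def _interp_weights(nodes: np.ndarray, x: np.ndarray):
    """Index of the left bracketing node (clamped) and fractional offset."""
    dx = nodes[1] - nodes[0] if nodes.size > 1 else 1.0
    f = (np.asarray(x, dtype=float) - nodes[0]) / dx
    i = np.clip(np.floor(f).astype(int), 0, max(nodes.size - 2, 0))
    return i, f - i


def sample_velocity(field: VectorGridField, lon, lat, time):
    """Bilinear-in-space, linear-in-time velocity at arbitrary points.

    Land-masked grid nodes contribute zero velocity with their weight retained
    (free-slip decay toward the coast).  Returns (u, v, inside) where ``inside``
    flags points within the field's space-time bounding box; outside points get
    zero velocity.
    """
    g = field.grid
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    time = np.broadcast_to(np.asarray(time, dtype=float), lon.shape)

    inside = (
        (lon >= g.lon_nodes[0]) & (lon <= g.lon_nodes[-1])
        & (lat >= g.lat_nodes[0]) & (lat <= g.lat_nodes[-1])
        & (time >= g.time_nodes[0]) & (time <= g.time_nodes[-1])
    )

    jx, fx = _interp_weights(g.lon_nodes, lon)
    iy, fy = _interp_weights(g.lat_nodes, lat)
    if g.time_nodes.size > 1:
        tstep = np.diff(g.time_nodes)
        ft = (time - g.time_nodes[0]) / tstep[0]
        if not np.allclose(tstep, tstep[0]):
            ft = np.interp(time, g.time_nodes, np.arange(g.time_nodes.size))
        it = np.clip(np.floor(ft).astype(int), 0, g.time_nodes.size - 2)
        ft = np.clip(ft - it, 0.0, 1.0)
    else:
        it = np.zeros(lon.shape, dtype=int)
        ft = np.zeros(lon.shape)

    fx = np.clip(fx, 0.0, 1.0)
    fy = np.clip(fy, 0.0, 1.0)

    def bilin(arr):
        out = 0.0
        for dt_, wt in ((0, 1 - ft), (1, ft)):
            tt = np.minimum(it + dt_, field.grid.time_nodes.size - 1)
            for dy, wy in ((0, 1 - fy), (1, fy)):
                for dx_, wx in ((0, 1 - fx), (1, fx)):
                    out = out + wt * wy * wx * arr[tt, iy + dy, jx + dx_]
        return out

    # masked cells already hold zero velocity in u/v
    u = np.where(inside, bilin(field.u), 0.0)
    v = np.where(inside, bilin(field.v), 0.0)
    return u, v, inside


def _rhs(field: VectorGridField, lon, lat, time):
    """d(lon,lat)/dt in degrees/s from the m/s velocity at (lon, lat, time)."""
    u, v, inside = sample_velocity(field, lon, lat, time)
    coslat = np.cos(np.clip(lat, -89.9, 89.9) * DEG)
    dlon = u / (_R_EARTH * coslat) / DEG
    dlat = v / _R_EARTH / DEG
    return dlon, dlat, inside


def _step_positions(field, lons, lats, t, dt, scheme):
    """One integrator step for an array of positions; returns new pos + inside flag."""
    if scheme == "euler":
        k1x, k1y, inside = _rhs(field, lons, lats, t)
        return lons + dt * k1x, lats + dt * k1y, inside
    if scheme == "rk4":
        k1x, k1y, in1 = _rhs(field, lons, lats, t)
        k2x, k2y, in2 = _rhs(field, lons + 0.5 * dt * k1x, lats + 0.5 * dt * k1y, t + 0.5 * dt)
        k3x, k3y, in3 = _rhs(field, lons + 0.5 * dt * k2x, lats + 0.5 * dt * k2y, t + 0.5 * dt)
        k4x, k4y, in4 = _rhs(field, lons + dt * k3x, lats + dt * k3y, t + dt)
        new_lon = lons + dt / 6.0 * (k1x + 2 * k2x + 2 * k3x + k4x)
        new_lat = lats + dt / 6.0 * (k1y + 2 * k2y + 2 * k3y + k4y)
        return new_lon, new_lat, in1
    raise ValueError(f"unknown scheme {scheme!r}")


def advect_step(
    state: ParticleState, field: VectorGridField, dt: float, scheme: str = "rk4"
) -> ParticleState:
    """Advance a single drifting particle by one step of length dt seconds."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    if state.status != Status.DRIFTING:
        raise ValueError(f"particle {state.particle_id} is not drifting")
    lon, lat, inside = _step_positions(
        field, np.array([state.lon]), np.array([state.lat]), state.time, dt, scheme
    )
    g = field.grid
    new_lon, new_lat = float(lon[0]), float(lat[0])
    status = Status.DRIFTING
    if not (
        g.lon_nodes[0] <= new_lon <= g.lon_nodes[-1]
        and g.lat_nodes[0] <= new_lat <= g.lat_nodes[-1]
    ):
        status = Status.OUT_OF_DOMAIN
    return ParticleState(
        particle_id=state.particle_id,
        lon=new_lon,
        lat=new_lat,
        time=state.time + dt,
        status=status,
    )


def run_dispersal(
    releases: list[ReleaseSpec],
    field: VectorGridField,
    coast: CoastMask,
    dt: float = 3 * 3600.0,
    scheme: str = "rk4",
    seed: int = 0,
    min_age_days: float = 0.0,
    record_every: int = 1,
) -> list[TrajectoryEnsemble]:
    """Run the dispersal experiment for a list of releases.

    Particles start uniformly scattered in a disc of ``jitter_radius`` degrees,
    step with the chosen scheme, and stop at settlement (first coastal cell at
    drift age >= ``min_age_days``), on leaving the domain, or at the end of the
    release duration.  A step that would beach on a land cell settles the
    particle at its previous (coastal) position.  Fully seeded and vectorized.
    """
    g = field.grid
    if not (
        np.array_equal(g.lon_nodes, coast.lon_nodes)
        and np.array_equal(g.lat_nodes, coast.lat_nodes)
    ):
        raise ValueError("field and coast mask grids differ")
    rng = np.random.default_rng(seed)
    out = []
    for rel in releases:
        if coast.is_land(rel.lon, rel.lat):
            raise ValueError(f"release site {rel.site_id} lies on a land cell")
        t_end = rel.release_time + rel.duration_days * 86400.0
        if rel.release_time < g.time_nodes[0] or t_end > g.time_nodes[-1]:
            raise ValueError(
                f"release window for {rel.site_id} not covered by the field's time axis"
            )
        n = rel.n_particles
        # uniform scatter on a disc, rejected onto ocean cells
        r = rel.jitter_radius * np.sqrt(rng.random(n))
        ang = rng.random(n) * 2 * np.pi
        lons = rel.lon + r * np.cos(ang)
        lats = rel.lat + r * np.sin(ang)
        onland = coast.is_land(lons, lats)
        for _ in range(100):
            if not onland.any():
                break
            k = int(onland.sum())
            r2 = rel.jitter_radius * np.sqrt(rng.random(k))
            a2 = rng.random(k) * 2 * np.pi
            lons[onland] = rel.lon + r2 * np.cos(a2)
            lats[onland] = rel.lat + r2 * np.sin(a2)
            onland = coast.is_land(lons, lats)

        n_steps = int(round(rel.duration_days * 86400.0 / dt))
        times = rel.release_time + dt * np.arange(n_steps + 1)
        rec_idx = list(range(0, n_steps + 1, record_every))
        if rec_idx[-1] != n_steps:
            rec_idx.append(n_steps)
        rec_lon = np.full((n, len(rec_idx)), np.nan)
        rec_lat = np.full((n, len(rec_idx)), np.nan)
        rec_map = {s: k for k, s in enumerate(rec_idx)}

        status = np.zeros(n, dtype=int)  # 0 drifting, 1 settled, 2 out
        settle_time = np.full(n, np.nan)
        min_age_s = min_age_days * 86400.0

        # settlement check at t=0 (age 0) only if min_age is 0
        if min_age_s <= 0:
            sett0 = coast.is_coastal(lons, lats) & (status == 0)
            status[sett0] = 1
            settle_time[sett0] = times[0]
        rec_lon[:, 0], rec_lat[:, 0] = lons, lats

        for s in range(1, n_steps + 1):
            active = status == 0
            new_lon = lons.copy()
            new_lat = lats.copy()
            if active.any():
                nl, nt, _ = _step_positions(
                    field, lons[active], lats[active], times[s - 1], dt, scheme
                )
                new_lon[active], new_lat[active] = nl, nt
            # domain exit
            oob = active & ~(
                (new_lon >= g.lon_nodes[0]) & (new_lon <= g.lon_nodes[-1])
                & (new_lat >= g.lat_nodes[0]) & (new_lat <= g.lat_nodes[-1])
            )
            status[oob] = 2
            inb = active & ~oob
            age = times[s] - rel.release_time
            # beaching: a step that would land on a land cell settles the
            # particle at its previous (coastal) position; pre-competent
            # particles (age < min_age) hold position and keep drifting
            beach = inb.copy()
            beach[inb] = coast.is_land(new_lon[inb], new_lat[inb])
            if age >= min_age_s:
                status[beach] = 1
                settle_time[beach] = times[s]
            move = inb & ~beach
            lons[move] = new_lon[move]
            lats[move] = new_lat[move]
            lons[oob] = new_lon[oob]
            lats[oob] = new_lat[oob]
            # settlement on coastal cells after minimum drift age
            if age >= min_age_s:
                sett = move.copy()
                sett[move] = coast.is_coastal(lons[move], lats[move])
                status[sett] = 1
                settle_time[sett] = times[s]
            if s in rec_map:
                k = rec_map[s]
                rec = status != 2  # out-of-domain particles are not recorded
                rec_lon[rec, k] = lons[rec]
                rec_lat[rec, k] = lats[rec]

        finals = [
            ParticleState(
                particle_id=i,
                lon=float(lons[i]),
                lat=float(lats[i]),
                time=float(times[-1]),
                status=(Status.DRIFTING, Status.SETTLED, Status.OUT_OF_DOMAIN)[status[i]],
                settle_time=None if np.isnan(settle_time[i]) else float(settle_time[i]),
            )
            for i in range(n)
        ]
        out.append(
            TrajectoryEnsemble(
                release=rel,
                times=times[rec_idx],
                lons=rec_lon,
                lats=rec_lat,
                final_states=finals,
                integrator_config={"scheme": scheme, "dt": dt,
                                   "min_age_days": min_age_days, "seed": seed},
            )
        )
    return out


def coastal_arrival_fraction(
    ensembles: list[TrajectoryEnsemble], coast: CoastMask | None = None
) -> pd.DataFrame:
    """Fraction of released particles that settled, per (site, release time).

    When the coast mask carries a site assignment, adds one row per destination
    site with the fraction of particles settling in that site's cells.
    """
    rows = []
    for ens in ensembles:
        if ens.n_particles == 0:
            raise ValueError("empty ensemble")
        settled = [s for s in ens.final_states if s.status == Status.SETTLED]
        frac = len(settled) / ens.n_particles
        row = {
            "site_id": ens.release.site_id,
            "release_time": ens.release.release_time,
            "n_released": ens.n_particles,
            "n_settled": len(settled),
            "fraction_settled": frac,
        }
        if coast is not None and coast.site_assignment:
            dest_counts: dict = {}
            for s in settled:
                i, j = coast.cell_index(s.lon, s.lat)
                dest = coast.site_assignment.get((int(i), int(j)))
                if dest is not None:
                    dest_counts[dest] = dest_counts.get(dest, 0) + 1
            for dest, cnt in sorted(dest_counts.items()):
                row[f"to_{dest}"] = cnt / ens.n_particles
        rows.append(row)
    return pd.DataFrame(rows)


def density_grid(
    ensembles: list[TrajectoryEnsemble], resolution: float = 1.0,
    bounds: tuple[float, float, float, float] | None = None,
) -> ScalarGridField:
    """Count recorded (particle, time) samples on a regular grid (Figure-5-style).

    ``bounds`` is (lon_min, lon_max, lat_min, lat_max); by default the snapped
    bounding box of all recorded samples.  The sum over cells equals the total
    number of recorded in-domain samples.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    if not ensembles:
        raise ValueError("no ensembles given")
    all_lon = np.concatenate([e.lons.ravel() for e in ensembles])
    all_lat = np.concatenate([e.lats.ravel() for e in ensembles])
    ok = np.isfinite(all_lon) & np.isfinite(all_lat)
    all_lon, all_lat = all_lon[ok], all_lat[ok]
    if bounds is None:
        lon0 = np.floor(all_lon.min() / resolution) * resolution
        lon1 = np.ceil(all_lon.max() / resolution) * resolution
        lat0 = np.floor(all_lat.min() / resolution) * resolution
        lat1 = np.ceil(all_lat.max() / resolution) * resolution
    else:
        lon0, lon1, lat0, lat1 = bounds
    lon_edges = np.arange(lon0, lon1 + resolution * 0.5, resolution)
    lat_edges = np.arange(lat0, lat1 + resolution * 0.5, resolution)
    # a grid axis needs >= 2 cells; pad with empty cells if necessary
    while lon_edges.size < 3:
        lon_edges = np.append(lon_edges, lon_edges[-1] + resolution)
    while lat_edges.size < 3:
        lat_edges = np.append(lat_edges, lat_edges[-1] + resolution)
    counts, _, _ = np.histogram2d(all_lat, all_lon, bins=[lat_edges, lon_edges])
    grid = GridSpec(
        lon_nodes=0.5 * (lon_edges[:-1] + lon_edges[1:]),
        lat_nodes=0.5 * (lat_edges[:-1] + lat_edges[1:]),
        time_nodes=np.array([0.0]),
    )
    return ScalarGridField(grid=grid, values=counts[None, :, :], units="count")
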