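"""Gridded surface-velocity fields: synthesis, geostrophy, Ekman response, NetCDF I/O.

Velocity fields live on regular lon/lat/time grids (degrees east in [-180, 180),
degrees north, seconds since an epoch).  Geostrophic currents are derived from
sea-surface height via the f-plane balance and Ekman currents from wind stress
via a complex transfer coefficient, mirroring how merged altimeter/wind current
products (GlobCurrent-style) are constructed.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import xarray as xr

__all__ = [
    "GridSpec",
    "ScalarGridField",
    "VectorGridField",
    "PhysicalConstants",
    "EkmanParams",
    "geostrophic_from_ssh",
    "ekman_from_wind_stress",
    "combine_currents",
    "make_synthetic_field",
    "load_velocity_netcdf",
    "save_velocity_netcdf",
]

DEG = np.pi / 180.0


def _check_axis(name: str, vals: np.ndarray, uniform: bool = True) -> np.ndarray:
    vals = np.asarray(vals, dtype=float)
    if vals.ndim != 1 or vals.size < 1:
        raise ValueError(f"{name} axis must be a 1-D vector")
    d = np.diff(vals)
    if vals.size > 1 and not np.all(d > 0):
        raise ValueError(f"{name} axis must be strictly ascending")
    if uniform and vals.size > 2 and not np.allclose(d, d[0], atol=1e-9, rtol=0):
        raise ValueError(f"{name} axis must be uniformly spaced")
    return vals


@dataclass(frozen=True)
class GridSpec:
    """Regular lon/lat/time grid.

    lon_nodes : degrees east, ascending, uniform
    lat_nodes : degrees north, ascending, uniform
    time_nodes : seconds since an arbitrary epoch, ascending
    """

    lon_nodes: np.ndarray
    lat_nodes: np.ndarray
    time_nodes: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "lon_nodes", _check_axis("lon", self.lon_nodes))
        object.__setattr__(self, "lat_nodes", _check_axis("lat", self.lat_nodes))
        object.__setattr__(
            self, "time_nodes", _check_axis("time", self.time_nodes, uniform=False)
        )
        if self.lon_nodes.size < 2 or self.lat_nodes.size < 2:
            raise ValueError("spatial axes need at least 2 nodes")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.time_nodes.size, self.lat_nodes.size, self.lon_nodes.size)

    @property
    def dlon(self) -> float:
        return float(self.lon_nodes[1] - self.lon_nodes[0])

    @property
    def dlat(self) -> float:
        return float(self.lat_nodes[1] - self.lat_nodes[0])

    def same_grid(self, other: "GridSpec") -> bool:
        return (
            np.array_equal(self.lon_nodes, other.lon_nodes)
            and np.array_equal(self.lat_nodes, other.lat_nodes)
            and np.array_equal(self.time_nodes, other.time_nodes)
        )


@dataclass(frozen=True)
class PhysicalConstants:
    g: float = 9.81  # m s^-2
    omega: float = 7.292115e-5  # rad s^-1
    earth_radius: float = 6_371_000.0  # m

    def __post_init__(self):
        if not (self.g > 0 and self.omega > 0 and self.earth_radius > 0):
            raise ValueError("physical constants must be strictly positive")

    def coriolis(self, lat_deg: np.ndarray) -> np.ndarray:
        return 2.0 * self.omega * np.sin(np.asarray(lat_deg) * DEG)


@dataclass(frozen=True)
class EkmanParams:
    """Complex Ekman transfer per depth level: v_ek(z) = beta(z) * tau * exp(i theta(z)).

    The published current products fit beta and theta to drifter/Argo data; the
    source papers for this pipeline do not print the fitted numbers, so these
    defaults are placeholders and a warning is emitted when they are used.
    """

    beta: dict = field(default_factory=lambda: {0.0: 0.3, 15.0: 0.3})
    theta: dict = field(default_factory=lambda: {0.0: np.pi / 4, 15.0: np.pi / 4})
    _defaults_used: bool = True

    def __post_init__(self):
        for z, b in self.beta.items():
            if b < 0:
                raise ValueError("beta must be >= 0")
        for z, t in self.theta.items():
            if not (-np.pi < t <= np.pi):
                raise ValueError("theta must lie in (-pi, pi]")


@dataclass
class ScalarGridField:
    grid: GridSpec
    values: np.ndarray  # (time, lat, lon)
    units: str = ""
    mask: np.ndarray | None = None  # True where land / invalid

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if self.mask is None:
            self.mask = np.zeros(self.grid.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.grid.shape:
                raise ValueError("mask shape must match grid")


@dataclass
class VectorGridField:
    grid: GridSpec
    u: np.ndarray  # zonal component, (time, lat, lon)
    v: np.ndarray  # meridional component
    units: str = "m s-1"
    mask: np.ndarray | None = None

    def __post_init__(self):
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.u.shape != self.grid.shape or self.v.shape != self.grid.shape:
            raise ValueError("u/v shape must match grid shape")
        if self.mask is None:
            self.mask = np.zeros(self.grid.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.grid.shape:
                raise ValueError("mask shape must match grid")


def _masked_gradient(values: np.ndarray, mask: np.ndarray, spacing: np.ndarray | float,
                     axis: int) -> np.ndarray:
    """Centered differences in the interior, one-sided next to edges and masked cells.

    ``spacing`` is the physical step between adjacent nodes along ``axis`` (scalar
    or broadcastable array).  Cells with no valid neighbour along the axis get nan.
    """
    v = np.where(mask, np.nan, values)
    fwd = np.roll(v, -1, axis=axis)
    bwd = np.roll(v, 1, axis=axis)
    # roll wraps around; invalidate the wrapped entries
    idx_last = [slice(None)] * v.ndim
    idx_last[axis] = -1
    idx_first = [slice(None)] * v.ndim
    idx_first[axis] = 0
    fwd[tuple(idx_last)] = np.nan
    bwd[tuple(idx_first)] = np.nan

    ok_f = np.isfinite(fwd)
    ok_b = np.isfinite(bwd)
    grad = np.full_like(v, np.nan)
    # centered where both neighbours valid
    both = ok_f & ok_b
    grad[both] = ((fwd - bwd) / (2.0 * spacing * np.ones_like(v)))[both]
    # one-sided elsewhere
    only_f = ok_f & ~ok_b
    grad[only_f] = ((fwd - v) / (spacing * np.ones_like(v)))[only_f]
    only_b = ok_b & ~ok_f
    grad[only_b] = ((v - bwd) / (spacing * np.ones_like(v)))[only_b]
    return grad


def geostrophic_from_ssh(
    ssh: ScalarGridField,
    constants: PhysicalConstants = PhysicalConstants(),
    equator_mask_deg: float = 5.0,
) -> VectorGridField:
    """Geostrophic surface current from sea-surface height.

    u_geo = -(g/f) dη/dy,  v_geo = +(g/f) dη/dx  (f = 2 Ω sin lat).
    Finite differences are centered in the interior and one-sided at edges and
    next to land.  A band |lat| < ``equator_mask_deg`` is masked because f → 0.
    """
    if ssh.units not in ("m", "metre", "meter", "metres", "meters"):
        raise ValueError(f"SSH must be in metres, got units={ssh.units!r}")
    g = ssh.grid
    if g.lat_nodes.size < 2 or g.lon_nodes.size < 2:
        raise ValueError("need at least 2 nodes per spatial axis")
    lat = g.lat_nodes[None, :, None]
    R = constants.earth_radius
    dy = R * g.dlat * DEG
    dx = R * np.cos(lat * DEG) * g.dlon * DEG  # varies with latitude

    deta_dy = _masked_gradient(ssh.values, ssh.mask, dy, axis=1)
    deta_dx = _masked_gradient(ssh.values, ssh.mask, dx, axis=2)

    f = constants.coriolis(lat)
    with np.errstate(divide="ignore", invalid="ignore"):
        u = -(constants.g / f) * deta_dy
        v = +(constants.g / f) * deta_dx

    out_mask = ssh.mask | ~np.isfinite(u) | ~np.isfinite(v)
    out_mask |= np.broadcast_to(np.abs(lat) < equator_mask_deg, ssh.values.shape)
    u = np.where(out_mask, 0.0, u)
    v = np.where(out_mask, 0.0, v)
    return VectorGridField(grid=g, u=u, v=v, units="m s-1", mask=out_mask)


def ekman_from_wind_stress(
    tau: VectorGridField, params: EkmanParams, depth: float = 0.0
) -> VectorGridField:
    """Ekman current from wind stress: v_ek(z) = beta(z) · tau · e^{i theta(z)}.

    The wind-stress vector is treated as the complex number tau_u + i·tau_v;
    the response is scaled by beta(z) and rotated by theta(z).
    """
    if tau.units not in ("N m-2", "N/m^2", "N/m2", "N m^-2"):
        raise ValueError(f"wind stress must be in N/m^2, got units={tau.units!r}")
    if depth not in params.beta or depth not in params.theta:
        raise ValueError(
            f"depth {depth} m not configured (levels: {sorted(params.beta)})"
        )
    if params._defaults_used:
        warnings.warn(
            "EkmanParams placeholder defaults in use; supply fitted beta/theta "
            "for quantitative work",
            stacklevel=2,
        )
    w = tau.u + 1j * tau.v
    resp = params.beta[depth] * w * np.exp(1j * params.theta[depth])
    u = np.where(tau.mask, 0.0, resp.real)
    v = np.where(tau.mask, 0.0, resp.imag)
    return VectorGridField(grid=tau.grid, u=u, v=v, units="m s-1",
                           mask=tau.mask.copy())


def combine_currents(
    geostrophic: VectorGridField, ekman: VectorGridField
) -> VectorGridField:
    """Component-wise sum of two current fields; output mask is the union."""
    if not geostrophic.grid.same_grid(ekman.grid):
        raise ValueError("cannot combine fields on different grids")
    mask = geostrophic.mask | ekman.mask
    u = np.where(mask, 0.0, geostrophic.u + ekman.u)
    v = np.where(mask, 0.0, geostrophic.v + ekman.v)
    return VectorGridField(grid=geostrophic.grid, u=u, v=v, units="m s-1", mask=mask)


# ---------------------------------------------------------------------------
# synthetic analytic fields


def _grid_mesh(grid: GridSpec):
    lon = grid.lon_nodes[None, None, :]
    lat = grid.lat_nodes[None, :, None]
    return lon, lat


def _solid_body_rotation(grid: GridSpec, params: dict) -> tuple[np.ndarray, np.ndarray]:
    """Rotation in lon/lat coordinate space about (lon0, lat0), angular speed
    omega rad/s.  Velocities are reported in m/s such that, after the standard
    degree<->metre conversion at the particle's latitude, trajectories are exact
    circles of period 2*pi/omega in degree space — the analytic advection oracle.
    """
    omega = params["omega"]
    lon0, lat0 = params["lon0"], params["lat0"]
    R = params.get("earth_radius", PhysicalConstants().earth_radius)
    lon, lat = _grid_mesh(grid)
    # dlon/dt = -omega*(lat-lat0), dlat/dt = +omega*(lon-lon0)   [deg/s]
    u = -omega * (lat - lat0) * DEG * R * np.cos(lat * DEG)
    v = omega * (lon - lon0) * DEG * R
    shape = grid.shape
    return np.broadcast_to(u, shape).copy(), np.broadcast_to(v, shape).copy()


def _uniform_flow(grid: GridSpec, params: dict) -> tuple[np.ndarray, np.ndarray]:
    shape = grid.shape
    return (
        np.full(shape, float(params.get("u0", 0.0))),
        np.full(shape, float(params.get("v0", 0.0))),
    )


def _double_gyre(grid: GridSpec, params: dict) -> tuple[np.ndarray, np.ndarray]:
    """Two counter-rotating gyres from a streamfunction, differentiated with the
    same centered stencil the divergence diagnostic uses, so the discrete
    divergence vanishes identically at interior nodes."""
    A = params.get("amplitude", 1e4)  # m^2/s
    R = params.get("earth_radius", PhysicalConstants().earth_radius)
    lon, lat = _grid_mesh(grid)
    lat0 = 0.5 * (grid.lat_nodes[0] + grid.lat_nodes[-1])
    x = R * np.cos(lat0 * DEG) * (lon - grid.lon_nodes[0]) * DEG
    y = R * (lat - grid.lat_nodes[0]) * DEG
    Lx = R * np.cos(lat0 * DEG) * (grid.lon_nodes[-1] - grid.lon_nodes[0]) * DEG
    Ly = R * (grid.lat_nodes[-1] - grid.lat_nodes[0]) * DEG
    psi = A * np.sin(2 * np.pi * x / Lx) * np.sin(np.pi * y / Ly)
    psi = np.broadcast_to(psi, grid.shape).copy()
    dx = R * np.cos(lat0 * DEG) * grid.dlon * DEG
    dy = R * grid.dlat * DEG
    nomask = np.zeros(grid.shape, dtype=bool)
    u = -_masked_gradient(psi, nomask, dy, axis=1)
    v = _masked_gradient(psi, nomask, dx, axis=2)
    return u, v


def _boundary_current_with_eddies(grid: GridSpec, params: dict):
    """Southwestward shelf jet along the western edge plus stationary Gaussian
    eddies — a qualitative stand-in for a western-boundary-current system."""
    jet_speed = params.get("jet_speed", 1.0)  # m/s
    jet_width = params.get("jet_width", 1.5)  # degrees offshore e-folding
    coast_lon = params.get("coast_lon", grid.lon_nodes[0])
    onshore_frac = params.get("onshore_frac", 0.1)  # cross-shore / alongshore ratio
    eddies = params.get("eddies", [])  # list of (lon, lat, radius_deg, strength m/s)
    lon, lat = _grid_mesh(grid)
    offshore = lon - coast_lon
    jet = jet_speed * np.exp(-((offshore / jet_width) ** 2))
    u = -onshore_frac * jet * np.ones_like(lat)
    v = -jet * np.ones_like(lat)
    for (elon, elat, rad, strength) in eddies:
        dxe = (lon - elon) * np.cos(lat * DEG)
        dye = lat - elat
        r2 = (dxe**2 + dye**2) / rad**2
        swirl = strength * np.exp(-r2)
        u = u + (-dye / rad) * swirl
        v = v + (dxe / rad) * swirl
    shape = grid.shape
    return np.broadcast_to(u, shape).copy(), np.broadcast_to(v, shape).copy()


_PRESETS = {
    "solid_body_rotation": _solid_body_rotation,
    "uniform_flow": _uniform_flow,
    "double_gyre": _double_gyre,
    "boundary_current_with_eddies": _boundary_current_with_eddies,
}


def make_synthetic_field(
    preset: str, params: dict, grid: GridSpec, mask: np.ndarray | None = None
) -> VectorGridField:
    """Sample a named analytic velocity field on a grid (deterministic)."""
    try:
        fn = _PRESETS[preset]
    except KeyError:
        raise ValueError(
            f"unknown preset {preset!r}; choose from {sorted(_PRESETS)}"
        ) from None
    u, v = fn(grid, params)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape == grid.shape[1:]:
            mask = np.broadcast_to(mask, grid.shape).copy()
        u = np.where(mask, 0.0, u)
        v = np.where(mask, 0.0, v)
    return VectorGridField(grid=grid, u=u, v=v, units="m s-1", mask=mask)


# ---------------------------------------------------------------------------
# NetCDF I/O (CF-style)


def _to_dataset(field_: VectorGridField, u_name="uo", v_name="vo") -> xr.Dataset:
    g = field_.grid
    coords = {
        "time": ("time", g.time_nodes, {"units": "seconds since epoch"}),
        "lat": ("lat", g.lat_nodes, {"units": "degrees_north"}),
        "lon": ("lon", g.lon_nodes, {"units": "degrees_east"}),
    }
    u = np.where(field_.mask, np.nan, field_.u)
    v = np.where(field_.mask, np.nan, field_.v)
    return xr.Dataset(
        {
            u_name: (("time", "lat", "lon"), u, {"units": field_.units}),
            v_name: (("time", "lat", "lon"), v, {"units": field_.units}),
        },
        coords=coords,
    )


def save_velocity_netcdf(field_: VectorGridField, path, u_name="uo", v_name="vo"):
    _to_dataset(field_, u_name, v_name).to_netcdf(path)


def load_velocity_netcdf(
    path,
    var_names: tuple[str, str] = ("uo", "vo"),
    time_window: tuple[float, float] | None = None,
) -> VectorGridField:
    """Load a u/v pair from a CF-style NetCDF file.

    Axes are coerced to ascending order; the land mask is taken from fill
    values (NaNs after decoding).  ``time_window`` selects a closed interval on
    the time axis (in the file's numeric time units).
    """
    u_name, v_name = var_names
    with xr.open_dataset(path, decode_times=False) as ds:
        for name in (u_name, v_name):
            if name not in ds:
                raise KeyError(f"variable {name!r} not found in {path}")
        da_u, da_v = ds[u_name], ds[v_name]
        if da_u.dims != da_v.dims:
            raise ValueError("u and v variables must share dimensions")
        tdim, ydim, xdim = da_u.dims
        t = ds[tdim].values.astype(float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("non-monotonic time axis")
        for dim in (ydim, xdim):
            if float(ds[dim][1]) < float(ds[dim][0]):
                ds = ds.isel({dim: slice(None, None, -1)})
        if time_window is not None:
            t0, t1 = time_window
            sel = (ds[tdim].values >= t0) & (ds[tdim].values <= t1)
            if not sel.any():
                raise ValueError(f"time_window {time_window} outside file range")
            ds = ds.isel({tdim: sel})
        u = ds[u_name].values.astype(float)
        v = ds[v_name].values.astype(float)
        grid = GridSpec(
            lon_nodes=ds[xdim].values.astype(float),
            lat_nodes=ds[ydim].values.astype(float),
            time_nodes=ds[tdim].values.astype(float),
        )
    mask = ~np.isfinite(u) | ~np.isfinite(v)
    u = np.where(mask, 0.0, u)
    v = np.where(mask, 0.0, v)
    return VectorGridField(grid=grid, u=u, v=v, units="m s-1", mask=mask)
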