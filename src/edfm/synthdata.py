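"""Synthetic input generation: weather, soil moisture, plant point clouds
and ground-truth trait trajectories.

Every generator is seeded and bit-exactly reproducible. A single global
seed fans out to per-generator child seeds through a fixed splitting
rule (``numpy.random.SeedSequence(seed, spawn_key=(STREAM,))`` with one
frozen stream id per generator), so adding a generator never shifts an
existing stream.

Weather is produced at daily resolution (the simulator consumes daily
aggregates); an optional hourly sinusoidal expansion represents the
sub-daily diurnal cycle.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError
from .morphology import GrowthParams, logistic_size
from .physiology import PhenologyParams, pdt_increment

__all__ = [
    "WeatherScenario",
    "EnvironmentDay",
    "SyntheticPlantSpec",
    "generate_weather",
    "expand_diurnal",
    "generate_point_cloud",
    "generate_trait_trajectories",
    "weather_to_frame",
    "write_weather_csv",
    "write_point_cloud_ply",
    "write_ground_truth_json",
]

# frozen stream ids for the seed-splitting rule
_STREAM_WEATHER = 0
_STREAM_CLOUD = 1
_STREAM_TRAITS = 2


def child_rng(seed: int, stream: int) -> np.random.Generator:
    """Per-generator child RNG from the global seed (documented split rule)."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


@dataclass
class EnvironmentDay:
    """One day of driving data for the simulator."""

    day: int
    t_mean: float
    t_min: float
    t_max: float
    par: float  # daily PAR integral, mol m-2 d-1
    soil_moisture: np.ndarray  # volumetric water content per layer, m3 m-3


@dataclass
class WeatherScenario:
    """Season-scale weather generator settings.

    The seasonal mean-temperature curve is
    ``t_base_mean + t_amplitude * cos(2 pi (day - t_peak_day) / 365)``;
    the diurnal range is symmetric about the mean. ``par_max`` is the
    clear-sky midday PAR (umol m-2 s-1) converted internally to a daily
    integral assuming a half-sine diurnal course over ``day_length_h``
    hours. Noise terms default to zero so degenerate flat scenarios are
    exactly flat; realistic scenarios switch them on.
    """

    n_days: int
    t_base_mean: float = 24.0
    t_amplitude: float = 4.0
    t_peak_day: int = 45
    diurnal_amplitude: float = 8.0
    par_max: float = 1800.0
    day_length_h: float = 12.0
    rain_events: list[tuple[int, float]] = field(default_factory=list)  # (day, mm)
    seed: int = 0
    t_noise_sd: float = 0.0
    par_noise_cv: float = 0.0
    # soil bucket
    n_layers: int = 3
    layer_depth_m: float = 0.3
    theta_init: float = 0.30
    theta_wp: float = 0.10
    theta_fc: float = 0.32
    theta_sat: float = 0.45
    et_coeff: float = 0.22  # mm of ET per degree-day above t_base_et
    t_base_et: float = 5.0
    root_fractions: tuple[float, ...] = (0.5, 0.3, 0.2)

    def __post_init__(self) -> None:
        if self.n_days < 1:
            raise InvalidArgumentError("n_days must be >= 1")
        if self.par_max <= 0:
            raise InvalidArgumentError("par_max must be positive")
        if not 0 < self.theta_wp < self.theta_fc < self.theta_sat:
            raise InvalidArgumentError("require theta_wp < theta_fc < theta_sat")
        if len(self.root_fractions) != self.n_layers:
            raise InvalidArgumentError("root_fractions must have one entry per layer")


def generate_weather(scenario: WeatherScenario) -> list[EnvironmentDay]:
    """Generate one season of daily weather plus bucket-model soil moisture.

    The bucket draws water down by temperature-driven evapotranspiration
    (distributed over layers by root fraction and availability), refills
    the top layer from rain/irrigation events with saturation excess
    cascading downward, and clips every layer into [theta_wp, theta_sat].
    """
    rng = child_rng(scenario.seed, _STREAM_WEATHER)
    days = np.arange(scenario.n_days)
    t_mean = scenario.t_base_mean + scenario.t_amplitude * np.cos(
        2 * np.pi * (days - scenario.t_peak_day) / 365.0
    )
    if scenario.t_noise_sd > 0:
        t_mean = t_mean + rng.normal(0.0, scenario.t_noise_sd, scenario.n_days)
    half = scenario.diurnal_amplitude / 2.0
    # clear-sky daily PAR integral from the half-sine diurnal course
    par_clear = scenario.par_max * (2 / np.pi) * scenario.day_length_h * 3600.0 / 1e6
    seasonal = np.clip(
        0.75 + 0.25 * np.cos(2 * np.pi * (days - scenario.t_peak_day) / 365.0), 0.2, 1.0
    )
    par = par_clear * seasonal
    if scenario.par_noise_cv > 0:
        par = par * np.clip(
            rng.normal(1.0, scenario.par_noise_cv, scenario.n_days), 0.25, 1.2
        )

    rain = np.zeros(scenario.n_days)
    for day, depth in scenario.rain_events:
        if 0 <= day < scenario.n_days:
            rain[day] += depth

    theta = np.full(scenario.n_layers, scenario.theta_init, dtype=float)
    theta = np.clip(theta, scenario.theta_wp, scenario.theta_sat)
    depth_mm = scenario.layer_depth_m * 1000.0
    roots = np.asarray(scenario.root_fractions, dtype=float)
    out: list[EnvironmentDay] = []
    for d in range(scenario.n_days):
        # infiltration: rain into the top layer, excess cascades down
        flux = rain[d] / depth_mm
        for i in range(scenario.n_layers):
            theta[i] += flux
            excess = max(0.0, theta[i] - scenario.theta_sat)
            theta[i] -= excess
            flux = excess
        # ET extraction, weighted by roots and relative availability
        et_mm = scenario.et_coeff * max(0.0, t_mean[d] - scenario.t_base_et)
        avail = np.clip(
            (theta - scenario.theta_wp) / (scenario.theta_fc - scenario.theta_wp), 0, 1
        )
        weights = roots * avail
        if weights.sum() > 0:
            take = et_mm * weights / weights.sum() / depth_mm
            theta = np.maximum(theta - take, scenario.theta_wp)
        theta = np.clip(theta, scenario.theta_wp, scenario.theta_sat)
        out.append(
            EnvironmentDay(
                day=d,
                t_mean=float(t_mean[d]),
                t_min=float(t_mean[d] - half),
                t_max=float(t_mean[d] + half),
                par=float(par[d]),
                soil_moisture=theta.copy(),
            )
        )
    return out


def expand_diurnal(day: EnvironmentDay, scenario: WeatherScenario) -> np.ndarray:
    """Hourly temperature expansion: sinusoid between t_min and t_max, peak 14:00."""
    hours = np.arange(24)
    half = (day.t_max - day.t_min) / 2.0
    return day.t_mean + half * np.cos(2 * np.pi * (hours - 14) / 24.0)


@dataclass
class SyntheticPlantSpec:
    """Parametric maize plant for point-cloud generation (dimensions in cm).

    Leaves are inclined curved laminae (quadratic-arc midrib, sine width
    profile); the stem is a cylinder stack. Gaussian coordinate noise of
    ``noise_sd`` cm emulates depth-camera error; ``outlier_fraction``
    adds uniform-box outliers for the SOR filter to remove.
    """

    n_leaves: int = 8
    leaf_length_max: float = 70.0
    leaf_width_max: float = 8.0
    internode_lengths: list[float] = field(default_factory=lambda: [12.0] * 8)
    leaf_inclination: float = 45.0
    leaf_arch: float = 0.2
    points_per_leaf: int = 400
    points_per_internode: int = 150
    stem_radius: float = 1.2
    noise_sd: float = 0.0
    outlier_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_leaves > 0 and self.points_per_leaf < 10:
            raise InvalidArgumentError("points_per_leaf must be >= 10")
        if not 0 <= self.outlier_fraction < 0.5:
            raise InvalidArgumentError("outlier_fraction must be in [0, 0.5)")
        if self.n_leaves < 0 or self.noise_sd < 0:
            raise InvalidArgumentError("n_leaves and noise_sd must be >= 0")


def _leaf_points(
    n: int,
    length_m: float,
    width_m: float,
    inclination_deg: float,
    arch: float,
    azimuth_deg: float,
    z_base: float,
    rng: np.random.Generator,
) -> np.ndarray:
    s = rng.random(n)
    t = rng.uniform(-1.0, 1.0, n)
    inc = math.radians(inclination_deg)
    x = length_m * s * math.cos(inc)
    z = z_base + length_m * (s * math.sin(inc) - arch * s**2)
    y = 0.5 * width_m * np.sin(np.pi * s) * t
    az = math.radians(azimuth_deg)
    xr = x * math.cos(az) - y * math.sin(az)
    yr = x * math.sin(az) + y * math.cos(az)
    return np.column_stack([xr, yr, z])


def generate_point_cloud(spec: SyntheticPlantSpec) -> tuple[np.ndarray, dict]:
    """Sample a synthetic plant point cloud (metres) plus ground truth.

    Returns ``(points, truth)`` where ``truth`` records the per-leaf
    lengths/widths, internode lengths and total stem height in cm.
    Leaves alternate azimuth by 180 degrees (maize distichous phyllotaxis)
    and attach at the cumulative internode heights.
    """
    rng = child_rng(spec.seed, _STREAM_CLOUD)
    internodes_m = np.asarray(spec.internode_lengths, dtype=float) / 100.0
    heights_m = np.concatenate([[0.0], np.cumsum(internodes_m)])
    stem_top = float(heights_m[-1])
    parts: list[np.ndarray] = []

    # stem: points on the cylinder surfaces of each internode
    r_m = spec.stem_radius / 100.0
    for i, ln in enumerate(internodes_m):
        if ln <= 0:
            continue
        ang = rng.uniform(0, 2 * np.pi, spec.points_per_internode)
        zz = heights_m[i] + rng.random(spec.points_per_internode) * ln
        parts.append(np.column_stack([r_m * np.cos(ang), r_m * np.sin(ang), zz]))

    leaf_lengths_cm: list[float] = []
    leaf_widths_cm: list[float] = []
    for i in range(spec.n_leaves):
        # mid-rank leaves are the longest, tapering toward base and tip
        frac = 0.55 + 0.45 * math.sin(math.pi * (i + 1) / (spec.n_leaves + 1))
        length_cm = spec.leaf_length_max * frac
        width_cm = spec.leaf_width_max * frac
        z_attach = heights_m[min(i + 1, len(heights_m) - 1)]
        azimuth = 180.0 * (i % 2)
        parts.append(
            _leaf_points(
                spec.points_per_leaf,
                length_cm / 100.0,
                width_cm / 100.0,
                spec.leaf_inclination,
                spec.leaf_arch,
                azimuth,
                z_attach,
                rng,
            )
        )
        leaf_lengths_cm.append(length_cm)
        leaf_widths_cm.append(width_cm)

    if not parts:
        raise InvalidArgumentError("spec describes an empty plant")
    points = np.concatenate(parts, axis=0)
    if spec.noise_sd > 0:
        points = points + rng.normal(0.0, spec.noise_sd / 100.0, points.shape)
    if spec.outlier_fraction > 0:
        n_out = int(round(spec.outlier_fraction * len(points) / (1 - spec.outlier_fraction)))
        lo = points.min(axis=0) - 0.5
        hi = points.max(axis=0) + 0.5
        outliers = rng.uniform(lo, hi, (n_out, 3))
        points = np.concatenate([points, outliers], axis=0)

    truth = {
        "leaf_lengths_cm": leaf_lengths_cm,
        "leaf_widths_cm": leaf_widths_cm,
        "internode_lengths_cm": list(map(float, spec.internode_lengths)),
        "stem_height_cm": stem_top * 100.0,
        "n_leaves": spec.n_leaves,
    }
    return points, truth


def generate_trait_trajectories(
    params: GrowthParams,
    weather: list[EnvironmentDay],
    noise_sd: float = 0.0,
    phenology: PhenologyParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Daily ground-truth and noisy observed logistic trait trajectories.

    PDT accumulates from the weather through the thermal-time model; the
    true trait follows the logistic growth law on PDT; observations add
    seeded Gaussian noise of ``noise_sd`` (trait units).
    """
    if not weather:
        raise InvalidArgumentError("weather must cover the simulated span")
    phen = phenology or PhenologyParams()
    rng = child_rng(seed, _STREAM_TRAITS)
    pdt = np.cumsum([pdt_increment(day.t_mean, phen) for day in weather])
    true = np.asarray(logistic_size(pdt, params), dtype=float)
    obs = true + (rng.normal(0.0, noise_sd, len(true)) if noise_sd > 0 else 0.0)
    return pd.DataFrame(
        {
            "day": [d.day for d in weather],
            "pdt": pdt,
            "true": true,
            "observed": obs,
        }
    )


# --------------------------------------------------------------------------
# Writers
# --------------------------------------------------------------------------


def weather_to_frame(days: list[EnvironmentDay], start_date: str = "2025-06-18") -> pd.DataFrame:
    dates = pd.date_range(start_date, periods=len(days), freq="D")
    rec = {
        "date": dates.strftime("%Y-%m-%d"),
        "t_mean": [d.t_mean for d in days],
        "t_min": [d.t_min for d in days],
        "t_max": [d.t_max for d in days],
        "par_mol_m2_d": [d.par for d in days],
    }
    n_layers = len(days[0].soil_moisture) if days else 0
    for i in range(n_layers):
        rec[f"theta_layer{i + 1}"] = [float(d.soil_moisture[i]) for d in days]
    return pd.DataFrame(rec)


def write_weather_csv(days: list[EnvironmentDay], path: str, start_date: str = "2025-06-18") -> None:
    weather_to_frame(days, start_date).to_csv(path, index=False)


def write_point_cloud_ply(points: np.ndarray, path: str, binary: bool = True) -> None:
    """Write a point cloud as PLY (binary little-endian or ASCII) via trimesh."""
    import trimesh

    cloud = trimesh.PointCloud(np.asarray(points, dtype=float))
    encoding = "binary" if binary else "ascii"
    data = trimesh.exchange.ply.export_ply(cloud, encoding=encoding)
    with open(path, "wb") as fh:
        fh.write(data)


def write_ground_truth_json(truth: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2)


def scenario_to_dict(scenario: WeatherScenario) -> dict:
    return asdict(scenario)
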