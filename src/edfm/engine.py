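"""The daily closed growth loop.

Each 24-h step runs, in order: (1) gated-attention fusion of the three
modality features (logged; the mechanistic loop itself is driven by the
physiological equations), (2) the soil-moisture water-stress factor,
(3) daily assimilate supply from *yesterday's* light capture and Vcmax
(the one-day lag is what makes the loop well defined without a same-day
fixed point), (4) sink-strength allocation, (5) thermal-time advance,
(6) organ expansion limited by the logistic potential, the allocated
carbon and water stress, (7) NURBS organ rescaling, scene rebuild and
ray-traced light interception, (8) the light-capture feedback on Vcmax.

Organ complement is instantiated at the seedling stage with
rank-staggered logistic midpoints (a phyllochron apart), so organs
"appear" as their potential curves rise; the initial state exposes
three visible leaves at 5 % of their asymptote and one internode.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import fusion as fusion_mod
from .encoders import (
    ConvLSTMParams,
    FeatureBundle,
    encode_environment,
    encode_image,
    encode_point_cloud,
)
from .errors import InvalidArgumentError
from .morphology import (
    CanopyScene,
    GrowthParams,
    light_interception,
    logistic_size,
    nurbs_leaf_template,
    render_canopy_image,
    sample_scene_points,
    surface_area,
    tessellate,
)
from .physiology import (
    AssimilateSupply,
    LightUseParams,
    OrganState,
    PhenologyParams,
    WaterParams,
    allocate,
    daily_assimilation,
    pdt_increment,
    update_vcmax,
    water_stress_factor,
)
from .preprocess import fit_zscore, apply_zscore, standardize_image
from .synthdata import EnvironmentDay, WeatherScenario, generate_weather

__all__ = [
    "PlantParams",
    "SimulationConfig",
    "PlantState",
    "SeasonResult",
    "initial_state",
    "step_day",
    "run_season",
    "default_water_limited_scenario",
    "well_watered_scenario",
]


@dataclass
class PlantParams:
    """Architecture and organ growth-potential parameters (cm units).

    Per-rank asymptotes follow a sine profile over rank (mid-canopy
    organs largest); logistic midpoints are staggered one phyllochron
    apart so organs develop sequentially.
    """

    n_leaves: int = 14
    leaf_area_max: float = 550.0  # cm2, largest rank
    leaf_aspect: float = 0.11  # max width / length of the lamina
    leaf_k: float = 0.15  # per physiological day
    leaf_pdt_first: float = 10.0
    phyllochron: float = 3.0
    leaf_inclination: float = 50.0
    leaf_arch: float = 0.2
    n_internodes: int = 10
    internode_len_max: float = 25.0  # cm, largest rank
    internode_k: float = 0.15
    internode_pdt_first: float = 16.0
    internode_phyllochron: float = 3.0
    init_visible_leaves: int = 3
    init_fraction: float = 0.05
    stem_radius_cm: float = 1.2

    def rank_fraction(self, i: int, n: int) -> float:
        return 0.55 + 0.45 * math.sin(math.pi * (i + 1) / (n + 1))


@dataclass
class SimulationConfig:
    """All parameter groups of a simulation run."""

    phenology: PhenologyParams = field(default_factory=PhenologyParams)
    water: WaterParams = field(default_factory=WaterParams)
    lue: LightUseParams = field(default_factory=LightUseParams)
    plant: PlantParams = field(default_factory=PlantParams)
    density: float = 6.0  # plants m-2
    sla_cm2_per_g: float = 180.0  # specific leaf area, carbon -> leaf area
    internode_cm_per_g: float = 15.0  # carbon -> internode elongation
    capture_ref_fraction: float = 0.7  # reference interception for the Vcmax feedback
    n_rays: int = 800
    seed: int = 0
    silking_pdt: float = 70.0
    fusion_mode: str = "self"  # "self" | "off" | "provided"
    fusion_dim: int = 32
    convlstm_hidden: int = 64
    window_width: int = 7
    image_resolution: int = 48
    point_sample: int = 1200
    root_weights: tuple[float, ...] = (0.5, 0.3, 0.2)
    gap_policy: str = "fail"  # "fail" | "interpolate"

    def __post_init__(self) -> None:
        if self.density <= 0 or self.sla_cm2_per_g <= 0 or self.internode_cm_per_g <= 0:
            raise InvalidArgumentError("density and conversion factors must be positive")
        if self.fusion_mode not in ("self", "off", "provided"):
            raise InvalidArgumentError(f"unknown fusion_mode {self.fusion_mode!r}")
        if self.gap_policy not in ("fail", "interpolate"):
            raise InvalidArgumentError("gap_policy must be 'fail' or 'interpolate'")

    @property
    def plant_ground_area(self) -> float:
        return 1.0 / self.density  # m2 per plant


class _PlantGeometry:
    """Cached unit organ meshes; daily rebuild is pure affine array work."""

    def __init__(self, config: SimulationConfig):
        p = config.plant
        side = math.sqrt(config.plant_ground_area)
        self.side = side
        self.center = np.array([side / 2, side / 2, 0.0])
        self.leaf_tris: list[np.ndarray] = []
        self.leaf_unit_area: list[float] = []
        n = p.n_leaves
        for i in range(p.n_leaves):
            frac = p.rank_fraction(i, p.n_leaves)
            length_m = math.sqrt(p.leaf_area_max * frac * math.pi / (2 * p.leaf_aspect)) / 100.0
            # lower leaves flatter, upper more erect; spiral azimuth disperses
            # the distichous plan the way neighbouring plants interleave
            incl = p.leaf_inclination + (i / max(n - 1, 1) - 0.5) * 30.0
            surf = nurbs_leaf_template(
                length_m, p.leaf_aspect * length_m, incl, p.leaf_arch
            )
            tris = tessellate(surf, nu=6, nv=3)
            az = math.radians(180.0 * i + 137.5 * i)
            rot = np.array(
                [[math.cos(az), -math.sin(az), 0], [math.sin(az), math.cos(az), 0], [0, 0, 1]]
            )
            self.leaf_tris.append(tris @ rot.T)
            ab = tris[:, 1] - tris[:, 0]
            ac = tris[:, 2] - tris[:, 0]
            self.leaf_unit_area.append(
                float(0.5 * np.linalg.norm(np.cross(ab, ac), axis=1).sum())
            )
        # octagonal prism template for the stem, unit height and radius
        ang = np.linspace(0, 2 * np.pi, 9)
        ring = np.column_stack([np.cos(ang), np.sin(ang), np.zeros(9)])
        tris = []
        for j in range(8):
            a, b = ring[j], ring[j + 1]
            a1, b1 = a + [0, 0, 1], b + [0, 0, 1]
            tris.append([a, b, b1])
            tris.append([a, b1, a1])
        self.stem_tris = np.array(tris)


@dataclass
class PlantState:
    """The simulated plant: organs, thermal time and carbon ledger."""

    pdt: float
    day: int
    organs: list[OrganState]
    prev_intercepted: float  # mol PAR per plant per day, from yesterday's scene
    carbon_ledger: list[tuple[float, float]] = field(default_factory=list)  # (E, sum Q)
    geometry: _PlantGeometry | None = None

    @property
    def leaves(self) -> list[OrganState]:
        return [o for o in self.organs if o.organ_type == "leaf"]

    @property
    def internodes(self) -> list[OrganState]:
        return [o for o in self.organs if o.organ_type == "internode"]

    @property
    def height(self) -> float:
        """Plant height, cm (sum of internode lengths)."""
        return sum(o.size for o in self.internodes)

    def lai(self, ground_area_m2: float) -> float:
        """One-sided leaf area per unit ground area."""
        return sum(o.size for o in self.leaves) / 1e4 / ground_area_m2

    @property
    def mean_vcmax(self) -> float:
        lv = self.leaves
        return sum(o.vcmax for o in lv) / len(lv) if lv else 0.0


def _potential(organ: OrganState, pdt: float) -> float:
    return float(
        logistic_size(pdt, GrowthParams(organ.size_max, organ.k, organ.pdt_mid))
    )


def initial_state(config: SimulationConfig) -> PlantState:
    """Seedling state with the full organ complement pre-instantiated."""
    p = config.plant
    organs: list[OrganState] = []
    for i in range(p.n_leaves):
        smax = p.leaf_area_max * p.rank_fraction(i, p.n_leaves)
        size0 = p.init_fraction * smax if i < p.init_visible_leaves else min(
            _potential_at_zero(smax, p.leaf_k, p.leaf_pdt_first + i * p.phyllochron), smax
        )
        organs.append(
            OrganState(
                id=f"leaf_{i}", organ_type="leaf", size=size0, size_max=smax,
                vcmax=config.lue.vcmax_ref, k=p.leaf_k,
                pdt_mid=p.leaf_pdt_first + i * p.phyllochron,
            )
        )
    for i in range(p.n_internodes):
        smax = p.internode_len_max * p.rank_fraction(i, p.n_internodes)
        size0 = p.init_fraction * smax if i == 0 else min(
            _potential_at_zero(smax, p.internode_k, p.internode_pdt_first + i * p.internode_phyllochron),
            smax,
        )
        organs.append(
            OrganState(
                id=f"internode_{i}", organ_type="internode", size=size0, size_max=smax,
                vcmax=config.lue.vcmax_ref, k=p.internode_k,
                pdt_mid=p.internode_pdt_first + i * p.internode_phyllochron,
            )
        )
    state = PlantState(pdt=0.0, day=0, organs=organs, prev_intercepted=0.0,
                       geometry=_PlantGeometry(config))
    scene = build_scene(state, config)
    inter = light_interception(scene, 40.0, max(config.n_rays, 100), seed=config.seed % 2**31)
    state.prev_intercepted = inter.total
    return state


def _potential_at_zero(smax: float, k: float, pdt_mid: float) -> float:
    return smax / (1.0 + math.exp(k * pdt_mid))


def build_scene(state: PlantState, config: SimulationConfig) -> CanopyScene:
    """Rebuild the triangulated canopy from current organ sizes.

    The plant is replicated over a 3x3 periodic grid of neighbour cells
    (a uniform stand at the configured density) while rays are cast over
    the centre cell only, so leaves reaching past the plant's own ground
    cell are compensated by the neighbours' leaves reaching in. All
    copies of an organ share its id, so per-organ interception totals
    are per-plant equivalents.
    """
    geo = state.geometry
    if geo is None:
        geo = state.geometry = _PlantGeometry(config)
    side = geo.side
    offsets = [
        np.array([dx * side, dy * side, 0.0])
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
    ]
    organs: dict[str, np.ndarray] = {}
    height_m = state.height / 100.0
    if height_m > 1e-6:
        r = config.plant.stem_radius_cm / 100.0
        stem = geo.stem_tris * np.array([r, r, height_m]) + geo.center
        organs["stem"] = np.concatenate([stem + off for off in offsets])
    leaves = state.leaves
    n = len(leaves)
    for i, leaf in enumerate(leaves):
        if leaf.size <= 1e-9:
            continue
        unit = geo.leaf_tris[i]
        s = math.sqrt(leaf.size / 1e4 / geo.leaf_unit_area[i])
        z_attach = height_m * (i + 1) / max(n, 1)
        base = unit * s + geo.center + np.array([0, 0, z_attach])
        organs[leaf.id] = np.concatenate([base + off for off in offsets])
    return CanopyScene(organs, (0.0, 0.0, side, side))


class _FusionContext:
    """Holds the encoder/gate parameters and the trailing weather window."""

    def __init__(self, config: SimulationConfig, weather: list[EnvironmentDay]):
        rows = np.array(
            [
                [d.t_mean, d.t_min, d.t_max, d.par, float(np.mean(d.soil_moisture))]
                for d in weather
            ]
        )
        # variance guard: constant channels get unit sigma instead of failing
        mu = rows.mean(axis=0)
        sigma = rows.std(axis=0)
        sigma[sigma <= 0] = 1.0
        from .preprocess import NormalizationStats

        self.stats = NormalizationStats(mu, sigma)
        self.conv = ConvLSTMParams.initialize(
            in_channels=1, hidden_channels=config.convlstm_hidden,
            kernel_size=3, seed=config.seed,
        )
        dims = {"env": config.convlstm_hidden, "point": 22, "rgb": 33}
        self.gate = fusion_mod.GateParams.initialize(
            dims, d=config.fusion_dim, seed=config.seed
        )
        self.width = config.window_width
        self.window: list[np.ndarray] = []

    def push(self, day: EnvironmentDay) -> np.ndarray:
        row = np.array(
            [day.t_mean, day.t_min, day.t_max, day.par, float(np.mean(day.soil_moisture))]
        )
        self.window.append(apply_zscore(row, self.stats))
        if len(self.window) > self.width:
            self.window.pop(0)
        win = self.window
        while len(win) < self.width:
            win = [win[0]] + win
        return np.array(win)


def _self_observe(
    state: PlantState, config: SimulationConfig, ctx: _FusionContext, window: np.ndarray
) -> FeatureBundle:
    scene = build_scene(state, config)
    h_env = encode_environment(window, ctx.conv, expected_width=ctx.width)
    seed = (config.seed + 7919 * (state.day + 1)) % 2**31
    if scene.organs:
        pts = sample_scene_points(scene, config.point_sample, seed=seed)
    else:
        pts = np.zeros((8, 3))
    h_point = encode_point_cloud(pts)
    img = render_canopy_image(scene, resolution=config.image_resolution)
    h_rgb = encode_image(standardize_image(img))
    return FeatureBundle(h_env=h_env, h_point=h_point, h_rgb=h_rgb)


def step_day(
    state: PlantState,
    env: EnvironmentDay,
    config: SimulationConfig,
    bundle: FeatureBundle | None = None,
    fusion_ctx: _FusionContext | None = None,
) -> tuple[PlantState, dict]:
    """Advance the plant by one day; returns the new state and diagnostics."""
    state = copy.copy(state)
    state.organs = [copy.copy(o) for o in state.organs]
    state.carbon_ledger = list(state.carbon_ledger)
    diag: dict = {"day": env.day}
    try:
        # (1) multimodal fusion (interpretability surface; logged)
        weights = None
        if fusion_ctx is not None:
            window = fusion_ctx.push(env)
            if bundle is None and config.fusion_mode == "self":
                bundle = _self_observe(state, config, fusion_ctx, window)
            if bundle is not None:
                fused = fusion_mod.fuse(bundle, fusion_ctx.gate)
                weights = fused.weights
        diag["weights"] = weights

        # (2) water stress from the root-zone moisture profile
        theta = np.asarray(env.soil_moisture, dtype=float)
        w = np.asarray(config.root_weights[: len(theta)], dtype=float)
        w = w / w.sum() if w.sum() > 0 else np.full(len(theta), 1.0 / len(theta))
        theta_root = float(theta @ w) if len(theta) else config.water.theta_fc
        wsf = water_stress_factor(theta_root, config.water)
        diag["wsf"] = wsf

        # (3) supply from yesterday's capture and capacity
        supply = daily_assimilation(state.prev_intercepted, state.mean_vcmax, wsf, config.lue)
        diag["E"] = supply.e

        # (4) sink-strength allocation
        pdt_old = state.pdt
        for o in state.organs:
            pot = _potential(o, pdt_old)
            conv = config.sla_cm2_per_g if o.organ_type == "leaf" else config.internode_cm_per_g
            # potential carbon demand rate: logistic slope / carbon-to-size conversion
            o.sink_strength = o.k * pot * (1.0 - pot / o.size_max) / conv
        q = allocate(supply, state.organs)
        diag["sum_Q"] = float(q.sum())
        state.carbon_ledger.append((supply.e, float(q.sum())))

        # (5) thermal time
        state.pdt = pdt_old + pdt_increment(env.t_mean, config.phenology)

        # (6) realized expansion: potential-, carbon- and water-limited
        for o, qi in zip(state.organs, q):
            dl_pot = max(0.0, _potential(o, state.pdt) - _potential(o, pdt_old))
            conv = config.sla_cm2_per_g if o.organ_type == "leaf" else config.internode_cm_per_g
            dl = min(dl_pot, qi * conv) * wsf
            dl = min(dl, o.size_max - o.size)
            o.size += dl
            o.carbon_received += dl / conv if conv > 0 else 0.0

        # (7) morphology update and light capture
        scene = build_scene(state, config)
        seed = (config.seed + 104729 * (env.day + 1)) % 2**31
        inter = light_interception(scene, env.par, config.n_rays, seed=seed)
        diag["intercepted"] = inter.total
        diag["interception_fraction"] = inter.fraction

        # (8) Vcmax feedback from the capture ratio
        reference = env.par * config.plant_ground_area * config.capture_ref_fraction
        ratio = inter.total / reference if reference > 0 else 0.0
        for o in state.leaves:
            update_vcmax(o, ratio, config.lue.beta, config.lue.vcmax_ref)
        diag["capture_ratio"] = ratio
        diag["mean_vcmax"] = state.mean_vcmax

        state.prev_intercepted = inter.total
        state.day = env.day + 1
        diag["pdt"] = state.pdt
        diag["height_cm"] = state.height
        diag["lai"] = state.lai(config.plant_ground_area)
        return state, diag
    except Exception as exc:  # attach the day index for debuggability
        exc.add_note(f"while stepping day {env.day}")
        raise


@dataclass
class SeasonResult:
    traits: pd.DataFrame
    diagnostics: pd.DataFrame
    weights: pd.DataFrame | None
    final_state: PlantState
    states: list[PlantState]

    def write(self, out_dir: str) -> None:
        import os

        os.makedirs(out_dir, exist_ok=True)
        self.traits.to_csv(os.path.join(out_dir, "traits.csv"), index=False)
        self.diagnostics.to_csv(os.path.join(out_dir, "diagnostics.csv"), index=False)
        if self.weights is not None:
            self.weights.to_csv(os.path.join(out_dir, "weights.csv"), index=False)


def _check_gaps(weather: list[EnvironmentDay], policy: str) -> list[EnvironmentDay]:
    days = [d.day for d in weather]
    if list(range(days[0], days[0] + len(days))) == days:
        return weather
    if policy == "fail":
        raise InvalidArgumentError("weather has gaps (set gap_policy='interpolate' to fill)")
    filled: list[EnvironmentDay] = []
    for prev, nxt in zip(weather[:-1], weather[1:]):
        filled.append(prev)
        span = nxt.day - prev.day
        for j in range(1, span):
            f = j / span
            filled.append(
                EnvironmentDay(
                    day=prev.day + j,
                    t_mean=prev.t_mean + f * (nxt.t_mean - prev.t_mean),
                    t_min=prev.t_min + f * (nxt.t_min - prev.t_min),
                    t_max=prev.t_max + f * (nxt.t_max - prev.t_max),
                    par=prev.par + f * (nxt.par - prev.par),
                    soil_moisture=prev.soil_moisture + f * (nxt.soil_moisture - prev.soil_moisture),
                )
            )
    filled.append(weather[-1])
    return filled


def run_season(
    config: SimulationConfig,
    weather: list[EnvironmentDay],
    observations: list[FeatureBundle] | None = None,
) -> SeasonResult:
    """Fold the daily step over a season from the seedling state.

    With no observation bundles and ``fusion_mode='self'`` the fusion
    stage runs on encoder outputs computed from the simulator's own
    scene, keeping the loop closed and self-contained. Deterministic for
    a fixed config seed.
    """
    state = initial_state(config)
    if not weather:
        empty = pd.DataFrame()
        return SeasonResult(empty, empty, None, state, [state])
    weather = _check_gaps(weather, config.gap_policy)
    if observations is not None and len(observations) != len(weather):
        raise InvalidArgumentError("one observation bundle per weather day required")
    ctx = _FusionContext(config, weather) if config.fusion_mode != "off" else None
    states = [state]
    diags: list[dict] = []
    p = config.plant
    trait_rows: list[dict] = []
    for i, env in enumerate(weather):
        bundle = observations[i] if observations is not None else None
        state, diag = step_day(state, env, config, bundle=bundle, fusion_ctx=ctx)
        states.append(state)
        diags.append(diag)
        row = {
            "day": env.day,
            "pdt": state.pdt,
            "height_cm": state.height,
            "lai": state.lai(config.plant_ground_area),
        }
        for j, leaf in enumerate(state.leaves):
            length = math.sqrt(leaf.size * math.pi / (2 * p.leaf_aspect))
            row[f"leaf{j}_length_cm"] = length
            row[f"leaf{j}_width_cm"] = p.leaf_aspect * length
        trait_rows.append(row)
    traits = pd.DataFrame(trait_rows)
    weights_df = None
    if any(d.get("weights") is not None for d in diags):
        weights_df = pd.DataFrame(
            [
                {
                    "day": d["day"],
                    "alpha_point": d["weights"].alpha["point"],
                    "alpha_rgb": d["weights"].alpha["rgb"],
                    "alpha_env": d["weights"].alpha["env"],
                }
                for d in diags
                if d.get("weights") is not None
            ]
        )
    diag_df = pd.DataFrame([{k: v for k, v in d.items() if k != "weights"} for d in diags])
    return SeasonResult(traits, diag_df, weights_df, state, states)


# --------------------------------------------------------------------------
# Reference scenarios
# --------------------------------------------------------------------------


def default_water_limited_scenario(
    seed: int = 0, n_days: int = 120, fusion: bool = False
) -> tuple[SimulationConfig, list[EnvironmentDay]]:
    """Mid-season drought scenario: sparse irrigation, declining soil moisture.

    Rain events refill only partially, so root-zone moisture spends much
    of the season between wilting point and field capacity and the
    water-stress factor actively limits growth.
    """
    scenario = WeatherScenario(
        n_days=n_days,
        t_base_mean=25.0,
        t_amplitude=3.0,
        t_peak_day=50,
        diurnal_amplitude=9.0,
        par_max=1800.0,
        rain_events=[(10, 18.0), (35, 15.0), (70, 20.0), (95, 12.0)],
        seed=seed,
        t_noise_sd=1.2,
        par_noise_cv=0.12,
        theta_init=0.28,
    )
    weather = generate_weather(scenario)
    config = SimulationConfig(seed=seed, fusion_mode="self" if fusion else "off")
    return config, weather


def well_watered_scenario(
    seed: int = 0, n_days: int = 120, fusion: bool = False
) -> tuple[SimulationConfig, list[EnvironmentDay]]:
    """Irrigated control: frequent refills keep moisture near field capacity."""
    scenario = WeatherScenario(
        n_days=n_days,
        t_base_mean=25.0,
        t_amplitude=3.0,
        t_peak_day=50,
        diurnal_amplitude=9.0,
        par_max=1800.0,
        rain_events=[(d, 25.0) for d in range(0, n_days, 7)],
        seed=seed,
        t_noise_sd=1.2,
        par_noise_cv=0.12,
        theta_init=0.32,
    )
    weather = generate_weather(scenario)
    config = SimulationConfig(seed=seed, fusion_mode="self" if fusion else "off")
    return config, weather
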