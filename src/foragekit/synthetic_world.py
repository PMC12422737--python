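"""Synthetic foraging worlds with known ground truth.

Generates circular arenas with circular food patches, simulates midpoint
trajectories of foragers that encounter, sense, and sometimes exploit
patches, and produces covariate-level datasets with exact soft labels.
Every stochastic routine takes an integer seed; per-worm streams are
derived by ``numpy.random.SeedSequence`` spawning so that adding worms
never perturbs earlier worms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = [
    "Patch",
    "ArenaSpec",
    "BehaviorParams",
    "TrajectoryRecord",
    "generate_world",
    "simulate_forager",
    "simulate_population",
    "generate_covariate_dataset",
    "write_trajectories",
    "write_arena",
    "read_arena",
    "write_ground_truth",
]

#: default encounter margin (mm); kept in sync with encounter_detection
ENTRY_MARGIN_MM = 0.46024

GROUND_TRUTH_COLUMNS = [
    "worm_id", "patch_id", "entry_time", "exit_time",
    "sensed_true", "exploited_true", "rho_k", "tau_s", "rho_h", "rho_e",
]


class Patch(NamedTuple):
    patch_id: int
    x: float
    y: float
    radius: float
    relative_density: float


@dataclass(frozen=True)
class ArenaSpec:
    """Circular arena with circular patches, all lengths in mm."""

    arena_radius: float
    patches: tuple[Patch, ...]
    layout_kind: str = "custom"
    grid_spacing: float = 6.0

    def __post_init__(self) -> None:
        if self.arena_radius <= 0:
            raise ConfigurationError("arena_radius must be positive")
        for p in self.patches:
            if p.radius <= 0:
                raise ConfigurationError(f"patch {p.patch_id}: radius must be > 0")
            if p.relative_density < 0:
                raise ConfigurationError(
                    f"patch {p.patch_id}: relative density must be >= 0")
            if math.hypot(p.x, p.y) + p.radius > self.arena_radius + 1e-9:
                raise ConfigurationError(
                    f"patch {p.patch_id} does not lie fully inside the arena")

    def density_of(self, patch_id: int) -> float:
        for p in self.patches:
            if p.patch_id == patch_id:
                return p.relative_density
        raise KeyError(patch_id)


def _default_sensing(density: float) -> float:
    """Saturating, monotone non-decreasing map density -> P(sense)."""
    return float(density) / (1.0 + float(density))


@dataclass(frozen=True)
class BehaviorParams:
    """Kinematic and decision parameters of the simulated forager.

    Speeds are in um/s, windows in seconds, duration mixture in log10
    seconds.  ``beta_true`` orders coefficients as
    (intercept, rho_k, tau_s, rho_h, rho_e).
    """

    speed_off: float = 198.0
    speed_on: float = 52.0
    fps: float = 3.0
    heading_noise_sd: float = 0.65          # rad / sqrt(s)
    speed_jitter: float = 0.10              # fractional, uniform
    slowdown_window: float = 8.0            # s, edge ramp for sensed entries
    short_log10_mean: float = 1.2
    short_log10_sd: float = 0.35
    long_log10_mean: float = 2.9
    long_log10_sd: float = 0.35
    sensing_fn: Callable[[float], float] = _default_sensing
    beta_true: tuple[float, ...] = (-2.0, 1.0, 0.5, -0.5, -0.5)
    acclimation_density: float = 10.0

    def __post_init__(self) -> None:
        if not self.speed_on < self.speed_off:
            raise ConfigurationError("speed_on must be < speed_off")
        if self.fps <= 0:
            raise ConfigurationError("fps must be > 0")
        if self.acclimation_density <= 0:
            raise ConfigurationError("acclimation_density must be > 0")
        probe = [self.sensing_fn(d) for d in (0.0, 0.5, 1.0, 5.0, 10.0, 100.0)]
        if any(not (0.0 <= p <= 1.0) for p in probe):
            raise ConfigurationError("sensing_fn must map densities into [0, 1]")
        if any(b - a < -1e-12 for a, b in zip(probe, probe[1:])):
            raise ConfigurationError("sensing_fn must be monotone non-decreasing")


@dataclass
class TrajectoryRecord:
    """Midpoint track of one worm at constant frame rate."""

    worm_id: int
    time: np.ndarray       # s, strictly increasing, step 1/fps
    x: np.ndarray          # mm
    y: np.ndarray          # mm
    fps: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "frame": np.arange(len(self.time)),
            "time_s": self.time,
            "worm_id": self.worm_id,
            "x_mm": self.x,
            "y_mm": self.y,
        })


# ---------------------------------------------------------------------------
# world generation
# ---------------------------------------------------------------------------

def generate_world(layout_kind: str, density_condition: float,
                   seed: int) -> ArenaSpec:
    """Build an ArenaSpec for a named layout.

    ``isometric_grid``: 30 mm arena holding 19 patches of radius 0.9 mm on a
    hexagonal grid with 6 mm center-to-center spacing.  ``single_patch``:
    9 mm arena with one centered patch.  Deterministic given the seed.
    """
    if density_condition < 0:
        raise ConfigurationError("density_condition must be >= 0")
    if layout_kind == "isometric_grid":
        spacing = 6.0
        rows = [3, 4, 5, 4, 3]
        dy = spacing * math.sqrt(3.0) / 2.0
        patches: list[Patch] = []
        pid = 0
        for i, n in enumerate(rows):
            y = (i - 2) * dy
            x0 = -(n - 1) * spacing / 2.0
            for jcol in range(n):
                patches.append(Patch(pid, x0 + jcol * spacing, y, 0.9,
                                     float(density_condition)))
                pid += 1
        return ArenaSpec(15.0, tuple(patches), "isometric_grid", spacing)
    if layout_kind == "single_patch":
        return ArenaSpec(4.5, (Patch(0, 0.0, 0.0, 0.9, float(density_condition)),),
                         "single_patch", 0.0)
    raise ConfigurationError(f"unknown layout_kind: {layout_kind!r}")


# ---------------------------------------------------------------------------
# trajectory simulation
# ---------------------------------------------------------------------------

def _signed_dist(x: float, y: float, arena: ArenaSpec) -> tuple[float, int]:
    """Signed distance (mm, positive inside) to nearest patch edge."""
    best = -np.inf
    best_id = -1
    for p in arena.patches:
        d = p.radius - math.hypot(x - p.x, y - p.y)
        if d > best:
            best = d
            best_id = p.patch_id
    return best, best_id


def _reflect_circle(x: float, y: float, r: float) -> tuple[float, float]:
    """Reflect a point that stepped outside a circle of radius r back inside."""
    rho = math.hypot(x, y)
    if rho <= r or rho == 0.0:
        return x, y
    # mirror across the circle: rho -> 2 r - rho along the same ray
    scale = max(2.0 * r - rho, 0.0) / rho
    return x * scale, y * scale


def simulate_forager(arena: ArenaSpec, params: BehaviorParams,
                     duration_s: float, seed) -> tuple[TrajectoryRecord, pd.DataFrame]:
    """Simulate one worm for ``duration_s`` seconds.

    Off patch the worm performs a correlated random walk at ``speed_off``
    reflecting off the arena wall.  Crossing into the encounter zone of a
    patch triggers a sensing draw; sensed encounters trigger an exploit
    draw from ``logistic(beta_true . x)`` with covariates built from the
    realized history, after which the worm dwells on the patch at
    ``speed_on`` for a duration drawn from the long (exploit) or short
    (sample) log-normal mode.  Non-responding worms pass straight through.
    Returns the trajectory and a ground-truth encounter log.
    """
    if duration_s <= 0:
        raise ConfigurationError("duration_s must be > 0")
    rng = np.random.default_rng(seed)
    dt = 1.0 / params.fps
    n = int(round(duration_s * params.fps)) + 1
    margin = ENTRY_MARGIN_MM

    # start outside every encounter zone
    for _ in range(1000):
        r = arena.arena_radius * math.sqrt(rng.uniform())
        th = rng.uniform(0, 2 * math.pi)
        x0, y0 = r * math.cos(th), r * math.sin(th)
        if not arena.patches or _signed_dist(x0, y0, arena)[0] < -margin:
            break
    heading = rng.uniform(0, 2 * math.pi)
    patch_by_id = {p.patch_id: p for p in arena.patches}

    xs = np.empty(n)
    ys = np.empty(n)
    xs[0], ys[0] = x0, y0

    log_rows: list[dict] = []
    ln_accl = math.log(params.acclimation_density)
    rho_h = ln_accl
    rho_e = ln_accl
    off_clock = 0.0             # s off patch since last exploited departure
    beta = np.asarray(params.beta_true, dtype=float)

    in_zone = False
    zone_patch = -1
    entry_i = 0
    cur: dict | None = None
    # dwell state for sensed encounters
    dwell_left = 0.0
    mode = "off"                # off | dwell
    ramp_left = 0.0

    x, y = x0, y0
    for i in range(1, n):
        if mode == "dwell":
            speed = params.speed_on
            if ramp_left > 0.0:
                frac = ramp_left / params.slowdown_window
                speed = params.speed_on + (params.speed_off - params.speed_on) * frac
                ramp_left -= dt
        else:
            speed = params.speed_off
        speed *= 1.0 + params.speed_jitter * rng.uniform(-1.0, 1.0)
        heading += params.heading_noise_sd * math.sqrt(dt) * rng.standard_normal()
        step = speed * dt / 1000.0  # um/s -> mm
        nx = x + step * math.cos(heading)
        ny = y + step * math.sin(heading)

        if mode == "dwell":
            # confine to the patch interior once inside; while still walking
            # in from the edge, keep heading toward the center unreflected
            p = patch_by_id[zone_patch]
            r_conf = 0.9 * p.radius
            was_inside = math.hypot(x - p.x, y - p.y) <= r_conf
            if was_inside:
                rlx, rly = _reflect_circle(nx - p.x, ny - p.y, r_conf)
                if rlx != nx - p.x or rly != ny - p.y:
                    heading = rng.uniform(0, 2 * math.pi)
                nx, ny = rlx + p.x, rly + p.y
            dwell_left -= dt
            if dwell_left <= 0.0:
                # leave: head radially outward
                heading = math.atan2(ny - p.y, nx - p.x)
                mode = "off"
        else:
            rx, ry = _reflect_circle(nx, ny, arena.arena_radius)
            if rx != nx or ry != ny:
                heading = rng.uniform(0, 2 * math.pi)
            nx, ny = rx, ry

        x, y = nx, ny
        xs[i], ys[i] = x, y
        t = i * dt

        if arena.patches:
            d, pid = _signed_dist(x, y, arena)
            if not in_zone and d >= -margin:
                # new encounter
                in_zone = True
                zone_patch = pid
                entry_i = i
                dens = arena.density_of(pid)
                sensed = int(rng.uniform() < params.sensing_fn(dens))
                cur = {"worm_id": 0, "patch_id": pid, "entry_time": t,
                       "exit_time": np.nan, "sensed_true": sensed,
                       "exploited_true": 0, "rho_k": np.nan, "tau_s": np.nan,
                       "rho_h": np.nan, "rho_e": np.nan}
                if sensed:
                    rho_k = math.log(dens) if dens > 0 else math.log(1e-6)
                    tau_s = off_clock / 3600.0
                    xv = np.array([1.0, rho_k, tau_s, rho_h, rho_e])
                    p_ex = 1.0 / (1.0 + math.exp(-float(beta @ xv)))
                    exploited = int(rng.uniform() < p_ex)
                    cur.update(exploited_true=exploited, rho_k=rho_k,
                               tau_s=tau_s, rho_h=rho_h, rho_e=rho_e)
                    if exploited:
                        dwell_s = 10.0 ** rng.normal(params.long_log10_mean,
                                                     params.long_log10_sd)
                    else:
                        dwell_s = 10.0 ** rng.normal(params.short_log10_mean,
                                                     params.short_log10_sd)
                    mode = "dwell"
                    dwell_left = dwell_s
                    ramp_left = params.slowdown_window
                    # steer toward the patch center
                    p = patch_by_id[pid]
                    heading = math.atan2(p.y - y, p.x - x)
            elif in_zone:
                dz, _ = (d, pid) if pid == zone_patch else _patch_dist(x, y, arena, zone_patch)
                if dz < -margin:
                    in_zone = False
                    assert cur is not None
                    cur["exit_time"] = t
                    if cur["sensed_true"]:
                        rho_h = math.log(max(arena.density_of(zone_patch), 1e-6))
                        if cur["exploited_true"]:
                            rho_e = rho_h
                            off_clock = 0.0
                    log_rows.append(cur)
                    cur = None
                    mode = "off"

        if not in_zone:
            off_clock += dt

    if cur is not None:            # encounter censored at recording end
        cur["exit_time"] = (n - 1) * dt
        log_rows.append(cur)

    traj = TrajectoryRecord(0, np.arange(n) * dt, xs, ys, params.fps)
    log = pd.DataFrame(log_rows, columns=GROUND_TRUTH_COLUMNS)
    return traj, log


def _patch_dist(x: float, y: float, arena: ArenaSpec, patch_id: int) -> tuple[float, int]:
    p = next(q for q in arena.patches if q.patch_id == patch_id)
    return p.radius - math.hypot(x - p.x, y - p.y), patch_id


def simulate_population(arena: ArenaSpec, params: BehaviorParams,
                        n_worms: int, duration_s: float,
                        seed: int) -> tuple[list[TrajectoryRecord], pd.DataFrame]:
    """Simulate ``n_worms`` independent worms from spawned seed streams."""
    if n_worms < 1:
        raise ConfigurationError("n_worms must be >= 1")
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    children = ss.spawn(n_worms)
    trajs: list[TrajectoryRecord] = []
    logs: list[pd.DataFrame] = []
    for w, child in enumerate(children):
        traj, log = simulate_forager(arena, params, duration_s, child)
        traj.worm_id = w
        log["worm_id"] = w
        trajs.append(traj)
        logs.append(log)
    log = pd.concat(logs, ignore_index=True) if logs else pd.DataFrame(
        columns=GROUND_TRUTH_COLUMNS)
    return trajs, log


# ---------------------------------------------------------------------------
# covariate-level dataset
# ---------------------------------------------------------------------------

def generate_covariate_dataset(beta_true: Sequence[float], n_worms: int,
                               encounters_per_worm: int,
                               density_menu: Sequence[float], seed: int,
                               acclimation_density: float = 10.0,
                               mean_search_hr: float = 0.25,
                               dwell_exploit_hr: float = 0.2,
                               dwell_sample_s: float = 30.0,
                               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a covariate-level soft-label dataset with known coefficients.

    Densities are sampled uniformly from ``density_menu``; inter-encounter
    search times are exponential with mean ``mean_search_hr``; history
    covariates propagate sequentially from the acclimation density using
    realized (Bernoulli) exploit draws.  Soft labels are the *exact* model
    probabilities ``logistic(beta_true . x)`` with sensing probability 1,
    so a downstream fit sees noiseless labels.

    Returns ``(dataset, ground_truth)`` where the dataset carries columns
    worm_id, encounter, density, entry_s, exit_s, rho_k, tau_s, rho_h,
    rho_e, tau_t, q, p_sense.
    """
    if n_worms < 1:
        raise ConfigurationError("n_worms must be >= 1")
    menu = [float(d) for d in density_menu]
    if not menu:
        raise ConfigurationError("density_menu must be non-empty")
    if any(d <= 0 for d in menu):
        raise ConfigurationError("density_menu entries must be > 0")
    beta = np.asarray(beta_true, dtype=float)
    if beta.shape != (5,):
        raise ConfigurationError(
            "beta_true must have 5 entries: intercept, rho_k, tau_s, rho_h, rho_e")

    children = np.random.SeedSequence(seed).spawn(n_worms)
    ln_accl = math.log(acclimation_density)
    rows: list[dict] = []
    truth_rows: list[dict] = []
    for w, child in enumerate(children):
        rng = np.random.default_rng(child)
        rho_h = ln_accl
        rho_e = ln_accl
        off_hr = 0.0
        t_hr = 0.0
        for k in range(encounters_per_worm):
            search = rng.exponential(mean_search_hr)
            off_hr += search
            t_hr += search
            dens = menu[rng.integers(len(menu))]
            rho_k = math.log(dens)
            x = np.array([1.0, rho_k, off_hr, rho_h, rho_e])
            q = 1.0 / (1.0 + math.exp(-float(beta @ x)))
            exploited = int(rng.uniform() < q)
            entry_s = t_hr * 3600.0
            dwell_hr = dwell_exploit_hr if exploited else dwell_sample_s / 3600.0
            rows.append({
                "worm_id": w, "encounter": k, "density": dens,
                "entry_s": entry_s, "exit_s": (t_hr + dwell_hr) * 3600.0,
                "rho_k": rho_k, "tau_s": off_hr, "rho_h": rho_h,
                "rho_e": rho_e, "tau_t": t_hr, "q": q, "p_sense": 1.0,
            })
            truth_rows.append({
                "worm_id": w, "patch_id": -1, "entry_time": entry_s,
                "exit_time": (t_hr + dwell_hr) * 3600.0, "sensed_true": 1,
                "exploited_true": exploited, "rho_k": rho_k, "tau_s": off_hr,
                "rho_h": rho_h, "rho_e": rho_e,
            })
            rho_h = rho_k
            if exploited:
                rho_e = rho_k
                off_hr = 0.0
            t_hr += dwell_hr
    return pd.DataFrame(rows), pd.DataFrame(truth_rows, columns=GROUND_TRUTH_COLUMNS)


# ---------------------------------------------------------------------------
# delimited-text I/O
# ---------------------------------------------------------------------------

def write_trajectories(trajs: Sequence[TrajectoryRecord], path) -> None:
    pd.concat([t.to_frame() for t in trajs], ignore_index=True).to_csv(
        path, index=False)


def write_arena(arena: ArenaSpec, path) -> None:
    df = pd.DataFrame(arena.patches,
                      columns=["patch_id", "x_mm", "y_mm", "radius_mm",
                               "relative_density"])
    with open(path, "w") as fh:
        fh.write(f"# arena_radius_mm={arena.arena_radius}\n")
        fh.write(f"# layout_kind={arena.layout_kind}\n")
        fh.write(f"# grid_spacing_mm={arena.grid_spacing}\n")
        df.to_csv(fh, index=False)


def read_arena(path) -> ArenaSpec:
    meta: dict[str, str] = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val.strip()
            body_start = i + 1
        else:
            break
    from io import StringIO
    df = pd.read_csv(StringIO("".join(lines[body_start:])))
    patches = tuple(Patch(int(r.patch_id), float(r.x_mm), float(r.y_mm),
                          float(r.radius_mm), float(r.relative_density))
                    for r in df.itertuples())
    return ArenaSpec(float(meta["arena_radius_mm"]), patches,
                     meta.get("layout_kind", "custom"),
                     float(meta.get("grid_spacing_mm", 0.0)))


def write_ground_truth(log: pd.DataFrame, path) -> None:
    log.to_csv(path, index=False)
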