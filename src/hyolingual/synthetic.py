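"""Ground-truth swallow generator.

Produces marker trajectories (200 Hz), bone-fixed cluster trajectories,
oral-boundary landmark clouds, and multichannel EMG with the kinematic and
statistical structure the analysis pipeline assumes, so every stage can be
tested closed-loop against known ground truth.  Default parameters are the
observed swallow magnitudes this pipeline is designed to measure: posterior
surface / posterior deep / vallecular retractions of 6.25 / 4.30 / 4.08 mm,
tongue-base length increase 3.61 mm, regional volume changes of +0.85 mL
(posterior oral tongue) and +0.65 mL (tongue base) with the anterior oral
tongue held constant, hyoid protraction 4.23 mm and elevation 2.13 mm,
styloglossus shortening 0.76 mm and hyoglossus shortening 4.74 mm, and a
marker noise SD of 0.07 mm.

The deformation model is kinematic, not biomechanical: markers follow smooth
ramps between their onset and offset configurations, and two in-plane ring
deformation modes (posterior-ring radial expansion; middle-ring scaling with
an anterior-apex correction) are tuned by 1D secant iterations against the
forward volume model until the programmed regional volume changes are met
within 2%.  All randomness derives from a single seed; two runs with the same
seed are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import MIDDLE_RING_ORDER, POSTERIOR_RING_ORDER, frame_volumes
from .io import MarkerTrajectorySet

__all__ = [
    "SwallowScenario",
    "SyntheticDataset",
    "GenerationError",
    "generate_scenario",
    "generate_tongue_deformation",
    "generate_precision_trial",
    "correlated_cycle_summaries",
]


class GenerationError(RuntimeError):
    """Scale search failed or the requested geometry is infeasible."""


# ---------------------------------------------------------------------------
# Scenario definition
# ---------------------------------------------------------------------------


@dataclass
class SwallowScenario:
    """Programmed swallow-cycle conditions (all per-cycle deltas over TBR)."""

    seed: int
    frame_rate: float = 200.0
    n_frames: int = 200
    tbr_onset: int = 80                  # frame of TBR onset
    tbr_offset: int = 120                # frame of TBR offset
    ip_plateau_frames: int = 22          # static-gape plateau (interior = 0.1 s)
    ip_start: int = 30                   # first plateau frame
    # Marker displacement targets over TBR (mm, X positive anterior)
    posterior_surface_retraction: float = 6.25
    posterior_deep_retraction: float = 4.30
    vallecula_retraction: float = 4.08
    posterior_lateral_retraction: float = 0.47   # gives +3.61 mm TB length
    lateral_right_protraction: float = 0.93
    lateral_left_protraction: float = 0.30
    posterior_surface_elevation: float = 3.0
    # Regional volume targets over TBR (mL)
    delta_aot_ml: float = 0.0
    delta_pot_ml: float = 0.85
    delta_tb_ml: float = 0.65
    # Hyoid excursion targets over TBR (mm)
    hyoid_protraction: float = 4.23
    hyoid_elevation: float = 2.13
    # Muscle length-change targets over TBR (mm; negative = shortening)
    styloglossus_delta: float = -0.76
    hyoglossus_delta: float = -4.74
    palatoglossus_delta: float = 0.07
    # Noise
    marker_noise_sd: float = 0.07        # mm, per coordinate per frame
    emg_fs: float = 2000.0               # Hz
    emg_noise_sd: float = 0.1
    emg_burst_amplitude: float = 1.0
    # Forward-model discretization used for volume-target tuning
    ring_samples: int = 300
    interior_spacing_factor: float = 2.0
    volume_tolerance: float = 0.02       # relative closure tolerance of the tuner
    max_iterations: int = 50

    def __post_init__(self) -> None:
        if not 0 < self.tbr_onset < self.tbr_offset < self.n_frames:
            raise ValueError("TBR events must be ordered within the cycle")
        for name in ("marker_noise_sd", "emg_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


# Baseline (TBR-onset) constellation, cranial frame, mm.
TONGUE_BASE_POSITIONS = {
    "anterior": (40.0, 2.0, 0.0),
    "lateral_right": (28.0, 3.0, 8.0),
    "lateral_left": (28.0, 3.0, -8.0),
    "middle_surface": (20.0, 5.0, 0.0),
    "middle_deep": (20.0, -9.0, 0.0),
    "middle_right": (20.0, -2.0, 10.0),
    "middle_left": (20.0, -2.0, -10.0),
    "posterior_surface": (0.0, 4.0, 0.0),
    "posterior_right": (0.0, -3.0, 9.0),
    "posterior_left": (0.0, -3.0, -9.0),
    "posterior_deep": (0.0, -9.0, 0.0),
    "vallecula": (-4.0, -3.0, 0.0),
}
DORSAL_HYOID_BASE = np.array([0.0, -11.0, 0.0])
HYOID_CENTER = np.array([-14.0, -22.0, 0.0])

CRANIUM_CLUSTER = np.array(
    [[10.0, 30.0, 12.0], [10.0, 30.0, -12.0], [-15.0, 35.0, 0.0],
     [25.0, 28.0, 8.0], [25.0, 28.0, -8.0], [0.0, 40.0, 5.0]]
)
MANDIBLE_CLUSTER = np.array(
    [[34.0, -8.0, 4.0], [34.0, -8.0, -4.0], [10.0, -14.0, 14.0],
     [10.0, -14.0, -14.0], [-12.0, -6.0, 16.0], [-12.0, -6.0, -16.0]]
)
HYOID_CLUSTER = HYOID_CENTER + np.array(
    [[4.0, 0.0, 0.0], [-4.0, 1.0, 0.0], [0.0, -2.0, 4.0], [0.0, -2.0, -4.0]]
)
CONDYLE_CENTER = np.array([-28.0, 4.0, 0.0])

# Muscle attachment geometry (origins on bone, insertions in the tongue).
STYLOGLOSSUS_ORIGIN = np.array([-25.0, 8.0, 12.0])
STYLOGLOSSUS_INSERTION0 = np.array([2.0, -2.0, 8.5])
HYOGLOSSUS_ORIGIN0 = HYOID_CENTER + np.array([-2.0, 2.0, 8.0])
HYOGLOSSUS_INSERTION0 = np.array([4.0, -4.0, 8.5])
PALATOGLOSSUS_ORIGIN = np.array([4.0, 10.0, 6.0])
PALATOGLOSSUS_INSERTION0 = np.array([12.0, -1.0, 7.0])
GENIOHYOID_ORIGIN = np.array([32.0, -12.0, 0.0])  # symphysis, mandible-fixed


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return 0.5 * (1.0 - np.cos(np.pi * u))


def _quadratic_ramp(u: np.ndarray) -> np.ndarray:
    """Fast-start, smooth-stop ramp u(2-u)."""
    u = np.clip(u, 0.0, 1.0)
    return u * (2.0 - u)


def _linear_ramp(u: np.ndarray) -> np.ndarray:
    return np.clip(u, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Tongue deformation
# ---------------------------------------------------------------------------


def _ring_plane_radial(positions: dict) -> dict:
    """Unit Y-Z radial directions of the posterior ring tongue markers about
    the base posterior-ring centroid (the ring plane is Y-Z at baseline)."""
    ring = [np.array(TONGUE_BASE_POSITIONS[m]) for m in
            ("posterior_surface", "posterior_right", "posterior_left")]
    ring.append(DORSAL_HYOID_BASE)
    centroid = np.mean(ring, axis=0)
    out = {}
    for m in ("posterior_surface", "posterior_right", "posterior_left"):
        d = np.array(TONGUE_BASE_POSITIONS[m]) - centroid
        d[0] = 0.0
        out[m] = d / np.linalg.norm(d)
    return out


def _tongue_paths(
    sc: SwallowScenario,
    s_post: float,
    s_mid: float,
    d_ant: float,
    frames: np.ndarray,
) -> tuple[dict, np.ndarray]:
    """Noiseless tongue-marker paths plus the dorsal-hyoid series at ``frames``.

    ``s_post`` (mm): posterior-ring in-plane radial expansion amplitude;
    ``s_mid``: middle-ring in-plane scale factor increment; ``d_ant`` (mm):
    anterior-marker X displacement (anterior-apex correction).
    """
    f = np.asarray(frames, float)
    dur = sc.tbr_offset - sc.tbr_onset
    u = (f - sc.tbr_onset) / dur
    r_s = _smoothstep(u)
    r_q = _quadratic_ramp(u)
    r_l = _linear_ramp(u)
    # anticipatory protraction ending (with non-zero slope) at TBR onset, and
    # post-offset recovery ramps (linear start => sharp vallecular trough);
    # amplitudes scale with the corresponding retraction targets so a
    # zero-target scenario is exactly static
    pre = np.clip((f - (sc.tbr_onset - 30)) / 30.0, 0.0, 1.0) ** 2
    reb = np.clip((f - sc.tbr_offset) / 25.0, 0.0, 1.0)

    base = {k: np.array(v) for k, v in TONGUE_BASE_POSITIONS.items()}
    radial = _ring_plane_radial(base)
    mid_centroid = np.mean(
        [base[m] for m in ("middle_surface", "middle_right", "middle_left", "middle_deep")],
        axis=0,
    )
    n = len(f)
    paths = {k: np.tile(v, (n, 1)) for k, v in base.items()}

    def add(name, axis, series):
        paths[name][:, axis] = paths[name][:, axis] + series

    psr = sc.posterior_surface_retraction
    add("posterior_surface", 0, 0.29 * psr * pre - psr * r_q + 0.032 * psr * reb)
    add("posterior_surface", 1, sc.posterior_surface_elevation * r_s)
    add("posterior_deep", 0, -sc.posterior_deep_retraction * r_s)
    add("posterior_deep", 1, 0.35 * sc.posterior_deep_retraction * r_s)
    add("vallecula", 0, -sc.vallecula_retraction * r_l + 0.37 * sc.vallecula_retraction * reb)
    add("vallecula", 1, 0.25 * sc.vallecula_retraction * r_s)
    for m in ("posterior_right", "posterior_left"):
        add(m, 0, -sc.posterior_lateral_retraction * r_s)
        add(m, 1, 0.6 * sc.posterior_lateral_retraction * r_s)
    add("lateral_right", 0, sc.lateral_right_protraction * r_s)
    add("lateral_left", 0, sc.lateral_left_protraction * r_s)
    add("anterior", 0, d_ant * r_s)
    # posterior-ring radial expansion mode (pure Y-Z: X targets untouched)
    for m in ("posterior_surface", "posterior_right", "posterior_left"):
        paths[m] += np.outer(s_post * r_s, radial[m])
    # middle-ring in-plane scaling mode about the ring centroid
    for m in ("middle_surface", "middle_right", "middle_left", "middle_deep"):
        d = base[m] - mid_centroid
        d[0] = 0.0
        paths[m] += np.outer(s_mid * r_s, d)
    hyoid_disp = np.outer(r_s, [sc.hyoid_protraction, sc.hyoid_elevation, 0.0])
    dorsal_hyoid = DORSAL_HYOID_BASE + hyoid_disp
    return paths, dorsal_hyoid


def _forward_deltas(sc: SwallowScenario, s_post: float, s_mid: float, d_ant: float):
    """(dAOT, dPOT, dTB) in mL between TBR onset and offset for given knobs."""
    frames = np.array([sc.tbr_onset, sc.tbr_offset])
    paths, hy = _tongue_paths(sc, s_post, s_mid, d_ant, frames)
    vols = []
    for i in range(2):
        mid = np.array([paths[m][i] for m in MIDDLE_RING_ORDER])
        post_order = ["posterior_right", "posterior_surface", "posterior_left"]
        post = np.vstack([hy[i], [paths[m][i] for m in post_order]])
        vols.append(
            frame_volumes(
                mid, post, paths["anterior"][i], paths["vallecula"][i],
                sc.ring_samples, sc.interior_spacing_factor,
            )
        )
    v0, v1 = vols
    return tuple(b - a for a, b in zip(v0, v1))


def _secant(fun, target, x0, x1, tol, max_iter):
    """1D secant iteration for fun(x) = target; volumes are near-linear in
    the deformation knobs so this converges in a handful of steps."""
    f0 = fun(x0) - target
    if abs(f0) <= tol:
        return x0, 1
    f1 = fun(x1) - target
    evals = 2
    while evals < max_iter:
        if abs(f1) <= tol:
            return x1, evals
        if f1 == f0:
            raise GenerationError("secant stalled (flat response)")
        x0, x1, f0 = x1, x1 - f1 * (x1 - x0) / (f1 - f0), f1
        f1 = fun(x1) - target
        evals += 1
    raise GenerationError(f"volume scale search did not converge in {max_iter} evaluations")


_KNOB_CACHE: dict = {}


def _knob_key(sc: SwallowScenario) -> tuple:
    """Deterministic deformation inputs (seed and noise do not enter)."""
    return (
        sc.n_frames, sc.tbr_onset, sc.tbr_offset,
        sc.posterior_surface_retraction, sc.posterior_deep_retraction,
        sc.vallecula_retraction, sc.posterior_lateral_retraction,
        sc.lateral_right_protraction, sc.lateral_left_protraction,
        sc.posterior_surface_elevation,
        sc.delta_aot_ml, sc.delta_pot_ml, sc.delta_tb_ml,
        sc.hyoid_protraction, sc.hyoid_elevation,
        sc.ring_samples, sc.interior_spacing_factor,
        sc.volume_tolerance, sc.max_iterations,
    )


def _solve_knobs(sc: SwallowScenario) -> dict:
    key = _knob_key(sc)
    if key in _KNOB_CACHE:
        return _KNOB_CACHE[key]

    def tol(target):
        return max(sc.volume_tolerance * abs(target), 0.002)

    evals = 0
    s_post, n = _secant(
        lambda s: _forward_deltas(sc, s, 0.0, 0.0)[2],
        sc.delta_tb_ml, 0.0, 1.0, tol(sc.delta_tb_ml), sc.max_iterations,
    )
    evals += n
    s_mid, n = _secant(
        lambda s: _forward_deltas(sc, s_post, s, 0.0)[1],
        sc.delta_pot_ml, 0.0, 0.05, tol(sc.delta_pot_ml), sc.max_iterations - evals,
    )
    evals += n
    d_ant, n = _secant(
        lambda d: _forward_deltas(sc, s_post, s_mid, d)[0],
        sc.delta_aot_ml, 0.0, 1.0, tol(sc.delta_aot_ml), sc.max_iterations - evals,
    )
    achieved = _forward_deltas(sc, s_post, s_mid, d_ant)
    info = {
        "s_post": s_post, "s_mid": s_mid, "d_ant": d_ant,
        "achieved_delta_aot_ml": achieved[0],
        "achieved_delta_pot_ml": achieved[1],
        "achieved_delta_tb_ml": achieved[2],
        "forward_evaluations": evals + n + 1,
    }
    _KNOB_CACHE[key] = info
    return info


def generate_tongue_deformation(sc: SwallowScenario) -> tuple[dict, np.ndarray, dict]:
    """Solve the deformation knobs for the scenario's volume targets and
    return (marker paths over all frames, dorsal-hyoid series, achieved info).

    The three knobs are solved sequentially (the dependence is triangular):
    posterior-ring expansion for the tongue-base target, middle-ring scaling
    for the posterior-oral-tongue target, then the anterior-apex correction
    for the anterior-oral-tongue target.  Raises :class:`GenerationError` if
    any 1D search fails to close within ``volume_tolerance`` (relative, with a
    0.002 mL floor) in ``max_iterations`` forward evaluations.  The solve is
    deterministic in the scenario's deformation targets and is cached on them.
    """
    info = _solve_knobs(sc)
    frames = np.arange(sc.n_frames)
    paths, hy = _tongue_paths(sc, info["s_post"], info["s_mid"], info["d_ant"], frames)
    return paths, hy, dict(info)


# ---------------------------------------------------------------------------
# Bone kinematics and EMG
# ---------------------------------------------------------------------------


def _gape_series(sc: SwallowScenario) -> np.ndarray:
    """Programmed jaw gape (degrees; 0 = intercuspation) with an exact static
    plateau of ``ip_plateau_frames`` frames starting at ``ip_start``."""
    f = np.arange(sc.n_frames, dtype=float)
    g = np.zeros(sc.n_frames)
    a = sc.ip_start
    b = a + sc.ip_plateau_frames
    close = f < a
    g[close] = 4.4 * (a - f[close]) / a  # linear fast close into the plateau
    open_start = b
    open_mid = min(sc.n_frames, sc.tbr_offset + 30)
    rise = (f >= open_start) & (f < open_mid)
    u = (f[rise] - open_start) / (open_mid - open_start)
    g[rise] = 6.0 * u * (0.4 + 0.6 * u)  # slow open, non-zero initial slope
    fast = f >= open_mid
    # fast open continues through the final frame (the jaw keeps depressing;
    # no trailing static segment that would mimic a second intercuspal phase)
    u = (f[fast] - open_mid) / max(sc.n_frames - 1 - open_mid, 1)
    g[fast] = 6.0 + 6.0 * (u * (0.3 + 0.7 * u))
    return g


def _rot_z(angle_rad: float) -> np.ndarray:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _mandible_trajectory(sc: SwallowScenario, gape_deg: np.ndarray) -> np.ndarray:
    """Mandible cluster rotated about the condylar Z axis by the gape angle
    (opening = negative rotation about +Z in this frame convention)."""
    out = np.empty((sc.n_frames, len(MANDIBLE_CLUSTER), 3))
    for i, g in enumerate(gape_deg):
        rot = _rot_z(-np.radians(g))
        out[i] = (MANDIBLE_CLUSTER - CONDYLE_CENTER) @ rot.T + CONDYLE_CENTER
    return out


def _muscle_attachment_paths(sc: SwallowScenario, hyoid_disp: np.ndarray, r_s: np.ndarray) -> dict:
    """Virtual intramuscular attachment trajectories realizing the programmed
    muscle length changes exactly (insertions slide along the line of action)."""
    n = sc.n_frames
    paths = {}
    # styloglossus: cranial origin fixed, insertion approaches it radially
    u0 = STYLOGLOSSUS_INSERTION0 - STYLOGLOSSUS_ORIGIN
    l0 = np.linalg.norm(u0)
    u0 = u0 / l0
    paths["styloglossus_origin"] = np.tile(STYLOGLOSSUS_ORIGIN, (n, 1))
    paths["styloglossus_insertion"] = (
        STYLOGLOSSUS_ORIGIN + np.outer(l0 + sc.styloglossus_delta * r_s, u0)
    )
    # hyoglossus: origin rides the hyoid; direction re-aims at the resting
    # insertion so the line of action rotates as the hyoid protracts
    org = HYOGLOSSUS_ORIGIN0 + hyoid_disp
    l0 = np.linalg.norm(HYOGLOSSUS_INSERTION0 - HYOGLOSSUS_ORIGIN0)
    dirs = HYOGLOSSUS_INSERTION0 - org
    dirs = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
    paths["hyoglossus_origin"] = org
    paths["hyoglossus_insertion"] = org + dirs * (l0 + sc.hyoglossus_delta * r_s)[:, None]
    # palatoglossus: palatal origin fixed, slight lengthening
    u0 = PALATOGLOSSUS_INSERTION0 - PALATOGLOSSUS_ORIGIN
    l0 = np.linalg.norm(u0)
    u0 = u0 / l0
    paths["palatoglossus_origin"] = np.tile(PALATOGLOSSUS_ORIGIN, (n, 1))
    paths["palatoglossus_insertion"] = (
        PALATOGLOSSUS_ORIGIN + np.outer(l0 + sc.palatoglossus_delta * r_s, u0)
    )
    return paths


def _emg_channels(sc: SwallowScenario, rng: np.random.Generator) -> tuple[dict, dict]:
    """Raw EMG channels (fs samples/s) with bursts time-locked to TBR phases."""
    duration = sc.n_frames / sc.frame_rate
    n = int(round(duration * sc.emg_fs))
    t_frame = sc.emg_fs / sc.frame_rate  # raw samples per motion frame
    onset, offset = sc.tbr_onset, sc.tbr_offset
    schedule = {
        "geniohyoid": [(onset, offset, 1.0)],
        "mylohyoid": [(onset - 40, onset + 10, 1.0)],
        "genioglossus": [(onset - 50, onset - 10, 1.0), (onset, offset, 0.3)],
        "anterior_digastric": [(onset - 35, onset, 1.0)],
        "styloglossus": [(onset, offset, 0.4)],
    }
    signals = {}
    truth = {}
    ramp = int(round(0.01 * sc.emg_fs))  # 10 ms envelope ramps
    for name, bursts in schedule.items():
        env = np.zeros(n)
        for f0, f1, rel in bursts:
            a, b = int(f0 * t_frame), int(f1 * t_frame)
            a, b = max(a, 0), min(b, n)
            env[a:b] = np.maximum(env[a:b], rel * sc.emg_burst_amplitude)
        if ramp > 1:
            kernel = np.ones(ramp) / ramp
            env = np.convolve(env, kernel, mode="same")
        noise = rng.normal(0.0, sc.emg_noise_sd, n)
        drive = rng.normal(0.0, 1.0, n)
        signals[name] = noise + env * drive
        truth[name] = [(int(f0), int(f1), rel) for f0, f1, rel in bursts]
    return signals, truth


# ---------------------------------------------------------------------------
# Oral-cavity boundary clouds
# ---------------------------------------------------------------------------


def _grid(xr, yr, zr, nx, ny, nz):
    xs = np.linspace(*xr, nx)
    ys = np.linspace(*yr, ny)
    zs = np.linspace(*zr, nz)
    pts = np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1).reshape(-1, 3)
    return pts


def oral_reference_clouds() -> dict:
    """Static reference landmark clouds for the oral-cavity boundary.

    Cloud sizes reproduce the order of magnitude of a posed bony-landmark set
    (the assembled total falls in the 4684-8308 range).
    """
    palate = _grid((2, 38), (9.5, 10.5), (-9, 9), 50, 2, 19)   # 1900
    wall_r = _grid((0, 36), (-2, 9), (8.5, 10), 44, 25, 2)     # 2200
    wall_l = wall_r * np.array([1.0, 1.0, -1.0])               # 2200
    symphysis = _grid((34, 36), (-4, 8), (-7, 7), 3, 13, 10)   # 390
    hyoid = _grid((-16, -12), (-8, 2), (-5, 5), 4, 11, 9)      # 396
    return {
        "palate": palate,
        "mandible_right": wall_r,
        "mandible_left": wall_l,
        "symphysis": symphysis,
        "hyoid": hyoid,
    }


RAPHE_HYOID_POLE = np.array([-14.0, -8.0, 0.0])   # inferior hyoid pole (ref)
RAPHE_SYMPHYSIS = np.array([34.0, -4.0, 0.0])     # symphysis point (ref)


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------


@dataclass
class SyntheticDataset:
    """One generated swallow trial plus its ground truth."""

    scenario: SwallowScenario
    tongue: MarkerTrajectorySet
    extra_points: dict                 # muscle attachments & dorsal hyoid (per-frame)
    hyoid_dorsal: np.ndarray
    cranium_ref: np.ndarray
    cranium: np.ndarray                # (n_frames, k, 3)
    mandible_ref: np.ndarray
    mandible: np.ndarray
    hyoid_ref: np.ndarray
    hyoid: np.ndarray
    palate_landmarks: np.ndarray
    midline_landmarks: np.ndarray
    oral_surfaces: dict
    gape_deg: np.ndarray
    emg: dict
    ground_truth: dict


def generate_scenario(sc: SwallowScenario) -> SyntheticDataset:
    """Generate a full synthetic swallow trial (deterministic given the seed)."""
    rng = np.random.default_rng(sc.seed)
    frames = np.arange(sc.n_frames)
    u = (frames - sc.tbr_onset) / (sc.tbr_offset - sc.tbr_onset)
    r_s = _smoothstep(u)

    paths, hyoid_dorsal, vol_info = generate_tongue_deformation(sc)
    hyoid_disp = np.outer(r_s, [sc.hyoid_protraction, sc.hyoid_elevation, 0.0])
    gape = _gape_series(sc)
    mandible = _mandible_trajectory(sc, gape)
    cranium = np.tile(CRANIUM_CLUSTER, (sc.n_frames, 1, 1))
    hyoid = HYOID_CLUSTER[None, :, :] + hyoid_disp[:, None, :]
    muscles = _muscle_attachment_paths(sc, hyoid_disp, r_s)
    emg, emg_truth = _emg_channels(sc, rng)

    names = list(TONGUE_BASE_POSITIONS)
    coords = np.stack([paths[m] for m in names], axis=1)
    if sc.marker_noise_sd > 0:
        coords = coords + rng.normal(0.0, sc.marker_noise_sd, coords.shape)
        mandible = mandible + rng.normal(0.0, sc.marker_noise_sd, mandible.shape)
        cranium = cranium + rng.normal(0.0, sc.marker_noise_sd, cranium.shape)
        hyoid = hyoid + rng.normal(0.0, sc.marker_noise_sd, hyoid.shape)
        muscles = {
            k: v + rng.normal(0.0, sc.marker_noise_sd, v.shape) for k, v in muscles.items()
        }
    tongue = MarkerTrajectorySet(sc.frame_rate, names, coords)

    palate_landmarks = _grid((5, 35), (10, 10), (-8, 8), 4, 1, 3)
    midline_landmarks = np.array([[0.0, 10.0, 0.0], [30.0, 10.0, 0.0]])

    # Programmed per-frame zero-velocity plateau of the gape trace: the
    # interior frames of the static plateau (discrete central differences
    # vanish there exactly).
    ip_truth = (sc.ip_start + 1, sc.ip_start + sc.ip_plateau_frames - 1)

    onset, offset = sc.tbr_onset, sc.tbr_offset
    ground_truth = {
        "tbr_onset": onset,
        "tbr_offset": offset,
        "ip_interval": ip_truth,
        "gape_deg": gape,
        "posterior_surface_retraction": sc.posterior_surface_retraction,
        "posterior_deep_retraction": sc.posterior_deep_retraction,
        "vallecula_retraction": sc.vallecula_retraction,
        "tb_length_increase": sc.vallecula_retraction - sc.posterior_lateral_retraction,
        "hyoid_protraction": sc.hyoid_protraction,
        "hyoid_elevation": sc.hyoid_elevation,
        "styloglossus_delta": sc.styloglossus_delta,
        "hyoglossus_delta": sc.hyoglossus_delta,
        "palatoglossus_delta": sc.palatoglossus_delta,
        "delta_aot_ml": vol_info["achieved_delta_aot_ml"],
        "delta_pot_ml": vol_info["achieved_delta_pot_ml"],
        "delta_tb_ml": vol_info["achieved_delta_tb_ml"],
        "volume_tuning": vol_info,
        "emg_bursts_frames": emg_truth,
    }
    extra = dict(muscles)
    extra["dorsal_hyoid"] = hyoid_dorsal
    extra["geniohyoid_origin"] = np.tile(GENIOHYOID_ORIGIN, (sc.n_frames, 1))
    extra["geniohyoid_insertion"] = HYOID_CENTER + np.array([4.0, 0.0, 0.0]) + hyoid_disp
    return SyntheticDataset(
        scenario=sc,
        tongue=tongue,
        extra_points=extra,
        hyoid_dorsal=hyoid_dorsal,
        cranium_ref=CRANIUM_CLUSTER.copy(),
        cranium=cranium,
        mandible_ref=MANDIBLE_CLUSTER.copy(),
        mandible=mandible,
        hyoid_ref=HYOID_CLUSTER.copy(),
        hyoid=hyoid,
        palate_landmarks=palate_landmarks,
        midline_landmarks=midline_landmarks,
        oral_surfaces=oral_reference_clouds(),
        gape_deg=gape,
        emg=emg,
        ground_truth=ground_truth,
    )


def generate_precision_trial(
    seed: int, n_frames: int = 400, noise_sd: float = 0.07, frame_rate: float = 200.0
) -> SyntheticDataset:
    """Static-specimen trial: the baseline constellation plus noise only."""
    sc = SwallowScenario(
        seed=seed, n_frames=n_frames, tbr_onset=1, tbr_offset=2,
        marker_noise_sd=noise_sd, frame_rate=frame_rate,
    )
    rng = np.random.default_rng(seed)
    names = list(TONGUE_BASE_POSITIONS)
    base = np.array([TONGUE_BASE_POSITIONS[m] for m in names])
    coords = np.tile(base, (n_frames, 1, 1))
    mandible = np.tile(MANDIBLE_CLUSTER, (n_frames, 1, 1))
    cranium = np.tile(CRANIUM_CLUSTER, (n_frames, 1, 1))
    hyoid = np.tile(HYOID_CLUSTER, (n_frames, 1, 1))
    if noise_sd > 0:
        coords = coords + rng.normal(0.0, noise_sd, coords.shape)
        mandible = mandible + rng.normal(0.0, noise_sd, mandible.shape)
        cranium = cranium + rng.normal(0.0, noise_sd, cranium.shape)
        hyoid = hyoid + rng.normal(0.0, noise_sd, hyoid.shape)
    tongue = MarkerTrajectorySet(frame_rate, names, coords)
    return SyntheticDataset(
        scenario=sc, tongue=tongue, extra_points={}, hyoid_dorsal=np.tile(DORSAL_HYOID_BASE, (n_frames, 1)),
        cranium_ref=CRANIUM_CLUSTER.copy(), cranium=cranium,
        mandible_ref=MANDIBLE_CLUSTER.copy(), mandible=mandible,
        hyoid_ref=HYOID_CLUSTER.copy(), hyoid=hyoid,
        palate_landmarks=_grid((5, 35), (10, 10), (-8, 8), 4, 1, 3),
        midline_landmarks=np.array([[0.0, 10.0, 0.0], [30.0, 10.0, 0.0]]),
        oral_surfaces=oral_reference_clouds(), gape_deg=np.zeros(n_frames),
        emg={}, ground_truth={"static": True},
    )


def correlated_cycle_summaries(
    r: float, n: int, seed: int, means=(4.23, -6.25), sds=(1.51, 1.88)
) -> np.ndarray:
    """(n, 2) per-cycle summaries (hyoid X, tongue-base X) with programmed
    population correlation ``r`` (bivariate normal, seeded)."""
    rng = np.random.default_rng(seed)
    cov = np.array([[sds[0] ** 2, r * sds[0] * sds[1]],
                    [r * sds[0] * sds[1], sds[1] ** 2]])
    return rng.multivariate_normal(np.asarray(means, float), cov, size=n)
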