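"""Ground-truth tissue models and synthetic multi-electrode recordings.

The generator emulates an ex vivo left-atrium preparation on a 5x5 bipolar grid
(0.5 mm pitch, 2 kHz sampling): a spatially correlated log-normal conduction-speed
field, wavefront propagation as shortest-path travel times on an 8-connected fine
lattice, symmetric biphasic electrogram deflections centred at the local activation
time, an all-or-none capture rule driven by a saturating-exponential ERP
restitution, and piecewise-linear intracellular action potentials realizing
commanded APD20/50/90 targets.  Every generator is bit-reproducible given its
parameters and seed, and each synthetic recording carries a ground-truth sidecar
for recovery testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse
from scipy.ndimage import gaussian_filter
from scipy.sparse.csgraph import dijkstra

from .cellular_metrics import APTrace
from .errors import InvalidParameterError, OutOfDomainError, ResolutionError
from .pacing_analysis import ProtocolConfig, default_protocol
from .recording_io import ElectrodeGrid, Recording, StimulusEvent, StimulusLog

#: default fine-lattice spacing (mm); 5 nodes per 0.5 mm electrode pitch
FINE_SPACING_MM = 0.1
#: margin of simulated tissue beyond the electrode footprint (mm), so that a
#: corner stimulus clears the post-stimulus blanking at the nearest electrode;
#: a multiple of the fine spacing so electrodes sit exactly on lattice nodes
TISSUE_MARGIN_MM = 0.8
#: characteristic electrogram deflection width (ms)
WAVELET_WIDTH_MS = 4.0
#: default deflection amplitude (mV)
WAVELET_AMPLITUDE_MV = 1.0
SAMPLING_RATE_HZ = 2000.0


# ---------------------------------------------------------------------------
# tissue model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TissueModel:
    """Ground-truth parameters of one synthetic preparation.

    ERP restitution: ``ERP(CL) = erp_min + erp_gain * (1 - exp(-CL / erp_tau))``,
    strictly increasing in cycle length whenever ``erp_gain > 0`` (refractoriness
    shortens at faster rates).  APD rate adaptation is not modelled.
    """

    velocity_mean_mps: float = 0.341
    velocity_cv_frac: float = 0.15
    erp_min_ms: float = 50.0
    erp_gain_ms: float = 76.0
    erp_tau_ms: float = 2000.0
    apd_targets_ms: tuple[float, float, float] = (8.93, 19.94, 49.31)
    correlation_length_mm: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.velocity_mean_mps <= 0:
            raise InvalidParameterError("velocity_mean must be positive")
        if self.velocity_cv_frac < 0:
            raise InvalidParameterError("velocity_cv_frac must be >= 0")
        if self.erp_min_ms <= 0 or self.erp_tau_ms <= 0 or self.erp_gain_ms < 0:
            raise InvalidParameterError("invalid restitution parameters")
        a, b, c = self.apd_targets_ms
        if not 0 < a < b < c:
            raise InvalidParameterError("apd_targets must be strictly increasing and positive")

    def erp_true_ms(self, cycle_length_ms: float) -> float:
        return self.erp_min_ms + self.erp_gain_ms * (
            1.0 - math.exp(-cycle_length_ms / self.erp_tau_ms)
        )


@dataclass
class VelocityField:
    """Per-node conduction speed (m/s == mm/ms) on a fine regular lattice."""

    origin_mm: tuple[float, float]
    spacing_mm: float
    speeds: np.ndarray  # (ny, nx)

    def __post_init__(self) -> None:
        self.speeds = np.asarray(self.speeds, dtype=float)
        if np.any(self.speeds <= 0):
            raise InvalidParameterError("all speeds must be positive")
        if self.spacing_mm > FINE_SPACING_MM + 1e-12:
            raise InvalidParameterError(
                f"fine spacing must be <= {FINE_SPACING_MM} mm for adequate resolution"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.speeds.shape

    def node_coords_mm(self) -> tuple[np.ndarray, np.ndarray]:
        ny, nx = self.speeds.shape
        x = self.origin_mm[0] + np.arange(nx) * self.spacing_mm
        y = self.origin_mm[1] + np.arange(ny) * self.spacing_mm
        return x, y

    def bounds_mm(self) -> tuple[float, float, float, float]:
        ny, nx = self.speeds.shape
        x0, y0 = self.origin_mm
        return (x0, y0, x0 + (nx - 1) * self.spacing_mm, y0 + (ny - 1) * self.spacing_mm)

    def nearest_node(self, position_mm: tuple[float, float]) -> tuple[int, int]:
        x0, y0, x1, y1 = self.bounds_mm()
        px, py = position_mm
        tol = 1e-9
        if not (x0 - tol <= px <= x1 + tol and y0 - tol <= py <= y1 + tol):
            raise OutOfDomainError(f"position {position_mm} outside field bounds {self.bounds_mm()}")
        ix = int(round((px - x0) / self.spacing_mm))
        iy = int(round((py - y0) / self.spacing_mm))
        return iy, ix


@dataclass
class ActivationField:
    """Per-fine-node activation time (ms, relative to the stimulus)."""

    origin_mm: tuple[float, float]
    spacing_mm: float
    times_ms: np.ndarray  # (ny, nx)
    stim_node: tuple[int, int]

    def __post_init__(self) -> None:
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        if not np.all(np.isfinite(self.times_ms)) or np.any(self.times_ms < 0):
            raise InvalidParameterError("activation times must be finite and >= 0")

    def sample_at(self, positions_mm: np.ndarray) -> np.ndarray:
        """Activation times at arbitrary positions (nearest fine node)."""
        x0, y0 = self.origin_mm
        ix = np.rint((positions_mm[:, 0] - x0) / self.spacing_mm).astype(int)
        iy = np.rint((positions_mm[:, 1] - y0) / self.spacing_mm).astype(int)
        ny, nx = self.times_ms.shape
        if ix.min() < 0 or iy.min() < 0 or ix.max() >= nx or iy.max() >= ny:
            raise OutOfDomainError("sample position outside the activation field")
        return self.times_ms[iy, ix]


# ---------------------------------------------------------------------------
# velocity-field and activation-field construction
# ---------------------------------------------------------------------------

def build_velocity_field(
    grid: ElectrodeGrid,
    mean_speed_mps: float,
    cv_frac: float,
    correlation_length_mm: float = 0.4,
    seed: int | None = None,
    *,
    fine_spacing_mm: float = FINE_SPACING_MM,
    margin_mm: float = TISSUE_MARGIN_MM,
) -> VelocityField:
    """Log-normal spatially correlated speed field over the electrode footprint
    plus a tissue margin.

    White Gaussian noise is smoothed with a Gaussian kernel of scale
    ``correlation_length_mm``, renormalized to unit sample variance, exponentiated
    to a log-normal with coefficient of variation ``cv_frac``, and rescaled so the
    sample mean equals ``mean_speed_mps`` exactly.  ``cv_frac = 0`` yields a
    constant field and consumes no randomness.
    """
    if mean_speed_mps <= 0:
        raise InvalidParameterError("mean_speed must be positive")
    if correlation_length_mm <= 0:
        raise InvalidParameterError("correlation_length must be positive")
    if cv_frac < 0:
        raise InvalidParameterError("cv_frac must be >= 0")

    x0, y0, x1, y1 = grid.bounds_mm()
    ox, oy = x0 - margin_mm, y0 - margin_mm
    nx = int(round((x1 - x0 + 2 * margin_mm) / fine_spacing_mm)) + 1
    ny = int(round((y1 - y0 + 2 * margin_mm) / fine_spacing_mm)) + 1

    if cv_frac == 0:
        speeds = np.full((ny, nx), mean_speed_mps)
    else:
        rng = np.random.default_rng(seed)
        z = rng.standard_normal((ny, nx))
        z = gaussian_filter(z, sigma=correlation_length_mm / fine_spacing_mm, mode="reflect")
        z = (z - z.mean()) / z.std()
        sigma_ln = math.sqrt(math.log(1.0 + cv_frac**2))
        speeds = mean_speed_mps * np.exp(sigma_ln * z - 0.5 * sigma_ln**2)
        speeds *= mean_speed_mps / speeds.mean()
    return VelocityField(origin_mm=(ox, oy), spacing_mm=fine_spacing_mm, speeds=speeds)


def simulate_activation(
    field: VelocityField, stim_position_mm: tuple[float, float]
) -> ActivationField:
    """Wavefront arrival times as minimal travel times over 8-connected lattice
    paths, with per-edge time = edge length / harmonic mean of endpoint speeds.

    On a constant field this reproduces d / v exactly along lattice axes and
    diagonals, and overestimates oblique directions by at most sec(22.5 deg) - 1
    (about 8.3%), the usual octile-distance bound.
    """
    iy0, ix0 = field.nearest_node(stim_position_mm)
    ny, nx = field.shape
    n = ny * nx
    inv = 1.0 / field.speeds  # slowness, ms/mm
    h = field.spacing_mm

    rows_l: list[np.ndarray] = []
    cols_l: list[np.ndarray] = []
    wts_l: list[np.ndarray] = []
    idx = np.arange(n).reshape(ny, nx)
    for dy, dx in ((0, 1), (1, 0), (1, 1), (1, -1)):
        sy = slice(max(0, -dy), ny - max(0, dy))
        sx = slice(max(0, -dx), nx - max(0, dx))
        ty = slice(max(0, dy), ny - max(0, -dy))
        tx = slice(max(0, dx), nx - max(0, -dx))
        src = idx[sy, sx].ravel()
        dst = idx[ty, tx].ravel()
        length = h * math.hypot(dy, dx)
        w = length * 0.5 * (inv[sy, sx].ravel() + inv[ty, tx].ravel())
        rows_l.append(src)
        cols_l.append(dst)
        wts_l.append(w)
    graph = sparse.csr_matrix(
        (np.concatenate(wts_l), (np.concatenate(rows_l), np.concatenate(cols_l))),
        shape=(n, n),
    )
    times = dijkstra(graph, directed=False, indices=idx[iy0, ix0])
    return ActivationField(
        origin_mm=field.origin_mm,
        spacing_mm=field.spacing_mm,
        times_ms=times.reshape(ny, nx),
        stim_node=(iy0, ix0),
    )


def planar_activation_field(
    grid: ElectrodeGrid,
    speed_mps: float,
    direction_deg: float = 0.0,
    *,
    fine_spacing_mm: float = FINE_SPACING_MM,
    margin_mm: float = TISSUE_MARGIN_MM,
) -> ActivationField:
    """Analytic planar wavefront: T(p) = ((p - p0) . n) / v, with the base point p0
    chosen on the margin boundary so every electrode activates strictly after the
    stimulus (clearing the post-stimulus blanking)."""
    if speed_mps <= 0:
        raise InvalidParameterError("speed must be positive")
    x0, y0, x1, y1 = grid.bounds_mm()
    ox, oy = x0 - margin_mm, y0 - margin_mm
    nx = int(round((x1 - x0 + 2 * margin_mm) / fine_spacing_mm)) + 1
    ny = int(round((y1 - y0 + 2 * margin_mm) / fine_spacing_mm)) + 1
    nvec = np.array([math.cos(math.radians(direction_deg)), math.sin(math.radians(direction_deg))])
    xs = ox + np.arange(nx) * fine_spacing_mm
    ys = oy + np.arange(ny) * fine_spacing_mm
    xx, yy = np.meshgrid(xs, ys)
    proj = xx * nvec[0] + yy * nvec[1]
    times = (proj - proj.min()) / speed_mps
    stim_flat = int(np.argmin(times))
    return ActivationField(
        origin_mm=(ox, oy),
        spacing_mm=fine_spacing_mm,
        times_ms=times,
        stim_node=(stim_flat // nx, stim_flat % nx),
    )


def corner_position(field_or_grid, corner: str) -> tuple[float, float]:
    """Stimulation-corner coordinates: LAA at the (xmin, ymin) corner of the
    tissue, LAFW at the opposite corner."""
    x0, y0, x1, y1 = field_or_grid.bounds_mm()
    if corner == "LAA":
        return (x0, y0)
    if corner == "LAFW":
        return (x1, y1)
    raise InvalidParameterError(f"unknown corner {corner!r}")


# ---------------------------------------------------------------------------
# electrogram synthesis
# ---------------------------------------------------------------------------

def biphasic_wavelet(t_ms: np.ndarray, amplitude_mv: float = WAVELET_AMPLITUDE_MV) -> np.ndarray:
    """Symmetric biphasic deflection (difference of Gaussians) with its maximum
    absolute deviation exactly at t = 0 and characteristic width ~4 ms."""
    s1 = WAVELET_WIDTH_MS / 5.0
    s2 = 2.0 * s1
    w = np.exp(-(t_ms**2) / (2 * s1**2)) - 0.6 * np.exp(-(t_ms**2) / (2 * s2**2))
    return amplitude_mv * w / 0.4


_WAVELET_SUPPORT_MS = 4.0 * (WAVELET_WIDTH_MS / 5.0) * 2.0  # 4 sigma of the broad lobe


def _check_resolution(sampling_rate_hz: float) -> float:
    dt = 1000.0 / sampling_rate_hz
    if dt > 1.0:
        raise ResolutionError(
            f"sampling period {dt:g} ms too coarse to place deflections (need <= 1 ms)"
        )
    return dt


def _insert_deflections(
    traces: np.ndarray,
    dt_ms: float,
    centers_ms: np.ndarray,
    amplitude_mv: float,
) -> None:
    """Add one wavelet per channel, centred at ``centers_ms`` (continuous times)."""
    n_ch, n_samp = traces.shape
    half = int(np.ceil(_WAVELET_SUPPORT_MS / dt_ms))
    i0 = np.rint(centers_ms / dt_ms).astype(int) - half
    offs = np.arange(2 * half + 1)
    idx = i0[:, None] + offs[None, :]
    valid = (idx >= 0) & (idx < n_samp)
    t_rel = idx * dt_ms - centers_ms[:, None]
    w = biphasic_wavelet(t_rel, amplitude_mv)
    flat = (np.arange(n_ch)[:, None] * n_samp + idx)[valid]
    np.add.at(traces.ravel(), flat, w[valid])


def _snap(t_ms: float, dt_ms: float) -> float:
    return round(t_ms / dt_ms) * dt_ms


def synthesize_s1_train(
    act: ActivationField,
    grid: ElectrodeGrid,
    cycle_length_ms: float,
    n_beats: int = 8,
    *,
    corner: str = "LAA",
    noise_sd_mv: float = 0.0,
    seed: int | None = None,
    sampling_rate_hz: float = SAMPLING_RATE_HZ,
    amplitude_mv: float = WAVELET_AMPLITUDE_MV,
    pre_ms: float = 50.0,
    tail_ms: float = 60.0,
    tissue: TissueModel | None = None,
) -> Recording:
    """Constant-capture S1 drive train used for conduction mapping."""
    if noise_sd_mv < 0:
        raise InvalidParameterError("noise_sd must be >= 0")
    dt = _check_resolution(sampling_rate_hz)
    lats = act.sample_at(grid.positions_mm())
    t0 = _snap(pre_ms, dt)
    stim_times = [t0 + k * cycle_length_ms for k in range(n_beats)]
    duration = stim_times[-1] + float(lats.max()) + tail_ms
    n_samp = int(round(duration / dt)) + 1
    traces = np.zeros((grid.n_channels, n_samp))
    events = []
    for st in stim_times:
        _insert_deflections(traces, dt, st + lats, amplitude_mv)
        events.append(
            StimulusEvent(t_ms=st, kind="S1", corner=corner, cl_ms=cycle_length_ms)
        )
    if noise_sd_mv > 0:
        rng = np.random.default_rng(seed)
        traces += rng.normal(0.0, noise_sd_mv, traces.shape)
    truth = {
        "lat_ms": {grid.channel_names()[i]: float(lats[i]) for i in range(grid.n_channels)},
        "corner": corner,
        "cycle_length_ms": cycle_length_ms,
    }
    if tissue is not None:
        truth["apd_targets_ms"] = list(tissue.apd_targets_ms)
    return Recording(
        grid=grid,
        sampling_rate_hz=sampling_rate_hz,
        traces=traces,
        stimulus_log=StimulusLog(events),
        truth=truth,
    )


def synthesize_erp_sweep(
    act: ActivationField,
    grid: ElectrodeGrid,
    tissue: TissueModel,
    cycle_length_ms: float,
    protocol: ProtocolConfig | None = None,
    *,
    corner: str = "LAA",
    replicate: int = 0,
    noise_sd_mv: float = 0.0,
    seed: int | None = None,
    sampling_rate_hz: float = SAMPLING_RATE_HZ,
    amplitude_mv: float = WAVELET_AMPLITUDE_MV,
) -> Recording:
    """One decremental S1-S2 sweep: drive trains with a premature S2 whose coupling
    interval decrements until the first failure to capture.

    An S2 captures iff its coupling interval is >= the tissue's true ERP at the
    drive cycle length (all-or-none capture, no local block).  If the true ERP is
    at or above the starting coupling interval, the sweep restarts from the drive
    cycle length (extended-start rule).
    """
    protocol = protocol or default_protocol()
    if noise_sd_mv < 0:
        raise InvalidParameterError("noise_sd must be >= 0")
    dt = _check_resolution(sampling_rate_hz)
    cl = float(cycle_length_ms)
    erp_t = tissue.erp_true_ms(cl)
    if cl <= erp_t:
        raise InvalidParameterError(
            f"cycle length {cl} ms is within the refractory period ({erp_t:.1f} ms)"
        )
    start = protocol.s2_start_ms
    if erp_t >= start:
        start = cl  # extended-start rule: sweep from the drive cycle length
    cis: list[float] = []
    ci = start
    while ci >= protocol.s2_decrement_ms:
        cis.append(ci)
        if ci < erp_t:  # first failure ends the sweep
            break
        ci -= protocol.s2_decrement_ms

    lats = act.sample_at(grid.positions_mm())
    lat_max = float(lats.max())
    gap = 200.0
    events: list[StimulusEvent] = []
    captured_flags: list[bool] = []
    t0 = _snap(50.0, dt)
    for ci in cis:
        s1_times = [t0 + k * cl for k in range(protocol.n_s1)]
        s2_time = s1_times[-1] + ci
        for st in s1_times:
            events.append(
                StimulusEvent(t_ms=st, kind="S1", corner=corner, cl_ms=cl, replicate=replicate)
            )
        events.append(
            StimulusEvent(
                t_ms=s2_time, kind="S2", corner=corner, ci_ms=ci, cl_ms=cl, replicate=replicate
            )
        )
        captured_flags.append(ci >= erp_t)
        t0 = _snap(s2_time + lat_max + gap, dt)

    duration = events[-1].t_ms + lat_max + 60.0
    n_samp = int(round(duration / dt)) + 1
    traces = np.zeros((grid.n_channels, n_samp))
    for ev in events:
        if ev.kind == "S1" or (ev.ci_ms is not None and ev.ci_ms >= erp_t):
            _insert_deflections(traces, dt, ev.t_ms + lats, amplitude_mv)
    if noise_sd_mv > 0:
        rng = np.random.default_rng(seed)
        traces += rng.normal(0.0, noise_sd_mv, traces.shape)

    truth = {
        "lat_ms": {grid.channel_names()[i]: float(lats[i]) for i in range(grid.n_channels)},
        "erp_true_ms": {f"{cl:g}": erp_t},
        "s2_captured": captured_flags,
        "corner": corner,
        "cycle_length_ms": cl,
        "replicate": replicate,
    }
    return Recording(
        grid=grid,
        sampling_rate_hz=sampling_rate_hz,
        traces=traces,
        stimulus_log=StimulusLog(events),
        truth=truth,
    )


def synthesize_recording(
    act: ActivationField,
    grid: ElectrodeGrid,
    protocol: ProtocolConfig,
    tissue: TissueModel,
    noise_sd_mv: float = 0.0,
    seed: int | None = None,
    *,
    corner: str = "LAA",
    cycle_length_ms: float | None = None,
    replicate: int = 0,
) -> Recording:
    """Protocol-level entry point: one S1-S2 sweep recording for one corner and cycle
    length (defaulting to the protocol's first cycle length)."""
    cl = cycle_length_ms if cycle_length_ms is not None else protocol.cycle_lengths_ms[0]
    return synthesize_erp_sweep(
        act,
        grid,
        tissue,
        cl,
        protocol,
        corner=corner,
        replicate=replicate,
        noise_sd_mv=noise_sd_mv,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# intracellular action potentials
# ---------------------------------------------------------------------------

def synthesize_action_potential(
    apd_targets_ms: tuple[float, float, float],
    rest_mv: float = -80.0,
    peak_mv: float = 20.0,
    sampling_rate_hz: float = SAMPLING_RATE_HZ,
    *,
    upstroke_ms: float = 50.0,
    plateau_ms: float = 2.5,
    duration_ms: float | None = None,
    noise_sd_mv: float = 0.0,
    seed: int | None = None,
) -> APTrace:
    """Monotone-repolarizing piecewise-linear action potential whose APD20/50/90,
    measured from the maximum-upstroke time, equal the commanded targets.

    The upstroke is a single-sample depolarization at ``upstroke_ms`` (snapped to
    the sample grid), followed by a short plateau and linear segments through the
    three repolarization anchors; the terminal limb continues the APD50-to-APD90
    slope down to rest so the 90% level is crossed without a slope break.
    """
    a20, a50, a90 = (float(x) for x in apd_targets_ms)
    if not 0 < a20 < a50 < a90:
        raise InvalidParameterError("apd_targets must be strictly increasing and positive")
    if peak_mv <= rest_mv:
        raise InvalidParameterError("peak must exceed resting potential")
    dt = 1000.0 / sampling_rate_hz
    plateau = min(plateau_ms, 0.5 * a20)
    amp = peak_mv - rest_mv
    t_up = _snap(upstroke_ms, dt)
    tail = 0.25 * (a90 - a50)  # continues the 50->90 slope from 90% down to rest
    if duration_ms is None:
        duration_ms = t_up + a90 + tail + 40.0
    anchors_t = np.array([0.0, t_up - dt, t_up, t_up + plateau, t_up + a20, t_up + a50, t_up + a90, t_up + a90 + tail, duration_ms])
    anchors_v = np.array([rest_mv, rest_mv, peak_mv, peak_mv, peak_mv - 0.2 * amp, peak_mv - 0.5 * amp, peak_mv - 0.9 * amp, rest_mv, rest_mv])
    t = np.arange(int(round(duration_ms / dt)) + 1) * dt
    v = np.interp(t, anchors_t, anchors_v)
    if noise_sd_mv > 0:
        rng = np.random.default_rng(seed)
        v = v + rng.normal(0.0, noise_sd_mv, v.shape)
    return APTrace(voltage_mv=v, sampling_rate_hz=sampling_rate_hz)


# ---------------------------------------------------------------------------
# presets: group means used as ground-truth simulation settings
# ---------------------------------------------------------------------------

#: Conduction-speed means (m/s), APD triples (ms) and restitution parameters are
#: the published group means used here as simulation ground truth; the velocity
#: heterogeneity fractions are generator settings chosen so the emergent
#: conduction-heterogeneity index reproduces the groups' ordering.
PRESETS: dict[str, TissueModel] = {
    "wt-young": TissueModel(
        velocity_mean_mps=0.341,
        velocity_cv_frac=0.15,
        erp_min_ms=45.0,
        erp_gain_ms=76.0,
        erp_tau_ms=2000.0,
        apd_targets_ms=(8.93, 19.94, 49.31),
    ),
    "hcm-young": TissueModel(
        velocity_mean_mps=0.323,
        velocity_cv_frac=0.30,
        erp_min_ms=44.0,
        erp_gain_ms=76.0,
        erp_tau_ms=2000.0,
        apd_targets_ms=(4.74, 12.19, 33.09),
    ),
    "wt-aged": TissueModel(
        velocity_mean_mps=0.353,
        velocity_cv_frac=0.15,
        erp_min_ms=50.0,
        erp_gain_ms=76.0,
        erp_tau_ms=2000.0,
        apd_targets_ms=(8.93, 19.94, 49.31),
    ),
    "hcm-aged": TissueModel(
        velocity_mean_mps=0.251,
        velocity_cv_frac=0.30,
        erp_min_ms=58.0,
        erp_gain_ms=28.0,
        erp_tau_ms=170.0,
        apd_targets_ms=(4.74, 12.19, 33.09),
    ),
}

#: default additive per-sample electrogram noise (mV) for preset simulations
PRESET_NOISE_SD_MV = 0.05
#: default additive intracellular noise (mV) for preset simulations
PRESET_AP_NOISE_SD_MV = 0.5


def preset_tissue(name: str, seed: int = 0) -> TissueModel:
    if name not in PRESETS:
        raise InvalidParameterError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return replace(PRESETS[name], seed=seed)
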