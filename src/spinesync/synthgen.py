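"""Seeded generators of synthetic imaging data with machine-readable truth.

Three generators cover the three experimental geometries:

``simulate_spine_recording``
    A dendritic spine and its parent dendrite. Back-propagating action
    potentials (BPs) appear in both traces at identical times; local
    synaptic events appear in the spine trace only. The local event process
    is inhomogeneous Poisson whose rate is multiplied inside
    microglia-contact epochs.

``simulate_population``
    A field of neurons with 2D positions. Shared "assembly" events recruit
    neurons with probability decaying exponentially with distance from the
    event center, producing distance-dependent pairwise synchrony on top of
    independent background events.

``simulate_contact_stack``
    A two-channel (red = spine, green = microglia) T x Z x Y x X stack in
    which a microglial process blob approaches a static spine blob and
    overlaps it in >= 2 Z sections exactly during the programmed epochs.

All events are convolved with a difference-of-exponentials kernel with
GCaMP6f-like kinetics (rise 0.07 s, decay 0.6 s), and traces carry additive
Gaussian noise plus a slow sinusoidal drift so that detrending is exercised.
Identical (config, seed) reproduces bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import InvalidConfigError
from .traces import FluorescenceTrace

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_spine_recording",
    "simulate_population",
    "simulate_contact_stack",
    "render_cell_stack",
    "write_spine_recording",
    "write_population",
    "write_contact_stack",
]


@dataclass(frozen=True)
class SimulationConfig:
    """All generator parameters with acquisition-matched defaults.

    Defaults describe spine/dendrite imaging (0.242-s frames, 3000 frames =
    ~12 min); :meth:`population` returns the population-imaging preset
    (0.390-s frames, 424.27-um field). Rates are events/s; amplitudes are in
    ΔF/F units.
    """

    seed: int = 0
    n_frames: int = 3000
    frame_interval_s: float = 0.242
    rate_local_hz: float = 0.010
    rate_bp_hz: float = 0.074
    contact_rate_multiplier: float = 2.0
    contact_duration_s: float = 300.0
    kernel_rise_s: float = 0.07
    kernel_decay_s: float = 0.6
    amplitude_dff: float = 0.4
    noise_sd: float = 0.05
    drift_amplitude: float = 0.12
    drift_period_s: float = 120.0
    n_neurons: int = 60
    field_size_um: float = 424.27
    assembly_decay_length_um: float = 50.0
    assembly_rate_hz: float = 0.10
    p_join_at_zero: float = 0.9

    def __post_init__(self) -> None:
        numeric = {
            f.name: getattr(self, f.name)
            for f in dataclasses.fields(self)
            if f.name != "seed"
        }
        for name, val in numeric.items():
            if name == "assembly_decay_length_um":
                # +inf means no spatial decay and is explicitly allowed
                if np.isnan(val) or val < 0:
                    raise InvalidConfigError(f"{name} must be nonnegative")
                continue
            if not np.isfinite(val) or val < 0:
                raise InvalidConfigError(f"{name} must be finite and nonnegative")
        if self.frame_interval_s <= 0:
            raise InvalidConfigError("frame_interval_s must be positive")
        if self.n_frames < 1:
            raise InvalidConfigError("n_frames must be >= 1")
        if not (0 <= self.p_join_at_zero <= 1):
            raise InvalidConfigError("p_join_at_zero must be a probability")
        if self.drift_amplitude > 0 and self.drift_period_s <= 0:
            raise InvalidConfigError("drift_period_s must be positive when drift is on")
        if self.kernel_decay_s <= 0:
            raise InvalidConfigError("kernel_decay_s must be positive")

    @classmethod
    def population(cls, **overrides) -> "SimulationConfig":
        """Population-imaging preset: 0.390-s frames, higher somatic rate."""
        params = dict(
            frame_interval_s=0.390,
            n_frames=3000,
            rate_local_hz=0.040,
        )
        params.update(overrides)
        return cls(**params)

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.frame_interval_s


@dataclass
class GroundTruth:
    """Machine-readable ground truth accompanying every synthetic dataset."""

    local_event_times_s: dict = field(default_factory=dict)
    bp_event_times_s: dict = field(default_factory=dict)
    contact_epochs: list = field(default_factory=list)
    neuron_positions_um: np.ndarray | None = None
    assembly_event_times_s: np.ndarray | None = None
    assembly_memberships: list | None = None
    contact_z_overlap: np.ndarray | None = None
    spine_mask: np.ndarray | None = None


# ---------------------------------------------------------------------------
# kernels and trace rendering
# ---------------------------------------------------------------------------


def _kernel_norm(rise: float, decay: float) -> float:
    """Peak value of exp(-t/decay) - exp(-t/rise), for peak normalization."""
    if rise <= 0:
        return 1.0
    if rise >= decay:
        raise InvalidConfigError("kernel_rise_s must be smaller than kernel_decay_s")
    t_peak = rise * decay / (decay - rise) * np.log(decay / rise)
    return float(np.exp(-t_peak / decay) - np.exp(-t_peak / rise))


def _render_events(
    event_times: np.ndarray, times_s: np.ndarray, cfg: SimulationConfig
) -> np.ndarray:
    """Superpose one peak-normalized kernel per event, scaled to amplitude."""
    sig = np.zeros_like(times_s)
    if len(event_times) == 0 or cfg.amplitude_dff == 0:
        return sig
    norm = _kernel_norm(cfg.kernel_rise_s, cfg.kernel_decay_s)
    for e in np.asarray(event_times, dtype=float):
        tau = times_s - e
        m = tau >= 0
        k = np.exp(-tau[m] / cfg.kernel_decay_s)
        if cfg.kernel_rise_s > 0:
            k = k - np.exp(-tau[m] / cfg.kernel_rise_s)
        sig[m] += cfg.amplitude_dff * k / norm
    return sig


def _noise_and_drift(rng: np.random.Generator, times_s, cfg: SimulationConfig):
    noise = rng.normal(0.0, cfg.noise_sd, times_s.size) if cfg.noise_sd > 0 else 0.0
    if cfg.drift_amplitude > 0:
        phase = rng.uniform(0, 2 * np.pi)
        drift = cfg.drift_amplitude * np.sin(2 * np.pi * times_s / cfg.drift_period_s + phase)
    else:
        drift = 0.0
    return noise + drift


def _poisson_times(rng: np.random.Generator, rate_hz: float, t0: float, t1: float):
    if rate_hz <= 0 or t1 <= t0:
        return np.empty(0)
    n = rng.poisson(rate_hz * (t1 - t0))
    return np.sort(rng.uniform(t0, t1, n))


def _local_event_times(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    epochs_s: list[tuple[float, float]],
) -> np.ndarray:
    """Inhomogeneous Poisson times: base rate outside epochs, multiplied inside."""
    edges = [0.0]
    for s, e in sorted(epochs_s):
        edges.extend([s, e])
    edges.append(cfg.duration_s)
    times = []
    inside = False
    for t0, t1 in zip(edges[:-1], edges[1:]):
        rate = cfg.rate_local_hz * (cfg.contact_rate_multiplier if inside else 1.0)
        times.append(_poisson_times(rng, rate, t0, t1))
        inside = not inside
    return np.sort(np.concatenate(times)) if times else np.empty(0)


# ---------------------------------------------------------------------------
# spine + dendrite recording
# ---------------------------------------------------------------------------


def simulate_spine_recording(
    config: SimulationConfig,
    contact_epochs_s: list[tuple[float, float]] | None = None,
):
    """Simulate one spine trace, its parent-dendrite trace, and ground truth.

    BP events (rate ``rate_bp_hz``) are injected into both traces at
    identical times; local synaptic events into the spine trace only, at
    ``rate_local_hz`` outside contact epochs and ``rate_local_hz x
    contact_rate_multiplier`` inside. If no epochs are supplied a single
    epoch of ``contact_duration_s`` is placed mid-recording.
    """
    rng = np.random.default_rng(config.seed)
    D = config.duration_s
    if contact_epochs_s is None:
        if config.contact_duration_s > 0:
            half = min(config.contact_duration_s, D) / 2.0
            contact_epochs_s = [(D / 2 - half, D / 2 + half)]
        else:
            contact_epochs_s = []
    for s, e in contact_epochs_s:
        if not (0 <= s < e <= D):
            raise InvalidConfigError("contact epochs must satisfy 0 <= start < end <= duration")

    local = _local_event_times(rng, config, contact_epochs_s)
    bp = _poisson_times(rng, config.rate_bp_hz, 0.0, D)

    times = (np.arange(config.n_frames) + 0.5) * config.frame_interval_s
    spine_sig = _render_events(np.concatenate([local, bp]), times, config)
    dend_sig = _render_events(bp, times, config)
    spine = FluorescenceTrace(
        spine_sig + _noise_and_drift(rng, times, config),
        config.frame_interval_s,
        roi_id="spine0",
        state="raw",
    )
    dend = FluorescenceTrace(
        dend_sig + _noise_and_drift(rng, times, config),
        config.frame_interval_s,
        roi_id="dendrite0",
        state="raw",
    )
    truth = GroundTruth(
        local_event_times_s={"spine0": local},
        bp_event_times_s={"dendrite0": bp},
        contact_epochs=[("spine0", s, e) for s, e in contact_epochs_s],
    )
    return spine, dend, truth


# ---------------------------------------------------------------------------
# neuronal population with distance-decaying shared events
# ---------------------------------------------------------------------------


def simulate_population(config: SimulationConfig):
    """Simulate a 2D neuronal population with distance-dependent synchrony.

    Positions are uniform in a square field of side ``field_size_um``.
    Assembly events occur at ``assembly_rate_hz``; each has a random center
    and recruits neuron i with probability ``p_join_at_zero *
    exp(-d_i / assembly_decay_length_um)``. Recruited neurons share the
    event time; every neuron also gets independent background events at
    ``rate_local_hz``.
    """
    if config.n_neurons < 2:
        raise InvalidConfigError("simulate_population requires n_neurons >= 2")
    rng = np.random.default_rng(config.seed)
    D = config.duration_s
    n = config.n_neurons
    positions = rng.uniform(0.0, config.field_size_um, size=(n, 2))

    assembly_times = _poisson_times(rng, config.assembly_rate_hz, 0.0, D)
    memberships: list[np.ndarray] = []
    per_neuron: list[list[np.ndarray]] = [[] for _ in range(n)]
    for t_ev in assembly_times:
        center = rng.uniform(0.0, config.field_size_um, size=2)
        d = np.linalg.norm(positions - center, axis=1)
        if np.isinf(config.assembly_decay_length_um):
            p = np.full(n, config.p_join_at_zero)
        else:
            p = config.p_join_at_zero * np.exp(-d / config.assembly_decay_length_um)
        members = np.flatnonzero(rng.random(n) < p)
        memberships.append(members)
        for i in members:
            per_neuron[i].append(np.array([t_ev]))
    for i in range(n):
        per_neuron[i].append(_poisson_times(rng, config.rate_local_hz, 0.0, D))

    times = (np.arange(config.n_frames) + 0.5) * config.frame_interval_s
    traces = []
    truth_events = {}
    for i in range(n):
        ev = np.sort(np.concatenate(per_neuron[i])) if per_neuron[i] else np.empty(0)
        nid = f"n{i:03d}"
        truth_events[nid] = ev
        sig = _render_events(ev, times, config)
        traces.append(
            FluorescenceTrace(
                sig + _noise_and_drift(rng, times, config),
                config.frame_interval_s,
                roi_id=nid,
                state="raw",
            )
        )
    truth = GroundTruth(
        local_event_times_s=truth_events,
        neuron_positions_um=positions,
        assembly_event_times_s=assembly_times,
        assembly_memberships=memberships,
    )
    return traces, positions, truth


def render_cell_stack(
    traces: list[FluorescenceTrace],
    positions_um: np.ndarray,
    field_size_um: float,
    fov_px: int = 64,
    cell_radius_px: int = 2,
    baseline: float = 1.0,
    pixel_noise_sd: float = 0.02,
    seed: int = 0,
):
    """Render traces as disk-shaped cells in a T x Y x X stack.

    Returns ``(stack, masks, pixel_size_um)`` where ``masks`` holds one
    boolean ground-truth mask per cell. Used to exercise ROI segmentation
    and trace extraction end to end.
    """
    rng = np.random.default_rng(seed)
    pixel_size_um = field_size_um / fov_px
    T = traces[0].n_frames
    stack = np.full((T, fov_px, fov_px), baseline, dtype=float)
    yy, xx = np.mgrid[0:fov_px, 0:fov_px]
    masks = []
    for trace, pos in zip(traces, positions_um):
        cy, cx = pos[1] / pixel_size_um, pos[0] / pixel_size_um
        mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= cell_radius_px**2
        masks.append(mask)
        stack[:, mask] += trace.values[:, None]
    if pixel_noise_sd > 0:
        stack += rng.normal(0.0, pixel_noise_sd, stack.shape)
    return stack, masks, pixel_size_um


# ---------------------------------------------------------------------------
# two-channel contact stack
# ---------------------------------------------------------------------------

# contact-stack geometry (voxel units); mask = intensity > MASK_LEVEL.
# Axial sigmas give the blobs a 3-section mask span with interior voxels at
# every section, so photon noise at half-peak thresholds cannot drop a section.
SPINE_SIGMA = (1.2, 1.5, 1.5)
PROCESS_SIGMA = (1.2, 2.0, 2.0)
SHAFT_SIGMA = (1.0, 1.0)
MASK_LEVEL = 0.5
REST_OFFSET_X = -14.0
NEAR_OFFSET_X = -8.0
APPROACH_FRAMES = 8
SINGLE_Z_SHIFT = 2.0


def _gauss_blob(center, sigma, zz, yy, xx):
    cz, cy, cx = center
    sz, sy, sx = sigma
    return np.exp(
        -0.5 * (((zz - cz) / sz) ** 2 + ((yy - cy) / sy) ** 2 + ((xx - cx) / sx) ** 2)
    )


def simulate_contact_stack(
    config: SimulationConfig,
    epochs_frames: list[tuple[int, int]],
    n_frames: int | None = None,
    shape_zyx: tuple[int, int, int] = (7, 32, 32),
    single_z: bool = False,
    photon_scale: float = 100.0,
    background_photons: float = 2.0,
):
    """Render a two-channel Z-stack movie with programmed contact epochs.

    The red channel holds a static Gaussian spine blob (spanning >= 2 Z
    sections at the mask level) plus a dendrite shaft; the green channel
    holds a microglial-process blob that approaches the spine and overlaps
    its mask in >= 2 Z sections exactly during ``epochs_frames`` (inclusive
    frame intervals) and in <= 1 Z section otherwise. With ``single_z`` the
    in-epoch overlap is confined to exactly one Z section (a contact that
    the >= 2-Z rule must reject). Poisson shot noise is applied to photon
    counts ``background_photons + photon_scale * intensity``.

    Returns ``(stack, truth)`` with ``stack`` shaped (T, 2, Z, Y, X),
    channel 0 red / 1 green; ``truth`` carries per-frame Z-overlap counts
    from a noiseless brute-force mask intersection and the spine ROI mask.
    """
    Z, Y, X = shape_zyx
    if Z < 3:
        raise InvalidConfigError("contact stacks need at least 3 Z sections")
    T = int(n_frames if n_frames is not None else config.n_frames)
    for s, e in epochs_frames:
        if not (0 <= s <= e < T):
            raise InvalidConfigError("epochs must lie within the recording span")
    rng = np.random.default_rng(config.seed)
    zz, yy, xx = np.mgrid[0:Z, 0:Y, 0:X].astype(float)

    spine_center = (min(2.0, Z - 2.0), Y / 2.0, X * 0.625)
    shaft_y = spine_center[1] - 6.0
    red = _gauss_blob(spine_center, SPINE_SIGMA, zz, yy, xx)
    red += np.exp(
        -0.5
        * (
            ((zz - spine_center[0]) / SHAFT_SIGMA[0]) ** 2
            + ((yy - shaft_y) / SHAFT_SIGMA[1]) ** 2
        )
    )
    spine_mask = _gauss_blob(spine_center, SPINE_SIGMA, zz, yy, xx) > MASK_LEVEL
    red_mask = red > MASK_LEVEL

    offsets = np.full(T, REST_OFFSET_X)
    z_shift = np.zeros(T)
    for s, e in epochs_frames:
        a0 = max(0, s - APPROACH_FRAMES)
        if s > a0:
            ramp = np.linspace(REST_OFFSET_X, NEAR_OFFSET_X, s - a0, endpoint=False)
            offsets[a0:s] = ramp
        offsets[s : e + 1] = 0.0
        r1 = min(T, e + 1 + APPROACH_FRAMES)
        if r1 > e + 1:
            ramp = np.linspace(NEAR_OFFSET_X, REST_OFFSET_X, r1 - e - 1)
            offsets[e + 1 : r1] = ramp
        if single_z:
            z_shift[s : e + 1] = SINGLE_Z_SHIFT

    green_clean = np.empty((T, Z, Y, X))
    z_overlap = np.zeros(T, dtype=int)
    blob_cache: dict[tuple[float, float], np.ndarray] = {}
    for t in range(T):
        key = (round(float(z_shift[t]), 6), round(float(offsets[t]), 6))
        if key not in blob_cache:
            g_center = (spine_center[0] + key[0], spine_center[1], spine_center[2] + key[1])
            blob_cache[key] = _gauss_blob(g_center, PROCESS_SIGMA, zz, yy, xx)
        green_clean[t] = blob_cache[key]
        overlap = spine_mask & red_mask & (green_clean[t] > MASK_LEVEL)
        z_overlap[t] = int(overlap.any(axis=(1, 2)).sum())
    # red can reach ~2x photon_scale where the spine blob meets the shaft
    dtype = np.uint16 if background_photons + 2.5 * photon_scale < 60000 else np.uint32
    stack = np.empty((T, 2, Z, Y, X), dtype=dtype)
    red_lam = np.broadcast_to(background_photons + photon_scale * red, (T, Z, Y, X))
    stack[:, 0] = rng.poisson(red_lam)
    stack[:, 1] = rng.poisson(background_photons + photon_scale * green_clean)

    dt = config.frame_interval_s
    truth = GroundTruth(
        contact_epochs=[("spine0", s * dt, (e + 1) * dt) for s, e in epochs_frames],
        contact_z_overlap=z_overlap,
        spine_mask=spine_mask,
    )
    return stack, truth


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def _events_frame(truth: GroundTruth):
    import pandas as pd

    rows = []
    for roi, times in truth.local_event_times_s.items():
        rows += [(roi, "local", t) for t in times]
    for roi, times in truth.bp_event_times_s.items():
        rows += [(roi, "bp", t) for t in times]
    return pd.DataFrame(rows, columns=["roi_id", "label", "time_s"])


def _trace_frame(trace: FluorescenceTrace):
    import pandas as pd

    return pd.DataFrame(
        {
            "roi_id": trace.roi_id,
            "frame": np.arange(trace.n_frames),
            "time_s": trace.times_s,
            "value": trace.values,
        }
    )


def write_config(outdir: Path, config: SimulationConfig, **extra) -> None:
    payload = dataclasses.asdict(config)
    payload.update(extra)
    payload["axis_order"] = "TZYX (contact stacks carry a leading channel axis: T,C,Z,Y,X)"
    (Path(outdir) / "config.json").write_text(json.dumps(payload, indent=2, default=float))


def write_spine_recording(outdir, spine, dend, truth, config) -> None:
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.concat([_trace_frame(spine), _trace_frame(dend)]).to_csv(
        outdir / "spine_traces.csv", index=False
    )
    _events_frame(truth).to_csv(outdir / "spine_truth_events.csv", index=False)
    pd.DataFrame(
        truth.contact_epochs, columns=["spine_id", "start_s", "end_s"]
    ).to_csv(outdir / "contact_truth_epochs.csv", index=False)
    write_config(outdir, config)


def write_population(outdir, traces, positions, truth, config, stack=None) -> None:
    import pandas as pd
    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.concat([_trace_frame(t) for t in traces]).to_csv(
        outdir / "population_traces.csv", index=False
    )
    pd.DataFrame(
        {
            "roi_id": [t.roi_id for t in traces],
            "x_um": positions[:, 0],
            "y_um": positions[:, 1],
        }
    ).to_csv(outdir / "population_positions.csv", index=False)
    _events_frame(truth).to_csv(outdir / "population_truth_events.csv", index=False)
    if stack is not None:
        tifffile.imwrite(outdir / "population_stack.tif", stack.astype(np.float32))
    write_config(outdir, config)


def write_contact_stack(outdir, stack, truth, config) -> None:
    import pandas as pd
    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(outdir / "contact_red.tif", stack[:, 0])
    tifffile.imwrite(outdir / "contact_green.tif", stack[:, 1])
    tifffile.imwrite(outdir / "contact_spine_mask.tif", truth.spine_mask.astype(np.uint8))
    pd.DataFrame(
        truth.contact_epochs, columns=["spine_id", "start_s", "end_s"]
    ).to_csv(outdir / "contact_truth_epochs.csv", index=False)
    pd.DataFrame(
        {"frame": np.arange(len(truth.contact_z_overlap)), "z_overlap": truth.contact_z_overlap}
    ).to_csv(outdir / "contact_truth_z_overlap.csv", index=False)
    write_config(outdir, config)
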