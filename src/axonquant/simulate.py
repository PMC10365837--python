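"""Synthetic ground-truth generators for every pipeline stage.

Each generator emulates one acquisition modality of a corticostriatal
synapse study and emits, alongside the rendered data, a :class:`TruthRecord`
with one entry per simulated entity so downstream recovery can be scored
exactly:

- :func:`simulate_axonal_movie` — vesicles switching among anterograde /
  retrograde / paused states along a straight axon, imaged every 200 ms for
  1 min and rendered as Gaussian spots with Poisson (or Gaussian) noise.
- :func:`simulate_phluorin_movie` — per-synapse fluorescence with step-rise /
  exponential-decay exocytosis events, one acquisition before and three
  after a stimulation epoch.
- :func:`simulate_em_synapse` — presynaptic terminal geometry with a vesicle
  point cloud placed at controlled distances from the active zone.
- :func:`simulate_two_channel_puncta` — two-channel spot images with a
  controlled colocalized fraction.
- :func:`simulate_epsc_pair` — paired EPSC sweeps with a controlled
  amplitude ratio.

Axial convention: position increases toward the presynapse, so anterograde
motion is a positive displacement. Default pixel size is 0.1 µm/px (63x
objective scale).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, Polygon

from .em import SynapseGeometry
from .ephys import SweepPair

logger = logging.getLogger(__name__)

STATES = ("antero", "retro", "pause")

__all__ = [
    "TransportSimConfig",
    "TruthRecord",
    "simulate_axonal_movie",
    "simulate_phluorin_movie",
    "simulate_em_synapse",
    "simulate_two_channel_puncta",
    "simulate_epsc_pair",
    "amplitude_for_snr",
    "default_terminal_shape",
]


@dataclass
class TruthRecord:
    """Ground truth emitted by a generator; unused tables are None.

    ``positions`` — per vesicle and frame: axial position (µm), motion state,
    realized signed velocity (µm/s). ``vesicles`` — per-vesicle class and
    per-state mean segment speeds. ``events`` — exocytosis onsets (field,
    epoch, acquisition, roi, onset frame, amplitude). ``zones`` — per-centroid
    distance-band membership. ``puncta`` — per-punctum channel coordinates
    and colocalization label. ``sweeps`` — per-sweep true amplitudes/ratio.
    """

    positions: pd.DataFrame | None = None
    vesicles: pd.DataFrame | None = None
    events: pd.DataFrame | None = None
    zones: pd.DataFrame | None = None
    puncta: pd.DataFrame | None = None
    sweeps: pd.DataFrame | None = None


@dataclass
class TransportSimConfig:
    """Parameters of the axonal-transport movie generator.

    Speeds are (mean, sd) in µm/s, drawn once per motion segment.
    ``state_switch_rates`` are per-second hazards keyed ``(from, to)`` over
    {antero, retro, pause}. ``fraction_static`` is the probability that a
    vesicle never moves. SNR is ``amplitude / sqrt(background)`` (shot-noise
    limited); see :func:`amplitude_for_snr`.
    """

    n_vesicles: int = 30
    frame_interval: float = 0.2  # s
    duration: float = 60.0  # s
    pixel_size: float = 0.1  # µm/px
    axon_length: float = 100.0  # µm analysis window
    speed_antero: tuple[float, float] = (1.2, 0.3)
    speed_retro: tuple[float, float] = (1.0, 0.3)
    state_switch_rates: dict = field(
        default_factory=lambda: {
            ("antero", "pause"): 0.05,
            ("antero", "retro"): 0.02,
            ("retro", "pause"): 0.05,
            ("retro", "antero"): 0.02,
            ("pause", "antero"): 0.10,
            ("pause", "retro"): 0.10,
        }
    )
    fraction_static: float = 0.2
    psf_sigma: float = 1.3  # px
    background: float = 100.0  # photons
    amplitude: float = 80.0  # photons at spot peak
    noise_model: str = "poisson"  # or "gaussian", or "none"
    seed: int = 0
    image_half_height: int = 6  # px either side of the axon row
    initial_state: str | None = None  # force every motile vesicle's first state

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        n = self.duration / self.frame_interval
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration/frame_interval must be an integer frame count")
        if not 0 <= self.fraction_static <= 1:
            raise ValueError("fraction_static must be in [0, 1]")
        for mean, sd in (self.speed_antero, self.speed_retro):
            if mean < 0 or sd < 0:
                raise ValueError("speeds must be non-negative")
        if self.noise_model not in ("poisson", "gaussian", "none"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")

    @property
    def n_frames(self) -> int:
        return round(self.duration / self.frame_interval)


def amplitude_for_snr(snr: float, background: float) -> float:
    """Spot peak amplitude giving the requested shot-noise-limited SNR."""
    return snr * np.sqrt(background)


def _render_spots(frame: np.ndarray, xy: np.ndarray, amplitude: float, sigma: float) -> None:
    """Add Gaussian spots (peak ``amplitude``, width ``sigma`` px) in place."""
    h, w = frame.shape
    r = max(1, int(np.ceil(4 * sigma)))
    for x, y in xy:
        x0, y0 = int(round(x)), int(round(y))
        xs = slice(max(0, x0 - r), min(w, x0 + r + 1))
        ys = slice(max(0, y0 - r), min(h, y0 + r + 1))
        if xs.start >= xs.stop or ys.start >= ys.stop:
            continue
        gx = np.arange(xs.start, xs.stop) - x
        gy = np.arange(ys.start, ys.stop) - y
        frame[ys, xs] += amplitude * np.exp(
            -(gx[None, :] ** 2 + gy[:, None] ** 2) / (2 * sigma**2)
        )


def _apply_noise(clean: np.ndarray, model: str, rng: np.random.Generator) -> np.ndarray:
    if model == "poisson":
        return rng.poisson(np.clip(clean, 0, None)).astype(np.float32)
    if model == "gaussian":
        return (clean + rng.normal(0, np.sqrt(np.clip(clean, 1e-12, None)))).astype(np.float32)
    return clean.astype(np.float32)


def _simulate_vesicle_path(cfg: TransportSimConfig, rng: np.random.Generator):
    """Per-frame positions, states and realized velocities for one vesicle."""
    nf, dt, L = cfg.n_frames, cfg.frame_interval, cfg.axon_length
    pos = np.empty(nf)
    states = np.empty(nf, dtype=object)
    pos[0] = rng.uniform(0, L)
    static = rng.random() < cfg.fraction_static
    if static:
        pos[:] = pos[0]
        states[:] = "pause"
        vel = np.zeros(nf - 1)
        return pos, states, vel, True

    speed_of = {"antero": cfg.speed_antero, "retro": cfg.speed_retro, "pause": (0.0, 0.0)}
    state = cfg.initial_state or rng.choice(STATES, p=(0.4, 0.4, 0.2))

    def draw_speed(s: str) -> float:
        mean, sd = speed_of[s]
        return 0.0 if s == "pause" else max(0.05, rng.normal(mean, sd))

    speed = draw_speed(state)
    leave = {
        s: [(to, r) for (frm, to), r in cfg.state_switch_rates.items() if frm == s]
        for s in STATES
    }
    vel = np.zeros(nf - 1)
    for k in range(nf - 1):
        states[k] = state
        sign = {"antero": 1.0, "retro": -1.0, "pause": 0.0}[state]
        new = pos[k] + sign * speed * dt
        if new < 0 or new > L:  # reflect at the window edge: flip direction
            state = {"antero": "retro", "retro": "antero"}.get(state, state)
            speed = draw_speed(state)
            new = float(np.clip(new, 0, L))
        pos[k + 1] = new
        vel[k] = (pos[k + 1] - pos[k]) / dt
        # per-frame switching: competing exponential hazards
        dests, rates = zip(*leave[state]) if leave[state] else ((), ())
        total = sum(rates)
        if total > 0 and rng.random() < 1 - np.exp(-total * dt):
            state = rng.choice(dests, p=np.asarray(rates) / total)
            speed = draw_speed(state)
    states[nf - 1] = states[nf - 2]
    return pos, states, vel, False


def _truth_vesicle_class(pos, states, vel, dt, static_threshold=0.4):
    """Ground-truth class from the noiseless trajectory.

    Static: maximal excursion from the start below ``static_threshold`` µm.
    Otherwise the direction with the largest cumulative unsigned displacement.
    """
    if np.max(np.abs(pos - pos[0])) < static_threshold:
        return "static"
    disp = vel * dt
    ant = disp[disp > 0].sum()
    ret = -disp[disp < 0].sum()
    return "anterograde" if ant >= ret else "retrograde"


def simulate_axonal_movie(config: TransportSimConfig) -> tuple[np.ndarray, TruthRecord]:
    """Render an axonal-transport movie with per-frame ground truth.

    Returns the movie as a (frames, height, width) float32 stack and the
    truth (``positions`` per vesicle/frame, ``vesicles`` classes and mean
    segment speeds). The axon runs horizontally along the central image row.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    nf = cfg.n_frames
    width = int(round(cfg.axon_length / cfg.pixel_size))
    height = 2 * cfg.image_half_height + 1
    y_axon = cfg.image_half_height

    rows_pos, rows_ves = [], []
    paths = []
    for v in range(cfg.n_vesicles):
        pos, states, vel, static = _simulate_vesicle_path(cfg, rng)
        paths.append(pos)
        cls = _truth_vesicle_class(pos, states, vel, cfg.frame_interval)
        vel_full = np.append(vel, np.nan)
        for k in range(nf):
            rows_pos.append((v, k, pos[k], states[k], vel_full[k]))
        sp = np.abs(vel)
        mean_ant = sp[vel > 0].mean() if (vel > 0).any() else np.nan
        mean_ret = sp[vel < 0].mean() if (vel < 0).any() else np.nan
        rows_ves.append((v, cls, static, mean_ant, mean_ret, pos[-1] - pos[0]))

    positions = pd.DataFrame(
        rows_pos, columns=["vesicle", "frame", "position_um", "state", "velocity_um_s"]
    )
    vesicles = pd.DataFrame(
        rows_ves,
        columns=["vesicle", "class", "static", "mean_antero_speed", "mean_retro_speed", "net_displacement_um"],
    )

    movie = np.empty((nf, height, width), dtype=np.float32)
    for k in range(nf):
        frame = np.full((height, width), float(cfg.background))
        if cfg.n_vesicles:
            xy = np.column_stack(
                [np.array([p[k] for p in paths]) / cfg.pixel_size, np.full(cfg.n_vesicles, y_axon)]
            )
            _render_spots(frame, xy, cfg.amplitude, cfg.psf_sigma)
        movie[k] = _apply_noise(frame, cfg.noise_model, rng)
    return movie, TruthRecord(positions=positions, vesicles=vesicles)


# ---------------------------------------------------------------------------
# pHluorin exocytosis movies


def _roi_grid(n_rois: int, field_size: int, radius: int, margin: int = 8) -> np.ndarray:
    """Disc-ROI centers on a regular grid, (n, 2) as (y, x)."""
    per_side = int(np.ceil(np.sqrt(n_rois)))
    coords = np.linspace(margin + radius, field_size - margin - radius, per_side)
    yy, xx = np.meshgrid(coords, coords, indexing="ij")
    return np.column_stack([yy.ravel(), xx.ravel()])[:n_rois]


def simulate_phluorin_movie(
    n_fields: int = 3,
    rois_per_field: int = 10,
    pre_rate: float = 2.0,  # events/min per ROI
    post_rate: float = 6.0,
    event_amplitude: float = 50.0,  # ΔF over baseline
    decay_tau: float = 2.0,  # s
    baseline: float = 100.0,
    noise_sd: float = 0.0,  # per-pixel Gaussian sd
    frame_interval: float = 0.2,
    duration: float = 60.0,
    field_size: int = 128,
    roi_radius: int = 4,
    seed: int = 0,
):
    """Per-field pHluorin acquisitions: one pre- and three post-stimulation.

    Exocytosis events are Poisson in time per ROI (``rate`` per minute) and
    rendered as a uniform step of ``event_amplitude`` over the ROI disc
    followed by exponential decay with ``decay_tau``.

    Returns ``(fields, rois, truth)`` where ``fields[i]`` is
    ``{"pre": stack, "post": [stack, stack, stack]}`` and ``rois`` is a
    DataFrame (field, roi, y, x, radius).
    """
    if pre_rate < 0 or post_rate < 0:
        raise ValueError("rates must be non-negative")
    if decay_tau <= 0:
        raise ValueError("decay_tau must be positive")
    rng = np.random.default_rng(seed)
    nf = round(duration / frame_interval)
    centers = _roi_grid(rois_per_field, field_size, roi_radius)
    t = np.arange(nf) * frame_interval

    yy, xx = np.mgrid[:field_size, :field_size]
    masks = [
        (yy - cy) ** 2 + (xx - cx) ** 2 <= roi_radius**2 for cy, cx in centers
    ]

    fields, truth_rows, roi_rows = [], [], []
    for f in range(n_fields):
        for r, (cy, cx) in enumerate(centers):
            roi_rows.append((f, r, cy, cx, roi_radius))
        stacks = {}
        for epoch, acqs, rate in (("pre", 1, pre_rate), ("post", 3, post_rate)):
            movies = []
            for a in range(acqs):
                traces = np.zeros((rois_per_field, nf))
                n_ev = rng.poisson(rate * duration / 60.0, size=rois_per_field)
                for r in range(rois_per_field):
                    onsets = np.sort(rng.integers(0, nf, size=n_ev[r]))
                    for onset in onsets:
                        traces[r, onset:] += event_amplitude * np.exp(
                            -(t[onset:] - t[onset]) / decay_tau
                        )
                        truth_rows.append((f, epoch, a, r, int(onset), event_amplitude))
                movie = np.full((nf, field_size, field_size), baseline, dtype=np.float32)
                for r, m in enumerate(masks):
                    movie[:, m] += traces[r][:, None]
                if noise_sd > 0:
                    movie += rng.normal(0, noise_sd, movie.shape).astype(np.float32)
                movies.append(movie)
            stacks[epoch] = movies[0] if epoch == "pre" else movies
        fields.append(stacks)

    rois = pd.DataFrame(roi_rows, columns=["field", "roi", "y", "x", "radius"])
    events = pd.DataFrame(
        truth_rows, columns=["field", "epoch", "acquisition", "roi", "onset_frame", "amplitude"]
    )
    return fields, rois, TruthRecord(events=events)


# ---------------------------------------------------------------------------
# EM synapse geometries


def default_terminal_shape(width_nm: float = 800.0, depth_nm: float = 500.0) -> np.ndarray:
    """A plausible bouton outline: flat PSD-facing base, rounded distal cap.

    The base runs along y = 0 from -width/2 to +width/2; the cap is a
    half-ellipse of the given depth. Counter-clockwise vertex order.
    """
    theta = np.linspace(np.pi, 0.0, 25)[1:-1]  # cap vertices, left to right; base corners added explicitly
    arc = np.column_stack([width_nm / 2 * np.cos(theta), depth_nm * np.sin(theta)])
    return np.vstack([[-width_nm / 2, 0.0], arc, [width_nm / 2, 0.0]])


def _largest_remainder_counts(proportions: np.ndarray, n: int) -> np.ndarray:
    raw = proportions * n
    counts = np.floor(raw).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:rem]] += 1
    return counts


def simulate_em_synapse(
    terminal_shape: np.ndarray | None = None,
    n_vesicles: int = 30,
    zone_mix: tuple = (0.30, 0.30, 0.25, 0.15),
    vesicle_radius: float = 20.0,
    band_width_nm: float = 40.0,
    seed: int = 0,
    max_attempts: int = 20000,
) -> tuple[SynapseGeometry, TruthRecord]:
    """Place vesicle centroids in distance bands from the active zone.

    ``zone_mix`` gives the proportions over (zone1, zone2, zone3, beyond);
    counts are allocated by largest remainder so they sum to ``n_vesicles``
    exactly. Centroids are sampled uniformly within each band clipped to the
    terminal, under a hard-core constraint (no two centroids closer than
    2x ``vesicle_radius`` — real SVs do not interpenetrate). The active zone
    is the terminal's PSD-facing base edge.
    """
    mix = np.asarray(zone_mix, dtype=float)
    if abs(mix.sum() - 1.0) > 1e-9:
        raise ValueError("zone_mix must sum to 1")
    outline = default_terminal_shape() if terminal_shape is None else np.asarray(terminal_shape, float)
    terminal = Polygon(outline)
    # active zone: the base edge (minimum-y span of the outline)
    ymin = outline[:, 1].min()
    base = outline[np.isclose(outline[:, 1], ymin)]
    az = np.array([[base[:, 0].min(), ymin], [base[:, 0].max(), ymin]])
    az_line = LineString(az)

    rng = np.random.default_rng(seed)
    counts = _largest_remainder_counts(mix, n_vesicles)
    n_bands = len(mix) - 1
    minx, miny, maxx, maxy = terminal.bounds
    placed: list[np.ndarray] = []
    labels: list[int] = []
    min_sep2 = (2 * vesicle_radius) ** 2
    for band, n_k in enumerate(counts):
        lo = band * band_width_nm
        hi = (band + 1) * band_width_nm if band < n_bands else np.inf
        got, attempts = 0, 0
        while got < n_k:
            attempts += 1
            if attempts > max_attempts:
                raise RuntimeError(
                    f"band [{lo}, {hi}) nm empty or too crowded after clipping"
                )
            p = rng.uniform((minx, miny), (maxx, maxy))
            pt = shapely.points(p)
            if not terminal.covers(pt):
                continue
            d = az_line.distance(pt)
            if not (lo <= d < hi):
                continue
            if placed and (np.sum((np.asarray(placed) - p) ** 2, axis=1) < min_sep2).any():
                continue
            placed.append(p)
            labels.append(band if band < n_bands else -1)
            got += 1

    centroids = np.asarray(placed).reshape(-1, 2)
    geometry = SynapseGeometry(outline, az, centroids, vesicle_radius)
    zones = pd.DataFrame(
        {
            "vesicle": np.arange(len(labels)),
            "zone": labels,  # 0-based band index, -1 = beyond
            "x_nm": centroids[:, 0] if len(labels) else [],
            "y_nm": centroids[:, 1] if len(labels) else [],
        }
    )
    return geometry, TruthRecord(zones=zones)


# ---------------------------------------------------------------------------
# Two-channel puncta fields


def simulate_two_channel_puncta(
    n_puncta: int = 100,
    coloc_fraction: float = 0.5,
    punctum_sigma: float = 1.5,
    field_size: int = 256,
    amplitude: float = 100.0,
    background: float = 10.0,
    noise_sd: float = 0.0,
    jitter_px: float = 0.5,
    seed: int = 0,
):
    """Two spot images sharing ``coloc_fraction`` of punctum centers.

    Shared puncta appear in both channels at the same center up to a uniform
    jitter of at most ``jitter_px`` per axis (<= 1 px total displacement by
    default); the remainder are placed independently per channel. Warns when
    the expected spot overlap is high enough to confound object counting.

    Returns ``(img_a, img_b, truth)``; truth.puncta lists every punctum with
    its channel, center, and shared-pair id (-1 if channel-specific).
    """
    if not 0 <= coloc_fraction <= 1:
        raise ValueError("coloc_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_shared = int(round(coloc_fraction * n_puncta))
    margin = 6 * punctum_sigma
    density = n_puncta * np.pi * (3 * punctum_sigma) ** 2 / field_size**2
    if density > 0.3:
        warnings.warn(
            f"expected punctum overlap high (crowding index {density:.2f} > 0.3); "
            "object counts will be unreliable",
            stacklevel=2,
        )

    shared = rng.uniform(margin, field_size - margin, size=(n_shared, 2))
    rows = []
    imgs = []
    for ch in ("A", "B"):
        centers = shared + rng.uniform(-jitter_px, jitter_px, size=shared.shape)
        extra = rng.uniform(margin, field_size - margin, size=(n_puncta - n_shared, 2))
        allc = np.vstack([centers, extra])
        pair_ids = np.concatenate([np.arange(n_shared), np.full(n_puncta - n_shared, -1)])
        for (y, x), pid in zip(allc, pair_ids):
            rows.append((ch, y, x, int(pid), pid >= 0))
        img = np.full((field_size, field_size), background, dtype=np.float64)
        _render_spots(img, allc[:, ::-1], amplitude, punctum_sigma)  # (x, y) order
        if noise_sd > 0:
            img += rng.normal(0, noise_sd, img.shape)
        imgs.append(img.astype(np.float32))

    puncta = pd.DataFrame(rows, columns=["channel", "y", "x", "pair_id", "colocalized"])
    return imgs[0], imgs[1], TruthRecord(puncta=puncta)


# ---------------------------------------------------------------------------
# Paired EPSC sweeps


def _epsc_kernel(t_ms: np.ndarray, rise_tau: float, decay_tau: float) -> np.ndarray:
    """Unit-peak biexponential synaptic conductance time course.

    Normalized by the maximum over the supplied sample grid, so the rendered
    peak amplitude equals the requested amplitude exactly at the sampled
    resolution.
    """
    if not decay_tau > rise_tau > 0:
        raise ValueError("need decay_tau > rise_tau > 0")
    out = np.zeros_like(t_ms)
    pos = t_ms >= 0
    out[pos] = np.exp(-t_ms[pos] / decay_tau) - np.exp(-t_ms[pos] / rise_tau)
    peak = out.max()
    return out / peak if peak > 0 else out


def simulate_epsc_pair(
    isi: float = 100.0,  # ms
    a1: float = 100.0,  # pA
    ppr_true: float = 1.0,
    rise_tau: float = 1.0,  # ms
    decay_tau: float = 10.0,  # ms
    noise_sd: float = 0.0,  # pA
    n_sweeps: int = 20,
    sampling_khz: float = 10.0,
    pre_ms: float = 50.0,
    post_ms: float = 200.0,
    r_input: float = 150.0,  # MΩ
    r_series: float = 15.0,
    seed: int = 0,
) -> tuple[list[SweepPair], TruthRecord]:
    """Paired EPSC sweeps: two inward biexponential currents at t1 and t1+isi.

    Peak amplitudes are ``a1`` and ``a1 * ppr_true`` pA plus white Gaussian
    noise. ISIs shorter than the response rise render overlapping peaks;
    this is allowed and flagged in the truth table.
    """
    if isi <= 0:
        raise ValueError("isi must be positive")
    if a1 <= 0:
        raise ValueError("a1 must be positive")
    rng = np.random.default_rng(seed)
    dt = 1.0 / sampling_khz
    t = np.arange(0, pre_ms + isi + post_ms, dt)
    t1, t2 = pre_ms, pre_ms + isi
    a2 = a1 * ppr_true
    clean = -(a1 * _epsc_kernel(t - t1, rise_tau, decay_tau) + a2 * _epsc_kernel(t - t2, rise_tau, decay_tau))
    t_peak = rise_tau * decay_tau / (decay_tau - rise_tau) * np.log(decay_tau / rise_tau)
    overlap = isi < 5 * t_peak

    sweeps, rows = [], []
    for s in range(n_sweeps):
        y = clean + (rng.normal(0, noise_sd, t.shape) if noise_sd > 0 else 0.0)
        sweeps.append(
            SweepPair(t, y, t1, t2, r_input=r_input, r_series=r_series, sweep_id=s, overlap_flag=overlap)
        )
        rows.append((s, isi, a1, a2, ppr_true, overlap))
    truth = pd.DataFrame(
        rows, columns=["sweep", "isi_ms", "a1_pA", "a2_pA", "ppr_true", "overlap"]
    )
    return sweeps, TruthRecord(sweeps=truth)
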