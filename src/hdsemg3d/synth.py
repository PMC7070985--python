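"""Synthetic HD-sEMG benchmark generator.

Emulates the statistical structure the recognition pipeline relies on,
without claiming physiological realism: each gesture is a smooth spatial
activation pattern (an isotropic Gaussian bump of motor activity) on the
electrode grid, amplitude-modulating a 20-400 Hz band-limited stochastic
carrier per channel, embedded in a rest-activity-rest trial with
raised-cosine on/off ramps, plus broadband baseline noise at a configurable
SNR.

Static gestures (isometric holds) keep their activation centroid fixed.
Dynamic gestures move it along a path; the dynamics-only benchmark uses
pairs of gestures sharing one centroid and circling it in opposite
directions, so any single frame is class-ambiguous by construction and only
the temporal evolution within a cube separates the pair -- the substrate
for comparing spatiotemporal against per-frame classifiers.  (A linear
centroid path, also supported, cannot keep single-frame marginals identical
over a multi-second trial while staying on a small grid.)

Sampling-rate note: at 1000-2000 Hz a cube spans only tens of
milliseconds, so the orbital period is chosen short enough that the
centroid moves about one pixel per cube.
"""

from __future__ import annotations

import csv as _csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import butter, filtfilt

from .grid_io import ElectrodeGrid, Recording, capgmyo_grid

__all__ = [
    "GestureTemplate",
    "SynthConfig",
    "make_gesture_templates",
    "simulate_trial",
    "make_benchmark",
    "nearest_template_classify",
    "write_manifest",
]


@dataclass
class GestureTemplate:
    """Spatial activation pattern and centroid path of one gesture.

    ``drift`` is a linear centroid velocity in (rows/s, cols/s); ``orbit``
    is an optional circular path ``(radius_px, period_s, direction)`` with
    direction +1/-1, overriding drift.  Static gestures have zero drift and
    no orbit.  ``spatial_map`` is the activation pattern at the initial
    centroid, normalized to sum to 1.
    """

    gesture_id: int
    center: tuple[float, float]
    sigma: float
    grid: ElectrodeGrid
    drift: tuple[float, float] = (0.0, 0.0)
    orbit: tuple[float, float, int] | None = None
    amplitude: float = 1.0
    spatial_map: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.spatial_map = self.map_at(*self.centroid_at(np.zeros(1))[0])

    def map_at(self, row: float, col: float) -> np.ndarray:
        rr, cc = np.mgrid[0:self.grid.rows, 0:self.grid.cols]
        bump = np.exp(-((rr - row) ** 2 + (cc - col) ** 2) / (2 * self.sigma ** 2))
        return bump / bump.sum()

    def centroid_at(self, t: np.ndarray) -> np.ndarray:
        """Centroid (row, col) at times ``t`` seconds from activity onset."""
        t = np.asarray(t, dtype=np.float64)
        r0, c0 = self.center
        if self.orbit is not None:
            radius, period, direction = self.orbit
            theta = direction * 2 * np.pi * t / period
            return np.column_stack([r0 + radius * np.sin(theta),
                                    c0 + radius * np.cos(theta)])
        vr, vc = self.drift
        return np.column_stack([r0 + vr * t, c0 + vc * t])

    @property
    def is_static(self) -> bool:
        return self.orbit is None and self.drift == (0.0, 0.0)


@dataclass
class SynthConfig:
    """Study conditions for a synthetic benchmark.

    Defaults emulate a 3 s trial on the 8 x 16 grid at 1000 Hz with the
    middle half active and a 10 dB active-to-baseline SNR.
    """

    G: int = 4
    grid: ElectrodeGrid = field(default_factory=capgmyo_grid)
    fs: float = 1000.0
    trial_s: float = 3.0
    activity_fraction: tuple[float, float] = (0.25, 0.75)
    carrier_band: tuple[float, float] = (20.0, 400.0)
    snr_db: float = 10.0
    n_trials_per_gesture: int = 10
    seed: int = 0
    sigma_px: float = 1.2
    orbit_radius_px: float = 2.0
    orbit_period_s: float = 0.25

    def __post_init__(self) -> None:
        onset, offset = self.activity_fraction
        if not 0 <= onset < offset <= 1:
            raise ValueError("need 0 <= onset < offset <= 1")
        if not np.isfinite(self.snr_db):
            raise ValueError("snr_db must be finite")
        if self.carrier_band[1] >= self.fs / 2:
            raise ValueError("carrier band exceeds Nyquist")


def _center_lattice(grid: ElectrodeGrid, n: int, margin: float,
                    min_sep: float) -> list[tuple[float, float]]:
    """Evenly spaced centers maximizing the pairwise separation.

    All (rows x cols) lattice layouts holding ``n`` centers are scored by
    their smallest neighbor distance; the best layout is used, and an error
    is raised if even that packs centers closer than ``min_sep``.
    """
    lo_r, hi_r = margin, grid.rows - 1 - margin
    lo_c, hi_c = margin, grid.cols - 1 - margin
    if hi_r < lo_r or hi_c < lo_c:
        raise ValueError("grid too small for the requested margin")
    best: tuple[float, list] | None = None
    for nr in range(1, n + 1):
        nc = -(-n // nr)
        rows = np.linspace(lo_r, hi_r, nr) if nr > 1 else [(lo_r + hi_r) / 2]
        cols = np.linspace(lo_c, hi_c, nc) if nc > 1 else [(lo_c + hi_c) / 2]
        sep_r = rows[1] - rows[0] if nr > 1 else np.inf
        sep_c = cols[1] - cols[0] if nc > 1 else np.inf
        sep = min(sep_r, sep_c)
        centers = [(float(r), float(c)) for r in rows for c in cols][:n]
        if best is None or sep > best[0]:
            best = (sep, centers)
    if best is None or best[0] < min_sep:
        raise ValueError(
            f"cannot place {n} activation centers at least {min_sep:.1f} px "
            f"apart on a {grid.rows}x{grid.cols} grid"
        )
    return best[1]


def make_gesture_templates(cfg: SynthConfig, dynamic: bool = False
                           ) -> list[GestureTemplate]:
    """G templates with distinct activation structure.

    Static: G distinct centers.  Dynamic: centers are shared in pairs, the
    two members circling the common centroid in opposite directions with
    identical radius and period -- identical initial maps, opposite drift.
    """
    if cfg.G < 2:
        raise ValueError("need at least two gestures")
    if not dynamic:
        centers = _center_lattice(cfg.grid, cfg.G,
                                  margin=cfg.sigma_px + 1.0,
                                  min_sep=2 * cfg.sigma_px)
        return [GestureTemplate(g, centers[g], cfg.sigma_px, cfg.grid)
                for g in range(cfg.G)]
    n_centers = -(-cfg.G // 2)
    # keep the centroid path on the grid; the bump tail may truncate at the
    # edge (maps are renormalized per frame)
    margin = cfg.orbit_radius_px + 0.5
    centers = _center_lattice(cfg.grid, n_centers, margin=margin,
                              min_sep=2 * (cfg.sigma_px + cfg.orbit_radius_px))
    templates = []
    for g in range(cfg.G):
        center = centers[g // 2]
        direction = 1 if g % 2 == 0 else -1
        templates.append(GestureTemplate(
            g, center, cfg.sigma_px, cfg.grid,
            orbit=(cfg.orbit_radius_px, cfg.orbit_period_s, direction)))
    return templates


def _raised_cosine_envelope(n_frames: int, onset_f: int, offset_f: int
                            ) -> np.ndarray:
    """Rest-ramp-plateau-ramp-rest profile; ramps span 10% of activity."""
    env = np.zeros(n_frames)
    active = offset_f - onset_f
    ramp = max(1, int(round(0.1 * active)))
    t_up = np.arange(ramp)
    env[onset_f:onset_f + ramp] = 0.5 * (1 - np.cos(np.pi * (t_up + 1) / ramp))
    env[onset_f + ramp:offset_f - ramp] = 1.0
    env[offset_f - ramp:offset_f] = 0.5 * (
        1 - np.cos(np.pi * (t_up[::-1] + 1) / ramp))
    return env


def simulate_trial(template: GestureTemplate, cfg: SynthConfig,
                   seed: int | np.random.SeedSequence = 0,
                   trial_index: int = 0) -> Recording:
    """One rest-activity-rest trial of the given gesture.

    Channel c's signal is ``noise + amplitude * env(t) * map_c(t) *
    carrier_c(t)`` where the carrier is white noise band-passed to the
    configured 20-400 Hz band (unit variance per channel) and the map
    follows the template's centroid path during activity.  Baseline noise
    is white with standard deviation set ``snr_db`` below the plateau
    signal RMS; with amplitude 0 the trial is exactly zero, so activity
    detection must fail.
    """
    rng = np.random.default_rng(seed)
    n = int(round(cfg.trial_s * cfg.fs))
    onset_f = int(round(cfg.activity_fraction[0] * n))
    offset_f = int(round(cfg.activity_fraction[1] * n))
    grid = template.grid
    C = grid.n_channels

    env = _raised_cosine_envelope(n, onset_f, offset_f)

    # centroid path (time measured from activity onset)
    t_rel = (np.arange(n) - onset_f) / cfg.fs
    path = template.centroid_at(t_rel)
    if template.is_static:
        maps_per_channel = np.tile(
            template.spatial_map[grid.channel_map[:, 0],
                                 grid.channel_map[:, 1]][:, np.newaxis],
            (1, n))
    else:
        rr = grid.channel_map[:, 0][:, np.newaxis]          # (C, 1)
        cc = grid.channel_map[:, 1][:, np.newaxis]
        pr, pc = path[:, 0][np.newaxis], path[:, 1][np.newaxis]  # (1, n)
        bump = np.exp(-((rr - pr) ** 2 + (cc - pc) ** 2)
                      / (2 * template.sigma ** 2))
        maps_per_channel = bump / bump.sum(axis=0, keepdims=True)

    # band-limited carrier, unit variance per channel
    low, high = cfg.carrier_band
    nyq = cfg.fs / 2
    b, a = butter(4, [low / nyq, high / nyq], btype="bandpass")
    carrier = filtfilt(b, a, rng.standard_normal((C, n)), axis=-1)
    carrier /= carrier.std(axis=-1, keepdims=True)

    signal_part = template.amplitude * env * maps_per_channel * carrier
    plateau = env >= 1.0
    plateau_rms = (np.sqrt(np.mean(signal_part[:, plateau] ** 2))
                   if plateau.any() else 0.0)
    noise_std = plateau_rms / 10 ** (cfg.snr_db / 20)
    noise = noise_std * rng.standard_normal((C, n))

    return Recording(
        signal=signal_part + noise,
        fs=cfg.fs,
        grid=grid,
        meta={
            "gesture": template.gesture_id,
            "trial": trial_index,
            "onset_frame": onset_f,
            "offset_frame": offset_f,
            "dynamic": not template.is_static,
        },
    )


def make_benchmark(cfg: SynthConfig, dynamic: bool = False
                   ) -> list[Recording]:
    """G x n_trials_per_gesture labeled trials, balanced classes.

    Per-trial RNG streams are spawned from ``(seed, gesture_id, trial)`` so
    the dataset is reproducible and order-independent.
    """
    templates = make_gesture_templates(cfg, dynamic=dynamic)
    trials = []
    for template in templates:
        for k in range(cfg.n_trials_per_gesture):
            ss = np.random.SeedSequence(
                entropy=cfg.seed, spawn_key=(template.gesture_id, k))
            trials.append(simulate_trial(template, cfg, seed=ss,
                                         trial_index=k))
    return trials


def nearest_template_classify(image: np.ndarray,
                              templates: list[GestureTemplate]) -> int:
    """Single-frame baseline: correlate rectified activity with each map.

    Normalized [0, 1] images encode zero signal as 0.5, so the activity
    magnitude is ``|image - 0.5|``.  Returns the gesture whose initial
    spatial map correlates best.  Chance-level performance of this baseline
    on orbit-paired gestures is what makes the dynamic benchmark a clean
    3D-vs-2D discriminator.
    """
    act = np.abs(np.asarray(image, dtype=np.float64) - 0.5).ravel()
    act = act - act.mean()
    scores = []
    for template in templates:
        m = template.spatial_map.ravel() - template.spatial_map.mean()
        denom = np.linalg.norm(act) * np.linalg.norm(m)
        scores.append(float(act @ m / denom) if denom else 0.0)
    return int(np.argmax(scores))


def write_manifest(trials: list[Recording], path: str | Path) -> Path:
    """CSV manifest: trial-id, gesture, onset/offset ground truth."""
    path = Path(path)
    with open(path, "w", newline="") as f:
        writer = _csv.writer(f)
        writer.writerow(["trial_id", "gesture", "trial",
                         "onset_frame", "offset_frame", "fs", "n_frames"])
        for i, rec in enumerate(trials):
            writer.writerow([
                i, rec.meta["gesture"], rec.meta["trial"],
                rec.meta["onset_frame"], rec.meta["offset_frame"],
                rec.fs, rec.n_frames,
            ])
    return path
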