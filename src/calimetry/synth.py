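"""Synthetic calcium-imaging data with full ground truth.

The generator emulates widefield recordings of cultured neurons expressing
a genetically encoded calcium indicator: disk-shaped somata placed without
overlap on a flat background, spiking as Poisson processes optionally mixed
with a shared network drive, calcium following an AR(1) (exponential-decay)
kernel, and fluorescence

    F = baseline * (1 + transient_amplitude * calcium)
        + drift_amplitude * sin(2*pi*t / period)  +  Gaussian noise.

In evoked mode a pulse schedule drives extra spikes at each pulse onset:
cells inside the stimulation mask respond with ``direct_drive_prob`` and a
saturating amplitude; cells outside respond with the (weaker)
``propagated_drive_prob`` and half the direct gain, mimicking network
propagation.  All ground truth (spike frames and amplitudes per cell,
stimulation log, per-cell geometry) is returned, and the same parameters
with the same seed reproduce the output bit-for-bit.

Defaults describe a desk-scale version of a typical experiment: 10 Hz
acquisition, ~1 s indicator decay, sparse spontaneous firing (0.1 Hz),
unit dF/F transients on a baseline of 100 counts with 2 counts of shot
noise and a slow 90 s sinusoidal drift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .errors import GenerationError
from .evoked import StimProtocol
from .plate import FovRecording, write_experiment

__all__ = ["EvokedParams", "SimParams", "FovTruth", "simulate_fov", "simulate_plate"]


@dataclass(frozen=True)
class EvokedParams:
    """Pulse-locked stimulation settings for evoked mode."""

    pulse_onset_frames: tuple[int, ...]
    pulse_duration_ms: float = 100.0
    led_power_pct: tuple[float, ...] = ()
    irradiance_mw_cm2: tuple[float, ...] = ()
    # stimulation mask: axis-aligned box (y0, y1, x0, x1), exclusive ends
    stim_box: tuple[int, int, int, int] = (0, 64, 0, 64)
    direct_drive_prob: float = 0.9
    propagated_drive_prob: float = 0.3
    direct_gain: float = 2.0          # evoked amplitude scale inside the mask
    propagated_gain: float = 1.0      # and outside
    half_saturation_mw_cm2: float = 16.0


@dataclass(frozen=True)
class SimParams:
    """Everything that defines one simulated field of view."""

    grid: tuple[int, int] = (96, 96)
    n_cells: int = 20
    cell_radius_px: int = 4
    frame_rate_hz: float = 10.0
    duration_s: float = 120.0
    spike_rate_hz: float = 0.1
    gamma: float | None = None          # default exp(-dt / decay_s)
    decay_s: float = 1.0
    transient_amplitude: float = 1.0    # dF/F per unit spike
    baseline_counts: float = 100.0
    drift_amplitude: float = 5.0        # counts, additive sinusoid
    drift_period_s: float = 90.0
    noise_sigma_counts: float = 2.0
    shared_drive_weight: float = 0.0
    refractory_frames: int = 0   # min gap between spontaneous spikes
    pixel_size_um: float = 1.0
    evoked: EvokedParams | None = None
    seed: int = 0

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.frame_rate_hz))

    @property
    def kernel_gamma(self) -> float:
        if self.gamma is not None:
            return self.gamma
        return math.exp(-1.0 / (self.frame_rate_hz * self.decay_s))


@dataclass
class FovTruth:
    """Ground truth for one simulated field of view."""

    centers: np.ndarray               # (N, 2) y, x
    spike_frames: list[np.ndarray]    # per cell, sorted
    spike_amplitudes: list[np.ndarray]
    evoked_flags: list[np.ndarray]    # per spike: driven by a pulse?
    calcium: np.ndarray               # (N, T) noiseless kernel output
    dff_clean: np.ndarray             # (N, T) amplitude * calcium
    params: SimParams


def _place_cells(params: SimParams, rng: np.random.Generator) -> np.ndarray:
    """Cell centres by rejection sampling on a jittered grid."""
    Y, X = params.grid
    r = params.cell_radius_px
    pitch = 2 * r + 3
    ys = np.arange(r + 1, Y - r - 1, pitch)
    xs = np.arange(r + 1, X - r - 1, pitch)
    slots = [(y, x) for y in ys for x in xs]
    if len(slots) < params.n_cells:
        raise GenerationError(
            f"grid {params.grid} fits only {len(slots)} cells of radius {r}; "
            f"{params.n_cells} requested"
        )
    order = rng.permutation(len(slots))[: params.n_cells]
    centers = []
    max_jitter = 1  # keeps the pitch-based non-overlap guarantee
    for k in order:
        y, x = slots[k]
        centers.append(
            (
                int(np.clip(y + rng.integers(-max_jitter, max_jitter + 1), r, Y - r - 1)),
                int(np.clip(x + rng.integers(-max_jitter, max_jitter + 1), r, X - r - 1)),
            )
        )
    return np.array(centers, dtype=np.int64)


def _label_mask(params: SimParams, centers: np.ndarray) -> np.ndarray:
    Y, X = params.grid
    yy, xx = np.mgrid[0:Y, 0:X]
    mask = np.zeros((Y, X), dtype=np.uint16)
    for i, (cy, cx) in enumerate(centers, start=1):
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= params.cell_radius_px**2
        mask[disk] = i
    return mask


def simulate_fov(params: SimParams):
    """Simulate one field of view.

    Returns ``(video, label_mask, stim_protocol_or_None, truth)``; the video
    is float32 ``T x Y x X`` clipped at zero, the mask uint16 with labels
    1..n_cells matching truth ordering.
    """
    rng = np.random.default_rng(params.seed)
    T = params.n_frames
    N = params.n_cells
    gamma = params.kernel_gamma
    centers = _place_cells(params, rng)
    mask = _label_mask(params, centers)

    # --- spikes: independent Poisson + shared drive, weight-mixed so the
    # per-cell expected rate stays spike_rate_hz
    dt = 1.0 / params.frame_rate_hz
    w = params.shared_drive_weight
    own = rng.random((N, T)) < (1.0 - w) * params.spike_rate_hz * dt
    shared_events = rng.random(T) < params.spike_rate_hz * dt
    adopt = rng.random((N, T)) < w
    spont = own | (shared_events[None, :] & adopt)
    if params.refractory_frames > 0:
        # forward thinning: drop spikes closer than the refractory gap
        for i in range(N):
            last = -params.refractory_frames - 1
            for t in np.flatnonzero(spont[i]):
                if t - last <= params.refractory_frames:
                    spont[i, t] = False
                else:
                    last = t
    spikes = spont.astype(np.float64)
    evoked_marks = np.zeros((N, T), dtype=bool)

    stim = None
    if params.evoked is not None:
        ev = params.evoked
        y0, y1, x0, x1 = ev.stim_box
        stim_mask = np.zeros(params.grid, dtype=bool)
        stim_mask[y0:y1, x0:x1] = True
        inside = np.array(
            [stim_mask[cy, cx] for cy, cx in centers], dtype=bool
        )
        n_pulses = len(ev.pulse_onset_frames)
        power = np.asarray(
            ev.led_power_pct if ev.led_power_pct else [5.0] * n_pulses
        )
        irr = np.asarray(
            ev.irradiance_mw_cm2
            if ev.irradiance_mw_cm2
            else 10.0 * power
        )
        for p_idx, onset in enumerate(ev.pulse_onset_frames):
            if not 0 <= onset < T:
                raise GenerationError(f"pulse onset {onset} outside recording")
            resp = irr[p_idx] / (irr[p_idx] + ev.half_saturation_mw_cm2)
            prob = np.where(inside, ev.direct_drive_prob, ev.propagated_drive_prob)
            gain = np.where(inside, ev.direct_gain, ev.propagated_gain)
            fires = rng.random(N) < prob
            spikes[fires, onset] += gain[fires] * resp
            evoked_marks[fires, onset] = True
        stim = StimProtocol(
            pulse_onset_frames=np.asarray(ev.pulse_onset_frames, dtype=np.int64),
            pulse_duration_ms=ev.pulse_duration_ms,
            led_power_pct=power,
            irradiance_mw_cm2=irr,
            stim_mask=stim_mask,
        )

    # --- calcium and fluorescence
    calcium = lfilter([1.0], [1.0, -gamma], spikes, axis=1)
    dff_clean = params.transient_amplitude * calcium
    t = np.arange(T)
    drift = params.drift_amplitude * np.sin(
        2 * np.pi * t / (params.drift_period_s * params.frame_rate_hz)
    )
    Y, X = params.grid
    video = np.empty((T, Y, X), dtype=np.float32)
    base = params.baseline_counts
    flat = base + drift  # background level per frame
    video[:] = flat[:, None, None]
    for i in range(N):
        sel = mask == (i + 1)
        video[:, sel] = (base * (1.0 + dff_clean[i]) + drift)[:, None]
    if params.noise_sigma_counts > 0:
        video += rng.normal(0.0, params.noise_sigma_counts, size=video.shape).astype(
            np.float32
        )
    np.clip(video, 0.0, None, out=video)

    spike_frames = [np.flatnonzero(spikes[i] > 0) for i in range(N)]
    truth = FovTruth(
        centers=centers,
        spike_frames=spike_frames,
        spike_amplitudes=[spikes[i][f] for i, f in enumerate(spike_frames)],
        evoked_flags=[evoked_marks[i][f] for i, f in enumerate(spike_frames)],
        calcium=calcium,
        dff_clean=dff_clean,
        params=params,
    )
    return video, mask, stim, truth


def simulate_plate(
    conditions: dict[str, SimParams],
    wells_per_condition: int,
    fovs_per_well: int,
    seed: int,
    out_dir: str | Path | None = None,
    dialect: str = "tiff",
):
    """Simulate a multi-condition plate, optionally writing it to disk.

    Wells are assigned row-major (A01, A02, ...) in condition order; the
    per-FOV seed is derived deterministically from the master seed.
    Returns ``(recordings, plate_map_dict, truths)`` where ``truths`` maps
    (well, fov) -> FovTruth; when ``out_dir`` is given the experiment and
    truth CSVs are written in the loadable layout.
    """
    if not conditions:
        raise ValueError("need at least one condition")
    recordings: list[FovRecording] = []
    plate_map: dict[str, str] = {}
    truths: dict[tuple[str, int], FovTruth] = {}
    well_counter = 0
    ss = np.random.SeedSequence(seed)
    for cond_name, base_params in conditions.items():
        for _ in range(wells_per_condition):
            row, col = divmod(well_counter, 12)
            well_id = f"{chr(ord('A') + row)}{col + 1:02d}"
            well_counter += 1
            plate_map[well_id] = cond_name
            for fov in range(fovs_per_well):
                child = ss.spawn(1)[0]
                fov_seed = int(child.generate_state(1)[0] % (2**31))
                p = replace(base_params, seed=fov_seed)
                video, mask, stim, truth = simulate_fov(p)
                recordings.append(
                    FovRecording(
                        well_id=well_id,
                        fov_index=fov,
                        frame_rate_hz=p.frame_rate_hz,
                        video=video,
                        pixel_size_um=p.pixel_size_um,
                        stim=stim,
                        label_mask=mask,
                    )
                )
                truths[(well_id, fov)] = truth
    if out_dir is not None:
        out_dir = Path(out_dir)
        write_experiment(out_dir, recordings, dialect=dialect)
        _write_truth(out_dir / "truth", truths, plate_map)
    return recordings, plate_map, truths


def _write_truth(truth_dir: Path, truths, plate_map) -> None:
    truth_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for (well, fov), truth in truths.items():
        for cell, frames in enumerate(truth.spike_frames, start=1):
            for frame, amp in zip(frames, truth.spike_amplitudes[cell - 1]):
                rows.append(
                    {"well": well, "fov": fov, "roi": cell,
                     "frame": int(frame), "amplitude": float(amp)}
                )
    pd.DataFrame(rows).to_csv(truth_dir / "spikes.csv", index=False)
    pd.DataFrame(
        [{"well": w, "condition": c} for w, c in plate_map.items()]
    ).to_csv(truth_dir / "plate_map.csv", index=False)
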