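"""Synthetic two-mode migration data with known ground truth.

Everything the pipeline consumes can be generated here with prescribed
parameters, so every stage is testable without microscope data:

* persistent-random-walk trajectories whose ensemble MSD follows the Furth
  model exactly, via the exact discretization of an Ornstein–Uhlenbeck
  velocity process with relaxation time t_p and per-component stationary
  velocity variance M/t_p (so MSD(t) = 4M(t − t_p(1 − e^{−t/t_p})));
* membrane protrusion/retraction event series with mode-specific temporal
  coupling — Continuous: retraction repeats protrusion one frame later
  (tightly coupled, protrusion-led); Discontinuous: sparse large retraction
  events each followed after a delay by a protrusion burst (retraction-led,
  decoupled) on top of weaker one-frame coupling, giving a bimodal
  retraction-size distribution and a second cross-correlation peak at
  positive lag;
* two-mode feature tables: multivariate Gaussian populations with prescribed
  per-feature mean shifts and a latent speed variable coupled to chosen
  features with mode-specific signs;
* rendered label-mask movies: a deformable disk per frame whose boundary is
  edited pixel-by-pixel (angle-contiguous removal/addition) so each frame
  transition realizes the prescribed protrusion/retraction pixel counts
  exactly, plus optional CMAC blobs with known intensities.

All generators are deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.morphology import disk as disk_footprint

from .datatypes import CELL_LAYER, CMAC_LAYER, IntensityMovie, LabelMovie

__all__ = [
    "SyntheticSpec",
    "simulate_trajectory",
    "simulate_membrane_events",
    "simulate_membrane_population",
    "simulate_feature_table",
    "render_mask_movie",
]


@dataclass
class SyntheticSpec:
    """Study conditions for the synthetic two-mode population.

    Defaults mirror the imaging setup (0.21 µm pixels, 5-min frames, 8-h
    movies = 96 frames) and produce the qualitative mode signatures: tightly
    coupled protrusion-led dynamics in the Continuous mode, sparse large
    delayed-coupled retractions in the Discontinuous mode, and a 4-sd shift
    on three of twenty features between the mode populations.
    """

    n_cells_per_mode: int = 50
    frames: int = 96
    frame_interval_min: float = 5.0
    pixel_size_um: float = 0.21
    # trajectory: (migration coefficient µm²/min, persistence time min)
    m_continuous: float = 0.5
    tp_continuous: float = 20.0
    m_discontinuous: float = 2.0
    tp_discontinuous: float = 5.0
    # membrane events
    base_protrusion_um2: float = 8.0
    ar_coefficient: float = 0.7
    coupling_noise_sd: float = 1.0
    retraction_event_rate: float = 0.10
    retraction_event_size_um2: float = 40.0
    response_delay_frames: int = 5
    response_gain: float = 0.8
    baseline_noise_sd: float = 2.0
    # feature table
    n_features: int = 20
    n_shifted_features: int = 3
    effect_size_sd: float = 4.0
    speed_coupling_rs: float = 0.6
    seed: int = 0


def simulate_trajectory(
    m: float,
    t_p: float,
    frames: int,
    dt: float,
    rng: np.random.Generator,
    x0: tuple = (0.0, 0.0),
) -> np.ndarray:
    """2-D persistent random walk sampled exactly at the frame grid.

    The velocity is a stationary Ornstein–Uhlenbeck process (relaxation time
    ``t_p`` min, per-component variance ``m / t_p``), and position/velocity
    are advanced jointly with the exact Gaussian transition, so the ensemble
    MSD equals 4M(t − t_p(1 − e^{−t/t_p})) at every lag.  ``t_p = 0`` is the
    diffusive limit (independent steps of variance 2·M·dt per component).

    Returns positions in µm, shape ``(frames, 2)``.
    """
    if m < 0 or t_p < 0:
        raise ValueError("M and t_p must be non-negative")
    pos = np.empty((frames, 2))
    pos[0] = x0
    if frames == 1:
        return pos
    if m == 0:
        pos[:] = x0
        return pos
    if t_p < 1e-9:
        steps = rng.normal(0.0, np.sqrt(2.0 * m * dt), size=(frames - 1, 2))
        pos[1:] = np.asarray(x0) + np.cumsum(steps, axis=0)
        return pos
    c = m / t_p  # stationary velocity variance per component
    mu = np.exp(-dt / t_p)
    var_v = c * (1.0 - mu**2)
    var_x = c * (2.0 * t_p * dt - t_p**2 * (3.0 - 4.0 * mu + mu**2))
    cov_xv = c * t_p * (1.0 - mu) ** 2
    cov = np.array([[var_x, cov_xv], [cov_xv, var_v]])
    # guard tiny negative eigenvalues from rounding
    evals, evecs = np.linalg.eigh(cov)
    chol = evecs @ np.diag(np.sqrt(np.clip(evals, 0.0, None)))
    v = rng.normal(0.0, np.sqrt(c), size=2)
    for t in range(1, frames):
        z = rng.standard_normal((2, 2))  # (xi_x, xi_v) per component
        noise = z @ chol.T
        pos[t] = pos[t - 1] + v * t_p * (1.0 - mu) + noise[:, 0]
        v = v * mu + noise[:, 1]
    return pos


def simulate_membrane_events(
    mode: str,
    frames: int,
    rng: np.random.Generator,
    spec: SyntheticSpec | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Protrusion and retraction area series (µm²) for one cell.

    Continuous: protrusion follows a positive AR(1) fluctuation and the
    retraction series repeats it one frame later plus Gaussian noise
    (``coupling_noise_sd``; 0 gives an exact one-frame copy, so the
    cross-correlation peaks at lag −1 with value 1).

    Discontinuous: retraction mixes a small noisy baseline, weak one-frame
    coupling and sparse large events (rate ``retraction_event_rate``, size
    ``retraction_event_size_um2``); each large event triggers a protrusion
    burst ``response_delay_frames`` later, so retraction leads protrusion at
    a positive lag and retraction sizes are bimodal.
    """
    spec = spec or SyntheticSpec()
    base = spec.base_protrusion_um2
    if mode == "Continuous":
        innov = rng.normal(0.0, 2.0, size=frames)
        u = np.empty(frames)
        u[0] = innov[0]
        for t in range(1, frames):
            u[t] = spec.ar_coefficient * u[t - 1] + innov[t]
        p = base + u
        r = np.empty(frames)
        r[0] = p[0]
        r[1:] = p[:-1]
        if spec.coupling_noise_sd > 0:
            r = r + rng.normal(0.0, spec.coupling_noise_sd, size=frames)
        return p, r
    if mode == "Discontinuous":
        events = (
            rng.random(frames) < spec.retraction_event_rate
        ) * spec.retraction_event_size_um2 * (1.0 + 0.2 * rng.standard_normal(frames))
        events = np.clip(events, 0.0, None)
        p = base + np.abs(rng.normal(0.0, spec.baseline_noise_sd, size=frames))
        d = spec.response_delay_frames
        if d < frames:
            p[d:] += spec.response_gain * events[:-d]
        r = (
            np.abs(rng.normal(2.0, spec.baseline_noise_sd, size=frames))
            + events
        )
        r[1:] += 0.3 * (p[:-1] - base)
        return p, np.clip(r, 0.0, None)
    raise ValueError(f"mode must be 'Continuous' or 'Discontinuous', got {mode!r}")


def simulate_membrane_population(
    mode: str,
    n_cells: int,
    frames: int,
    seed: int,
    spec: SyntheticSpec | None = None,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Independent per-cell event series; deterministic for a given seed."""
    rng = np.random.default_rng(seed)
    return [simulate_membrane_events(mode, frames, rng, spec) for _ in range(n_cells)]


def simulate_feature_table(
    spec: SyntheticSpec | None = None,
    seed: int | None = None,
    frames_per_cell: int = 20,
    coupled_features: dict | None = None,
) -> pd.DataFrame:
    """Two-mode feature table with prescribed effects and speed couplings.

    Each (cell, frame) row draws ``n_features`` Gaussian features (unit sd);
    the first ``n_shifted_features`` are shifted by ``effect_size_sd`` in the
    Continuous mode.  A latent per-observation speed drives chosen features
    with mode-specific correlation signs: ``coupled_features`` maps a feature
    name to ``(sign_discontinuous, sign_continuous)``; the default couples
    ``f19`` at (+, −), an "inverted" coupling.

    Feature columns are ``f00``..; speed is ``cell_speed_um_per_min``.
    """
    spec = spec or SyntheticSpec()
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)
    names = [f"f{i:02d}" for i in range(spec.n_features)]
    if coupled_features is None:
        coupled_features = {names[-1]: (1.0, -1.0)}
    rho = spec.speed_coupling_rs
    rows = []
    cell_id = 0
    for mode_idx, mode in enumerate(["Discontinuous", "Continuous"]):
        # Discontinuous cells migrate faster on average
        speed_mean = 0.30 if mode == "Discontinuous" else 0.15
        for _ in range(spec.n_cells_per_mode):
            z_speed = rng.standard_normal(frames_per_cell)
            speed = np.clip(speed_mean * (1.0 + 0.4 * z_speed), 1e-3, None)
            x = rng.standard_normal((frames_per_cell, spec.n_features))
            x[:, : spec.n_shifted_features] += mode_idx * spec.effect_size_sd
            for fname, (sign_d, sign_c) in coupled_features.items():
                j = names.index(fname)
                sign = sign_d if mode == "Discontinuous" else sign_c
                x[:, j] = (
                    sign * rho * z_speed
                    + np.sqrt(1.0 - rho**2) * rng.standard_normal(frames_per_cell)
                )
            for t in range(frames_per_cell):
                row = {
                    "cell_track_id": cell_id,
                    "frame": t,
                    "condition": "synthetic",
                    "repeat_id": 1,
                    "mode": mode,
                    "cell_speed_um_per_min": speed[t],
                }
                row.update(dict(zip(names, x[t])))
                rows.append(row)
            cell_id += 1
    return pd.DataFrame(rows)


def _angle_contiguous(pixels: np.ndarray, center: np.ndarray, k: int, start: float) -> np.ndarray:
    """Pick k pixels contiguous in polar angle around ``center``."""
    ang = np.arctan2(pixels[:, 0] - center[0], pixels[:, 1] - center[1])
    order = np.argsort((ang - start) % (2 * np.pi))
    return pixels[order[:k]]


def render_mask_movie(
    protrusion_px: np.ndarray,
    retraction_px: np.ndarray,
    track_um: np.ndarray | None = None,
    shape: tuple = (128, 128),
    radius_px: int = 18,
    pixel_size_um: float = 0.21,
    frame_interval_min: float = 5.0,
    seed: int = 0,
    cmac_offsets_px: tuple = ((-5, -4), (4, 5), (6, -3)),
    cmac_radius_px: int = 2,
    background_intensity: float = 2.0,
    cmac_intensity: float = 10.0,
    intensity_noise_sd: float = 0.0,
) -> dict:
    """Render a single-cell label movie realizing prescribed event areas.

    Frame t+1 derives from frame t by translating the mask by the rounded
    trajectory displacement, removing ``retraction_px[t]`` boundary pixels
    and adding ``protrusion_px[t]`` adjacent outside pixels, both as
    angle-contiguous arcs (localized, protrusion-like).  For an integer-
    stationary track the per-transition pixel differences measured back from
    the movie equal the prescribed counts exactly.

    Also renders a CMAC label layer (blobs riding at fixed offsets from the
    cell position) and paxillin/LifeAct intensity stacks with the CMAC pixels
    at ``cmac_intensity`` on ``background_intensity``.

    Returns ``{"cells", "cmacs", "paxillin", "lifeact"}``.
    """
    protrusion_px = np.asarray(protrusion_px, dtype=int)
    retraction_px = np.asarray(retraction_px, dtype=int)
    if len(protrusion_px) != len(retraction_px):
        raise ValueError("event series lengths differ")
    n_frames = len(protrusion_px) + 1
    if track_um is None:
        track_um = np.zeros((n_frames, 2))
    track_px = np.round(np.asarray(track_um) / pixel_size_um).astype(int)
    if len(track_px) != n_frames:
        raise ValueError("trajectory and event series lengths inconsistent")
    rng = np.random.default_rng(seed)
    center0 = np.array([shape[0] // 2, shape[1] // 2]) + track_px[0][::-1]
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    mask = (rr - center0[0]) ** 2 + (cc - center0[1]) ** 2 <= radius_px**2
    masks = [mask]
    for t in range(n_frames - 1):
        delta = track_px[t + 1] - track_px[t]  # (dx, dy) in pixels
        m = np.roll(np.roll(masks[-1], delta[1], axis=0), delta[0], axis=1)
        center = np.array(ndimage.center_of_mass(m))
        k_r = int(retraction_px[t])
        k_p = int(protrusion_px[t])
        if k_r >= m.sum():
            raise ValueError(f"retraction of {k_r} px exceeds cell area at frame {t}")
        if k_r > 0:
            boundary = m & ~ndimage.binary_erosion(m)
            cand = np.argwhere(boundary)
            if len(cand) < k_r:
                raise ValueError(f"retraction of {k_r} px exceeds boundary at frame {t}")
            chosen = _angle_contiguous(cand, center, k_r, rng.uniform(0, 2 * np.pi))
            m = m.copy()
            m[chosen[:, 0], chosen[:, 1]] = False
        if k_p > 0:
            ring = ndimage.binary_dilation(m) & ~m & ~masks[-1]
            cand = np.argwhere(ring)
            if len(cand) < k_p:
                # widen the search ring away from the previous mask
                ring = (
                    ndimage.binary_dilation(m, iterations=3) & ~m & ~masks[-1]
                )
                cand = np.argwhere(ring)
            if len(cand) < k_p:
                raise ValueError(f"cannot place {k_p} protrusion px at frame {t}")
            chosen = _angle_contiguous(cand, center, k_p, rng.uniform(0, 2 * np.pi))
            m = m.copy()
            m[chosen[:, 0], chosen[:, 1]] = True
        masks.append(m)
    cell_frames = np.stack(masks).astype(np.uint16)
    cmac_frames = np.zeros_like(cell_frames)
    foot = disk_footprint(cmac_radius_px).astype(bool)
    fr = cmac_radius_px
    for t in range(n_frames):
        base = np.array([shape[0] // 2, shape[1] // 2]) + track_px[t][::-1]
        for lab, (dy, dx) in enumerate(cmac_offsets_px, start=1):
            r0, c0 = base[0] + dy, base[1] + dx
            sl = (slice(r0 - fr, r0 + fr + 1), slice(c0 - fr, c0 + fr + 1))
            region = cmac_frames[t][sl]
            region[foot] = lab
    pax = np.full(cell_frames.shape, background_intensity, dtype=float)
    pax[cmac_frames > 0] = cmac_intensity
    if intensity_noise_sd > 0:
        pax = pax + rng.normal(0.0, intensity_noise_sd, size=pax.shape)
    lifeact = np.full(cell_frames.shape, background_intensity, dtype=float)
    lifeact[cell_frames > 0] = background_intensity + 2.0
    lifeact[cmac_frames > 0] = cmac_intensity * 0.8
    meta = dict(pixel_size_um=pixel_size_um, frame_interval_min=frame_interval_min)
    return {
        "cells": LabelMovie(cell_frames, layer=CELL_LAYER, **meta),
        "cmacs": LabelMovie(cmac_frames, layer=CMAC_LAYER, **meta),
        "paxillin": IntensityMovie(pax, channel="paxillin", **meta),
        "lifeact": IntensityMovie(lifeact, channel="lifeact", **meta),
    }
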