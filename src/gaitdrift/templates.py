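"""Closed-form stride-curve templates.

These are statistical emulations of typical barefoot-walking waveforms, not
forward dynamics: a double-peaked vertical ground reaction force (GRF) with a
mid-stance valley, a braking/propulsive anterior-posterior force lobe pair
with near-zero impulse, a small mediolateral force, and smooth sinusoid/bump
joint-angle trajectories.  Only smoothness, channel count and a handful of
gross features (peak heights, threshold crossings) are contractual; the exact
shapes are free parameters of the generator.

All templates are functions of normalised stance/stride time ``s`` in [0, 1].
GRF templates are in body-weight (BW) units; angles in degrees.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "GRF_CHANNELS",
    "ANGLE_CHANNELS",
    "grf_template",
    "angle_template",
    "joined_template",
    "channels_for",
]

#: Canonical channel order for the kinetic modality:
#: 2 ground contacts (right then left foot) x 3 force directions.
GRF_CHANNELS: tuple[str, ...] = tuple(
    f"grf_{side}_{direction}"
    for side in ("right", "left")
    for direction in ("vertical", "anterior_posterior", "medio_lateral")
)

#: Canonical channel order for the kinematic modality:
#: 2 legs x 3 joints x 3 planes = 18 channels.
ANGLE_CHANNELS: tuple[str, ...] = tuple(
    f"{joint}_{side}_{plane}"
    for side in ("right", "left")
    for joint in ("hip", "knee", "ankle")
    for plane in ("sagittal", "frontal", "transverse")
)


def _grid(n_points: int) -> np.ndarray:
    if n_points < 10:
        raise ValueError(f"n_points must be >= 10, got {n_points}")
    return np.linspace(0.0, 1.0, n_points)


def _vertical(s: np.ndarray) -> np.ndarray:
    # Two narrow loading/push-off humps on a broad base: peaks ~1.1 BW near
    # 25% and 75% of stance, valley in mid-stance, ends < 0.05 BW.
    humps = 0.84 * (
        np.exp(-(((s - 0.25) / 0.13) ** 2)) + np.exp(-(((s - 0.75) / 0.13) ** 2))
    )
    base = 0.55 * np.exp(-(((s - 0.5) / 0.28) ** 2))
    return humps + base


def _anterior_posterior(s: np.ndarray) -> np.ndarray:
    # Braking (negative) then propulsive lobe; sin(2*pi*s) is antisymmetric
    # about mid-stance and sin(pi*s) symmetric, so the impulse is exactly 0
    # in continuous time.
    return -0.2 * np.sin(2 * np.pi * s) * np.sin(np.pi * s)


def _medio_lateral(s: np.ndarray) -> np.ndarray:
    return 0.05 * np.sin(2 * np.pi * s) * np.sin(np.pi * s) + 0.03 * np.sin(
        np.pi * s
    )


def grf_template(n_points: int = 100) -> dict[str, np.ndarray]:
    """Per-channel GRF template curves in body-weight units.

    The left-foot contact reuses the right-foot shapes mirrored in time
    (and sign-flipped mediolaterally), which keeps every channel smooth while
    making the two contacts distinguishable.
    """
    s = _grid(n_points)
    right = {
        "grf_right_vertical": _vertical(s),
        "grf_right_anterior_posterior": _anterior_posterior(s),
        "grf_right_medio_lateral": _medio_lateral(s),
    }
    left = {
        "grf_left_vertical": _vertical(1.0 - s),
        "grf_left_anterior_posterior": -_anterior_posterior(1.0 - s),
        "grf_left_medio_lateral": -_medio_lateral(1.0 - s),
    }
    out = {**right, **left}
    return {name: out[name] for name in GRF_CHANNELS}


def _hip_sagittal(s: np.ndarray) -> np.ndarray:
    return 20.0 * np.cos(2 * np.pi * s) + 8.0


def _knee_sagittal(s: np.ndarray) -> np.ndarray:
    stance_flexion = 15.0 * np.exp(-(((s - 0.15) / 0.10) ** 2))
    swing_flexion = 60.0 * np.exp(-(((s - 0.72) / 0.12) ** 2))
    return stance_flexion + swing_flexion + 5.0


def _ankle_sagittal(s: np.ndarray) -> np.ndarray:
    return -10.0 * np.sin(2 * np.pi * s) + 5.0 * np.sin(np.pi * s)


_SAGITTAL = {"hip": _hip_sagittal, "knee": _knee_sagittal, "ankle": _ankle_sagittal}
# Small out-of-sagittal-plane motion; (amplitude in degrees, phase) per joint.
_MINOR = {
    ("hip", "frontal"): (6.0, 0.1),
    ("hip", "transverse"): (4.0, 0.7),
    ("knee", "frontal"): (3.0, 0.4),
    ("knee", "transverse"): (5.0, 1.1),
    ("ankle", "frontal"): (4.0, 0.9),
    ("ankle", "transverse"): (3.0, 1.6),
}


def angle_template(n_points: int = 100) -> dict[str, np.ndarray]:
    """Per-channel joint-angle template curves in degrees.

    Sagittal hip/knee/ankle use textbook-shaped trajectories; frontal and
    transverse planes are low-amplitude sinusoids with joint-specific phases.
    The left leg mirrors the right in time (half-cycle phase relationship of
    alternating gait).
    """
    s = _grid(n_points)
    out: dict[str, np.ndarray] = {}
    for side in ("right", "left"):
        u = s if side == "right" else 1.0 - s
        for joint in ("hip", "knee", "ankle"):
            out[f"{joint}_{side}_sagittal"] = _SAGITTAL[joint](u)
            for plane in ("frontal", "transverse"):
                amp, phase = _MINOR[(joint, plane)]
                out[f"{joint}_{side}_{plane}"] = amp * np.sin(
                    2 * np.pi * u + phase
                )
    return {name: out[name] for name in ANGLE_CHANNELS}


def channels_for(modality: str) -> tuple[str, ...]:
    if modality == "grf":
        return GRF_CHANNELS
    if modality == "angles":
        return ANGLE_CHANNELS
    raise ValueError(f"unknown modality {modality!r}")


def joined_template(modality: str, n_points: int = 100) -> np.ndarray:
    """Template joined vector (channel-major, time-minor order)."""
    curves = grf_template(n_points) if modality == "grf" else angle_template(n_points)
    return np.concatenate([curves[c] for c in channels_for(modality)])
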