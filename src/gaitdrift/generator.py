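"""Synthetic multi-session stride-curve datasets.

The generator emulates the study design — 9 subjects x 6 sessions x 15 trials,
with 600-feature GRF vectors (100 points x 2 contacts x 3 directions) or
1800-feature joint-angle vectors (100 points x 2 legs x 3 joints x 3 planes) —
with two stochastic layers on top of a fixed per-subject template:

* **session drift**: a Gaussian random walk (Brownian motion) in the
  coefficients of a smooth orthonormal basis, evaluated at the session start
  times, so that ``E ||drift(s_i) - drift(s_j)||^2 = basis_rank *
  drift_scale^2 * |t_i - t_j|``.  Separation between sessions therefore grows
  with elapsed time, which is the structure the classification analysis is
  designed to detect.
* **trial noise**: independent Gaussian noise in the same basis with scale
  ``noise_scale`` per coefficient (stride-to-stride fluctuation).

Because the basis rows are orthonormal over the joined feature vector, the
stated drift expectation holds exactly in curve space.  GRF curves are
emitted in Newtons (template and perturbations act in body-weight units and
are scaled by m*g), so the preprocessing chain's body-weight normalisation is
exercised for real; angle curves are in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .schedule import SessionSchedule, default_schedule
from .templates import channels_for, joined_template, _vertical

G_ACCEL = 9.81  # m/s^2

__all__ = [
    "GeneratorConfig",
    "StrideTrial",
    "smooth_basis",
    "generate_dataset",
    "raw_vertical_grf",
    "trials_to_frame",
    "frame_to_trials",
    "write_trials_csv",
    "read_trials_csv",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Generator settings; defaults reproduce the emulated study design."""

    n_subjects: int = 9
    n_sessions: int = 6
    n_trials: int = 15
    n_points: int = 100
    modality: str = "grf"
    drift_scale: float = 0.0125  # per sqrt(minute), body-weight units
    noise_scale: float = 0.05  # per trial per basis coefficient
    basis_rank: int = 8
    subject_scale: float = 0.2  # between-subject template perturbation
    body_mass_mean: float = 73.2  # kg
    body_mass_sd: float = 13.3  # kg
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_sessions", "n_trials", "n_points"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.drift_scale < 0 or self.noise_scale < 0:
            raise ValueError("drift_scale and noise_scale must be >= 0")
        if self.basis_rank < 1 or self.basis_rank > self.n_points:
            raise ValueError("basis_rank must be in [1, n_points]")
        if self.modality not in ("grf", "angles"):
            raise ValueError(f"unknown modality {self.modality!r}")


@dataclass
class StrideTrial:
    """One trial's multichannel stride curves with identifying labels."""

    subject_id: str
    session_id: str
    trial_index: int
    channels: tuple[str, ...]
    curves: dict[str, np.ndarray]
    body_mass: float | None = None  # kg; GRF modality only

    def joined(self) -> np.ndarray:
        """Channel-major, time-minor joined vector."""
        return np.concatenate([self.curves[c] for c in self.channels])


def smooth_basis(modality: str, basis_rank: int, n_points: int = 100) -> np.ndarray:
    """Orthonormal smooth basis over the joined feature vector.

    Rows are cosine modes cos(pi*k*s), k = 1..rank, repeated over every
    channel, then orthonormalised by QR so that ``B @ B.T = I`` exactly.
    Linear combinations of cosines stay smooth, and orthonormality makes the
    drift-separation identity exact in joined-curve space.
    """
    channels = channels_for(modality)
    s = np.linspace(0.0, 1.0, n_points)
    raw = np.stack(
        [
            np.tile(np.cos(np.pi * k * s), len(channels))
            for k in range(1, basis_rank + 1)
        ]
    )
    q, _ = np.linalg.qr(raw.T)  # (features, rank), orthonormal columns
    basis = q.T
    # canonical sign: largest-magnitude element of each row positive
    for row in basis:
        j = np.argmax(np.abs(row))
        if row[j] < 0:
            row *= -1.0
    return basis


def _split(joined: np.ndarray, channels: tuple[str, ...], n_points: int):
    return {
        c: joined[i * n_points : (i + 1) * n_points].copy()
        for i, c in enumerate(channels)
    }


def generate_dataset(
    config: GeneratorConfig, schedule: SessionSchedule | None = None
) -> list[StrideTrial]:
    """Generate all trials of the configured design.

    Each trial's joined vector is ``template + subject offset +
    B^T theta_session + B^T eta_trial`` where ``theta`` follows a Brownian
    random walk across session start times and ``eta`` is i.i.d. trial noise.
    Fully reproducible under a fixed ``config.seed``.
    """
    if schedule is None:
        schedule = default_schedule()
    if schedule.n_sessions < config.n_sessions:
        raise ValueError("schedule has fewer sessions than requested")
    sessions = schedule.session_ids[: config.n_sessions]
    times = np.asarray(schedule.start_times[: config.n_sessions])

    rng = np.random.default_rng(config.seed)
    channels = channels_for(config.modality)
    template = joined_template(config.modality, config.n_points)
    basis = smooth_basis(config.modality, config.basis_rank, config.n_points)
    rank = config.basis_rank

    trials: list[StrideTrial] = []
    for si in range(config.n_subjects):
        subject_id = f"sub{si + 1:02d}"
        mass = None
        if config.modality == "grf":
            mass = float(
                np.clip(
                    rng.normal(config.body_mass_mean, config.body_mass_sd),
                    40.0,
                    None,
                )
            )
        subj_offset = basis.T @ rng.normal(0.0, config.subject_scale, rank)
        # Brownian walk over session start times (theta = 0 at first session)
        theta = np.zeros(rank)
        for j, session_id in enumerate(sessions):
            if j > 0:
                dt = times[j] - times[j - 1]
                theta = theta + rng.normal(
                    0.0, config.drift_scale * np.sqrt(dt), rank
                )
            drift = basis.T @ theta
            for ti in range(config.n_trials):
                eta = rng.normal(0.0, config.noise_scale, rank)
                joined = template + subj_offset + drift + basis.T @ eta
                if config.modality == "grf":
                    joined = joined * (mass * G_ACCEL)  # BW units -> Newtons
                trials.append(
                    StrideTrial(
                        subject_id=subject_id,
                        session_id=session_id,
                        trial_index=ti,
                        channels=channels,
                        curves=_split(joined, channels, config.n_points),
                        body_mass=mass,
                    )
                )
    return trials


def raw_vertical_grf(
    body_mass: float = 73.2,
    n_raw: int = 250,
    contact: tuple[int, int] = (25, 224),
    rng: np.random.Generator | None = None,
    noise_scale: float = 0.0,
) -> tuple[np.ndarray, tuple[int, int]]:
    """A raw (unsegmented) vertical GRF series in Newtons with known contacts.

    Zeros outside the stance window, the double-peak template inside; used to
    exercise threshold-based stride segmentation with a known ground truth.
    Returns ``(series, (first_contact_index, last_contact_index))``.
    """
    i0, i1 = contact
    if not (0 <= i0 < i1 < n_raw):
        raise ValueError("contact window must lie inside the series")
    series = np.zeros(n_raw)
    s = np.linspace(0.0, 1.0, i1 - i0 + 1)
    stance = _vertical(s)
    if noise_scale > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        stance = stance + rng.normal(0.0, noise_scale, stance.shape)
    series[i0 : i1 + 1] = stance * body_mass * G_ACCEL
    return series, (i0, i1)


# ---------------------------------------------------------------------------
# CSV interchange: one row per trial-channel, columns t000..t0NN.

def trials_to_frame(trials: list[StrideTrial]) -> pd.DataFrame:
    if not trials:
        raise ValueError("no trials to write")
    n_points = len(next(iter(trials[0].curves.values())))
    tcols = [f"t{i:03d}" for i in range(n_points)]
    rows = []
    for tr in trials:
        for ch in tr.channels:
            rows.append(
                {
                    "subject": tr.subject_id,
                    "session": tr.session_id,
                    "trial": tr.trial_index,
                    "channel": ch,
                    "body_mass": np.nan if tr.body_mass is None else tr.body_mass,
                    **dict(zip(tcols, tr.curves[ch])),
                }
            )
    return pd.DataFrame(rows)


def frame_to_trials(frame: pd.DataFrame) -> list[StrideTrial]:
    tcols = [c for c in frame.columns if c.startswith("t") and c[1:].isdigit()]
    trials = []
    for (subj, sess, ti), grp in frame.groupby(
        ["subject", "session", "trial"], sort=True
    ):
        channels = tuple(grp["channel"])
        mass = grp["body_mass"].iloc[0]
        trials.append(
            StrideTrial(
                subject_id=str(subj),
                session_id=str(sess),
                trial_index=int(ti),
                channels=channels,
                curves={
                    row["channel"]: row[tcols].to_numpy(dtype=float)
                    for _, row in grp.iterrows()
                },
                body_mass=None if pd.isna(mass) else float(mass),
            )
        )
    return trials


def write_trials_csv(trials: list[StrideTrial], path) -> None:
    trials_to_frame(trials).to_csv(path, index=False)


def read_trials_csv(path) -> list[StrideTrial]:
    return frame_to_trials(pd.read_csv(path))
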