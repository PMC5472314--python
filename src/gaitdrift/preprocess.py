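"""Preprocessing chain from raw stride curves to joined classification vectors.

Order of operations for the full chain (per subject):

1. stride segmentation by a 10 N vertical-force threshold (raw recordings);
2. zero-phase 2nd-order Butterworth low-pass at 18 Hz (joint angles);
3. body-weight normalisation (GRF);
4. time normalisation of every channel to 100 points;
5. joining of all channels into one row per trial (channel-major order);
6. z-transform — per trial for angles, per feature across all of the
   subject's trials for GRF;
7. affine scaling of every feature column to [-1, 1].

Steps 6-7 are defined across the subject's trial set, so the implementation
assembles the joined matrix first and then standardises/scales it; the
per-row / per-column scopes are exactly the per-trial / across-trials
conventions of the processing chain.  A fold-safe variant (fitting the
standardisation and scaling on training rows only) is available to the
cross-validation harness via :func:`fit_column_transform`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from .generator import G_ACCEL, StrideTrial
from .templates import channels_for

__all__ = [
    "StrideSegmentationError",
    "DegenerateInputError",
    "FeatureMatrix",
    "segment_stride",
    "butterworth_lowpass",
    "normalize_bodyweight",
    "time_normalize",
    "z_transform",
    "scale_to_range",
    "join_vectors",
    "build_feature_matrix",
    "fit_column_transform",
    "apply_column_transform",
]


class StrideSegmentationError(ValueError):
    """Raised when no supra-threshold epoch exists in a force series."""


class DegenerateInputError(ValueError):
    """Raised when a standardisation unit has zero variance."""


@dataclass
class FeatureMatrix:
    """n_trials x n_features joined-vector matrix for one subject."""

    values: np.ndarray
    session_labels: np.ndarray
    subject_id: str
    modality: str
    feature_names: list[str]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.values, columns=self.feature_names)
        frame.insert(0, "session", self.session_labels)
        return frame

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, subject_id: str = "", modality: str = "") -> "FeatureMatrix":
        frame = pd.read_csv(path)
        labels = frame.pop("session").to_numpy()
        return cls(
            values=frame.to_numpy(dtype=float),
            session_labels=labels,
            subject_id=subject_id,
            modality=modality,
            feature_names=list(frame.columns),
        )


def segment_stride(
    vertical_grf: np.ndarray,
    threshold_newton: float = 10.0,
    left_vertical_grf: np.ndarray | None = None,
) -> tuple[int, int]:
    """Stride window from right heel strike to left toe off.

    Returns ``(first, last)`` sample indices: the first index of the
    (right-foot) series at or above the threshold through the last index of
    the left-foot series at or above it.  With a single combined series the
    same series serves both roles.
    """
    right = np.asarray(vertical_grf, dtype=float)
    left = right if left_vertical_grf is None else np.asarray(
        left_vertical_grf, dtype=float
    )
    above_r = right >= threshold_newton
    above_l = left >= threshold_newton
    if not above_r.any() or not above_l.any():
        raise StrideSegmentationError(
            f"no sample reaches the {threshold_newton} N threshold; unusable trial"
        )
    first = int(np.argmax(above_r))
    last = int(len(left) - 1 - np.argmax(above_l[::-1]))
    if last < first:
        raise StrideSegmentationError("left toe off precedes right heel strike")
    return first, last


def butterworth_lowpass(
    curve: np.ndarray,
    sample_rate_hz: float = 250.0,
    cutoff_hz: float = 18.0,
    order: int = 2,
) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth low-pass filter."""
    if cutoff_hz >= sample_rate_hz / 2:
        raise ValueError("cutoff must be below the Nyquist frequency")
    b, a = butter(order, cutoff_hz, btype="low", fs=sample_rate_hz)
    curve = np.asarray(curve, dtype=float)
    padlen = min(3 * max(len(a), len(b)), len(curve) - 1)
    return filtfilt(b, a, curve, padlen=padlen)


def normalize_bodyweight(
    grf_curves: dict[str, np.ndarray] | np.ndarray,
    body_mass_kg: float,
    g: float = G_ACCEL,
) -> dict[str, np.ndarray] | np.ndarray:
    """Divide force samples by body weight (m*g), yielding body-weight units."""
    if body_mass_kg <= 0:
        raise ValueError("body mass must be positive")
    bw = body_mass_kg * g
    if isinstance(grf_curves, dict):
        return {k: np.asarray(v, dtype=float) / bw for k, v in grf_curves.items()}
    return np.asarray(grf_curves, dtype=float) / bw


def time_normalize(curve: np.ndarray, n_out: int = 100) -> np.ndarray:
    """Linear interpolation onto ``n_out`` equally spaced points.

    First and last samples are preserved; linear functions are resampled
    exactly.
    """
    curve = np.asarray(curve, dtype=float)
    if curve.size < 2:
        raise ValueError("curve must contain at least 2 samples")
    x_in = np.linspace(0.0, 1.0, curve.size)
    x_out = np.linspace(0.0, 1.0, n_out)
    return np.interp(x_out, x_in, curve)


def z_transform(matrix: np.ndarray, mode: str) -> np.ndarray:
    """Standardise to mean 0, sd 1 (population sd).

    ``per_trial``: each row across its own features (kinematic convention);
    ``global``: each feature column across all trials (kinetic convention).
    """
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    if mode == "per_trial":
        mean = matrix.mean(axis=1, keepdims=True)
        sd = matrix.std(axis=1, keepdims=True)
        if np.any(sd == 0):
            raise DegenerateInputError("constant trial row: zero variance")
        return (matrix - mean) / sd
    if mode == "global":
        mean = matrix.mean(axis=0, keepdims=True)
        sd = matrix.std(axis=0, keepdims=True)
        if np.any(sd == 0):
            raise DegenerateInputError("constant feature column: zero variance")
        return (matrix - mean) / sd
    raise ValueError(f"mode must be 'per_trial' or 'global', got {mode!r}")


def scale_to_range(
    matrix: np.ndarray, lo: float = -1.0, hi: float = 1.0
) -> np.ndarray:
    """Affinely map each feature column so its min -> lo and max -> hi.

    Constant columns map to the midpoint (lo + hi) / 2.
    """
    if lo >= hi:
        raise ValueError("lo must be < hi")
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    cmin = matrix.min(axis=0, keepdims=True)
    cmax = matrix.max(axis=0, keepdims=True)
    span = cmax - cmin
    constant = span == 0
    safe_span = np.where(constant, 1.0, span)
    scaled = lo + (matrix - cmin) * (hi - lo) / safe_span
    return np.where(constant, (lo + hi) / 2.0, scaled)


def join_vectors(trials: list[StrideTrial], modality: str) -> FeatureMatrix:
    """Concatenate each trial's channels (channel-major, time-minor) into rows.

    Row order is the trial order given; session labels are attached.  Raises
    on inconsistent channel sets or lengths.
    """
    if not trials:
        raise ValueError("no trials")
    channels = channels_for(modality)
    n_points = len(next(iter(trials[0].curves.values())))
    rows = []
    for tr in trials:
        if set(tr.channels) != set(channels):
            raise ValueError(
                f"trial {tr.subject_id}/{tr.session_id}/{tr.trial_index} has "
                f"channel set inconsistent with modality {modality!r}"
            )
        vec = np.concatenate([tr.curves[c] for c in channels])
        if vec.size != len(channels) * n_points:
            raise ValueError("inconsistent curve lengths across trials")
        rows.append(vec)
    feature_names = [
        f"{c}_t{i:03d}" for c in channels for i in range(n_points)
    ]
    return FeatureMatrix(
        values=np.vstack(rows),
        session_labels=np.asarray([tr.session_id for tr in trials]),
        subject_id=trials[0].subject_id,
        modality=modality,
        feature_names=feature_names,
    )


def fit_column_transform(values: np.ndarray, modality: str) -> dict:
    """Fit the across-trials stages (global z for GRF, column scaling) on a
    training block only, for leakage-free cross-validation."""
    params: dict = {"modality": modality}
    work = values
    if modality == "grf":
        mean = work.mean(axis=0)
        sd = work.std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
        params["z_mean"], params["z_sd"] = mean, sd
        work = (work - mean) / sd
    cmin = work.min(axis=0)
    cmax = work.max(axis=0)
    params["cmin"], params["cmax"] = cmin, cmax
    return params


def apply_column_transform(values: np.ndarray, params: dict) -> np.ndarray:
    work = np.atleast_2d(values)
    if "z_mean" in params:
        work = (work - params["z_mean"]) / params["z_sd"]
    cmin, cmax = params["cmin"], params["cmax"]
    span = cmax - cmin
    constant = span == 0
    safe = np.where(constant, 1.0, span)
    out = -1.0 + (work - cmin) * 2.0 / safe
    return np.where(constant, 0.0, out)


def build_feature_matrix(
    trials: list[StrideTrial],
    modality: str,
    n_points: int = 100,
    apply_filter: bool = True,
    filter_sample_rate_hz: float = 250.0,
    scaled: bool = True,
) -> FeatureMatrix:
    """Run the full per-subject chain on stride-extracted trials.

    ``scaled=False`` stops after joining (before the across-trials z/scale
    stages); the cross-validation harness uses that variant together with
    :func:`fit_column_transform` when fold-safe scaling is requested.
    """
    subjects = {tr.subject_id for tr in trials}
    if len(subjects) != 1:
        raise ValueError(
            "feature matrices are per subject; got trials from "
            f"{sorted(subjects)}"
        )
    processed = []
    for tr in trials:
        curves = {}
        for ch in tr.channels:
            curve = tr.curves[ch]
            if modality == "angles" and apply_filter:
                curve = butterworth_lowpass(
                    curve, sample_rate_hz=filter_sample_rate_hz
                )
            curves[ch] = time_normalize(curve, n_out=n_points)
        if modality == "grf":
            if tr.body_mass is None:
                raise ValueError("GRF trials need a body mass")
            curves = normalize_bodyweight(curves, tr.body_mass)
        processed.append(
            StrideTrial(
                subject_id=tr.subject_id,
                session_id=tr.session_id,
                trial_index=tr.trial_index,
                channels=tr.channels,
                curves=curves,
                body_mass=tr.body_mass,
            )
        )
    fm = join_vectors(processed, modality)
    if modality == "angles":
        fm.values = z_transform(fm.values, "per_trial")
    if not scaled:
        return fm
    if modality == "grf":
        fm.values = z_transform(fm.values, "global")
    fm.values = scale_to_range(fm.values)
    return fm
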