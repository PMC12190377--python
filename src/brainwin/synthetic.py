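"""Seeded synthetic rs-fMRI cohort generator.

Produces 4D phantoms in which the two diagnostic classes differ only in the
*temporal frequency* of a sinusoidal signal carried by a small spherical
blob inside an ellipsoidal "brain"; everything else (baseline, white noise,
slow scanner drift, optional head motion) is class-independent. Classes are
therefore temporally — not statically — separable, so a temporal feature
pathway is required to tell them apart. An amplitude-difference mode is
available for experiments where static separability is wanted instead.

The emulated structure mirrors a multi-site resting-state collection:
balanced classes, site labels assigned round-robin, per-subject motion
parameter traces, and a phenotype table. No hemodynamic-response modelling
or scanner-specific artifact is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .core import (
    SubjectRecord,
    Volume4D,
    save_mask,
    save_motion_trace,
    save_volume,
    write_phenotype,
)

__all__ = [
    "AcquisitionSpec",
    "ClassSignalSpec",
    "NoiseSpec",
    "generate_subject",
    "generate_cohort",
    "inject_motion",
    "brain_mask",
    "subject_seed",
]

#: Baseline intensity added inside the brain mask, in arbitrary scanner units.
#: Large relative to the signal, as in raw BOLD data, so that intensity
#: normalization has real work to do.
BASELINE = 100.0


@dataclass(frozen=True)
class AcquisitionSpec:
    """Acquisition geometry and timing.

    The default is a desk-scale phantom; ``full_scale()`` gives the spatial
    dimensions of a standard-template adult brain grid.
    """

    shape: tuple[int, int, int] = (16, 16, 12)
    t: int = 50
    tr: float = 2.0
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 3.0)

    def __post_init__(self) -> None:
        if any(int(d) < 4 for d in self.shape):
            raise ValueError(f"all spatial dimensions must be >= 4, got {self.shape}")
        if self.t < 2:
            raise ValueError("t must be >= 2")
        if self.tr <= 0:
            raise ValueError("tr must be positive")

    @property
    def nyquist(self) -> float:
        """Highest representable temporal frequency, Hz."""
        return 0.5 / self.tr

    @staticmethod
    def full_scale(t: int = 200, tr: float = 2.0) -> "AcquisitionSpec":
        """Preset with the full-resolution (99, 117, 95) template grid."""
        return AcquisitionSpec(shape=(99, 117, 95), t=t, tr=tr, voxel_size=(2.0, 2.0, 2.0))


@dataclass(frozen=True)
class ClassSignalSpec:
    """Class-coded signal carried by a spherical blob.

    ``freq_class0`` / ``freq_class1`` are the sinusoid frequencies (Hz) for
    the two classes; both must sit below the Nyquist frequency of the
    acquisition and, to survive the standard 0.01-0.1 Hz band-pass, inside
    that band. ``amplitude`` is the sinusoid amplitude in the same units as
    the noise standard deviation. With ``amplitude_ratio_class1 != 1`` the
    classes additionally (or, with equal frequencies, solely) differ in
    amplitude — static separability mode.
    """

    blob_center: tuple[int, int, int] = (8, 8, 6)
    blob_radius: float = 3.0
    freq_class0: float = 0.03
    freq_class1: float = 0.08
    amplitude: float = 1.0
    amplitude_ratio_class1: float = 1.0

    def __post_init__(self) -> None:
        if self.blob_radius <= 0:
            raise ValueError("blob_radius must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.freq_class0 <= 0 or self.freq_class1 <= 0:
            raise ValueError("class frequencies must be positive")

    def frequency(self, label: int) -> float:
        return self.freq_class1 if label == 1 else self.freq_class0

    def class_amplitude(self, label: int) -> float:
        return self.amplitude * (self.amplitude_ratio_class1 if label == 1 else 1.0)


@dataclass(frozen=True)
class NoiseSpec:
    """Nuisance components: white noise, global activity, drift, motion.

    ``white_sd`` is the per-voxel, per-frame Gaussian noise sd.
    ``background_amp`` / ``background_freq`` describe a class-independent
    global oscillation shared by every in-mask voxel (random phase per
    subject) — the stand-in for whole-brain resting activity. It matters
    for realism of global signal regression: without a shared component
    the in-mask mean would be dominated by the class blob and GSR would
    strip the class signal itself. ``drift_amp`` scales a per-voxel linear
    + half-cosine drift whose fundamental lies below 0.01 Hz for any
    series of at least 100 s, so the band-pass stage has something to
    remove. ``motion_amp`` / ``rot_amp`` are random-walk step scales
    (mm, radians) for the six rigid-body parameters.
    """

    white_sd: float = 0.5
    background_amp: float = 0.4
    background_freq: float = 0.05
    drift_amp: float = 0.3
    motion_amp: float = 0.0
    rot_amp: float = 0.0

    def __post_init__(self) -> None:
        for name in ("white_sd", "background_amp", "drift_amp", "motion_amp", "rot_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.background_freq <= 0:
            raise ValueError("background_freq must be positive")


def brain_mask(shape: Sequence[int]) -> np.ndarray:
    """Ellipsoidal stand-in for a brain mask, inscribed in the grid."""
    shape = tuple(int(d) for d in shape)
    center = [(d - 1) / 2.0 for d in shape]
    semi = [0.45 * d for d in shape]
    grids = np.ogrid[tuple(slice(0, d) for d in shape)]
    r2 = sum(((g - c) / s) ** 2 for g, c, s in zip(grids, center, semi))
    return r2 <= 1.0


def _blob_mask(shape: Sequence[int], center: Sequence[int], radius: float) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, d) for d in shape)]
    r2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return r2 <= radius**2


def _validate_signal(acq: AcquisitionSpec, sig: ClassSignalSpec) -> None:
    for f in (sig.freq_class0, sig.freq_class1):
        if f >= acq.nyquist:
            raise ValueError(
                f"class frequency {f} Hz is at or above Nyquist "
                f"{acq.nyquist} Hz for tr={acq.tr} s"
            )
    for c, d in zip(sig.blob_center, acq.shape):
        if c - sig.blob_radius < 0 or c + sig.blob_radius > d - 1:
            raise ValueError(
                f"blob (center {sig.blob_center}, radius {sig.blob_radius}) "
                f"extends outside the {acq.shape} volume"
            )


def generate_subject(
    acq: AcquisitionSpec,
    sig: ClassSignalSpec,
    noise: NoiseSpec,
    label: int,
    seed: int,
) -> tuple[Volume4D, np.ndarray]:
    """Generate one subject's 4D volume and motion-parameter trace.

    In-blob voxels carry ``baseline + A*sin(2*pi*f_label*t + phase) + drift
    + white noise``; other in-mask voxels lack the sinusoid; out-of-mask
    voxels are exactly zero. The returned motion trace is *not* applied to
    the volume — pass both through :func:`inject_motion` to corrupt it.
    Deterministic given ``seed``.
    """
    if label not in (0, 1):
        raise ValueError(f"label must be 0 or 1, got {label!r}")
    _validate_signal(acq, sig)
    rng = np.random.default_rng(seed)

    mask = brain_mask(acq.shape)
    blob = _blob_mask(acq.shape, sig.blob_center, sig.blob_radius) & mask
    n_mask = int(mask.sum())
    tt = np.arange(acq.t) * acq.tr

    data = np.zeros((*acq.shape, acq.t), dtype=np.float64)
    series = np.full((n_mask, acq.t), BASELINE)

    # slow drift: per-voxel mix of a linear ramp and a half-cosine whose
    # fundamental period is twice the scan length (always < 0.01 Hz for
    # scans of 100 s or longer)
    tau = tt / tt[-1]
    ramp = 2.0 * (tau - 0.5)
    halfcos = np.cos(np.pi * tau)
    c_lin = rng.uniform(-1.0, 1.0, n_mask)
    c_cos = rng.uniform(-1.0, 1.0, n_mask)
    series += noise.drift_amp * (np.outer(c_lin, ramp) + np.outer(c_cos, halfcos))

    # shared whole-brain oscillation, identical in every in-mask voxel
    if noise.background_amp > 0:
        if noise.background_freq >= acq.nyquist:
            raise ValueError(
                f"background_freq {noise.background_freq} Hz is at or above "
                f"Nyquist {acq.nyquist} Hz"
            )
        bg_phase = rng.uniform(0.0, 2.0 * np.pi)
        series += noise.background_amp * np.sin(
            2.0 * np.pi * noise.background_freq * tt + bg_phase
        )

    # class-coded sinusoid in the blob, common phase per subject
    phase = rng.uniform(0.0, 2.0 * np.pi)
    wave = sig.class_amplitude(label) * np.sin(
        2.0 * np.pi * sig.frequency(label) * tt + phase
    )
    series[blob[mask]] += wave

    if noise.white_sd > 0:
        series += rng.normal(0.0, noise.white_sd, (n_mask, acq.t))

    data[mask] = series

    trace = np.zeros((acq.t, 6))
    if noise.motion_amp > 0 or noise.rot_amp > 0:
        steps = np.concatenate(
            [
                rng.normal(0.0, noise.motion_amp, (acq.t - 1, 3)),
                rng.normal(0.0, noise.rot_amp, (acq.t - 1, 3)),
            ],
            axis=1,
        )
        trace[1:] = np.cumsum(steps, axis=0)

    vol = Volume4D(data=data, tr=acq.tr, voxel_size=acq.voxel_size, mask=mask)
    return vol, trace


def inject_motion(vol: Volume4D, trace: np.ndarray) -> Volume4D:
    """Rigidly displace each frame according to its motion parameters.

    Translations (columns 0-2, mm) are converted to voxels and applied as
    nearest-voxel integer shifts with zero fill; rotations (columns 3-5,
    radians) are applied exactly about the volume center by inverse-mapping
    with trilinear interpolation. Frame 0 is the reference and its trace row
    must be zero by construction; it is never resampled.
    """
    from scipy import ndimage

    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 2 or trace.shape != (vol.t, 6):
        raise ValueError(
            f"trace shape {trace.shape} does not match (t, 6) = ({vol.t}, 6)"
        )
    out = np.array(vol.data, dtype=np.float64, copy=True)
    center = (np.array(vol.spatial_shape) - 1) / 2.0
    for i in range(1, vol.t):
        shift_mm, rot = trace[i, :3], trace[i, 3:]
        if not (np.any(shift_mm) or np.any(rot)):
            continue
        frame = vol.data[..., i]
        if np.any(rot):
            ca, sa = np.cos(rot), np.sin(rot)
            rx = np.array([[1, 0, 0], [0, ca[0], -sa[0]], [0, sa[0], ca[0]]])
            ry = np.array([[ca[1], 0, sa[1]], [0, 1, 0], [-sa[1], 0, ca[1]]])
            rz = np.array([[ca[2], -sa[2], 0], [sa[2], ca[2], 0], [0, 0, 1]])
            rot_m = rz @ ry @ rx
            shift_vox = shift_mm / np.asarray(vol.voxel_size)
            # content moves by u = R (x - c) + c + t; affine_transform pulls
            # from x = R^T (u - c - t) + c
            inv = rot_m.T
            offset = center - inv @ (center + shift_vox)
            frame = ndimage.affine_transform(
                frame, inv, offset=offset, order=1, mode="constant", cval=0.0
            )
        else:
            shift_vox = np.rint(shift_mm / np.asarray(vol.voxel_size)).astype(int)
            frame = _integer_shift(frame, shift_vox)
        out[..., i] = frame
    return vol.with_data(out)


def _integer_shift(frame: np.ndarray, shift: np.ndarray) -> np.ndarray:
    """Shift a 3D array by integer voxels with zero fill."""
    out = np.zeros_like(frame)
    src = []
    dst = []
    for d, s in enumerate(shift):
        n = frame.shape[d]
        if abs(s) >= n:
            return out
        if s >= 0:
            dst.append(slice(s, n))
            src.append(slice(0, n - s))
        else:
            dst.append(slice(0, n + s))
            src.append(slice(-s, n))
    out[tuple(dst)] = frame[tuple(src)]
    return out


def subject_seed(master_seed: int, index: int) -> int:
    """Stable per-subject seed derived from the master seed."""
    ss = np.random.SeedSequence([int(master_seed), int(index)])
    return int(ss.generate_state(1)[0] % (2**31))


def generate_cohort(
    acq: AcquisitionSpec,
    sig: ClassSignalSpec,
    noise: NoiseSpec,
    n_per_class: int,
    sites: Sequence[str],
    seed: int,
    out_dir: Optional[Path | str] = None,
) -> tuple[list[SubjectRecord], dict[str, Volume4D], dict[str, np.ndarray]]:
    """Generate a balanced multi-site cohort of ``2 * n_per_class`` subjects.

    Labels are assigned in two blocks (controls first), sites round-robin
    over subject index; per-subject seeds derive from the master seed via
    :func:`subject_seed`, so any cohort is reproducible subject-by-subject.
    When the noise spec requests motion, each volume is corrupted with its
    own trace via :func:`inject_motion`. If ``out_dir`` is given, volumes,
    traces, the shared mask and ``phenotype.tsv`` are written there.

    Returns the records plus in-memory volume and trace maps keyed by
    subject id.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if len(sites) < 1:
        raise ValueError("at least one site is required")

    n_total = 2 * n_per_class
    records: list[SubjectRecord] = []
    volumes: dict[str, Volume4D] = {}
    traces: dict[str, np.ndarray] = {}
    seen: set[str] = set()
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    for idx in range(n_total):
        label = 0 if idx < n_per_class else 1
        sid = f"sub-{idx:04d}"
        if sid in seen:
            raise ValueError(f"duplicate subject id {sid}")
        seen.add(sid)
        site = sites[idx % len(sites)]
        vol, trace = generate_subject(acq, sig, noise, label, subject_seed(seed, idx))
        if np.any(trace):
            vol = inject_motion(vol, trace)
        rec = SubjectRecord(subject_id=sid, site=site, label=label)
        if out_dir is not None:
            rec.volume_path = save_volume(vol, out_dir / f"{sid}_bold.nii.gz")
            rec.motion_path = save_motion_trace(trace, out_dir / f"{sid}_motion.txt")
        records.append(rec)
        volumes[sid] = vol
        traces[sid] = trace

    if out_dir is not None:
        save_mask(brain_mask(acq.shape), acq.voxel_size, out_dir / "mask.nii.gz")
        write_phenotype(records, out_dir / "phenotype.tsv")
    return records, volumes, traces
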