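"""Synthetic free-breathing lung time-series with known ground truth.

The phantom emulates what a coronal bSSFP free-breathing acquisition looks
like to the perfusion pipeline: static anatomy (two lungs, a mediastinal
block between them), a slow respiratory signal modulation strongest near
the diaphragm, a cardiac-frequency parenchymal oscillation whose local
amplitude is proportional to local perfusion, a fully blood-filled
high-amplitude region inside the mediastinum, planted perfusion-defect
regions with near-zero cardiac amplitude, and additive Gaussian noise.

Every downstream stage (filtering, blood-pool detection, phase sorting,
Q_N/QDP quantification, segmental scoring) is therefore testable against
exact ground truth without any patient data.

The voxel signal model is

    s(x, t) = baseline(x)
              + resp_amplitude * w_resp(x) * sin(2*pi*f_resp*t)
              + A_card(x) * sin(2*pi*f_card*t + phi(x))
              + eps(x, t)

with A_card(x) = qn_truth(x) * blood_amplitude inside the lungs and
A_card(x) = blood_amplitude (with a small seeded per-voxel spread) on the
blood-pool region, and eps i.i.d. Gaussian with sd ``noise_sigma``.
Anatomical realism is a non-goal: lungs are ellipses and the 18 lung
segments (10 right, 8 left) are procedurally drawn equal-area bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .preproc import FrameSeries

__all__ = ["PhantomSpec", "PhantomTruth", "generate_phantom", "DEFECT_QN"]

#: ground-truth Q_N fraction assigned to planted defect voxels; well below
#: the 2% (0.02) defect threshold so defects are unambiguous by construction
DEFECT_QN = 0.005

N_SEGMENTS_RIGHT = 10
N_SEGMENTS_LEFT = 8
N_SEGMENTS = N_SEGMENTS_RIGHT + N_SEGMENTS_LEFT


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic free-breathing series.

    Defaults mirror a typical acquisition: 250 frames over 62 s
    (frame interval 0.248 s), cardiac frequency 1.2 Hz (72 bpm),
    respiratory frequency 0.25 Hz (15 breaths/min).  Signal units are
    arbitrary; only the ratio Q/S_Blood matters downstream.
    """

    grid_height: int = 64
    grid_width: int = 64
    n_frames: int = 250
    frame_interval: float = 0.248
    f_card: float = 1.2
    f_resp: float = 0.25
    blood_amplitude: float = 100.0
    parenchyma_qn: float = 0.10
    defect_regions: tuple = ()  # (segment_label, fraction of segment area)
    resp_amplitude: float = 30.0
    noise_sigma: float = 2.0
    blood_spread: float = 0.03  # deterministic +/- relative spread of blood amplitude
    phase_gradient: float = 0.0  # rad across the image width
    seed: int = 0

    def __post_init__(self) -> None:
        nyquist = 0.5 / self.frame_interval
        if self.f_card >= nyquist:
            raise ValueError(
                f"cardiac frequency {self.f_card:g} Hz is at/above the Nyquist "
                f"frequency {nyquist:g} Hz for frame interval "
                f"{self.frame_interval:g} s: the cardiac signal would alias"
            )
        if not self.f_resp < self.f_card:
            raise ValueError("f_resp must be below f_card")
        if min(self.blood_amplitude, self.resp_amplitude, self.noise_sigma) < 0:
            raise ValueError("amplitudes and noise_sigma must be >= 0")
        if not 0.02 <= self.parenchyma_qn <= 1.0:
            raise ValueError(
                "parenchyma_qn must be in [0.02, 1]: healthy parenchyma must sit "
                "at or above the 2% defect threshold so planted defects are the "
                "only sub-threshold voxels"
            )
        if not 0.0 <= self.blood_spread < 0.5:
            raise ValueError("blood_spread must be in [0, 0.5)")
        for label, frac in self.defect_regions:
            if not 1 <= int(label) <= N_SEGMENTS:
                raise ValueError(f"defect segment label {label} outside 1..{N_SEGMENTS}")
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"defect fraction {frac} outside [0, 1]")
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["defect_regions"] = [list(r) for r in self.defect_regions]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PhantomSpec":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["defect_regions"] = tuple(tuple(r) for r in d.get("defect_regions", ()))
        return cls(**d)


@dataclass(frozen=True)
class PhantomTruth:
    """Ground truth accompanying a generated phantom series."""

    lung_mask: np.ndarray
    mediastinum_mask: np.ndarray
    blood_roi_mask: np.ndarray
    segment_map: np.ndarray  # 0 outside lung; labels 1..18 inside
    qn_truth: np.ndarray  # per-voxel Q_N fraction, 0 outside lung
    defect_mask: np.ndarray
    f_card: float
    f_resp: float

    @property
    def qdp_truth(self) -> float:
        """Planted perfusion defect percentage of the lung area."""
        return 100.0 * self.defect_mask.sum() / self.lung_mask.sum()


def _ellipse(h: int, w: int, cy: float, cx: float, ry: float, rx: float) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def _build_anatomy(h: int, w: int):
    """Two elliptical lungs, a mediastinal block, and a blood-pool region.

    The blood region is sized to roughly 2.5% of the search region so that
    the 98th-percentile candidate selection lands inside it.
    """
    ry, rx = 0.38 * h, 0.18 * w
    cy = 0.52 * h
    right = _ellipse(h, w, cy, 0.27 * w, ry, rx)  # image left = patient right
    left = _ellipse(h, w, cy, 0.73 * w, ry, rx)
    lung = right | left
    med = np.zeros((h, w), dtype=bool)
    med[int(0.25 * h) : int(0.80 * h), int(0.42 * w) : int(0.58 * w)] = True
    med &= ~lung

    roi_total = int(lung.sum() + med.sum())
    n_blood = max(8, int(round(0.025 * roi_total)))
    # two blood clusters (great vessels / heart chambers) inside the mediastinum
    blood = np.zeros((h, w), dtype=bool)
    med_rows = np.where(med.any(axis=1))[0]
    r0 = med_rows[len(med_rows) // 3]
    c0 = int(0.46 * w)
    side = max(2, int(np.sqrt(n_blood / 2)))
    blood[r0 : r0 + side, c0 : c0 + side] = True
    blood[r0 + side + 3 : r0 + 2 * side + 3, c0 : c0 + side + 1] = True
    blood &= med
    return right, left, lung, med, blood


def _segment_map(right: np.ndarray, left: np.ndarray) -> np.ndarray:
    """18 procedural equal-area segments: labels 1-10 right, 11-18 left.

    Voxels of each lung are ordered row-major (top to bottom) and split into
    contiguous near-equal-area bands; segments therefore tile each lung
    exactly.
    """
    seg = np.zeros(right.shape, dtype=np.int32)
    for lung, n_seg, offset in ((right, N_SEGMENTS_RIGHT, 0),
                                (left, N_SEGMENTS_LEFT, N_SEGMENTS_RIGHT)):
        coords = np.argwhere(lung)  # already sorted row-major
        chunks = np.array_split(coords, n_seg)
        for i, chunk in enumerate(chunks):
            seg[chunk[:, 0], chunk[:, 1]] = offset + i + 1
    return seg


def generate_phantom(spec: PhantomSpec) -> tuple[FrameSeries, PhantomTruth]:
    """Generate a seeded synthetic free-breathing series plus ground truth.

    Identical ``spec`` (including seed) yields bit-identical arrays.
    Defect regions are planted as contiguous sub-areas of the requested
    segments with ground-truth Q_N of 0.5% (below the 2% defect threshold);
    healthy parenchyma gets ``spec.parenchyma_qn``.
    """
    h, w = spec.grid_height, spec.grid_width
    right, left, lung, med, blood = _build_anatomy(h, w)
    seg = _segment_map(right, left)

    qn = np.zeros((h, w))
    qn[lung] = spec.parenchyma_qn
    defect = np.zeros((h, w), dtype=bool)
    for label, frac in spec.defect_regions:
        coords = np.argwhere(seg == int(label))
        n_def = int(round(frac * len(coords)))
        take = coords[:n_def]
        defect[take[:, 0], take[:, 1]] = True
    qn[defect] = DEFECT_QN

    rng = np.random.default_rng(spec.seed)

    # cardiac amplitude map: perfusion-proportional in the lung; on the blood
    # pool the full blood amplitude with a small deterministic spatial spread
    # (mean exactly 1) mimicking intra-ROI signal variability and keeping the
    # strict percentile selection non-degenerate even without noise
    a_card = qn * spec.blood_amplitude
    n_blood = int(blood.sum())
    factors = (
        np.linspace(1.0 - spec.blood_spread, 1.0 + spec.blood_spread, n_blood)
        if n_blood > 1
        else np.ones(n_blood)
    )
    a_card[blood] = spec.blood_amplitude * factors

    # respiratory weight: linear gradient, largest near the diaphragm (bottom)
    yy = np.mgrid[0:h, 0:w][0] / max(h - 1, 1)
    w_resp = np.where(lung | med, 0.2 + 0.8 * yy, 0.0)

    baseline = np.full((h, w), 20.0)
    baseline[lung] = 100.0
    baseline[med] = 140.0
    baseline[blood] = 160.0

    phi = np.zeros((h, w))
    if spec.phase_gradient:
        phi = spec.phase_gradient * (np.mgrid[0:h, 0:w][1] / max(w - 1, 1))

    t = np.arange(spec.n_frames) * spec.frame_interval
    resp = np.sin(2 * np.pi * spec.f_resp * t)  # (T,)
    card = np.sin(
        2 * np.pi * spec.f_card * t[:, None, None] + phi[None, :, :]
    )  # (T, H, W)

    data = (
        baseline[None]
        + spec.resp_amplitude * w_resp[None] * resp[:, None, None]
        + a_card[None] * card
    )
    if spec.noise_sigma > 0:
        data = data + rng.normal(0.0, spec.noise_sigma, size=data.shape)

    series = FrameSeries(data, frame_interval=spec.frame_interval, slice_id="phantom")
    truth = PhantomTruth(
        lung_mask=lung,
        mediastinum_mask=med,
        blood_roi_mask=blood,
        segment_map=seg,
        qn_truth=qn,
        defect_mask=defect,
        f_card=spec.f_card,
        f_resp=spec.f_resp,
    )
    return series, truth
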