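"""Synthetic dynamic-series phantoms and labelled patient cohorts.

Every downstream stage of the pipeline (kinetics, segmentation, texture,
statistics, prediction) is exercised on data from this module, so the
generator is first-class, tested code rather than a fixture.

The enhancement curve family is piecewise-linear — baseline, linear rise
to the configured amplitude at a configurable peak frame (the last
segment of the rise carries the configured wash-in slope), then a linear
tail with the configured wash-out slope.  This keeps the ground truth in
exactly the parameterisation the kinetic analysis measures; no
pharmacokinetic model is implied.  Note that a strictly positive
wash-out moves the enhancement maximum to the final frame, so the
configured amplitude is only the *measured* amplitude when the tail does
not rise above the peak.

Texture heterogeneity inside the lesion is a multiplicative log-normal
field: the lesion curve is scaled pixel-wise by exp(σ·G) where G is a
unit-variance Gaussian random field with the configured correlation
length.  Larger correlation lengths give smoother, more homogeneous
lesions.  A correlation length (or σ) of zero disables the field.

Noise is additive zero-mean Gaussian on every frame.  The analysis
operates on subtracted, high-SNR images, so a Rician model would add
realism only at enhancement levels far below those simulated here; the
Gaussian choice is a documented simplification.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy.ndimage import gaussian_filter

from .kinetics import DynamicSeries, KineticParams
from .masks import RoiMask

__all__ = [
    "PhantomConfig",
    "CohortConfig",
    "GroundTruth",
    "PatientRecord",
    "SUBTYPES",
    "STUDY_BIOMARKER_PROBS",
    "generate_phantom",
    "generate_cohort",
    "sample_biomarkers",
]

RESPONSE_CLASSES = ("NR", "PR", "CR")

SUBTYPES = (
    "LuminalA",
    "LuminalB/HER2-",
    "LuminalB/HER2+",
    "NonLuminal/HER2+",
    "TripleNegative",
)

# Conditional biomarker probabilities given response class, taken from the
# observed frequencies in the 69-patient cohort the generator emulates
# (19 NR / 36 PR / 14 CR).  Mass prevalence is only reported for NR vs
# PR+CR, so PR and CR share the pooled value.
STUDY_BIOMARKER_PROBS: dict[str, dict] = {
    "NR": {
        "subtype": {
            "LuminalA": 8 / 19,
            "LuminalB/HER2-": 4 / 19,
            "LuminalB/HER2+": 3 / 19,
            "NonLuminal/HER2+": 1 / 19,
            "TripleNegative": 3 / 19,
        },
        "er": 15 / 19,
        "pgr": 14 / 19,
        "ki67_high": 11 / 19,
        "her2": 4 / 19,
        "mass": 12 / 19,
    },
    "PR": {
        "subtype": {
            "LuminalA": 5 / 36,
            "LuminalB/HER2-": 16 / 36,
            "LuminalB/HER2+": 8 / 36,
            "NonLuminal/HER2+": 5 / 36,
            "TripleNegative": 2 / 36,
        },
        "er": 28 / 36,
        "pgr": 24 / 36,
        "ki67_high": 30 / 36,
        "her2": 14 / 36,
        "mass": 27 / 50,
    },
    "CR": {
        "subtype": {
            "LuminalA": 0.0,
            "LuminalB/HER2-": 5 / 14,
            "LuminalB/HER2+": 4 / 14,
            "NonLuminal/HER2+": 4 / 14,
            "TripleNegative": 1 / 14,
        },
        "er": 9 / 14,
        "pgr": 4 / 14,
        "ki67_high": 11 / 14,
        "her2": 8 / 14,
        "mass": 27 / 50,
    },
}

# Mean shifts applied to non-responder lesions relative to the responder
# baseline: smoother texture (longer correlation length), slower contrast
# uptake and slightly lower peak enhancement.  Directions follow the
# group medians observed in the emulated study; magnitudes are the
# generator's own calibration (see docs/methods.md).
DEFAULT_CLASS_EFFECT: dict[str, dict[str, float]] = {
    "NR": {"corr_len": 2.5, "wash_in": -0.09, "amplitude": -7.0},
    "PR": {},
    "CR": {},
}


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, kinetics and noise of a single-slice dynamic phantom."""

    grid_size: tuple[int, int] = (64, 64)
    n_timepoints: int = 6  # 1 pre + 5 post
    dt: float = 60.0  # seconds
    lesion_shape: str = "mass_ellipse"  # or "nonmass_patchy"
    lesion_center: tuple[float, float] = (32.0, 32.0)
    lesion_radii: tuple[float, float] = (10.0, 7.0)
    lesion_kinetics: tuple[float, float, float] = (75.0, 0.72, -0.04)  # amplitude, wash-in, wash-out
    peak_frame: int = 2
    lesion_texture_corr_len: float = 1.0  # pixels; 0 disables the texture field
    field_sigma: float = 0.4  # log-sd of the multiplicative heterogeneity field
    background_kinetics: tuple[float, float, float] = (12.0, 0.12, 0.0)
    fat_fraction: float = 0.3
    noise_sd: float = 2.0  # AU
    baseline: float = 100.0  # AU, pre-contrast signal level
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_timepoints < 4:
            raise ValueError("n_timepoints must be >= 4 (wash-out needs 3 trailing points)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 1 <= self.peak_frame < self.n_timepoints:
            raise ValueError("peak_frame must index a post-contrast frame")
        if self.lesion_shape not in ("mass_ellipse", "nonmass_patchy"):
            raise ValueError(f"unknown lesion_shape {self.lesion_shape!r}")
        if not 0 <= self.fat_fraction < 1:
            raise ValueError("fat_fraction must be in [0, 1)")
        h, w = self.grid_size
        cy, cx = self.lesion_center
        ry, rx = self.lesion_radii
        if cy - ry < 0 or cy + ry > h - 1 or cx - rx < 0 or cx + rx > w - 1:
            raise ValueError("lesion extends outside the grid")
        for name, (amp, win, _) in (
            ("lesion", self.lesion_kinetics),
            ("background", self.background_kinetics),
        ):
            if amp < 0 or win < 0:
                raise ValueError(f"{name} amplitude and wash-in must be >= 0")
            if amp > 0 and not 0 <= amp - win * self.dt <= amp:
                raise ValueError(
                    f"{name} wash-in {win} is inconsistent with amplitude {amp} at "
                    f"dt={self.dt}: the pre-peak point would fall outside [0, amplitude]"
                )


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually put into a phantom."""

    lesion_mask: RoiMask
    true_kinetics: KineticParams
    amplitude_field: np.ndarray  # per-pixel true lesion amplitude (NaN outside)
    class_label: str | None = None

    def __post_init__(self) -> None:
        if self.lesion_mask.n_pixels == 0:
            raise ValueError("ground-truth lesion mask is empty")


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    response: str  # NR / PR / CR
    subtype: str
    er: bool
    pgr: bool
    ki67_high: bool
    her2: bool
    mass: bool

    @property
    def hr_neg_her2_pos(self) -> bool:
        """Hormone-receptor negative, HER2 positive."""
        return (not self.er) and (not self.pgr) and self.her2


def _enhancement_curve(times: np.ndarray, amplitude: float, wash_in: float,
                       wash_out: float, peak_frame: int) -> np.ndarray:
    """Piecewise-linear curve through 0 at t0, amplitude at the peak frame."""
    t = np.asarray(times, dtype=float)
    s = np.zeros_like(t)
    tp = t[peak_frame]
    pre_peak = amplitude - wash_in * (tp - t[peak_frame - 1])
    # linear from 0 at t0 up to the pre-peak control point, then the
    # wash-in segment, then the wash-out tail
    for k in range(1, len(t)):
        if k < peak_frame:
            denom = t[peak_frame - 1] - t[0]
            s[k] = pre_peak * (t[k] - t[0]) / denom if denom > 0 else 0.0
        elif k == peak_frame:
            s[k] = amplitude
        else:
            s[k] = amplitude + wash_out * (t[k] - tp)
    return s


def _gaussian_field(shape: tuple[int, int], corr_len: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian random field with the given correlation length."""
    white = rng.standard_normal(shape)
    if corr_len <= 0:
        return white
    f = gaussian_filter(white, sigma=corr_len, mode="reflect")
    sd = f.std()
    if sd == 0:  # pathological tiny grids
        return np.zeros(shape)
    return f / sd


def _lesion_mask(cfg: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    h, w = cfg.grid_size
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = cfg.lesion_center
    ry, rx = cfg.lesion_radii
    ellipse = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
    if cfg.lesion_shape == "mass_ellipse":
        return ellipse
    # non-mass: patchy subset of the ellipse support, thresholded random field
    g = _gaussian_field((h, w), max(cfg.lesion_texture_corr_len, 1.5), rng)
    patchy = ellipse & (g > np.median(g[ellipse]) - 0.5)
    return patchy if patchy.any() else ellipse


def generate_phantom(config: PhantomConfig) -> tuple[DynamicSeries, GroundTruth]:
    """Build one dynamic series plus its ground truth.

    Frame 0 is the pre-contrast baseline.  Lesion pixels follow the
    configured piecewise-linear curve scaled by the multiplicative
    heterogeneity field; parenchyma enhances weakly; fat stays at
    baseline; additive Gaussian noise is applied to every frame.
    Identical configs (including seed) give bit-identical output.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.grid_size
    times = np.arange(cfg.n_timepoints) * cfg.dt

    lesion = _lesion_mask(cfg, rng)
    # fat: smooth-field threshold outside the lesion
    fat_field = _gaussian_field((h, w), 4.0, rng)
    if cfg.fat_fraction > 0:
        thr = np.quantile(fat_field, 1.0 - cfg.fat_fraction)
        fat = (fat_field > thr) & ~lesion
    else:
        fat = np.zeros((h, w), dtype=bool)
    parenchyma = ~lesion & ~fat

    amp, win, wout = cfg.lesion_kinetics
    lesion_curve = _enhancement_curve(times, amp, win, wout, cfg.peak_frame)
    bg_amp, bg_win, bg_wout = cfg.background_kinetics
    bg_curve = _enhancement_curve(times, bg_amp, bg_win, bg_wout, cfg.peak_frame)

    if cfg.lesion_texture_corr_len > 0 and cfg.field_sigma > 0:
        g = _gaussian_field((h, w), cfg.lesion_texture_corr_len, rng)
        hetero = np.exp(cfg.field_sigma * g)
    else:
        hetero = np.ones((h, w))

    baseline_img = np.full((h, w), cfg.baseline)
    frames = np.empty((cfg.n_timepoints, h, w))
    for k in range(cfg.n_timepoints):
        enh = np.zeros((h, w))
        enh[lesion] = lesion_curve[k] * hetero[lesion]
        enh[parenchyma] = bg_curve[k]
        frames[k] = baseline_img + enh
    if cfg.noise_sd > 0:
        frames += rng.normal(0.0, cfg.noise_sd, frames.shape)

    amplitude_field = np.where(lesion, amp * hetero, np.nan)
    truth = GroundTruth(
        lesion_mask=RoiMask(lesion, kind="manual_lesion"),
        true_kinetics=KineticParams(amp, win, wout, cfg.peak_frame),
        amplitude_field=amplitude_field,
    )
    return DynamicSeries(frames, times), truth


@dataclass(frozen=True)
class CohortConfig:
    """A labelled cohort of dynamic phantoms.

    Class counts default to the emulated study (19 NR / 36 PR / 14 CR).
    ``class_effect`` maps each response class to additive mean shifts of
    the lesion parameters relative to ``base_phantom``'s values; the
    defaults make non-responder lesions smoother in texture with a lower
    wash-in, the directions the analysis is designed to detect.  Empty
    shift dicts give an uninformative (null) cohort.
    """

    n_nr: int = 19
    n_pr: int = 36
    n_cr: int = 14
    class_effect: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CLASS_EFFECT.items()}
    )
    biomarker_probs: Mapping[str, Mapping] = field(
        default_factory=lambda: {k: dict(v) for k, v in STUDY_BIOMARKER_PROBS.items()}
    )
    base_phantom: PhantomConfig = field(default_factory=PhantomConfig)
    kinetic_jitter: float = 0.08  # log-sd of per-patient lognormal scatter
    geometry_jitter: float = 0.08  # relative scatter of lesion radii/centre
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_nr, self.n_pr, self.n_cr) < 0:
            raise ValueError("class counts must be >= 0")
        for cls, probs in self.biomarker_probs.items():
            _validate_probs(cls, probs)


def _validate_probs(cls: str, probs: Mapping) -> None:
    sub = probs.get("subtype", {})
    total = float(sum(sub.values()))
    if sub and abs(total - 1.0) > 1e-9:
        raise ValueError(f"subtype probabilities for {cls} sum to {total}, not 1")
    for key, p in list(sub.items()) + [(k, v) for k, v in probs.items() if k != "subtype"]:
        if not 0.0 <= float(p) <= 1.0:
            raise ValueError(f"probability {key}={p} for class {cls} outside [0, 1]")


def sample_biomarkers(class_label: str, biomarker_probs: Mapping[str, Mapping],
                      rng: np.random.Generator) -> dict:
    """Draw one subtype and the binary markers conditional on class.

    The subtype comes from the conditional categorical distribution; the
    binary markers (ER, PgR, Ki67 > 14 %, HER2, mass enhancement) are
    drawn independently given the class.
    """
    probs = biomarker_probs[class_label]
    _validate_probs(class_label, probs)
    sub_probs = probs["subtype"]
    names = list(sub_probs)
    p = np.array([sub_probs[n] for n in names], dtype=float)
    subtype = names[rng.choice(len(names), p=p / p.sum())]
    return {
        "subtype": subtype,
        "er": bool(rng.random() < probs["er"]),
        "pgr": bool(rng.random() < probs["pgr"]),
        "ki67_high": bool(rng.random() < probs["ki67_high"]),
        "her2": bool(rng.random() < probs["her2"]),
        "mass": bool(rng.random() < probs["mass"]),
    }


def _patient_phantom_config(cfg: CohortConfig, label: str, mass: bool,
                            rng: np.random.Generator) -> PhantomConfig:
    base = cfg.base_phantom
    shifts = cfg.class_effect.get(label, {})
    amp, win, wout = base.lesion_kinetics
    amp = max(amp + shifts.get("amplitude", 0.0), 1.0)
    win = max(win + shifts.get("wash_in", 0.0), 1e-3)
    corr = max(base.lesion_texture_corr_len + shifts.get("corr_len", 0.0), 0.0)

    # per-patient biological scatter
    amp *= float(np.exp(rng.normal(0.0, cfg.kinetic_jitter)))
    win *= float(np.exp(rng.normal(0.0, cfg.kinetic_jitter)))
    if corr > 0:
        corr *= float(np.exp(rng.normal(0.0, cfg.kinetic_jitter)))
    # keep wash-in consistent with the piecewise-linear family
    win = min(win, amp / base.dt)

    h, w = base.grid_size
    ry = base.lesion_radii[0] * float(np.exp(rng.normal(0.0, cfg.geometry_jitter)))
    rx = base.lesion_radii[1] * float(np.exp(rng.normal(0.0, cfg.geometry_jitter)))
    ry = float(np.clip(ry, 3.0, (h - 3) / 2))
    rx = float(np.clip(rx, 3.0, (w - 3) / 2))
    cy = h / 2 + float(rng.uniform(-3, 3))
    cx = w / 2 + float(rng.uniform(-3, 3))
    cy = float(np.clip(cy, ry + 1, h - 1 - ry - 1))
    cx = float(np.clip(cx, rx + 1, w - 1 - rx - 1))

    return replace(
        base,
        lesion_shape="mass_ellipse" if mass else "nonmass_patchy",
        lesion_center=(cy, cx),
        lesion_radii=(ry, rx),
        lesion_kinetics=(amp, win, wout),
        lesion_texture_corr_len=corr,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def generate_cohort(config: CohortConfig) -> list[tuple[PatientRecord, DynamicSeries, GroundTruth]]:
    """Generate the full labelled cohort.

    Class labels are fixed by the configured counts (not sampled); the
    biomarkers and images are drawn conditional on the label.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    labels = ["NR"] * cfg.n_nr + ["PR"] * cfg.n_pr + ["CR"] * cfg.n_cr
    out = []
    for i, label in enumerate(labels):
        markers = sample_biomarkers(label, cfg.biomarker_probs, rng)
        pcfg = _patient_phantom_config(cfg, label, markers["mass"], rng)
        series, truth = generate_phantom(pcfg)
        truth = replace(truth, class_label=label)
        rec = PatientRecord(patient_id=f"P{i + 1:03d}", response=label, **markers)
        out.append((rec, series, truth))
    return out
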