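"""Synthetic abdominal-CT phantom cohorts with planted, recoverable texture effects.

The real study population (severe atherosclerotic renal artery stenosis
patients imaged before percutaneous transluminal renal angioplasty) is not
publicly available, so this module generates a stand-in: 2D axial slices in
Hounsfield units containing an elliptical kidney-like region (ROI1) inside a
perirenal-fat annulus (ROI2), an unlabeled 64x64 patch corpus for the
degradation pretext task, and an outcome-labeled cohort whose binary
benefit/non-benefit label depends on per-case texture heterogeneity through a
known logistic effect model.  Every planted parameter is recorded so that
downstream feature screening, selection and modeling can be validated against
ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

DEGRADATION_KINDS = ("normal", "blur", "noise", "distort", "shift")

#: Default degradation magnitude ranges (chosen to be visibly non-trivial yet
#: learnable on 64x64 patches): blur sigma in px, noise sigma in HU, elastic
#: amplitude in px, translation in px.
MAGNITUDE_RANGES = {
    "blur": (1.0, 3.0),
    "noise": (10.0, 30.0),
    "distort": (2.0, 6.0),
    "shift": (8.0, 16.0),
}

AIR_HU = -1000.0


class PhantomGeometryError(ValueError):
    """Kidney/fat geometry does not fit the requested canvas."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic axial slice.

    Mean intensities follow standard tissue HU ranges: soft-tissue body
    background ~ +40 HU, renal parenchyma ~ +32 HU, adipose ~ -90 HU.
    Texture SDs are i.i.d. per-pixel Gaussian heterogeneity inside each
    tissue; ``noise_sd`` is global acquisition noise.
    """

    image_size: tuple[int, int] = (256, 256)
    pixel_spacing: float = 1.0  # mm
    body_hu: float = 40.0
    kidney_hu: float = 32.0
    fat_hu: float = -90.0
    kidney_texture_sd: float = 12.0
    fat_texture_sd: float = 15.0
    noise_sd: float = 5.0
    # geometry, as fractions of the smaller canvas dimension
    kidney_axes: tuple[float, float] = (0.14, 0.085)
    kidney_angle_deg: float = 25.0
    fat_ring_px: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fat_hu >= self.body_hu:
            raise ValueError("fat must be hypodense relative to body tissue")
        for name in ("kidney_texture_sd", "fat_texture_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive")


@dataclass(frozen=True)
class DegradationSpec:
    """One of the five pretext-task degradations applied to a 64x64 patch.

    ``magnitude`` is kind-specific: blur sigma (px), additive Gaussian noise
    sigma (HU), elastic displacement amplitude (px) or translation (px,
    signed).  ``kind='normal'`` leaves the patch untouched and carries no
    magnitude.
    """

    kind: str
    magnitude: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in DEGRADATION_KINDS:
            raise ValueError(f"unknown degradation kind {self.kind!r}")
        if self.kind != "normal" and abs(self.magnitude) <= 0:
            # identity degradations would leak the 'normal' label
            raise ValueError("non-normal degradations require magnitude != 0")


@dataclass(frozen=True)
class OutcomeRecord:
    """Post-angioplasty renal-function outcome for one case.

    ``category`` partitions relative eGFR change: improvement (>= +20%
    sustained for at least 3 months), exacerbation (<= -20%), stable
    (otherwise).  ``label`` is benefit iff improvement; it is ``None`` (status
    undetermined) when follow-up is shorter than 3 months.
    """

    case_id: str
    pre_egfr: float
    post_egfr: float
    followup_months: float
    category: str
    label: str | None

    @property
    def is_benefit(self) -> bool:
        return self.label == "benefit"


def classify_outcome(
    pre_egfr: float, post_egfr: float, followup_months: float, case_id: str = ""
) -> OutcomeRecord:
    """Apply the eGFR outcome rule.

    Improvement requires a >= 20% relative increase sustained for at least
    3 months; a >= 20% decrease is exacerbation; anything in between is
    stable.  Thresholds are inclusive.  Follow-up shorter than 3 months
    yields an explicit undetermined status rather than a silent non-benefit.
    """
    if pre_egfr <= 0:
        raise ValueError("pre-treatment eGFR must be positive")
    if followup_months < 0:
        raise ValueError("follow-up duration cannot be negative")
    rel = (post_egfr - pre_egfr) / pre_egfr
    if followup_months < 3:
        return OutcomeRecord(case_id, pre_egfr, post_egfr, followup_months, "undetermined", None)
    if rel >= 0.20:
        category = "improvement"
    elif rel <= -0.20:
        category = "exacerbation"
    else:
        category = "stable"
    label = "benefit" if category == "improvement" else "non-benefit"
    return OutcomeRecord(case_id, pre_egfr, post_egfr, followup_months, category, label)


def _ellipse_mask(shape, center, semi_axes, angle_deg):
    rows, cols = np.indices(shape)
    dy = rows - center[0]
    dx = cols - center[1]
    t = math.radians(angle_deg)
    u = dx * math.cos(t) + dy * math.sin(t)
    v = -dx * math.sin(t) + dy * math.cos(t)
    return (u / semi_axes[1]) ** 2 + (v / semi_axes[0]) ** 2 <= 1.0


def generate_slice(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render one HU slice plus the kidney (ROI1) and perirenal-fat (ROI2) masks.

    The body is a large soft-tissue ellipse on an air background; the kidney
    ellipse sits off-center inside a hypodense fat annulus.  ROI2 excludes
    ROI1 by construction.  Same spec (same seed) reproduces the arrays
    bit-exactly.
    """
    h, w = spec.image_size
    short = min(h, w)
    ky = spec.kidney_axes[0] * short
    kx = spec.kidney_axes[1] * short
    ring = spec.fat_ring_px
    center = (h * 0.52, w * 0.38)
    if ky + ring >= 0.4 * short or kx + ring >= 0.4 * short or ring < 1:
        raise PhantomGeometryError("kidney plus fat ring does not fit the canvas")

    body = _ellipse_mask((h, w), (h / 2, w / 2), (h * 0.45, w * 0.45), 0.0)
    roi1 = _ellipse_mask((h, w), center, (ky, kx), spec.kidney_angle_deg)
    fat_outer = _ellipse_mask((h, w), center, (ky + ring, kx + ring), spec.kidney_angle_deg)
    roi2 = fat_outer & ~roi1
    if not (roi1 <= body).all() or not (roi2 <= body).all():
        raise PhantomGeometryError("kidney/fat region extends outside the body")

    img = np.full((h, w), AIR_HU, dtype=np.float64)
    img[body] = spec.body_hu
    img[roi2] = spec.fat_hu
    img[roi1] = spec.kidney_hu

    rng = np.random.default_rng(spec.seed)
    if spec.kidney_texture_sd > 0:
        img[roi1] += rng.normal(0.0, spec.kidney_texture_sd, int(roi1.sum()))
    if spec.fat_texture_sd > 0:
        img[roi2] += rng.normal(0.0, spec.fat_texture_sd, int(roi2.sum()))
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, img.shape)
    return img, roi1, roi2


def degrade_patch(patch: np.ndarray, d: DegradationSpec) -> np.ndarray:
    """Apply one degradation kind to a 64x64 patch; 'normal' is the identity."""
    patch = np.asarray(patch, dtype=np.float64)
    if patch.shape != (64, 64):
        raise ValueError(f"expected a 64x64 patch, got {patch.shape}")
    if d.kind == "normal":
        return patch.copy()
    rng = np.random.default_rng(d.seed)
    if d.kind == "blur":
        return ndimage.gaussian_filter(patch, sigma=d.magnitude, mode="reflect")
    if d.kind == "noise":
        return patch + rng.normal(0.0, d.magnitude, patch.shape)
    if d.kind == "distort":
        # smooth random displacement field, rescaled so its largest
        # displacement component equals the requested amplitude
        field_ = rng.normal(0.0, 1.0, (2,) + patch.shape)
        field_ = ndimage.gaussian_filter(field_, sigma=(0, 8, 8), mode="reflect")
        peak = np.abs(field_).max()
        if peak > 0:
            field_ *= d.magnitude / peak
        rows, cols = np.indices(patch.shape, dtype=np.float64)
        return ndimage.map_coordinates(
            patch, [rows + field_[0], cols + field_[1]], order=1, mode="reflect"
        )
    if d.kind == "shift":
        m = float(np.round(d.magnitude))
        return ndimage.shift(patch, (m, m), order=1, mode="reflect")
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# pretext patch corpus
# ---------------------------------------------------------------------------


def sample_patches(
    n_patients: int,
    patches_per_patient: int,
    seed: int = 0,
    patch_size: int = 64,
    image_size: tuple[int, int] = (192, 192),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Build an unlabeled-by-outcome pretext corpus of degraded patches.

    Each synthetic 'patient' is one phantom slice with randomized tissue
    parameters; patches are sampled inside the body and assigned one of the
    five degradation kinds uniformly, with magnitudes drawn from
    :data:`MAGNITUDE_RANGES`.

    Returns ``(patches, kind_labels, patient_ids)`` where ``kind_labels``
    index into :data:`DEGRADATION_KINDS`.
    """
    rng = np.random.default_rng(seed)
    patches, labels, pids = [], [], []
    h, w = image_size
    for p in range(n_patients):
        spec = PhantomSpec(
            image_size=image_size,
            body_hu=rng.uniform(30, 50),
            kidney_hu=rng.uniform(25, 40),
            fat_hu=rng.uniform(-110, -70),
            kidney_texture_sd=rng.uniform(6, 18),
            fat_texture_sd=rng.uniform(8, 22),
            noise_sd=rng.uniform(3, 8),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        img, _, _ = generate_slice(spec)
        lo_r, hi_r = int(0.15 * h), int(0.85 * h) - patch_size
        lo_c, hi_c = int(0.15 * w), int(0.85 * w) - patch_size
        for _ in range(patches_per_patient):
            r = int(rng.integers(lo_r, hi_r + 1))
            c = int(rng.integers(lo_c, hi_c + 1))
            patch = img[r : r + patch_size, c : c + patch_size]
            kind = DEGRADATION_KINDS[int(rng.integers(0, 5))]
            if kind == "normal":
                d = DegradationSpec("normal")
            else:
                lo, hi = MAGNITUDE_RANGES[kind]
                d = DegradationSpec(kind, float(rng.uniform(lo, hi)), int(rng.integers(0, 2**31 - 1)))
            patches.append(degrade_patch(patch, d))
            labels.append(DEGRADATION_KINDS.index(kind))
            pids.append(p)
    return (
        np.asarray(patches, dtype=np.float64),
        np.asarray(labels, dtype=np.int64),
        np.asarray(pids, dtype=np.int64),
    )


def grouped_split(
    patient_ids: np.ndarray,
    fractions: tuple[float, float, float] = (0.7, 0.1, 0.2),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Patient-disjoint train/validation/test index split (default 7:1:2)."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    rng = np.random.default_rng(seed)
    uniq = np.unique(patient_ids)
    rng.shuffle(uniq)
    n = len(uniq)
    n_train = max(1, int(round(fractions[0] * n)))
    n_val = max(1, int(round(fractions[1] * n)))
    n_train = min(n_train, n - 2)
    train_p, val_p = uniq[:n_train], uniq[n_train : n_train + n_val]
    test_p = uniq[n_train + n_val :]
    idx = np.arange(len(patient_ids))
    return (
        idx[np.isin(patient_ids, train_p)],
        idx[np.isin(patient_ids, val_p)],
        idx[np.isin(patient_ids, test_p)],
    )


# ---------------------------------------------------------------------------
# outcome-labeled cohort
# ---------------------------------------------------------------------------

#: Default planted standardized effects (log-texture-SD scale).  The
#: perirenal-fat effect is the stronger one, mirroring the scientific claim
#: that perirenal adipose texture carries the larger predictive signal.
DEFAULT_EFFECT_SIZES = {"fat_texture_sd": 1.5, "kidney_texture_sd": 1.0}


@dataclass(frozen=True)
class PhantomCase:
    case_id: str
    image: np.ndarray
    roi1: np.ndarray
    roi2: np.ndarray
    record: OutcomeRecord
    planted: dict = field(default_factory=dict)


@dataclass(frozen=True)
class SyntheticCohort:
    """A labeled cohort of phantom cases with a known logistic effect model.

    ``effect_model`` stores, per planted parameter, the class-conditional
    log-scale means/SD and the implied logistic coefficient
    ``beta = delta / tau**2`` so recovery tests can compare against ground
    truth.  ``is_null`` flags a cohort generated with all effects zero.
    """

    cases: list
    effect_model: dict
    n_benefit: int
    n_nonbenefit: int
    is_null: bool
    seed: int

    @property
    def labels(self) -> np.ndarray:
        return np.array([1 if c.record.is_benefit else 0 for c in self.cases])

    def outcome_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "case_id": c.case_id,
                    "pre_eGFR": c.record.pre_egfr,
                    "post_eGFR": c.record.post_egfr,
                    "followup_months": c.record.followup_months,
                    "category": c.record.category,
                    "label": c.record.label,
                }
                for c in self.cases
            ]
        )


def build_cohort(
    n: int = 52,
    n_benefit: int = 18,
    effect_sizes: dict | None = None,
    seed: int = 0,
    image_size: tuple[int, int] = (256, 256),
    base_spec: PhantomSpec | None = None,
    tau: float = 0.25,
) -> SyntheticCohort:
    """Generate an outcome-labeled phantom cohort (default 18 benefit / 34 not).

    Labels are assigned first at the fixed composition; per-case texture SDs
    are then drawn class-conditionally on the log scale,
    ``log sd ~ N(log base + label * d * tau, tau^2)``, which implies a
    logistic model ``logit P(benefit | sd) = const + (d/tau) * z`` with
    ``z = (log sd - mean)/tau``.  ``effect_sizes`` gives the standardized
    separation ``d`` per parameter; all-zero effects are allowed and flag a
    null cohort.  eGFR trajectories are drawn consistently with the label and
    re-checked through :func:`classify_outcome`.
    """
    if not 0 < n_benefit < n:
        raise ValueError("need 0 < n_benefit < n")
    if effect_sizes is None:
        effect_sizes = dict(DEFAULT_EFFECT_SIZES)
    base = base_spec if base_spec is not None else PhantomSpec(image_size=image_size)
    rng = np.random.default_rng(seed)

    labels = np.zeros(n, dtype=int)
    labels[:n_benefit] = 1
    rng.shuffle(labels)

    is_null = all(v == 0 for v in effect_sizes.values())
    effect_model = {}
    for param, d in effect_sizes.items():
        base_val = getattr(base, param)
        effect_model[param] = {
            "d": float(d),
            "tau": tau,
            "log_base": math.log(base_val),
            "logistic_beta": float(d) / tau,  # per unit z of log-sd
        }

    cases = []
    for i in range(n):
        lab = int(labels[i])
        overrides = {}
        planted = {}
        for param, d in effect_sizes.items():
            log_base = effect_model[param]["log_base"]
            val = math.exp(rng.normal(log_base + lab * d * tau, tau))
            overrides[param] = val
            planted[param] = val
        spec = replace(base, seed=int(rng.integers(0, 2**31 - 1)), **overrides)
        img, roi1, roi2 = generate_slice(spec)

        pre = float(np.clip(rng.normal(70.0, 28.0), 15.0, 160.0))
        months = 3.0 + float(rng.exponential(1.01))  # median follow-up ~ 3.7 mo
        if lab == 1:
            rel = rng.uniform(0.20, 0.60)
        elif rng.uniform() < 0.2:
            rel = rng.uniform(-0.45, -0.20)
        else:
            rel = rng.uniform(-0.19, 0.19)
        post = pre * (1.0 + rel)
        record = classify_outcome(pre, post, months, case_id=f"case{i:03d}")
        assert (record.label == "benefit") == (lab == 1)
        cases.append(PhantomCase(f"case{i:03d}", img, roi1, roi2, record, planted))

    return SyntheticCohort(
        cases=cases,
        effect_model=effect_model,
        n_benefit=int(labels.sum()),
        n_nonbenefit=int(n - labels.sum()),
        is_null=is_null,
        seed=seed,
    )
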