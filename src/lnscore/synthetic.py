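"""Synthetic cohorts emulating a paired-design preclinical lymph-node study.

The generator reproduces the statistical structure the downstream analysis
assumes, without any image data: each subject carries one tumor-draining
(left) and one internal-control (right) inguinal node.  Tumor-group left
nodes are "involved": inflated volume (left/right ratio drawn around the
study-scale effect of ~9.9x), round shape (L/W ~ 1.6 vs ~2.4), lost hilum,
lengthened time-to-peak (~4.0 s vs ~1.9 s) and reduced wash-in rate.
Control-group subjects and all right nodes are uninvolved.

Two special cases mirror the hard cases of a real cohort: a subject whose
control-node CEUS loses too many frames to motion (TTP/WiR unavailable),
and an imaging-positive/pathology-negative subject whose left node looks
involved but is better perfused than its control and carries no
metastasis.

Node geometry is an axis-aligned ellipsoid sliced perpendicular to the
third (elevational) semiaxis, optionally with a wedge-shaped hilar
indentation carved into the central slices; curves are lognormal-bolus
time-intensity curves with additive iid Gaussian noise and a uniformly
random excluded-frame mask.  All randomness flows from the single integer
seed through a spawned `numpy` SeedSequence tree: one child stream per
subject, consumed in subject order; within a subject the draw order is
left geometry, right geometry, left curve, right curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import InvalidSpecError
from .morphometry import ContourStack
from .perfusion import TimeIntensityCurve, lognormal_bolus

__all__ = [
    "CohortSpec",
    "SyntheticNode",
    "SyntheticSubject",
    "generate_ellipsoid_contours",
    "generate_tic",
    "generate_cohort",
]

#: lognormal bolus shape parameter shared by all generated curves.
BOLUS_SIGMA = 0.5

#: excluded-frame fraction given to the motion-corrupted control node.
UNUSABLE_EXCLUDED_FRACTION = 0.6


@dataclass
class CohortSpec:
    """Study conditions of one synthetic cohort.

    Defaults reproduce the pilot study scale: 5 tumor-injected and 3
    control-injected subjects; involved nodes ~9.9x larger than their
    controls, round (L/W 1.62 vs 2.43), hilum lost, TTP 4.01 s vs 1.93 s.
    Wash-in rates are in arbitrary units (only the left/right contrast
    matters); the involved/control ratio of 0.25 encodes a clearly
    reduced wash-in.  Dispersions are per-node lognormal scatter.
    """

    n_tumor_subjects: int = 5
    n_control_subjects: int = 3
    volume_ratio_involved: float = 9.92
    volume_ratio_cv: float = 0.2
    control_volume_mm3: float = 1.438
    control_volume_sd: float = 0.691
    wt_volume_mm3: float = 1.38
    wt_volume_sd: float = 0.3
    shape_ratio_involved: float = 1.621
    shape_ratio_involved_sd: float = 0.181
    shape_ratio_control: float = 2.432
    shape_ratio_control_sd: float = 0.166
    hilum_loss_prob_involved: float = 1.0
    ttp_involved_s: float = 4.01
    ttp_involved_sd_s: float = 1.26
    ttp_control_s: float = 1.93
    ttp_control_sd_s: float = 0.77
    wir_involved: float = 1.5
    wir_control: float = 6.0
    wir_cv: float = 0.3
    hyperperfused_wir_factor: float = 2.0
    baseline_au: float = 1.0
    t_arrival_s: float = 6.0
    noise_sd: float = 0.2
    excluded_fraction: float = 0.05
    slice_spacing_mm: float = 0.038
    frame_rate_hz: float = 20.0
    n_frames: int = 1000
    n_vertices: int = 64
    seed: int = 0
    include_missing_ceus_subject: bool = True
    include_imaging_pos_path_neg_subject: bool = True

    def validate(self) -> None:
        if self.n_tumor_subjects < 0 or self.n_control_subjects < 0:
            raise InvalidSpecError("subject counts must be >= 0")
        if not (0.0 <= self.hilum_loss_prob_involved <= 1.0):
            raise InvalidSpecError("hilum_loss_prob_involved must be in [0, 1]")
        if not (0.0 <= self.excluded_fraction <= 1.0):
            raise InvalidSpecError("excluded_fraction must be in [0, 1]")
        for name in (
            "volume_ratio_involved", "control_volume_mm3", "shape_ratio_involved",
            "shape_ratio_control", "ttp_involved_s", "ttp_control_s",
            "wir_involved", "wir_control", "slice_spacing_mm", "frame_rate_hz",
        ):
            if getattr(self, name) <= 0:
                raise InvalidSpecError(f"{name} must be > 0")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be >= 0")
        if self.n_frames < 50:
            raise InvalidSpecError("n_frames must be >= 50")
        n_special = int(self.include_missing_ceus_subject) + int(
            self.include_imaging_pos_path_neg_subject
        )
        if self.n_tumor_subjects < n_special:
            raise InvalidSpecError(
                "not enough tumor subjects to host the special cases"
            )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticNode:
    """Raw inputs of one generated node, plus its generative ground truth."""

    node_id: str
    side: str
    contours: ContourStack
    tic: TimeIntensityCurve | None
    hilum_visible: bool
    truth: dict = field(default_factory=dict)


@dataclass
class SyntheticSubject:
    """One generated animal: paired nodes and pathology labels."""

    subject_id: str
    group: str  # "tumor_injected" | "control_injected"
    left: SyntheticNode
    right: SyntheticNode
    pathology_positive_left: bool
    pathology_positive_right: bool = False


def generate_ellipsoid_contours(
    semiaxes_mm: tuple[float, float, float],
    spacing_mm: float,
    n_vertices: int = 64,
    hilum_indent: bool = False,
    seed: int = 0,
    node_id: str = "",
) -> ContourStack:
    """Contour stack of an axis-aligned ellipsoid sliced along its third axis.

    Slices are midpoints of slabs covering [-c, c]; each contour is the
    inscribed ``n_vertices``-gon of the elliptical cross-section, with a
    seeded angular phase.  With ``hilum_indent``, a wedge-shaped radial
    concavity (the sonographic hilar notch) is carved into the central
    slices; the contour stays star-shaped, hence simple.
    """
    a, b, c = (float(s) for s in semiaxes_mm)
    if min(a, b, c) <= 0:
        raise InvalidSpecError(f"semiaxes must be positive, got {semiaxes_mm}")
    if spacing_mm >= min(a, b, c):
        raise InvalidSpecError(
            f"spacing {spacing_mm} must be finer than the smallest semiaxis"
        )
    if n_vertices < 8:
        raise InvalidSpecError("need at least 8 vertices per contour")
    n_slices = int(np.floor(2.0 * c / spacing_mm))
    if n_slices < 3:
        raise InvalidSpecError(
            f"spacing {spacing_mm} too coarse for semiaxis c={c}: < 3 slices"
        )
    rng = np.random.default_rng(seed)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    notch_theta = rng.uniform(0.0, 2.0 * np.pi)
    offset = (2.0 * c - n_slices * spacing_mm) / 2.0
    theta = phase + 2.0 * np.pi * np.arange(n_vertices) / n_vertices
    slices = []
    for k in range(n_slices):
        z = -c + offset + (k + 0.5) * spacing_mm
        shrink = np.sqrt(max(1.0 - (z / c) ** 2, 1e-12))
        r_mult = np.ones(n_vertices)
        if hilum_indent and abs(z) < c / 2.0:
            depth = 0.35 * (1.0 - abs(z) / (c / 2.0))
            ang = np.angle(np.exp(1j * (theta - notch_theta)))
            r_mult -= depth * np.clip(1.0 - np.abs(ang) / 0.6, 0.0, None)
        slices.append(
            np.column_stack(
                (a * shrink * r_mult * np.cos(theta), b * shrink * r_mult * np.sin(theta))
            )
        )
    return ContourStack(slices=slices, spacing_mm=spacing_mm, node_id=node_id)


def generate_tic(
    t_arrival_s: float,
    mu: float,
    sigma: float,
    amplitude: float,
    baseline: float,
    frame_rate_hz: float,
    n_frames: int,
    noise_sd: float,
    excluded_fraction: float,
    seed: int | np.random.Generator = 0,
    node_id: str = "",
) -> TimeIntensityCurve:
    """Sampled lognormal-bolus curve with noise and an excluded-frame mask."""
    if n_frames < 50:
        raise InvalidSpecError("n_frames must be >= 50")
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    t = np.arange(n_frames) / frame_rate_hz
    y = lognormal_bolus(t, t_arrival_s, mu, sigma, amplitude, baseline)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, n_frames)
    excluded = np.zeros(n_frames, dtype=bool)
    n_excl = int(round(excluded_fraction * n_frames))
    if n_excl > 0:
        excluded[rng.choice(n_frames, size=n_excl, replace=False)] = True
    return TimeIntensityCurve(time_s=t, intensity=y, excluded=excluded, node_id=node_id)


def _lognormal_mean_sd(rng: np.random.Generator, mean: float, sd: float) -> float:
    """One lognormal draw parameterised by its mean and standard deviation."""
    if sd == 0:
        return mean
    s2 = np.log1p((sd / mean) ** 2)
    return float(rng.lognormal(np.log(mean) - s2 / 2.0, np.sqrt(s2)))


def _semiaxes_from(volume_mm3: float, lw_ratio: float) -> tuple[float, float, float]:
    """Ellipsoid semiaxes (a, b, c) with in-plane L/W = lw_ratio, c = b."""
    b = (3.0 * volume_mm3 / (4.0 * np.pi * lw_ratio)) ** (1.0 / 3.0)
    return lw_ratio * b, b, b


def _wir_unit_slope(
    mu: float, sigma: float, frame_rate_hz: float
) -> float:
    """OLS wash-in slope of a unit-amplitude bolus, arrival to peak."""
    ttp = np.exp(mu - sigma**2)
    t = np.arange(0.0, ttp + 0.5 / frame_rate_hz, 1.0 / frame_rate_hz)
    y = lognormal_bolus(t, 0.0, mu, sigma, 1.0, 0.0)
    slope, _ = np.polyfit(t, y, 1)
    return float(slope)


def _make_node(
    spec: CohortSpec,
    rng_geom: np.random.Generator,
    rng_tic: np.random.Generator,
    node_id: str,
    side: str,
    involved: bool,
    volume_mm3: float,
    wir_override: float | None = None,
    excluded_fraction: float | None = None,
) -> SyntheticNode:
    """Generate one node's geometry and curve from its latent phenotype."""
    if involved:
        lw = _lognormal_mean_sd(
            rng_geom, spec.shape_ratio_involved, spec.shape_ratio_involved_sd
        )
        hilum_visible = rng_geom.random() >= spec.hilum_loss_prob_involved
        ttp = _lognormal_mean_sd(rng_tic, spec.ttp_involved_s, spec.ttp_involved_sd_s)
        wir_mean = spec.wir_involved
    else:
        lw = _lognormal_mean_sd(
            rng_geom, spec.shape_ratio_control, spec.shape_ratio_control_sd
        )
        hilum_visible = True
        ttp = _lognormal_mean_sd(rng_tic, spec.ttp_control_s, spec.ttp_control_sd_s)
        wir_mean = spec.wir_control
    lw = max(lw, 1.05)
    ttp = max(ttp, 0.5)
    if wir_override is not None:
        wir = wir_override
    else:
        wir = _lognormal_mean_sd(rng_tic, wir_mean, spec.wir_cv * wir_mean)
    contours = generate_ellipsoid_contours(
        _semiaxes_from(volume_mm3, lw),
        spec.slice_spacing_mm,
        n_vertices=spec.n_vertices,
        hilum_indent=hilum_visible,
        seed=int(rng_geom.integers(2**31)),
        node_id=node_id,
    )
    sigma = BOLUS_SIGMA
    mu = np.log(ttp) + sigma**2
    amplitude = wir / _wir_unit_slope(mu, sigma, spec.frame_rate_hz)
    t_arr = spec.t_arrival_s + rng_tic.uniform(-0.5, 0.5)
    frac = spec.excluded_fraction if excluded_fraction is None else excluded_fraction
    tic = generate_tic(
        t_arr, mu, sigma, amplitude, spec.baseline_au,
        spec.frame_rate_hz, spec.n_frames, spec.noise_sd, frac,
        seed=rng_tic, node_id=node_id,
    )
    return SyntheticNode(
        node_id=node_id,
        side=side,
        contours=contours,
        tic=tic,
        hilum_visible=hilum_visible,
        truth={
            "involved": involved,
            "volume_mm3": volume_mm3,
            "lw_ratio": lw,
            "ttp_s": ttp,
            "wir_au_per_s": wir,
            "t_arrival_s": t_arr,
            "mu": mu,
            "sigma": sigma,
            "amplitude": amplitude,
            "baseline_au": spec.baseline_au,
        },
    )


def generate_cohort(spec: CohortSpec) -> list[SyntheticSubject]:
    """Generate the full cohort of paired-node subjects.

    Tumor-group subjects have involved left nodes; all right nodes and
    control-group left nodes are uninvolved.  When enabled, the last
    tumor-group subject is the missing-CEUS case (control node loses 60%
    of frames, above the quality gate) and the second-to-last is the
    imaging-positive/pathology-negative case (involved morphology and
    lengthened TTP, but hyperperfused left node and negative pathology).
    """
    spec.validate()
    n_total = spec.n_tumor_subjects + spec.n_control_subjects
    children = np.random.SeedSequence(spec.seed).spawn(n_total)
    idx_missing = spec.n_tumor_subjects - 1 if spec.include_missing_ceus_subject else -1
    idx_pathneg = (
        spec.n_tumor_subjects - 1 - int(spec.include_missing_ceus_subject)
        if spec.include_imaging_pos_path_neg_subject
        else -1
    )
    subjects = []
    for i in range(n_total):
        tumor = i < spec.n_tumor_subjects
        sid = f"KPN-{i + 1}" if tumor else f"WT-{i - spec.n_tumor_subjects + 1}"
        gl, gr, tl, tr = (
            np.random.default_rng(s) for s in children[i].spawn(4)
        )
        if tumor:
            right_vol = max(
                _lognormal_mean_sd(gr, spec.control_volume_mm3, spec.control_volume_sd),
                0.2,
            )
            ratio = _lognormal_mean_sd(
                gl, spec.volume_ratio_involved,
                spec.volume_ratio_cv * spec.volume_ratio_involved,
            )
            wir_override = None
            path_left = True
            if i == idx_pathneg:
                wir_override = _lognormal_mean_sd(
                    tl,
                    spec.hyperperfused_wir_factor * spec.wir_control,
                    0.2 * spec.hyperperfused_wir_factor * spec.wir_control,
                )
                path_left = False
            left = _make_node(
                spec, gl, tl, f"{sid}-L", "left",
                involved=True, volume_mm3=right_vol * ratio,
                wir_override=wir_override,
            )
            right = _make_node(
                spec, gr, tr, f"{sid}-R", "right",
                involved=False, volume_mm3=right_vol,
                excluded_fraction=(
                    UNUSABLE_EXCLUDED_FRACTION if i == idx_missing else None
                ),
            )
        else:
            path_left = False
            left = _make_node(
                spec, gl, tl, f"{sid}-L", "left", involved=False,
                volume_mm3=max(
                    _lognormal_mean_sd(gl, spec.wt_volume_mm3, spec.wt_volume_sd), 0.2
                ),
            )
            right = _make_node(
                spec, gr, tr, f"{sid}-R", "right", involved=False,
                volume_mm3=max(
                    _lognormal_mean_sd(gr, spec.wt_volume_mm3, spec.wt_volume_sd), 0.2
                ),
            )
        subjects.append(
            SyntheticSubject(
                subject_id=sid,
                group="tumor_injected" if tumor else "control_injected",
                left=left,
                right=right,
                pathology_positive_left=path_left,
            )
        )
    return subjects
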