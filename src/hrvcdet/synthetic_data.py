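"""Synthetic stage-labeled RR cohorts.

The real athlete recordings behind this kind of study are confidential, so
the package ships a generator that emulates their statistical structure: each
subject's tachogram is a mean RR level plus two autonomic oscillators — a
0.1 Hz (LF, mixed sympathetic/vagal) and a 0.25 Hz (HF, respiratory/vagal)
sinusoid — plus white beat-to-beat noise.  Stage differences are encoded only
through the profile parameters (overall variability via a calibrated SDNN
target, sympathovagal balance via the LF/HF amplitude ratio), which is the
simplest structure under which SDNN and LF n.u. discriminate training-load
stages the way the published stage tables suggest.

Between-subject heterogeneity is multiplicative lognormal jitter on the
profile parameters (an invention — the source tables give only mean ± SD per
stage, no within-stage distribution).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .hrv_features import SpectralConfig, extract_features, time_domain
from .io_formats import FeatureTable, RRSeries

__all__ = [
    "StageProfile",
    "CohortSpec",
    "simulate_rr",
    "calibrate_profile",
    "simulate_cohort",
    "default_stage_profiles",
]

LF_HZ = 0.1  # canonical LF band center
HF_HZ = 0.25  # canonical HF band center


@dataclass(frozen=True)
class StageProfile:
    """Generator parameters for one training stage.

    mean_rr, lf_amp, hf_amp, noise_sd in ms; duration in seconds;
    target_sdnn (ms) is the calibration set-point, NaN if uncalibrated.
    """

    stage: str
    mean_rr: float = 800.0
    lf_amp: float = 25.0
    hf_amp: float = 40.0
    noise_sd: float = 10.0
    target_sdnn: float = float("nan")
    duration: float = 300.0

    def __post_init__(self) -> None:
        if self.mean_rr <= 0:
            raise ValueError("mean_rr must be positive")
        if min(self.lf_amp, self.hf_amp, self.noise_sd) < 0:
            raise ValueError("amplitudes and noise_sd must be nonnegative")
        if self.duration < 60:
            raise ValueError("duration must be at least 60 s")


@dataclass(frozen=True)
class CohortSpec:
    """A cohort: one StageProfile per stage, subjects per stage, jitter, seed."""

    profiles: tuple
    subjects_per_stage: int = 25
    between_subject_sd: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.subjects_per_stage < 1:
            raise ValueError("subjects_per_stage must be >= 1")
        if self.between_subject_sd < 0:
            raise ValueError("between_subject_sd must be >= 0")
        object.__setattr__(self, "profiles", tuple(self.profiles))


def simulate_rr(profile: StageProfile, seed: int, subject_id: str = "") -> RRSeries:
    """Generate one subject's RR series.

    Beats are produced iteratively: the k-th interval is evaluated at the
    cumulative onset time t_k of the previous beats,

        RR_k = mean_rr + lf_amp sin(2π·0.1 t_k + φ_LF)
                       + hf_amp sin(2π·0.25 t_k + φ_HF) + noise_sd ε_k,

    with the two phases drawn once per subject and ε_k standard normal.
    Intervals are clipped to the physiological range [300, 2000] ms.  Raises
    if more than 1% of beats would be non-positive before clipping.
    """
    rng = np.random.default_rng(seed)
    phi_lf, phi_hf = rng.uniform(0.0, 2.0 * math.pi, size=2)
    t = 0.0
    intervals = []
    n_nonpos = 0
    two_pi = 2.0 * math.pi
    while t < profile.duration:
        rr = (
            profile.mean_rr
            + profile.lf_amp * math.sin(two_pi * LF_HZ * t + phi_lf)
            + profile.hf_amp * math.sin(two_pi * HF_HZ * t + phi_hf)
            + profile.noise_sd * rng.standard_normal()
        )
        if rr <= 0:
            n_nonpos += 1
        rr = min(max(rr, 300.0), 2000.0)
        intervals.append(rr)
        t += rr / 1000.0
    if n_nonpos > 0.01 * len(intervals):
        raise ValueError(
            f"profile {profile.stage!r} yields {n_nonpos}/{len(intervals)} "
            "non-positive beats before clipping; amplitudes too large for mean_rr"
        )
    return RRSeries(
        subject_id=subject_id or f"{profile.stage}_sim",
        stage=profile.stage,
        intervals=np.array(intervals),
    )


def _mean_sdnn(profile: StageProfile, n_subjects: int, seed: int) -> float:
    vals = [
        time_domain(simulate_rr(profile, seed + i)).sdnn for i in range(n_subjects)
    ]
    return float(np.mean(vals))


def calibrate_profile(
    target_sdnn: float,
    base: StageProfile,
    n_subjects: int = 50,
    seed: int = 12345,
    rel_tol: float = 0.01,
    max_iter: int = 40,
) -> StageProfile:
    """Scale (lf_amp, hf_amp, noise_sd) by a common factor, found by
    deterministic bisection, so the mean SDNN over ``n_subjects`` seeded
    subjects matches ``target_sdnn`` (within ``rel_tol`` relative).

    The scale family responds nearly linearly, so bisection converges fast.
    Raises if no bracketing factor exists (e.g. all base amplitudes zero).
    """
    if target_sdnn <= 0:
        raise ValueError("target_sdnn must be positive")

    def scaled(s: float) -> StageProfile:
        return replace(
            base,
            lf_amp=base.lf_amp * s,
            hf_amp=base.hf_amp * s,
            noise_sd=base.noise_sd * s,
            target_sdnn=target_sdnn,
        )

    def f(s: float) -> float:
        return _mean_sdnn(scaled(s), n_subjects, seed)

    lo, hi = 1e-6, 1.0
    f_hi = f(hi)
    n_doublings = 0
    while f_hi < target_sdnn:
        hi *= 2.0
        n_doublings += 1
        if n_doublings > 20:
            raise ValueError("calibration cannot bracket the SDNN target")
        try:
            f_hi = f(hi)
        except ValueError as exc:  # amplitudes outgrew mean_rr
            raise ValueError("calibration cannot bracket the SDNN target") from exc
    if f(lo) > target_sdnn:
        raise ValueError("calibration cannot bracket the SDNN target")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        if abs(fm - target_sdnn) <= rel_tol * target_sdnn:
            return scaled(mid)
        if fm < target_sdnn:
            lo = mid
        else:
            hi = mid
    return scaled(0.5 * (lo + hi))


#: Stage SDNN set-points (ms) and LF n.u. set-points (%) taken from published
#: stage tables for elite female volleyball players over a winter-training
#: period: variability rises early -> middle -> late, sympathovagal balance
#: dips in the middle stage.
STAGE_SDNN_TARGETS = {"early": 52.31, "middle": 55.93, "late": 69.67}
STAGE_LF_NU_TARGETS = {"early": 30.33, "middle": 26.62, "late": 32.51}


def default_stage_profiles(calibrate: bool = True, seed: int = 12345) -> tuple:
    """The three winter-training stage profiles.

    The LF/HF amplitude ratio is set from each stage's LF n.u. set-point
    (band powers scale with amplitude squared, so
    lf_amp/hf_amp = sqrt(lf_nu / hf_nu)); the overall oscillation scale is
    calibrated to the stage's SDNN set-point when ``calibrate`` is true.
    """
    profiles = []
    for stage, sdnn in STAGE_SDNN_TARGETS.items():
        lf_nu = STAGE_LF_NU_TARGETS[stage]
        ratio = math.sqrt(lf_nu / (100.0 - lf_nu))
        base = StageProfile(
            stage=stage,
            mean_rr=800.0,
            lf_amp=40.0 * ratio,
            hf_amp=40.0,
            noise_sd=10.0,
            target_sdnn=sdnn,
            duration=300.0,
        )
        if calibrate:
            base = calibrate_profile(sdnn, base, seed=seed)
        profiles.append(base)
    return tuple(profiles)


def _jitter_profile(profile: StageProfile, sd: float, rng: np.random.Generator) -> StageProfile:
    if sd == 0:
        return profile
    # multiplicative lognormal jitter, median-preserving
    factors = np.exp(rng.normal(0.0, sd, size=4))
    return replace(
        profile,
        mean_rr=profile.mean_rr * factors[0],
        lf_amp=profile.lf_amp * factors[1],
        hf_amp=profile.hf_amp * factors[2],
        noise_sd=profile.noise_sd * factors[3],
    )


def simulate_cohort(
    spec: CohortSpec, cfg: SpectralConfig = SpectralConfig()
) -> tuple:
    """Simulate a full cohort and extract its HRV feature table.

    Returns ``(table, series)``: a FeatureTable with one row per subject
    (class = stage, the 10 HRV indices as columns) and the underlying dict of
    RRSeries keyed by subject id.  Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    subject_ids = []
    labels = []
    rows = []
    series = {}
    for profile in spec.profiles:
        for i in range(spec.subjects_per_stage):
            sid = f"{profile.stage}_{i:03d}"
            subj_profile = _jitter_profile(profile, spec.between_subject_sd, rng)
            subj_seed = int(rng.integers(0, 2**31 - 1))
            rr = simulate_rr(subj_profile, subj_seed, subject_id=sid)
            feats = extract_features(rr, cfg)
            subject_ids.append(sid)
            labels.append(profile.stage)
            rows.append([feats[k] for k in feats])
            series[sid] = rr
    feature_names = tuple(extract_features(series[subject_ids[0]], cfg).keys())
    table = FeatureTable(
        subject_ids=tuple(subject_ids),
        class_labels=tuple(labels),
        X=np.array(rows),
        feature_names=feature_names,
    )
    return table, series
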