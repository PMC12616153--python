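"""Synthetic cohorts, SPR trials, ROI feature tables, and a BOLD phantom.

Every downstream stage of the package is exercisable without any real data.
The generators emulate the study conditions of an adult-lifespan reading
cohort:

* a **bimodal age distribution** (younger and older modes, few middle-aged
  participants), clipped to 20-80 years;
* memory scores that decline with age with standardized slopes of -0.61
  (working memory) and -0.54 (auditory-verbal short-term memory);
* self-paced-reading trials (24 per condition, 48 total) whose
  relative-clause reading times are lognormal, calibrated so the cohort
  means/SDs of per-participant summaries match the reference values
  (OR RT 2.89 s (1.28), SR RT 2.43 s (0.99), OR accuracy 86.6% (8.4),
  SR accuracy 89.7% (8.8)), with an age slowing that is larger for the OR
  condition so the RT disadvantage score grows more negative with age;
* per-ROI imaging features with a common age slope and, optionally,
  *planted* mediation effects (a standardized age->ROI path ``a`` and
  ROI->outcome path ``b``) whose ground truth is recorded for recovery
  tests;
* a small 4D phantom with an in-band (0.05 Hz) sinusoid block, an
  out-of-band (0.20 Hz) sinusoid block, and a white-noise block, by default
  427 volumes at TR 1.65 s.

Calibration is done against the *empirical* cohort (closed-form lognormal
moment matching for RTs; nested root-finds for accuracies), so the targets
are met without assuming normal ages.  All generators are bit-reproducible
under a master seed with per-generator stream splitting.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from ._seeds import stream_rng
from .roi_features import AtlasVolume, Volume3D, Volume4D, nyquist

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_cohort",
    "generate_trials",
    "generate_roi_features",
    "generate_phantom_bold",
    "generate_scored_cohort",
    "RoiFeatureTable",
    "LANGUAGE_ROI_BASENAMES",
]

#: The 12 per-hemisphere language ROIs: three regions, four subregions each.
LANGUAGE_ROI_BASENAMES = (
    # frontal cortex
    "IFGtri", "IFGoper", "IFGorb", "MFG",
    # mid-to-anterior temporal lobe
    "MTG", "STG", "MTGpole", "STGpole",
    # temporoparietal junction
    "pMTG", "pSTG", "SMG", "AG",
)


@dataclass(frozen=True)
class SyntheticConfig:
    """All knobs of the synthetic-data generators (defaults = study conditions)."""

    n_participants: int = 187
    seed: int = 0

    # cohort ------------------------------------------------------------
    #: (mean yr, sd yr, weight) of the two age-mixture components.
    age_mixture: tuple[tuple[float, float, float], ...] = ((30.0, 7.0, 0.45), (67.0, 8.0, 0.55))
    age_range: tuple[float, float] = (20.0, 80.0)
    path_age_wm: float = -0.61  # standardized age -> WM slope
    path_age_stm: float = -0.54  # standardized age -> STM slope
    wm_score_mean: float = 107.96
    wm_score_sd: float = 13.88
    stm_score_mean: float = 26.17
    stm_score_sd: float = 6.39
    p_female: float = 0.74
    education_mean: float = 5.1  # 1 = middle school .. 6 = graduate degree
    education_sd: float = 1.0
    # TIV spread is not reported anywhere; plausible adult values (ml).
    tiv_mean: float = 1450.0
    tiv_sd: float = 130.0

    # SPR trials ---------------------------------------------------------
    trials_per_condition: int = 24
    sr_rt_mean: float = 2.43  # across-participant mean of per-participant mean RC RT (s)
    sr_rt_sd: float = 0.99
    or_rt_mean: float = 2.89
    or_rt_sd: float = 1.28
    sr_acc: float = 0.897  # across-participant mean accuracy
    or_acc: float = 0.866
    sr_acc_sd: float = 0.088
    or_acc_sd: float = 0.084
    #: share of the between-person accuracy latent carried by working memory
    #: (the rest is independent ability), sized so the standardized
    #: WM -> accuracy path lands near the reference 0.35
    acc_wm_weight: float = 0.5
    rt_log_within_sd: float = 0.45  # trial-to-trial lognormal sigma
    rt_age_slope_sr: float = 0.10  # log-RT change per SD of age
    rt_age_slope_or: float = 0.122  # larger: OR-specific slowing

    # ROI features --------------------------------------------------------
    n_rois: int = 12  # per hemisphere
    planted_rois: tuple[tuple[str, float, float], ...] = ()  # (name, a, b)
    planted_outcome: str = "rt_sds"
    roi_age_slope: float = -0.004  # feature units per year
    roi_feature_mean: float = 1.0
    noise_sd: float = 0.1  # feature units

    # BOLD phantom ---------------------------------------------------------
    phantom_shape: tuple[int, int, int] = (9, 3, 3)
    phantom_n_volumes: int = 427
    phantom_tr: float = 1.65
    phantom_inband_freq: float = 0.05
    phantom_outband_freq: float = 0.20
    phantom_noise_sd: float = 0.0
    phantom_baseline: float = 100.0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be positive")
        weights = [w for _m, _s, w in self.age_mixture]
        if abs(sum(weights) - 1.0) > 1e-9:
            raise ValueError(f"age mixture weights must sum to 1, got {sum(weights)}")
        if any(s <= 0 for _m, s, _w in self.age_mixture):
            raise ValueError("age mixture sds must be positive")
        for name in ("sr_rt_sd", "or_rt_sd", "sr_acc_sd", "or_acc_sd", "rt_log_within_sd",
                     "wm_score_sd", "stm_score_sd", "education_sd", "tiv_sd", "noise_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("sr_acc", "or_acc", "p_female"):
            p = getattr(self, name)
            if not 0.0 < p <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {p}")
        if self.trials_per_condition < 1:
            raise ValueError("trials_per_condition must be >= 1")
        if self.phantom_tr <= 0:
            raise ValueError("phantom_tr must be positive")
        if abs(self.path_age_wm) > 1 or abs(self.path_age_stm) > 1:
            raise ValueError("standardized age->memory slopes must be in [-1, 1]")
        names = [n for n, _a, _b in self.planted_rois]
        if len(set(names)) != len(names):
            raise ValueError("duplicate planted ROI names")
        for n, a, _b in self.planted_rois:
            if abs(a) >= 1:
                raise ValueError(f"planted a-path for {n} must be in (-1, 1)")

    def roi_names(self) -> list[str]:
        """Interleaved L/R ROI names (hemisphere alternates over 2*n_rois)."""
        if self.n_rois == len(LANGUAGE_ROI_BASENAMES):
            base = LANGUAGE_ROI_BASENAMES
        else:
            base = tuple(f"roi{i + 1:02d}" for i in range(self.n_rois))
        return [f"{h}_{b}" for b in base for h in ("L", "R")]


@dataclass
class SyntheticTruth:
    """Ground truth of the planted structure, for recovery tests."""

    path_age_wm: float
    path_age_stm: float
    #: roi name -> (a, b, ab); ab is exactly a*b.
    planted: dict[str, tuple[float, float, float]] = field(default_factory=dict)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


@dataclass
class RoiFeatureTable:
    """Participants x ROIs feature matrix for one imaging modality."""

    data: pd.DataFrame  # index participant_id, one column per ROI
    hemispheres: dict[str, str]  # roi name -> "L"/"R"
    modality: str = "GMV"

    def __post_init__(self) -> None:
        missing = [c for c in self.data.columns if c not in self.hemispheres]
        if missing:
            raise ValueError(f"ROIs without hemisphere label: {missing}")


# ---------------------------------------------------------------------------
# cohort


def generate_cohort(config: SyntheticConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Draw a cohort table and record the planted ground truth.

    Ages come from the two-component normal mixture clipped to the age
    range; WM and STM are standardized linear functions of standardized age
    with the configured slopes plus Gaussian residuals scaled so the
    marginal variance is 1, then mapped to their reported score scales.
    """
    rng = stream_rng(config.seed, "cohort")
    n = config.n_participants
    means = np.array([m for m, _s, _w in config.age_mixture])
    sds = np.array([s for _m, s, _w in config.age_mixture])
    weights = np.array([w for _m, _s, w in config.age_mixture])
    comp = rng.choice(len(weights), size=n, p=weights)
    age = np.clip(rng.normal(means[comp], sds[comp]), *config.age_range)
    if np.unique(age).size < 2:
        raise ValueError("degenerate age distribution; increase n or widen the mixture")
    z_age = (age - age.mean()) / age.std(ddof=1)

    def memory_z(slope: float) -> np.ndarray:
        resid = rng.standard_normal(n)
        return slope * z_age + np.sqrt(1.0 - slope**2) * resid

    wm_z = memory_z(config.path_age_wm)
    stm_z = memory_z(config.path_age_stm)
    sex = (rng.random(n) < config.p_female).astype(int)  # 1 = female
    education = np.clip(
        np.rint(rng.normal(config.education_mean, config.education_sd, n)), 1, 6
    ).astype(int)
    tiv = rng.normal(config.tiv_mean, config.tiv_sd, n)

    cohort = pd.DataFrame(
        {
            "participant_id": [f"sub-{i + 1:05d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "education": education,
            "tiv": tiv,
            "nih_wm": config.wm_score_mean + config.wm_score_sd * wm_z,
            "nih_stm": config.stm_score_mean + config.stm_score_sd * stm_z,
        }
    )
    truth = SyntheticTruth(
        path_age_wm=config.path_age_wm,
        path_age_stm=config.path_age_stm,
        planted={name: (a, b, a * b) for name, a, b in config.planted_rois},
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# SPR trials


def _zscore(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std(ddof=1)


def _solve_rt_log_params(
    mean_rt: float, sd_rt: float, sigma_w: float, beta: float,
    z_age: np.ndarray, n_trials: int,
) -> tuple[float, float]:
    """Lognormal moment matching against the empirical age distribution.

    Per-participant trial RTs are exp(nu + eta_i + beta*z_i + sigma_w*eps)
    with eta_i ~ N(0, sigma_b2).  Returns (nu, sigma_b2) such that the
    across-participant mean and SD of the n_trials-trial mean equal
    (mean_rt, sd_rt) exactly in expectation.
    """
    w = np.expm1(sigma_w**2) / n_trials
    g1 = np.exp(beta * z_age).mean()
    g2 = np.exp(2.0 * beta * z_age).mean()
    val = (1.0 + sd_rt**2 / mean_rt**2) / (1.0 + w) * g1**2 / g2
    if val <= 1.0:
        raise ValueError(
            "requested between-participant RT sd is smaller than the variance "
            "already implied by trial noise and the age slope; lower "
            "rt_log_within_sd or the age slopes"
        )
    sigma_b2 = float(np.log(val))
    nu = float(np.log(mean_rt) - sigma_w**2 / 2.0 - sigma_b2 / 2.0 - np.log(g1))
    return nu, sigma_b2


def _solve_acc_params(
    mean_acc: float, sd_acc: float, modulator: np.ndarray, n_trials: int,
) -> tuple[float, float]:
    """Solve (mu, gamma) of p_i = expit(mu + gamma * wm_z_i).

    Matches the across-participant mean accuracy exactly on the empirical
    modulator distribution, and the across-participant SD of the
    n_trials-trial accuracy (binomial variance + spread of p_i).  If the
    target SD is at or below the pure-binomial floor, gamma is 0.
    """

    def mu_for(gamma: float) -> float:
        return brentq(
            lambda mu: expit(mu + gamma * modulator).mean() - mean_acc, -20.0, 20.0
        )

    def total_sd(gamma: float) -> float:
        p = expit(mu_for(gamma) + gamma * modulator)
        var = (p * (1.0 - p)).mean() / n_trials + p.var()
        return float(np.sqrt(var))

    if sd_acc <= total_sd(0.0):
        # target at or below the pure-binomial floor: no WM modulation
        return float(logit(mean_acc)), 0.0
    hi = 1.0
    while total_sd(hi) < sd_acc:
        hi *= 2.0
        if hi > 64.0:
            raise ValueError("cannot reach the requested accuracy SD")
    gamma = brentq(lambda g: total_sd(g) - sd_acc, 0.0, hi, xtol=1e-10)
    return float(mu_for(gamma)), float(gamma)


def generate_trials(cohort: pd.DataFrame, config: SyntheticConfig) -> pd.DataFrame:
    """Generate trial-level SPR records for every cohort participant.

    Exactly ``trials_per_condition`` trials per condition per participant.
    Relative-clause RTs are lognormal with condition-specific parameters
    solved from the configured across-participant mean/SD targets and a
    log-scale age slowing that is larger for OR than SR; comprehension
    correctness is Bernoulli at condition-specific probabilities modulated
    by the participant's working memory.  Other region RTs are positive
    lognormal draws, unused by the default analyses.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    rng = stream_rng(config.seed, "trials")
    n = len(cohort)
    tpc = config.trials_per_condition
    z_age = _zscore(cohort["age"].to_numpy(dtype=float))
    wm_z = _zscore(cohort["nih_wm"].to_numpy(dtype=float))
    sigma_w = config.rt_log_within_sd

    nu_sr, sb2_sr = _solve_rt_log_params(
        config.sr_rt_mean, config.sr_rt_sd, sigma_w, config.rt_age_slope_sr, z_age, tpc
    )
    nu_or, sb2_or = _solve_rt_log_params(
        config.or_rt_mean, config.or_rt_sd, sigma_w, config.rt_age_slope_or, z_age, tpc
    )
    # shared participant speed (SR as reference) + OR-specific extra spread
    sigma_u2 = sb2_sr
    v_or2 = sb2_or - sigma_u2
    if v_or2 < -1e-12:
        raise ValueError(
            "config implies negative OR-specific variance; the OR RT sd target "
            "is too small relative to the SR one"
        )
    u = rng.normal(0.0, np.sqrt(sigma_u2), n) if sigma_u2 > 0 else np.zeros(n)
    v_or = rng.normal(0.0, np.sqrt(max(v_or2, 0.0)), n) if v_or2 > 1e-12 else np.zeros(n)

    # accuracy latent: WM share + independent ability, shared across conditions
    w_acc = config.acc_wm_weight
    if not 0.0 <= w_acc <= 1.0:
        raise ValueError("acc_wm_weight must be in [0, 1]")
    ability = w_acc * wm_z + np.sqrt(1.0 - w_acc**2) * rng.standard_normal(n)
    mu_acc_sr, gam_sr = _solve_acc_params(config.sr_acc, config.sr_acc_sd, ability, tpc)
    mu_acc_or, gam_or = _solve_acc_params(config.or_acc, config.or_acc_sd, ability, tpc)

    cond_params = {
        "SR": (nu_sr + u + config.rt_age_slope_sr * z_age, mu_acc_sr + gam_sr * ability),
        "OR": (nu_or + u + v_or + config.rt_age_slope_or * z_age, mu_acc_or + gam_or * ability),
    }

    def other_region(mean: float, sd_log: float = 0.35) -> np.ndarray:
        return np.exp(np.log(mean) - sd_log**2 / 2 + sd_log * rng.standard_normal((n, tpc)))

    from .behavioral import QUESTION_TYPES

    frames = []
    qtypes = np.resize(np.array(QUESTION_TYPES), tpc)
    for cond in ("SR", "OR"):
        mu_i, logit_i = cond_params[cond]
        rc = np.exp(mu_i[:, None] + sigma_w * rng.standard_normal((n, tpc)))
        correct = rng.random((n, tpc)) < expit(logit_i)[:, None]
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": np.repeat(cohort["participant_id"].to_numpy(), tpc),
                    "condition": cond,
                    "trial": np.tile(np.arange(1, tpc + 1), n),
                    "rt_subject": other_region(0.85).ravel(),
                    "rt_relative_clause": rc.ravel(),
                    "rt_main_clause": other_region(0.95).ravel(),
                    "rt_modifier": other_region(0.75).ravel(),
                    "question_type": np.tile(qtypes, n),
                    "question_correct": correct.ravel(),
                }
            )
        )
    trials = pd.concat(frames, ignore_index=True)
    return trials.sort_values(["participant_id", "condition", "trial"], kind="stable").reset_index(
        drop=True
    )


# ---------------------------------------------------------------------------
# ROI features


def generate_roi_features(
    cohort: pd.DataFrame,
    truth: SyntheticTruth,
    config: SyntheticConfig,
    modality: str = "GMV",
) -> RoiFeatureTable:
    """Per-participant, per-ROI features with optional planted mediation.

    Non-planted ROIs follow ``intercept + roi_age_slope * age + noise``.
    A planted ROI carries a standardized age path ``a`` (its correlation
    with age), and its configured ``b`` path is injected into the designated
    outcome column: when any planted ``b`` is nonzero, ``cohort[outcome]``
    is **replaced in place** by a unit-variance construction whose
    population standardized paths equal the planted values exactly, built
    from the original outcome's age slope and residuals.  The cohort must
    already carry the outcome column (i.e., be scored).
    """
    rng = stream_rng(config.seed, "roi_features")
    names = config.roi_names()
    hemis = {nm: nm.split("_", 1)[0] for nm in names}
    unknown = [nm for nm, _a, _b in config.planted_rois if nm not in names]
    if unknown:
        raise ValueError(f"planted ROI(s) not in the ROI list: {unknown}")

    n = len(cohort)
    age = cohort["age"].to_numpy(dtype=float)
    z_age = _zscore(age)
    sd_age = age.std(ddof=1)
    scale = float(np.hypot(config.roi_age_slope * sd_age, config.noise_sd))
    planted = {nm: (a, b) for nm, a, b in config.planted_rois}

    cols = {}
    m_std: dict[str, np.ndarray] = {}
    for nm in names:
        if nm in planted:
            a, _b = planted[nm]
            u = rng.standard_normal(n)
            m = a * z_age + np.sqrt(1.0 - a**2) * u
            m_std[nm] = m
            cols[nm] = config.roi_feature_mean + config.roi_age_slope * age.mean() + scale * m
        else:
            cols[nm] = (
                config.roi_feature_mean
                + config.roi_age_slope * age
                + rng.normal(0.0, config.noise_sd, n)
            )
    data = pd.DataFrame(cols, index=pd.Index(cohort["participant_id"], name="participant_id"))

    b_paths = {nm: b for nm, (a, b) in planted.items() if b != 0.0}
    if b_paths:
        outcome = config.planted_outcome
        if outcome not in cohort.columns:
            raise ValueError(
                f"outcome column {outcome!r} missing from cohort; score the cohort first"
            )
        y0 = _zscore(cohort[outcome].to_numpy(dtype=float))
        c_hat = float(z_age @ y0 / (z_age @ z_age))
        resid = y0 - c_hat * z_age
        e = resid / resid.std(ddof=1)
        a_of = {nm: planted[nm][0] for nm in b_paths}
        var_struct = c_hat**2 + sum(b**2 for b in b_paths.values())
        var_struct += 2.0 * c_hat * sum(b * a_of[nm] for nm, b in b_paths.items())
        items = list(b_paths.items())
        for i, (nm_i, b_i) in enumerate(items):
            for nm_j, b_j in items[i + 1 :]:
                var_struct += 2.0 * b_i * b_j * a_of[nm_i] * a_of[nm_j]
        lam2 = 1.0 - var_struct
        if lam2 <= 0:
            raise ValueError(
                "planted paths plus the outcome's age slope leave no residual "
                "variance; reduce the planted effect sizes"
            )
        y_new = c_hat * z_age + np.sqrt(lam2) * e
        for nm, b in b_paths.items():
            y_new = y_new + b * m_std[nm]
        cohort[outcome] = y_new

    truth.planted = {nm: (a, b, a * b) for nm, (a, b) in planted.items()}
    return RoiFeatureTable(data=data, hemispheres=hemis, modality=modality)


# ---------------------------------------------------------------------------
# BOLD phantom


def generate_phantom_bold(
    config: SyntheticConfig,
) -> tuple[Volume4D, Volume3D, AtlasVolume]:
    """A tiny 4D phantom with known spectral content per voxel block.

    The grid is split into three equal blocks along the first axis:
    an in-band sinusoid (0.05 Hz), an out-of-band sinusoid (0.20 Hz), and a
    unit-variance white-noise block, each riding on a constant baseline plus
    a configurable noise floor.  The mask covers all blocks; the atlas
    labels them as three ROIs with hemisphere tags.
    """
    shape = tuple(config.phantom_shape)
    if len(shape) != 3 or any(s < 3 for s in shape):
        raise ValueError("phantom_shape must have >= 3 voxels per axis")
    nyq = nyquist(config.phantom_tr)
    for f in (config.phantom_inband_freq, config.phantom_outband_freq):
        if f >= nyq:
            raise ValueError(
                f"sinusoid frequency {f} Hz is at or above Nyquist {nyq:.4g} Hz "
                f"for TR {config.phantom_tr}"
            )
    rng = stream_rng(config.seed, "phantom")
    nt = config.phantom_n_volumes
    t = np.arange(nt) * config.phantom_tr
    nx = shape[0]
    edges = [0, nx // 3, 2 * nx // 3, nx]

    data = np.full((*shape, nt), float(config.phantom_baseline))
    labels = np.zeros(shape, dtype=np.int32)
    freqs = {1: config.phantom_inband_freq, 2: config.phantom_outband_freq}
    for lab in (1, 2, 3):
        sl = slice(edges[lab - 1], edges[lab])
        labels[sl] = lab
        block_shape = labels[sl].shape
        nvox = int(np.prod(block_shape))
        if lab in freqs:
            phase = rng.uniform(0.0, 2.0 * np.pi, nvox)
            sig = np.sin(2.0 * np.pi * freqs[lab] * t[None, :] + phase[:, None])
        else:
            sig = rng.standard_normal((nvox, nt))
        data[sl] += sig.reshape(*block_shape, nt)
    if config.phantom_noise_sd > 0:
        data += rng.normal(0.0, config.phantom_noise_sd, data.shape)

    affine = _phantom_affine()
    bold = Volume4D(data, affine, tr=config.phantom_tr)
    mask = Volume3D((labels > 0).astype(np.int16), affine)
    atlas = AtlasVolume(
        labels,
        {1: ("inband_sine", "L"), 2: ("outband_sine", "R"), 3: ("white_noise", "L")},
        affine,
    )
    return bold, mask, atlas


def _phantom_affine() -> np.ndarray:
    return np.diag([3.0, 3.0, 3.0, 1.0])


# ---------------------------------------------------------------------------
# convenience: one call for a scored synthetic cohort


def generate_scored_cohort(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Cohort merged with its scored SPR summaries (exclusions applied).

    Convenience wrapper used by the pipeline demos and the reproduction
    script: generates the cohort and trials, scores them, applies the
    default 3-SD both-condition exclusion, and returns the merged table of
    retained participants together with the ground truth.
    """
    from .behavioral import apply_outlier_exclusion, score_trials

    cohort, truth = generate_cohort(config)
    trials = generate_trials(cohort, config)
    summaries = apply_outlier_exclusion(score_trials(trials))
    merged = cohort.merge(summaries, on="participant_id", validate="1:1")
    merged = merged.loc[~merged["excluded"]].reset_index(drop=True)
    return merged, truth
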