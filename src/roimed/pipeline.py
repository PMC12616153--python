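"""Orchestration of the four study analyses with per-group FDR.

1. **Age-correlation maps** — partial correlation of each ROI feature with
   age given nuisance covariates.
2. **ROI-wise mediation of sentence processing** — one bootstrap mediation
   per ROI with X = age, M = the ROI feature, Y = a behavioral outcome.
3. **SDS mediation with memory covariates** — the same machinery with
   working memory and/or short-term memory added as nuisance covariates.
4. **Mediation of memory itself** — Y = a memory score, covarying the other
   memory score.

Covariate policy: sex and education always; total intracranial volume (TIV)
in gray-matter-volume models only, never in pALFF models.  Indirect-effect
p-values are Benjamini-Hochberg adjusted separately within each
(hemisphere x modality) family.  Per-ROI bootstrap seeds derive from the
master seed and the ROI name, so the resamples of one ROI never depend on
which other ROIs are in the table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._seeds import child_seed
from .mediation import MediationSpec, bootstrap_mediation
from .roi_features import AtlasVolume, Volume3D
from .synthetic import LANGUAGE_ROI_BASENAMES, RoiFeatureTable

__all__ = [
    "AnalysisConfig",
    "DEFAULT_ROI_GROUPS",
    "default_roi_set",
    "bh_fdr",
    "age_correlation_map",
    "run_roi_mediation",
    "behavioral_mediation_suite",
    "write_stat_map",
]

#: The default language ROI specification: three groups of four subregions,
#: mirrored over both hemispheres (12 left + 12 right ROIs).
DEFAULT_ROI_GROUPS: dict[str, tuple[str, ...]] = {
    "frontal": ("IFGtri", "IFGoper", "IFGorb", "MFG"),
    "mid_anterior_temporal": ("MTG", "STG", "MTGpole", "STGpole"),
    "temporoparietal": ("pMTG", "pSTG", "SMG", "AG"),
}

BASE_COVARIATES = ("sex", "education")


def default_roi_set() -> list[tuple[str, str]]:
    """[(roi name, hemisphere)] for the 24 default language ROIs."""
    assert tuple(r for grp in DEFAULT_ROI_GROUPS.values() for r in grp) == LANGUAGE_ROI_BASENAMES
    return [
        (f"{h}_{r}", h)
        for grp in DEFAULT_ROI_GROUPS.values()
        for r in grp
        for h in ("L", "R")
    ]


@dataclass(frozen=True)
class AnalysisConfig:
    """One ROI-mediation analysis: outcome, modality, covariate policy."""

    outcome: str = "rt_sds"
    modality: str = "GMV"  # GMV => +TIV covariate; pALFF => no TIV
    memory_covariates: tuple[str, ...] = ()  # subset of ("nih_wm", "nih_stm")
    rois: tuple[str, ...] | None = None  # None = all ROIs of the feature table
    alpha: float = 0.05
    n_boot: int = 5000
    tails: str = "one"
    expected_sign_ab: int = -1
    robust: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.modality not in ("GMV", "pALFF"):
            raise ValueError("modality must be 'GMV' or 'pALFF'")
        bad = set(self.memory_covariates) - {"nih_wm", "nih_stm"}
        if bad:
            raise ValueError(f"unknown memory covariates: {sorted(bad)}")
        if self.outcome in self.memory_covariates:
            raise ValueError("outcome cannot also be a covariate")

    @property
    def covariates(self) -> tuple[str, ...]:
        tiv = ("tiv",) if self.modality == "GMV" else ()
        return (*BASE_COVARIATES, *tiv, *self.memory_covariates)


def bh_fdr(pvals: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def age_correlation_map(
    roi_table: RoiFeatureTable,
    cohort: pd.DataFrame,
    covariates: tuple[str, ...] = BASE_COVARIATES,
    tails: str = "two",
) -> pd.DataFrame:
    """Partial correlation of every ROI feature with age, given covariates.

    Residual-on-residual Pearson correlation; p from the t distribution on
    n - k - 2 degrees of freedom.  FDR-adjusted within hemisphere.
    One-tailed p-values test the negative direction (feature loss with age).
    """
    df = cohort.merge(
        roi_table.data, left_on="participant_id", right_index=True, validate="1:1"
    )
    rois = list(roi_table.data.columns)
    used = ["age", *covariates, *rois]
    df = df.loc[:, used].apply(pd.to_numeric).dropna()
    n, k = len(df), len(covariates)
    if n < k + 3:
        raise ValueError(f"need at least {k + 3} complete rows, got {n}")
    C = np.column_stack([np.ones(n), df[list(covariates)].to_numpy(dtype=float)])
    age = df["age"].to_numpy(dtype=float)
    M = df[rois].to_numpy(dtype=float)
    beta_age, *_ = np.linalg.lstsq(C, age, rcond=None)
    ra = age - C @ beta_age
    beta_m, *_ = np.linalg.lstsq(C, M, rcond=None)
    rm = M - C @ beta_m
    ra_n = ra / np.linalg.norm(ra)
    rm_n = rm / np.linalg.norm(rm, axis=0)
    r = rm_n.T @ ra_n
    dof = n - k - 2
    with np.errstate(divide="ignore"):
        tstat = r * np.sqrt(dof / np.clip(1.0 - r**2, 1e-300, None))
    if tails == "two":
        p = 2.0 * stats.t.sf(np.abs(tstat), dof)
    elif tails == "one":
        p = stats.t.cdf(tstat, dof)  # H1: negative association
    else:
        raise ValueError("tails must be 'one' or 'two'")
    out = pd.DataFrame(
        {
            "roi": rois,
            "hemisphere": [roi_table.hemispheres[roi] for roi in rois],
            "modality": roi_table.modality,
            "n_used": n,
            "partial_r": r,
            "p": p,
        }
    )
    out["p_fdr"] = _grouped_fdr(out, "p")
    return out


def _grouped_fdr(table: pd.DataFrame, p_col: str) -> np.ndarray:
    adj = np.empty(len(table))
    for _hemi, idx in table.groupby("hemisphere").groups.items():
        pos = table.index.get_indexer(idx)
        adj[pos] = bh_fdr(table.loc[idx, p_col].to_numpy())
    return adj


def run_roi_mediation(
    cohort: pd.DataFrame,
    roi_table: RoiFeatureTable,
    cfg: AnalysisConfig,
) -> pd.DataFrame:
    """One bootstrap mediation per ROI (X = age, M = ROI feature, Y = outcome).

    Returns one row per ROI with the five standardized paths, BC bootstrap
    p-values, the descriptive indirect-effect t statistic (bootstrap mean /
    bootstrap SD), and the indirect p FDR-adjusted within hemisphere.
    Participants are aligned by id with listwise deletion per ROI model.
    """
    rois = list(cfg.rois) if cfg.rois is not None else list(roi_table.data.columns)
    if len(rois) < 2:
        raise ValueError("need at least 2 ROIs")
    missing = [r for r in rois if r not in roi_table.data.columns]
    if missing:
        raise ValueError(f"ROI(s) missing from feature table: {missing}")
    if cfg.outcome not in cohort.columns:
        raise ValueError(f"outcome column {cfg.outcome!r} missing from cohort")
    df = cohort.merge(
        roi_table.data[rois], left_on="participant_id", right_index=True, validate="1:1"
    ).sort_values("participant_id", kind="stable")

    rows = []
    for roi in rois:
        spec = MediationSpec(
            x="age",
            m=roi,
            y=cfg.outcome,
            covariates=cfg.covariates,
            n_boot=cfg.n_boot,
            alpha=cfg.alpha,
            tails=cfg.tails,
            expected_sign_ab=cfg.expected_sign_ab,
            robust=cfg.robust,
            seed=child_seed(cfg.seed, roi),
        )
        res = bootstrap_mediation(df, spec)
        t_ind = res.boot_ab_mean / res.boot_ab_sd if res.boot_ab_sd > 0 else np.nan
        rows.append(
            {
                "roi": roi,
                "hemisphere": roi_table.hemispheres[roi],
                "modality": roi_table.modality,
                "outcome": cfg.outcome,
                "n_used": res.n_used,
                "beta_a": res.beta_a,
                "beta_b": res.beta_b,
                "beta_c": res.beta_c,
                "beta_c_prime": res.beta_c_prime,
                "beta_ab": res.beta_ab,
                "p_a": res.p_a,
                "p_b": res.p_b,
                "p_c": res.p_c,
                "p_c_prime": res.p_c_prime,
                "p_ab": res.p_ab,
                "t_indirect": t_ind,
                "n_boot_effective": res.n_boot_effective,
            }
        )
    table = pd.DataFrame(rows)
    table["p_ab_fdr"] = _grouped_fdr(table, "p_ab")
    table["significant"] = table["p_ab_fdr"] <= cfg.alpha
    return table


#: outcome -> a-priori direction of the indirect effect of age through memory
#: (age lowers memory; lower memory lowers accuracy but lengthens RT).
_EXPECTED_AB_SIGN = {
    "acc_overall": -1,
    "acc_sds": -1,
    "rt_overall": 1,
    "rt_sds": -1,
}


def behavioral_mediation_suite(
    cohort: pd.DataFrame,
    n_boot: int = 5000,
    seed: int = 0,
    robust: bool = False,
) -> pd.DataFrame:
    """The eight behavioral mediation models (memory mediating age effects).

    Mediator in {working memory, short-term memory} x outcome in
    {acc_overall, acc_sds, rt_overall, rt_sds}; sex and education as
    covariates; one-tailed BC bootstrap tests.  The cohort must be scored
    (and exclusions applied) beforehand.
    """
    rows = []
    for mediator in ("nih_wm", "nih_stm"):
        for outcome, sign in _EXPECTED_AB_SIGN.items():
            spec = MediationSpec(
                x="age",
                m=mediator,
                y=outcome,
                covariates=BASE_COVARIATES,
                n_boot=n_boot,
                tails="one",
                expected_sign_ab=sign,
                robust=robust,
                seed=child_seed(seed, f"{mediator}:{outcome}"),
            )
            res = bootstrap_mediation(cohort, spec)
            rows.append(
                {
                    "mediator": mediator,
                    "outcome": outcome,
                    "n_used": res.n_used,
                    "beta_a": res.beta_a,
                    "beta_b": res.beta_b,
                    "beta_c": res.beta_c,
                    "beta_c_prime": res.beta_c_prime,
                    "beta_ab": res.beta_ab,
                    "p_a": res.p_a,
                    "p_b": res.p_b,
                    "p_c": res.p_c,
                    "p_c_prime": res.p_c_prime,
                    "p_ab": res.p_ab,
                }
            )
    return pd.DataFrame(rows)


def write_stat_map(
    atlas: AtlasVolume, table: pd.DataFrame, stat: str = "t_indirect"
) -> Volume3D:
    """Paint each ROI's statistic into a volume (background 0).

    A NIfTI-writable substitute for surface renders of ROI results.
    """
    if stat not in table.columns:
        raise KeyError(f"unknown stat field {stat!r}; available: {list(table.columns)}")
    name_to_label = atlas.name_to_label
    missing = [r for r in table["roi"] if r not in name_to_label]
    if missing:
        raise ValueError(f"table ROI(s) not present in atlas: {missing}")
    out = np.zeros(atlas.data.shape, dtype=float)
    for _, row in table.iterrows():
        out[atlas.data == name_to_label[row["roi"]]] = float(row[stat])
    return Volume3D(out, np.asarray(atlas.affine).copy())
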