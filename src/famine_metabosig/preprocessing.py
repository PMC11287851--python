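"""NMR biomarker preprocessing.

Raw Nightingale-style concentrations are taken to analysis scale by a
fixed, order-enforced pipeline:

1. below-LOD values imputed to the observed per-biomarker minimum;
2. +1 shift for biomarkers containing exact zeroes;
3. natural log, then scaling to SD units (mean 0, SD 1, sample SD);
4. sample exclusions (non-fasted, then PCA outliers) with
   re-standardization of the retained samples.

State flags on :class:`BiomarkerMatrix` enforce the ordering: running a
step out of order raises.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BiomarkerMatrix",
    "impute_below_lod",
    "shift_zero_biomarkers",
    "log_scale",
    "exclude_samples",
    "derive_clinical",
    "friedewald_ldl",
    "validate_against_clinchem",
]

RAW = "raw"
LOG_SCALED = "log_scaled"


@dataclass
class BiomarkerMatrix:
    """Participants x biomarkers with a below-LOD mask and a state flag.

    ``values`` is indexed by participant ID with biomarker-named
    columns; ``below_lod`` is an aligned boolean mask.  ``state`` is
    ``"raw"`` (non-negative concentrations) or ``"log_scaled"``
    (unitless z-scores of the log concentrations).
    """

    values: pd.DataFrame
    below_lod: pd.DataFrame | None = None
    state: str = RAW

    def __post_init__(self) -> None:
        if self.below_lod is None:
            self.below_lod = pd.DataFrame(
                False, index=self.values.index, columns=self.values.columns
            )
        if not self.below_lod.index.equals(self.values.index) or not (
            self.below_lod.columns.equals(self.values.columns)
        ):
            raise ValueError("below_lod mask must align with values")
        if self.state not in (RAW, LOG_SCALED):
            raise ValueError(f"unknown state {self.state!r}")
        if self.state == RAW and (self.values.to_numpy() < 0).any():
            raise ValueError("raw concentrations must be non-negative")

    @property
    def biomarkers(self) -> list[str]:
        return list(self.values.columns)

    def copy(self) -> "BiomarkerMatrix":
        return BiomarkerMatrix(
            self.values.copy(), self.below_lod.copy(), self.state
        )

    def _require_state(self, state: str, op: str) -> None:
        if self.state != state:
            raise ValueError(
                f"{op} requires state={state!r}, matrix is {self.state!r}"
            )

    # -- TSV round trip (values file plus optional .lod mask file) ------
    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        self.values.to_csv(path, sep="\t", index_label="participant_id")
        if self.below_lod.to_numpy().any():
            self.below_lod.astype(int).to_csv(
                path.with_suffix(path.suffix + ".lod"),
                sep="\t",
                index_label="participant_id",
            )

    @classmethod
    def from_tsv(cls, path: str | Path, state: str = RAW) -> "BiomarkerMatrix":
        path = Path(path)
        values = pd.read_csv(path, sep="\t", index_col="participant_id")
        values.index = values.index.astype(str)
        lod_path = path.with_suffix(path.suffix + ".lod")
        mask = None
        if lod_path.exists():
            mask = (
                pd.read_csv(lod_path, sep="\t", index_col="participant_id")
                .astype(bool)
            )
            mask.index = mask.index.astype(str)
        return cls(values, mask, state)


def impute_below_lod(matrix: BiomarkerMatrix) -> BiomarkerMatrix:
    """Set below-LOD cells to the observed (non-LOD) minimum per biomarker.

    The mask is retained for audit.  A biomarker whose values are all
    below LOD has no observed minimum and raises.
    """
    matrix._require_state(RAW, "impute_below_lod")
    out = matrix.copy()
    mask = out.below_lod
    for col in out.values.columns:
        m = mask[col].to_numpy()
        if not m.any():
            continue
        if m.all():
            raise ValueError(f"biomarker {col!r} has all values below LOD")
        observed_min = out.values.loc[~m, col].min()
        out.values.loc[m, col] = observed_min
    return out


def shift_zero_biomarkers(matrix: BiomarkerMatrix) -> BiomarkerMatrix:
    """Add 1 to every value of each biomarker column containing a zero."""
    matrix._require_state(RAW, "shift_zero_biomarkers")
    out = matrix.copy()
    has_zero = (out.values == 0).any(axis=0)
    cols = has_zero[has_zero].index
    out.values[cols] = out.values[cols] + 1.0
    return out


def log_scale(matrix: BiomarkerMatrix) -> BiomarkerMatrix:
    """Natural log then z-score each biomarker (sample SD, n-1).

    Requires strictly positive values (i.e. the zero-shift step already
    applied).  A constant column has SD 0 and raises.
    """
    matrix._require_state(RAW, "log_scale")
    vals = matrix.values
    nonpos = (vals <= 0)
    if nonpos.to_numpy().any():
        col = nonpos.any(axis=0)
        bad = list(col[col].index)
        raise ValueError(
            f"non-positive values in {bad}; run shift_zero_biomarkers first"
        )
    logged = np.log(vals)
    sd = logged.std(axis=0, ddof=1)
    degenerate = sd[sd == 0].index
    if len(degenerate):
        raise ValueError(f"constant biomarker column(s): {list(degenerate)}")
    z = (logged - logged.mean(axis=0)) / sd
    return BiomarkerMatrix(z, matrix.below_lod.copy(), LOG_SCALED)


def _rescale(values: pd.DataFrame) -> pd.DataFrame:
    sd = values.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = list(sd[sd == 0].index)
        raise ValueError(f"constant biomarker column(s) after exclusion: {bad}")
    return (values - values.mean(axis=0)) / sd


def _pc_scores(values: pd.DataFrame, n_components: int = 2) -> np.ndarray:
    """Standardized scores on the leading principal components."""
    x = values.to_numpy()
    x = x - x.mean(axis=0)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    scores = u[:, :n_components] * s[:n_components]
    return scores / scores.std(axis=0, ddof=1)


def exclude_samples(
    cohort: pd.DataFrame,
    matrix: BiomarkerMatrix,
    fasting_required: bool = True,
    outlier_sd: float = 5.0,
    fasting_col: str = "fasted",
    id_col: str = "participant_id",
) -> tuple[pd.DataFrame, BiomarkerMatrix, pd.DataFrame]:
    """Drop non-fasted samples, then PCA outliers; re-standardize.

    A participant is a PCA outlier when its standardized score on PC1 or
    PC2 of the processed matrix exceeds ``outlier_sd`` in absolute
    value.  Returns the filtered cohort, the filtered re-standardized
    matrix, and an exclusion log (participant, step, reason).
    """
    matrix._require_state(LOG_SCALED, "exclude_samples")
    cohort = cohort.set_index(cohort[id_col].astype(str), drop=False)
    values = matrix.values
    if not cohort.index.equals(values.index):
        cohort = cohort.loc[values.index]
    log_rows: list[dict] = []

    keep = pd.Series(True, index=values.index)
    if fasting_required and fasting_col in cohort:
        nonfasted = cohort[fasting_col].astype(int) == 0
        for pid in cohort.index[nonfasted]:
            log_rows.append(
                {"participant_id": pid, "step": "fasting", "reason": "non-fasted"}
            )
        keep &= ~nonfasted

    values = values.loc[keep]
    mask = matrix.below_lod.loc[keep]
    values = _rescale(values)

    scores = _pc_scores(values)
    outlier = (np.abs(scores) > outlier_sd).any(axis=1)
    for pid, sc in zip(values.index[outlier], scores[outlier]):
        log_rows.append(
            {
                "participant_id": pid,
                "step": "pca_outlier",
                "reason": f"|PC score| > {outlier_sd} (PC1={sc[0]:.2f}, PC2={sc[1]:.2f})",
            }
        )
    values = values.loc[~outlier]
    mask = mask.loc[~outlier]
    if len(values) == 0:
        raise ValueError("all samples excluded")
    values = _rescale(values)

    cohort_out = cohort.loc[values.index].reset_index(drop=True)
    exclusion_log = pd.DataFrame(
        log_rows, columns=["participant_id", "step", "reason"]
    )
    return cohort_out, BiomarkerMatrix(values, mask, LOG_SCALED), exclusion_log


def friedewald_ldl(
    total_chol_mgdl: float, hdl_mgdl: float, triglycerides_mgdl: float
) -> float:
    """Friedewald LDL (mg/dl); NaN when triglycerides >= 400 mg/dl."""
    if triglycerides_mgdl >= 400:
        return float("nan")
    return total_chol_mgdl - hdl_mgdl - triglycerides_mgdl / 5.0


def derive_clinical(cohort: pd.DataFrame) -> pd.DataFrame:
    """Derive BMI, type-2-diabetes status and (optionally) Friedewald LDL.

    BMI = weight (kg) / height (m)^2.  T2D is positive on reported
    history OR fasting glucose >= 7.0 mmol/l OR 2-h OGTT glucose >= 11.1
    mmol/l (inclusive thresholds); it is missing when all three inputs
    are missing.  LDL is derived only when the lipid panel (mg/dl) is
    present and triglycerides < 400 mg/dl.
    """
    out = pd.DataFrame(index=cohort.index)
    if "weight_kg" in cohort and "height_m" in cohort:
        h = cohort["height_m"].astype(float)
        if (h <= 0).any():
            raise ValueError("non-positive height")
        out["bmi"] = cohort["weight_kg"].astype(float) / h**2
    elif "bmi" in cohort:
        out["bmi"] = cohort["bmi"].astype(float)
    else:
        raise ValueError("need weight_kg/height_m or bmi")

    history = cohort.get("t2d_history")
    fasting = cohort.get("fasting_glucose")
    ogtt = cohort.get("ogtt_2h_glucose")
    parts = []
    if history is not None:
        parts.append(history.astype(float) > 0)
    if fasting is not None:
        parts.append(fasting.astype(float) >= 7.0)
    if ogtt is not None:
        parts.append(ogtt.astype(float) >= 11.1)
    if not parts:
        raise ValueError(
            "T2D needs at least one of t2d_history/fasting_glucose/ogtt_2h_glucose"
        )
    t2d = parts[0].fillna(False)
    for p in parts[1:]:
        t2d = t2d | p.fillna(False)
    all_missing = pd.concat(
        [p.isna() if hasattr(p, "isna") else pd.Series(False, index=cohort.index)
         for p in (history, fasting, ogtt) if p is not None],
        axis=1,
    ).all(axis=1)
    out["t2d"] = t2d.astype(float).where(~all_missing)

    lipid_cols = ("total_chol_mgdl", "hdl_mgdl", "triglycerides_mgdl")
    if all(c in cohort for c in lipid_cols):
        out["ldl_friedewald_mgdl"] = [
            friedewald_ldl(tc, hdl, tg)
            for tc, hdl, tg in cohort[list(lipid_cols)].itertuples(index=False)
        ]
    return out


def validate_against_clinchem(
    nmr: pd.DataFrame, clinchem: pd.DataFrame, r_floor: float = 0.9
) -> pd.DataFrame:
    """Pearson r between NMR and clinical-chemistry duplicate measures.

    Columns are matched by name; rows by shared index.  Returns one row
    per biomarker with r, the two-sided p, n, and a pass flag at
    ``r_floor``.
    """
    shared_cols = [c for c in nmr.columns if c in clinchem.columns]
    rows = []
    for col in shared_cols:
        pair = pd.concat(
            [nmr[col], clinchem[col]], axis=1, join="inner", keys=["nmr", "cc"]
        ).dropna()
        if len(pair) < 3:
            raise ValueError(f"fewer than 3 matched pairs for {col!r}")
        if pair["nmr"].std() == 0 or pair["cc"].std() == 0:
            raise ValueError(f"zero-variance column for {col!r}")
        r, p = stats.pearsonr(pair["nmr"], pair["cc"])
        rows.append(
            {"biomarker": col, "r": r, "p": p, "n": len(pair), "pass": r >= r_floor}
        )
    return pd.DataFrame(rows)
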