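"""Synthetic cohort, biomarker, polygenic-score and disease-atlas generator.

Emulates the statistical structure the famine-metabolomics analysis
assumes, so every downstream stage is testable without access to the
original cohort:

* a sibship-structured cohort of famine-exposed participants (LMP dates
  inside the published exposure windows) and unexposed controls (born
  1943 or 1947), a fraction of whom are same-sex siblings of exposed
  participants;
* a block-correlated biomarker panel whose leading principal components
  are calibrated so that ~14 PCs explain 95% of variance, with
  exposure effects in SD units partially mediated through a simulated
  BMI variable, within-sibship residual correlation, below-LOD flags
  and zero-valued trace biomarkers;
* per-biomarker polygenic scores with a configured R^2, residualized on
  ten simulated genetic principal components;
* a disease atlas whose signatures load on a shared axis (the expected
  famine signature), with case counts and per-biomarker p-values
  spanning both sides of the atlas filters.

``true_effects`` are *total* exposure effects in SD units of the
standardized log biomarker — the scale on which the MWAS reports — and
the raw-scale shift is pre-compensated so that the configured value is
recovered in expectation by an unbiased estimator.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .preprocessing import RAW, BiomarkerMatrix
from .signatures import DiseaseAtlas, Signature

__all__ = [
    "SimConfig",
    "SyntheticStudy",
    "biomarker_names",
    "generate_cohort",
    "generate_biomarkers",
    "generate_pgs",
    "generate_atlas",
    "generate_study",
]

#: Named analogs occupying the first covariance block; the remaining
#: panel is filled with generic ``bm_###`` names.
NAMED_ANALOGS = (
    "tyrosine", "leucine", "isoleucine", "valine", "phenylalanine",
    "glucose", "lactate", "citrate", "total_cholesterol",
    "ldl_cholesterol", "hdl_cholesterol", "triglycerides",
)

#: Reported famine associations used as default simulation truth
#: (total effects, SD units of the standardized log biomarker).
DEFAULT_TRUE_EFFECTS = {
    "tyrosine": 0.28,
    "leucine": 0.21,
    "glucose": 0.23,
    "isoleucine": 0.18,
    "phenylalanine": 0.12,
    "valine": 0.12,
}

_EXPOSED_LMP_RANGE = (date(1944, 4, 30), date(1945, 5, 12))


@dataclass
class SimConfig:
    """Simulation design; defaults are the study's stated quantities."""

    n_exposed: int = 480
    n_control: int = 464
    sibship_fraction: float = 0.5
    n_biomarkers: int = 168
    block_structure: list[tuple[int, float]] = field(
        default_factory=lambda: [(12, 0.97)] * 14
    )
    between_block_corr: float = 0.0
    target_pc95: int = 14
    true_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRUE_EFFECTS)
    )
    bmi_mediation: float = 0.3
    sibship_icc: float = 0.3
    pgs_r2: float = 0.03
    pgs_targets: tuple[str, ...] = ("tyrosine", "leucine", "glucose")
    n_genetic_pcs: int = 10
    n_diseases: int = 190
    shared_axis_loading_range: tuple[float, float] = (0.3, 0.9)
    frac_negative_loading: float = 0.1
    frac_null_diseases: float = 0.08
    frac_small_diseases: float = 0.10
    atlas_se_scale: float = 10.0
    lod_fraction: float = 0.02
    n_lod_biomarkers: int = 10
    n_zero_biomarkers: int = 2
    n_nonfasted: int = 0
    n_outliers: int = 0
    outlier_magnitude: float = 10.0
    bmi_exposure_effect: float = 0.27
    bmi_axis_sd: float = 0.10
    bmi_mean: float = 27.0
    bmi_sd: float = 4.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "sibship_fraction", "bmi_mediation", "sibship_icc",
            "frac_negative_loading", "frac_null_diseases",
            "frac_small_diseases", "lod_fraction",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.n_biomarkers < 1:
            raise ValueError("n_biomarkers must be >= 1")
        self.block_structure = [tuple(b) for b in self.block_structure]
        if sum(b[0] for b in self.block_structure) != self.n_biomarkers:
            raise ValueError("block sizes must sum to n_biomarkers")
        if not 0 <= self.pgs_r2 < 1:
            raise ValueError("pgs_r2 must be in [0, 1)")
        if self.n_exposed < 0 or self.n_control < 0:
            raise ValueError("cohort sizes must be non-negative")

    # -- serialization -------------------------------------------------
    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        data = asdict(self)
        data["block_structure"] = [list(b) for b in self.block_structure]
        data["pgs_targets"] = list(self.pgs_targets)
        data["shared_axis_loading_range"] = list(self.shared_axis_loading_range)
        if path.suffix == ".json":
            path.write_text(json.dumps(data, indent=2))
        else:
            path.write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_file(cls, path: str | Path) -> "SimConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        data["pgs_targets"] = tuple(data.get("pgs_targets", cls.pgs_targets))
        data["shared_axis_loading_range"] = tuple(
            data.get("shared_axis_loading_range", cls.shared_axis_loading_range)
        )
        return cls(**data)


@dataclass
class SyntheticStudy:
    """A fully realized simulated study plus the truth that generated it."""

    cohort: pd.DataFrame
    biomarkers: BiomarkerMatrix
    truth: dict
    atlas: DiseaseAtlas
    pgs: pd.DataFrame
    genetic_pcs: pd.DataFrame


def biomarker_names(n: int) -> list[str]:
    names = list(NAMED_ANALOGS[:n])
    names += [f"bm_{i:03d}" for i in range(len(names) + 1, n + 1)]
    return names


def _rng_streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(4)
    keys = ("cohort", "biomarkers", "atlas", "pgs")
    return {k: np.random.default_rng(c) for k, c in zip(keys, children)}


def generate_cohort(
    config: SimConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Simulate the participant table.

    Exposed participants get LMP dates inside the published exposure
    windows; controls are 1943/1947 births whose LMPs classify to zero
    windows.  Sibling controls share sibship ID and sex with an exposed
    participant.
    """
    rng = rng or _rng_streams(config.seed)["cohort"]
    n_exp, n_ctl = config.n_exposed, config.n_control
    n_sib = int(round(config.sibship_fraction * n_ctl))
    if n_sib > n_exp:
        raise ValueError(
            f"sibship_fraction requires {n_sib} sibling pairs but only "
            f"{n_exp} exposed participants exist"
        )
    n = n_exp + n_ctl
    exposed = np.concatenate([np.ones(n_exp, int), np.zeros(n_ctl, int)])

    sibship = [f"S{i:04d}" for i in range(n_exp)]
    sibship += [f"S{j:04d}" for j in range(n_sib)]  # sibling controls
    sibship += [f"S{n_exp + k:04d}" for k in range(n_ctl - n_sib)]

    sex = rng.binomial(1, 0.45, n)
    sex[n_exp : n_exp + n_sib] = sex[:n_sib]  # same-sex siblings

    # LMP / birth dates
    gestation = np.clip(np.round(rng.normal(280, 10, n)), 259, 293).astype(int)
    lmp = np.empty(n, dtype=object)
    lo, hi = _EXPOSED_LMP_RANGE
    span = (hi - lo).days
    for i in range(n_exp):
        lmp[i] = lo + timedelta(days=int(rng.integers(0, span + 1)))
    for i in range(n_exp, n):
        year = 1943 if rng.random() < 0.5 else 1947
        birth = date(year, 1, 1) + timedelta(days=int(rng.integers(0, 365)))
        lmp[i] = birth - timedelta(days=int(gestation[i]))
    birth_date = [l + timedelta(days=int(g)) for l, g in zip(lmp, gestation)]

    age = np.where(
        exposed == 1, rng.normal(58.8, 0.5, n), rng.normal(57.9, 5.4, n)
    )
    age = np.clip(age, 40, 80)
    medication = rng.binomial(1, 0.123, n)

    fasted = np.ones(n, int)
    if config.n_nonfasted:
        if config.n_nonfasted > n:
            raise ValueError("n_nonfasted exceeds cohort size")
        idx = rng.choice(n, config.n_nonfasted, replace=False)
        fasted[idx] = 0

    # BMI: shared axis linking exposure and the biomarker panel
    bmi_z = config.bmi_exposure_effect * exposed + rng.normal(0, 1, n)
    bmi = config.bmi_mean + config.bmi_sd * bmi_z
    waist = 88.0 + 10.0 * bmi_z + rng.normal(0, 4, n)
    height = np.where(
        sex == 1, rng.normal(1.77, 0.07, n), rng.normal(1.64, 0.06, n)
    )
    weight = bmi * height**2

    high_gluc = rng.binomial(1, 0.06, n)
    fasting_glucose = (
        5.3 + 0.55 * (0.4 * bmi_z + rng.normal(0, 1, n)) + 2.2 * high_gluc
    )
    ogtt = 6.0 + 1.4 * (0.3 * bmi_z + rng.normal(0, 1, n)) + 3.5 * high_gluc
    t2d_history = rng.binomial(1, 0.03, n)
    t2d = (
        (t2d_history == 1) | (fasting_glucose >= 7.0) | (ogtt >= 11.1)
    ).astype(int)

    return pd.DataFrame(
        {
            "participant_id": [f"P{i:04d}" for i in range(n)],
            "sibship_id": sibship,
            "lmp_date": [d.isoformat() for d in lmp],
            "birth_date": [d.isoformat() for d in birth_date],
            "age": np.round(age, 2),
            "sex": sex,
            "medication": medication,
            "bmi": np.round(bmi, 3),
            "waist": np.round(waist, 2),
            "height_m": np.round(height, 3),
            "weight_kg": np.round(weight, 2),
            "fasting_glucose": np.round(fasting_glucose, 3),
            "ogtt_2h_glucose": np.round(ogtt, 3),
            "t2d_history": t2d_history,
            "t2d": t2d,
            "fasted": fasted,
            "exposed": exposed,
        }
    )


def _block_covariance(config: SimConfig) -> np.ndarray:
    p = config.n_biomarkers
    sigma = np.full((p, p), config.between_block_corr)
    start = 0
    for bi, (size, rho) in enumerate(config.block_structure):
        if size > 1 and not -1.0 / (size - 1) < rho <= 1.0:
            raise ValueError(
                f"block {bi} (size {size}, rho {rho}) is not positive definite"
            )
        blk = np.full((size, size), rho)
        np.fill_diagonal(blk, 1.0)
        sigma[start : start + size, start : start + size] = blk
        start += size
    try:
        np.linalg.cholesky(sigma + 1e-12 * np.eye(p))
    except np.linalg.LinAlgError:
        raise ValueError(
            "implied covariance is not positive definite "
            f"(between_block_corr={config.between_block_corr})"
        )
    return sigma


def generate_biomarkers(
    cohort: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[BiomarkerMatrix, dict]:
    """Simulate the raw concentration matrix for a generated cohort.

    The latent log-scale value for participant i and biomarker b is

        y_ib = a_b z_i + delta_raw_b E_i + s_b (sqrt(icc) u_{sib(i),b}
                                                + sqrt(1-icc) e_ib)

    where z is the non-exposure component of standardized BMI, a_b
    combines a background BMI-axis loading with the mediated share of
    the exposure effect, u/e carry the block covariance, and
    s_b = sqrt(1 - a_b^2) keeps unit conditional variance.
    Concentrations are exp(mu_b + tau_b y_ib) so the preprocessing log
    step is exercised; trace biomarkers receive zeros and below-LOD
    flags in their lowest quantile.
    """
    rng = rng or _rng_streams(config.seed)["biomarkers"]
    names = biomarker_names(config.n_biomarkers)
    unknown = set(config.true_effects) - set(names)
    if unknown:
        raise ValueError(f"true_effects name unknown biomarkers: {sorted(unknown)}")
    n = len(cohort)
    p = config.n_biomarkers
    exposed = cohort["exposed"].to_numpy(float)
    frac_exp = exposed.mean() if n else 0.0

    delta = np.array([config.true_effects.get(b, 0.0) for b in names])
    comp = 1.0 - delta**2 * frac_exp * (1 - frac_exp)
    if (comp <= 0).any():
        raise ValueError("true effect too large to compensate")
    delta_raw = delta / np.sqrt(comp)

    w = rng.normal(0.0, config.bmi_axis_sd, p)
    mediated = np.zeros(p)
    if config.bmi_mediation > 0 and (delta != 0).any():
        if config.bmi_exposure_effect == 0:
            raise ValueError("bmi_mediation > 0 requires bmi_exposure_effect != 0")
        mediated = config.bmi_mediation * delta_raw / config.bmi_exposure_effect
    a = w + mediated
    if (a**2 >= 1).any():
        bad = [names[i] for i in np.where(a**2 >= 1)[0]]
        raise ValueError(f"BMI-axis loading >= 1 for {bad}; lower bmi_axis_sd "
                         "or bmi_mediation")
    s = np.sqrt(1.0 - a**2)

    z = (
        (cohort["bmi"].to_numpy(float) - config.bmi_mean) / config.bmi_sd
        - config.bmi_exposure_effect * exposed
    )

    sigma = _block_covariance(config)
    chol = np.linalg.cholesky(sigma + 1e-12 * np.eye(p))
    sib_codes, sib_idx = np.unique(cohort["sibship_id"], return_inverse=True)
    u = rng.standard_normal((len(sib_codes), p)) @ chol.T
    e = rng.standard_normal((n, p)) @ chol.T
    icc = config.sibship_icc
    resid = np.sqrt(icc) * u[sib_idx] + np.sqrt(1 - icc) * e

    y = a * z[:, None] + delta_raw * exposed[:, None] + s * resid

    outlier_ids: list[str] = []
    if config.n_outliers:
        fasted_idx = np.where(cohort["fasted"].to_numpy(int) == 1)[0]
        chosen = rng.choice(fasted_idx, config.n_outliers, replace=False)
        # a global panel-wide shift (sample-level technical artifact):
        # a displacement confined to one block would spread across the
        # degenerate top eigenspace and stay invisible on PC1/PC2
        y[chosen, :] += config.outlier_magnitude
        outlier_ids = cohort["participant_id"].iloc[chosen].tolist()

    mu = rng.uniform(np.log(0.05), np.log(3.0), p)
    tau = rng.uniform(0.2, 0.8, p)
    conc = np.exp(mu + tau * y)

    # trace biomarkers: zeros (below limit of quantification) and LOD flags
    n_zero = min(config.n_zero_biomarkers, p)
    n_lod = min(config.n_lod_biomarkers, p - n_zero)
    zero_cols = list(range(p - n_zero, p))
    lod_cols = list(range(p - n_zero - n_lod, p - n_zero))
    k = max(1, int(round(config.lod_fraction * n))) if n else 0
    below_lod = np.zeros((n, p), bool)
    if k and config.lod_fraction > 0:
        for j in zero_cols:
            cut = np.partition(conc[:, j], k - 1)[k - 1]
            conc[conc[:, j] <= cut, j] = 0.0
        for j in lod_cols:
            order = np.argsort(conc[:, j], kind="stable")[:k]
            below_lod[order, j] = True

    index = pd.Index(cohort["participant_id"].astype(str), name="participant_id")
    matrix = BiomarkerMatrix(
        pd.DataFrame(conc, index=index, columns=names),
        pd.DataFrame(below_lod, index=index, columns=names),
        RAW,
    )
    truth = {
        "names": names,
        "expected_effects": pd.Series(delta, index=names),
        "delta_raw": pd.Series(delta_raw, index=names),
        "bmi_axis": pd.Series(a, index=names),
        "background_axis": pd.Series(w, index=names),
        "expected_adjusted_effects": pd.Series(
            (1 - config.bmi_mediation) * delta_raw
            - config.bmi_exposure_effect * w,
            index=names,
        ),
        "mu": pd.Series(mu, index=names),
        "tau": pd.Series(tau, index=names),
        "outlier_ids": outlier_ids,
        "lod_biomarkers": [names[j] for j in lod_cols],
        "zero_biomarkers": [names[j] for j in zero_cols],
    }
    return matrix, truth


def generate_pgs(
    cohort: pd.DataFrame,
    biomarkers: BiomarkerMatrix,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Polygenic scores with configured R^2, residualized on genetic PCs.

    For each target biomarker, score = sqrt(R2) * z(log concentration)
    + sqrt(1 - R2) * noise, then residualized on ``n_genetic_pcs``
    simulated principal components and scaled to mean 0, SD 1.
    """
    rng = rng or _rng_streams(config.seed)["pgs"]
    n = len(cohort)
    index = biomarkers.values.index
    pcs = pd.DataFrame(
        rng.standard_normal((n, config.n_genetic_pcs)),
        index=index,
        columns=[f"genetic_pc{i + 1}" for i in range(config.n_genetic_pcs)],
    )
    scores = {}
    r2 = config.pgs_r2
    for target in config.pgs_targets:
        if target not in biomarkers.values.columns:
            continue
        vals = biomarkers.values[target].to_numpy(float)
        if biomarkers.state == RAW:
            vals = np.log(np.where(vals <= 0, np.nan, vals))
        yz = (vals - np.nanmean(vals)) / np.nanstd(vals, ddof=1)
        raw = np.sqrt(r2) * yz + np.sqrt(1 - r2) * rng.standard_normal(n)
        # residualize on [intercept, PCs] so the scaled score stays
        # exactly orthogonal to every PC column
        x = np.column_stack([np.ones(n), pcs.to_numpy()])
        coef, *_ = np.linalg.lstsq(x, raw, rcond=None)
        resid = raw - x @ coef
        scores[target] = (resid - resid.mean()) / resid.std(ddof=1)
    return pd.DataFrame(scores, index=index), pcs


def generate_atlas(
    config: SimConfig,
    shared_axis: pd.Series,
    rng: np.random.Generator | None = None,
    loadings: np.ndarray | None = None,
    noise_scale: float = 1.0,
) -> DiseaseAtlas:
    """Disease-signature atlas loading on a shared biomarker axis.

    Each non-null disease signature is tau_d * (L_d * g + sqrt(1-L_d^2)
    * noise) with g the standardized shared axis, so its correlation
    with the axis is approximately L_d.  Null diseases are pure
    estimation noise.  Case counts and standard-error-based p-values
    are drawn so both sides of the >=1000-case and p < 5e-4 atlas
    filters occur.
    """
    rng = rng or _rng_streams(config.seed)["atlas"]
    if config.n_diseases == 0:
        return DiseaseAtlas({}, {}, {})
    axis = shared_axis.astype(float)
    if len(axis) != config.n_biomarkers:
        raise ValueError("shared_axis length must equal n_biomarkers")
    sd = axis.std(ddof=1)
    # a flat axis (e.g. a null truth) leaves diseases as pure noise
    g = (axis - axis.mean()) / sd if sd > 0 else axis * 0.0
    lo, hi = config.shared_axis_loading_range

    sigs, cases, dnames = {}, {}, {}
    for d in range(config.n_diseases):
        code = f"D{d + 1:03d}"
        is_null = rng.random() < config.frac_null_diseases
        is_small = rng.random() < config.frac_small_diseases
        if loadings is not None:
            load = float(loadings[d])
            is_null = False
        else:
            load = float(rng.uniform(lo, hi))
            if rng.random() < config.frac_negative_loading:
                load = -load
        n_cases = int(
            rng.integers(100, 1000) if is_small else rng.integers(1000, 60000)
        )
        tau = float(rng.uniform(0.05, 0.25))
        eps = rng.standard_normal(config.n_biomarkers) * noise_scale
        se = tau * config.atlas_se_scale / np.sqrt(n_cases)
        if is_null:
            beta = se * eps
        else:
            beta = tau * (load * g.to_numpy() + np.sqrt(1 - load**2) * eps)
        z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
        pvals = 2 * stats.norm.sf(np.abs(z))
        sigs[code] = Signature(
            code,
            pd.Series(beta, index=axis.index),
            pd.Series(pvals, index=axis.index),
        )
        cases[code] = n_cases
        dnames[code] = f"disease_{d + 1:03d}"
    return DiseaseAtlas(sigs, cases, dnames)


def generate_study(config: SimConfig) -> SyntheticStudy:
    """Generate a full synthetic study from one master seed.

    One RNG stream per component (cohort, biomarkers, atlas, pgs) is
    derived from the master seed, so adding diseases does not perturb
    the cohort draw.  The atlas loads on the expected famine signature
    (the total-effect vector).
    """
    streams = _rng_streams(config.seed)
    cohort = generate_cohort(config, streams["cohort"])
    biomarkers, truth = generate_biomarkers(cohort, config, streams["biomarkers"])
    atlas = generate_atlas(
        config, truth["expected_effects"], streams["atlas"]
    )
    pgs, genetic_pcs = generate_pgs(cohort, biomarkers, config, streams["pgs"])
    truth["config"] = config
    return SyntheticStudy(cohort, biomarkers, truth, atlas, pgs, genetic_pcs)
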