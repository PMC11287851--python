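"""End-to-end orchestration: simulate -> classify -> preprocess -> MWAS
-> signature comparison, with a reproducible JSON run manifest."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exposure import classify_cohort
from .mwas import (
    bonferroni_threshold,
    effective_tests,
    run_mwas,
    sensitivity_suite,
)
from .preprocessing import (
    BiomarkerMatrix,
    exclude_samples,
    impute_below_lod,
    log_scale,
    shift_zero_biomarkers,
)
from .signatures import (
    DiseaseAtlas,
    Signature,
    attenuation,
    correlate_all,
    filter_atlas,
    order_heatmap,
)
from .synthetic import SimConfig, generate_study

__all__ = ["RunConfig", "run_all", "preprocess_matrix"]


@dataclass
class RunConfig:
    """Inputs, thresholds and output location for one full run.

    Exactly one of ``sim`` (synthetic mode) or the three real-input
    paths must be set.
    """

    out_dir: str = "results"
    sim: SimConfig | None = None
    cohort_path: str | None = None
    biomarkers_path: str | None = None
    atlas_path: str | None = None
    alpha: float = 0.05
    variance_threshold: float = 0.95
    min_cases: int = 1000
    sig_p: float = 5e-4
    outlier_sd: float = 5.0
    nominal_p: float = 0.05
    top_k: int = 30
    seed: int | None = None
    include_periconception: bool = True

    def __post_init__(self) -> None:
        synthetic = self.sim is not None
        real = self.cohort_path is not None
        if synthetic == real:
            raise ValueError("set exactly one of sim / real input paths")
        if real and (self.biomarkers_path is None or self.atlas_path is None):
            raise ValueError("real mode needs cohort, biomarkers and atlas paths")
        if real:
            for p in (self.cohort_path, self.biomarkers_path, self.atlas_path):
                if not Path(p).exists():
                    raise FileNotFoundError(p)
        for name, lo, hi in (
            ("alpha", 0, 1), ("variance_threshold", 0, 1),
            ("sig_p", 0, 1), ("nominal_p", 0, 1),
        ):
            v = getattr(self, name)
            if not lo < v <= hi:
                raise ValueError(f"{name} out of range: {v}")
        if self.seed is not None and self.sim is not None:
            self.sim.seed = self.seed

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        sim = data.pop("sim", None)
        if sim is not None:
            sim = SimConfig(**sim)
        return cls(sim=sim, **data)

    def config_hash(self) -> str:
        data = asdict(self)
        blob = json.dumps(data, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def preprocess_matrix(
    cohort: pd.DataFrame,
    matrix: BiomarkerMatrix,
    outlier_sd: float = 5.0,
) -> tuple[pd.DataFrame, BiomarkerMatrix, pd.DataFrame]:
    """LOD-impute -> zero-shift -> log/scale -> exclusions, in order."""
    m = impute_below_lod(matrix)
    m = shift_zero_biomarkers(m)
    m = log_scale(m)
    return exclude_samples(cohort, m, outlier_sd=outlier_sd)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline and write outputs plus a manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.sim.seed if config.sim else config.seed,
        "version": __version__,
        "stages": {},
        "files": {},
    }

    def _write(df: pd.DataFrame, name: str, index: bool = False) -> None:
        path = out / name
        df.to_csv(path, sep="\t", index=index, float_format="%.10g")
        manifest["files"][name] = _checksum(path)

    stage = "simulate"
    try:
        if config.sim is not None:
            study = generate_study(config.sim)
            cohort, matrix, atlas = study.cohort, study.biomarkers, study.atlas
            _write(cohort, "cohort.tsv")
            matrix.to_tsv(out / "biomarkers_raw.tsv")
            manifest["files"]["biomarkers_raw.tsv"] = _checksum(
                out / "biomarkers_raw.tsv"
            )
            atlas.to_long_tsv(out / "atlas.tsv")
            manifest["files"]["atlas.tsv"] = _checksum(out / "atlas.tsv")
        else:
            cohort = pd.read_csv(config.cohort_path, sep="\t")
            matrix = BiomarkerMatrix.from_tsv(config.biomarkers_path)
            atlas = DiseaseAtlas.from_long_tsv(config.atlas_path)
        manifest["stages"][stage] = {"n_participants": len(cohort)}

        stage = "classify_exposure"
        cohort = classify_cohort(
            cohort, include_periconception=config.include_periconception
        )
        manifest["stages"][stage] = {
            "n_any_exposure": int(cohort["any_exposure"].sum())
        }

        stage = "preprocess"
        cohort, matrix, excl_log = preprocess_matrix(
            cohort, matrix, config.outlier_sd
        )
        _write(excl_log, "exclusions.tsv")
        _write(cohort, "cohort_analysis.tsv")
        matrix.values.to_csv(
            out / "biomarkers_processed.tsv", sep="\t",
            index_label="participant_id", float_format="%.10g",
        )
        manifest["files"]["biomarkers_processed.tsv"] = _checksum(
            out / "biomarkers_processed.tsv"
        )
        manifest["stages"][stage] = {
            "n_analysis": len(cohort),
            "n_excluded": len(excl_log),
        }

        stage = "mwas"
        m_eff = effective_tests(matrix, config.variance_threshold)
        threshold = bonferroni_threshold(config.alpha, m_eff)
        main = run_mwas(matrix, cohort, alpha=config.alpha, m_eff=m_eff)
        _write(main, "mwas_main.tsv")
        volcano = main[["biomarker", "beta"]].copy()
        volcano["neg_log10_p"] = -np.log10(main["p"])
        _write(volcano, "volcano_source.tsv")
        hits = main.loc[main["significant"], "biomarker"].tolist()
        targets = hits or main.nsmallest(3, "p")["biomarker"].tolist()
        sens = sensitivity_suite(
            matrix, cohort, targets, m_eff=m_eff, alpha=config.alpha
        )
        _write(sens, "mwas_sensitivity.tsv")
        bmi_adjusted = run_mwas(
            matrix, cohort,
            covariates=("age", "sex", "medication", "bmi"),
            alpha=config.alpha, m_eff=m_eff, model_tag="bmi",
        )
        _write(bmi_adjusted, "mwas_bmi_adjusted.tsv")
        manifest["stages"][stage] = {
            "m_eff": m_eff,
            "bonferroni_threshold": threshold,
            "n_significant": len(hits),
            "significant_biomarkers": hits,
        }

        stage = "signatures"
        famine_sig = Signature.from_mwas(main, "famine_main")
        famine_adj = Signature.from_mwas(bmi_adjusted, "famine_bmi_adjusted")
        filtered = filter_atlas(atlas, config.min_cases, config.sig_p)
        comp_main = correlate_all(famine_sig, filtered, config.alpha)
        comp_adj = correlate_all(famine_adj, filtered, config.alpha)
        att, att_summary = attenuation(comp_main, comp_adj)
        comp = comp_main.merge(
            att[["disease", "r_adjusted", "attenuation_pct"]], on="disease"
        )
        _write(comp, "signature_comparisons.tsv")
        summary = {
            "n_diseases_tested": len(filtered),
            "n_significant_positive": comp_main.attrs["n_significant_positive"],
            "n_significant_negative": comp_main.attrs["n_significant_negative"],
            **att_summary,
        }
        (out / "signature_summary.json").write_text(json.dumps(summary, indent=2))
        manifest["files"]["signature_summary.json"] = _checksum(
            out / "signature_summary.json"
        )
        try:
            heat = order_heatmap(
                comp_main, famine_sig, filtered, config.top_k, config.nominal_p
            )
            _write(heat, "heatmap_source.tsv", index=True)
        except ValueError:
            pass  # no nominally significant biomarkers at desk scale
        manifest["stages"][stage] = summary
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
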