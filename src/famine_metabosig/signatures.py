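"""Effect-size signature comparison against a disease atlas.

A *signature* is a named vector of per-biomarker effect sizes for one
contrast (famine exposure, or an incident disease).  Signatures are
compared by Pearson correlation over their harmonized shared biomarker
panel; the atlas is first filtered to common diseases (case count and
minimum association p), multiple testing is Bonferroni over the
diseases tested, and covariate-adjustment attenuation is the percent
change in correlation strength |r|.
"""

from __future__ import annotations

import functools
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = [
    "Signature",
    "DiseaseAtlas",
    "harmonize",
    "filter_atlas",
    "correlate_signatures",
    "correlate_all",
    "attenuation",
    "order_heatmap",
]


@functools.lru_cache(maxsize=65536)
def _normalize_key(name: str) -> str:
    key = re.sub(r"[\s\-_./]+", " ", str(name).casefold()).strip()
    return re.sub(r"[^\w ]", "", key)


def _normalize_name(name: str, synonyms: dict[str, str] | None = None) -> str:
    key = _normalize_key(name)
    if synonyms:
        norm_syn = {_normalize_key(k): v for k, v in synonyms.items()}
        key = norm_syn.get(key, key)
    return key


@dataclass
class Signature:
    """Named per-biomarker effect-size vector (per-SD scale)."""

    label: str
    effects: pd.Series  # index: biomarker names
    pvalues: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.effects.index.has_duplicates:
            raise ValueError(f"duplicate biomarker names in {self.label!r}")

    def __len__(self) -> int:
        return len(self.effects)

    @classmethod
    def from_mwas(cls, mwas_table: pd.DataFrame, label: str) -> "Signature":
        t = mwas_table.dropna(subset=["beta"]).set_index("biomarker")
        return cls(label, t["beta"], t["p"] if "p" in t else None)


@dataclass
class DiseaseAtlas:
    """Collection of disease signatures with case counts.

    ``signatures`` maps a disease code (ICD-10-style opaque string) to
    its :class:`Signature`; ``n_cases`` maps codes to case counts.
    """

    signatures: dict[str, Signature]
    n_cases: dict[str, int]
    disease_names: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.signatures)

    def min_p(self, code: str) -> float:
        sig = self.signatures[code]
        if sig.pvalues is None or len(sig.pvalues) == 0:
            return float("nan")
        return float(sig.pvalues.min())

    def to_long_tsv(self, path: str | Path) -> None:
        rows = []
        for code, sig in self.signatures.items():
            for bm in sig.effects.index:
                rows.append(
                    {
                        "disease_id": code,
                        "disease_name": self.disease_names.get(code, code),
                        "n_cases": self.n_cases[code],
                        "biomarker": bm,
                        "beta": sig.effects[bm],
                        "se": np.nan,
                        "p": np.nan if sig.pvalues is None else sig.pvalues[bm],
                    }
                )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_long_tsv(cls, path: str | Path) -> "DiseaseAtlas":
        df = pd.read_csv(path, sep="\t")
        sigs, cases, names = {}, {}, {}
        for code, grp in df.groupby("disease_id", sort=True):
            grp = grp.set_index("biomarker")
            sigs[code] = Signature(
                str(code),
                grp["beta"],
                grp["p"] if grp["p"].notna().any() else None,
            )
            cases[code] = int(grp["n_cases"].iloc[0])
            names[code] = str(grp["disease_name"].iloc[0])
        return cls(sigs, cases, names)


def harmonize(
    sig_a: Signature,
    sig_b: Signature,
    synonyms: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Inner-join two signatures on normalized biomarker names.

    Names are case-folded with punctuation/whitespace collapsed; an
    optional synonym map is applied after normalization.  Returns the
    paired effect-size table (columns ``a``, ``b``, indexed by the
    normalized name) and a report of unmatched names per side.  Fewer
    than 3 matches is an error.
    """
    if len(sig_a) == 0 or len(sig_b) == 0:
        raise ValueError("empty signature")
    norm_a = {_normalize_name(n, synonyms): n for n in sig_a.effects.index}
    norm_b = {_normalize_name(n, synonyms): n for n in sig_b.effects.index}
    shared = [k for k in norm_a if k in norm_b]  # order-stable (a's order)
    report = {
        "unmatched_a": [norm_a[k] for k in norm_a if k not in norm_b],
        "unmatched_b": [norm_b[k] for k in norm_b if k not in norm_a],
    }
    if len(shared) < 3:
        raise ValueError(
            f"only {len(shared)} shared biomarkers between "
            f"{sig_a.label!r} and {sig_b.label!r}"
        )
    paired = pd.DataFrame(
        {
            "a": sig_a.effects.loc[[norm_a[k] for k in shared]].to_numpy(),
            "b": sig_b.effects.loc[[norm_b[k] for k in shared]].to_numpy(),
        },
        index=shared,
    )
    return paired, report


def filter_atlas(
    atlas: DiseaseAtlas, min_cases: int = 1000, sig_p: float = 5e-4
) -> DiseaseAtlas:
    """Keep diseases with case count >= min_cases AND min biomarker p < sig_p."""
    keep = [
        code
        for code in atlas.signatures
        if atlas.n_cases[code] >= min_cases and atlas.min_p(code) < sig_p
    ]
    return DiseaseAtlas(
        {c: atlas.signatures[c] for c in keep},
        {c: atlas.n_cases[c] for c in keep},
        {c: atlas.disease_names.get(c, c) for c in keep},
    )


def correlate_signatures(
    sig_a: Signature, sig_b: Signature, synonyms: dict[str, str] | None = None
) -> tuple[float, float, int]:
    """Pearson r over matched effect sizes with a two-sided p.

    The p-value is the standard t transform with n-2 degrees of
    freedom, treating biomarkers as independent observations.
    """
    paired, _ = harmonize(sig_a, sig_b, synonyms)
    a, b = paired["a"].to_numpy(), paired["b"].to_numpy()
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance in a signature")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p), len(paired)


def correlate_all(
    famine_sig: Signature,
    atlas: DiseaseAtlas,
    alpha: float = 0.05,
    synonyms: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Correlate a famine signature with every atlas disease.

    Bonferroni significance at ``alpha / (number of diseases tested)``;
    per-disease harmonization failures are logged in the ``error``
    column, not fatal.  Sorted by \\|r\\| descending.
    """
    m = len(atlas)
    rows = []
    for code, sig in atlas.signatures.items():
        row = {
            "disease": code,
            "disease_name": atlas.disease_names.get(code, code),
            "n_cases": atlas.n_cases[code],
        }
        try:
            r, p, n = correlate_signatures(famine_sig, sig, synonyms)
            row.update(n_matched=n, r=r, p=p, error="")
        except ValueError as exc:
            row.update(n_matched=0, r=np.nan, p=np.nan, error=str(exc))
        rows.append(row)
    out = pd.DataFrame(rows)
    out["significant"] = out["p"] < (alpha / m if m else np.nan)
    out = out.reindex(
        out["r"].abs().sort_values(ascending=False, kind="stable").index
    ).reset_index(drop=True)
    out.attrs["n_significant_positive"] = int(
        ((out["r"] > 0) & out["significant"]).sum()
    )
    out.attrs["n_significant_negative"] = int(
        ((out["r"] < 0) & out["significant"]).sum()
    )
    return out


def attenuation(
    comparisons_main: pd.DataFrame, comparisons_adjusted: pd.DataFrame
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Percent change in correlation strength after covariate adjustment.

    attenuation_pct = 100 * (|r_adjusted| - |r_main|) / |r_main| per
    disease; negative values indicate attenuation.  Diseases with
    |r_main| < 1e-6 are excluded (flagged in the ``excluded`` column).
    Returns the per-disease table and a summary with the mean and SD
    over included diseases.
    """
    main = comparisons_main.set_index("disease")
    adj = comparisons_adjusted.set_index("disease")
    if set(main.index) != set(adj.index):
        raise ValueError("main and adjusted comparisons cover different diseases")
    adj = adj.loc[main.index]
    out = pd.DataFrame(
        {
            "r_main": main["r"],
            "r_adjusted": adj["r"],
        }
    )
    tiny = out["r_main"].abs() < 1e-6
    out["attenuation_pct"] = np.where(
        tiny,
        np.nan,
        100.0 * (adj["r"].abs() - main["r"].abs()) / main["r"].abs(),
    )
    out["excluded"] = tiny
    vals = out.loc[~tiny, "attenuation_pct"]
    summary = {
        "mean_attenuation_pct": float(vals.mean()),
        "sd_attenuation_pct": float(vals.std(ddof=1)) if len(vals) > 1 else float("nan"),
        "n_diseases": int(len(vals)),
        "n_excluded": int(tiny.sum()),
    }
    return out.reset_index(), summary


def order_heatmap(
    comparisons: pd.DataFrame,
    famine_sig: Signature,
    atlas: DiseaseAtlas,
    top_k: int = 30,
    nominal_p: float = 0.05,
) -> pd.DataFrame:
    """Disease-by-biomarker effect matrix ordered for plotting.

    Rows are the ``top_k`` diseases by r (descending, clamped to the
    atlas size); columns are the biomarkers nominally associated with
    famine exposure (famine p < ``nominal_p``), ordered by
    complete-linkage hierarchical clustering on Euclidean distance of
    their per-disease effect-size profiles.
    """
    if len(comparisons) == 0:
        raise ValueError("no comparisons")
    if famine_sig.pvalues is None:
        raise ValueError("famine signature carries no p-values")
    nominal = famine_sig.pvalues[famine_sig.pvalues < nominal_p].index.tolist()
    if not nominal:
        raise ValueError("no nominally significant biomarkers")
    top = (
        comparisons.dropna(subset=["r"])
        .sort_values("r", ascending=False, kind="stable")
        .head(top_k)
    )
    mat = pd.DataFrame(
        {
            code: atlas.signatures[code].effects.reindex(nominal)
            for code in top["disease"]
        }
    ).T  # diseases x biomarkers
    profiles = mat.to_numpy().T  # biomarker profiles across diseases
    if mat.shape[1] > 2:
        link = hierarchy.linkage(pdist(profiles), method="complete")
        order = hierarchy.leaves_list(link)
        mat = mat.iloc[:, order]
    return mat
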