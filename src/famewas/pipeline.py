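"""End-to-end scans: QC'd methylation -> heritability, covariate, and
association tables, with multiple-testing flags and an optional
Manhattan-style plot.

Each scan works on in-memory objects (the CLI layer handles files).
Complete-case analysis is applied per trait-unit pair: subjects missing
the unit value, the trait, or a covariate are dropped and the kinship
matrix is subset accordingly; polygenic model rotations are cached per
subject subset.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .pedigree import KinshipMatrix
from .multiple_testing import bh_fdr, per_test_threshold
from .varcomp import (
    PolygenicModel,
    association_test,
    covariate_scan,
    normalize_expression,
    rank_normalize,
    covariate_design,
)

__all__ = [
    "heritability_scan",
    "association_scan",
    "expression_association",
    "plot_association",
    "write_manifest",
]


class _ModelCache:
    """PolygenicModel per complete-case subject subset."""

    def __init__(self, kinship: KinshipMatrix):
        self.kinship = kinship
        self._cache: dict[tuple[str, ...], tuple[list[str], PolygenicModel]] = {}

    def get(self, ids: Sequence[str]) -> tuple[list[str], PolygenicModel]:
        key = tuple(ids)
        if key not in self._cache:
            sub = self.kinship.subset(list(ids))
            self._cache[key] = (list(ids), PolygenicModel(sub))
        return self._cache[key]


def _complete_ids(kinship: KinshipMatrix, *frames_or_series) -> list[str]:
    ids = [i for i in kinship.ids]
    keep = []
    for i in ids:
        ok = True
        for obj in frames_or_series:
            if i not in obj.index:
                ok = False
                break
            v = obj.loc[i]
            if np.any(pd.isna(v)):
                ok = False
                break
        if ok:
            keep.append(i)
    return keep


def heritability_scan(
    meth_matrix: pd.DataFrame,
    covariates: pd.DataFrame,
    kinship: KinshipMatrix,
    min_families: int = 3,
) -> pd.DataFrame:
    """Per-unit heritability with age and sex effects.

    ``meth_matrix`` is the QC'd subject x unit matrix (including the
    regional-average column); ``covariates`` must carry ``age`` and
    ``female``.  Returns one row per unit with h2 +- SE, the
    boundary-mixture LRT p, and per-covariate raw-scale effects.
    """
    if "family" in covariates.columns and covariates["family"].nunique() < min_families:
        raise ValueError("fewer than 3 families: no between-family information")
    cache = _ModelCache(kinship)
    rows = []
    for unit in meth_matrix.columns:
        col = meth_matrix[unit]
        ids = _complete_ids(kinship, col.to_frame(), covariates[["age", "female"]])
        if len(ids) < 10 or col.loc[ids].nunique() < 3:
            rows.append({"unit": unit, "n": len(ids)})
            continue
        ids, model = cache.get(ids)
        X = covariate_design(
            covariates.loc[ids, "age"].to_numpy(),
            covariates.loc[ids, "female"].to_numpy(),
        )
        res = covariate_scan(col.loc[ids].to_numpy(), X, model)
        res["unit"] = unit
        rows.append(res)
    cols = [
        "unit", "h2", "h2_se", "p_h2",
        "beta_age", "se_age", "p_age", "ve_age",
        "beta_sex", "se_sex", "p_sex", "ve_sex", "n",
    ]
    return pd.DataFrame(rows).reindex(columns=cols)


def association_scan(
    meth_matrix: pd.DataFrame,
    phenotypes: pd.DataFrame,
    covariates: pd.DataFrame,
    kinship: KinshipMatrix,
    traits: Sequence[str] | None = None,
    alpha_significant: float = 0.05,
    alpha_suggestive: float = 0.10,
    method: str = "bonferroni",
    m_tests: float | None = None,
) -> pd.DataFrame:
    """Trait x unit association table with significance flags.

    Both the trait and the focal methylation values are rank-normalized;
    the LRT p-value is 1-df chi-squared.  Effects are back-transformed to
    raw trait units per 1% methylation using the raw standard deviations.
    Flags use per-test thresholds for ``m_tests`` tests (default: the
    number of units scanned, i.e. panel units plus regional average).
    """
    traits = list(traits) if traits is not None else list(phenotypes.columns)
    missing = [t for t in traits if t not in phenotypes.columns]
    if missing:
        raise ValueError(f"trait column(s) absent from phenotypes: {missing}")
    units = list(meth_matrix.columns)
    M = float(m_tests) if m_tests is not None else float(len(units))
    thr_sig = per_test_threshold(alpha_significant, M, method)
    thr_sug = per_test_threshold(alpha_suggestive, M, method)

    cache = _ModelCache(kinship)
    rows = []
    for trait in traits:
        y_raw_all = phenotypes[trait]
        for unit in units:
            col = meth_matrix[unit]
            ids = _complete_ids(
                kinship, col.to_frame(), y_raw_all.to_frame(), covariates[["age", "female"]]
            )
            if len(ids) < 10 or col.loc[ids].nunique() < 3:
                rows.append({"trait": trait, "unit": unit, "n": len(ids)})
                continue
            ids, model = cache.get(ids)
            X = covariate_design(
                covariates.loc[ids, "age"].to_numpy(),
                covariates.loc[ids, "female"].to_numpy(),
            )
            y_raw = y_raw_all.loc[ids].to_numpy(dtype=float)
            x_raw = col.loc[ids].to_numpy(dtype=float)
            res = association_test(
                rank_normalize(y_raw),
                X,
                model,
                x_raw,
                meth_raw_sd=float(np.std(x_raw, ddof=1)),
                trait_raw_sd=float(np.std(y_raw, ddof=1)),
            )
            rows.append(
                {
                    "trait": trait,
                    "unit": unit,
                    "beta": res.beta,
                    "se": res.se,
                    "ve": res.variance_explained,
                    "raw_change_per_pct": res.raw_change_per_percent,
                    "p": res.p_value,
                    "significant": res.p_value < thr_sig,
                    "suggestive": res.p_value < thr_sug,
                    "n": res.n,
                }
            )
    return pd.DataFrame(rows)


def expression_association(
    expression: pd.DataFrame,
    phenotypes: pd.DataFrame,
    covariates: pd.DataFrame,
    kinship: KinshipMatrix,
    traits: Sequence[str] | None = None,
    detection_q: float = 0.05,
    detection_log2_background: float = 6.0,
) -> pd.DataFrame:
    """Kinship-adjusted trait-probe associations on normalized expression.

    Intensities are log2 transformed and quantile normalized; probes not
    detectable above background at BH-FDR ``detection_q`` (one-sided
    t-test of mean log2 level against ``detection_log2_background``) are
    dropped, and each surviving probe is tested against each trait under
    the polygenic model.
    """
    from scipy import stats as sstats

    traits = list(traits) if traits is not None else list(phenotypes.columns)
    norm = normalize_expression(expression)
    # detection: probe mean above background
    tvals, pvals = sstats.ttest_1samp(
        norm.to_numpy(), detection_log2_background, axis=0, alternative="greater"
    )
    detected_mask, _ = bh_fdr(pvals, q=detection_q)
    detected = list(norm.columns[detected_mask])
    cache = _ModelCache(kinship)
    rows = []
    for trait in traits:
        y_all = phenotypes[trait]
        for probe in detected:
            col = norm[probe]
            ids = _complete_ids(
                kinship, col.to_frame(), y_all.to_frame(), covariates[["age", "female"]]
            )
            if len(ids) < 10:
                continue
            ids, model = cache.get(ids)
            X = covariate_design(
                covariates.loc[ids, "age"].to_numpy(),
                covariates.loc[ids, "female"].to_numpy(),
            )
            res = association_test(
                rank_normalize(y_all.loc[ids].to_numpy(dtype=float)),
                X,
                model,
                col.loc[ids].to_numpy(dtype=float),
            )
            rows.append(
                {
                    "trait": trait,
                    "probe": probe,
                    "beta": res.beta,
                    "se": res.se,
                    "p": res.p_value,
                    "n": res.n,
                }
            )
    return pd.DataFrame(rows, columns=["trait", "probe", "beta", "se", "p", "n"])


def plot_association(
    results: pd.DataFrame,
    path,
    unit_order: Sequence[str] | None = None,
    threshold_p: float | None = None,
):
    """Manhattan-style plot of -log10(p) by unit position, one marker per trait."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    units = list(unit_order) if unit_order is not None else list(results["unit"].unique())
    xpos = {u: i for i, u in enumerate(units)}
    fig, ax = plt.subplots(figsize=(8, 4))
    for trait, grp in results.groupby("trait"):
        grp = grp[grp["unit"].isin(xpos)]
        ax.scatter(
            [xpos[u] for u in grp["unit"]],
            -np.log10(grp["p"].astype(float)),
            label=str(trait),
            s=18,
        )
    if threshold_p is not None:
        ax.axhline(-np.log10(threshold_p), ls="--", c="steelblue", lw=1)
    ax.set_xticks(range(len(units)))
    ax.set_xticklabels(units, rotation=90, fontsize=7)
    ax.set_ylabel("-log10(p)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def write_manifest(path, config: dict, seed: int | None, tables: dict[str, pd.DataFrame]):
    """Run manifest: config hash, seed, and row counts, as JSON."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    manifest = {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": seed,
        "row_counts": {k: int(len(v)) for k, v in tables.items()},
    }
    Path(path).write_text(json.dumps(manifest, indent=2))
    return manifest
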