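"""End-to-end study analysis over a sample set.

``run_study`` reproduces the full analysis sequence on any sample set:

1. joint GPA over all wings (left wings mirrored), colony-level averaging
   of tangent coordinates;
2. PCA of colony means to 34 "wing shape" scores;
3. CVA over area/period groups plus any reference taxa: canonical axes,
   the full squared-Mahalanobis distance table with pairwise significance;
4. two-factor MANOVA (area x period, Wilks' lambda) on the non-reference
   colonies;
5. leave-one-out discriminant classification for the two competing
   two-group partitions — by mountain-ridge area and by mean annual
   temperature above/below a threshold (default 9 degrees C) — with the
   corresponding combined squared Mahalanobis distances;
6. multivariate regressions of shape on latitude, longitude, altitude and
   temperature (Wilks' lambda each);
7. two-factor ANOVAs of the cubital index and of wing size (ln centroid
   size), with cell means and confidence intervals;
8. Pearson correlations among the univariate variables.

Reference-taxon samples take part in the distance table but are excluded
from the area/period MANOVA, the LOO partitions, the regressions and the
trait ANOVAs.  Samples lacking temperature metadata are skipped by the
temperature partition with a log entry.  The report is a pure function of
(sample set, config): rerunning yields identical output.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .landmark_io import SampleSet
from .superimpose import gpa
from .shapespace import (
    cva, fit_groups, loo_cross_validation, loo_cross_validation_refit_pca,
    mahalanobis_sq, pca,
)
from .inference import (
    anova_two_factor, manova_two_factor, multivariate_regression_wilks, pearson,
)
from .traits import CubitalIndexConvention, IDENTIFLY_19, sample_trait_table

logger = logging.getLogger(__name__)

#: significance-code thresholds for rendered distance tables
SIGNIFICANCE_CODES = ((1e-4, "***"), (1e-3, "**"), (5e-2, "*"))


@dataclass
class StudyConfig:
    temperature_threshold: float = 9.0  # deg C partition of the climate grouping
    mirror_left: bool = True
    n_components: int = 34
    convention: CubitalIndexConvention = IDENTIFLY_19
    include_reference_in_pooled: bool = True  # references join the pooled CVA covariance
    refit_pca_in_loo: bool = False  # refit PCA inside each LOO fold


@dataclass
class StudyReport:
    n_samples: int
    n_wings: int
    groups: pd.DataFrame  # per analysis group: n colonies, n wings
    distance_matrix: pd.DataFrame
    pairwise_p: pd.DataFrame
    canonical_eigenvalues: np.ndarray
    manova: Optional[dict]  # per effect: lambda, F, dfs, p
    area_d2: Optional[float]  # combined-period between-area distance
    area_loo_rate: Optional[float]
    area_loo_table: Optional[pd.DataFrame]
    temperature_d2: Optional[float]
    temperature_loo_rate: Optional[float]
    temperature_loo_table: Optional[pd.DataFrame]
    regressions: dict  # covariate -> {lambda, F, df1, df2, p}
    anova_cubital: Optional[dict]
    anova_size: Optional[dict]
    cell_means_cubital: Optional[pd.DataFrame]
    cell_means_size: Optional[pd.DataFrame]
    correlations: dict  # (x, y) name pair -> {r, p}
    trait_table: pd.DataFrame
    notes: list[str] = field(default_factory=list)


def _effect_dict(t) -> dict:
    return {"lambda": t.statistic, "F": t.F, "df1": t.df1, "df2": t.df2, "p": t.p}


def _anova_dict(res) -> dict:
    return {
        name: {"F": e.F, "df1": e.df1, "df2": e.df2, "p": e.p}
        for name, e in res.effects.items()
    }


def run_study(samples: SampleSet, config: Optional[StudyConfig] = None) -> StudyReport:
    """Run the full analysis and collect every result surface in a report."""
    cfg = config or StudyConfig()
    notes: list[str] = []

    meta = samples.metadata_frame()
    romanian = meta[meta["area"] != "reference"]
    if romanian["area"].nunique() < 2 or (romanian.groupby("area").size() < 2).any():
        raise ValueError("need >= 2 samples in each of >= 2 areas")

    aligned = gpa(samples, mirror_left=cfg.mirror_left)
    means, order = aligned.sample_means()
    meta = meta.loc[order]
    space = pca(means, k=cfg.n_components)
    scores = space.scores

    # ---- group structure: area/period for Romanian, taxon for references
    def group_label(row) -> str:
        if row["area"] == "reference":
            return str(row["reference_taxon"])
        return f"{row['area']}_{'pre' if row['period'] == 'pre2000' else 'post'}"

    glabels = [group_label(meta.loc[sid]) for sid in order]
    groups_df = (
        pd.DataFrame({"group": glabels, "n_wings": meta["n_wings"].to_numpy()})
        .groupby("group")
        .agg(n_colonies=("group", "size"), n_wings=("n_wings", "sum"))
    )

    is_ref = (meta["area"] == "reference").to_numpy()
    if cfg.include_reference_in_pooled:
        model = fit_groups(scores, glabels)
        cva_res = cva(model, scores, glabels)
    else:
        keep = ~is_ref
        model = fit_groups(scores[keep], [g for g, r in zip(glabels, is_ref) if not r])
        cva_res = cva(model, scores[keep], [g for g, r in zip(glabels, is_ref) if not r])

    rom = ~is_ref
    rom_scores = scores[rom]
    rom_meta = meta[rom]
    rom_ids = list(rom_meta.index)

    # ---- MANOVA area x period
    manova_dict = None
    try:
        mres = manova_two_factor(
            rom_scores, rom_meta["area"], rom_meta["period"], names=("area", "period")
        )
        manova_dict = {
            "area": _effect_dict(mres["factor_a"]),
            "period": _effect_dict(mres["factor_b"]),
            "interaction": _effect_dict(mres["interaction"]),
        }
    except ValueError as exc:
        notes.append(f"MANOVA skipped: {exc}")
        logger.warning("MANOVA skipped: %s", exc)

    # ---- competing two-group partitions: area vs temperature threshold
    rom_means = means[rom]

    def _loo(sc, tmeans, labs, ids):
        if cfg.refit_pca_in_loo:
            return loo_cross_validation_refit_pca(
                tmeans, labs, ids, k=cfg.n_components
            )
        return loo_cross_validation(sc, labs, ids)

    area_labels = list(rom_meta["area"])
    area_model = fit_groups(rom_scores, area_labels)
    area_d2 = mahalanobis_sq(area_model, "intra", "extra")
    area_rate, area_table = _loo(rom_scores, rom_means, area_labels, rom_ids)

    temp = rom_meta["mean_annual_temperature"]
    have_temp = temp.notna().to_numpy()
    temperature_d2 = temperature_rate = None
    temp_table = None
    if (~have_temp).any():
        notes.append(
            f"{int((~have_temp).sum())} samples lack temperature; excluded from "
            "the temperature partition"
        )
    tlabels = np.where(
        temp[have_temp] >= cfg.temperature_threshold, "warm", "cold"
    )
    tcounts = pd.Series(tlabels).value_counts()
    if len(tcounts) == 2 and tcounts.min() >= 2:
        tmodel = fit_groups(rom_scores[have_temp], tlabels)
        temperature_d2 = mahalanobis_sq(tmodel, "warm", "cold")
        temperature_rate, temp_table = _loo(
            rom_scores[have_temp], rom_means[have_temp], list(tlabels),
            [i for i, h in zip(rom_ids, have_temp) if h],
        )
    else:
        notes.append("temperature partition degenerate; skipped")

    # ---- multivariate regressions of shape on covariates
    regressions = {}
    for cov in ("latitude", "longitude", "altitude", "mean_annual_temperature"):
        vals = rom_meta[cov]
        ok = vals.notna().to_numpy()
        if ok.sum() < rom_scores.shape[1] + 3:
            notes.append(f"regression on {cov} skipped: too few samples with data")
            continue
        lam, F, dfs, p, coef = multivariate_regression_wilks(
            rom_scores[ok], vals[ok].to_numpy(dtype=float)
        )
        regressions[cov] = {
            "lambda": lam, "F": F, "df1": dfs[0], "df2": dfs[1], "p": p,
        }

    # ---- univariate traits
    trait_table = sample_trait_table(samples, cfg.convention)
    trait_table = trait_table.loc[order]
    rom_traits = trait_table[trait_table["area"] != "reference"]
    anova_ci = anova_size = None
    cells_ci = cells_size = None
    try:
        a1 = anova_two_factor(
            rom_traits["cubital_index"], rom_traits["area"], rom_traits["period"],
            names=("area", "period"),
        )
        anova_ci, cells_ci = _anova_dict(a1), a1.cell_means
        a2 = anova_two_factor(
            rom_traits["ln_centroid_size"], rom_traits["area"], rom_traits["period"],
            names=("area", "period"),
        )
        anova_size, cells_size = _anova_dict(a2), a2.cell_means
    except ValueError as exc:
        notes.append(f"trait ANOVA skipped: {exc}")

    # ---- Pearson correlations among univariate variables
    correlations = {}
    pairs = [
        ("mean_annual_temperature", "latitude"),
        ("mean_annual_temperature", "longitude"),
        ("mean_annual_temperature", "altitude"),
        ("ln_centroid_size", "latitude"),
        ("ln_centroid_size", "longitude"),
        ("ln_centroid_size", "altitude"),
        ("ln_centroid_size", "mean_annual_temperature"),
    ]
    for xnm, ynm in pairs:
        sub = rom_traits[[xnm, ynm]].dropna()
        if len(sub) < 3:
            continue
        try:
            r, p = pearson(sub[xnm], sub[ynm])
        except ValueError:
            continue
        correlations[f"{xnm}~{ynm}"] = {"r": r, "p": p}

    return StudyReport(
        n_samples=len(samples),
        n_wings=samples.n_wings,
        groups=groups_df,
        distance_matrix=cva_res.squared_mahalanobis,
        pairwise_p=cva_res.pairwise_p,
        canonical_eigenvalues=cva_res.canonical_eigenvalues,
        manova=manova_dict,
        area_d2=area_d2,
        area_loo_rate=area_rate,
        area_loo_table=area_table,
        temperature_d2=temperature_d2,
        temperature_loo_rate=temperature_rate,
        temperature_loo_table=temp_table,
        regressions=regressions,
        anova_cubital=anova_ci,
        anova_size=anova_size,
        cell_means_cubital=cells_ci,
        cell_means_size=cells_size,
        correlations=correlations,
        trait_table=trait_table,
        notes=notes,
    )


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def significance_code(p: float) -> str:
    for thr, code in SIGNIFICANCE_CODES:
        if p < thr:
            return code
    return "ns"


def _jsonable(obj):
    if isinstance(obj, pd.DataFrame):
        return json.loads(obj.to_json(orient="split"))
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def report_to_dict(report: StudyReport) -> dict:
    return {f.name: _jsonable(getattr(report, f.name))
            for f in dataclasses.fields(report)}


def report_render(
    report: StudyReport, format: str = "json", path: Optional[str | Path] = None
) -> str:
    """Serialize a report deterministically as JSON or markdown.

    The markdown distance table follows the conventional layout: squared
    Mahalanobis distances in the lower triangle, significance codes in the
    upper triangle.
    """
    if format == "json":
        text = json.dumps(report_to_dict(report), indent=1, sort_keys=True)
    elif format == "markdown":
        text = _render_markdown(report)
    else:
        raise ValueError(f"unknown format {format!r}")
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def _fmt(x, nd=4) -> str:
    if x is None:
        return "—"
    if isinstance(x, float):
        return f"{x:.{nd}g}"
    return str(x)


def _render_markdown(r: StudyReport) -> str:
    lines = ["# Wing morphometry study report", ""]
    lines.append(f"Samples: {r.n_samples} ({r.n_wings} wings)")
    lines.append("")
    lines.append("## Group separation (squared Mahalanobis distances, lower "
                 "triangle; significance, upper triangle)")
    labels = list(r.distance_matrix.index)
    lines.append("| group | " + " | ".join(labels) + " |")
    lines.append("|---" * (len(labels) + 1) + "|")
    for i, gi in enumerate(labels):
        cells = []
        for j, gj in enumerate(labels):
            if i > j:
                cells.append(f"{r.distance_matrix.iloc[i, j]:.2f}")
            elif i < j:
                cells.append(significance_code(float(r.pairwise_p.iloc[i, j])))
            else:
                cells.append("")
        lines.append("| " + gi + " | " + " | ".join(cells) + " |")
    lines.append("")
    if r.manova:
        lines.append("## MANOVA of wing shape (area x period)")
        for eff, d in r.manova.items():
            lines.append(
                f"- {eff}: Wilks' lambda = {d['lambda']:.4f}, "
                f"F({d['df1']},{d['df2']}) = {d['F']:.2f}, p = {d['p']:.4g}"
            )
        lines.append("")
    lines.append("## Competing two-group partitions")
    lines.append(
        f"- area (intra vs extra): D^2 = {_fmt(r.area_d2)}, LOO rate = "
        f"{_fmt(r.area_loo_rate)}%"
    )
    lines.append(
        f"- temperature threshold: D^2 = {_fmt(r.temperature_d2)}, LOO rate = "
        f"{_fmt(r.temperature_loo_rate)}%"
    )
    lines.append("")
    if r.regressions:
        lines.append("## Multivariate regressions of wing shape")
        for cov, d in r.regressions.items():
            lines.append(
                f"- {cov}: Wilks' lambda = {d['lambda']:.4f}, "
                f"F({d['df1']},{d['df2']}) = {d['F']:.2f}, p = {d['p']:.4g}"
            )
        lines.append("")
    for title, an in (("cubital index", r.anova_cubital), ("wing size", r.anova_size)):
        if an:
            lines.append(f"## Two-factor ANOVA of {title}")
            for eff, d in an.items():
                lines.append(
                    f"- {eff}: F({d['df1']},{d['df2']}) = {d['F']:.2f}, "
                    f"p = {d['p']:.4g}"
                )
            lines.append("")
    if r.correlations:
        lines.append("## Pearson correlations")
        for pair, d in r.correlations.items():
            lines.append(f"- {pair}: r = {d['r']:.2f}, p = {d['p']:.4g}")
        lines.append("")
    if r.notes:
        lines.append("## Notes")
        lines.extend(f"- {n}" for n in r.notes)
        lines.append("")
    return "\n".join(lines)
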