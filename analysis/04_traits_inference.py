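#!/usr/bin/env python
"""Hypothesis tests: MANOVA, shape regressions, trait ANOVAs, correlations.

On the Romanian colonies of the simulated study: the two-factor MANOVA of
wing shape (area x period, Wilks' lambda), multivariate regressions of
shape on latitude / longitude / altitude / mean annual temperature, the
two-factor ANOVAs of cubital index and wing size with cell means, and the
Pearson correlations among the univariate variables.
"""

import json
from pathlib import Path

import pandas as pd

from wingmorph import landmark_io
from wingmorph.inference import (
    anova_two_factor, manova_two_factor, multivariate_regression_wilks, pearson,
)
from wingmorph.shapespace import pca
from wingmorph.superimpose import gpa
from wingmorph.traits import sample_trait_table

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"


def main() -> None:
    samples = landmark_io.read_tps(
        SCRATCH / "study_wings.tps",
        metadata=pd.read_csv(SCRATCH / "study_metadata.csv"),
    )
    aligned = gpa(samples)
    means, order = aligned.sample_means()
    meta = samples.metadata_frame().loc[order]
    traits = sample_trait_table(samples).loc[order]
    traits.round(5).to_csv(RESULTS / "04_trait_table.csv")

    rom = (meta["area"] != "reference").to_numpy()
    scores = pca(means, k=34).scores[rom]
    rm = meta[rom]
    rt = traits[rom]

    out: dict = {}
    man = manova_two_factor(scores, rm["area"], rm["period"], names=("area", "period"))
    out["manova_wing_shape"] = {
        k: {"wilks_lambda": e.statistic, "F": e.F, "df": [e.df1, e.df2], "p": e.p}
        for k, e in (("area", man["factor_a"]), ("period", man["factor_b"]),
                     ("interaction", man["interaction"]))
    }
    print("MANOVA of wing shape (Wilks' lambda):")
    for k, v in out["manova_wing_shape"].items():
        print(f"  {k:12s} lambda = {v['wilks_lambda']:.3f}  p = {v['p']:.2e}")

    out["shape_regressions"] = {}
    for cov in ("latitude", "longitude", "altitude", "mean_annual_temperature"):
        lam, F, dfs, p, _ = multivariate_regression_wilks(
            scores, rm[cov].to_numpy(float)
        )
        out["shape_regressions"][cov] = {"wilks_lambda": lam, "p": p}
        print(f"shape ~ {cov:26s} lambda = {lam:.3f}  p = {p:.2e}")

    for trait in ("cubital_index", "ln_centroid_size"):
        res = anova_two_factor(rt[trait], rt["area"], rt["period"],
                               names=("area", "period"))
        out[f"anova_{trait}"] = {
            k: {"F": e.F, "df": [e.df1, e.df2], "p": e.p}
            for k, e in res.effects.items()
        }
        out[f"cells_{trait}"] = json.loads(
            res.cell_means.round(5).to_json(orient="records")
        )
        fa = res.effects["factor_a"]
        print(f"ANOVA {trait}: area F({fa.df1},{fa.df2}) = {fa.F:.2f}, p = {fa.p:.4f}")

    out["correlations"] = {}
    for x, y in (("mean_annual_temperature", "latitude"),
                 ("mean_annual_temperature", "altitude"),
                 ("ln_centroid_size", "latitude"),
                 ("ln_centroid_size", "mean_annual_temperature")):
        r, p = pearson(rt[x], rt[y])
        out["correlations"][f"{x}~{y}"] = {"r": r, "p": p}
        print(f"r({x}, {y}) = {r:+.2f}")

    (RESULTS / "04_inference.json").write_text(
        json.dumps(out, indent=1), encoding="utf-8"
    )


if __name__ == "__main__":
    main()
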