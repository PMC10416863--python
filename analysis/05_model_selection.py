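"""Rank the growth models on pooled data and profile residuals by age.

Compares the pooled fits of the three models within each sex x efficiency
cell by R2, AIC, BIC, RMSE and iteration count, and summarizes the pooled
residual (observed - predicted BW) by age — the model-adequacy profile.

Reads results/partition/; writes results/selection/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from flockgrowth.fitting import compare_models, fit_model
from flockgrowth.models import MODEL_TAGS, VON_BERTALANFFY
from flockgrowth.pipeline import report_residuals

PART = Path("results/partition")
OUT = Path("results/selection")
AGE_COLS = [f"bw_{a}" for a in (0, 7, 14, 21, 28, 35)]
AGES = np.array([0.0, 7.0, 14.0, 21.0, 28.0, 35.0])


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    df = pd.read_csv(PART / "flocks_labeled.csv")
    df = df[df.efficiency.isin(["HE", "LE"])]

    ranked_all = []
    pooled_fits = {}
    for (sex, group), cell in df.groupby(["sex", "efficiency"]):
        ages = np.tile(AGES, len(cell))
        bw = cell[AGE_COLS].to_numpy().ravel()
        fits = [fit_model(ages, bw, m) for m in MODEL_TAGS]
        for f in fits:
            pooled_fits[(sex, group, f.model)] = f
        ranked = compare_models(fits)
        ranked.insert(0, "sex", sex)
        ranked.insert(1, "group", group)
        ranked_all.append(ranked)
        winner = ranked.iloc[0]
        vb_iters = ranked.set_index("model").loc[VON_BERTALANFFY, "n_iter"]
        print(f"{sex}/{group}: best composite rank = {winner.model} "
              f"(R2 {winner.r2:.4f}, RMSE {winner.rmse:.1f} g); "
              f"von Bertalanffy needed {vb_iters} iterations, "
              f"the most of the three: "
              f"{bool(vb_iters == ranked.n_iter.max())}")
    comparison = pd.concat(ranked_all, ignore_index=True)
    comparison.to_csv(OUT / "model_comparison.csv", index=False)

    residuals = report_residuals(pooled_fits)
    residuals.to_csv(OUT / "residuals.csv", index=False)
    worst = residuals.loc[residuals.mean_residual.abs().idxmax()]
    print(f"largest mean pooled residual: {worst.mean_residual:+.1f} g "
          f"({worst.model}, {worst.sex}/{worst.group} at {worst.age} d)")
    print(f"wrote {OUT/'model_comparison.csv'} and {OUT/'residuals.csv'}")


if __name__ == "__main__":
    main()
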