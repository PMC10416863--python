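"""Compare performance variables and fitted parameters between HE and LE.

One-way ANOVA with efficiency as the main effect, pooled-t letter
separation, arcsine-square-root transform for mortality percentages, and
the K-versus-t_i correlation across per-flock fits.

Reads results/partition/ and results/fits/; writes results/comparison/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from flockgrowth.stats import compare_groups, correlate_estimates

PART = Path("results/partition")
FITS = Path("results/fits")
OUT = Path("results/comparison")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    flocks = pd.read_csv(PART / "flocks_labeled.csv")
    flocks = flocks[flocks.efficiency.isin(["HE", "LE"])]
    fits = pd.read_csv(FITS / "fits.csv")
    per_flock = fits[fits.scope == "flock"]

    rows = []
    value_cols = [c for c in flocks.columns
                  if c not in ("flock_id", "sex", "efficiency")]
    for sex, sub in flocks.groupby("sex"):
        for col in value_cols:
            grouped = {g: sub[sub.efficiency == g][col].dropna().to_numpy()
                       for g in ("HE", "LE")}
            comp = compare_groups(grouped, variable=col,
                                  percentage=col.startswith(("wmort", "cmort")))
            rows.append({"sex": sex, "variable": col,
                         "mean_HE": comp.means["HE"], "mean_LE": comp.means["LE"],
                         "letter_HE": comp.letters["HE"],
                         "letter_LE": comp.letters["LE"],
                         "sem": comp.sem, "cv": comp.cv, "p": comp.p_value})
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "group_comparison.csv", index=False)

    fcr35 = table[table.variable == "fcr_35"]
    print("35-d FCR, HE vs LE (ANOVA on efficiency):")
    print(fcr35.round(4).to_string(index=False))

    print("\nK vs t_i correlation across per-flock logistic fits "
          "(faster-growing flocks inflect younger):")
    corr_rows = []
    for (sex, group), cell in per_flock[per_flock.model == "logistic"].groupby(
            ["sex", "group"]):
        r, p = correlate_estimates(cell.k.to_numpy(), cell.t_i.to_numpy())
        corr_rows.append({"sex": sex, "group": group, "r": r, "p": p})
        print(f"  {sex}/{group}: r = {r:.2f} (p = {p:.2g})")
    pd.DataFrame(corr_rows).to_csv(OUT / "k_ti_correlation.csv", index=False)
    print(f"wrote {OUT/'group_comparison.csv'} and {OUT/'k_ti_correlation.csv'}")


if __name__ == "__main__":
    main()
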