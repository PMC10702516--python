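"""Summarize the effect table: sign, significance, and scale dependence.

Reads results/effects.csv (from 04_fit_sar_models.py) and writes a compact
per-metric/per-scale summary; optionally draws a forest-style figure of the
percentage differences to scratch/figures/.
"""

from pathlib import Path

import pandas as pd

SEED = 1
ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    eff = pd.read_csv(ROOT / "results" / "effects.csv")
    summary = (eff.assign(negative=eff["beta1"] < 0,
                          significant=eff["p"] < 0.05)
               .groupby(["metric", "scale"])
               .agg(n=("pct_diff", "size"), negative=("negative", "sum"),
                    significant=("significant", "sum"),
                    median_pct=("pct_diff", "median"))
               .round(3).reset_index())
    summary.to_csv(ROOT / "results" / "effect_summary.csv", index=False)
    print(summary.to_string(index=False))
    print(f"\noverall: {(eff['beta1'] < 0).mean():.1%} of greenspace "
          f"coefficients negative; {(eff['p'] < 0.05).mean():.1%} significant "
          f"at the 5% level")

    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 3, figsize=(13, 6), sharey=True)
        scales = ["point", "100 m", "300 m", "500 m", "1000 m", "2000 m"]
        for ax, metric in zip(axes, ("gvi", "ndvi", "ratio")):
            sub = eff[eff["metric"] == metric]
            for i, p in enumerate(sub["pollutant"].unique()):
                s = sub[sub["pollutant"] == p].set_index("scale").reindex(scales)
                x = range(len(scales))
                ax.errorbar([v + i * 0.12 for v in x], s["pct_diff"],
                            yerr=[s["pct_diff"] - s["ci_low"],
                                  s["ci_high"] - s["pct_diff"]],
                            fmt="o", ms=3, capsize=2, label=p)
            ax.axhline(0, color="k", lw=0.5)
            ax.set_xticks(range(len(scales)), scales, rotation=45)
            ax.set_title(metric.upper())
        axes[0].set_ylabel("% difference per IQR")
        axes[0].legend(fontsize=8)
        figdir = ROOT / "scratch" / "figures"
        figdir.mkdir(parents=True, exist_ok=True)
        fig.tight_layout()
        fig.savefig(figdir / "effects_forest.png", dpi=150)
        print(f"figure -> {figdir / 'effects_forest.png'}")
    except ImportError:
        print("matplotlib not available; skipping the figure")


if __name__ == "__main__":
    main()
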