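"""Build the growth-chart table and figure indexed by weight at day 0.

The spreadsheet-friendly face of the model: one reference curve per P0
from 100 to 1,000 g over days 0-21, exported as CSV and as a plot.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

import puppygrowth as pg

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    p0s = [100, 150, 200, 300, 400, 500, 700, 1000]
    table = pg.growth_chart_table(p0s, 0, 21)
    RESULTS.mkdir(exist_ok=True)
    pg.export_chart_csv(table, RESULTS / "growth_chart.csv")

    fig, ax = plt.subplots(figsize=(7, 5))
    for col in table.columns:
        ax.plot(table.index, table[col], lw=1.2)
        ax.annotate(f"{col.split('_')[1]} g", (21.2, table[col].iloc[-1]),
                    fontsize=7, va="center")
    ax.set_xlim(0, 24)
    ax.set_xlabel("days since birth")
    ax.set_ylabel("weight (g)")
    ax.set_title("Maximum-growth curves by weight at day 0")
    fig.tight_layout()
    fig.savefig(RESULTS / "growth_chart.png", dpi=150)
    print(f"wrote growth chart for P0 in {p0s} g -> results/growth_chart.csv/.png")


if __name__ == "__main__":
    main()
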