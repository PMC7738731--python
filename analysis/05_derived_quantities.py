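"""Scalar quantities the growth law implies for husbandry guidance.

Relative daily gain at the window ends, the mean rate over the first three
weeks, doubling times with and without an early setback, and the setback-
adjusted P0 fractions for the classic scenarios (no gain in 24 h; 20% loss
by 48 h).
"""

import json
from pathlib import Path

import puppygrowth as pg

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    p02 = pg.setback_adjusted_p0(1.0, 1)   # stagnant first day
    p03 = pg.setback_adjusted_p0(0.8, 2)   # 20% loss by day 2
    out = {
        "relative_daily_gain_day0_pct": round(100 * pg.relative_daily_gain(0), 1),
        "relative_daily_gain_day21_pct": round(100 * pg.relative_daily_gain(21), 1),
        "mean_relative_daily_gain_0_21": round(pg.mean_relative_daily_gain(0, 21), 3),
        "doubling_time_days": round(pg.time_to_multiple(2.0), 1),
        "setback_p0_fraction_no_gain_24h": round(p02, 4),
        "setback_p0_fraction_20pct_loss_48h": round(p03, 4),
        "doubling_time_after_no_gain_24h": round(
            pg.time_to_multiple(2.0, start_ratio=p02), 1
        ),
        "doubling_time_after_20pct_loss_48h": round(
            pg.time_to_multiple(2.0, start_ratio=p03), 1
        ),
    }
    RESULTS.mkdir(exist_ok=True)
    with open(RESULTS / "derived_quantities.json", "w") as fh:
        json.dump(out, fh, indent=2)
    for k, v in out.items():
        print(f"{k}: {v}")


if __name__ == "__main__":
    main()
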