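"""Aggregate epoch-level accelerometer streams into wave-level activity.

Runs a small epoch-bearing cohort (10 wearers, 14-day desk wear period) so
the full measurement chain — MET categorization, daily summaries, weekly
averages, wave extraction — is exercised end to end, and reports how closely
the aggregated wave-1 totals recover the generating panel targets.  Bulky
epoch streams stay under scratch/.
"""

from pathlib import Path

import pandas as pd

from riclpm.pipeline import RunConfig, run_pipeline

OUT = Path("results/analysis")


def main() -> None:
    cfg = RunConfig.from_dict({
        "seed": 1,
        "out_dir": "scratch/analysis_epochs",
        "include_epochs": True,
        "cohort": {
            "n_assessed": 12, "n_died": 0, "n_questionnaire_completers": 12,
            "n_no_accelerometer": 2, "wear_days": 14,
            "epoch_missing_rate": 0.144,
        },
    })
    res = run_pipeline(cfg, stages=("simulate", "aggregate"))
    wave_pa = res["wave_pa"]
    panel = res["dataset"].panel

    OUT.mkdir(parents=True, exist_ok=True)
    wave_pa.to_csv(OUT / "wave_pa_from_epochs.csv", index=False)

    merged = wave_pa[wave_pa["wave"] == 1].merge(
        panel[panel["wave"] == 1], on=["patient_id", "wave"],
        suffixes=("_agg", "_panel"),
    )
    err = (merged["pa_total_agg"] - merged["pa_total_panel"]).abs()
    print(f"wave-1 totals recovered for {len(merged)} wearers")
    print("aggregated vs panel total PA (min/day):")
    print(merged[["patient_id", "pa_total_agg", "pa_total_panel"]].round(2)
          .to_string(index=False))
    print(f"\nmax abs deviation: {err.max():.2f} min/day "
          "(epoch-level missingness at 14.4% removes active epochs, so "
          "aggregated totals sit slightly below the generating targets)")


if __name__ == "__main__":
    main()
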