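"""Validate the risk models on the synthetic cohort.

Fits the intercept-only recalibration and the combined (prescreening +
image) model, produces 8-fold out-of-fold risks, and reports discrimination
(AUC with bootstrap optimism adjustment for the refit models) and mean
calibration (expected/observed ratio with its lognormal 95% CI), alongside
the precomputed comparator risk.  Writes results/validation/table2.csv.
"""

from _common import RESULTS, SYNTHETIC_CSV, load_synthetic_cohort

from lunginterval import RunConfig, run_pipeline


def main() -> None:
    load_synthetic_cohort()  # ensures the shared cohort exists
    config = RunConfig(
        input_csv=str(SYNTHETIC_CSV),
        model_kinds=["recalibrated", "combined", "comparator"],
        k=8,
        n_boot=200,
        seed=1,
        output_dir=str(RESULTS / "validation"),
    )
    bundle = run_pipeline(config)

    for row in bundle["table2"]:
        adj = row["optimism_adjusted_auc"]
        adj_text = f", optimism-adjusted {adj}" if adj != "" else ""
        print(
            f"{row['model']:>12}: AUC {row['auc']}{adj_text}; "
            f"E/O {row['expected']}/{row['observed']} = {row['eo_ratio']} "
            f"({row['eo_ci_low']}-{row['eo_ci_high']})"
        )
    print(f"\nwrote {RESULTS / 'validation' / 'table2.csv'}")


if __name__ == "__main__":
    main()
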