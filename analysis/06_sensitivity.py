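"""Sensitivity analyses: one screen per person, and Lung-RADS 2 only.

Repeats the validation and assignment analysis (i) keeping a single
randomly chosen screen per person, removing within-person repetition, and
(ii) restricted to screens with a Lung-RADS category of exactly 2 — the
screens a guideline policy would already place on an annual interval.
Writes results/sensitivity_one_screen/ and results/sensitivity_lungrads2/.
"""

from _common import RESULTS, SYNTHETIC_CSV, load_synthetic_cohort

from lunginterval import RunConfig, run_pipeline


def main() -> None:
    load_synthetic_cohort()
    for name, flags in (
        ("sensitivity_one_screen", {"one_screen_only": True}),
        ("sensitivity_lungrads2", {"lungrads2_only": True, "lungrads_table": False}),
    ):
        config = RunConfig(
            input_csv=str(SYNTHETIC_CSV),
            model_kinds=["recalibrated", "comparator"],
            k=8,
            seed=4,
            output_dir=str(RESULTS / name),
            **flags,
        )
        bundle = run_pipeline(config)
        print(f"{name}: {bundle['n_screens']} screens, {bundle['n_cancers']} cancers")
        for row in bundle["table2"]:
            print(
                f"  {row['model']:>12}: AUC {row['auc']}, E/O {row['eo_ratio']}, "
                f"risk at 80% assigned = {row['risk_pct_at_80']}%"
            )


if __name__ == "__main__":
    main()
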