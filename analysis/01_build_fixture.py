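"""Expand the published Lung-RADS x outcome counts into an exact cohort.

Writes results/fixture_cohort.csv: 10,831 screens (195 cancers, 10,636
benign) whose per-category counts match the published characteristics table.
This fixture drives the guideline-comparator analysis (02), which depends
only on categories and outcomes.
"""

from _common import FIXTURE_CSV, RESULTS

from lunginterval import LungRadsCategory, table1_fixture, write_cohort


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    fixture = table1_fixture()
    write_cohort(fixture, FIXTURE_CSV)

    print(f"wrote {FIXTURE_CSV} ({len(fixture)} screens, {fixture.n_cases} cancers)")
    print(f"{'Lung-RADS':>10}  cancer  benign")
    for cat in LungRadsCategory:
        recs = [r for r in fixture if r.lung_rads is cat]
        n_cancer = sum(r.outcome for r in recs)
        print(f"{cat.label:>10}  {n_cancer:6d}  {len(recs) - n_cancer:6d}")


if __name__ == "__main__":
    main()
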