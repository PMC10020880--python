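"""Shared paths and cohort loading for the numbered analysis drivers."""

from pathlib import Path

from lunginterval import SyntheticConfig, generate_cohort, read_cohort, write_cohort

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"

# Study conditions: cohort of the published size, ~1.8% outcome prevalence,
# image score at AUC 0.87, comparator at 0.79.
DEFAULT_CONFIG = SyntheticConfig(n_screens=10_831, seed=12)
SYNTHETIC_CSV = RESULTS / "synthetic_cohort.csv"
FIXTURE_CSV = RESULTS / "fixture_cohort.csv"


def load_synthetic_cohort():
    """Read the shared synthetic cohort, generating it if 03 has not run."""
    RESULTS.mkdir(exist_ok=True)
    if not SYNTHETIC_CSV.exists():
        write_cohort(generate_cohort(DEFAULT_CONFIG), SYNTHETIC_CSV)
    return read_cohort(SYNTHETIC_CSV)
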