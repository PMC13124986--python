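"""Shared study conditions for the numbered analysis drivers.

The synthetic study bundle emulates an antidepressant safety cohort: one
target drug among 20, suicide-related and gastrointestinal preferred terms
planted at the relative reporting rates seen in real vortioxetine signal
tables, 10% of cases submitted in multiple versions, and an early-failure
Weibull onset profile (shape 0.58, scale 30 days, median ~16 days).

Bulk data land in scratch/ (regenerated on demand); the drivers write only
small summary tables under results/.
"""

from pathlib import Path

from pvsignal import SimulationConfig
from pvsignal.synthetic import simulate_to_directory

ROOT = Path(__file__).resolve().parent.parent
BUNDLE_DIR = ROOT / "scratch" / "analysis_bundle"
RESULTS_DIR = ROOT / "results"

QUARTERS = ("2014Q1", "2014Q2", "2014Q3", "2014Q4")

# (drug, event) -> planted relative reporting rate; drug 0 is the target.
# Events 0-4 are the suicide-related PTs, 12/13 nausea/vomiting.
PLANTED_RR = {
    (0, 0): 20.0,   # Suicidal ideation
    (0, 1): 7.0,    # Suicide attempt
    (0, 2): 4.7,    # Completed suicide
    (0, 3): 13.6,   # Suicidal behaviour
    (0, 4): 15.5,   # Suicide threat
    (0, 12): 5.0,   # Nausea
    (0, 13): 3.2,   # Vomiting
}

# Suicide-related PTs are rare in the background (~0.15% baseline each, so
# the planted 20x pair reaches the ~6% within-cohort share seen for the top
# suicide PT in real antidepressant cohorts); nausea is the most common
# event; the rest share the remainder evenly.
_weights = [0.0015] * 7 + [0.02] * 5 + [0.10, 0.06] + [0.0] * 16
_rest = (1.0 - sum(_weights)) / 16
BASELINE_EVENT_PROBS = tuple(w if w > 0 else _rest for w in _weights)

STUDY_CONFIG = SimulationConfig(
    n_reports=20_000,
    n_drugs=20,
    n_events=30,
    baseline_event_probs=BASELINE_EVENT_PROBS,
    planted_rr=PLANTED_RR,
    duplicate_rate=0.10,
    onset_shape=0.58,
    onset_scale_days=30.0,
    quarters=QUARTERS,
    seed=20_140_101,
)


def ensure_bundle() -> Path:
    """Create the study bundle if it is not already on disk."""
    if not (BUNDLE_DIR / "ground_truth.json").exists():
        simulate_to_directory(STUDY_CONFIG, BUNDLE_DIR)
    RESULTS_DIR.mkdir(exist_ok=True)
    return BUNDLE_DIR
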