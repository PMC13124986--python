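"""Generate the synthetic FAERS-style study bundle.

Emits the five quarterly ASCII tables (DEMO/DRUG/REAC/OUTC/THER), the
PT->SOC map, the drug-synonym and suicide-PT lists, and the ground-truth
sidecar used by every later driver to validate its stage.
"""

from _common import BUNDLE_DIR, STUDY_CONFIG, ensure_bundle

from pvsignal.synthetic import GroundTruth


def main() -> None:
    ensure_bundle()
    truth = GroundTruth.from_json(BUNDLE_DIR / "ground_truth.json")
    n_versions = sum(len(v) for v in truth.duplicate_map.values())
    print(f"bundle: {BUNDLE_DIR}")
    print(f"cases simulated:        {STUDY_CONFIG.n_reports:>7,}")
    print(f"report versions emitted:{n_versions:>7,} "
          f"({truth.n_extra_versions:,} duplicates to be removed)")
    print(f"target-drug PS cases:   {len(truth.target_case_ids):>7,}")
    print(f"planted signal pairs:   {len(truth.true_rr):>7}")
    print(f"true onset shape/scale: {truth.true_onset_shape} / "
          f"{truth.true_onset_scale_days} days")


if __name__ == "__main__":
    main()
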