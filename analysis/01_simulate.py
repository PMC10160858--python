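#!/usr/bin/env python
"""Generate the synthetic study datasets used by the downstream analyses.

Writes a child-like study (7 broad causes, 1,589 survey deaths, two CCVA
algorithms, 56 reference-standard deaths per cause) and a neonate-like study
(5 causes, 632 survey deaths, 90 per cause) under results/data/, each as
unpaired.csv, paired.csv and truth.csv. Ground truth is known, so the later
scripts can measure how well calibration recovers it.
"""
from pathlib import Path

from vacalib import preset_scenarios, generate
from vacalib.synthetic_data import write_scenario_outputs

OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    for preset in ("child_like", "neonate_like"):
        scenario = preset_scenarios(preset)
        unpaired, paired, truth = generate(scenario)
        paths = write_scenario_outputs(unpaired, paired, truth, OUT / preset)
        print(
            f"{preset}: {len(unpaired)} unpaired deaths, {len(paired)} paired "
            f"deaths across {scenario.causes.C} causes -> {paths['unpaired'].parent}"
        )
        print(f"  true CSMF: {dict(zip(scenario.causes.labels, scenario.p_true.p))}")


if __name__ == "__main__":
    main()
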