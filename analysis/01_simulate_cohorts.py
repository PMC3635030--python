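#!/usr/bin/env python
"""Generate the two synthetic study cohorts and write their tables.

Cohort A (binary): 26 young (19-35) + 26 old (55-85) subjects, 3 scans
each, 100 ROIs.  Cohort B (three-group / regression): 28 young + 22
middle-aged + 15 old = 65 subjects.  Both plant 50 informative ROI-pair
edges whose Fisher-z connectivity changes linearly with age, with the
slope calibrated so the binary groups differ by a subject-level Cohen's d
of 1.5.  Writes subject, truth and per-scan connectome tables under
scratch/cohorts/ — the tables are bulky and fully regenerable from the
seed, and the downstream analysis scripts regenerate the cohorts directly.
"""

from pathlib import Path

from connage.synthetic import (edge_effect_for_cohens_d, generate_cohort,
                               three_group_spec, young_old_spec)

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "scratch" / "cohorts"

SEED_BINARY = 11
SEED_THREE = 21


def main() -> None:
    beta = edge_effect_for_cohens_d(young_old_spec(), 1.5)
    print(f"planted edge slope: {beta:.4f} z-units per decade "
          "(Cohen's d = 1.5 between young and old)")

    binary = generate_cohort(young_old_spec(edge_effect=beta,
                                            seed=SEED_BINARY))
    binary.write(OUT / "binary")
    print(f"binary cohort: {len(binary.subjects)} subjects, "
          f"{len(binary.scans)} scans -> {OUT / 'binary'}")

    three = generate_cohort(three_group_spec(edge_effect=beta,
                                             seed=SEED_THREE))
    three.write(OUT / "three_group")
    print(f"three-group cohort: {len(three.subjects)} subjects, "
          f"{len(three.scans)} scans -> {OUT / 'three_group'}")


if __name__ == "__main__":
    main()
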