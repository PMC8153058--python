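#!/usr/bin/env python
"""Button-response check: distance effect vs shared-button structure.

In the compare task, numerosities 2 and 4 share a response button and 6
and 8 share the other, so motor-plan decoding would confuse within-button
pairs.  A numerical distance effect instead predicts confusions that
decline with distance.  This script regresses each participant's
compare-task confusion rates (targets 4 and 6) on numerical distance and a
shared-button indicator, then tests both coefficients across participants.
Writes results/06_button_check/.
"""

from pathlib import Path

from numdecode import (
    apply_selection, decode, distance_button_model, select_voxels,
    simulate_cohort, znormalize_trials,
)

from importlib import import_module
sim = import_module("01_simulate")

OUT = Path("results/06_button_check")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort(sim.COHORT, roi_names=("L_parietal",))
    confusions = {}
    for pid in cohort.participants:
        raw = cohort.patterns[(pid, "L_parietal")]
        ds = apply_selection(znormalize_trials(raw),
                             select_voxels(raw.voxel_tstats, 120))
        confusions[pid] = decode(ds, {"task": "compare"}, max_folds=150,
                                 seed=0)
    res = distance_button_model(confusions)
    res.coefficients.to_csv(OUT / "coefficients.csv", index=False)
    print(f"distance effect:  t({res.df}) = {res.distance_t:6.2f}, "
          f"p = {res.distance_p:.4f}")
    print(f"button effect:    t({res.df}) = {res.button_t:6.2f}, "
          f"p = {res.button_p:.4f}")
    if res.distance_p < 0.05 and res.button_p > 0.05:
        print("confusions follow numerical distance, not the button "
              "mapping: the decoder is reading numerosity, not motor "
              "plans")
    elif res.distance_p < 0.05:
        print("distance effect present; note the generator has no motor "
              "component, so a residual button loading here reflects the "
              "linear-distance regressor approximating the generator's "
              "log-spaced tuning (2-4 confusions exceed 6-8 confusions), "
              "not response coding")


if __name__ == "__main__":
    main()
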