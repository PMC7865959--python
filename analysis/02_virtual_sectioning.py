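#!/usr/bin/env python
"""Section a 190 um^3 synthetic neuropil into 75 virtual micrographs.

Builds the reference block (2.0 synapses/um^3), cuts 75 random 5 x 5 um
fields of 65 nm slabs (~1900 um^2 of sampled neuropil), writes the 2D
profile table and the 3D ground-truth table, and reports how the sectioned
measurements compare with the underlying population (profile counts, PSD
vs SAL lengths, the 2D underestimation of head size).
"""

import json
from pathlib import Path

import numpy as np

from spinestereo import geometry
from spinestereo.experiment import run_density_experiment
from spinestereo.io import write_profile_table, write_spine_table
from spinestereo.stats import summarize

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    exp = run_density_experiment(seed=SEED)
    write_spine_table(exp.volume.spines, OUT / "scene_spines_3d.csv")
    write_profile_table(exp.profiles, OUT / "scene_profiles_2d.csv")
    exp.config.to_yaml(OUT / "scene_config.yaml")

    prof = exp.profiles
    areas = np.array([p.head_area for p in prof])
    psd = np.array([p.psd_length for p in prof])
    sal = np.array([p.sal_length for p in prof])
    heads = [s for s in exp.volume.spines if s.is_head]
    mean_v = float(np.mean([s.head_volume for s in heads]))

    report = {
        "n_micrographs": len(exp.micrographs),
        "total_area_um2": exp.total_area,
        "n_profiles": len(prof),
        "profile_area": summarize(areas, "head_area_2d", "um2").__dict__,
        "psd_length": summarize(psd, "psd_length", "um").__dict__,
        "sal_length": summarize(sal, "sal_length", "um").__dict__,
        "mean_true_volume_um3": mean_v,
        "equiv_area_of_mean_true_volume_um2": geometry.volume_to_equivalent_area(mean_v),
    }
    (OUT / "sectioning_report.json").write_text(json.dumps(report, indent=2) + "\n")
    print(
        f"{len(prof)} profiles on {len(exp.micrographs)} micrographs "
        f"({exp.total_area:.0f} um^2): <area>={areas.mean():.3f} um^2 vs "
        f"equivalent area of mean true volume "
        f"{report['equiv_area_of_mean_true_volume_um2']:.3f} um^2 "
        f"(2D underestimates); <PSD_L>={psd.mean():.3f} um <= <SAL>={sal.mean():.3f} um"
    )
    print(f"wrote {OUT / 'sectioning_report.json'}")


if __name__ == "__main__":
    main()
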