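#!/usr/bin/env python
"""2D-vs-3D morphometry: summaries, frequency curves, correlations, tests.

On the reference sectioned block, compares the spine-head measurements the
two modalities deliver once placed on a common scale with the sphere/disc
conversions: PSD_S and SAL_S (disc areas of the sectioned lengths) against
the 3D SAS; measured 2D head profile areas against the equivalent areas of
the 3D volumes; and 2D-derived volumes against the true ones. Writes the
summary tables, fixed-bin frequency curves, the Spearman correlation
matrix, and the between-modality tests; draws the distribution-curve
figures when matplotlib is available.
"""

import dataclasses
import json
from pathlib import Path

import numpy as np

from spinestereo import geometry
from spinestereo.experiment import run_density_experiment
from spinestereo.stats import (
    AREA_BINS,
    LENGTH_BINS,
    VOLUME_BINS,
    compare_groups,
    frequency_curve,
    spearman,
    summarize,
)

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    exp = run_density_experiment(seed=SEED)
    prof = exp.profiles
    heads = [s for s in exp.volume.spines if s.is_head]

    psd_l = np.array([p.psd_length for p in prof])
    sal_l = np.array([p.sal_length for p in prof])
    a2d = np.array([p.head_area for p in prof])
    v3d = np.array([s.head_volume for s in heads])
    sas = np.array([s.sas_area for s in heads])
    psd_s = geometry.length_to_disc_area(psd_l)
    sal_s = geometry.length_to_disc_area(sal_l)
    a3d = geometry.volume_to_equivalent_area(v3d)
    v2d = geometry.area_to_equivalent_volume(a2d)

    variables = {
        "psd_length_um": psd_l, "sal_length_um": sal_l,
        "psd_s_um2": psd_s, "sal_s_um2": sal_s, "sas_um2": sas,
        "head_area_2d_um2": a2d, "head_area_from_3d_um2": a3d,
        "head_volume_from_2d_um3": v2d, "head_volume_3d_um3": v3d,
    }
    summaries = {k: dataclasses.asdict(summarize(v, k)) for k, v in variables.items()}

    curves = {
        "lengths": {
            "bins_um": LENGTH_BINS.edges.tolist(),
            "psd_l": frequency_curve(psd_l, LENGTH_BINS).tolist(),
            "sal": frequency_curve(sal_l, LENGTH_BINS).tolist(),
        },
        "contact_areas": {
            "bins_um2": AREA_BINS.edges.tolist(),
            "psd_s": frequency_curve(psd_s, AREA_BINS).tolist(),
            "sal_s": frequency_curve(sal_s, AREA_BINS).tolist(),
            "sas": frequency_curve(sas, AREA_BINS).tolist(),
        },
        "head_areas": {
            "bins_um2": AREA_BINS.edges.tolist(),
            "area_2d": frequency_curve(a2d, AREA_BINS).tolist(),
            "area_from_3d": frequency_curve(a3d, AREA_BINS).tolist(),
        },
        "head_volumes": {
            "bins_um3": VOLUME_BINS.edges.tolist(),
            "volume_from_2d": frequency_curve(v2d, VOLUME_BINS).tolist(),
            "volume_3d": frequency_curve(v3d, VOLUME_BINS).tolist(),
        },
    }

    correlations = {
        "sal_vs_psd_l_2d": spearman(sal_l, psd_l),
        "sas_vs_volume_3d": spearman(sas, v3d),
        "area_vs_psd_l_2d": spearman(a2d, psd_l),
        "area_vs_sal_2d": spearman(a2d, sal_l),
    }
    tests = {
        "head_area_2d_vs_3d": dataclasses.asdict(compare_groups(a2d, a3d)),
        "contact_psd_s_vs_sal_s_vs_sas": dataclasses.asdict(
            compare_groups(psd_s, sal_s, sas)
        ),
    }

    report = {"summaries": summaries, "frequency_curves": curves,
              "spearman": correlations, "tests": tests}
    (OUT / "morphometry_comparison.json").write_text(json.dumps(report, indent=2) + "\n")
    print(
        f"<PSD_S>={psd_s.mean():.3f} < <SAL_S>={sal_s.mean():.3f} um^2 "
        f"(3D <SAS>={sas.mean():.3f}); <A>2D={a2d.mean():.3f} < <A>3D={a3d.mean():.3f} um^2; "
        f"<V>2D={v2d.mean():.3f} < <V>3D={v3d.mean():.3f} um^3"
    )
    print(
        f"Spearman: SAL~PSD_L={correlations['sal_vs_psd_l_2d']:.2f}, "
        f"SAS~V={correlations['sas_vs_volume_3d']:.2f}"
    )
    print(f"wrote {OUT / 'morphometry_comparison.json'}")

    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:
        return
    fig, axes = plt.subplots(2, 2, figsize=(10, 8))
    centers = lambda e: (np.asarray(e[:-1]) + np.asarray(e[1:])) / 2
    panels = [
        ("lengths", "bins_um", "length (um)", ["psd_l", "sal"]),
        ("contact_areas", "bins_um2", "contact area (um^2)", ["psd_s", "sal_s", "sas"]),
        ("head_areas", "bins_um2", "head area (um^2)", ["area_2d", "area_from_3d"]),
        ("head_volumes", "bins_um3", "head volume (um^3)", ["volume_from_2d", "volume_3d"]),
    ]
    for ax, (group, bk, xlabel, keys) in zip(axes.flat, panels):
        for k in keys:
            ax.plot(centers(curves[group][bk]), curves[group][k], marker="o", label=k)
        ax.set_xlabel(xlabel)
        ax.set_ylabel("relative frequency")
        ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(OUT / "figures_distributions.png", dpi=150)
    print(f"wrote {OUT / 'figures_distributions.png'}")


if __name__ == "__main__":
    main()
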