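"""Body-phantom study: planar vs SPECT sphere quantification.

Simulates the two-sphere + bowel-tube body phantom (posterior planar
statics and dual-head SPECT, MEGP and HEGP), then measures:

* the isocontour threshold table (50-80% of the sphere maximum) and the
  volume-matching calibration against the true 11.5 cm^3 sphere;
* the sphere-1/sphere-2 uptake ratio -- inflated on planar images by the
  overlapping tube, near 1 on SPECT;
* the sphere-to-background ratio (SBR) in both modalities;
* count-vs-concentration linearity over 3.75/7.5/15 kBq/mL.
"""

from pathlib import Path

from ra223spect.studies import StudyConfig, run_study_b


def main() -> None:
    report = run_study_b(StudyConfig(seed=1, n_replicates=5))
    out = report.save(Path("results"))

    m = report.tables["metrics"]
    med = m.groupby("collimator")[
        ["sbr_planar", "sbr_spect", "uptake_ratio_planar", "uptake_ratio_spect"]
    ].median()
    print("Median SBR and sphere-1/sphere-2 uptake ratios:")
    print(med.round(2).to_string())
    for coll, row in med.iterrows():
        print(
            f"{coll}: SPECT/planar SBR gain x{row.sbr_spect / row.sbr_planar:.2f}; "
            f"planar overlap inflates sphere 1 by "
            f"{100 * (row.uptake_ratio_planar - 1):.0f}% vs "
            f"{100 * (row.uptake_ratio_spect - 1):.0f}% on SPECT"
        )
    print(
        "Simulated threshold calibration selects "
        f"{report.provenance['chosen_threshold_pct']:.0f}% of maximum "
        "(volume tables in study_b_threshold_volumes.csv)"
    )
    print(report.tables["linearity_fits"].round(4).to_string(index=False))
    print(f"Tables written to {out}/study_b_*.csv")


if __name__ == "__main__":
    main()
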