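"""Cylinder-phantom image-quality study: energy windows and collimators.

Simulates SPECT of the hot-rod cylinder under four energy windows
(84 keV +/- 20%, 84 keV +/- 10%, 154 keV +/- 10%, 269 keV +/- 5%) with
the MEGP and HEGP collimators, reconstructs with OSEM (5 subsets, 10
iterations) + Butterworth (0.20 cycles/cm, order 10), and measures
Hr/BKG/HBR/CNR on 10 transaxial slices.  Wilcoxon, Friedman and
Steel-Dwass comparisons mirror the statistical protocol.

Expected outcome: the wide 84-keV window raises Hr, BKG and CNR while
leaving HBR nearly unchanged, and HEGP shows a lower BKG than MEGP at
every window.
"""

from pathlib import Path

from ra223spect.studies import StudyConfig, run_study_a


def main() -> None:
    report = run_study_a(StudyConfig(seed=1, n_replicates=10))
    out = report.save(Path("results"))

    m = report.tables["metrics"]
    medians = m.groupby(["collimator", "window"])[
        ["Hr", "BKG", "HBR", "CNR"]
    ].median()
    print("Median image-quality metrics per condition:")
    print(medians.round(3).to_string())

    for coll in ("MEGP", "HEGP"):
        wide = medians.loc[(coll, "84_20")]
        narrow = medians.loc[(coll, "84_10")]
        print(
            f"{coll}: widening 84 keV +/-10% -> +/-20% multiplies "
            f"Hr x{wide.Hr / narrow.Hr:.2f}, CNR x{wide.CNR / narrow.CNR:.2f}, "
            f"HBR x{wide.HBR / narrow.HBR:.2f}"
        )
    print(f"Tables written to {out}/study_a_*.csv")


if __name__ == "__main__":
    main()
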