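"""Synthetic clinical-correlation study.

Generates a cohort of synthetic bone-metastasis lesions (shared latent
uptake contrast plus independent per-tracer noise), images each lesion
with the Ra-223 model (MEGP and HEGP collimators, 84 keV +/- 20%) and a
high-count reference bone tracer, and compares the lesion-to-background
ratios: LBRme, LBRhe, LBRtc.

Reported: per-lesion LBR table, the Pearson correlations of LBRme/LBRhe
against LBRtc, and the paired-t comparison of the two Ra-223 collimators.
Lesions whose image maximum falls below twice the background reference
are excluded, mirroring the clinical inclusion rule.
"""

from pathlib import Path

from ra223spect.phantoms import LesionCohortSpec
from ra223spect.studies import StudyConfig, run_clinical_sim


def main() -> None:
    cfg = StudyConfig(seed=1, cohort=LesionCohortSpec(n_lesions=36))
    report = run_clinical_sim(cfg)
    out = report.save(Path("results"))

    t = report.tables["lbr"]
    included = t.dropna(subset=["LBRme", "LBRhe", "LBRtc"])
    print(
        f"{len(included)}/{len(t)} lesions pass the 2x-background inclusion "
        "rule for all three tracers"
    )
    print(included[["LBRme", "LBRhe", "LBRtc"]].describe().round(2).to_string())
    print((included.LBRhe > included.LBRme).mean().round(2),
          "fraction of lesions with LBRhe > LBRme")
    print(report.stats.round(4).to_string(index=False))
    print(f"Tables written to {out}/clinical_sim_*.csv")


if __name__ == "__main__":
    main()
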