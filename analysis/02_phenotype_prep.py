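#!/usr/bin/env python
"""Phenotype preparation and descriptive models.

Applies the duplicate-measurement selection rules (first reading for
baPWV/cfPWV, averaged readings for bfPWV, discard when the pair disagrees by
more than 5/10/25 m/s), log-transforms PWV and blood pressures, fits the
univariate descriptive regressions of each log-PWV mode on sex, age, SBP and
DBP, and reports the SBP-partialled cross-mode correlations.

Reads results/cohort/, writes results/phenotypes/.
"""

import os

import numpy as np

from stiffpipe import io, phenoprep

BASE = os.path.join(os.path.dirname(__file__), "..", "results")
OUT = os.path.join(BASE, "phenotypes")


def main() -> None:
    raw = io.read_phenotypes(os.path.join(BASE, "cohort", "phenotypes_raw.tsv"))
    clean = phenoprep.select_measurements(raw)
    clean = phenoprep.log_transform(clean, list(phenoprep.PWV_MODES) + ["SBP", "DBP"])
    io.ensure_dir(OUT)
    io.write_phenotypes(os.path.join(OUT, "phenotypes_clean.tsv"), clean)

    print("measurement selection:")
    for mode in phenoprep.PWV_MODES:
        print(f"  {mode}: {clean[mode].isna().mean():.1%} discarded/missing")

    desc = phenoprep.fit_descriptive_models(
        clean,
        [f"log{m}" for m in phenoprep.PWV_MODES],
        ["sex", "age", "logSBP", "logDBP"],
    )
    desc.to_csv(os.path.join(OUT, "descriptive_models.tsv"), sep="\t", index=False)
    print("univariate models (slope / adj R2):")
    for rec in desc.itertuples(index=False):
        print(f"  {rec.outcome} ~ {rec.covariate}: {rec.slope:+.4f} / {rec.adj_r2:.3f}")

    z = np.column_stack([clean["logSBP"], clean["age"], clean["sex"]])
    print("cross-mode partial correlations given SBP, age, sex:")
    pairs = (("baPWV", "cfPWV"), ("baPWV", "bfPWV"), ("cfPWV", "bfPWV"))
    with open(os.path.join(OUT, "partial_correlations.tsv"), "w") as fh:
        fh.write("mode_a\tmode_b\tpartial_r\n")
        for a, b in pairs:
            mask = clean[f"log{a}"].notna() & clean[f"log{b}"].notna()
            pc = phenoprep.partial_correlation(
                clean.loc[mask, f"log{a}"], clean.loc[mask, f"log{b}"], z[mask.to_numpy()]
            )
            fh.write(f"{a}\t{b}\t{pc:.4f}\n")
            print(f"  {a} / {b}: {pc:.3f}")


if __name__ == "__main__":
    main()
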