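#!/usr/bin/env python
"""LD-score-regression heritability, QC gates and genetic correlation.

Two analyses at two scales:

1. cohort scale — LD scores from the simulated dosages (1 Mb window) and
   heritability of each PWV mode from the sex/age-adjusted scans.  At n =
   2,000 x 2,000 variants the jackknife SEs are wide; the QC gates
   (z > 1.5, mean chi2 > 1.02, intercept in (0.9, 1.1)) decide which modes
   support interpretation, exactly as they would on real data.
2. recovery scale — summary statistics simulated directly from the
   polygenic model at M = 20,000, N = 6,000 with true h2 = 0.28 and genetic
   correlation 0.27, showing the estimator recovers both within its
   uncertainty.

Reads results/cohort/ and results/gwas/, writes results/ldsc/.
"""

import json
import os

from stiffpipe import io, ldsc, phenoprep, synthdata

BASE = os.path.join(os.path.dirname(__file__), "..", "results")
OUT = os.path.join(BASE, "ldsc")


def main() -> None:
    dosages, variants, _ = io.read_dosages(os.path.join(BASE, "cohort", "dosages.tsv"))
    io.ensure_dir(OUT)
    scores = ldsc.compute_ld_scores(dosages, variants)
    scores.to_csv(os.path.join(OUT, "ld_scores.tsv"), sep="\t", index=False)
    M = int(scores["ld_score"].notna().sum())
    print(f"LD scores for {M} variants (mean {scores['ld_score'].mean():.2f})")

    cohort = {}
    for mode in phenoprep.PWV_MODES:
        scan = io.read_sumstats(os.path.join(BASE, "gwas", f"sumstats_{mode}_basic.tsv"))
        scan = scan.dropna(subset=["beta", "se"])
        res = ldsc.ldsc_h2(scan, scores, N=int(scan["n"].median()), M=M)
        cohort[mode] = res.as_dict()
        gates = "pass" if res.qc_pass else "fail"
        print(
            f"  {mode}: h2 = {res.h2:.3f} +/- {res.h2_se:.3f}, intercept {res.intercept:.3f}, "
            f"mean chi2 {res.mean_chi2:.3f} -> QC {gates}"
        )

    sim = synthdata.simulate_polygenic_sumstats(M=20_000, N=6_000, h2=0.28, rg=0.27, seed=60)
    h2_res = ldsc.ldsc_h2(sim["sumstats"][0], sim["ld_scores"], N=6_000, M=20_000)
    rg_res = ldsc.ldsc_rg(sim["sumstats"][0], sim["sumstats"][1], sim["ld_scores"], N1=6_000, N2=6_000, M=20_000)
    print(
        f"recovery at M = 20,000: h2 = {h2_res.h2:.3f} +/- {h2_res.h2_se:.3f} (true 0.28); "
        f"rg = {rg_res['rg']:.3f} +/- {rg_res['se']:.3f} (true 0.27)"
    )
    with open(os.path.join(OUT, "ldsc_results.json"), "w") as fh:
        json.dump(
            {
                "cohort": cohort,
                "recovery": {"h2": h2_res.as_dict(), "rg": {k: v for k, v in rg_res.items() if k not in ("h2_1", "h2_2")}},
            },
            fh,
            indent=2,
        )


if __name__ == "__main__":
    main()
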