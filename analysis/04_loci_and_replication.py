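#!/usr/bin/env python
"""Priority pruning, locus definition and candidate replication.

Prunes the suggestive signals (p < 1e-6, tagging at r2 >= 0.5) to
independent lead SNPs, defines the +/-500 kb loci around them, and runs two
replication analyses: the synthetic cohort's planted candidates against the
local scans, and the packaged panel of 14 published PWV SNPs with its
recorded cohort statistics (the Bonferroni rule p < 0.05/3 gives 7
replications there).

Reads results/cohort/ and results/gwas/, writes results/loci/.
"""

import os

import pandas as pd

from stiffpipe import io, loci, phenoprep, replication

BASE = os.path.join(os.path.dirname(__file__), "..", "results")
OUT = os.path.join(BASE, "loci")
SUGGESTIVE_P = 1e-6


def main() -> None:
    dosages, variants, _ = io.read_dosages(os.path.join(BASE, "cohort", "dosages.tsv"))
    scans = {
        m: io.read_sumstats(os.path.join(BASE, "gwas", f"sumstats_{m}.tsv"))
        for m in phenoprep.PWV_MODES
    }
    io.ensure_dir(OUT)

    best = pd.concat(scans.values()).dropna(subset=["p"]).groupby("variant_id", as_index=False)["p"].min()
    best = best.merge(variants[["variant_id", "chrom", "pos"]], on="variant_id")
    sugg = best[best["p"] < SUGGESTIVE_P]
    if len(sugg):
        mask = variants["variant_id"].isin(sugg["variant_id"]).to_numpy()
        ld = loci.ld_matrix(dosages[:, mask], variants.loc[mask, "variant_id"].tolist())
        leads, tags = loci.priority_prune(sugg, ld, 0.5)
    else:
        leads, tags = [], {}
    print(f"{len(sugg)} suggestive SNPs -> {len(leads)} independent leads: {leads}")

    locus_list = loci.define_loci(leads, variants, 500_000)
    table = pd.DataFrame(
        [
            {"chrom": l.chrom, "start": l.start, "end": l.end, "lead": l.lead,
             "n_members": len(l.members), "members": ",".join(l.members)}
            for l in locus_list
        ]
    )
    io.write_loci(os.path.join(OUT, "loci.tsv"), table)
    for l in locus_list:
        print(f"  locus {l.chrom}:[{l.start}, {l.end}] lead {l.lead} ({len(l.members)} members)")

    # synthetic candidates: the planted direct-effect SNPs
    truth = pd.read_csv(os.path.join(BASE, "cohort", "ground_truth_effects.tsv"), sep="\t")
    planted = truth[truth["phenotype"].isin(phenoprep.PWV_MODES) & (truth["beta"].abs() >= 0.04)]
    cands = pd.DataFrame(
        {
            "variant_id": planted["variant_id"],
            "reported_EA": "A",
            "reported_beta": planted["beta"],
            "reported_p": 1e-7,
            "reported_phenotype": planted["phenotype"],
            "inverted_phenotype": False,
        }
    )
    results, count = replication.test_replication(cands, scans)
    results.to_csv(os.path.join(OUT, "replication_synthetic.tsv"), sep="\t", index=False)
    print(f"synthetic candidates: {count} of {len(cands)} planted effects replicate at p < 0.05/3")

    panel = replication.load_candidate_panel()
    panel_results, panel_count = replication.test_replication(panel)
    panel_results.to_csv(os.path.join(OUT, "replication_published.tsv"), sep="\t", index=False)
    print(f"published panel: {panel_count} of {len(panel)} candidates replicate at p < 0.05/3")


if __name__ == "__main__":
    main()
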