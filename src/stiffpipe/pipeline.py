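"""End-to-end orchestration: simulate -> prep -> QC -> GWAS -> downstream.

One :func:`run_pipeline` call executes every analysis stage on a (simulated
or provided) cohort and writes per-stage outputs plus a JSON manifest with
the configuration, seeds, input hashes and stage summaries.  Reruns with the
same seeds are bit-reproducible.

Two covariate sets are carried through the scan: the primary PWV model
adjusts for sex, age and log-SBP (so blood-pressure-driven SNPs do not
masquerade as stiffness SNPs), while the heritability and Mendelian-
randomization stages use the sex/age-adjusted scan — the exposure must not
be conditioned away when SBP is the exposure of interest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import assoc, enrichment, io, ldsc, loci, mr, phenoprep, replication, synthdata

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]

PWV_MODES = phenoprep.PWV_MODES


@dataclass
class RunConfig:
    """Pipeline configuration with the standard significance conventions."""

    out_dir: str = "stiffpipe_run"
    seed: int = 0

    # stage inputs; when dosage_file is None a cohort is simulated
    dosage_file: str | None = None
    phenotype_file: str | None = None
    candidate_file: str | None = None

    # simulation scale (used when simulating)
    n_samples: int = 2_000
    n_variants: int = 2_000

    # thresholds
    genome_wide_p: float = 5e-8
    suggestive_p: float = 1e-6
    nominal_p: float = 0.05
    bonferroni_divisor: int = 3
    prune_r2: float = 0.5
    instrument_ld_r2: float = 0.1
    locus_window: int = 500_000
    permutations: int = 200

    covariates: list[str] = field(default_factory=lambda: ["sex", "age", "logSBP"])

    @property
    def bonferroni_p(self) -> float:
        return self.nominal_p / self.bonferroni_divisor

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for name in ("genome_wide_p", "suggestive_p", "nominal_p", "prune_r2", "instrument_ld_r2"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name}={v} outside (0, 1)")
        if self.permutations < 1:
            raise ValueError("permutations must be >= 1")
        for path in (self.dosage_file, self.phenotype_file, self.candidate_file):
            if path is not None and not os.path.exists(path):
                raise ValueError(f"input file not found: {path}")


def _hash_file(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns the manifest (also written as JSON)."""
    config.validate()
    out = io.ensure_dir(config.out_dir)
    manifest: dict = {"config": asdict(config), "stages": {}, "inputs": {}}
    completed: list[str] = []

    def _stage(name: str, summary: dict) -> None:
        manifest["stages"][name] = summary
        completed.append(name)
        logger.info("stage %s done: %s", name, summary)

    try:
        # ---------------- simulate / load -----------------------------------
        truth = None
        if config.dosage_file is None:
            sim = synthdata.SimConfig(
                n_samples=config.n_samples, n_variants=config.n_variants, seed=config.seed
            )
            dosages, variants = synthdata.simulate_genotypes(sim)
            raw_pheno, truth = synthdata.simulate_phenotypes(dosages, variants, sim)
            # degrade imputation quality for a slice of variants so the info
            # filter has work to do
            rng = np.random.default_rng(config.seed + 7)
            info_targets = np.ones(config.n_variants)
            degraded = rng.choice(config.n_variants, size=config.n_variants // 10, replace=False)
            info_targets[degraded] = rng.uniform(0.3, 0.95, size=degraded.size)
            dosages = synthdata.inject_imputation_noise(dosages, info_targets, seed=config.seed + 8)
            variants["info"] = [assoc.info_score(dosages[:, j]) for j in range(dosages.shape[1])]
            sample_ids = raw_pheno["sample_id"].tolist()
            _stage("simulate", {"n_samples": len(sample_ids), "n_variants": len(variants)})
        else:
            dosages, variants, sample_ids = io.read_dosages(config.dosage_file)
            manifest["inputs"]["dosages"] = _hash_file(config.dosage_file)
            raw_pheno = io.read_phenotypes(config.phenotype_file)
            manifest["inputs"]["phenotypes"] = _hash_file(config.phenotype_file)
            _stage("load", {"n_samples": len(sample_ids), "n_variants": len(variants)})

        # ---------------- phenotype preparation -----------------------------
        pheno = phenoprep.select_measurements(raw_pheno)
        pheno = phenoprep.log_transform(pheno, [m for m in PWV_MODES if m in pheno.columns] + ["SBP", "DBP"])
        discard = {m: float(pheno[m].isna().mean()) for m in PWV_MODES if m in pheno.columns}
        io.write_phenotypes(os.path.join(out, "phenotypes_clean.tsv"), pheno)
        _stage("phenoprep", {"missing_fraction": discard})

        # ---------------- SNP QC --------------------------------------------
        kept, qc_report = assoc.snp_qc(variants, dosages)
        qc_report.to_csv(os.path.join(out, "snp_qc.tsv"), sep="\t", index=False)
        keep_mask = variants["variant_id"].isin(kept).to_numpy()
        variants_qc = variants.loc[keep_mask].reset_index(drop=True)
        dosages_qc = dosages[:, keep_mask]
        _stage("snp_qc", {"kept": len(kept), "dropped": int((~keep_mask).sum())})

        # ---------------- association scans ---------------------------------
        covars_full = np.column_stack([pheno["sex"], pheno["age"], pheno["logSBP"]])
        covars_basic = np.column_stack([pheno["sex"], pheno["age"]])
        scans: dict[str, pd.DataFrame] = {}
        scans_basic: dict[str, pd.DataFrame] = {}
        lambdas: dict[str, float] = {}
        for mode in PWV_MODES:
            y = pheno[f"log{mode}"].to_numpy(dtype=float)
            scans[mode] = assoc.run_gwas(dosages_qc, y, covars_full, variants_qc, phenotype_name=f"log{mode}")
            scans_basic[mode] = assoc.run_gwas(dosages_qc, y, covars_basic, variants_qc, phenotype_name=f"log{mode}_basic")
            io.write_sumstats(os.path.join(out, f"sumstats_{mode}.tsv"), scans[mode])
            lambdas[mode] = assoc.genomic_inflation(scans[mode]["p"].dropna())
        sbp_scan = assoc.run_gwas(
            dosages_qc, pheno["logSBP"].to_numpy(dtype=float), covars_basic, variants_qc, phenotype_name="logSBP"
        )
        io.write_sumstats(os.path.join(out, "sumstats_logSBP.tsv"), sbp_scan)
        _stage("gwas", {"lambda": lambdas})

        # ---------------- pruning and loci -----------------------------------
        suggestive_ids: dict[str, list[str]] = {}
        leads: dict[str, list[str]] = {}
        best = pd.concat(scans.values()).dropna(subset=["p"]).groupby("variant_id", as_index=False)["p"].min()
        best = best.merge(variants_qc[["variant_id", "chrom", "pos"]], on="variant_id")
        sugg = best[best["p"] < config.suggestive_p]
        if len(sugg):
            ld = loci.ld_matrix(
                dosages_qc[:, variants_qc["variant_id"].isin(sugg["variant_id"]).to_numpy()],
                sugg["variant_id"].tolist(),
            )
            lead_ids, _tags = loci.priority_prune(sugg, ld, config.prune_r2)
        else:
            lead_ids = []
        locus_list = loci.define_loci(lead_ids, variants_qc, config.locus_window)
        loci_table = pd.DataFrame(
            [
                {"chrom": l.chrom, "start": l.start, "end": l.end, "lead": l.lead, "members": ",".join(l.members), "traits": ""}
                for l in locus_list
            ]
        )
        io.write_loci(os.path.join(out, "loci.tsv"), loci_table)
        _stage("loci", {"suggestive": int(len(sugg)), "leads": len(lead_ids)})

        # ---------------- replication ----------------------------------------
        if config.candidate_file is not None:
            candidates = pd.read_csv(config.candidate_file, sep="\t")
            manifest["inputs"]["candidates"] = _hash_file(config.candidate_file)
        elif truth is not None:
            direct = truth.effects[truth.effects["phenotype"].isin(PWV_MODES)]
            planted = direct.loc[direct["beta"].abs() >= 0.02]
            candidates = pd.DataFrame(
                {
                    "variant_id": planted["variant_id"],
                    "reported_EA": "A",
                    "reported_beta": planted["beta"],
                    "reported_p": 1e-7,
                    "reported_phenotype": planted["phenotype"],
                    "inverted_phenotype": False,
                }
            )
        else:
            candidates = replication.load_candidate_panel()
        rep_results, rep_count = replication.test_replication(
            candidates, {m: scans[m] for m in PWV_MODES}, alpha=config.bonferroni_p
        )
        rep_results.to_csv(os.path.join(out, "replication.tsv"), sep="\t", index=False)
        _stage("replication", {"candidates": len(candidates), "replicated": rep_count})

        # ---------------- enrichment -----------------------------------------
        if truth is not None:
            panel_ids = truth.effects.loc[truth.effects["phenotype"] == "logSBP", "variant_id"].unique().tolist()
        else:
            panel_ids = variants_qc["variant_id"].head(50).tolist()
        panel_mask = variants_qc["variant_id"].isin(panel_ids).to_numpy()
        pheno_block = pheno[[f"log{m}" for m in PWV_MODES]].to_numpy(dtype=float)
        enr = enrichment.permutation_null(
            dosages_qc[:, panel_mask],
            pheno_block,
            covars_full,
            B=config.permutations,
            alpha=config.bonferroni_p,
            seed=config.seed + 11,
        )
        with open(os.path.join(out, "enrichment.json"), "w") as fh:
            json.dump({**enr.as_dict(), "null_histogram": np.bincount(enr.null_counts).tolist()}, fh, indent=2)
        _stage("enrichment", enr.as_dict())

        # ---------------- LDSC ------------------------------------------------
        ld_scores = ldsc.compute_ld_scores(dosages_qc, variants_qc)
        M = int(ld_scores["ld_score"].notna().sum())
        h2_results = {}
        for mode in PWV_MODES:
            scan_b = scans_basic[mode].dropna(subset=["beta", "se"])
            res = ldsc.ldsc_h2(scan_b, ld_scores, N=int(scan_b["n"].median()), M=M)
            h2_results[mode] = res.as_dict()
        ld_scores.to_csv(os.path.join(out, "ld_scores.tsv"), sep="\t", index=False)
        _stage("ldsc", h2_results)

        # ---------------- Mendelian randomization ----------------------------
        bp_panel = pd.DataFrame({"variant_id": panel_ids})
        sugg_set = set(sugg["variant_id"]) | set(panel_ids)
        ld_all = None
        if sugg_set:
            ids = [v for v in variants_qc["variant_id"] if v in sugg_set]
            ld_all = loci.ld_matrix(
                dosages_qc[:, variants_qc["variant_id"].isin(ids).to_numpy()], ids
            )
        forward_results = {}
        try:
            instruments, fw_ledger = mr.select_instruments_forward(
                bp_panel,
                sbp_scan,
                {m: scans[m] for m in PWV_MODES},
                lead_ids,
                ld_all,
                nominal_alpha=config.nominal_p,
                ld_r2_max=config.instrument_ld_r2,
            )
            fw_ledger.to_csv(os.path.join(out, "mr_forward_exclusions.tsv"), sep="\t", index=False)
            for mode in PWV_MODES:
                with_outcome = mr.attach_outcome(instruments, scans_basic[mode])
                forward_results[mode] = mr.ivw(with_outcome, model="random")
        except ValueError as err:
            logger.warning("forward MR skipped: %s", err)
        reverse_results = {}
        for mode in PWV_MODES:
            mode_stats = scans_basic[mode].set_index("variant_id")
            rows = []
            for vid in lead_ids:
                if vid in mode_stats.index:
                    rows.append(
                        {
                            "variant_id": vid,
                            "beta": float(mode_stats.at[vid, "beta"]),
                            "se": float(mode_stats.at[vid, "se"]),
                            "p": float(mode_stats.at[vid, "p"]),
                        }
                    )
            if not rows:
                continue
            try:
                rev_ins = mr.select_instruments_reverse(
                    pd.DataFrame(rows), mode, panel_ids, ld_all,
                    nominal_alpha=config.nominal_p, ld_r2_max=config.instrument_ld_r2,
                )
                rev_with_outcome = mr.attach_outcome(rev_ins, sbp_scan)
                reverse_results[mode] = mr.ivw(rev_with_outcome, model="random")
            except ValueError as err:
                logger.warning("reverse MR skipped for %s: %s", mode, err)
        report = mr.bidirectional_report(forward_results or None, reverse_results or None)
        report.to_csv(os.path.join(out, "mr_report.tsv"), sep="\t", index=False)
        _stage(
            "mr",
            {
                "forward": {m: r.as_dict() for m, r in forward_results.items()},
                "reverse": {m: r.as_dict() for m, r in reverse_results.items()},
            },
        )
    except Exception:
        manifest["completed_stages"] = completed
        with open(os.path.join(out, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        raise

    manifest["completed_stages"] = completed
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
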