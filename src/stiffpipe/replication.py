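"""Replication of published candidate PWV SNPs in local summary statistics.

A candidate replicates when its best local p-value across the three PWV
modes clears the Bonferroni-corrected nominal threshold 0.05/3 (strict
less-than: a local p of 1.69e-2 does not replicate).  Effect directions are
harmonized to the reported effect allele before comparison; candidates whose
source modelled a reciprocal phenotype (1000/cfPWV) are expected to show the
opposite sign.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "BONFERRONI_ALPHA",
    "load_candidate_panel",
    "harmonize",
    "test_replication",
]

BONFERRONI_ALPHA = 0.05 / 3

_STRAND_AMBIGUOUS = {frozenset({"A", "T"}), frozenset({"G", "C"})}

CANDIDATE_COLUMNS = [
    "cytoband",
    "variant_id",
    "source",
    "reported_EA",
    "reported_EAF",
    "reported_beta",
    "reported_p",
    "reported_phenotype",
    "inverted_phenotype",
]


def load_candidate_panel() -> pd.DataFrame:
    """Packaged look-up table of published PWV candidate SNPs.

    Fourteen SNPs that reached at least suggestive significance (p < 1e-6)
    in earlier PWV GWAS (Mitchell 2012, Tarasov 2009, Park 2015), together
    with the association results observed for them in a population-based
    cohort GWAS of the three PWV modes (columns ``local_*``).  Candidates
    from the source that modelled 1000/cfPWV carry ``inverted_phenotype =
    True``: their effect direction is expected to be opposite.
    """
    with resources.files("stiffpipe.data").joinpath("known_pwv_snps.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    df["inverted_phenotype"] = df["inverted_phenotype"].astype(bool)
    return df


@dataclass
class HarmonizedPair:
    variant_id: str
    beta_reported: float
    beta_local: float
    eaf_local: float
    flipped: bool
    strand_ambiguous: bool
    direction_consistent: bool


def harmonize(
    reported_ea: str,
    reported_beta: float,
    local_ea: str,
    local_oa: str,
    local_beta: float,
    local_eaf: float,
    inverted_phenotype: bool = False,
    variant_id: str = "",
) -> HarmonizedPair:
    """Align a local effect estimate to the reported effect allele.

    When the local effect allele equals the reported other allele, the local
    beta is negated and the frequency complemented.  If neither local allele
    matches the reported effect allele the pair is not resolvable and a
    ``ValueError`` is raised.  A/T and G/C pairs are flagged as
    strand-ambiguous.  With ``inverted_phenotype`` the expected concordance
    is opposite signs (the source modelled a reciprocal of the phenotype).
    """
    ambiguous = frozenset({local_ea, local_oa}) in _STRAND_AMBIGUOUS
    if reported_ea == local_ea:
        beta, eaf, flipped = local_beta, local_eaf, False
    elif reported_ea == local_oa:
        beta, eaf, flipped = -local_beta, 1.0 - local_eaf, True
    else:
        raise ValueError(f"allele mismatch for {variant_id or 'candidate'}: reported EA {reported_ea} vs local {local_ea}/{local_oa}")
    same_sign = np.sign(beta) == np.sign(reported_beta)
    consistent = (not same_sign) if inverted_phenotype else bool(same_sign)
    return HarmonizedPair(variant_id, reported_beta, beta, eaf, flipped, ambiguous, consistent)


def test_replication(
    candidates: pd.DataFrame,
    local_sumstats: dict[str, pd.DataFrame] | None = None,
    alpha: float = BONFERRONI_ALPHA,
    mode_order: tuple[str, ...] = ("baPWV", "cfPWV", "bfPWV"),
) -> tuple[pd.DataFrame, int]:
    """Apply the Bonferroni replication rule to a candidate panel.

    Two input shapes are supported:

    - ``local_sumstats`` given: a dict of per-mode summary-statistics tables
      (``variant_id, beta, se, p``); the best phenotype per candidate is the
      mode with the minimal local p (ties broken by ``mode_order``).
      Candidates absent from every mode are reported as untested.
    - ``local_sumstats`` omitted: the candidate table itself carries
      ``local_p`` (and optionally ``local_beta``, ``best_phenotype``)
      columns, as in the packaged look-up panel.

    Returns the per-candidate result table and the replicated count.
    """
    rows = []
    for cand in candidates.itertuples(index=False):
        vid = cand.variant_id
        if local_sumstats is not None:
            best_mode, best_p, best_beta = None, np.inf, np.nan
            for mode in mode_order:
                stats_df = local_sumstats.get(mode)
                if stats_df is None:
                    continue
                hit = stats_df.loc[stats_df["variant_id"] == vid]
                if hit.empty:
                    continue
                p = float(hit["p"].iloc[0])
                if p < best_p:
                    best_mode, best_p, best_beta = mode, p, float(hit["beta"].iloc[0])
            if best_mode is None:
                rows.append({"variant_id": vid, "tested": False, "replicated": False, "best_phenotype": None, "local_beta": np.nan, "local_p": np.nan, "direction_consistent": None})
                continue
        else:
            if "local_p" not in candidates.columns or pd.isna(cand.local_p):
                rows.append({"variant_id": vid, "tested": False, "replicated": False, "best_phenotype": None, "local_beta": np.nan, "local_p": np.nan, "direction_consistent": None})
                continue
            best_mode = getattr(cand, "best_phenotype", None)
            best_p = float(cand.local_p)
            best_beta = float(getattr(cand, "local_beta", np.nan))
        inverted = bool(getattr(cand, "inverted_phenotype", False))
        reported_beta = float(getattr(cand, "reported_beta", np.nan))
        if np.isnan(best_beta) or np.isnan(reported_beta):
            consistent = None
        else:
            same = np.sign(best_beta) == np.sign(reported_beta)
            consistent = (not same) if inverted else bool(same)
        rows.append(
            {
                "variant_id": vid,
                "tested": True,
                "best_phenotype": best_mode,
                "local_beta": best_beta,
                "local_p": best_p,
                "replicated": bool(best_p < alpha),
                "direction_consistent": consistent,
            }
        )
    columns = ["variant_id", "tested", "best_phenotype", "local_beta", "local_p", "replicated", "direction_consistent"]
    results = pd.DataFrame(rows, columns=columns)
    return results, int(results["replicated"].fillna(False).sum())
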