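"""Linkage disequilibrium, priority pruning and locus definition.

LD between two variants is the squared Pearson correlation of their dosages.
Priority pruning selects independent association signals greedily by
significance: the most significant unassigned SNP becomes a lead, every
unassigned SNP with r^2 >= 0.5 to it is tagged by it, and the procedure
repeats.  A locus is the closed +/-500 kb interval around a lead SNP
(1-based coordinates).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Locus",
    "ld_r2",
    "ld_matrix",
    "priority_prune",
    "define_loci",
    "overlap_loci",
]

DEFAULT_PRUNE_R2 = 0.5
DEFAULT_LOCUS_WINDOW = 500_000


@dataclass
class Locus:
    """A +/-window interval around a lead SNP (closed, 1-based)."""

    lead: str
    chrom: str
    start: int
    end: int
    members: list[str] = field(default_factory=list)
    trait_labels: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.lead not in self.members:
            self.members.append(self.lead)


def ld_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors (complete cases)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dosage vectors must have equal length")
    mask = ~np.isnan(a) & ~np.isnan(b)
    if mask.sum() < 3:
        raise ValueError("need at least 3 complete cases")
    a, b = a[mask], b[mask]
    if a.std() == 0.0 or b.std() == 0.0:
        raise ValueError("zero-variance dosage vector")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def ld_matrix(dosages: np.ndarray, variant_ids: list[str]) -> pd.DataFrame:
    """Pairwise r^2 matrix for a dosage block (samples x variants)."""
    d = np.asarray(dosages, dtype=float)
    if d.shape[1] != len(variant_ids):
        raise ValueError("variant id count does not match dosage columns")
    r = np.corrcoef(d, rowvar=False)
    r2 = np.atleast_2d(r) ** 2
    np.fill_diagonal(r2, 1.0)
    return pd.DataFrame(r2, index=variant_ids, columns=variant_ids)


def _sort_for_pruning(records: pd.DataFrame) -> pd.DataFrame:
    # deterministic tie-break: ascending p, then chrom, pos, id
    cols = ["p"]
    for c in ("chrom", "pos", "variant_id"):
        if c in records.columns:
            cols.append(c)
    return records.sort_values(cols, kind="stable")


def priority_prune(
    records: pd.DataFrame,
    ld: pd.DataFrame,
    r2_threshold: float = DEFAULT_PRUNE_R2,
) -> tuple[list[str], dict[str, str]]:
    """Greedy significance-ordered LD pruning.

    Parameters
    ----------
    records
        Association records with at least ``variant_id`` and ``p`` columns
        (``chrom``/``pos`` used for deterministic tie-breaking when present).
    ld
        Symmetric r^2 matrix indexed by variant id covering every record.
    r2_threshold
        Tagging threshold; SNPs with r^2 >= threshold to a more significant
        SNP are considered tagged by it.

    Returns
    -------
    leads : variant ids of the independent lead SNPs, in selection order.
    tags : mapping of every input variant to the lead that tags it (leads map
        to themselves).

    After pruning, leads are pairwise below the threshold and every input
    SNP is assigned to exactly one lead.  Output is invariant to input order.
    """
    missing = set(records["variant_id"]) - set(ld.index)
    if missing:
        raise KeyError(f"variants absent from LD matrix: {sorted(missing)[:5]}")
    ordered = _sort_for_pruning(records)["variant_id"].tolist()
    unassigned = dict.fromkeys(ordered)  # insertion-ordered set
    leads: list[str] = []
    tags: dict[str, str] = {}
    while unassigned:
        lead = next(iter(unassigned))
        leads.append(lead)
        remaining = list(unassigned)
        r2_row = ld.loc[lead, remaining].to_numpy(dtype=float)
        for v, r2 in zip(remaining, r2_row):
            if v == lead or r2 >= r2_threshold:
                tags[v] = lead
                del unassigned[v]
    return leads, tags


def define_loci(
    leads: list[str],
    variants: pd.DataFrame,
    window: int = DEFAULT_LOCUS_WINDOW,
) -> list[Locus]:
    """One locus per lead: the closed +/-window interval and its members.

    ``variants`` must carry ``variant_id``, ``chrom`` and ``pos`` for every
    SNP considered for membership.  Loci of different leads may overlap; they
    are reported separately, not merged.
    """
    v = variants.set_index("variant_id")
    loci = []
    for lead in leads:
        chrom = str(v.at[lead, "chrom"])
        pos = int(v.at[lead, "pos"])
        start = max(1, pos - window)
        end = pos + window
        same = v[(v["chrom"].astype(str) == chrom) & (v["pos"] >= start) & (v["pos"] <= end)]
        loci.append(Locus(lead=lead, chrom=chrom, start=start, end=end, members=list(same.index)))
    return loci


def overlap_loci(
    panels: pd.DataFrame,
    pwv_assoc: pd.DataFrame,
    variants: pd.DataFrame,
    alpha: float = 0.05 / 3,
    window: int = DEFAULT_LOCUS_WINDOW,
) -> pd.DataFrame:
    """Locus-level overlap between published SNP panels and PWV association.

    Parameters
    ----------
    panels
        Published SNPs with columns ``variant_id`` and ``trait`` (e.g. "CAD",
        "BP"); the combined set seeds the loci.  The most associated panel
        SNP per region leads (here: panel order of priority is by the
        minimal local PWV p-value, then position), and loci are assigned
        greedily over the +/-window interval.
    pwv_assoc
        Local summary statistics across the PWV modes (``variant_id``, ``p``;
        several rows per variant allowed — the minimum p per variant is used).
    variants
        Position table covering the panel SNPs.
    alpha
        Bonferroni-corrected nominal threshold for calling a locus
        PWV-overlapping via its lead SNP.

    Returns a DataFrame with one row per locus: lead, span, member SNPs, the
    trait panels represented, whether the locus contains both CAD and BP
    SNPs (``cross_trait_overlap``) and whether the lead is associated with at
    least one PWV mode at ``alpha`` (``pwv_overlap``).
    """
    best_p = pwv_assoc.groupby("variant_id")["p"].min()
    pan = panels.drop_duplicates(subset=["variant_id", "trait"])
    snp_traits = pan.groupby("variant_id")["trait"].agg(set)
    v = variants.set_index("variant_id")

    order = pd.DataFrame({"variant_id": snp_traits.index})
    order["p"] = order["variant_id"].map(best_p).fillna(1.0)
    order["chrom"] = order["variant_id"].map(v["chrom"]).astype(str)
    order["pos"] = order["variant_id"].map(v["pos"])
    leads = _greedy_window_leads(order, window)

    rows = []
    assigned: set[str] = set()
    for lead in leads:
        chrom = str(v.at[lead, "chrom"])
        pos = int(v.at[lead, "pos"])
        start, end = max(1, pos - window), pos + window
        members = [
            s
            for s in snp_traits.index
            if s not in assigned
            and str(v.at[s, "chrom"]) == chrom
            and start <= int(v.at[s, "pos"]) <= end
        ]
        assigned.update(members)
        traits = set().union(*(snp_traits[m] for m in members))
        lead_p = float(best_p.get(lead, np.nan))
        rows.append(
            {
                "lead": lead,
                "chrom": chrom,
                "start": start,
                "end": end,
                "members": ",".join(sorted(members)),
                "traits": ",".join(sorted(traits)),
                "cross_trait_overlap": len(traits) > 1,
                "lead_best_pwv_p": lead_p,
                "pwv_overlap": bool(lead_p < alpha),
            }
        )
    return pd.DataFrame(rows)


def _greedy_window_leads(order: pd.DataFrame, window: int) -> list[str]:
    """Greedy region seeding: best local p first, claim the window, repeat."""
    ordered = order.sort_values(["p", "chrom", "pos", "variant_id"], kind="stable")
    leads: list[str] = []
    claimed: list[tuple[str, int, int]] = []
    for rec in ordered.itertuples(index=False):
        pos = int(rec.pos)
        if any(c == rec.chrom and s <= pos <= e for c, s, e in claimed):
            continue
        leads.append(rec.variant_id)
        claimed.append((rec.chrom, max(1, pos - window), pos + window))
    return leads
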