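"""Annotation evidence: shared domains, pan-homology, tiers, intersection tallies.

Classified hit pairs are joined with two annotation sources — protein domain
(InterPro-style) ID sets per accession and rice-human ortholog pairs from a
pan-taxonomic homology resource — and assigned an evidence tier:

    both          shared domain AND ortholog relationship
    domain_only   shared domain, no ortholog
    homology_only ortholog, no shared domain
    neither       no support from either source

Missing annotation rows mean "no evidence" (empty set / false), never an
error: public annotation coverage is incomplete.  The five-attribute
intersection tally (all pairs, shared domain, HS–HS, pan-homology, unique
LS–HS) is the data behind an UpSet plot.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

TIERS = ("both", "domain_only", "homology_only", "neither")

UPSET_ATTRIBUTES = (
    "all_pairs",
    "shared_interpro",
    "hs_hs",
    "pan_homology",
    "unique_ls_hs",
)


@dataclass
class AnnotationTables:
    """Domain sets per accession and the set of ortholog pairs."""

    domains: dict[str, frozenset[str]] = field(default_factory=dict)
    orthologs: set[tuple[str, str]] = field(default_factory=set)

    @classmethod
    def from_frames(cls, domains: pd.DataFrame, orthologs: pd.DataFrame) -> "AnnotationTables":
        """Build from long-format tables: (accession, interpro_id) and
        (rice_gene_id, human_gene_symbol)."""
        dom: dict[str, set[str]] = {}
        for acc, ipr in zip(domains["accession"], domains["interpro_id"]):
            dom.setdefault(str(acc), set()).add(str(ipr))
        orth = set(zip(orthologs["rice_gene_id"].astype(str), orthologs["human_gene_symbol"].astype(str)))
        return cls({k: frozenset(v) for k, v in dom.items()}, orth)

    def domain_set(self, accession: str) -> frozenset[str]:
        return self.domains.get(accession, frozenset())


def shared_domain(rice_acc: str, human_acc: str, annotations: AnnotationTables) -> bool:
    """True iff the two accessions share at least one domain ID."""
    return bool(annotations.domain_set(rice_acc) & annotations.domain_set(human_acc))


def tier_of(has_domain: bool, has_homology: bool) -> str:
    if has_domain and has_homology:
        return "both"
    if has_domain:
        return "domain_only"
    if has_homology:
        return "homology_only"
    return "neither"


def assign_tiers(classified: pd.DataFrame, annotations: AnnotationTables) -> pd.DataFrame:
    """Attach shared_interpro, pan_homology and tier to every classified pair."""
    shared = [
        shared_domain(r, h, annotations)
        for r, h in zip(classified["rice_accession"], classified["human_accession"])
    ]
    homol = [
        (str(g), str(s)) in annotations.orthologs
        for g, s in zip(classified["rice_gene_id"], classified.get("human_gene_symbol", [""] * len(classified)))
    ]
    return classified.assign(
        shared_interpro=shared,
        pan_homology=homol,
        tier=[tier_of(d, h) for d, h in zip(shared, homol)],
    )


def intersection_tally(evidenced: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Count pairs per observed attribute combination (UpSet-plot data).

    Attributes per pair: membership of the full set (always true), shared
    domain, HS–HS quadrant, pan-homology, unique LS–HS membership.  Returns
    the combination table (one boolean column per attribute, a bitmask and a
    count, sorted by count descending) and per-attribute set sizes.
    Combination counts sum to the number of input pairs.
    """
    if evidenced.empty:
        cols = {a: pd.Series(dtype=bool) for a in UPSET_ATTRIBUTES}
        empty = pd.DataFrame({**cols, "bitmask": pd.Series(dtype=int), "count": pd.Series(dtype=int)})
        return empty, {a: 0 for a in UPSET_ATTRIBUTES}

    flags = pd.DataFrame(
        {
            "all_pairs": True,
            "shared_interpro": evidenced["shared_interpro"].astype(bool),
            "hs_hs": (evidenced["quadrant"] == "HS_HS"),
            "pan_homology": evidenced["pan_homology"].astype(bool),
            "unique_ls_hs": evidenced.get("unique_ls_hs", False),
        }
    )
    flags["unique_ls_hs"] = flags["unique_ls_hs"].fillna(False).astype(bool)
    tally = (
        flags.groupby(list(UPSET_ATTRIBUTES), as_index=False)
        .size()
        .rename(columns={"size": "count"})
    )
    tally["bitmask"] = sum(
        tally[attr].astype(int) * (1 << i) for i, attr in enumerate(UPSET_ATTRIBUTES)
    )
    tally = tally.sort_values(["count", "bitmask"], ascending=[False, True], ignore_index=True)
    set_sizes = {a: int(flags[a].sum()) for a in UPSET_ATTRIBUTES}
    return tally, set_sizes
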