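"""Triage of contact-culture-induced molecules into borrowed, intrinsic and
conditioned-media components.

The donor-high catalog (genes upregulated in the stromal donor relative to
the recipient tumor line in monoculture) serves as the denominator of
plausibly transferable molecules. Molecules induced in the recipient during
direct-contact co-culture are split against it: those also in the catalog
are *borrowed* (the recipient lacked them, the donor had them, contact
delivered them); the rest are the recipient's *intrinsic* contact response.
Molecules induced by conditioned media alone form the third, soluble-factor
bin. A molecule induced in both contact culture and conditioned media stays
in its contact-derived bin but carries a ``cm_shared`` flag rather than
being excluded.

Evidence from RNA and protein platforms is unioned before triage; per-gene
provenance (rna / protein / both) is retained, and the cross-platform
signature is the RNA-and-protein intersection of the borrowed evidence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from cocultnet.differential import DEResult, filter_deg
from cocultnet.io import GeneSet, write_gmt, write_tsv

logger = logging.getLogger(__name__)


@dataclass
class TriagePartition:
    """Borrowed / intrinsic / conditioned-media gene bins with provenance.

    Invariants (asserted on construction): borrowed and intrinsic are
    disjoint; borrowed lies inside the donor-high catalog; intrinsic lies
    outside it; their union is exactly the set of contact-induced genes.
    """

    msc_high: GeneSet
    borrowed: GeneSet
    intrinsic: GeneSet
    cm_unique: GeneSet
    provenance: dict[str, str] = field(default_factory=dict)  # gene -> rna|protein|both
    cm_shared: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        assert not (self.borrowed.genes & self.intrinsic.genes), "borrowed/intrinsic overlap"
        assert self.borrowed.genes <= self.msc_high.genes, "borrowed outside catalog"
        assert not (self.intrinsic.genes & self.msc_high.genes), "intrinsic inside catalog"

    @property
    def up_cc(self) -> frozenset[str]:
        return self.borrowed.genes | self.intrinsic.genes

    def sizes(self) -> dict[str, int]:
        return {
            "msc_high": len(self.msc_high),
            "borrowed": len(self.borrowed),
            "intrinsic": len(self.intrinsic),
            "cm_unique": len(self.cm_unique),
            "cm_shared": len(self.cm_shared),
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for gs, bin_name in ((self.borrowed, "borrowed"), (self.intrinsic, "intrinsic"), (self.cm_unique, "cm_unique")):
            for g in sorted(gs.genes):
                rows.append(
                    {
                        "gene": g,
                        "bin": bin_name,
                        "provenance": self.provenance.get(g, "rna"),
                        "cm_shared": g in self.cm_shared,
                    }
                )
        return pd.DataFrame(rows, columns=["gene", "bin", "provenance", "cm_shared"])

    def export(self, gmt_path, tsv_path) -> None:
        write_gmt(
            [
                self.msc_high,
                GeneSet("borrowed", self.borrowed.genes),
                GeneSet("intrinsic", self.intrinsic.genes),
                GeneSet("cm_unique", self.cm_unique.genes),
            ],
            gmt_path,
        )
        write_tsv(self.to_frame(), tsv_path)


def build_msc_high_catalog(
    de_donor_vs_recipient: DEResult,
    lfc_min: float = 2.0,
    adj_p_max: float = 0.05,
) -> GeneSet:
    """Genes upregulated in the donor (group_b) relative to the recipient
    monoculture — the denominator catalog of transfer candidates."""
    catalog = filter_deg(de_donor_vs_recipient, lfc_min, adj_p_max, "up", name="msc_high")
    if not catalog.genes:
        logger.warning("donor-high catalog is empty at the given thresholds")
    return catalog


def classify_induced(
    up_cc: GeneSet,
    up_cm: GeneSet,
    msc_high: GeneSet,
    provenance: dict[str, str] | None = None,
) -> TriagePartition:
    """Partition contact-induced genes against the donor-high catalog.

    borrowed  = up_cc ∩ msc_high
    intrinsic = up_cc \\ msc_high
    cm_unique = up_cm \\ up_cc
    Genes induced in both contact culture and conditioned media stay in
    their contact-derived bin, flagged ``cm_shared``.
    """
    cc, cm, cat = up_cc.genes, up_cm.genes, msc_high.genes
    return TriagePartition(
        msc_high=msc_high,
        borrowed=GeneSet("borrowed", cc & cat),
        intrinsic=GeneSet("intrinsic", cc - cat),
        cm_unique=GeneSet("cm_unique", cm - cc),
        provenance=dict(provenance or {}),
        cm_shared=frozenset(cc & cm),
    )


def union_evidence(rna: GeneSet, protein: GeneSet, name: str = "up_cc") -> tuple[GeneSet, dict[str, str]]:
    """Union RNA- and protein-level inductions, keeping per-gene provenance."""
    prov = {g: "rna" for g in rna.genes}
    for g in protein.genes:
        prov[g] = "both" if g in prov else "protein"
    return GeneSet(name, rna.genes | protein.genes), prov


def cross_platform_overlap(rna_borrowed: GeneSet, protein_borrowed: GeneSet) -> GeneSet:
    """Genes supported by both RNA-seq and proteomics (the cross-platform
    signature; provenance 'both')."""
    return GeneSet(
        "rna_protein_overlap",
        rna_borrowed.genes & protein_borrowed.genes,
        description="provenance=both",
    )
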