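"""Ultrarare-variant severity filter.

A variant passes when it is ultrarare in every population dataset
(MAC <= 2) and either truncates the protein (stop gain, frameshift,
canonical splice site) or is a protein-altering variant with a severe
in-silico effect (REVEL >= 0.932 or CADD_phred >= 28.1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "VariantRecord",
    "classify_consequence",
    "passes_rarity",
    "passes_severity",
    "filter_variants",
    "MAX_MAC",
    "REVEL_MIN",
    "CADD_MIN",
]

log = logging.getLogger(__name__)

MAX_MAC = 2
REVEL_MIN = 0.932
CADD_MIN = 28.1

# canonical +/-1,2 splice sites only; splice-region variants are "other"
PTV_CONSEQUENCES = {
    "stop_gained",
    "frameshift_variant",
    "splice_donor_variant",
    "splice_acceptor_variant",
}
PAV_CONSEQUENCES = {
    "missense_variant",
    "inframe_insertion",
    "inframe_deletion",
}


@dataclass(frozen=True)
class VariantRecord:
    """One annotated variant."""

    chrom: str
    pos: int
    ref: str
    alt: str
    consequence: str
    mac_by_dataset: dict = field(default_factory=dict)
    revel: float | None = None
    cadd_phred: float | None = None
    transcript: str = ""
    classification: str = ""  # free-text labels (e.g. ACMG), never computed

    @property
    def variant_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


def classify_consequence(v: VariantRecord) -> str:
    """Classify as 'PTV', 'PAV' or 'other'."""
    csq = v.consequence.strip().lower()
    if csq in PTV_CONSEQUENCES:
        return "PTV"
    if csq in PAV_CONSEQUENCES:
        return "PAV"
    if csq not in {"synonymous_variant", "intron_variant", "splice_region_variant",
                   "5_prime_utr_variant", "3_prime_utr_variant",
                   "upstream_gene_variant", "downstream_gene_variant",
                   "non_coding_transcript_variant", "intergenic_variant"}:
        log.info("unrecognized consequence %r for %s -> other", v.consequence,
                 v.variant_id)
    return "other"


def passes_rarity(v: VariantRecord, max_mac: int = MAX_MAC) -> bool:
    """True iff MAC <= max_mac in every listed population dataset."""
    if not v.mac_by_dataset:
        raise ValueError(f"{v.variant_id}: no MAC annotations")
    return all(mac <= max_mac for mac in v.mac_by_dataset.values())


def passes_severity(v: VariantRecord, revel_min: float = REVEL_MIN,
                    cadd_min: float = CADD_MIN) -> bool:
    """Severe in-silico effect for a protein-altering variant.

    REVEL >= revel_min or CADD_phred >= cadd_min; a missing score fails
    its branch rather than erroring.
    """
    if classify_consequence(v) != "PAV":
        raise ValueError(
            f"passes_severity applies to PAV only, got {v.consequence!r}")
    revel_ok = v.revel is not None and v.revel >= revel_min
    cadd_ok = v.cadd_phred is not None and v.cadd_phred >= cadd_min
    return revel_ok or cadd_ok


def filter_variants(records, max_mac: int = MAX_MAC,
                    revel_min: float = REVEL_MIN,
                    cadd_min: float = CADD_MIN) -> tuple[list, pd.DataFrame]:
    """Apply the combined rarity + consequence/severity filter.

    Returns the passing records and an audit table with per-variant
    branch outcomes.
    """
    passing = []
    rows = []
    for v in records:
        category = classify_consequence(v)
        rare = passes_rarity(v, max_mac=max_mac)
        severe = (passes_severity(v, revel_min=revel_min, cadd_min=cadd_min)
                  if category == "PAV" else False)
        ok = rare and (category == "PTV" or (category == "PAV" and severe))
        if ok:
            passing.append(v)
        rows.append({
            "variant_id": v.variant_id,
            "consequence": v.consequence,
            "category": category,
            "rarity_pass": rare,
            "severity_pass": severe,
            "revel": v.revel,
            "cadd_phred": v.cadd_phred,
            "max_mac_observed": max(v.mac_by_dataset.values()),
            "pass": ok,
        })
    audit = pd.DataFrame(rows)
    return passing, audit
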