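"""Synthetic annotated variant tables covering every filter branch."""

from __future__ import annotations

import numpy as np

from ..variants import (CADD_MIN, MAX_MAC, REVEL_MIN, VariantRecord,
                        classify_consequence)
from .truth import GroundTruth

__all__ = ["simulate_variant_table", "DATASETS"]

DATASETS = ("gnomad_v3", "ukbiobank", "internal_controls")

_CONSEQUENCE_POOL = (
    "stop_gained", "frameshift_variant", "splice_donor_variant",
    "splice_acceptor_variant", "missense_variant", "inframe_insertion",
    "inframe_deletion", "synonymous_variant", "intron_variant",
    "splice_region_variant", "5_prime_utr_variant",
)

# fixed records exercising each filter branch, including the printed
# boundary values (MAC 2, REVEL 0.932, CADD 28.1)
_BRANCH_FIXTURES = (
    ("ptv_pass", "stop_gained", {d: 0 for d in DATASETS}, None, None),
    ("missense_revel_pass", "missense_variant", {d: 1 for d in DATASETS}, 0.95, 10.0),
    ("missense_cadd_pass", "missense_variant", {d: 0 for d in DATASETS}, 0.40, 33.0),
    ("missense_fail", "missense_variant", {d: 1 for d in DATASETS}, 0.50, 20.0),
    ("mac_fail", "stop_gained", {"gnomad_v3": 5, "ukbiobank": 0,
                                 "internal_controls": 0}, None, None),
    ("boundary_mac", "frameshift_variant", {d: MAX_MAC for d in DATASETS},
     None, None),
    ("boundary_revel", "missense_variant", {d: 0 for d in DATASETS},
     REVEL_MIN, 0.0),
    ("boundary_cadd", "missense_variant", {d: 0 for d in DATASETS},
     0.10, CADD_MIN),
)


def _expected_pass(consequence: str, macs: dict, revel, cadd) -> bool:
    """Independent restatement of the filter rule for the ground truth."""
    rare = all(m <= MAX_MAC for m in macs.values())
    probe = VariantRecord("x", 1, "A", "T", consequence, dict(macs))
    category = classify_consequence(probe)
    severe = ((revel is not None and revel >= REVEL_MIN)
              or (cadd is not None and cadd >= CADD_MIN))
    return rare and (category == "PTV" or (category == "PAV" and severe))


def simulate_variant_table(n: int, seed: int = 0) -> tuple[list, GroundTruth]:
    """Generate ``n >= 8`` annotated variants spanning all filter branches.

    The first eight records are fixed branch fixtures; the remainder are
    random draws from the consequence/score space.
    """
    if n < 8:
        raise ValueError("n must be at least 8 to cover every filter branch")
    rng = np.random.default_rng(seed)

    records: list[VariantRecord] = []
    labels: list[str] = []
    expected: list[bool] = []
    pos = 1000
    for label, csq, macs, revel, cadd in _BRANCH_FIXTURES:
        records.append(VariantRecord(
            chrom="19", pos=pos, ref="C", alt="T", consequence=csq,
            mac_by_dataset=dict(macs), revel=revel, cadd_phred=cadd,
            transcript="NM_000435.3"))
        labels.append(label)
        expected.append(_expected_pass(csq, macs, revel, cadd))
        pos += 10

    bases = ("A", "C", "G", "T")
    for _ in range(n - len(_BRANCH_FIXTURES)):
        csq = str(rng.choice(_CONSEQUENCE_POOL))
        macs = {d: int(rng.integers(0, 6)) for d in DATASETS}
        revel = float(np.round(rng.uniform(0, 1), 3)) if rng.random() < 0.8 else None
        cadd = float(np.round(rng.uniform(0, 40), 1)) if rng.random() < 0.8 else None
        ref, alt = rng.choice(bases, size=2, replace=False)
        records.append(VariantRecord(
            chrom="19", pos=pos, ref=str(ref), alt=str(alt), consequence=csq,
            mac_by_dataset=macs, revel=revel, cadd_phred=cadd,
            transcript="NM_000435.3"))
        labels.append("random")
        expected.append(_expected_pass(csq, macs, revel, cadd))
        pos += int(rng.integers(1, 50))

    truth = GroundTruth("variants", {
        "seed": seed,
        "n": n,
        "branch_labels": labels,
        "expected_pass": expected,
        "variant_ids": [v.variant_id for v in records],
    })
    return records, truth
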