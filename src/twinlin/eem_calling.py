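"""Classification of non-inherited variants into de novo vs EEM from trio VAFs.

A variant detected in a parent is inherited.  Among parent-absent variants,
pre-zygotic de novo variants are heterozygous in every somatic cell and so
sit near VAF 0.5 in every sibling; post-zygotic EEMs are mosaic and appear
at lower, variable VAFs in a subset of siblings.  The calling rule:

* inherited:  parental presence flag set (or detected in a parent sample);
* de novo:    parent-absent and VAF >= denovo_min_vaf in *every* sibling;
* eem:        parent-absent, detected (alt >= min_alt and VAF >= min_vaf)
              in at least one sibling;
* unresolved: everything else.

A caveat of VAF-only classification: an EEM that happens to be fully clonal
in both twins is indistinguishable from a de novo variant and is labelled
de novo.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variant_io import VariantTable

CLASSES = ("inherited", "de_novo", "eem", "unresolved")


class CallingConfigError(ValueError):
    """Required samples missing from the variant table."""


@dataclass
class CallSet:
    """Per-variant classification and per-sibling detection flags."""

    calls: pd.DataFrame  # index variant; columns: class, shared + detected_<sibling>
    siblings: list[str]

    def of_class(self, cls: str) -> pd.Index:
        return self.calls.index[self.calls["class"] == cls]


def _parent_samples(table: VariantTable, family: str | None = None) -> tuple[str, str]:
    mother = [s for s in table.samples if s.endswith("_mother")]
    father = [s for s in table.samples if s.endswith("_father")]
    if not mother or not father:
        raise CallingConfigError("variant table lacks mother/father samples")
    return mother[0], father[0]


def classify_variants(
    table: VariantTable,
    siblings: list[str] | None = None,
    min_alt: int = 3,
    min_vaf: float = 0.03,
    denovo_min_vaf: float = 0.3,
) -> CallSet:
    """Classify every variant of a single-family trio table.

    ``siblings`` are the sample ids representing each sibling's reference
    somatic tissue (buccal by default: every non-parent sample whose id
    ends in ``_buccal``); at least two are required.  Parental presence
    comes from the table's parent flags when available, otherwise from the
    detection rule applied to the parent sample reads.
    """
    fams = table.families
    if len(fams) != 1:
        raise CallingConfigError("classify_variants expects a single-family table")
    if siblings is None:
        siblings = [s for s in table.samples if s.endswith("_buccal")]
    if len(siblings) < 2:
        raise CallingConfigError("need at least two sibling samples")

    vaf = table.pivot("vaf")
    alt = table.pivot("alt")
    variants = vaf.index

    if table.parent_flags is not None:
        flags = table.parent_flags.reindex(variants, fill_value=False)
        parent_present = (flags["mother"] | flags["father"]).to_numpy()
    else:
        mother, father = _parent_samples(table)
        pp = np.zeros(len(variants), dtype=bool)
        for s in (mother, father):
            pp |= (
                (alt[s].fillna(0).to_numpy() >= min_alt)
                & (vaf[s].fillna(0).to_numpy() >= min_vaf)
            )
        parent_present = pp

    det = pd.DataFrame(index=variants)
    for s in siblings:
        det[s] = (alt[s].fillna(0).to_numpy() >= min_alt) & (
            vaf[s].fillna(0).to_numpy() >= min_vaf
        )
    n_detected = det.sum(axis=1).to_numpy()
    all_high = np.ones(len(variants), dtype=bool)
    for s in siblings:
        all_high &= vaf[s].fillna(0).to_numpy() >= denovo_min_vaf

    cls = np.full(len(variants), "unresolved", dtype=object)
    cls[parent_present] = "inherited"
    denovo = ~parent_present & all_high
    cls[denovo] = "de_novo"
    eem = ~parent_present & ~all_high & (n_detected >= 1)
    cls[eem] = "eem"

    calls = pd.DataFrame({"class": cls}, index=variants)
    for s in siblings:
        calls[f"detected_{s}"] = det[s].to_numpy()
    calls["shared"] = n_detected >= 2
    return CallSet(calls, list(siblings))


def refine_with_targeted(
    callset: CallSet,
    targeted: VariantTable,
    denovo_min_vaf: float = 0.3,
) -> CallSet:
    """Re-check the de novo VAF rule against deep-targeted re-sequencing.

    Discovery-depth VAFs are noisy enough that a variant clonal in every
    sibling (true VAF 0.5) occasionally dips below ``denovo_min_vaf`` in
    one sample and is mis-called an EEM; the reverse error is also
    possible.  Where targeted counts are available for all siblings, the
    de-novo-vs-EEM boundary is re-evaluated on the deeper VAFs.
    """
    vaf_t = targeted.pivot("vaf")
    calls = callset.calls.copy()
    common = calls.index.intersection(vaf_t.index)
    sibs = [s for s in callset.siblings if s in vaf_t.columns]
    if len(sibs) != len(callset.siblings):
        return callset
    high = (vaf_t.loc[common, sibs].fillna(0) >= denovo_min_vaf).all(axis=1)
    is_eem = calls.loc[common, "class"] == "eem"
    is_dn = calls.loc[common, "class"] == "de_novo"
    calls.loc[common[high & is_eem], "class"] = "de_novo"
    calls.loc[common[~high & is_dn], "class"] = "eem"
    return CallSet(calls, callset.siblings)


def detection_matrix(callset: CallSet, classes=("eem",)) -> pd.DataFrame:
    """Variant x sibling boolean detection matrix restricted to classes."""
    sub = callset.calls[callset.calls["class"].isin(classes)]
    cols = [f"detected_{s}" for s in callset.siblings]
    out = sub[cols].copy()
    out.columns = callset.siblings
    return out


def pair_summary(callset: CallSet) -> dict:
    """Counts and shared fractions of de novo variants and EEMs.

    The shared fraction of a class is (variants detected in >= 2 siblings)
    over (variants of the class detected in >= 1 sibling); empty classes
    yield NaN fractions rather than an error.
    """
    out: dict = {}
    for cls, key in (("de_novo", "denovo"), ("eem", "eem")):
        sub = callset.calls[callset.calls["class"] == cls]
        cols = [f"detected_{s}" for s in callset.siblings]
        ndet = sub[cols].sum(axis=1)
        detected = sub[ndet >= 1]
        shared = int((ndet >= 2).sum())
        out[f"n_{key}"] = int(len(sub))
        out[f"n_{key}_detected"] = int(len(detected))
        out[f"{key}_shared_fraction"] = (
            shared / len(detected) if len(detected) else float("nan")
        )
    return out
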