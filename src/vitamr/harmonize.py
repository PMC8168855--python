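"""Allele harmonization of exposure and outcome summary statistics.

Two GWAS may report the same variant against opposite alleles (a *swap*:
negate beta, reflect the allele frequency) or off opposite strands (a
*strand flip*: complement both alleles, values unchanged) — or both.  For
standard variants the allele labels resolve the orientation exactly.  For
palindromic variants (A/T or C/G) the labels cannot distinguish a swap from
a flip, so orientation falls back on allele-frequency concordance; when
either study's frequency sits inside the intermediate window (0.42, 0.58 by
default, open interval) the variant is dropped as unresolvable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .io import VariantAssociation

logger = logging.getLogger("vitamr.harmonize")

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
DEFAULT_FREQ_WINDOW = (0.42, 0.58)


def classify_variant(effect_allele: str, other_allele: str) -> str:
    """Classify an allele pair as ``standard`` or ``palindromic``."""
    ea, oa = effect_allele.upper(), other_allele.upper()
    if ea == oa:
        raise ValueError(f"identical alleles {ea}/{oa}")
    if ea not in COMPLEMENT or oa not in COMPLEMENT:
        raise ValueError(f"invalid allele pair {ea}/{oa}")
    return "palindromic" if COMPLEMENT[ea] == oa else "standard"


@dataclass(frozen=True)
class HarmonizedPair:
    """Exposure and outcome effects of one variant on a shared effect allele."""

    variant_id: str
    effect_allele: str
    other_allele: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    eaf_exposure: Optional[float]
    eaf_outcome: Optional[float]
    action: str  # none | swap | strand_flip | strand_flip+swap
    status: str  # kept | dropped:<reason>

    @property
    def kept(self) -> bool:
        return self.status == "kept"

    @property
    def reason(self) -> str:
        return self.status.partition(":")[2]


def _dropped(exposure: VariantAssociation, outcome: VariantAssociation, reason: str) -> HarmonizedPair:
    return HarmonizedPair(
        variant_id=exposure.variant_id,
        effect_allele=exposure.effect_allele,
        other_allele=exposure.other_allele,
        beta_exposure=exposure.beta,
        se_exposure=exposure.se,
        beta_outcome=outcome.beta,
        se_outcome=outcome.se,
        eaf_exposure=exposure.eaf,
        eaf_outcome=outcome.eaf,
        action="none",
        status=f"dropped:{reason}",
    )


def harmonize_pair(
    exposure: VariantAssociation,
    outcome: VariantAssociation,
    freq_window: tuple[float, float] = DEFAULT_FREQ_WINDOW,
) -> HarmonizedPair:
    """Align one outcome record to the exposure record's effect allele.

    Drops (returned as status, never raised): ``allele_mismatch`` when the
    two allele pairs are irreconcilable even after strand complementation;
    ``palindromic_intermediate_freq`` when either study's frequency of a
    palindromic variant lies strictly inside ``freq_window``;
    ``palindromic_missing_eaf`` when a palindromic variant lacks the
    frequencies needed to orient it.
    """
    if exposure.variant_id != outcome.variant_id:
        raise ValueError(
            f"variant_id mismatch: {exposure.variant_id} vs {outcome.variant_id}"
        )
    exp_pair = (exposure.effect_allele, exposure.other_allele)
    out_pair = (outcome.effect_allele, outcome.other_allele)

    def build(beta_out: float, eaf_out: Optional[float], action: str) -> HarmonizedPair:
        return HarmonizedPair(
            variant_id=exposure.variant_id,
            effect_allele=exposure.effect_allele,
            other_allele=exposure.other_allele,
            beta_exposure=exposure.beta,
            se_exposure=exposure.se,
            beta_outcome=beta_out,
            se_outcome=outcome.se,
            eaf_exposure=exposure.eaf,
            eaf_outcome=eaf_out,
            action=action,
            status="kept",
        )

    if classify_variant(*exp_pair) == "palindromic":
        if set(out_pair) != set(exp_pair):
            return _dropped(exposure, outcome, "allele_mismatch")
        if exposure.eaf is None or outcome.eaf is None:
            return _dropped(exposure, outcome, "palindromic_missing_eaf")
        lo, hi = freq_window
        if lo < exposure.eaf < hi or lo < outcome.eaf < hi:
            return _dropped(exposure, outcome, "palindromic_intermediate_freq")
        # align by labels first, then let frequency concordance decide strand
        if out_pair == exp_pair:
            label_action, beta, eaf = "none", outcome.beta, outcome.eaf
        else:
            label_action, beta, eaf = "swap", -outcome.beta, 1.0 - outcome.eaf
        same_side = (exposure.eaf - 0.5) * (eaf - 0.5) > 0
        if same_side:
            return build(beta, eaf, label_action)
        # frequencies disagree: the outcome is on the opposite strand
        action = "strand_flip+swap" if label_action == "none" else "strand_flip"
        return build(-beta, 1.0 - eaf, action)

    # standard variant: labels are decisive
    if out_pair == exp_pair:
        return build(outcome.beta, outcome.eaf, "none")
    if out_pair == exp_pair[::-1]:
        return build(-outcome.beta, None if outcome.eaf is None else 1.0 - outcome.eaf, "swap")
    flipped = (COMPLEMENT[out_pair[0]], COMPLEMENT[out_pair[1]])
    if flipped == exp_pair:
        return build(outcome.beta, outcome.eaf, "strand_flip")
    if flipped == exp_pair[::-1]:
        return build(
            -outcome.beta,
            None if outcome.eaf is None else 1.0 - outcome.eaf,
            "strand_flip+swap",
        )
    return _dropped(exposure, outcome, "allele_mismatch")


def harmonize_tables(
    exposure: Union[Sequence[VariantAssociation], Iterable[VariantAssociation]],
    outcome: Union[Mapping[str, VariantAssociation], Sequence[VariantAssociation]],
    freq_window: tuple[float, float] = DEFAULT_FREQ_WINDOW,
) -> tuple[list[HarmonizedPair], list[dict[str, str]]]:
    """Harmonize every exposure instrument against an outcome table.

    Returns the kept pairs (sorted by variant_id for determinism) and an
    audit log covering every exposure variant: kept pairs with their action,
    dropped pairs with their reason, and instruments absent from the outcome
    table as ``missing_in_outcome`` (upstream proxy search is the remedy for
    those).
    """
    if isinstance(outcome, Mapping):
        out_map = dict(outcome)
    else:
        out_map = {r.variant_id: r for r in outcome}
    kept: list[HarmonizedPair] = []
    audit: list[dict[str, str]] = []
    for exp in exposure:
        out = out_map.get(exp.variant_id)
        if out is None:
            audit.append(
                {"variant_id": exp.variant_id, "action": "", "status": "dropped:missing_in_outcome"}
            )
            continue
        pair = harmonize_pair(exp, out, freq_window)
        audit.append({"variant_id": pair.variant_id, "action": pair.action, "status": pair.status})
        if pair.kept:
            kept.append(pair)
    kept.sort(key=lambda p: p.variant_id)
    n_dropped = sum(1 for a in audit if a["status"] != "kept")
    if n_dropped:
        logger.info("harmonize_tables: %d of %d instruments dropped", n_dropped, len(audit))
    return kept, audit


def write_audit(audit: Sequence[Mapping[str, str]], path: Union[str, Path]) -> None:
    """Write a harmonization audit log as TSV (variant, action, status)."""
    pd.DataFrame(audit, columns=["variant_id", "action", "status"]).to_csv(
        path, sep="\t", index=False
    )
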