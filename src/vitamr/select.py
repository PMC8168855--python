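"""Instrument selection filters for two-sample MR.

The pipeline applies, in order: genome-wide significance (p < 5e-8, strict),
minor-allele frequency (MAF > 1%, strict), greedy LD pruning (pairwise
r2 < 0.05 among retained instruments), proxy substitution (r2 >= 0.90) for
instruments unavailable in the outcome GWAS or palindromic at intermediate
frequency, optional restriction to vitamin-D-pathway gene regions, and an
annotation-based exclusion list (a local stand-in for a PhenoScanner screen).

Every operation returns a new :class:`InstrumentSet` carrying an exhaustive
provenance map: each input variant is ``kept``, ``dropped:<reason>`` or
``proxied-by:<id>``, so per-stage accounting is reconstructable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np

from .io import GeneRegion, LDTable, VariantAssociation, normalize_chrom

logger = logging.getLogger("vitamr.select")

GENOME_WIDE_P = 5e-8
DEFAULT_MAF_MIN = 0.01
DEFAULT_PRUNE_R2 = 0.05
DEFAULT_PROXY_R2 = 0.90
DEFAULT_PALINDROMIC_WINDOW = (0.42, 0.58)


class ProxyPhaseError(ValueError):
    """Raised when the winning proxy pair lacks the phase needed to orient effects."""


@dataclass
class InstrumentSet:
    """An ordered set of exposure-side instruments plus a per-variant audit trail."""

    variants: list[VariantAssociation]
    provenance: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_records(cls, records: Sequence[VariantAssociation]) -> "InstrumentSet":
        return cls(list(records), {r.variant_id: "kept" for r in records})

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self):
        return iter(self.variants)

    def ids(self) -> list[str]:
        return [v.variant_id for v in self.variants]

    def _derive(self, kept: list[VariantAssociation], drops: Mapping[str, str]) -> "InstrumentSet":
        prov = dict(self.provenance)
        for vid, reason in drops.items():
            prov[vid] = f"dropped:{reason}"
        return InstrumentSet(kept, prov)

    def counts(self) -> dict[str, int]:
        kept = sum(1 for s in self.provenance.values() if not s.startswith("dropped:"))
        return {"input": len(self.provenance), "kept": kept, "dropped": len(self.provenance) - kept}


def _as_set(x: Union[InstrumentSet, Sequence[VariantAssociation]]) -> InstrumentSet:
    return x if isinstance(x, InstrumentSet) else InstrumentSet.from_records(x)


def filter_significance(
    instruments: Union[InstrumentSet, Sequence[VariantAssociation]],
    p_threshold: float = GENOME_WIDE_P,
) -> InstrumentSet:
    """Keep variants with exposure p strictly below the genome-wide threshold."""
    if not (0.0 < p_threshold < 1.0):
        raise ValueError(f"p_threshold must be in (0, 1), got {p_threshold}")
    iset = _as_set(instruments)
    kept, drops = [], {}
    for v in iset:
        if v.pval < p_threshold:
            kept.append(v)
        else:
            drops[v.variant_id] = f"not_significant(p={v.pval:.3g})"
    return iset._derive(kept, drops)


def filter_maf(
    instruments: Union[InstrumentSet, Sequence[VariantAssociation]],
    maf_min: float = DEFAULT_MAF_MIN,
) -> InstrumentSet:
    """Keep variants whose minor allele frequency is strictly above ``maf_min``.

    A missing effect-allele frequency disqualifies the variant (dropped with
    its own reason) since the MAF cannot be established.
    """
    if not (0.0 < maf_min < 0.5):
        raise ValueError(f"maf_min must be in (0, 0.5), got {maf_min}")
    iset = _as_set(instruments)
    kept, drops = [], {}
    for v in iset:
        if v.maf is None:
            drops[v.variant_id] = "missing_eaf"
        elif v.maf > maf_min:
            kept.append(v)
        else:
            drops[v.variant_id] = f"low_maf({v.maf:.4g})"
    return iset._derive(kept, drops)


def ld_prune(
    instruments: Union[InstrumentSet, Sequence[VariantAssociation]],
    ld: LDTable,
    r2_max: float = DEFAULT_PRUNE_R2,
) -> InstrumentSet:
    """Greedy LD pruning, strongest association first.

    Candidates are ranked by ascending exposure p-value (ties broken by
    variant_id); a candidate is kept iff its tabled r2 with every
    already-kept variant is strictly below ``r2_max``.  Pairs absent from the
    LD table are treated as unlinked (r2 = 0); self-pairs are ignored.
    """
    iset = _as_set(instruments)
    order = sorted(iset.variants, key=lambda v: (v.pval, v.variant_id))
    kept_ids: list[str] = []
    drops: dict[str, str] = {}
    for v in order:
        clash = None
        for kid in kept_ids:
            r2 = ld.r2(v.variant_id, kid)
            if r2 is not None and r2 >= r2_max:
                clash = (kid, r2)
                break
        if clash is None:
            kept_ids.append(v.variant_id)
        else:
            drops[v.variant_id] = f"ld_pruned(r2={clash[1]:.3g} with {clash[0]})"
    kept_set = set(kept_ids)
    kept = [v for v in iset.variants if v.variant_id in kept_set]  # original order
    return iset._derive(kept, drops)


def find_proxy(
    variant: VariantAssociation,
    ld: LDTable,
    outcome_table: Union[Mapping[str, VariantAssociation], Sequence[VariantAssociation]],
    r2_min: float = DEFAULT_PROXY_R2,
    freq_window: tuple[float, float] = DEFAULT_PALINDROMIC_WINDOW,
    exposure_table: Optional[Mapping[str, VariantAssociation]] = None,
) -> Optional[VariantAssociation]:
    """Find a proxy instrument for a variant unusable on the outcome side.

    Candidates are tabled LD partners with r2 >= ``r2_min`` that are present
    in the outcome table and are not themselves palindromic at intermediate
    frequency; the highest-r2 candidate wins (ties by variant_id).  The
    returned record is exposure-side: the proxy's own exposure record when
    ``exposure_table`` provides one, otherwise the index variant's effect
    re-keyed onto the proxy's alleles via the tabled haplotype phase (a
    missing phase for the winning pair is an error, since the effect cannot
    be oriented).  Returns ``None`` when no candidate qualifies.
    """
    if isinstance(outcome_table, Mapping):
        out_map = dict(outcome_table)
    else:
        out_map = {r.variant_id: r for r in outcome_table}
    lo, hi = freq_window
    candidates = []
    for pid, r2 in ld.partners(variant.variant_id):
        if r2 < r2_min or pid not in out_map:
            continue
        rec = out_map[pid]
        if rec.is_palindromic and (rec.eaf is None or lo < rec.eaf < hi):
            continue
        candidates.append((r2, pid))
    if not candidates:
        return None
    candidates.sort(key=lambda t: (-t[0], t[1]))
    best_r2, best_id = candidates[0]

    if exposure_table is not None and best_id in exposure_table:
        return exposure_table[best_id]

    phase = ld.phase(variant.variant_id, best_id)
    if phase is None:
        raise ProxyPhaseError(
            f"proxy pair ({variant.variant_id}, {best_id}) has no phase; cannot orient effect"
        )
    idx_allele, proxy_allele = phase
    out_rec = out_map[best_id]
    proxy_alleles = {out_rec.effect_allele, out_rec.other_allele}
    # the LD reference may report phase off the opposite strand from either
    # GWAS: fall back to the complemented allele before giving up
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    if proxy_allele not in proxy_alleles:
        if comp[proxy_allele] in proxy_alleles:
            proxy_allele = comp[proxy_allele]
        else:
            raise ProxyPhaseError(
                f"phase allele {proxy_allele} of {best_id} not among its outcome alleles {proxy_alleles}"
            )
    if idx_allele not in (variant.effect_allele, variant.other_allele):
        if comp[idx_allele] in (variant.effect_allele, variant.other_allele):
            idx_allele = comp[idx_allele]
        else:
            raise ProxyPhaseError(
                f"phase allele {idx_allele} of {variant.variant_id} not among its alleles"
            )
    if idx_allele == variant.effect_allele:
        proxy_effect = proxy_allele
    else:
        proxy_effect = next(a for a in proxy_alleles if a != proxy_allele)
    proxy_other = next(a for a in proxy_alleles if a != proxy_effect)
    logger.info(
        "proxy %s (r2=%.3g) inherits exposure effect of %s via phase",
        best_id, best_r2, variant.variant_id,
    )
    # beta/se/p inherited from the index variant (r2 >= 0.90 makes this a
    # close approximation); eaf likewise carried over.
    return VariantAssociation(
        variant_id=best_id,
        chrom=out_rec.chrom,
        pos=out_rec.pos,
        effect_allele=proxy_effect,
        other_allele=proxy_other,
        eaf=variant.eaf,
        beta=variant.beta,
        se=variant.se,
        pval=variant.pval,
        n=variant.n,
    )


def restrict_to_regions(
    instruments: Union[InstrumentSet, Sequence[VariantAssociation]],
    regions: Sequence[GeneRegion],
) -> InstrumentSet:
    """Keep variants falling inside any region's windowed interval (closed bounds).

    Chromosome names are normalized ('chr4' and '4' match).  An empty
    intersection yields an empty set with a warning, not an error.
    """
    if not regions:
        raise ValueError("restrict_to_regions requires at least one region")
    iset = _as_set(instruments)
    kept, drops = [], {}
    for v in iset:
        hit = next((r for r in regions if r.contains(v.chrom, v.pos)), None)
        if hit is not None:
            kept.append(v)
        else:
            drops[v.variant_id] = "outside_regions"
    if not kept:
        logger.warning("restrict_to_regions: no instruments fall inside the supplied regions")
    return iset._derive(kept, drops)


def exclude_annotated(
    instruments: Union[InstrumentSet, Sequence[VariantAssociation]],
    exclusion_list: Union[Mapping[str, str], Iterable[str]],
) -> InstrumentSet:
    """Drop variants on an annotation-based exclusion list.

    Listed IDs absent from the set are a logged no-op.
    """
    excl = set(exclusion_list)
    iset = _as_set(instruments)
    present = set(iset.ids())
    for vid in excl - present:
        logger.info("exclusion list entry %s not in instrument set; ignored", vid)
    kept = [v for v in iset if v.variant_id not in excl]
    drops = {vid: "annotated" for vid in excl & present}
    return iset._derive(kept, drops)


def variance_explained(
    instruments: Union[InstrumentSet, Sequence[VariantAssociation]],
) -> float:
    """Exposure variance explained: sum_j 2 p_j (1 - p_j) beta_j^2.

    Valid for effects on a standardized trait scale.  Empty sets explain 0;
    a missing eaf is an error naming the offending variants.
    """
    iset = _as_set(instruments)
    missing = [v.variant_id for v in iset if v.eaf is None]
    if missing:
        raise ValueError(f"variance_explained: missing eaf for {missing}")
    return float(sum(2.0 * v.eaf * (1.0 - v.eaf) * v.beta**2 for v in iset))


def ld_r2_from_dosages(dosages_a: Sequence[float], dosages_b: Sequence[float]) -> float:
    """Squared Pearson correlation between two genotype-dosage vectors."""
    a = np.asarray(dosages_a, dtype=float)
    b = np.asarray(dosages_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("dosage vectors must be equal-length 1-D arrays")
    if np.any((a < 0) | (a > 2)) or np.any((b < 0) | (b > 2)):
        raise ValueError("dosages must lie in [0, 2]")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero-variance dosage vector")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)
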