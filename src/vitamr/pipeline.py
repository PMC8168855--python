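"""End-to-end orchestration of the two-sample MR analysis.

One config drives the full design: three COVID-19 outcomes (susceptibility,
hospitalization, severe disease — C2/B2/A2 in Host Genetics Initiative
terms) crossed with three instrument sets (all filtered instruments, the
subset near vitamin-D-pathway genes, and that subset minus annotation-based
exclusions) crossed with the full estimator battery.  Output is a single
results table (one row per outcome x set x method, value or reasoned NA), a
per-cell harmonization audit and per-SNP Wald-ratio table (forest/scatter
data), and a run manifest (input checksums, thresholds, seed, version) that
makes re-execution bit-reproducible.

Also here: ``make_fixtures`` (a miniature, fully self-consistent input
bundle for tests and demos) and ``replicate_study`` (a simulation harness
for calibration and robustness experiments).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import yaml

from . import estimators as est
from . import harmonize as hz
from . import io
from . import select as sel
from . import simulate as sim
from .util import split_rng

logger = logging.getLogger("vitamr.pipeline")

__version__ = "0.1.0"

OUTCOME_NAMES = ("susceptibility", "hospitalized", "severe")
INSTRUMENT_SETS = ("all", "vitd_pathway", "annotation_filtered")

#: Emitted atop every results table: the exposure scale and its reference
#: distribution, and the ancestry caveat for the severe-disease outcome.
REPORT_NOTES = (
    "Effects are per standard deviation increase in log-transformed 25OHD "
    "(reference distribution: mean 48.6 nmol/L, SD 21.1 nmol/L).",
    "Outcome effects are log odds ratios from case-control GWAS meta-analyses; "
    "ancestry restriction is handled upstream, and a European-only meta-analysis "
    "may be unavailable for the severe-disease outcome.",
)


@dataclass
class AnalysisConfig:
    """Everything one analysis run needs, with the study's default thresholds."""

    exposure_path: str
    outcome_paths: dict[str, str]
    ld_path: Optional[str] = None
    regions_path: Optional[str] = None
    exclusion_path: Optional[str] = None
    exposure_columns: Optional[str] = None
    outcome_columns: Optional[str] = None
    p_threshold: float = sel.GENOME_WIDE_P
    maf_min: float = sel.DEFAULT_MAF_MIN
    r2_prune: float = sel.DEFAULT_PRUNE_R2
    r2_proxy: float = sel.DEFAULT_PROXY_R2
    palindromic_window: tuple[float, float] = sel.DEFAULT_PALINDROMIC_WINDOW
    region_window_bp: int = 100_000
    ivw_variant: str = "multiplicative_random"
    n_boot: int = est.DEFAULT_N_BOOT
    mode_phi: float = 1.0
    methods: tuple[str, ...] = est.METHODS
    seed: int = 0
    output_dir: str = "."

    def __post_init__(self) -> None:
        if not (0 < self.p_threshold < 1):
            raise io.ConfigError("p_threshold out of range")
        if not (0 < self.maf_min < 0.5):
            raise io.ConfigError("maf_min out of range")
        for name in ("r2_prune", "r2_proxy"):
            if not (0 <= getattr(self, name) <= 1):
                raise io.ConfigError(f"{name} out of range")
        lo, hi = self.palindromic_window
        if not (0 < lo < hi < 1):
            raise io.ConfigError("palindromic_window out of range")
        unknown = set(self.methods) - set(est.METHODS)
        if unknown:
            raise io.ConfigError(f"unknown methods: {sorted(unknown)}")
        self.palindromic_window = (lo, hi)
        self.methods = tuple(self.methods)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise io.ConfigError(f"{path}: config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise io.ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        if "palindromic_window" in raw:
            raw["palindromic_window"] = tuple(raw["palindromic_window"])
        if "methods" in raw:
            raw["methods"] = tuple(raw["methods"])
        return cls(**raw)

    def to_yaml(self, path: Union[str, Path]) -> None:
        d = dataclasses.asdict(self)
        d["palindromic_window"] = list(self.palindromic_window)
        d["methods"] = list(self.methods)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# run_analysis
# ---------------------------------------------------------------------------


def _sha256(path: Union[str, Path]) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _na_row(outcome: str, set_name: str, method: str, n_snps: int, reason: str) -> dict:
    return {
        "outcome": outcome,
        "instrument_set": set_name,
        "method": method,
        "n_snps": n_snps,
        "status": "NA",
        "reason": reason,
    }


def _estimate_row(
    outcome: str, set_name: str, e: est.MREstimate,
    q: Optional[est.HeterogeneityResult], intercept: Optional[est.EggerIntercept],
) -> dict:
    row = {
        "outcome": outcome,
        "instrument_set": set_name,
        "method": e.method,
        "n_snps": e.n_snps,
        "beta": e.beta,
        "se": e.se,
        "ci_low": e.ci_low,
        "ci_high": e.ci_high,
        "pval": e.pval,
        "or": e.or_,
        "or_ci_low": e.or_ci_low,
        "or_ci_high": e.or_ci_high,
        "status": "ok",
        "reason": "",
    }
    if q is not None:
        row.update({"q": q.Q, "q_df": q.df, "q_pval": q.pval})
    if intercept is not None:
        row.update(
            {
                "egger_intercept": intercept.alpha,
                "egger_intercept_se": intercept.se,
                "egger_intercept_ci_low": intercept.ci_low,
                "egger_intercept_ci_high": intercept.ci_high,
                "egger_intercept_pval": intercept.pval,
            }
        )
    return row


def _substitute_proxies(
    iset: sel.InstrumentSet,
    outcome_map: Mapping[str, io.VariantAssociation],
    exposure_map: Mapping[str, io.VariantAssociation],
    ld: io.LDTable,
    config: AnalysisConfig,
) -> sel.InstrumentSet:
    """Swap in proxies for instruments absent from the outcome GWAS or
    palindromic at intermediate frequency; unresolved instruments stay and
    are handled (dropped or logged) at harmonization."""
    lo, hi = config.palindromic_window
    variants: list[io.VariantAssociation] = []
    prov = dict(iset.provenance)
    present = set(iset.ids())
    for v in iset:
        needs = v.variant_id not in outcome_map or (
            v.is_palindromic and v.eaf is not None and lo < v.eaf < hi
        )
        if not needs:
            variants.append(v)
            continue
        proxy = sel.find_proxy(
            v, ld, outcome_map,
            r2_min=config.r2_proxy,
            freq_window=config.palindromic_window,
            exposure_table=exposure_map,
        )
        if proxy is None or proxy.variant_id in present:
            variants.append(v)
            continue
        variants.append(proxy)
        present.add(proxy.variant_id)
        prov[v.variant_id] = f"proxied-by:{proxy.variant_id}"
        prov.setdefault(proxy.variant_id, "kept(proxy)")
    return sel.InstrumentSet(variants, prov)


def _cell_rows(
    outcome: str,
    set_name: str,
    pairs: Sequence[hz.HarmonizedPair],
    config: AnalysisConfig,
) -> list[dict]:
    j = len(pairs)
    rows: list[dict] = []
    q = est.cochran_q(pairs, "ivw") if j >= 2 else None
    try:
        egger_slope, intercept = est.egger(pairs) if j >= 3 else (None, None)
    except ValueError:
        egger_slope, intercept = None, None

    def seed_for(method: str) -> int:
        return int(split_rng(config.seed, outcome, set_name, method).integers(2**31))

    for method in config.methods:
        try:
            if j == 0:
                rows.append(_na_row(outcome, set_name, method, 0, "empty_instrument_set"))
                continue
            if method == "wald":
                if j == 1:
                    e = est.wald_ratio(pairs[0])
                else:
                    rows.append(_na_row(outcome, set_name, method, j, "per_variant_method"))
                    continue
            elif method == "ivw_fe":
                e = est.ivw(pairs, "fixed")
            elif method == "ivw_mre":
                e = est.ivw(pairs, "multiplicative_random")
            elif method == "egger_slope":
                if egger_slope is None:
                    rows.append(_na_row(outcome, set_name, method, j, "needs_3_snps"))
                    continue
                e = egger_slope
            elif method == "egger_bootstrap":
                e = est.egger_bootstrap(pairs, config.n_boot, seed_for(method))
            elif method == "weighted_median":
                e = est.weighted_median(pairs, False, config.n_boot, seed_for(method))
            elif method == "penalized_weighted_median":
                e = est.weighted_median(pairs, True, config.n_boot, seed_for(method))
            elif method == "simple_mode":
                e = est.mode_estimate(pairs, False, config.mode_phi, config.n_boot, seed_for(method))
            elif method == "weighted_mode":
                e = est.mode_estimate(pairs, True, config.mode_phi, config.n_boot, seed_for(method))
            else:  # pragma: no cover - guarded by config validation
                raise io.ConfigError(f"unknown method {method!r}")
        except ValueError as exc:
            rows.append(_na_row(outcome, set_name, method, j, str(exc)))
            continue
        rows.append(_estimate_row(outcome, set_name, est.to_odds_scale(e), q, intercept))
    return rows


def _wald_table(pairs: Sequence[hz.HarmonizedPair], path: Path) -> None:
    import pandas as pd

    rows = []
    for p in pairs:
        w = est.wald_ratio(p)
        rows.append(
            {
                "variant_id": p.variant_id,
                "beta_exposure": repr(p.beta_exposure),
                "se_exposure": repr(p.se_exposure),
                "beta_outcome": repr(p.beta_outcome),
                "se_outcome": repr(p.se_outcome),
                "wald_beta": repr(w.beta),
                "wald_se": repr(w.se),
            }
        )
    pd.DataFrame(
        rows,
        columns=["variant_id", "beta_exposure", "se_exposure",
                 "beta_outcome", "se_outcome", "wald_beta", "wald_se"],
    ).to_csv(path, sep="\t", index=False)


def run_analysis(config: AnalysisConfig) -> dict:
    """Run the full outcome x instrument-set x estimator grid from one config.

    Returns a bundle with the result rows, per-stage instrument sets, kept
    pairs per cell, and the manifest; writes results.tsv, per-cell audit and
    Wald tables, and manifest.json under ``config.output_dir``.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    exposure = io.read_summary_stats(config.exposure_path, config.exposure_columns, "continuous")
    exposure_map = {r.variant_id: r for r in exposure}
    outcomes: dict[str, dict[str, io.VariantAssociation]] = {}
    for name, path in config.outcome_paths.items():
        recs = io.read_summary_stats(path, config.outcome_columns, "binary")
        outcomes[name] = {r.variant_id: r for r in recs}
    ld = io.read_ld_table(config.ld_path) if config.ld_path else io.LDTable()
    regions = (
        io.read_regions(config.regions_path, config.region_window_bp)
        if config.regions_path
        else None
    )
    exclusions = io.read_exclusion_list(config.exclusion_path) if config.exclusion_path else {}

    # shared instrument selection (exposure side)
    sig = sel.filter_significance(exposure, config.p_threshold)
    maf = sel.filter_maf(sig, config.maf_min)
    pruned = sel.ld_prune(maf, ld, config.r2_prune)
    stage_counts = {
        "read": len(exposure),
        "significant": len(sig),
        "maf_ok": len(maf),
        "ld_pruned": len(pruned),
    }
    logger.info("instrument selection: %s", stage_counts)

    sets: dict[str, sel.InstrumentSet] = {"all": pruned}
    if regions:
        pathway = sel.restrict_to_regions(pruned, regions)
        sets["vitd_pathway"] = pathway
        sets["annotation_filtered"] = sel.exclude_annotated(pathway, exclusions)

    rows: list[dict] = []
    cells: dict[tuple[str, str], list[hz.HarmonizedPair]] = {}
    cell_provenance: dict[tuple[str, str], dict[str, str]] = {}
    cell_audit: dict[tuple[str, str], list[dict[str, str]]] = {}
    for set_name in INSTRUMENT_SETS:
        if set_name not in sets:
            for outcome in outcomes:
                for method in config.methods:
                    rows.append(_na_row(outcome, set_name, method, 0, "instrument_set_unavailable"))
            continue
        iset = sets[set_name]
        for outcome, out_map in outcomes.items():
            effective = _substitute_proxies(iset, out_map, exposure_map, ld, config)
            pairs, audit = hz.harmonize_tables(effective.variants, out_map, config.palindromic_window)
            cells[(outcome, set_name)] = pairs
            cell_provenance[(outcome, set_name)] = effective.provenance
            cell_audit[(outcome, set_name)] = audit
            hz.write_audit(audit, out_dir / f"audit_{outcome}_{set_name}.tsv")
            if pairs:
                _wald_table(pairs, out_dir / f"wald_{outcome}_{set_name}.tsv")
            logger.info(
                "%s/%s: %d instruments -> %d harmonized pairs "
                "(%d proxied)",
                outcome, set_name, len(iset), len(pairs),
                sum(1 for s in effective.provenance.values() if s.startswith("proxied-by:")),
            )
            rows.extend(_cell_rows(outcome, set_name, pairs, config))

    results_path = out_dir / "results.tsv"
    notes = REPORT_NOTES + (f"IVW variant: {config.ivw_variant}.",)
    io.write_results_table(rows, results_path, header_notes=notes)

    inputs = {"exposure": config.exposure_path, **{f"outcome_{k}": v for k, v in config.outcome_paths.items()}}
    for key, p in (("ld", config.ld_path), ("regions", config.regions_path), ("exclusions", config.exclusion_path)):
        if p:
            inputs[key] = p
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": {k: v for k, v in dataclasses.asdict(config).items()},
        "input_sha256": {k: _sha256(p) for k, p in inputs.items()},
        "stage_counts": stage_counts,
        "variance_explained": {
            name: sel.variance_explained(s) for name, s in sets.items()
        },
    }
    manifest["config"]["palindromic_window"] = list(config.palindromic_window)
    manifest["config"]["methods"] = list(config.methods)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return {
        "rows": rows,
        "sets": sets,
        "cells": cells,
        "cell_provenance": cell_provenance,
        "cell_audit": cell_audit,
        "stage_counts": stage_counts,
        "manifest": manifest,
        "results_path": str(results_path),
    }


# ---------------------------------------------------------------------------
# Simulation harness (calibration / robustness studies)
# ---------------------------------------------------------------------------

_POINT_ONLY = ("weighted_median", "penalized_weighted_median", "simple_mode", "weighted_mode")


def replicate_study(
    sim_config: sim.SimulationConfig,
    n_reps: int,
    seed: int = 0,
    methods: Sequence[str] = ("ivw_mre",),
    egger_intercept: bool = False,
) -> dict[str, np.ndarray]:
    """Repeatedly simulate, harmonize and estimate; collect per-replicate results.

    Returns arrays keyed ``<method>_beta`` (plus ``ivw_*_ci_low/high`` for
    IVW variants, and ``egger_alpha``/``egger_alpha_pval`` when requested).
    Robust estimators are evaluated as point estimates only — the quantity
    the bias/robustness studies need — keeping large replicate counts cheap.
    """
    out: dict[str, list[float]] = {f"{m}_beta": [] for m in methods}
    for m in methods:
        if m in ("ivw_fe", "ivw_mre"):
            out[f"{m}_ci_low"] = []
            out[f"{m}_ci_high"] = []
    if egger_intercept:
        out["egger_alpha"] = []
        out["egger_alpha_pval"] = []

    rep_seeds = split_rng(seed, "replicates").integers(2**31, size=n_reps)
    for r in range(n_reps):
        cfg = replace(sim_config, seed=int(rep_seeds[r]))
        truth = sim.simulate_truth(cfg)
        exposure, outcome = sim.simulate_summary_stats(truth, cfg)
        pairs, _ = hz.harmonize_tables(exposure, outcome)
        for m in methods:
            if m == "ivw_fe":
                e = est.ivw(pairs, "fixed")
                out["ivw_fe_ci_low"].append(e.ci_low)
                out["ivw_fe_ci_high"].append(e.ci_high)
            elif m == "ivw_mre":
                e = est.ivw(pairs, "multiplicative_random")
                out["ivw_mre_ci_low"].append(e.ci_low)
                out["ivw_mre_ci_high"].append(e.ci_high)
            elif m == "egger_slope":
                e, _icept = est.egger(pairs)
            elif m == "weighted_median":
                e = est.weighted_median(pairs, False, n_boot=0)
            elif m == "penalized_weighted_median":
                e = est.weighted_median(pairs, True, n_boot=0)
            elif m == "simple_mode":
                e = est.mode_estimate(pairs, False, n_boot=0)
            elif m == "weighted_mode":
                e = est.mode_estimate(pairs, True, n_boot=0)
            else:
                raise io.ConfigError(f"replicate_study does not support method {m!r}")
            out[f"{m}_beta"].append(e.beta)
        if egger_intercept:
            _slope, icept = est.egger(pairs)
            out["egger_alpha"].append(icept.alpha)
            out["egger_alpha_pval"].append(icept.pval)
    return {k: np.asarray(v) for k, v in out.items()}


# ---------------------------------------------------------------------------
# Fixture bundle
# ---------------------------------------------------------------------------

#: GRCh37 loci of the four vitamin-D-pathway genes (synthesis, transport,
#: degradation); 1-based inclusive.
VITD_GENE_REGIONS = (
    io.GeneRegion("GC", "4", 72_607_410, 72_669_758),
    io.GeneRegion("CYP2R1", "11", 14_899_553, 14_913_751),
    io.GeneRegion("DHCR7/NADSYN1", "11", 71_145_457, 71_210_000),
    io.GeneRegion("CYP24A1", "20", 52_769_985, 52_790_516),
)

#: The two instruments excluded for non-vitamin-D associations (white blood
#: cell count; glomerular filtration rate).
DEFAULT_EXCLUSIONS = {
    "rs11723621": "associated with white blood cell count",
    "rs6127099": "associated with glomerular filtration rate",
}

# Outcome case/control counts of the emulated meta-analyses.
FIXTURE_OUTCOME_COUNTS = {
    "susceptibility": (14_134, 1_284_876),
    "hospitalized": (6_406, 902_088),
    "severe": (4_336, 623_902),
}

_PROXY_ID = "rs77777"


def _fixture_truth(seed: int) -> sim.TrueInstrumentSet:
    """100 exposure variants with planted edge cases (see make_fixtures)."""
    rng = split_rng(seed, "fixtures", "truth")
    j = 100
    n_exp = sim.DEFAULT_EXPOSURE_N

    eaf = rng.uniform(0.1, 0.4, size=j)
    flip = rng.random(j) < 0.5
    eaf = np.where(flip, 1.0 - eaf, eaf)
    z_true = np.full(j, 15.0)

    chrom = [str((k % 22) + 1) for k in range(j)]
    pos = np.asarray([(k + 1) * 1_000_000 for k in range(j)], dtype=int)
    ids = [f"rs{1000 + k}" for k in range(j)]
    effect, other = [], []
    for k in range(j):
        pal = rng.random() < 0.2
        pool = sim._PALINDROMIC_PAIRS if pal else sim._STANDARD_PAIRS
        ea, oa = pool[rng.integers(len(pool))]
        effect.append(ea)
        other.append(oa)

    # rows 10..20: the 11 pathway instruments (standard alleles)
    region_spots = [
        ("4", 72_609_398), ("4", 72_620_000), ("4", 72_635_000), ("4", 72_650_000),   # GC
        ("11", 14_900_500), ("11", 14_905_000), ("11", 14_910_000),                   # CYP2R1
        ("11", 71_150_000), ("11", 71_190_000),                                       # DHCR7/NADSYN1
        ("20", 52_732_362), ("20", 52_780_000),                                       # CYP24A1
    ]
    for off, (c, p) in enumerate(region_spots):
        k = 10 + off
        chrom[k] = c
        pos[k] = p
        effect[k], other[k] = sim._STANDARD_PAIRS[rng.integers(len(sim._STANDARD_PAIRS))]
    ids[10] = "rs11723621"
    ids[19] = "rs6127099"

    # row 90: palindromic at exactly intermediate frequency -> must be dropped
    effect[90], other[90] = "A", "T"
    eaf[90] = 0.5
    # row 91: standard variant, absent from the susceptibility GWAS, with a proxy
    effect[91], other[91] = "A", "G"
    # rows 93/94: in LD (r2=0.6) with rows 0/1 but weaker -> pruned
    z_true[[93, 94]] = 9.0
    # rows 95/96: not genome-wide significant
    z_true[[95, 96]] = 1.0
    # rows 97-99: rare (MAF 0.5%) -> fail the MAF filter
    eaf[[97, 98, 99]] = 0.005

    se_x = sim.exposure_se(eaf, n_exp)
    gamma = z_true * se_x
    return sim.TrueInstrumentSet(
        variant_ids=ids,
        chrom=chrom,
        pos=pos,
        effect_allele=effect,
        other_allele=other,
        maf=np.minimum(eaf, 1.0 - eaf),
        eaf=eaf,
        gamma=gamma,
        alpha=np.zeros(j),
    )


def make_fixtures(out_dir: Union[str, Path], seed: int = 0) -> dict[str, str]:
    """Write a miniature but complete input bundle under ``out_dir``.

    100 exposure variants (a null causal effect throughout) engineered so the
    selection stages have exact, derivable accounting: 2 sub-significant,
    3 rare (MAF 0.5%), 2 pruned away by a tabled r2 of 0.6, one palindromic
    variant at frequency 0.50 (unresolvable, no proxy), one instrument absent
    from the susceptibility GWAS with an r2=0.95 phased proxy, 11 instruments
    inside the four vitamin-D-pathway gene regions (GRCh37), 2 of them on the
    exclusion list.  Outcome tables get seeded allele-coding corruptions that
    harmonization must undo.  Returns the bundle's paths (incl. a ready
    ``config.yaml``).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truth = _fixture_truth(seed)
    base = sim.SimulationConfig(
        n_variants=truth.n, causal_beta=0.0, target_r2=0.04, seed=seed
    )

    exposure, _ = sim.simulate_summary_stats(truth, base, stream="exposure-table")
    paths: dict[str, str] = {}
    io.write_summary_stats(exposure, out_dir / "exposure.tsv")
    paths["exposure"] = str(out_dir / "exposure.tsv")

    proxy_eaf = 0.3
    rng_proxy = split_rng(seed, "fixtures", "proxy")
    for name, (n_cases, n_controls) in FIXTURE_OUTCOME_COUNTS.items():
        cfg = replace(base, outcome_n_cases=n_cases, outcome_n_controls=n_controls)
        _, outcome = sim.simulate_summary_stats(truth, cfg, stream=name)
        se_p = float(sim.outcome_se(np.array([proxy_eaf]), cfg.outcome_n, cfg.case_fraction)[0])
        beta_p = float(rng_proxy.normal(0.0, se_p))
        outcome.append(
            io.VariantAssociation(
                variant_id=_PROXY_ID, chrom="11", pos=92_500_000,
                effect_allele="G", other_allele="T", eaf=proxy_eaf,
                beta=beta_p, se=se_p,
                pval=float(sim._pvals(np.array([beta_p]), np.array([se_p]))[0]),
                n=cfg.outcome_n, n_cases=n_cases, n_controls=n_controls,
            )
        )
        if name == "susceptibility":
            outcome = [r for r in outcome if r.variant_id != "rs1091"]
        corrupted, ledger = sim.corrupt_allele_coding(
            outcome, swap_frac=0.15, strandflip_frac=0.15,
            seed=int(split_rng(seed, "fixtures", "corrupt", name).integers(2**31)),
        )
        io.write_summary_stats(corrupted, out_dir / f"outcome_{name}.tsv")
        paths[f"outcome_{name}"] = str(out_dir / f"outcome_{name}.tsv")
        with open(out_dir / f"corruption_{name}.tsv", "w") as fh:
            fh.write("variant_id\taction\n")
            for vid, action in ledger:
                fh.write(f"{vid}\t{action}\n")

    ld_records = [
        io.LDRecord("rs1000", "rs1093", 0.6, truth.effect_allele[0], truth.effect_allele[93]),
        io.LDRecord("rs1001", "rs1094", 0.6, truth.effect_allele[1], truth.effect_allele[94]),
        io.LDRecord("rs1091", _PROXY_ID, 0.95, "A", "G"),
        io.LDRecord("rs1000", "rs1000", 1.0),
    ]
    io.write_ld_table(ld_records, out_dir / "ld.tsv")
    paths["ld"] = str(out_dir / "ld.tsv")

    io.write_regions(VITD_GENE_REGIONS, out_dir / "regions.tsv")
    paths["regions"] = str(out_dir / "regions.tsv")
    io.write_exclusion_list(DEFAULT_EXCLUSIONS, out_dir / "exclusions.tsv")
    paths["exclusions"] = str(out_dir / "exclusions.tsv")

    truth.write(out_dir / "truth.tsv")
    paths["truth"] = str(out_dir / "truth.tsv")

    config = AnalysisConfig(
        exposure_path=paths["exposure"],
        outcome_paths={name: paths[f"outcome_{name}"] for name in FIXTURE_OUTCOME_COUNTS},
        ld_path=paths["ld"],
        regions_path=paths["regions"],
        exclusion_path=paths["exclusions"],
        n_boot=200,
        seed=seed,
        output_dir=str(out_dir / "results"),
    )
    config.to_yaml(out_dir / "config.yaml")
    paths["config"] = str(out_dir / "config.yaml")
    return paths
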