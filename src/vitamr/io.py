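"""Reading and writing of GWAS summary-statistic tables and pipeline side files.

All tables are tab-delimited text with a header.  A ``column_map`` adapts
arbitrary header dialects to the canonical field names used throughout the
package; two presets ship for the common cases.  Validation is enforced at
this boundary: every record handed to downstream code satisfies the
``VariantAssociation`` invariants, and rows that do not are rejected with
row-numbered diagnostics on the package logger.

Coordinates are 1-based inclusive throughout (region files may be supplied
in 0-based BED-like form and are converted on read).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

logger = logging.getLogger("vitamr.io")

VALID_ALLELES = frozenset("ACGT")


class ConfigError(ValueError):
    """A configuration problem (missing column, bad mapping, bad threshold)."""


class DataError(ValueError):
    """A data problem that cannot be skipped row-wise (e.g. duplicate IDs)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariantAssociation:
    """One variant's association record in one GWAS.

    ``beta`` is the additive effect per copy of ``effect_allele``: SD units of
    the (standardized, log-transformed) exposure for a continuous trait, or a
    log odds ratio for a binary trait.  ``eaf`` is the effect-allele
    frequency; it may be missing, in which case the variant is unusable for
    palindromic-frequency orientation and variance-explained computations.
    """

    variant_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    chrom: str = "0"
    pos: int = 0
    eaf: Optional[float] = None
    n: Optional[int] = None
    n_cases: Optional[int] = None
    n_controls: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "effect_allele", str(self.effect_allele).upper())
        object.__setattr__(self, "other_allele", str(self.other_allele).upper())
        if self.effect_allele not in VALID_ALLELES or self.other_allele not in VALID_ALLELES:
            raise ValueError(
                f"{self.variant_id}: alleles must be single bases A/C/G/T, got "
                f"{self.effect_allele}/{self.other_allele}"
            )
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.variant_id}: effect and other allele are identical")
        if not self.se > 0:
            raise ValueError(f"{self.variant_id}: se must be > 0, got {self.se}")
        if not (0 < self.pval <= 1):
            raise ValueError(f"{self.variant_id}: pval must be in (0, 1], got {self.pval}")
        if self.eaf is not None and not (0 < self.eaf < 1):
            raise ValueError(f"{self.variant_id}: eaf must be strictly inside (0, 1), got {self.eaf}")

    @property
    def maf(self) -> Optional[float]:
        if self.eaf is None:
            return None
        return min(self.eaf, 1.0 - self.eaf)

    @property
    def is_palindromic(self) -> bool:
        return {self.effect_allele, self.other_allele} in ({"A", "T"}, {"C", "G"})


@dataclass(frozen=True)
class LDRecord:
    """A pairwise linkage-disequilibrium entry with allele phase.

    ``allele_a``/``allele_b`` record which allele of ``variant_b`` travels on
    the same haplotype as which allele of ``variant_a``; they may be absent
    when phase is unknown (such pairs cannot orient a proxy's effect).
    """

    variant_a: str
    variant_b: str
    r2: float
    allele_a: Optional[str] = None
    allele_b: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.r2 <= 1.0):
            raise ValueError(f"r2 must be in [0, 1], got {self.r2}")


class LDTable:
    """Lookup structure over pairwise r2/phase, symmetric in its two arguments."""

    def __init__(self, records: Iterable[LDRecord] = ()) -> None:
        self._pairs: dict[tuple[str, str], LDRecord] = {}
        for rec in records:
            self.add(rec)

    def add(self, rec: LDRecord) -> None:
        self._pairs[(rec.variant_a, rec.variant_b)] = rec

    def __len__(self) -> int:
        return len(self._pairs)

    def _get(self, a: str, b: str) -> Optional[LDRecord]:
        rec = self._pairs.get((a, b))
        if rec is not None:
            return rec
        rec = self._pairs.get((b, a))
        if rec is None:
            return None
        return LDRecord(a, b, rec.r2, rec.allele_b, rec.allele_a)

    def r2(self, a: str, b: str) -> Optional[float]:
        rec = self._get(a, b)
        return None if rec is None else rec.r2

    def phase(self, a: str, b: str) -> Optional[tuple[str, str]]:
        """Allele pairing oriented as (allele of a, co-travelling allele of b)."""
        rec = self._get(a, b)
        if rec is None or rec.allele_a is None or rec.allele_b is None:
            return None
        return (rec.allele_a, rec.allele_b)

    def partners(self, a: str) -> list[tuple[str, float]]:
        """All tabled partners of ``a`` (self-pairs excluded), with their r2."""
        out = []
        for (x, y), rec in self._pairs.items():
            if x == a and y != a:
                out.append((y, rec.r2))
            elif y == a and x != a:
                out.append((x, rec.r2))
        return sorted(out)


@dataclass(frozen=True)
class GeneRegion:
    """A gene locus (1-based inclusive) plus a flanking window in bp."""

    gene: str
    chrom: str
    start: int
    end: int
    window_bp: int = 100_000

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene}: start > end")
        if self.window_bp < 0:
            raise ValueError(f"{self.gene}: window_bp must be >= 0")

    def contains(self, chrom: str, pos: int) -> bool:
        return normalize_chrom(chrom) == normalize_chrom(self.chrom) and (
            self.start - self.window_bp <= pos <= self.end + self.window_bp
        )


def normalize_chrom(chrom: str) -> str:
    c = str(chrom).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    return c.upper()


# ---------------------------------------------------------------------------
# Column dialects
# ---------------------------------------------------------------------------

CANONICAL_COLUMNS = (
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
    "n_cases",
    "n_controls",
)

MANDATORY_COLUMNS = ("variant_id", "effect_allele", "other_allele", "beta", "se", "pval")

#: Header presets.  ``default`` is this package's own dialect; ``gwas`` is the
#: compact SNP/EA/OA/EAF/BETA/SE/P style; ``hgi`` is a best-effort mapping of
#: the COVID-19 Host Genetics Initiative meta-analysis headers (ALT is the
#: effect allele there).  All are overridable via an explicit column_map.
COLUMN_PRESETS: dict[str, dict[str, str]] = {
    "default": {c: c for c in CANONICAL_COLUMNS},
    "gwas": {
        "variant_id": "SNP",
        "chrom": "CHR",
        "pos": "BP",
        "effect_allele": "EA",
        "other_allele": "OA",
        "eaf": "EAF",
        "beta": "BETA",
        "se": "SE",
        "pval": "P",
        "n": "N",
    },
    "hgi": {
        "variant_id": "rsid",
        "chrom": "#CHR",
        "pos": "POS",
        "effect_allele": "ALT",
        "other_allele": "REF",
        "eaf": "all_meta_AF",
        "beta": "all_inv_var_meta_beta",
        "se": "all_inv_var_meta_sebeta",
        "pval": "all_inv_var_meta_p",
        "n_cases": "all_inv_var_meta_cases",
        "n_controls": "all_inv_var_meta_controls",
    },
}


def _resolve_column_map(column_map: Union[None, str, Mapping[str, str]]) -> dict[str, str]:
    if column_map is None:
        return COLUMN_PRESETS["default"]
    if isinstance(column_map, str):
        try:
            return COLUMN_PRESETS[column_map]
        except KeyError:
            raise ConfigError(
                f"unknown column preset {column_map!r}; available: {sorted(COLUMN_PRESETS)}"
            ) from None
    unknown = set(column_map) - set(CANONICAL_COLUMNS)
    if unknown:
        raise ConfigError(f"column_map contains unknown canonical names: {sorted(unknown)}")
    return {**COLUMN_PRESETS["default"], **dict(column_map)}


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def _opt_float(v) -> Optional[float]:
    if v is None or (isinstance(v, float) and pd.isna(v)) or v == "":
        return None
    return float(v)


def _opt_int(v) -> Optional[int]:
    f = _opt_float(v)
    return None if f is None else int(round(f))


def read_summary_stats(
    path: Union[str, Path],
    column_map: Union[None, str, Mapping[str, str]] = None,
    trait_type: str = "continuous",
) -> list[VariantAssociation]:
    """Read a delimited summary-statistic table into validated records.

    Rows violating record invariants (non-positive SE, p outside (0,1], bad
    alleles, unparseable numbers) are skipped and reported row-by-row on the
    ``vitamr.io`` logger; a duplicated variant_id is a hard error; a missing
    mandatory column is a configuration error.
    """
    if trait_type not in ("continuous", "binary"):
        raise ConfigError(f"trait_type must be 'continuous' or 'binary', got {trait_type!r}")
    cmap = _resolve_column_map(column_map)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [cmap[c] for c in MANDATORY_COLUMNS if cmap[c] not in df.columns]
    if missing:
        raise ConfigError(f"{path}: missing mandatory column(s) {missing}")

    records: list[VariantAssociation] = []
    seen: dict[str, int] = {}
    n_skipped = 0
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        rowd = dict(zip(df.columns, row))

        def get(canon: str):
            col = cmap.get(canon)
            return rowd.get(col) if col else None

        vid = str(get("variant_id"))
        if vid in seen:
            raise DataError(f"{path}: duplicate variant_id {vid!r} (lines {seen[vid]} and {i})")
        seen[vid] = i
        try:
            rec = VariantAssociation(
                variant_id=vid,
                chrom=str(get("chrom")) if get("chrom") is not None else "0",
                pos=_opt_int(get("pos")) or 0,
                effect_allele=str(get("effect_allele")),
                other_allele=str(get("other_allele")),
                eaf=_opt_float(get("eaf")),
                beta=float(get("beta")),
                se=float(get("se")),
                pval=float(get("pval")),
                n=_opt_int(get("n")),
                n_cases=_opt_int(get("n_cases")) if trait_type == "binary" else _opt_int(get("n_cases")),
                n_controls=_opt_int(get("n_controls")),
            )
        except (TypeError, ValueError) as exc:
            n_skipped += 1
            logger.warning("%s line %d: skipped row (%s)", path, i, exc)
            continue
        records.append(rec)
    if n_skipped:
        logger.warning("%s: skipped %d of %d rows failing validation", path, n_skipped, len(df))
    return records


def write_summary_stats(records: Sequence[VariantAssociation], path: Union[str, Path]) -> None:
    """Write records in the canonical tab-delimited dialect (round-trippable)."""
    rows = []
    for r in records:
        rows.append(
            {
                "variant_id": r.variant_id,
                "chrom": r.chrom,
                "pos": r.pos,
                "effect_allele": r.effect_allele,
                "other_allele": r.other_allele,
                "eaf": "" if r.eaf is None else repr(r.eaf),
                "beta": repr(r.beta),
                "se": repr(r.se),
                "pval": repr(r.pval),
                "n": "" if r.n is None else r.n,
                "n_cases": "" if r.n_cases is None else r.n_cases,
                "n_controls": "" if r.n_controls is None else r.n_controls,
            }
        )
    pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS)).to_csv(path, sep="\t", index=False)


def read_ld_table(path: Union[str, Path]) -> LDTable:
    """Read a pairwise LD table (variant_a, variant_b, r2[, allele_a, allele_b])."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("variant_a", "variant_b", "r2"):
        if col not in df.columns:
            raise ConfigError(f"{path}: missing mandatory column {col!r}")
    table = LDTable()
    n_skipped = 0
    for i, rowd in enumerate(df.to_dict("records"), start=2):
        try:
            a_a = rowd.get("allele_a")
            a_b = rowd.get("allele_b")
            rec = LDRecord(
                variant_a=str(rowd["variant_a"]),
                variant_b=str(rowd["variant_b"]),
                r2=float(rowd["r2"]),
                allele_a=None if a_a is None or pd.isna(a_a) else str(a_a).upper(),
                allele_b=None if a_b is None or pd.isna(a_b) else str(a_b).upper(),
            )
        except (TypeError, ValueError) as exc:
            n_skipped += 1
            logger.warning("%s line %d: skipped LD row (%s)", path, i, exc)
            continue
        table.add(rec)
    if n_skipped:
        logger.warning("%s: skipped %d LD rows failing validation", path, n_skipped)
    return table


def write_ld_table(records: Sequence[LDRecord], path: Union[str, Path]) -> None:
    rows = [
        {
            "variant_a": r.variant_a,
            "variant_b": r.variant_b,
            "r2": repr(r.r2),
            "allele_a": r.allele_a or "",
            "allele_b": r.allele_b or "",
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=["variant_a", "variant_b", "r2", "allele_a", "allele_b"]).to_csv(
        path, sep="\t", index=False
    )


def read_regions(path: Union[str, Path], default_window_bp: int = 100_000) -> list[GeneRegion]:
    """Read gene regions from a BED-like TSV: chrom, start(0-based), end, gene[, window_bp].

    Intervals are converted to the package's 1-based inclusive convention.
    """
    regions: list[GeneRegion] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise DataError(f"{path}: region lines need >= 4 columns, got {line!r}")
            try:
                start0, end0 = int(parts[1]), int(parts[2])
            except ValueError:
                continue  # header line
            window = int(parts[4]) if len(parts) > 4 and parts[4] != "" else default_window_bp
            regions.append(
                GeneRegion(gene=parts[3], chrom=parts[0], start=start0 + 1, end=end0, window_bp=window)
            )
    return regions


def write_regions(regions: Sequence[GeneRegion], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.gene}\t{r.window_bp}\n")


def read_exclusion_list(path: Union[str, Path]) -> dict[str, str]:
    """Read an exclusion list: one variant ID per line, optional tab-separated reason."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t", 1)
            out[parts[0]] = parts[1] if len(parts) > 1 else ""
    return out


def write_exclusion_list(exclusions: Mapping[str, str], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for vid, reason in exclusions.items():
            fh.write(f"{vid}\t{reason}\n" if reason else f"{vid}\n")


# ---------------------------------------------------------------------------
# Results table
# ---------------------------------------------------------------------------

RESULT_COLUMNS = (
    "outcome",
    "instrument_set",
    "method",
    "n_snps",
    "beta",
    "se",
    "ci_low",
    "ci_high",
    "pval",
    "or",
    "or_ci_low",
    "or_ci_high",
    "q",
    "q_df",
    "q_pval",
    "egger_intercept",
    "egger_intercept_se",
    "egger_intercept_ci_low",
    "egger_intercept_ci_high",
    "egger_intercept_pval",
    "status",
    "reason",
)


def write_results_table(
    rows: Sequence[Mapping[str, object]],
    path: Union[str, Path],
    header_notes: Sequence[str] = (),
) -> None:
    """Write the pipeline's results table: one row per (outcome x set x method).

    Column order is fixed (:data:`RESULT_COLUMNS`); floats are written with
    17 significant digits so a read-back reproduces them exactly.
    ``header_notes`` are emitted as ``#``-prefixed comment lines above the
    header (units, caveats); :func:`read_results_table` skips them.
    """
    if not rows:
        raise DataError("write_results_table: no rows to write")
    out = []
    for row in rows:
        rec = {}
        for col in RESULT_COLUMNS:
            v = row.get(col)
            if isinstance(v, float):
                rec[col] = "" if pd.isna(v) else repr(v)
            elif v is None:
                rec[col] = ""
            else:
                rec[col] = v
        out.append(rec)
    with open(path, "w") as fh:
        for note in header_notes:
            fh.write(f"# {note}\n")
        pd.DataFrame(out, columns=list(RESULT_COLUMNS)).to_csv(fh, sep="\t", index=False)


def read_results_table(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(RESULT_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"{path}: results table missing columns {sorted(missing)}")
    return df
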