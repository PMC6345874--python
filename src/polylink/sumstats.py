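"""GWAS summary-statistics tables: reading, validation, writing, allele
harmonization and risk orientation.

Tables are tab-delimited text with a header row (gzip-transparent).  Column
names from different sources are mapped through a *dialect*; odds-ratio
columns are converted to log odds ratios at read time.  All effects in a
harmonized set are expressed for one common effect allele per variant.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "SumstatTable",
    "Dialect",
    "DEFAULT_DIALECT",
    "read_sumstats",
    "write_sumstats",
    "harmonize",
    "orient_to_risk",
]

_CANON_COLS = ["variant_id", "chr", "pos", "effect_allele", "other_allele",
               "beta", "se", "pvalue", "eaf", "info", "n"]
_MANDATORY = ["variant_id", "chr", "pos", "effect_allele", "other_allele",
              "se", "pvalue", "eaf"]
_VALID_ALLELES = {"A", "C", "G", "T"}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class Dialect:
    """Maps source column names onto the canonical schema.

    ``effect_col`` names the effect-size column; ``effect_is_or`` forces
    odds-ratio interpretation (otherwise auto-detected from the name).
    """

    columns: dict[str, str] = field(default_factory=dict)  # canonical -> source
    effect_col: str = "beta"
    effect_is_or: bool | None = None

    def source_name(self, canonical: str) -> str:
        return self.columns.get(canonical, canonical)

    def or_scale(self) -> bool:
        if self.effect_is_or is not None:
            return self.effect_is_or
        return self.effect_col.strip().lower() in {"or", "odds_ratio", "oddsratio"}


DEFAULT_DIALECT = Dialect()


@dataclass
class SumstatTable:
    """One trait's per-variant association records, one allele orientation.

    ``data`` holds the canonical columns; variant_id is unique and rows are
    sorted by (chr, pos).
    """

    trait: str
    trait_type: str                 # "binary" | "quantitative"
    data: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        self.data = self.data.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    def sorted(self) -> "SumstatTable":
        df = self.data.sort_values(["chr", "pos"], kind="mergesort")
        return replace(self, data=df.reset_index(drop=True))


def _validate_rows(df: pd.DataFrame, check_p_consistency: bool = True,
                   ) -> tuple[pd.DataFrame, int]:
    """Drop rows violating record invariants; return (valid rows, n dropped)."""
    ok = pd.Series(True, index=df.index)
    ok &= df["se"] > 0
    ok &= df["effect_allele"].isin(_VALID_ALLELES)
    ok &= df["other_allele"].isin(_VALID_ALLELES)
    ok &= df["effect_allele"] != df["other_allele"]
    ok &= (df["pvalue"] > 0) & (df["pvalue"] <= 1)
    ok &= (df["eaf"] > 0) & (df["eaf"] < 1)
    if "info" in df:
        ok &= df["info"].between(0, 1) | df["info"].isna()
    ok &= df["beta"].notna() & np.isfinite(df["beta"])
    if check_p_consistency:
        # P should agree with the two-sided normal approximation of beta/se;
        # generous tolerance covers rounding of either column at the source
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (df["beta"] / df["se"]).abs()
            p_expect = 2.0 * stats.norm.sf(z)
        lp_obs = -np.log10(df["pvalue"].clip(lower=1e-300))
        lp_exp = -np.log10(np.clip(p_expect, 1e-300, 1.0))
        ok &= (lp_obs - lp_exp).abs() < 2.0
    dropped = int((~ok).sum())
    return df[ok], dropped


def read_sumstats(path: str | Path, dialect: Dialect | None = None,
                  trait: str = "", trait_type: str = "quantitative",
                  ) -> SumstatTable:
    """Read a tab-delimited summary-statistics file into canonical form.

    Rows failing record validation (non-positive SE, invalid alleles or
    frequencies, P outside (0, 1], P inconsistent with beta/se) are dropped
    with a logged count.  Raises if a mandatory column is missing or no
    valid rows remain.
    """
    dialect = dialect or DEFAULT_DIALECT
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        raw = pd.read_csv(fh, sep="\t", dtype={dialect.source_name("chr"): str})

    colmap = {}
    for canon in _CANON_COLS:
        src = dialect.source_name(canon) if canon != "beta" else dialect.effect_col
        if src in raw.columns:
            colmap[src] = canon
    df = raw.rename(columns=colmap)

    missing = [c for c in _MANDATORY if c not in df.columns]
    if "beta" not in df.columns:
        missing.append(f"effect column '{dialect.effect_col}'")
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s): {', '.join(missing)}")

    if dialect.or_scale():
        if (df["beta"] <= 0).any():
            bad = int((df["beta"] <= 0).sum())
            logger.warning("%s: dropping %d rows with non-positive OR", path, bad)
            df = df[df["beta"] > 0]
        df = df.assign(beta=np.log(df["beta"].astype(float)))

    for c in ("pos", "n"):
        if c in df.columns:
            df[c] = pd.to_numeric(df[c], errors="coerce")
    if "info" not in df.columns:
        df["info"] = np.nan
    if "n" not in df.columns:
        df["n"] = np.nan
    for c in ("effect_allele", "other_allele"):
        df[c] = df[c].astype(str).str.upper()

    df = df[_CANON_COLS]
    df, dropped = _validate_rows(df)
    if dropped:
        logger.info("%s: dropped %d invalid rows", path, dropped)
    if df["variant_id"].duplicated().any():
        ndup = int(df["variant_id"].duplicated().sum())
        logger.info("%s: dropped %d duplicate variant ids", path, ndup)
        df = df[~df["variant_id"].duplicated()]
    if len(df) == 0:
        raise ValueError(f"{path}: no valid rows after validation")

    table = SumstatTable(trait=trait or path.stem, trait_type=trait_type,
                         data=df.reset_index(drop=True),
                         provenance=str(path))
    return table.sorted()


def write_sumstats(table: SumstatTable, path: str | Path) -> None:
    """Write a table in the canonical tab-delimited dialect."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        table.data.to_csv(fh, sep="\t", index=False, na_rep="NA")


def _is_palindromic(ea: pd.Series, oa: pd.Series) -> pd.Series:
    return oa == ea.map(_COMPLEMENT)


def harmonize(tables: list[SumstatTable], drop_palindromic: bool = True,
              eaf_rescue_margin: float = 0.1,
              ) -> pd.DataFrame:
    """Join >= 2 tables over shared variants in one allele orientation.

    The first table is the reference.  Non-reference records whose
    effect/other alleles are swapped relative to the reference get their
    beta sign flipped and eaf replaced by 1 - eaf.  Strand-ambiguous (A/T,
    C/G) variants are dropped by default; with ``drop_palindromic=False``
    they are kept only when |eaf - 0.5| > ``eaf_rescue_margin`` in both
    tables and the frequencies are orientation-concordant.  Variants with
    incompatible allele pairs are dropped with a logged reason.

    Returns a wide frame indexed by variant_id with the reference variant
    columns plus ``beta_<trait>``, ``se_<trait>``, ``pvalue_<trait>``,
    ``eaf_<trait>`` for every table.
    """
    if len(tables) < 2:
        raise ValueError("harmonize needs at least two tables")
    names = [t.trait for t in tables]
    if len(set(names)) != len(names):
        raise ValueError("tables must have distinct trait labels")

    ref = tables[0].data.set_index("variant_id")
    out = ref[["chr", "pos", "effect_allele", "other_allele", "info"]].copy()
    out[f"beta_{names[0]}"] = ref["beta"]
    out[f"se_{names[0]}"] = ref["se"]
    out[f"pvalue_{names[0]}"] = ref["pvalue"]
    out[f"eaf_{names[0]}"] = ref["eaf"]

    pal = _is_palindromic(ref["effect_allele"], ref["other_allele"])
    if drop_palindromic and pal.any():
        logger.info("harmonize: dropping %d strand-ambiguous reference variants",
                    int(pal.sum()))
        out = out[~pal]

    for t in tables[1:]:
        other = t.data.set_index("variant_id")
        shared = out.index.intersection(other.index)
        out = out.loc[shared]
        oth = other.loc[shared]

        same = (oth["effect_allele"] == out["effect_allele"]) & \
               (oth["other_allele"] == out["other_allele"])
        swapped = (oth["effect_allele"] == out["other_allele"]) & \
                  (oth["other_allele"] == out["effect_allele"])
        # allow strand-complement matches for non-ambiguous variants
        comp_ea = oth["effect_allele"].map(_COMPLEMENT)
        comp_oa = oth["other_allele"].map(_COMPLEMENT)
        same |= (comp_ea == out["effect_allele"]) & (comp_oa == out["other_allele"])
        swapped |= (comp_ea == out["other_allele"]) & (comp_oa == out["effect_allele"])

        keep = same | swapped
        pal2 = _is_palindromic(oth["effect_allele"], oth["other_allele"])
        if drop_palindromic:
            keep &= ~pal2
        else:
            clear = ((oth["eaf"] - 0.5).abs() > eaf_rescue_margin) & \
                    ((out[f"eaf_{names[0]}"] - 0.5).abs() > eaf_rescue_margin)
            concordant = ((oth["eaf"] > 0.5) == (out[f"eaf_{names[0]}"] > 0.5))
            flip_conc = ((1 - oth["eaf"]) > 0.5) == (out[f"eaf_{names[0]}"] > 0.5)
            keep &= ~pal2 | (clear & np.where(swapped, flip_conc, concordant))
        n_drop = int((~keep).sum())
        if n_drop:
            logger.info("harmonize: dropping %d variants for table %s "
                        "(allele mismatch or strand ambiguity)", n_drop, t.trait)

        out = out[keep]
        oth = oth[keep]
        sign = np.where(swapped[keep], -1.0, 1.0)
        out[f"beta_{t.trait}"] = oth["beta"] * sign
        out[f"se_{t.trait}"] = oth["se"]
        out[f"pvalue_{t.trait}"] = oth["pvalue"]
        out[f"eaf_{t.trait}"] = np.where(swapped[keep], 1.0 - oth["eaf"], oth["eaf"])

    if len(out) == 0:
        raise ValueError("harmonize: zero shared variants after allele matching")
    return out.sort_values(["chr", "pos"], kind="mergesort")


def orient_to_risk(table: SumstatTable) -> SumstatTable:
    """Return a copy with every effect aligned to the risk-increasing allele.

    Where beta < 0, the effect and other alleles are swapped, eaf becomes
    1 - eaf and beta flips sign; |beta|, SE and P are unchanged.  beta == 0
    rows are left in their original orientation.  Idempotent.
    """
    if table.trait_type != "binary":
        raise ValueError("orient_to_risk applies to binary (case-control) tables")
    df = table.data.copy()
    flip = df["beta"] < 0
    ea = df["effect_allele"].where(~flip, df["other_allele"])
    oa = df["other_allele"].where(~flip, df["effect_allele"])
    df["effect_allele"] = ea
    df["other_allele"] = oa
    df["eaf"] = df["eaf"].where(~flip, 1.0 - df["eaf"])
    df["beta"] = df["beta"].abs().where(df["beta"] != 0, 0.0)
    return replace(table, data=df)
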