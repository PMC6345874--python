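"""Genetic-instrument selection: P/INFO/frequency filters and greedy LD
clumping.

The *conservative* set keeps genome-wide significant variants
(P < 5e-8); the *subthreshold* set uses the lenient P < 0.0015 cut.  Both
are restricted to well-imputed (INFO > 0.8), common (minor-allele
frequency > 0.01) variants and thinned to approximate independence by
greedy clumping (index variants by ascending P; neighbours within +/-500 kb
at LD r^2 >= 0.25 removed), matching PLINK clump semantics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .sumstats import SumstatTable

logger = logging.getLogger(__name__)

__all__ = [
    "CONSERVATIVE_P", "SUBTHRESHOLD_P",
    "InstrumentSet", "LdReference",
    "filter_variants", "clump", "instrument_strength",
]

CONSERVATIVE_P = 5e-8
SUBTHRESHOLD_P = 0.0015


class LdReference:
    """Pairwise LD r^2 accessor backed by reference-panel dosages or a
    sparse triplet file.

    ``r2(id1, id2)`` returns the squared dosage correlation, or None when a
    pair is unknown (triplet-file mode) -- the clumping routine decides how
    to treat missing entries.
    """

    def __init__(self, dosages: np.ndarray | None = None,
                 variant_ids: list[str] | None = None,
                 pairs: dict[tuple[str, str], float] | None = None):
        self._pairs = pairs
        self._dos = None
        if dosages is not None:
            if variant_ids is None or dosages.shape[1] != len(variant_ids):
                raise ValueError("dosages and variant_ids misaligned")
            x = dosages.astype(np.float32)
            x = x - x.mean(axis=0)
            sd = x.std(axis=0)
            sd[sd == 0] = np.inf
            self._dos = x / sd
            self._col = {v: i for i, v in enumerate(variant_ids)}

    @classmethod
    def from_triplets(cls, path: str | Path) -> "LdReference":
        """Load a sparse (id1, id2, r2) tab-delimited file."""
        df = pd.read_csv(path, sep="\t", names=["id1", "id2", "r2"],
                         header=None, comment="#", dtype={"r2": float})
        pairs: dict[tuple[str, str], float] = {}
        for a, b, r2 in df.itertuples(index=False):
            pairs[(str(a), str(b))] = r2
            pairs[(str(b), str(a))] = r2
        return cls(pairs=pairs)

    def r2(self, id1: str, id2: str) -> float | None:
        if id1 == id2:
            return 1.0
        if self._dos is not None:
            i, j = self._col.get(id1), self._col.get(id2)
            if i is None or j is None:
                return None
            n = self._dos.shape[0]
            r = float(self._dos[:, i] @ self._dos[:, j]) / n
            return r * r
        if self._pairs is not None:
            return self._pairs.get((id1, id2))
        return None


@dataclass
class InstrumentSet:
    """A clumped, filtered instrument list with selection provenance."""

    label: str
    p_threshold: float
    variants: pd.DataFrame
    r2_max: float = 0.25
    window_kb: float = 500.0
    filter_log: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.variants["variant_id"])

    def write(self, path: str | Path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write(f"# label={self.label} p_threshold={self.p_threshold:g} "
                     f"r2_max={self.r2_max:g} window_kb={self.window_kb:g}\n")
            for k, v in self.filter_log.items():
                fh.write(f"# {k}={v}\n")
            self.variants.to_csv(fh, sep="\t", index=False)


def filter_variants(table: SumstatTable, p_max: float = SUBTHRESHOLD_P,
                    info_min: float = 0.8, eaf_min: float = 0.01,
                    ) -> SumstatTable:
    """Apply the P, imputation-quality and frequency filters.

    The frequency filter acts on the minor-allele frequency,
    min(eaf, 1-eaf) > eaf_min; all comparisons are strict, so a variant at
    INFO == 0.8 exactly is excluded.  An empty result is returned with a
    warning, not an error.
    """
    df = table.data
    maf = np.minimum(df["eaf"], 1.0 - df["eaf"])
    info = df["info"].fillna(1.0)
    pass_p = df["pvalue"] < p_max
    pass_info = info > info_min
    pass_eaf = maf > eaf_min
    kept = pass_p & pass_info & pass_eaf
    log = {
        "input": len(df),
        "fail_p": int((~pass_p).sum()),
        "fail_info": int((~pass_info).sum()),
        "fail_eaf": int((~pass_eaf).sum()),
        "kept": int(kept.sum()),
    }
    logger.info("filter_variants: %s", log)
    if log["kept"] == 0:
        logger.warning("filter_variants: empty result (thresholds p<%g, "
                       "info>%g, maf>%g)", p_max, info_min, eaf_min)
    out = replace(table, data=df[kept].reset_index(drop=True))
    out.filter_log = log  # type: ignore[attr-defined]
    return out


def clump(table: SumstatTable, ld, r2_max: float = 0.25,
          window_kb: float = 500.0, label: str = "custom",
          p_threshold: float | None = None,
          missing_ld: str = "zero") -> InstrumentSet:
    """Greedy LD clumping with PLINK semantics.

    Repeatedly take the smallest-P unassigned variant as an index and
    remove all unassigned variants on the same chromosome within
    +/-window_kb whose LD r^2 with it is >= r2_max.  Ties in P are broken
    by (chr, pos).  ``ld`` is an :class:`LdReference` or a callable
    ``(id1, id2) -> r2 | None``; missing entries within the window count as
    r^2 = 0 (logged) unless ``missing_ld='strict'``.
    """
    r2_of = ld.r2 if hasattr(ld, "r2") else ld
    df = table.data.sort_values(["pvalue", "chr", "pos"],
                                kind="mergesort").reset_index(drop=True)
    window = window_kb * 1000.0
    assigned = np.zeros(len(df), dtype=bool)
    index_rows: list[int] = []
    n_missing_ld = 0
    poss = df["pos"].to_numpy(dtype=float)
    ids = df["variant_id"].to_numpy()

    # per-chromosome position order for fast window queries
    by_chr: dict = {}
    for c, sub in df.groupby("chr", sort=False):
        order = sub["pos"].to_numpy().argsort(kind="mergesort")
        rows = sub.index.to_numpy()[order]
        by_chr[c] = (rows, poss[rows])
    chrs = df["chr"].to_numpy()

    for i in range(len(df)):
        if assigned[i]:
            continue
        assigned[i] = True
        index_rows.append(i)
        rows, sorted_pos = by_chr[chrs[i]]
        lo = np.searchsorted(sorted_pos, poss[i] - window, side="left")
        hi = np.searchsorted(sorted_pos, poss[i] + window, side="right")
        for j in rows[lo:hi]:
            if assigned[j]:
                continue
            r2 = r2_of(ids[i], ids[j])
            if r2 is None:
                if missing_ld == "strict":
                    raise ValueError(f"missing LD entry for ({ids[i]}, {ids[j]})")
                n_missing_ld += 1
                continue
            if r2 >= r2_max:
                assigned[j] = True

    if n_missing_ld:
        logger.info("clump: %d in-window pairs without LD information "
                    "treated as r2=0", n_missing_ld)
    out = df.iloc[index_rows].sort_values(["chr", "pos"],
                                          kind="mergesort").reset_index(drop=True)
    return InstrumentSet(
        label=label,
        p_threshold=p_threshold if p_threshold is not None else float("nan"),
        variants=out, r2_max=r2_max, window_kb=window_kb,
        filter_log={"clump_input": len(df), "clump_kept": len(out),
                    "missing_ld_pairs": n_missing_ld},
    )


def select_instruments(table: SumstatTable, ld, p_max: float,
                       label: str, info_min: float = 0.8,
                       eaf_min: float = 0.01, r2_max: float = 0.25,
                       window_kb: float = 500.0) -> InstrumentSet:
    """Filter then clump: the full instrument-selection recipe."""
    filtered = filter_variants(table, p_max=p_max, info_min=info_min,
                               eaf_min=eaf_min)
    inst = clump(filtered, ld, r2_max=r2_max, window_kb=window_kb,
                 label=label, p_threshold=p_max)
    inst.filter_log.update(getattr(filtered, "filter_log", {}))
    return inst


def instrument_strength(inst: InstrumentSet) -> pd.DataFrame:
    """Per-variant F-statistics, F = (beta/se)^2, plus the mean F.

    Reported as a diagnostic of instrument strength only; no variants are
    filtered on it.  For an empty set an empty frame with NaN mean is
    returned.
    """
    df = inst.variants
    if len(df) == 0:
        out = pd.DataFrame(columns=["variant_id", "f_stat"])
        out.attrs["mean_f"] = float("nan")
        return out
    f = (df["beta"] / df["se"]) ** 2
    out = pd.DataFrame({"variant_id": df["variant_id"], "f_stat": f})
    out.attrs["mean_f"] = float(f.mean())
    return out
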