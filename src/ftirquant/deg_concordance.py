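"""Cross-condition concordance of differential-expression result tables.

Given two DE result tables (gene id, log2 fold change, adjusted p), both are
filtered at a significance threshold (strict ``padj < alpha``; missing padj
means never significant), intersected on gene id, and summarized:

* how many genes are significant in each table and shared between them;
* how many shared genes change in the same direction ("parallel", split
  into up- and down-regulated);
* the Pearson correlation of the two log2 fold-change vectors over the
  shared genes.

Gene identity is exact string match on gene id — no symbol/alias
resolution. Genes with log2fc exactly 0 cannot be assigned a direction and
are excluded from the parallel counts (but remain shared).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

_GENE_ALIASES = ("gene_id", "gene", "geneid", "ensembl_gene_id", "id")
_LFC_ALIASES = ("log2fc", "log2foldchange", "lfc", "logfc")
_PADJ_ALIASES = ("padj", "p_adj", "fdr", "adj_p", "qvalue", "adj.p.val")
_BIOTYPE_ALIASES = ("biotype", "gene_biotype", "gene_type")


def normalize_deg_table(df: pd.DataFrame, label: str = "") -> pd.DataFrame:
    """Map DESeq2-style column names onto gene_id / log2fc / padj and validate."""
    lower = {c.lower(): c for c in df.columns}

    def pick(aliases: tuple[str, ...], what: str) -> Optional[str]:
        for a in aliases:
            if a in lower:
                return lower[a]
        return None

    gcol = pick(_GENE_ALIASES, "gene id")
    lcol = pick(_LFC_ALIASES, "log2 fold change")
    pcol = pick(_PADJ_ALIASES, "adjusted p")
    if gcol is None or lcol is None or pcol is None:
        raise ParseError(
            f"could not find gene id / log2 fold change / padj columns in "
            f"{list(df.columns)}")
    out = pd.DataFrame({
        "gene_id": df[gcol].astype(str),
        "log2fc": pd.to_numeric(df[lcol], errors="coerce"),
        "padj": pd.to_numeric(df[pcol], errors="coerce"),
    })
    bcol = pick(_BIOTYPE_ALIASES, "biotype")
    if bcol is not None:
        out["biotype"] = df[bcol].astype(str)
    if out["gene_id"].duplicated().any():
        dup = out.loc[out["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValidationError(f"duplicate gene_id {dup!r} in DE table")
    bad = out["padj"].dropna()
    if ((bad < 0) | (bad > 1)).any():
        raise ValidationError("padj values outside [0, 1]")
    out.attrs["label"] = label
    return out


def load_deg_table(path: str | Path, label: str = "") -> pd.DataFrame:
    """Read a DE result table from CSV or TSV (delimiter sniffed)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except Exception as exc:
        raise ParseError(f"{path.name}: {exc}") from exc
    return normalize_deg_table(df, label=label or path.stem)


def filter_significant(t: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Rows with padj present and strictly below alpha."""
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    keep = t["padj"].notna() & (t["padj"] < alpha)
    out = t.loc[keep].copy()
    out.attrs["label"] = t.attrs.get("label", "")
    return out


def classify_direction(t: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Attach up/down labels by log2fc sign; zero-fold genes are dropped.

    Returns the labelled table and the number of excluded zero-fold rows.
    """
    zero = int((t["log2fc"] == 0).sum())
    out = t.loc[t["log2fc"] != 0].copy()
    out["direction"] = np.where(out["log2fc"] > 0, "up", "down")
    out.attrs["label"] = t.attrs.get("label", "")
    return out, zero


@dataclass
class OverlapResult:
    n_sig_1: int
    n_sig_2: int
    n_shared: int
    n_parallel: int
    n_parallel_up: int
    n_parallel_down: int
    pearson_r: Optional[float]
    n_used_for_r: int
    r_missing_reason: Optional[str] = None
    label_1: str = ""
    label_2: str = ""
    shared: pd.DataFrame = field(default_factory=pd.DataFrame, repr=False)

    def to_dict(self) -> dict:
        return {
            "label_1": self.label_1, "label_2": self.label_2,
            "n_sig_1": self.n_sig_1, "n_sig_2": self.n_sig_2,
            "n_shared": self.n_shared, "n_parallel": self.n_parallel,
            "n_parallel_up": self.n_parallel_up,
            "n_parallel_down": self.n_parallel_down,
            "pearson_r": self.pearson_r,
            "n_used_for_r": self.n_used_for_r,
            "r_missing_reason": self.r_missing_reason,
        }


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    xm = x - x.mean()
    ym = y - y.mean()
    denom = np.sqrt((xm ** 2).sum() * (ym ** 2).sum())
    return float((xm * ym).sum() / denom)


def concordance(t1: pd.DataFrame, t2: pd.DataFrame,
                alpha: float = 0.05) -> OverlapResult:
    """Filter both tables at alpha, intersect on gene_id, count and correlate.

    Parallel = shared, nonzero log2fc in both, same sign. Pearson r is
    computed over all shared genes and reported missing (with a reason) when
    fewer than 3 genes are shared or a fold-change vector is constant.
    """
    s1 = filter_significant(t1, alpha)
    s2 = filter_significant(t2, alpha)
    merged = s1.merge(s2, on="gene_id", suffixes=("_1", "_2"))
    n_shared = len(merged)

    signed = merged.loc[(merged["log2fc_1"] != 0) & (merged["log2fc_2"] != 0)]
    same = np.sign(signed["log2fc_1"]) == np.sign(signed["log2fc_2"])
    n_up = int((same & (signed["log2fc_1"] > 0)).sum())
    n_down = int((same & (signed["log2fc_1"] < 0)).sum())

    r: Optional[float] = None
    reason: Optional[str] = None
    if n_shared < 3:
        reason = f"only {n_shared} shared significant genes (need >= 3)"
    else:
        x = merged["log2fc_1"].to_numpy(float)
        y = merged["log2fc_2"].to_numpy(float)
        if np.std(x) == 0 or np.std(y) == 0:
            reason = "constant log2fc vector among shared genes"
        else:
            r = pearson_r(x, y)
    return OverlapResult(
        n_sig_1=len(s1), n_sig_2=len(s2), n_shared=n_shared,
        n_parallel=n_up + n_down, n_parallel_up=n_up, n_parallel_down=n_down,
        pearson_r=r, n_used_for_r=n_shared if r is not None else 0,
        r_missing_reason=reason,
        label_1=t1.attrs.get("label", ""), label_2=t2.attrs.get("label", ""),
        shared=merged,
    )
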