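"""Instrument selection: p-value thresholding, greedy LD clumping, F-statistics.

The clumping rule mirrors the usual reference-panel clump: iterate variants by
ascending p-value, keep a variant only if no already-kept variant on the same
chromosome is both within the window *and* correlated above the r^2 threshold.
With the conventional thresholds (window 10,000 kb, r^2 0.001) this prunes
essentially any correlated pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .summary_stats import SummaryTable

__all__ = ["LDInfo", "IVStrength", "pvalue_filter", "greedy_clump", "f_statistics"]


@dataclass
class LDInfo:
    """Pairwise squared-correlation matrix over an ordered set of variants."""

    variant_ids: list[str]
    r2: np.ndarray
    pos: dict[str, tuple[str, int]] | None = None  # variant_id -> (chrom, pos)

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        p = len(self.variant_ids)
        if self.r2.shape != (p, p):
            raise ValueError(f"r2 matrix shape {self.r2.shape} != ({p}, {p})")
        if not np.allclose(self.r2, self.r2.T, atol=1e-9):
            raise ValueError("r2 matrix is not symmetric")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-9):
            raise ValueError("r2 matrix diagonal must be 1")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def pairwise(self, a: str, b: str) -> float:
        return float(self.r2[self._index[a], self._index[b]])

    @classmethod
    def identity(cls, variant_ids: list[str], pos=None) -> "LDInfo":
        """LD structure for mutually independent variants."""
        return cls(list(variant_ids), np.eye(len(variant_ids)), pos)

    @classmethod
    def from_long_tsv(cls, path) -> "LDInfo":
        """Read long-format TSV with columns id1, id2, r2."""
        df = pd.read_csv(path, sep="\t", dtype={"id1": str, "id2": str})
        ids = sorted(set(df["id1"]) | set(df["id2"]))
        idx = {v: i for i, v in enumerate(ids)}
        mat = np.eye(len(ids))
        for row in df.itertuples(index=False):
            i, j = idx[row.id1], idx[row.id2]
            mat[i, j] = mat[j, i] = float(row.r2)
        return cls(ids, mat)

    @classmethod
    def from_dense_tsv(cls, path) -> "LDInfo":
        """Read a dense matrix TSV whose header row holds the variant IDs."""
        df = pd.read_csv(path, sep="\t")
        return cls([str(c) for c in df.columns], df.to_numpy(float))


@dataclass
class IVStrength:
    """Per-variant and mean instrument-strength F-statistics."""

    per_variant_F: dict[str, float]
    mean_F: float


def pvalue_filter(table: SummaryTable, threshold: float) -> SummaryTable:
    """Retain records with pvalue strictly below ``threshold``; order kept."""
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    mask = table.data["pvalue"].to_numpy(float) < threshold
    return table.subset(mask)


def greedy_clump(
    table: SummaryTable,
    ld: LDInfo | None,
    window_kb: int = 10_000,
    r2_threshold: float = 0.001,
) -> SummaryTable:
    """Greedy clumping by ascending p-value.

    A variant is kept iff no already-kept variant on the same chromosome lies
    within ``window_kb`` AND has pairwise r^2 > ``r2_threshold`` with it.
    Ties on p break lexicographically by variant_id for determinism.  When
    ``ld`` is None the variants are assumed mutually independent (r^2 = 0
    everywhere) and clumping keeps everything.
    """
    if window_kb <= 0:
        raise ValueError("window_kb must be > 0")
    df = table.data
    if ld is not None:
        missing = [v for v in df["variant_id"] if v not in ld._index]
        if missing:
            raise KeyError(f"variant {missing[0]} missing from LD information")

    have_pos = "chrom" in df.columns and "pos" in df.columns
    ld_pos = ld.pos if (ld is not None and ld.pos) else None

    def locate(row) -> tuple[str, float] | None:
        if have_pos and not pd.isna(row.pos):
            return (str(row.chrom), float(row.pos))
        if ld_pos is not None and row.variant_id in ld_pos:
            c, p = ld_pos[row.variant_id]
            return (str(c), float(p))
        return None

    order = df.assign(row_ix=np.arange(len(df))).sort_values(
        ["pvalue", "variant_id"], kind="mergesort"
    )
    kept: list[int] = []
    kept_info: list[tuple[str, tuple[str, float] | None]] = []
    for row in order.itertuples(index=False):
        loc = locate(row)
        conflict = False
        for kid, kloc in kept_info:
            within = (
                loc is not None
                and kloc is not None
                and loc[0] == kloc[0]
                and abs(loc[1] - kloc[1]) <= window_kb * 1000.0
            )
            if loc is None or kloc is None:
                within = True  # no coordinates: be conservative, window always hit
            correlated = ld is not None and ld.pairwise(row.variant_id, kid) > r2_threshold
            if within and correlated:
                conflict = True
                break
        if not conflict:
            kept.append(row.row_ix)
            kept_info.append((row.variant_id, loc))

    mask = np.zeros(len(df), dtype=bool)
    mask[kept] = True
    return table.subset(mask)


def f_statistics(table: SummaryTable) -> IVStrength:
    """Per-variant instrument strength F = (beta/se)^2 and the arithmetic mean."""
    se = table.data["se"].to_numpy(float)
    if np.any(se <= 0):
        raise ValueError("standard errors must be > 0")
    f = (table.data["beta"].to_numpy(float) / se) ** 2
    per = dict(zip(table.data["variant_id"], map(float, f)))
    return IVStrength(per, float(np.mean(f)) if len(f) else float("nan"))
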