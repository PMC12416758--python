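"""GWAS summary-statistic tables and exposure/outcome harmonization.

The canonical in-memory container is a :class:`SummaryTable`, a thin wrapper
around a :class:`pandas.DataFrame` with one row per variant and the columns

    variant_id, effect_allele, other_allele, eaf, beta, se, pvalue, n

(plus optional ``chrom``/``pos`` and any extra columns, which are preserved).
``beta`` is the per-allele effect of the *effect allele* on the trait scale
(log-odds for binary traits), ``se`` its standard error and ``eaf`` the
effect-allele frequency.

:func:`harmonize` aligns an exposure and an outcome table to a common effect
allele per variant, resolving strand flips and palindromic (A/T, G/C)
ambiguity, and records every exclusion with a reason.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "VariantAssoc",
    "SummaryTable",
    "HarmonizedSet",
    "read_summary_stats",
    "write_summary_stats",
    "harmonize",
    "CANONICAL_COLUMNS",
]

CANONICAL_COLUMNS = [
    "variant_id",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PALINDROMIC = {frozenset(("A", "T")), frozenset(("C", "G"))}


class SummaryStatsError(ValueError):
    """Malformed summary-statistic input."""


@dataclass
class VariantAssoc:
    """One variant's association record in one stratum.

    Holds the raw (or calibrated) effect estimate and its standard error for
    a single variant, e.g. a female-stratum variant-exposure estimate with
    its estimated standard error.
    """

    variant_id: str
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pvalue: float
    n: int
    chrom: str | None = None
    pos: int | None = None

    def __post_init__(self) -> None:
        self.effect_allele = str(self.effect_allele).upper()
        self.other_allele = str(self.other_allele).upper()
        if self.se is not None and not (self.se > 0):
            raise SummaryStatsError(
                f"{self.variant_id}: standard error must be > 0, got {self.se}"
            )
        if self.eaf is not None and not math.isnan(self.eaf):
            if not (0.0 <= self.eaf <= 1.0):
                raise SummaryStatsError(
                    f"{self.variant_id}: eaf must lie in [0, 1], got {self.eaf}"
                )
        if self.effect_allele == self.other_allele:
            raise SummaryStatsError(
                f"{self.variant_id}: effect and other allele are identical"
            )

    @property
    def zscore(self) -> float:
        return self.beta / self.se

    def pvalue_consistent(self, tol: float = 1e-6) -> bool:
        """Check the supplied p-value against the two-sided normal test.

        Compared on the z scale: the |z| implied by the p-value must match
        |beta/se| within ``tol`` (plus slack for p-values at the rounding
        floor).
        """
        if self.pvalue is None or math.isnan(self.pvalue):
            return True
        z_implied = stats.norm.isf(min(max(self.pvalue, 5e-324), 1.0) / 2.0)
        return abs(z_implied - abs(self.zscore)) <= tol


@dataclass
class SummaryTable:
    """An ordered set of variant association records for one trait/stratum."""

    data: pd.DataFrame
    trait_label: str = ""
    stratum: str = "combined"
    covariate_adjustment: str = ""
    n_dropped: int = 0

    def __post_init__(self) -> None:
        missing = [c for c in ("variant_id", "beta", "se") if c not in self.data.columns]
        if missing:
            raise SummaryStatsError(f"SummaryTable missing columns: {missing}")
        ids = self.data["variant_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise SummaryStatsError(f"duplicate variant_id: {dup}")
        self.data = self.data.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    def records(self) -> Iterable[VariantAssoc]:
        cols = set(self.data.columns)
        for row in self.data.itertuples(index=False):
            d = row._asdict()
            yield VariantAssoc(
                variant_id=d["variant_id"],
                effect_allele=d.get("effect_allele", "A"),
                other_allele=d.get("other_allele", "G"),
                eaf=d.get("eaf", float("nan")),
                beta=d["beta"],
                se=d["se"],
                pvalue=d.get("pvalue", float("nan")),
                n=int(d["n"]) if "n" in cols and not pd.isna(d.get("n")) else 0,
                chrom=str(d["chrom"]) if "chrom" in cols else None,
                pos=int(d["pos"]) if "pos" in cols and not pd.isna(d.get("pos")) else None,
            )

    @classmethod
    def from_records(
        cls, records: Sequence[VariantAssoc], trait_label: str = "",
        stratum: str = "combined", covariate_adjustment: str = "",
    ) -> "SummaryTable":
        rows = []
        for r in records:
            row = {
                "variant_id": r.variant_id,
                "effect_allele": r.effect_allele,
                "other_allele": r.other_allele,
                "eaf": r.eaf,
                "beta": r.beta,
                "se": r.se,
                "pvalue": r.pvalue,
                "n": r.n,
            }
            if r.chrom is not None:
                row["chrom"] = r.chrom
            if r.pos is not None:
                row["pos"] = r.pos
            rows.append(row)
        return cls(pd.DataFrame(rows), trait_label, stratum, covariate_adjustment)

    def subset(self, mask) -> "SummaryTable":
        return SummaryTable(
            self.data.loc[mask].reset_index(drop=True),
            self.trait_label, self.stratum, self.covariate_adjustment,
        )


def read_summary_stats(
    path,
    column_map: Mapping[str, str] | None = None,
    trait_label: str = "",
    stratum: str = "combined",
    covariate_adjustment: str = "",
    sep: str | None = None,
) -> SummaryTable:
    """Read a tab- or comma-separated summary-statistic file.

    ``column_map`` maps the canonical field names (``variant_id``, ``beta``,
    ``se``, ...) to the column headers actually present, so files using e.g.
    SNP/BETA/SE/A1/A2/EAF/P/N headers can be ingested directly.  Rows with
    missing beta or se are dropped and counted in ``n_dropped``.
    """
    if sep is None:
        with open(path) as fh:
            header = fh.readline()
        sep = "," if ("," in header and "\t" not in header) else "\t"
    raw = pd.read_csv(path, sep=sep, dtype={0: str})
    column_map = dict(column_map or {})
    rename = {}
    for std, col in column_map.items():
        if col not in raw.columns:
            raise SummaryStatsError(
                f"mapped column {col!r} (for field {std!r}) not found in {path}"
            )
        rename[col] = std
    df = raw.rename(columns=rename)
    missing = [c for c in ("variant_id", "beta", "se") if c not in df.columns]
    if missing:
        raise SummaryStatsError(f"required columns missing from {path}: {missing}")

    for col in ("beta", "se", "eaf", "pvalue"):
        if col in df.columns:
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if col in ("beta", "se") and bad.any():
                # genuinely non-numeric entries (not NA markers) are an error
                nonnum = df.loc[bad, col].astype(str)
                truly_bad = nonnum[~nonnum.str.upper().isin(["NA", "NAN", ""])]
                if len(truly_bad):
                    line = truly_bad.index[0] + 2  # 1-based + header
                    raise SummaryStatsError(
                        f"non-numeric {col} value {truly_bad.iloc[0]!r} at line {line}"
                    )
            df[col] = pd.to_numeric(df[col], errors="coerce")

    keep = df["beta"].notna() & df["se"].notna()
    n_dropped = int((~keep).sum())
    df = df.loc[keep].reset_index(drop=True)
    for col in ("effect_allele", "other_allele"):
        if col in df.columns:
            df[col] = df[col].astype(str).str.upper()
    df["variant_id"] = df["variant_id"].astype(str)
    table = SummaryTable(df, trait_label, stratum, covariate_adjustment)
    table.n_dropped = n_dropped
    return table


def write_summary_stats(table: SummaryTable, path) -> None:
    """Write a SummaryTable as TSV with the canonical header first.

    Extra columns (e.g. calibration diagnostics) are preserved after the
    canonical ones.  ``read_summary_stats(write(x))`` reproduces ``x`` up to
    float round-trip.
    """
    if len(table) == 0:
        raise SummaryStatsError("refusing to write an empty SummaryTable")
    cols = [c for c in CANONICAL_COLUMNS if c in table.data.columns]
    extras = [c for c in table.data.columns if c not in cols]
    table.data[cols + extras].to_csv(path, sep="\t", index=False)


@dataclass
class HarmonizedSet:
    """Allele-aligned exposure/outcome records for a set of instruments.

    ``data`` has one row per retained variant with exposure and outcome
    effects expressed for the same effect allele; every input variant that
    was not retained appears in ``exclusion_log`` as ``(variant_id, reason)``.
    """

    data: pd.DataFrame
    exclusion_log: list[tuple[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def gamma(self) -> np.ndarray:
        return self.data["beta_exp"].to_numpy(float)

    @property
    def gamma_se(self) -> np.ndarray:
        return self.data["se_exp"].to_numpy(float)

    @property
    def Gamma(self) -> np.ndarray:
        return self.data["beta_out"].to_numpy(float)

    @property
    def Gamma_se(self) -> np.ndarray:
        return self.data["se_out"].to_numpy(float)

    def exclusions(self, reason: str | None = None) -> list[tuple[str, str]]:
        if reason is None:
            return list(self.exclusion_log)
        return [e for e in self.exclusion_log if e[1] == reason]


def _is_palindromic(a1: str, a2: str) -> bool:
    return frozenset((a1, a2)) in _PALINDROMIC


def _flip(allele: str) -> str:
    return _COMPLEMENT.get(allele, allele)


def harmonize(
    exposure: SummaryTable,
    outcome: SummaryTable,
    palindrome_policy: str = "drop_ambiguous",
    eaf_tolerance: float = 0.08,
    eaf_mismatch_threshold: float = 0.2,
) -> HarmonizedSet:
    """Align exposure and outcome records to a common effect allele.

    For each variant present in both tables the outcome record is re-expressed
    for the exposure's effect allele: if the outcome's effect allele equals
    the exposure's other allele the outcome beta sign is flipped and its eaf
    replaced by 1-eaf.  If neither the direct nor the swapped match works, a
    strand flip (A<->T, C<->G) is attempted before declaring
    ``allele_mismatch``.

    Palindromic variants (A/T or G/C) are handled per ``palindrome_policy``:

    - ``drop_ambiguous`` (default): excluded when min(eaf, 1-eaf) is within
      ``eaf_tolerance`` of 0.5 in either table (reason
      ``palindromic_ambiguous``); otherwise orientation is inferred from eaf.
    - ``drop_all``: all palindromic variants excluded (reason ``palindromic``).
    - ``infer_by_eaf``: orientation always inferred from eaf, however close
      to 0.5.

    Variants whose aligned allele frequencies disagree by more than
    ``eaf_mismatch_threshold`` are excluded with reason ``eaf_mismatch``.
    """
    if not (0.0 < eaf_tolerance < 0.5):
        raise ValueError("eaf_tolerance must lie in (0, 0.5)")
    if palindrome_policy not in ("drop_ambiguous", "drop_all", "infer_by_eaf"):
        raise ValueError(f"unknown palindrome_policy {palindrome_policy!r}")

    exp = exposure.data.set_index("variant_id", verify_integrity=True)
    out = outcome.data.set_index("variant_id", verify_integrity=True)

    log: list[tuple[str, str]] = []
    rows = []
    for vid in exp.index:
        if vid not in out.index:
            log.append((vid, "not_in_outcome"))
            continue
        e = exp.loc[vid]
        o = out.loc[vid]
        ea_e, oa_e = str(e["effect_allele"]), str(e["other_allele"])
        ea_o, oa_o = str(o["effect_allele"]), str(o["other_allele"])
        beta_o = float(o["beta"])
        eaf_o = float(o.get("eaf", np.nan))
        eaf_e = float(e.get("eaf", np.nan))
        palindromic = _is_palindromic(ea_e, oa_e)

        if palindromic:
            # strand flips are a no-op on A/T and G/C sites; the allele
            # labels always "match" and only eaf can orient them.
            if (ea_o, oa_o) == (ea_e, oa_e):
                aligned = True
            elif (ea_o, oa_o) == (oa_e, ea_e):
                beta_o = -beta_o
                eaf_o = 1.0 - eaf_o if not np.isnan(eaf_o) else eaf_o
                aligned = True
            else:
                aligned = False
            if not aligned:
                log.append((vid, "allele_mismatch"))
                continue
            policy = palindrome_policy
            if np.isnan(eaf_e) or np.isnan(eaf_o):
                policy = "drop_all"  # cannot orient without frequencies
            if policy == "drop_all":
                log.append((vid, "palindromic"))
                continue
            ambiguous = (
                min(eaf_e, 1 - eaf_e) >= 0.5 - eaf_tolerance
                or min(eaf_o, 1 - eaf_o) >= 0.5 - eaf_tolerance
            )
            if policy == "drop_ambiguous" and ambiguous:
                log.append((vid, "palindromic_ambiguous"))
                continue
            # infer orientation: minor/major status must agree; if the
            # frequencies point in opposite directions the outcome is on
            # the other strand, which for a palindrome flips the allele
            # roles -> flip sign and eaf.
            if (eaf_e - 0.5) * (eaf_o - 0.5) < 0:
                beta_o = -beta_o
                eaf_o = 1.0 - eaf_o
        else:
            if (ea_o, oa_o) == (ea_e, oa_e):
                pass
            elif (ea_o, oa_o) == (oa_e, ea_e):
                beta_o = -beta_o
                eaf_o = 1.0 - eaf_o if not np.isnan(eaf_o) else eaf_o
            elif (_flip(ea_o), _flip(oa_o)) == (ea_e, oa_e):
                pass  # strand flip only
            elif (_flip(ea_o), _flip(oa_o)) == (oa_e, ea_e):
                beta_o = -beta_o
                eaf_o = 1.0 - eaf_o if not np.isnan(eaf_o) else eaf_o
            else:
                log.append((vid, "allele_mismatch"))
                continue

        if (
            not np.isnan(eaf_e)
            and not np.isnan(eaf_o)
            and abs(eaf_e - eaf_o) > eaf_mismatch_threshold
        ):
            log.append((vid, "eaf_mismatch"))
            continue

        rows.append(
            {
                "variant_id": vid,
                "effect_allele": ea_e,
                "other_allele": oa_e,
                "eaf_exp": eaf_e,
                "beta_exp": float(e["beta"]),
                "se_exp": float(e["se"]),
                "pvalue_exp": float(e.get("pvalue", np.nan)),
                "n_exp": float(e.get("n", np.nan)),
                "eaf_out": eaf_o,
                "beta_out": beta_o,
                "se_out": float(o["se"]),
                "pvalue_out": float(o.get("pvalue", np.nan)),
                "n_out": float(o.get("n", np.nan)),
            }
        )

    for vid in out.index:
        if vid not in exp.index:
            log.append((vid, "not_in_exposure"))

    data = pd.DataFrame(
        rows,
        columns=[
            "variant_id", "effect_allele", "other_allele",
            "eaf_exp", "beta_exp", "se_exp", "pvalue_exp", "n_exp",
            "eaf_out", "beta_out", "se_out", "pvalue_out", "n_out",
        ],
    )
    return HarmonizedSet(data, log)
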