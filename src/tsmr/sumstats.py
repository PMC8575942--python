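"""Reading, validating, combining and rescaling GWAS summary-statistics tables.

A summary-statistics table holds one row per variant: rsID, effect/other
allele, effect-allele frequency, effect size, standard error, p-value and
sample sizes.  Effect sizes are in trait units — mmHg per allele for blood
pressure, log-odds per allele for binary disease endpoints, z-score units for
a standardised trait — and everything downstream (harmonisation, estimation)
consumes these tables.

Two transformations used when building composite endpoints live here:
fixed-effects inverse-variance meta-analysis across studies, and genomic
control via standard-error inflation by the square root of an LD-score
regression intercept supplied by the user.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SummaryStatsTable",
    "DialectError",
    "ValidationError",
    "DEFAULT_DIALECT",
    "read_summary_stats",
    "write_summary_stats",
    "table_from_frame",
    "meta_analyse_fixed_effects",
    "inflate_standard_errors",
    "scale_effects",
    "two_sided_p",
]

#: canonical internal column names
CANONICAL_COLUMNS = [
    "variant_id",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
    "n_cases",
]

#: GWAS-SSF-like default header mapping (file column -> canonical name)
DEFAULT_DIALECT = {
    "variant_id": "variant_id",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "effect_allele_frequency": "eaf",
    "beta": "beta",
    "standard_error": "se",
    "p_value": "pvalue",
    "n": "n",
    "n_cases": "n_cases",
}

MANDATORY = ["variant_id", "effect_allele", "other_allele", "beta", "se"]

VALID_ALLELES = frozenset("ACGT")


class DialectError(ValueError):
    """A mandatory column is absent under the active column mapping."""


class ValidationError(ValueError):
    """The file content violates a table invariant (e.g. duplicate rsIDs)."""


def two_sided_p(beta, se):
    """Two-sided p-value from the normal approximation to beta/se."""
    z = np.abs(np.asarray(beta, dtype=float) / np.asarray(se, dtype=float))
    return 2.0 * stats.norm.sf(z)


@dataclass
class SummaryStatsTable:
    """One GWAS: per-variant associations plus trait metadata.

    Parameters
    ----------
    trait_name : str
        Human-readable trait label (e.g. ``"SBP"``).
    trait_type : str
        ``"continuous"`` or ``"binary"``.
    df : pandas.DataFrame
        One row per variant with the canonical columns
        (variant_id, effect_allele, other_allele, eaf, beta, se, pvalue,
        n, n_cases); extra columns such as ``pvalue_reported`` or
        ``n_studies`` are carried along.
    trait_sd : float, optional
        Phenotypic standard deviation in native units (20.1 mmHg for
        systolic, 11.2 mmHg for diastolic blood pressure); required for
        per-SD rescaling of per-unit effects.
    n_rejected : int
        Rows dropped during parsing for invariant violations.
    """

    trait_name: str
    trait_type: str
    df: pd.DataFrame
    trait_sd: float | None = None
    n_rejected: int = 0

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise ValueError(f"trait_type must be continuous|binary, got {self.trait_type!r}")
        if self.trait_sd is not None and not self.trait_sd > 0:
            raise ValueError("trait_sd must be positive when present")
        if self.df["variant_id"].duplicated().any():
            dups = sorted(self.df.loc[self.df["variant_id"].duplicated(), "variant_id"])
            raise ValidationError(f"duplicate variant_id values: {dups}")

    def __len__(self) -> int:
        return len(self.df)

    def record(self, variant_id: str) -> pd.Series:
        hit = self.df[self.df["variant_id"] == variant_id]
        if hit.empty:
            raise KeyError(variant_id)
        return hit.iloc[0]

    def subset(self, variant_ids) -> "SummaryStatsTable":
        keep = self.df[self.df["variant_id"].isin(set(variant_ids))].reset_index(drop=True)
        return replace(self, df=keep, n_rejected=0)

    @property
    def case_fraction(self) -> float | None:
        if self.trait_type != "binary":
            return None
        sub = self.df.dropna(subset=["n", "n_cases"])
        if sub.empty:
            return None
        return float(sub["n_cases"].sum() / sub["n"].sum())


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def _validate_rows(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Apply row invariants, returning (valid rows, reject count)."""
    ok = pd.Series(True, index=df.index)
    ok &= df["se"] > 0
    ok &= df["effect_allele"].isin(VALID_ALLELES)
    ok &= df["other_allele"].isin(VALID_ALLELES)
    ok &= df["effect_allele"] != df["other_allele"]
    eaf = df["eaf"]
    ok &= eaf.isna() | ((eaf >= 0) & (eaf <= 1))
    ok &= df["beta"].notna() & np.isfinite(df["beta"])
    n_rejected = int((~ok).sum())
    if n_rejected:
        warnings.warn(f"rejected {n_rejected} rows violating record invariants")
    return df[ok].reset_index(drop=True), n_rejected


def table_from_frame(
    df: pd.DataFrame,
    trait_name: str,
    trait_type: str = "continuous",
    trait_sd: float | None = None,
    validate: bool = True,
) -> SummaryStatsTable:
    """Build a table from an in-memory frame already using canonical columns."""
    df = df.copy()
    for col in CANONICAL_COLUMNS:
        if col not in df.columns:
            if col in MANDATORY:
                raise DialectError(f"missing mandatory column: {col}")
            df[col] = np.nan
    df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
    df["other_allele"] = df["other_allele"].astype(str).str.upper()
    n_rejected = 0
    if validate:
        df, n_rejected = _validate_rows(df)
    if "pvalue_reported" not in df.columns:
        df["pvalue_reported"] = df["pvalue"]
    # p-values are always carried as the two-sided normal recomputation
    df["pvalue"] = two_sided_p(df["beta"], df["se"])
    return SummaryStatsTable(
        trait_name=trait_name,
        trait_type=trait_type,
        df=df,
        trait_sd=trait_sd,
        n_rejected=n_rejected,
    )


def read_summary_stats(
    path,
    dialect: dict | None = None,
    trait_name: str | None = None,
    trait_type: str = "continuous",
    trait_sd: float | None = None,
    sep: str | None = None,
) -> SummaryStatsTable:
    """Read a tab- or comma-separated summary-statistics file.

    ``dialect`` maps file column names to canonical names; unspecified
    columns fall back to the GWAS-SSF-like default header.  Rows violating
    record invariants (non-positive SE, non-SNP or identical alleles,
    frequencies outside [0, 1]) are dropped and counted in
    ``table.n_rejected``.
    """
    mapping = dict(DEFAULT_DIALECT)
    if dialect:
        mapping.update(dialect)
    with _open_text(path) as fh:
        raw = pd.read_csv(fh, sep=sep if sep is not None else r"\s*[\t,]\s*", engine="python")
    rename = {src: dst for src, dst in mapping.items() if src in raw.columns}
    df = raw.rename(columns=rename)
    for col in MANDATORY:
        if col not in df.columns:
            src = next((s for s, d in mapping.items() if d == col), col)
            raise DialectError(f"missing mandatory column: {src!r} (canonical {col!r})")
    return table_from_frame(
        df,
        trait_name=trait_name or str(path),
        trait_type=trait_type,
        trait_sd=trait_sd,
    )


def write_summary_stats(table: SummaryStatsTable, path) -> None:
    """Write a table as TSV with the canonical header (gzip by extension)."""
    cols = [c for c in CANONICAL_COLUMNS if c in table.df.columns]
    extra = [c for c in table.df.columns if c not in cols]
    out = table.df[cols + extra]
    path = str(path)
    if path.endswith(".gz"):
        with gzip.open(path, "wt") as fh:
            out.to_csv(fh, sep="\t", index=False)
    else:
        out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# composite endpoints


def _align_to_reference(ref_row: pd.Series, row: pd.Series):
    """Return (beta, eaf, n, n_cases) of ``row`` expressed on ref's effect allele.

    Handles allele order swaps and strand flips; returns None when the
    allele pair is incompatible even after flipping.
    """
    from .harmonise import align_orientation  # local import to avoid cycle

    orient = align_orientation(
        ref_row["effect_allele"],
        ref_row["other_allele"],
        row["effect_allele"],
        row["other_allele"],
    )
    if orient is None:
        return None
    beta = row["beta"] * orient
    eaf = row["eaf"]
    if orient == -1 and pd.notna(eaf):
        eaf = 1.0 - eaf
    return beta, eaf, row.get("n", np.nan), row.get("n_cases", np.nan), row["se"]


def meta_analyse_fixed_effects(tables: list[SummaryStatsTable], trait_name: str | None = None) -> SummaryStatsTable:
    """Fixed-effects inverse-variance meta-analysis across studies.

    Pooled beta is the precision-weighted mean sum(b_i/se_i^2)/sum(1/se_i^2)
    and pooled SE is 1/sqrt(sum(1/se_i^2)).  Variants present in only some
    studies are pooled over the studies that carry them; the number of
    contributing studies is recorded per variant in ``n_studies`` so a
    strict-intersection analysis remains recoverable by filtering.  Alleles
    are aligned to the first table carrying each variant; a variant whose
    alleles cannot be reconciled by swapping/strand-flipping is dropped with
    a warning.
    """
    if not tables:
        raise ValueError("meta_analyse_fixed_effects requires at least one table")
    ttypes = {t.trait_type for t in tables}
    if len(ttypes) > 1:
        raise ValueError(f"all tables must share trait_type, got {ttypes}")
    if len(tables) == 1:
        t = tables[0]
        return replace(t, trait_name=trait_name or t.trait_name)

    rows = []
    seen_ref: dict[str, pd.Series] = {}
    contributions: dict[str, list] = {}
    dropped = []
    for t in tables:
        for _, row in t.df.iterrows():
            vid = row["variant_id"]
            if vid not in seen_ref:
                seen_ref[vid] = row
                contributions[vid] = [
                    (row["beta"], row["se"], row["eaf"], row.get("n", np.nan), row.get("n_cases", np.nan))
                ]
            else:
                aligned = _align_to_reference(seen_ref[vid], row)
                if aligned is None:
                    dropped.append(vid)
                    contributions.pop(vid, None)
                    continue
                beta, eaf, n, n_cases, se = aligned
                if vid in contributions:
                    contributions[vid].append((beta, se, eaf, n, n_cases))
    if dropped:
        warnings.warn(f"dropped {len(dropped)} variants with irreconcilable alleles: {sorted(set(dropped))}")

    for vid, contribs in contributions.items():
        ref = seen_ref[vid]
        betas = np.array([c[0] for c in contribs], dtype=float)
        ses = np.array([c[1] for c in contribs], dtype=float)
        w = 1.0 / ses**2
        pooled_beta = float(np.sum(w * betas) / np.sum(w))
        pooled_se = float(1.0 / np.sqrt(np.sum(w)))
        eafs = np.array([c[2] for c in contribs], dtype=float)
        ns = np.array([c[3] for c in contribs], dtype=float)
        ncs = np.array([c[4] for c in contribs], dtype=float)
        rows.append(
            {
                "variant_id": vid,
                "effect_allele": ref["effect_allele"],
                "other_allele": ref["other_allele"],
                "eaf": np.nanmean(eafs) if np.isfinite(eafs).any() else np.nan,
                "beta": pooled_beta,
                "se": pooled_se,
                "n": np.nansum(ns) if np.isfinite(ns).any() else np.nan,
                "n_cases": np.nansum(ncs) if np.isfinite(ncs).any() else np.nan,
                "n_studies": len(contribs),
            }
        )
    df = pd.DataFrame(rows, columns=CANONICAL_COLUMNS + ["n_studies"])
    df["pvalue"] = two_sided_p(df["beta"], df["se"]) if len(df) else df["beta"]
    df["pvalue_reported"] = df["pvalue"]
    return SummaryStatsTable(
        trait_name=trait_name or "+".join(t.trait_name for t in tables),
        trait_type=tables[0].trait_type,
        df=df,
        trait_sd=tables[0].trait_sd,
    )


def inflate_standard_errors(table: SummaryStatsTable, ldsc_intercept: float) -> SummaryStatsTable:
    """Genomic control: multiply every SE by sqrt(ldsc_intercept).

    Used after meta-analysing correlated sub-endpoints into a composite,
    where naive inverse-variance pooling understates the standard error.
    Betas are unchanged; p-values are recomputed from beta/SE.  Intercepts
    below 1 are accepted with a warning but no deflation is applied.
    """
    if not ldsc_intercept > 0:
        raise ValueError("ldsc_intercept must be positive")
    factor = float(np.sqrt(ldsc_intercept))
    if ldsc_intercept < 1:
        warnings.warn("ldsc_intercept < 1: no deflation applied")
        factor = 1.0
    df = table.df.copy()
    df["se"] = df["se"] * factor
    df["pvalue"] = two_sided_p(df["beta"], df["se"])
    return replace(table, df=df)


def scale_effects(
    table: SummaryStatsTable,
    mode: str = "per-sd",
    unit_increment: float | None = None,
) -> SummaryStatsTable:
    """Rescale per-unit effects: per-SD (multiply by trait SD) or per a fixed
    increment in native units (e.g. per 10 mmHg systolic, per 5 mmHg
    diastolic).  Beta and SE rescale together so p-values are invariant.
    """
    if mode == "per-sd":
        if table.trait_sd is None:
            raise ValueError("per-sd scaling requires trait_sd")
        factor = float(table.trait_sd)
    elif mode == "per-unit":
        if unit_increment is None:
            raise ValueError("per-unit scaling requires unit_increment")
        factor = float(unit_increment)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    df = table.df.copy()
    df["beta"] = df["beta"] * factor
    df["se"] = df["se"] * factor
    return replace(table, df=df)
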