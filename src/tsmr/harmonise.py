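"""Instrument selection and exposure/outcome allele harmonisation.

Two-sample MR combines SNP-exposure and SNP-outcome associations estimated in
different GWAS, which may report effects on opposite alleles or opposite
strands.  This module selects strong, independent instruments (p-value
threshold, greedy LD clumping at r^2 < 0.001), merges instruments shared by
several exposures keeping the lower p-value, and aligns every record to a
shared effect allele.

Palindromic variants (A/T or C/G) cannot be strand-resolved from alleles
alone; those with effect-allele frequency strictly inside (0.42, 0.58) are
replaced by an LD proxy (r^2 >= 0.8) when one is available and excluded
otherwise, while palindromes with a clearly minor allele are aligned by
frequency matching.  Variants missing from the outcome GWAS are likewise
proxy-substituted when possible.  Every exclusion is logged with a reason.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .sumstats import SummaryStatsTable

__all__ = [
    "LDReference",
    "HarmonisedSet",
    "align_orientation",
    "is_palindromic",
    "select_instruments",
    "clump",
    "merge_exposure_instruments",
    "harmonise",
    "screen_annotations",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _comp(a: str) -> str:
    return _COMPLEMENT[a]


def is_palindromic(a1: str, a2: str) -> bool:
    """True for A/T and C/G pairs, whose strand is ambiguous."""
    return _COMPLEMENT.get(a1.upper()) == a2.upper()


def align_orientation(ref_ea: str, ref_oa: str, ea: str, oa: str) -> int | None:
    """Orientation of (ea, oa) relative to (ref_ea, ref_oa).

    Returns +1 when the effect alleles agree (directly or after strand
    complement), -1 when they are swapped (beta sign and eaf must flip),
    and None when the pairs are incompatible.  Palindromic pairs are not
    resolvable here (both orientations match); callers must use frequency
    matching for those.
    """
    ref_ea, ref_oa, ea, oa = (x.upper() for x in (ref_ea, ref_oa, ea, oa))
    if (ea, oa) == (ref_ea, ref_oa):
        return 1
    if (ea, oa) == (ref_oa, ref_ea):
        return -1
    cea, coa = _comp(ea), _comp(oa)
    if (cea, coa) == (ref_ea, ref_oa):
        return 1
    if (cea, coa) == (ref_oa, ref_ea):
        return -1
    return None


@dataclass
class LDReference:
    """Pairwise r^2 lookups plus a proxy table for missing variants.

    ``r2`` maps unordered variant pairs to r^2; pairs absent from the
    mapping are treated as unlinked (r^2 = 0) unless ``strict`` is set.
    ``proxies`` maps a missing variant to candidate (proxy, r^2) pairs.
    """

    r2: dict = field(default_factory=dict)
    proxies: dict = field(default_factory=dict)
    strict: bool = False

    def pair_r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        val = self.r2.get(frozenset((a, b)))
        if val is None:
            if self.strict:
                raise KeyError(f"pair ({a}, {b}) absent from LD reference")
            return 0.0
        return float(val)

    def best_proxy(self, variant_id: str, r2_min: float, available=None):
        """Highest-r^2 proxy meeting ``r2_min`` (ties by variant_id).

        ``available`` optionally restricts candidates to ids usable
        downstream (present in both exposure and outcome tables).
        """
        cands = [
            (pid, r2)
            for pid, r2 in self.proxies.get(variant_id, [])
            if r2 >= r2_min and (available is None or pid in available)
        ]
        if not cands:
            return None
        cands.sort(key=lambda t: (-t[1], t[0]))
        return cands[0]

    @classmethod
    def from_frames(cls, ld_df: pd.DataFrame | None = None, proxy_df: pd.DataFrame | None = None, strict=False):
        """Build from 3-column frames: (id_a, id_b, r2) and (missing_id, proxy_id, r2)."""
        r2 = {}
        if ld_df is not None:
            for a, b, v in ld_df.itertuples(index=False):
                r2[frozenset((a, b))] = float(v)
        proxies: dict[str, list] = {}
        if proxy_df is not None:
            for m, p, v in proxy_df.itertuples(index=False):
                proxies.setdefault(m, []).append((p, float(v)))
        return cls(r2=r2, proxies=proxies, strict=strict)

    @classmethod
    def from_files(cls, ld_path=None, proxy_path=None, strict=False):
        ld_df = pd.read_csv(ld_path, sep="\t") if ld_path else None
        proxy_df = pd.read_csv(proxy_path, sep="\t") if proxy_path else None
        return cls.from_frames(ld_df, proxy_df, strict=strict)


@dataclass
class HarmonisedSet:
    """Exposure and outcome effects aligned to a shared effect allele.

    The estimator input: ``exposure_betas`` / ``exposure_ses`` are
    (n_snps, n_exposures) arrays, ``outcome_betas`` / ``outcome_ses`` are
    vectors, all on the harmonised effect allele.  ``exclusion_log`` maps
    excluded or substituted variants to reasons.
    """

    variant_ids: list[str]
    exposure_names: list[str]
    exposure_betas: np.ndarray
    exposure_ses: np.ndarray
    outcome_betas: np.ndarray
    outcome_ses: np.ndarray
    eafs: np.ndarray
    outcome_name: str = "outcome"
    outcome_type: str = "continuous"
    exposure_n: np.ndarray | None = None
    outcome_n: float | None = None
    case_fraction: float | None = None
    exposure_sds: np.ndarray | None = None
    exclusion_log: dict = field(default_factory=dict)

    def __post_init__(self):
        self.exposure_betas = np.atleast_2d(np.asarray(self.exposure_betas, dtype=float))
        if self.exposure_betas.shape[0] == 1 and len(self.variant_ids) != 1:
            self.exposure_betas = self.exposure_betas.T
        self.exposure_ses = np.atleast_2d(np.asarray(self.exposure_ses, dtype=float))
        if self.exposure_ses.shape != self.exposure_betas.shape:
            self.exposure_ses = self.exposure_ses.T
        self.outcome_betas = np.asarray(self.outcome_betas, dtype=float)
        self.outcome_ses = np.asarray(self.outcome_ses, dtype=float)
        self.eafs = np.asarray(self.eafs, dtype=float)
        k = len(self.variant_ids)
        for arr in (self.outcome_betas, self.outcome_ses, self.eafs):
            if arr.shape[0] != k:
                raise ValueError("all columns must have equal length")
        if self.exposure_betas.shape[0] != k:
            raise ValueError("exposure matrix row count must match variant_ids")
        if np.any(self.exposure_ses <= 0) or np.any(self.outcome_ses <= 0):
            raise ValueError("standard errors must be strictly positive")

    @property
    def n_snps(self) -> int:
        return len(self.variant_ids)

    @property
    def n_exposures(self) -> int:
        return self.exposure_betas.shape[1]

    def single(self, exposure_index: int = 0) -> "HarmonisedSet":
        """View restricted to one exposure column."""
        return replace(
            self,
            exposure_names=[self.exposure_names[exposure_index]],
            exposure_betas=self.exposure_betas[:, [exposure_index]],
            exposure_ses=self.exposure_ses[:, [exposure_index]],
            exposure_n=None if self.exposure_n is None else self.exposure_n[[exposure_index]],
            exposure_sds=None if self.exposure_sds is None else self.exposure_sds[[exposure_index]],
        )

    def subset(self, mask_or_ids, reason: str | None = None) -> "HarmonisedSet":
        """Keep a subset of variants; removed ones are logged with ``reason``."""
        if isinstance(mask_or_ids, (list, set, frozenset)):
            keep_ids = set(mask_or_ids)
            mask = np.array([v in keep_ids for v in self.variant_ids])
        else:
            mask = np.asarray(mask_or_ids, dtype=bool)
        log = dict(self.exclusion_log)
        if reason:
            for vid, m in zip(self.variant_ids, mask):
                if not m:
                    log[vid] = reason
        return replace(
            self,
            variant_ids=[v for v, m in zip(self.variant_ids, mask) if m],
            exposure_betas=self.exposure_betas[mask],
            exposure_ses=self.exposure_ses[mask],
            outcome_betas=self.outcome_betas[mask],
            outcome_ses=self.outcome_ses[mask],
            eafs=self.eafs[mask],
            exclusion_log=log,
        )

    def to_frame(self) -> pd.DataFrame:
        data = {"variant_id": self.variant_ids, "eaf": self.eafs}
        for i, name in enumerate(self.exposure_names):
            data[f"beta_{name}"] = self.exposure_betas[:, i]
            data[f"se_{name}"] = self.exposure_ses[:, i]
        data["beta_outcome"] = self.outcome_betas
        data["se_outcome"] = self.outcome_ses
        return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# instrument selection


def select_instruments(
    table: SummaryStatsTable,
    p_threshold: float = 5e-8,
    replicated_flags: dict | None = None,
) -> list[str]:
    """Variants with p < threshold (and, if flags given, externally
    replicated), sorted by ascending p-value."""
    if len(table) == 0:
        raise ValueError("empty summary-statistics table")
    df = table.df
    keep = df["pvalue"] < p_threshold
    if replicated_flags is not None:
        keep &= df["variant_id"].map(lambda v: bool(replicated_flags.get(v, False)))
    sel = df[keep].sort_values(["pvalue", "variant_id"])
    if sel.empty:
        warnings.warn("no variants pass the instrument-selection threshold")
    return list(sel["variant_id"])


def clump(
    candidates,
    ld: LDReference,
    r2_threshold: float = 0.001,
) -> list[str]:
    """Greedy p-value-ranked LD clumping.

    ``candidates`` is an iterable of (variant_id, pvalue).  Repeatedly the
    lowest-p unclaimed variant becomes an index variant and all unclaimed
    variants with r^2 >= threshold to it are discarded.  Ties are broken
    lexicographically by variant_id so the result is order-independent.
    """
    pool = sorted(candidates, key=lambda t: (t[1], t[0]))
    kept: list[str] = []
    claimed: set[str] = set()
    for vid, _ in pool:
        if vid in claimed:
            continue
        kept.append(vid)
        claimed.add(vid)
        for other, _p in pool:
            if other in claimed:
                continue
            if ld.pair_r2(vid, other) >= r2_threshold:
                claimed.add(other)
    return kept


def merge_exposure_instruments(per_exposure_candidates) -> dict[str, float]:
    """Union instruments over exposures, a shared variant keeping its lowest p.

    ``per_exposure_candidates`` is an iterable of (variant_id, pvalue,
    exposure_name) triples; returns {variant_id: retained p} suitable for
    :func:`clump`.
    """
    merged: dict[str, float] = {}
    seen: set[tuple[str, str]] = set()
    for vid, p, exposure in per_exposure_candidates:
        key = (vid, exposure)
        if key in seen:
            raise ValueError(f"variant {vid} listed twice for exposure {exposure}")
        seen.add(key)
        if vid not in merged or p < merged[vid]:
            merged[vid] = float(p)
    return merged


# ---------------------------------------------------------------------------
# harmonisation


def _orient_outcome(exp_row, out_row, window):
    """Resolve the outcome record orientation against the exposure record.

    Returns (+1/-1, None) on success or (None, reason) on failure.
    """
    ea_e, oa_e = exp_row["effect_allele"], exp_row["other_allele"]
    ea_o, oa_o = out_row["effect_allele"], out_row["other_allele"]
    orient = align_orientation(ea_e, oa_e, ea_o, oa_o)
    if orient is None:
        return None, "allele-mismatch"
    if not is_palindromic(ea_e, oa_e):
        return orient, None
    # palindromic: both orientations are allele-compatible; use frequencies
    f_e, f_o = exp_row["eaf"], out_row["eaf"]
    if pd.isna(f_e) or pd.isna(f_o):
        return None, "palindrome-ambiguous"
    lo, hi = window
    if lo < f_e < hi or lo < f_o < hi:
        return None, "palindrome-ambiguous"
    # minor-allele matching: effect alleles agree when minor allele is on
    # the same side in both datasets
    return (1 if (f_e < 0.5) == (f_o < 0.5) else -1), None


def harmonise(
    exposures: list[SummaryStatsTable],
    outcome: SummaryStatsTable,
    instruments,
    ld: LDReference | None = None,
    palindrome_window: tuple[float, float] = (0.42, 0.58),
    proxy_r2_min: float = 0.8,
) -> HarmonisedSet:
    """Align exposure and outcome records for the chosen instruments.

    For each instrument: variants absent from the outcome GWAS are replaced
    by the best available LD proxy (r^2 >= ``proxy_r2_min``) present in all
    tables, else excluded; non-palindromic variants are aligned by allele
    matching with strand-flip tolerance, flipping the outcome beta and eaf
    when effect/other alleles are swapped; palindromic variants with eaf
    strictly inside ``palindrome_window`` on either side are proxy-
    substituted when possible and otherwise excluded; palindromes outside
    the window are aligned by matching the minor allele across datasets.
    """
    if ld is None:
        ld = LDReference()
    instruments = list(instruments)
    exp_index = [t.df.set_index("variant_id") for t in exposures]
    out_index = outcome.df.set_index("variant_id")
    available = set(out_index.index)
    for idx in exp_index:
        available &= set(idx.index)

    log: dict[str, str] = {}
    rows = []

    def try_variant(vid):
        """Return a harmonised row dict or a terminal reason string."""
        if any(vid not in idx.index for idx in exp_index):
            return "missing-in-exposure"
        if vid not in out_index.index:
            return "missing-in-outcome"
        exp_rows = [idx.loc[vid] for idx in exp_index]
        out_row = out_index.loc[vid]
        ref = exp_rows[0]
        # align the other exposure columns to the first exposure's allele
        bx, sx = [], []
        for er in exp_rows:
            o = align_orientation(ref["effect_allele"], ref["other_allele"], er["effect_allele"], er["other_allele"])
            if o is None:
                return "allele-mismatch"
            if is_palindromic(ref["effect_allele"], ref["other_allele"]) and o == 1:
                # palindromes across exposure files: trust shared reporting
                # only when frequencies agree in minor-allele side
                f_r, f_e = ref["eaf"], er["eaf"]
                if pd.notna(f_r) and pd.notna(f_e) and (f_r < 0.5) != (f_e < 0.5):
                    o = -1
            bx.append(er["beta"] * o)
            sx.append(er["se"])
        orient, reason = _orient_outcome(ref, out_row, palindrome_window)
        if orient is None:
            return reason
        return {
            "bx": bx,
            "sx": sx,
            "by": out_row["beta"] * orient,
            "sy": out_row["se"],
            "eaf": ref["eaf"],
        }

    for vid in instruments:
        res = try_variant(vid)
        if isinstance(res, dict):
            rows.append((vid, res))
            continue
        # terminal for the original id -> attempt a proxy
        proxy = ld.best_proxy(vid, proxy_r2_min, available=available) if res in (
            "missing-in-outcome",
            "palindrome-ambiguous",
        ) else None
        if proxy is not None:
            pid, _r2 = proxy
            pres = try_variant(pid)
            if isinstance(pres, dict):
                log[vid] = f"proxy-substituted:{pid}"
                rows.append((pid, pres))
                continue
        log[vid] = res

    if not rows:
        warnings.warn("harmonisation produced an empty instrument set")
        k, p = 0, len(exposures)
        return HarmonisedSet(
            variant_ids=[],
            exposure_names=[t.trait_name for t in exposures],
            exposure_betas=np.empty((0, p)),
            exposure_ses=np.empty((0, p)),
            outcome_betas=np.empty(0),
            outcome_ses=np.empty(0),
            eafs=np.empty(0),
            outcome_name=outcome.trait_name,
            outcome_type=outcome.trait_type,
            exclusion_log=log,
        )

    vids = [v for v, _ in rows]
    exposure_n = np.array(
        [np.nanmedian(t.df["n"]) if t.df["n"].notna().any() else np.nan for t in exposures]
    )
    out_n = float(np.nanmedian(outcome.df["n"])) if outcome.df["n"].notna().any() else None
    return HarmonisedSet(
        variant_ids=vids,
        exposure_names=[t.trait_name for t in exposures],
        exposure_betas=np.array([r["bx"] for _, r in rows]),
        exposure_ses=np.array([r["sx"] for _, r in rows]),
        outcome_betas=np.array([r["by"] for _, r in rows]),
        outcome_ses=np.array([r["sy"] for _, r in rows]),
        eafs=np.array([r["eaf"] for _, r in rows], dtype=float),
        outcome_name=outcome.trait_name,
        outcome_type=outcome.trait_type,
        exposure_n=exposure_n,
        outcome_n=out_n,
        case_fraction=outcome.case_fraction,
        exposure_sds=np.array([np.nan if t.trait_sd is None else t.trait_sd for t in exposures]),
        exclusion_log=log,
    )


def screen_annotations(
    hset: HarmonisedSet,
    annotations: pd.DataFrame,
    traits: list[str],
    p_threshold: float = 5e-8,
) -> HarmonisedSet:
    """Remove instruments strongly associated with listed secondary traits.

    ``annotations`` is a long table (variant_id, trait, pvalue), e.g. a
    phenome-scan annotation export; variants associated with any listed trait at
    p < threshold are excluded with reason ``annotation-screened``.
    Variants absent from the annotation table pass the screen.
    """
    ann = annotations[annotations["trait"].isin(set(traits))]
    flagged = set(ann.loc[ann["pvalue"] < p_threshold, "variant_id"])
    mask = np.array([v not in flagged for v in hset.variant_ids])
    return hset.subset(mask, reason="annotation-screened")
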