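"""Instrument selection, clumping, and allele harmonisation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from tsmr.harmonise import (
    LDReference,
    align_orientation,
    clump,
    harmonise,
    is_palindromic,
    merge_exposure_instruments,
    screen_annotations,
    select_instruments,
)
from tsmr.sumstats import table_from_frame

from .test_sumstats import make_table


def make_pair(exp_rows, out_rows):
    """Build (exposure table, outcome table) from row dicts."""
    def build(rows, name):
        df = pd.DataFrame(rows)
        df.setdefault = None
        for col, default in [("eaf", np.nan), ("n", 1000.0), ("n_cases", np.nan)]:
            if col not in df:
                df[col] = default
        return table_from_frame(df, name, validate=False)

    return build(exp_rows, "X"), build(out_rows, "Y")


class TestSelect:
    def test_threshold(self):
        t = make_table([0.6, 0.05], [0.1, 0.01])  # p ~ 2e-9, 6e-7
        assert select_instruments(t, 5e-8) == ["rs0"]

    def test_threshold_one_keeps_all(self):
        t = make_table([0.1, 0.2, 0.05], [0.1, 0.1, 0.1])
        assert len(select_instruments(t, 1.0)) == 3

    def test_replication_flags(self):
        t = make_table([0.6, 0.7, 0.8], [0.1, 0.1, 0.1])
        flags = {"rs0": True, "rs1": False, "rs2": True}
        assert select_instruments(t, 5e-8, flags) == ["rs2", "rs1", "rs0"][::2] or \
            select_instruments(t, 5e-8, flags) == ["rs2", "rs0"]

    def test_sorted_by_p(self):
        t = make_table([0.6, 0.9], [0.1, 0.1])
        assert select_instruments(t, 5e-8) == ["rs1", "rs0"]


def brute_force_clump(candidates, r2_lookup, threshold):
    """Independent re-derivation of greedy p-ranked clumping by explicit
    simulation of the claim process over the sorted candidate list."""
    remaining = dict(sorted(candidates, key=lambda t: (t[1], t[0])))
    kept = []
    while remaining:
        index = next(iter(remaining))
        kept.append(index)
        remaining.pop(index)
        for other in list(remaining):
            r2 = r2_lookup.get(frozenset((index, other)), 0.0) if index != other else 1.0
            if r2 >= threshold:
                remaining.pop(other)
    return kept


class TestClump:
    def test_pairwise(self):
        ld = LDReference(r2={frozenset(("a", "b")): 0.5})
        assert clump([("a", 1e-10), ("b", 1e-9)], ld, 0.001) == ["a"]

    def test_independent_all_kept(self):
        ld = LDReference()
        out = clump([("a", 1e-10), ("b", 1e-9), ("c", 1e-8)], ld, 0.001)
        assert out == ["a", "b", "c"]

    def test_matches_brute_force_on_chain(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            ids = [f"v{i}" for i in range(5)]
            ps = rng.uniform(1e-12, 1e-8, size=5)
            r2 = {}
            for a, b in itertools.combinations(ids, 2):
                r2[frozenset((a, b))] = float(rng.choice([0.0, 0.002, 0.5, 0.9]))
            ld = LDReference(r2=r2)
            cands = list(zip(ids, ps))
            expected = brute_force_clump(cands, r2, 0.001)
            assert clump(cands, ld, 0.001) == expected

    def test_order_independent(self):
        rng = np.random.default_rng(6)
        ids = [f"v{i}" for i in range(8)]
        ps = rng.uniform(0, 1, size=8)
        r2 = {frozenset(p): float(rng.choice([0.0, 0.8])) for p in itertools.combinations(ids, 2)}
        ld = LDReference(r2=r2)
        cands = list(zip(ids, ps))
        ref = clump(cands, ld, 0.5)
        for _ in range(5):
            rng.shuffle(cands)
            assert clump(cands, ld, 0.5) == ref

    def test_tie_broken_lexicographically(self):
        ld = LDReference(r2={frozenset(("a", "b")): 0.9})
        assert clump([("b", 0.5), ("a", 0.5)], ld, 0.5) == ["a"]


class TestMerge:
    def test_lower_p_retained(self):
        merged = merge_exposure_instruments([("rs1", 1e-9, "DBP"), ("rs1", 1e-10, "SBP")])
        assert merged == {"rs1": 1e-10}

    def test_disjoint_union(self):
        cands = [(f"a{i}", 1e-9, "SBP") for i in range(3)] + [(f"b{i}", 1e-9, "DBP") for i in range(4)]
        assert len(merge_exposure_instruments(cands)) == 7

    def test_identical_sets_min_p(self):
        cands = [("rs1", 1e-9, "SBP"), ("rs2", 1e-12, "SBP"), ("rs1", 1e-11, "DBP"), ("rs2", 1e-10, "DBP")]
        assert merge_exposure_instruments(cands) == {"rs1": 1e-11, "rs2": 1e-12}

    def test_duplicate_within_exposure_rejected(self):
        with pytest.raises(ValueError):
            merge_exposure_instruments([("rs1", 1e-9, "SBP"), ("rs1", 1e-8, "SBP")])


class TestHarmonise:
    def test_sign_flip_on_swapped_alleles(self):
        exp, out = make_pair(
            [dict(variant_id="rs1", effect_allele="A", other_allele="G", beta=0.1, se=0.01, eaf=0.3)],
            [dict(variant_id="rs1", effect_allele="G", other_allele="A", beta=-0.1, se=0.01, eaf=0.7)],
        )
        h = harmonise([exp], out, ["rs1"])
        assert h.outcome_betas[0] == pytest.approx(0.1)

    def test_strand_flip_aligned(self):
        exp, out = make_pair(
            [dict(variant_id="rs1", effect_allele="A", other_allele="G", beta=0.1, se=0.01, eaf=0.3)],
            [dict(variant_id="rs1", effect_allele="T", other_allele="C", beta=0.2, se=0.01, eaf=0.3)],
        )
        h = harmonise([exp], out, ["rs1"])
        assert h.outcome_betas[0] == pytest.approx(0.2)

    def test_ambiguous_palindrome_excluded(self):
        exp, out = make_pair(
            [dict(variant_id="rs1", effect_allele="A", other_allele="T", beta=0.1, se=0.01, eaf=0.50)],
            [dict(variant_id="rs1", effect_allele="A", other_allele="T", beta=0.1, se=0.01, eaf=0.50)],
        )
        h = harmonise([exp], out, ["rs1"])
        assert h.n_snps == 0
        assert h.exclusion_log["rs1"] == "palindrome-ambiguous"

    def test_window_endpoints_alignable(self):
        # eaf exactly 0.42 sits on the (exclusive) boundary and is usable
        exp, out = make_pair(
            [dict(variant_id="rs1", effect_allele="A", other_allele="T", beta=0.1, se=0.01, eaf=0.42)],
            [dict(variant_id="rs1", effect_allele="A", other_allele="T", beta=0.2, se=0.01, eaf=0.40)],
        )
        h = harmonise([exp], out, ["rs1"])
        assert h.n_snps == 1 and h.outcome_betas[0] == pytest.approx(0.2)

    def test_palindrome_frequency_matching(self):
        # outcome reports the complementary allele: eaf 0.88 vs exposure 0.10
        exp, out = make_pair(
            [dict(variant_id="rs1", effect_allele="A", other_allele="T", beta=0.1, se=0.01, eaf=0.10)],
            [dict(variant_id="rs1", effect_allele="A", other_allele="T", beta=0.3, se=0.01, eaf=0.88)],
        )
        h = harmonise([exp], out, ["rs1"])
        assert h.outcome_betas[0] == pytest.approx(-0.3)

    def test_palindrome_missing_eaf_excluded(self):
        exp, out = make_pair(
            [dict(variant_id="rs1", effect_allele="A", other_allele="T", beta=0.1, se=0.01, eaf=np.nan)],
            [dict(variant_id="rs1", effect_allele="A", other_allele="T", beta=0.3, se=0.01, eaf=0.2)],
        )
        h = harmonise([exp], out, ["rs1"])
        assert h.exclusion_log["rs1"] == "palindrome-ambiguous"

    def test_allele_mismatch_excluded(self):
        exp, out = make_pair(
            [dict(variant_id="rs1", effect_allele="A", other_allele="G", beta=0.1, se=0.01, eaf=0.3)],
            [dict(variant_id="rs1", effect_allele="A", other_allele="C", beta=0.1, se=0.01, eaf=0.3)],
        )
        h = harmonise([exp], out, ["rs1"])
        assert h.exclusion_log["rs1"] == "allele-mismatch"

    def test_proxy_substitution_for_missing(self):
        exp, out = make_pair(
            [
                dict(variant_id="rs1", effect_allele="A", other_allele="G", beta=0.1, se=0.01, eaf=0.3),
                dict(variant_id="rs2", effect_allele="A", other_allele="G", beta=0.09, se=0.01, eaf=0.3),
            ],
            [dict(variant_id="rs2", effect_allele="A", other_allele="G", beta=0.2, se=0.01, eaf=0.3)],
        )
        ld = LDReference(proxies={"rs1": [("rs2", 0.9)]})
        h = harmonise([exp], out, ["rs1"], ld)
        assert h.variant_ids == ["rs2"]
        assert h.exclusion_log["rs1"] == "proxy-substituted:rs2"

    def test_low_r2_proxy_not_used(self):
        exp, out = make_pair(
            [
                dict(variant_id="rs1", effect_allele="A", other_allele="G", beta=0.1, se=0.01, eaf=0.3),
                dict(variant_id="rs2", effect_allele="A", other_allele="G", beta=0.09, se=0.01, eaf=0.3),
            ],
            [dict(variant_id="rs2", effect_allele="A", other_allele="G", beta=0.2, se=0.01, eaf=0.3)],
        )
        ld = LDReference(proxies={"rs1": [("rs2", 0.5)]})
        h = harmonise([exp], out, ["rs1"], ld)
        assert h.n_snps == 0 and h.exclusion_log["rs1"] == "missing-in-outcome"

    def test_outcome_flip_involution(self):
        """Relabelling the outcome's alleles (swap + beta sign + eaf flip)
        leaves the harmonised set unchanged."""
        exp, out = make_pair(
            [
                dict(variant_id="rs1", effect_allele="A", other_allele="G", beta=0.1, se=0.01, eaf=0.3),
                dict(variant_id="rs2", effect_allele="T", other_allele="C", beta=-0.2, se=0.02, eaf=0.6),
            ],
            [
                dict(variant_id="rs1", effect_allele="A", other_allele="G", beta=0.05, se=0.01, eaf=0.3),
                dict(variant_id="rs2", effect_allele="T", other_allele="C", beta=-0.07, se=0.02, eaf=0.6),
            ],
        )
        flipped = out.df.copy()
        flipped[["effect_allele", "other_allele"]] = flipped[["other_allele", "effect_allele"]].values
        flipped["beta"] = -flipped["beta"]
        flipped["eaf"] = 1 - flipped["eaf"]
        out2 = table_from_frame(flipped, "Y", validate=False)
        h1 = harmonise([exp], out, ["rs1", "rs2"])
        h2 = harmonise([exp], out2, ["rs1", "rs2"])
        np.testing.assert_allclose(h1.outcome_betas, h2.outcome_betas)
        np.testing.assert_allclose(h1.exposure_betas, h2.exposure_betas)

    def test_exclusion_accounting(self, default_study):
        """Every instrument ends up harmonised or in the exclusion log."""
        study = default_study
        ids = list(study.per_snp["variant_id"])
        h = harmonise(study.exposures, study.outcomes["lifespan"], ids, study.ld)
        terminal = [v for v, r in h.exclusion_log.items() if not r.startswith("proxy-substituted")]
        proxied = [v for v, r in h.exclusion_log.items() if r.startswith("proxy-substituted")]
        assert h.n_snps + len(terminal) == len(ids)
        assert len(proxied) == len([v for v in h.variant_ids if v.endswith("s1")])


class TestScreen:
    def make_hset(self):
        exp, out = make_pair(
            [dict(variant_id=f"rs{i}", effect_allele="A", other_allele="G", beta=0.1, se=0.01, eaf=0.3) for i in range(3)],
            [dict(variant_id=f"rs{i}", effect_allele="A", other_allele="G", beta=0.05, se=0.01, eaf=0.3) for i in range(3)],
        )
        return harmonise([exp], out, ["rs0", "rs1", "rs2"])

    def test_strong_association_removed(self):
        ann = pd.DataFrame({"variant_id": ["rs0"], "trait": ["BMI"], "pvalue": [1e-9]})
        h = screen_annotations(self.make_hset(), ann, ["BMI"])
        assert "rs0" not in h.variant_ids
        assert h.exclusion_log["rs0"] == "annotation-screened"

    def test_weak_association_kept(self):
        ann = pd.DataFrame({"variant_id": ["rs0"], "trait": ["BMI"], "pvalue": [1e-6]})
        h = screen_annotations(self.make_hset(), ann, ["BMI"])
        assert "rs0" in h.variant_ids

    def test_unlisted_trait_ignored(self):
        ann = pd.DataFrame({"variant_id": ["rs0"], "trait": ["height"], "pvalue": [1e-30]})
        h = screen_annotations(self.make_hset(), ann, ["BMI", "education", "smoking"])
        assert h.n_snps == 3


@pytest.mark.parametrize("a1,a2", [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")])
def test_palindromic_pairs(a1, a2):
    assert is_palindromic(a1, a2)


def test_align_orientation_exhaustive():
    """Orientation agrees with explicit enumeration for every valid pair."""
    bases = "ACGT"
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    for ref_ea, ref_oa, ea, oa in itertools.product(bases, repeat=4):
        if ref_ea == ref_oa or ea == oa:
            continue
        got = align_orientation(ref_ea, ref_oa, ea, oa)
        same = (ea, oa) == (ref_ea, ref_oa) or (comp[ea], comp[oa]) == (ref_ea, ref_oa)
        swapped = (ea, oa) == (ref_oa, ref_ea) or (comp[ea], comp[oa]) == (ref_oa, ref_ea)
        if is_palindromic(ref_ea, ref_oa) and is_palindromic(ea, oa):
            # both orientations are allele-compatible; the caller must
            # resolve by frequency matching, not by allele labels
            if same or swapped:
                assert got in (1, -1)
            else:
                assert got is None
        elif same:
            assert got == 1
        elif swapped:
            assert got == -1
        else:
            assert got is None
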