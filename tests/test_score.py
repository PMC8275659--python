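"""Hydropathy z-scale, per-position scores, ranking, proposals, ss2."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hisol import (
    AlignedFamily,
    FamilySpec,
    KYTE_DOOLITTLE,
    annotate_secondary_structure,
    conservation_rates,
    generate_family,
    hisol_score,
    hisol_table,
    map_target_positions,
    propose_substitution,
    rank_candidates,
    read_ss2,
    ss_summary,
    z_transform_scale,
)
from hisol.msa import AMINO_ACIDS
from hisol.score import _candidate_from_row
from hisol.synthetic import random_target


class TestZTransform:
    def test_kyte_doolittle_moments(self, kd_scale):
        assert kd_scale.mu == pytest.approx(-0.49)
        assert kd_scale.sigma == pytest.approx(2.9113, abs=1e-4)
        z = np.array(list(kd_scale.z.values()))
        assert z.mean() == pytest.approx(0.0, abs=1e-9)
        assert z.std() == pytest.approx(1.0, abs=1e-9)

    def test_reference_z_values(self, kd_scale):
        assert kd_scale.z["I"] == pytest.approx(1.714, abs=1e-3)
        assert kd_scale.z["R"] == pytest.approx(-1.377, abs=1e-3)
        assert kd_scale.z["E"] == pytest.approx(-1.034, abs=1e-3)

    def test_ordering_preserved(self, kd_scale):
        by_raw = sorted(AMINO_ACIDS, key=kd_scale.raw.__getitem__)
        by_z = sorted(AMINO_ACIDS, key=kd_scale.z.__getitem__)
        assert by_raw == by_z

    @given(shift=st.floats(-50, 50, allow_nan=False))
    @settings(max_examples=25, derandomize=True)
    def test_shift_invariance(self, shift):
        shifted = {a: v + shift for a, v in KYTE_DOOLITTLE.items()}
        base = z_transform_scale()
        other = z_transform_scale(shifted)
        for a in AMINO_ACIDS:
            assert other.z[a] == pytest.approx(base.z[a], abs=1e-9)

    def test_degenerate_scale_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            z_transform_scale({a: 1.0 for a in AMINO_ACIDS})

    def test_sample_mode_rescales_only(self):
        pop = z_transform_scale(mode="population")
        smp = z_transform_scale(mode="sample")
        ratio = smp.sigma / pop.sigma
        assert ratio == pytest.approx(np.sqrt(20 / 19))


def _uniform_family(target_row, *homolog_rows):
    ids = ("T",) + tuple(f"h{i}" for i in range(len(homolog_rows)))
    return AlignedFamily(ids, (target_row,) + homolog_rows, "T")


class TestScore:
    def test_self_consensus_scores_zero(self, kd_scale):
        fam = _uniform_family("IKE", "IKE", "IKE", "IKE")
        t = hisol_table(fam, scale=kd_scale)
        assert np.allclose(t["score"], 0.0, atol=1e-12)

    def test_hand_evaluated_two_residue_cases(self, kd_scale):
        # target I over 100% E family: z(I) - z(E) ~ +2.748
        fam = _uniform_family("I", "E", "E", "E", "E")
        t = hisol_table(fam, exclude_target=True, scale=kd_scale)
        assert t.at[1, "score"] == pytest.approx(2.748, abs=1e-3)
        # 50% I / 50% R consensus: z(I) - (z(I)+z(R))/2 ~ +1.546
        fam = _uniform_family("I", "I", "R", "I", "R")
        t = hisol_table(fam, exclude_target=True, scale=kd_scale)
        assert t.at[1, "score"] == pytest.approx(
            kd_scale.z["I"] - 0.5 * (kd_scale.z["I"] + kd_scale.z["R"]), abs=1e-12
        )
        assert t.at[1, "score"] == pytest.approx(1.546, abs=1e-3)

    def test_vectorized_equals_literal_loop(self, kd_scale):
        """Oracle equivalence on 100 seeded random families (10 x 30)."""
        for seed in range(100):
            spec = FamilySpec(
                target_sequence=random_target(30, seed=seed + 1000),
                n_sequences=10,
                conservation=float(np.random.default_rng(seed).uniform(0.2, 0.9)),
                gap_rate=0.05,
                seed=seed,
            )
            fam = generate_family(spec)
            pm = map_target_positions(fam)
            cons = conservation_rates(fam, pm)
            table = hisol_table(cons=cons, positions=pm, scale=kd_scale)
            for j in pm.positions:
                assert table.at[j, "score"] == pytest.approx(
                    hisol_score(j, kd_scale, cons, pm), abs=1e-12
                )

    def test_score_bound(self, kd_scale, small_family):
        zvals = np.array(list(kd_scale.z.values()))
        bound = zvals.max() - zvals.min()
        assert bound == pytest.approx(3.091, abs=1e-3)
        t = hisol_table(small_family, scale=kd_scale)
        assert t["score"].abs().max() <= bound + 1e-12

    def test_antisymmetry_on_swap(self, kd_scale):
        """Swapping target residue with a fully conserved family residue
        negates the score."""
        fam_fwd = _uniform_family("I", "E", "E", "E")
        fam_rev = _uniform_family("E", "I", "I", "I")
        s_fwd = hisol_table(fam_fwd, exclude_target=True, scale=kd_scale).at[1, "score"]
        s_rev = hisol_table(fam_rev, exclude_target=True, scale=kd_scale).at[1, "score"]
        assert s_fwd == pytest.approx(-s_rev, abs=1e-12)

    def test_uniform_family_consensus_term_vanishes(self, kd_scale):
        """Under an i.i.d. uniform family the consensus -> mean(z) = 0, so the
        score tends to z(target residue)."""
        target = "IWKRG"
        spec = FamilySpec(
            target_sequence=target,
            n_sequences=5000,
            conservation=1.0 / 20.0,  # uniform: consensus kept at 1/20 too
            seed=21,
        )
        fam = generate_family(spec)
        t = hisol_table(fam, exclude_target=True, scale=kd_scale)
        for j, aa in enumerate(target, start=1):
            assert t.at[j, "score"] == pytest.approx(kd_scale.z[aa], abs=0.1)

    def test_rank_abs_is_permutation(self, small_family):
        t = hisol_table(small_family)
        assert sorted(t["rank_abs"]) == list(range(1, len(t) + 1))


class TestRanking:
    def test_tiny_enumeration(self):
        t = pd.DataFrame(
            {"score": [2.0, -1.0, 0.5], "wt": ["I", "E", "A"],
             "proposal": ["E", "I", "G"], "proposal_rate_pct": [50.0] * 3},
            index=pd.Index([1, 2, 3], name="position"),
        )
        cands = rank_candidates(t, n_positive=1, n_negative=1)
        assert [c.position for c in cands] == [1, 2]
        assert [c.direction for c in cands] == ["to-hydrophilic", "to-hydrophobic"]

    def test_all_positive_gives_empty_negative_list(self, caplog):
        t = pd.DataFrame(
            {"score": [1.0, 2.0], "wt": ["I", "L"],
             "proposal": ["E", "D"], "proposal_rate_pct": [50.0, 60.0]},
            index=pd.Index([1, 2], name="position"),
        )
        with caplog.at_level("WARNING", logger="hisol.score"):
            cands = rank_candidates(t, n_positive=10, n_negative=10)
        assert all(c.score > 0 for c in cands)
        assert "negative" in caplog.text

    def test_matches_brute_force_sort_and_slice(self):
        rng = np.random.default_rng(33)
        scores = rng.normal(0, 1.2, size=300)
        t = pd.DataFrame(
            {"score": scores, "wt": ["A"] * 300,
             "proposal": ["G"] * 300, "proposal_rate_pct": [10.0] * 300},
            index=pd.Index(range(1, 301), name="position"),
        )
        cands = rank_candidates(t, 10, 10)
        pos = sorted((s, j) for j, s in zip(t.index, scores) if s > 0)[-10:]
        neg = sorted((s, j) for j, s in zip(t.index, scores) if s < 0)[:10]
        expected = {j for _, j in pos} | {j for _, j in neg}
        assert {c.position for c in cands} == expected
        # each sign block ordered by descending |score|
        half = [abs(c.score) for c in cands[:10]]
        assert half == sorted(half, reverse=True)
        half = [abs(c.score) for c in cands[10:]]
        assert half == sorted(half, reverse=True)


class TestProposals:
    def _table_for(self, fam):
        pm = map_target_positions(fam)
        cons = conservation_rates(fam, pm, exclude_target=True)
        return cons, pm, hisol_table(cons=cons, positions=pm)

    def test_argmax_conservation(self):
        fam = _uniform_family("I", "E", "E", "E", "E", "E", "E", "E", "E", "E", "I")
        cons, pm, t = self._table_for(fam)
        cand = propose_substitution(1, cons, t)
        assert cand.proposed == "E"
        assert cand.mutation == "I1E"
        assert cand.proposal_rate_pct == pytest.approx(90.0)

    def test_alphabetical_tie_break(self):
        fam = _uniform_family("V", "A", "G", "A", "G")
        cons, pm, t = self._table_for(fam)
        assert propose_substitution(1, cons, t).proposed == "A"

    def test_wild_type_never_proposed(self, small_family):
        t = hisol_table(small_family)
        bad = t[(t["proposal"] != "") & (t["proposal"] == t["wt"])]
        assert bad.empty

    def test_no_family_support(self):
        fam = _uniform_family("I", "I", "I", "I")
        cons, pm, t = self._table_for(fam)
        cand = propose_substitution(1, cons, t)
        assert cand.proposed is None
        assert cand.reason == "no family support"


SS2_HEADER = "# PSIPRED VFORMAT (PSIPRED V4.0)\n\n"


def _write_ss2(path, states, residues=None):
    lines = [SS2_HEADER]
    for i, s in enumerate(states, start=1):
        aa = (residues or "A" * len(states))[i - 1]
        conf = {"C": "1.000 0.000 0.000", "H": "0.000 1.000 0.000",
                "E": "0.000 0.000 1.000"}[s]
        lines.append(f"{i:>4d} {aa} {s}   {conf}\n")
    path.write_text("".join(lines))


class TestSecondaryStructure:
    def test_parse_and_annotate(self, tmp_path):
        p = tmp_path / "t.ss2"
        _write_ss2(p, "HEC")
        ss2 = read_ss2(p)
        assert list(ss2["state"]) == ["H", "E", "C"]
        t = pd.DataFrame(
            {"score": [1.0, -0.5, 0.2], "wt": list("IEA"),
             "proposal": list("EIG"), "proposal_rate_pct": [50.0] * 3},
            index=pd.Index([1, 2, 3], name="position"),
        )
        out = annotate_secondary_structure(t, ss2)
        assert list(out["ss"]) == ["H", "E", "C"]

    def test_no_ss2_is_noop(self):
        t = pd.DataFrame({"score": [1.0]}, index=pd.Index([1], name="position"))
        assert "ss" not in annotate_secondary_structure(t, None).columns

    def test_length_mismatch_raises(self, tmp_path):
        p = tmp_path / "t.ss2"
        _write_ss2(p, "HEC")
        t = pd.DataFrame({"score": [1.0]}, index=pd.Index([1], name="position"))
        with pytest.raises(ValueError, match="length mismatch"):
            annotate_secondary_structure(t, read_ss2(p))

    def test_summary_percentages(self):
        # 20 candidates: 9 strand, 6 coil, 5 helix -> 45 / 30 / 25 %
        states = ["E"] * 9 + ["C"] * 6 + ["H"] * 5
        rows = [
            _candidate_from_row(
                j,
                pd.Series({"score": 1.0, "wt": "I", "proposal": "E",
                           "proposal_rate_pct": 50.0, "ss": s}),
            )
            for j, s in enumerate(states, start=1)
        ]
        summary = ss_summary(rows)
        assert summary["strand_pct"] == pytest.approx(45.0)
        assert summary["coil_pct"] == pytest.approx(30.0)
        assert summary["helix_pct"] == pytest.approx(25.0)

    def test_all_coil(self):
        rows = [
            _candidate_from_row(
                1,
                pd.Series({"score": 1.0, "wt": "I", "proposal": "E",
                           "proposal_rate_pct": 50.0, "ss": "C"}),
            )
        ]
        assert ss_summary(rows)["coil_pct"] == 100.0
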