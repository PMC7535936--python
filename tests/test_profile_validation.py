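"""Progressive alignment, emission profiles, profile-profile search,
reciprocal best hits, and lineage-set correction."""

import numpy as np
import pytest

from cladespec import profile_validation as pv
from cladespec import synthetic_data as sd
from cladespec import taxonomy_filters as tf


def indicator_profile(og_id, seq, background=None):
    """Profile with unsmoothed one-hot emissions (alpha=0 single sequence)."""
    msa = pv.MultipleAlignment(og_id, {f"{og_id}_row": seq})
    return pv.build_profile(msa, alpha=0.0)


def random_family_profiles(rng, n_profiles, n_rows=5, length=80, alpha=1.0):
    out = []
    for k in range(n_profiles):
        base = rng.integers(0, 20, size=length)
        rows = {}
        for r in range(n_rows):
            seq = base.copy()
            hit = rng.random(length) < 0.1
            seq[hit] = (seq[hit] + rng.integers(1, 20, size=int(hit.sum()))) % 20
            rows[f"p{k}r{r}"] = "".join(sd.AMINO_ACIDS[a] for a in seq)
        out.append(pv.build_profile(pv.MultipleAlignment(f"P{k}", rows), alpha=alpha))
    return out


def dp_oracle(S, gap_open, gap_extend, local):
    """Brute-force recursive Gotoh oracle for small score matrices."""
    import functools
    n1, n2 = S.shape
    NEG = -1e30

    @functools.lru_cache(maxsize=None)
    def best(i, j, state):
        # state: 0 = last was match/start, 1 = gap consuming axis2, 2 = gap axis1
        if i == 0 and j == 0:
            return 0.0 if state == 0 else NEG
        vals = [NEG]
        if state == 0:
            if i > 0 and j > 0:
                vals.append(max(best(i - 1, j - 1, s) for s in (0, 1, 2)) + S[i - 1, j - 1])
            if local:
                vals.append(0.0)
        elif state == 1 and j > 0:
            vals.append(best(i, j - 1, 0) - gap_open)
            vals.append(best(i, j - 1, 1) - gap_extend)
        elif state == 2 and i > 0:
            vals.append(best(i - 1, j, 0) - gap_open)
            vals.append(best(i - 1, j, 2) - gap_extend)
        return max(vals)

    if local:
        return max(
            max(best(i, j, s) for s in (0, 1, 2))
            for i in range(n1 + 1) for j in range(n2 + 1)
        )
    return max(best(n1, n2, s) for s in (0, 1, 2))


class TestAffineDp:
    @pytest.mark.parametrize("local", [False, True])
    def test_matches_recursive_oracle(self, local):
        rng = np.random.default_rng(21)
        for _ in range(15):
            n1, n2 = rng.integers(2, 7, size=2)
            S = rng.normal(0, 2, size=(int(n1), int(n2)))
            score, ops = pv._affine_dp(S, 3.0, 0.3, local=local)
            assert score == pytest.approx(dp_oracle(S, 3.0, 0.3, local), abs=1e-9)
            # traceback reproduces the score
            replay = sum(S[i, j] for op, i, j in ops if op == "M")
            gaps = [op for op, _, _ in ops if op != "M"]
            run_cost = 0.0
            prev = None
            for op, i, j in ops:
                if op == "M":
                    prev = "M"
                elif op == prev:
                    run_cost += 0.3
                else:
                    run_cost += 3.0
                    prev = op
            if not local or ops:
                assert replay - run_cost == pytest.approx(score, abs=1e-9)


class TestBuildMsa:
    def test_identical_sequences_gapless(self):
        seqs = {f"s{i}": "ACDEFGHIKL" * 4 for i in range(4)}
        msa = pv.build_msa("OG_1", seqs)
        assert msa.n_columns == 40
        assert all("-" not in row for row in msa.rows.values())

    def test_single_insertion_one_gap_column(self):
        a = "ACDEFGHIKLMNPQRSTVWYACDEFGHIKL"
        b = a[:12] + "W" + a[12:]
        msa = pv.build_msa("OG_1", {"a": a, "b": b})
        assert msa.n_columns == 31
        assert msa.rows["a"].count("-") == 1
        assert msa.rows["b"].count("-") == 0

    def test_structural_properties(self, small_simulation):
        proteomes, truth = small_simulation
        seqs = {rid: s for t in proteomes for rid, s in proteomes[t]}
        fam = truth.families["F0000"]
        members = {m: seqs[m] for m in fam.members[:8]}
        msa = pv.build_msa("OG_1", members)
        assert set(msa.rows) == set(members)
        assert msa.n_columns >= max(len(s) for s in members.values())
        msa.validate()

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            pv.build_msa("OG_1", {})

    def test_aligned_fasta_output(self, tmp_path):
        msa = pv.build_msa("OG_1", {"a": "ACDEFGHIKL" * 8, "b": "ACDEFGHIKL" * 8})
        path = tmp_path / "aln.fasta"
        pv.write_aligned_fasta(msa, path)
        text = path.read_text()
        assert text.count(">") == 2
        assert max(len(l) for l in text.splitlines()) <= 60


class TestBuildProfile:
    def test_single_sequence_alpha_zero_indicator(self):
        p = indicator_profile("OG_1", "ACDE")
        assert p.L == 4
        expected = np.zeros((4, 20))
        for i, aa in enumerate("ACDE"):
            expected[i, sd.AMINO_ACIDS.index(aa)] = 1.0
        np.testing.assert_allclose(p.emissions, expected)

    def test_emissions_normalized(self, small_simulation):
        proteomes, truth = small_simulation
        seqs = {rid: s for t in proteomes for rid, s in proteomes[t]}
        fam = truth.families["F0001"]
        msa = pv.build_msa("OG_1", {m: seqs[m] for m in fam.members[:6]})
        p = pv.build_profile(msa, alpha=1.0)
        np.testing.assert_allclose(p.emissions.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(p.background.sum(), 1.0, atol=1e-9)

    def test_five_row_toy_matches_hand_computation(self):
        # 5 rows, 2 columns; second column has one gap
        rows = {"r1": "AC", "r2": "AC", "r3": "AD", "r4": "AC", "r5": "A-"}
        msa = pv.MultipleAlignment("OG_1", rows)
        p = pv.build_profile(msa, alpha=1.0)
        # background from all 9 residues: A:5, C:3, D:1
        f = {"A": 5 / 9, "C": 3 / 9, "D": 1 / 9}
        # column 1: counts A=5, n=5 -> (5 + f)/6 for A, (0 + f)/6 otherwise
        a = sd.AMINO_ACIDS.index("A")
        c = sd.AMINO_ACIDS.index("C")
        d = sd.AMINO_ACIDS.index("D")
        col1 = np.zeros(20)
        col1[a], col1[c], col1[d] = (5 + f["A"]) / 6, f["C"] / 6, f["D"] / 6
        np.testing.assert_allclose(p.emissions[0], col1 / col1.sum(), atol=1e-12)
        # column 2: counts C=3, D=1, n=4 -> (c + f)/5
        col2 = np.zeros(20)
        col2[a], col2[c], col2[d] = f["A"] / 5, (3 + f["C"]) / 5, (1 + f["D"]) / 5
        np.testing.assert_allclose(p.emissions[1], col2 / col2.sum(), atol=1e-12)
        # both columns occupied >= 50%
        assert p.L == 2

    def test_low_occupancy_columns_skipped(self):
        rows = {"r1": "A-", "r2": "A-", "r3": "A-", "r4": "AC", "r5": "A-"}
        p = pv.build_profile(pv.MultipleAlignment("OG_1", rows))
        assert p.L == 1

    def test_profile_file_roundtrip(self, tmp_path):
        p = indicator_profile("OG_9", "ACDEFGHIKL")
        path = tmp_path / "profile.tsv"
        pv.write_profile(p, path)
        loaded = pv.read_profile(path)
        assert loaded.og_id == "OG_9"
        np.testing.assert_allclose(loaded.emissions, p.emissions, atol=1e-6)


class TestProfileSearch:
    def test_self_is_top_hit(self):
        rng = np.random.default_rng(30)
        profiles = random_family_profiles(rng, 5)
        hits = pv.profile_search(profiles[0], profiles)
        assert hits[0].subject == profiles[0].og_id

    def test_split_family_halves_are_mutual_top_hits(self, small_simulation):
        proteomes, truth = small_simulation
        seqs = {rid: s for t in proteomes for rid, s in proteomes[t]}
        profiles = []
        for fam_id in ("F0002", "F0003", "F0004"):
            members = sorted(truth.families[fam_id].members)
            half = len(members) // 2
            for tag, part in (("a", members[:half]), ("b", members[half:])):
                msa = pv.build_msa(f"{fam_id}{tag}", {m: seqs[m] for m in part})
                profiles.append(pv.build_profile(msa))
        ranked = pv.all_vs_all_profile_search(profiles)
        rbh = pv.reciprocal_best_hits(ranked)
        assert rbh == {("F0002a", "F0002b"), ("F0003a", "F0003b"), ("F0004a", "F0004b")}

    def test_score_symmetric(self):
        rng = np.random.default_rng(31)
        a, b = random_family_profiles(rng, 2)
        s_ab, _ = pv.profile_pair_score(a, b)
        s_ba, _ = pv.profile_pair_score(b, a)
        assert s_ab == pytest.approx(s_ba, abs=1e-9)

    def test_self_score_is_maximal(self):
        rng = np.random.default_rng(32)
        profiles = random_family_profiles(rng, 6)
        for p in profiles:
            self_score, _ = pv.profile_pair_score(p, p)
            for q in profiles:
                if q.og_id != p.og_id:
                    other, _ = pv.profile_pair_score(p, q)
                    assert self_score >= other

    def test_empty_db_rejected(self):
        rng = np.random.default_rng(33)
        p, = random_family_profiles(rng, 1)
        with pytest.raises(ValueError):
            pv.profile_search(p, [])

    def test_unrelated_profiles_below_calibrated_threshold(self):
        rng = np.random.default_rng(34)
        calib = random_family_profiles(rng, 12)
        threshold = pv.calibrate_score_threshold(calib, n_trials=100, seed=0,
                                                 n_comparisons=66)
        below = 0
        for _ in range(40):
            a, b = random_family_profiles(rng, 2)
            s, _ = pv.profile_pair_score(a, b)
            below += s < threshold
        assert below >= 38  # >= 95%


class TestRbhAndCorrection:
    def _hits(self, pairs):
        out = {}
        for q, ranked in pairs.items():
            out[q] = [pv.ProfileHit(q, s, score, 30) for s, score in ranked]
        return out

    def test_symmetric_pair(self):
        hits = self._hits({"A": [("A", 99), ("B", 50)], "B": [("B", 99), ("A", 50)]})
        assert pv.reciprocal_best_hits(hits) == {("A", "B")}

    def test_asymmetric_chain_no_rbh(self):
        hits = self._hits({
            "A": [("B", 50)], "B": [("C", 60), ("A", 50)], "C": [("B", 60)]})
        assert pv.reciprocal_best_hits(hits) == {("B", "C")}

    def test_candidate_with_outside_partner_removed(self, taxonomy, tree):
        cnidarian = min(tree.species_below(tree.clade_labels["Cnidaria"]))
        insect = min(tree.species_below(tree.clade_labels["Insecta"]))
        fish = min(tree.species_below(tree.clade_labels["Gnathostomata"]))
        og_species = {"OG_1": {insect, fish}, "OG_2": {cnidarian},
                      "OG_3": {insect, fish}}
        verdicts = pv.correct_lineage_set(
            ["OG_1", "OG_3"], {("OG_1", "OG_2")}, og_species, taxonomy, "Bilateria")
        by_id = {v.og_id: v for v in verdicts}
        assert by_id["OG_1"].status == "removed_ancient"
        assert by_id["OG_1"].partner == "OG_2"
        assert by_id["OG_3"].status == "retained"

    def test_partner_inside_focal_clade_retained(self, taxonomy, tree):
        insect = min(tree.species_below(tree.clade_labels["Insecta"]))
        fish = min(tree.species_below(tree.clade_labels["Gnathostomata"]))
        og_species = {"OG_1": {insect, fish}, "OG_2": {fish}}
        verdicts = pv.correct_lineage_set(
            ["OG_1"], {("OG_1", "OG_2")}, og_species, taxonomy, "Bilateria")
        assert verdicts[0].status == "retained"
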