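"""Filtering cascade: each rule against enumeration/brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from grazeniche.filtering import (
    assign_taxa,
    bray_curtis_matrix,
    denoise_single_mismatch,
    discard_low_count_replicates,
    greedy_centroid_cluster,
    length_filter,
    merge_replicates,
    min_read_filter,
    remove_contaminants,
    remove_tag_leaks,
    run_filter_cascade,
)
from grazeniche.simulate import SimulationConfig, simulate_diets, simulate_reads

from conftest import build_table

RNG = np.random.default_rng(123)
BASES = "ACGT"


def _random_seq(length, rng=RNG):
    return "".join(rng.choice(list(BASES), size=length))


def _mutate(seq, k, rng=RNG):
    pos = rng.choice(len(seq), size=k, replace=False)
    out = list(seq)
    for p in pos:
        out[p] = BASES[(BASES.index(out[p]) + 1 + rng.integers(3)) % 4]
    return "".join(out)


# ---------------------------------------------------------------------------
# single-rule unit tests on tiny tables
# ---------------------------------------------------------------------------


def _tiny(seqs, cells, wells=None):
    wells = wells or {"w1": {"sample_id": "S1"}}
    return build_table(cells, wells, seqs)


class TestLengthFilter:
    def test_boundaries_are_inclusive(self):
        seqs = {
            "a": _random_seq(9),
            "b": _random_seq(10),
            "c": _random_seq(220),
            "d": _random_seq(221),
        }
        t = _tiny(seqs, {(s, "w1"): 100 for s in seqs})
        out = length_filter(t)
        assert set(out.counts["sequence_id"]) == {"b", "c"}

    def test_toy_survivor_count(self):
        seqs = {f"s{i}": _random_seq(n) for i, n in enumerate([8, 10, 100, 220, 300])}
        t = _tiny(seqs, {(s, "w1"): 50 for s in seqs})
        out = length_filter(t)
        assert len(set(out.counts["sequence_id"])) == 3

    def test_idempotent(self):
        seqs = {"a": _random_seq(8), "b": _random_seq(60)}
        t = _tiny(seqs, {(s, "w1"): 50 for s in seqs})
        once = length_filter(t)
        twice = length_filter(once)
        pd.testing.assert_frame_equal(once.counts, twice.counts)

    def test_bad_range(self):
        t = _tiny({"a": _random_seq(60)}, {("a", "w1"): 5})
        with pytest.raises(ValueError, match="min_len"):
            length_filter(t, min_len=100, max_len=50)


class TestMinReadFilter:
    def test_strict_below_threshold(self):
        seqs = {"a": _random_seq(60), "b": _random_seq(60)}
        t = _tiny(seqs, {("a", "w1"): 9, ("b", "w1"): 10})
        out = min_read_filter(t, threshold=10)
        assert set(out.counts["sequence_id"]) == {"b"}

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        seqs = {f"s{i}": _random_seq(60, rng) for i in range(6)}
        wells = {f"w{j}": {"sample_id": f"S{j}"} for j in range(4)}
        cells = {
            (s, w): int(rng.integers(0, 30))
            for s in seqs
            for w in wells
            if rng.random() < 0.8
        }
        cells = {k: v for k, v in cells.items() if v > 0}
        t = build_table(cells, wells, seqs)
        out = min_read_filter(t, threshold=10)
        expected = {k for k, v in cells.items() if v >= 10}
        got = set(zip(out.counts["sequence_id"], out.counts["well_id"]))
        assert got == expected


def _lev(a, b):
    # independent Levenshtein oracle (plain DP)
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


class TestDenoise:
    def test_single_mismatch_merges_into_abundant(self):
        a = _random_seq(60)
        seqs = {"big": a, "small": _mutate(a, 1)}
        t = _tiny(seqs, {("big", "w1"): 1000, ("small", "w1"): 10})
        out = denoise_single_mismatch(t)
        assert set(out.counts["sequence_id"]) == {"big"}
        assert out.counts["read_count"].sum() == 1010

    def test_two_mismatches_untouched(self):
        a = _random_seq(60)
        seqs = {"big": a, "small": _mutate(a, 2)}
        t = _tiny(seqs, {("big", "w1"): 1000, ("small", "w1"): 10})
        out = denoise_single_mismatch(t)
        assert set(out.counts["sequence_id"]) == {"big", "small"}

    def test_chain_matches_bruteforce_oracle(self):
        # 8 sequences containing a 3-step single-mismatch chain
        rng = np.random.default_rng(17)
        base = _random_seq(70, rng)
        s1 = _mutate(base, 1, rng)
        s2 = _mutate(s1, 1, rng)
        s3 = _mutate(s2, 1, rng)
        seqs = {"c0": base, "c1": s1, "c2": s2, "c3": s3}
        for i in range(4):
            seqs[f"r{i}"] = _random_seq(70, rng)
        totals = {"c0": 5000, "c1": 500, "c2": 50, "c3": 5,
                  "r0": 900, "r1": 80, "r2": 40, "r3": 20}
        t = _tiny(seqs, {(s, "w1"): n for s, n in totals.items()})
        out = denoise_single_mismatch(t)
        # oracle: process descending abundance; merge into the root of the
        # most abundant strictly-greater edit-distance-1 neighbour
        order = sorted(totals, key=lambda s: (-totals[s], seqs[s]))
        parent = {}

        def root(s):
            while s in parent:
                s = parent[s]
            return s

        for sid in order:
            cands = [
                o for o in totals
                if totals[o] > totals[sid] and _lev(seqs[sid], seqs[o]) == 1
            ]
            if cands:
                best = min(cands, key=lambda o: (-totals[o], seqs[o]))
                parent[sid] = root(best)
        expected = {}
        for sid, n in totals.items():
            expected[root(sid)] = expected.get(root(sid), 0) + n
        got = dict(zip(out.counts["sequence_id"], out.counts["read_count"]))
        assert got == expected

    def test_read_mass_conserved(self, study):
        t = min_read_filter(length_filter(study.reads))
        out = denoise_single_mismatch(t)
        assert out.total_reads == t.total_reads


def _lev_fast(a, b):
    # independent vectorized Levenshtein DP (row-wise, no edlib)
    A = np.frombuffer(a.encode(), dtype=np.uint8)
    B = np.frombuffer(b.encode(), dtype=np.uint8)
    m = len(B)
    idx = np.arange(m + 1)
    prev = idx.astype(np.int32).copy()
    for i in range(len(A)):
        d = np.empty(m + 1, dtype=np.int32)
        d[0] = i + 1
        d[1:] = np.minimum(prev[:-1] + (A[i] != B), prev[1:] + 1)
        prev = np.minimum.accumulate(d - idx) + idx
    return int(prev[-1])


def _oracle_identity(a, b):
    # test inputs are equal-length substitution families, so the global
    # alignment length equals the sequence length
    assert len(a) == len(b)
    return (len(a) - _lev_fast(a, b)) / len(a)


class TestClustering:
    def test_identical_sequences_form_one_otu(self):
        s = _random_seq(80)
        t = _tiny({"a": s, "b": s}, {("a", "w1"): 100, ("b", "w1"): 50})
        out = greedy_centroid_cluster(t)
        assert len(out.otus) == 1
        assert out.total_reads == 150

    def test_distant_sequences_stay_apart(self):
        t = _tiny(
            {"a": "A" * 40, "b": "A" * 20 + "C" * 20},
            {("a", "w1"): 100, ("b", "w1"): 50},
        )
        out = greedy_centroid_cluster(t)
        assert len(out.otus) == 2

    @pytest.mark.parametrize("block", range(5))
    def test_matches_bruteforce_oracle_across_seeds(self, block):
        # 100 seeds total: 4 base sequences, each with variants at 1-2
        # substitutions (inside the 97% radius) and 8-12 (outside)
        for seed in range(block * 20, block * 20 + 20):
            rng = np.random.default_rng(seed)
            seqs, totals = {}, {}
            i = 0
            for _ in range(4):
                base = _random_seq(90, rng)
                fam = [base] + [
                    _mutate(base, int(k), rng) for k in rng.choice(
                        [1, 1, 2, 8, 10, 12], size=4, replace=False)
                ]
                for s in fam:
                    seqs[f"q{i}"] = s
                    totals[f"q{i}"] = int(rng.integers(10, 10000))
                    i += 1
            t = _tiny(seqs, {(s, "w1"): n for s, n in totals.items()})
            out = greedy_centroid_cluster(t)
            got = out.counts.set_index("otu_id")["read_count"].to_dict()
            # oracle: same abundance order, brute-force max-match alignment
            order = sorted(totals, key=lambda s: (-totals[s], seqs[s]))
            centroids, assign = [], {}
            for sid in order:
                for cid in centroids:
                    if _oracle_identity(seqs[sid], seqs[cid]) >= 0.97:
                        assign[sid] = cid
                        break
                else:
                    centroids.append(sid)
                    assign[sid] = sid
            expected = {}
            for sid, n in totals.items():
                expected[assign[sid]] = expected.get(assign[sid], 0) + n
            assert got == expected, f"seed {seed}"

    def test_read_mass_conserved(self, study):
        t = denoise_single_mismatch(min_read_filter(length_filter(study.reads)))
        out = greedy_centroid_cluster(t)
        assert out.total_reads == t.total_reads


class TestAssignTaxa:
    def _refs(self, rng):
        return {f"ref{i}": _random_seq(80, rng) for i in range(4)}

    def test_exact_match_gets_identity_one(self):
        rng = np.random.default_rng(21)
        refs = self._refs(rng)
        t = _tiny({"o1": refs["ref2"]}, {("o1", "w1"): 100})
        out = assign_taxa(greedy_centroid_cluster(t), refs)
        assert out.otus["taxon"].iloc[0] == "ref2"
        assert out.otus["identity"].iloc[0] == 1.0

    def test_low_identity_removed(self):
        rng = np.random.default_rng(22)
        refs = self._refs(rng)
        t = _tiny({"o1": _mutate(refs["ref0"], 8, rng)}, {("o1", "w1"): 100})
        out = assign_taxa(greedy_centroid_cluster(t), refs)
        assert len(out.otus) == 0

    def test_best_hit_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(23)
        refs = self._refs(rng)
        otus = {}
        for i in range(6):
            ref = list(refs)[i % 4]
            otus[f"o{i}"] = _mutate(refs[ref], int(rng.integers(0, 3)), rng)
        t = _tiny(otus, {(o, "w1"): 100 + i for i, o in enumerate(otus)})
        out = assign_taxa(greedy_centroid_cluster(t), refs, min_identity=0.0)
        for oid, row in out.otus.iterrows():
            scores = {r: _oracle_identity(row["centroid"], s)
                      for r, s in refs.items()}
            assert row["taxon"] == max(scores, key=scores.get)


def _control_wells():
    return {
        "S1_r1": {"sample_id": "S1"},
        "S1_r2": {"sample_id": "S1"},
        "blank1": {"control_type": "blank"},
        "ext1": {"control_type": "extraction"},
    }


class TestContaminantRemoval:
    def test_blank_only_otu_removed(self):
        seqs = {"good": _random_seq(60), "bad": _random_seq(60)}
        cells = {("good", "S1_r1"): 1000, ("good", "S1_r2"): 900,
                 ("bad", "blank1"): 50}
        t = build_table(cells, _control_wells(), seqs)
        out = remove_contaminants(greedy_centroid_cluster(t))
        assert list(out.otus["centroid"]) == [seqs["good"]]

    def test_otu_absent_from_controls_retained(self):
        seqs = {"good": _random_seq(60)}
        cells = {("good", "S1_r1"): 1000}
        t = build_table(cells, _control_wells(), seqs)
        out = remove_contaminants(greedy_centroid_cluster(t))
        assert len(out.otus) == 1

    def test_no_controls_warns_and_returns_unchanged(self, caplog):
        seqs = {"good": _random_seq(60)}
        t = build_table({("good", "w1"): 10}, {"w1": {"sample_id": "S1"}}, seqs)
        otus = greedy_centroid_cluster(t)
        with caplog.at_level("WARNING", logger="grazeniche.filtering"):
            out = remove_contaminants(otus)
        assert "no control wells" in caplog.text
        assert len(out.otus) == 1

    def test_planted_contaminant_removed_with_truth_kept(self, community):
        census = pd.DataFrame(
            [(sp, 2018, "October", n) for sp, n in
             (("cattle", 200), ("horse", 500), ("red_deer", 2000),
              ("greylag_goose", 9000), ("barnacle_goose", 20000))],
            columns=["species", "year", "season", "count"],
        )
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            cfg = SimulationConfig(seed=seed, contamination_rate=0.05,
                                   n_samples_per_species_year=4)
            meta, diets = simulate_diets(census, community, cfg, years=(2018,))
            reads = simulate_reads(meta, diets, community, cfg)
            otus, prof = run_filter_cascade(
                reads, community.reference_sequences()
            )
            taxa = set(otus.otus["taxon"])
            ok = not any(t.startswith("contaminant") for t in taxa)
            ok &= set(community.taxon_ids) <= taxa
            hits += ok
        assert hits >= 0.95 * n_seeds


class TestTagLeakRemoval:
    def test_empty_blanks_leave_table_unchanged(self):
        seqs = {"a": _random_seq(60)}
        cells = {("a", "S1_r1"): 1000, ("a", "S1_r2"): 900}
        t = build_table(cells, _control_wells(), seqs)
        otus = greedy_centroid_cluster(t)
        out = remove_tag_leaks(otus)
        pd.testing.assert_frame_equal(
            out.counts.reset_index(drop=True), otus.counts.reset_index(drop=True)
        )

    def test_cell_below_tau_zeroed(self):
        # OTU holds 0.01% of its library total in a well; blanks put tau at
        # 0.1% -> the cell is zeroed
        seqs = {"a": _random_seq(60)}
        cells = {("a", "S1_r1"): 98_890, ("a", "S1_r2"): 10, ("a", "blank1"): 100}
        t = build_table(cells, _control_wells(), seqs)
        out = remove_tag_leaks(greedy_centroid_cluster(t))
        kept = set(out.counts["well_id"])
        assert kept == {"S1_r1"}

    def test_switched_cells_zeroed_true_cells_kept(self):
        # designed ground truth: two samples with disjoint diets in one
        # library; any taxon-B read in sample A's wells is a tag leak
        n_seeds = 20
        taxa = {"ta": _random_seq(60), "tb": _random_seq(60)}
        leak_zeroed, true_lost, true_total, leak_total = 0, 0, 0, 0
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            wells = {}
            for s, n in (("A", 2), ("B", 2)):
                for r in range(n):
                    wells[f"{s}_r{r}"] = {"sample_id": s}
            for b in range(4):
                wells[f"blank{b}"] = {"control_type": "blank"}
            cells = {}
            rate = 0.005
            depth = 200_000
            for wid, metaw in wells.items():
                for tid in taxa:
                    own = metaw.get("sample_id") == ("A" if tid == "ta" else "B")
                    lam = depth * (1 - rate) if own else depth * 2 * rate / 8
                    c = int(rng.poisson(lam))
                    if c > 0:
                        cells[(tid, wid)] = c
            t = build_table(cells, wells, taxa)
            out = remove_tag_leaks(greedy_centroid_cluster(t))
            kept = set(zip(out.counts["otu_id"].map(
                out.otus["centroid"].to_dict()), out.counts["well_id"]))

            def is_true(tid, wid):
                sid = wells[wid].get("sample_id")
                return sid == ("A" if tid == "ta" else "B")

            for (tid, wid) in cells:
                key = (taxa[tid], wid)
                if is_true(tid, wid):
                    true_total += 1
                    true_lost += key not in kept
                elif wells[wid].get("sample_id") is not None:
                    leak_total += 1
                    leak_zeroed += key not in kept
        assert leak_zeroed >= 0.9 * leak_total
        assert true_lost <= 0.01 * true_total


class TestReplicateFilterAndMerge:
    def test_zero_threshold_keeps_everything(self):
        seqs = {"a": _random_seq(60)}
        cells = {("a", "S1_r1"): 3}
        t = build_table(cells, _control_wells(), seqs)
        otus = greedy_centroid_cluster(t)
        out = discard_low_count_replicates(otus, 0)
        assert set(out.wells.index) == set(otus.wells.index)

    def test_shallow_well_dropped_matches_enumeration(self):
        rng = np.random.default_rng(31)
        seqs = {f"s{i}": _random_seq(60, rng) for i in range(3)}
        wells = {f"w{j}": {"sample_id": f"S{j}"} for j in range(5)}
        cells = {(s, w): int(rng.integers(5, 80)) for s in seqs for w in wells}
        t = build_table(cells, wells, seqs)
        out = discard_low_count_replicates(greedy_centroid_cluster(t), 100)
        well_tot = {}
        for (s, w), c in cells.items():
            well_tot[w] = well_tot.get(w, 0) + c
        expected = {w for w, tot in well_tot.items() if tot >= 100}
        assert set(out.wells.index) == expected

    def test_foo_and_rra_arithmetic(self):
        rng = np.random.default_rng(33)
        ta, tb, tc = (_random_seq(60, rng) for _ in range(3))
        wells = {f"S1_r{i}": {"sample_id": "S1"} for i in range(1, 5)}
        # taxon B present in 2 of 4 replicates; taxon C has within-replicate
        # proportions (0.2, 0.4, 0.0, 0.4)
        cells = {
            ("ta", "S1_r1"): 700, ("tb", "S1_r1"): 100, ("tc", "S1_r1"): 200,
            ("ta", "S1_r2"): 500, ("tb", "S1_r2"): 100, ("tc", "S1_r2"): 400,
            ("ta", "S1_r3"): 1000,
            ("ta", "S1_r4"): 600, ("tc", "S1_r4"): 400,
        }
        t = build_table(cells, wells, {"ta": ta, "tb": tb, "tc": tc})
        refs = {"A": ta, "B": tb, "C": tc}
        otus = assign_taxa(greedy_centroid_cluster(t), refs)
        prof = merge_replicates(discard_low_count_replicates(otus, 0))
        assert prof.foo.loc["S1", "B"] == pytest.approx(0.5)
        assert prof.rra.loc["S1", "C"] == pytest.approx(0.25)
        assert prof.rra.sum(axis=1).iloc[0] == pytest.approx(1.0, abs=1e-9)
        assert (prof.pa == (prof.foo > 0).astype(int)).all().all()


class TestBrayCurtis:
    def _profiles(self, mat):
        from grazeniche.filtering import DietProfiles

        df = pd.DataFrame(mat, columns=["t1", "t2", "t3"])
        df.index = [f"s{i}" for i in range(len(df))]
        meta = pd.DataFrame({
            "sample_id": df.index, "species": "cattle", "year": 2018,
            "subarea": 1, "n_replicates_retained": 4,
        })
        return DietProfiles(pa=(df > 0).astype(int), foo=df, rra=df, meta=meta)

    def test_identical_vectors_give_zero(self):
        p = self._profiles([[0.5, 0.5, 0.0], [0.5, 0.5, 0.0]])
        assert bray_curtis_matrix(p).iloc[0, 1] == pytest.approx(0.0)

    def test_disjoint_supports_give_one(self):
        p = self._profiles([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
        assert bray_curtis_matrix(p).iloc[0, 1] == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        p = self._profiles([[0.5, 0.5, 0.0], [0.5, 0.0, 0.5]])
        assert bray_curtis_matrix(p).iloc[0, 1] == pytest.approx(0.5)


class TestEndToEnd:
    def test_noise_free_pipeline_recovers_preference(self, community):
        # all noise off, near-infinite concentration, deep replicates:
        # recovered RRA must match the species preference vector within
        # multinomial sampling error
        from grazeniche.simulate import species_preferences

        census = pd.DataFrame(
            [(sp, 2018, "October", n) for sp, n in
             (("cattle", 200), ("horse", 500), ("red_deer", 2000),
              ("greylag_goose", 9000), ("barnacle_goose", 20000))],
            columns=["species", "year", "season", "count"],
        )
        cfg = SimulationConfig(
            seed=2, contamination_rate=0.0, tag_switch_rate=0.0, junk_rate=0.0,
            diet_concentration=1e9, n_samples_per_species_year=3,
            reads_per_replicate=100_000,
        )
        meta, diets = simulate_diets(census, community, cfg, years=(2018,))
        reads = simulate_reads(meta, diets, community, cfg)
        _, prof = run_filter_cascade(reads, community.reference_sequences())
        prefs = species_preferences(community, seed=cfg.seed)
        for sid in prof.rra.index:
            sp = prof.meta.set_index("sample_id").loc[sid, "species"]
            tv = 0.5 * float(
                (prof.rra.loc[sid].reindex(prefs.columns, fill_value=0.0)
                 - prefs.loc[sp]).abs().sum()
            )
            assert tv < 0.02
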