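"""ddG matrices, candidate selection, multi-mutant design."""

import itertools

import numpy as np
import pytest

from mutbind import conservation as cons
from mutbind import mutscan as ms
from mutbind import synthdata as sd


def tiny_matrix(values):
    """Build a DdgMatrix from {(mut_str, iface, etype): value}."""
    entries = {(ms.Mutation.parse(m), i, e): v for (m, i, e), v in values.items()}
    ifaces = tuple(dict.fromkeys(i for _, i, _ in entries))
    return ms.DdgMatrix(entries=entries, interface_ids=ifaces)


def flat_profile(positions, fraction=0.3):
    return cons.ConservationProfile(
        reference_id="REF",
        positions={p: ("A", fraction, "A") for p in positions},
    )


class TestMutationTypes:
    def test_parse_and_str(self):
        m = ms.Mutation.parse("N96W")
        assert (m.position, m.wt, m.mut) == (96, "N", "W")
        assert str(m) == "N96W"

    def test_wt_equals_mut_rejected(self):
        with pytest.raises(ValueError):
            ms.Mutation(position=5, wt="A", mut="A")

    def test_multimutation_duplicate_position_rejected(self):
        with pytest.raises(ValueError):
            ms.MultiMutation(frozenset({ms.Mutation.parse("N96W"), ms.Mutation.parse("N96F")}))

    def test_multimutation_parse_plus_or_semicolon(self):
        a = ms.MultiMutation.parse("N70G+S95R+H222R")
        b = ms.MultiMutation.parse("S95R;H222R;N70G")
        assert a == b
        assert str(a) == "N70G;S95R;H222R"


class TestLoadDdgTsv:
    HEADER = "position\twt\tmut\tinterface_id\tenergy_type\tddg_kj_mol\n"

    def _write(self, path, rows):
        path.write_text(self.HEADER + "".join("\t".join(map(str, r)) + "\n" for r in rows))

    def test_counting(self, tmp_path):
        rows = [(70, "N", "G", i, e, -1.0)
                for i in ("i1", "i2") for e in ("stability", "affinity")]
        rows += [(95, "S", "R", i, e, 2.0)
                 for i in ("i1", "i2") for e in ("stability", "affinity")]
        path = tmp_path / "m.tsv"
        self._write(path, rows)
        m = ms.load_ddg_tsv(path)
        assert len(m.entries) == 8
        assert m.interface_ids == ("i1", "i2")

    def test_duplicate_row_raises(self, tmp_path):
        rows = [(70, "N", "G", "i1", "affinity", -1.0)] * 2
        path = tmp_path / "dup.tsv"
        self._write(path, rows)
        with pytest.raises(ValueError, match="duplicate"):
            ms.load_ddg_tsv(path)

    def test_unknown_energy_type_raises(self, tmp_path):
        path = tmp_path / "bad.tsv"
        self._write(path, [(70, "N", "G", "i1", "entropy", -1.0)])
        with pytest.raises(ValueError, match="energy_type"):
            ms.load_ddg_tsv(path)

    def test_non_numeric_ddg_raises(self, tmp_path):
        path = tmp_path / "nan.tsv"
        self._write(path, [(70, "N", "G", "i1", "affinity", "oops")])
        with pytest.raises(ValueError, match="non-numeric"):
            ms.load_ddg_tsv(path)

    def test_kcal_conversion(self, tmp_path):
        path = tmp_path / "kcal.tsv"
        self._write(path, [(70, "N", "G", "i1", "affinity", -1.0)])
        m = ms.load_ddg_tsv(path, kcal=True)
        assert next(iter(m.entries.values())) == pytest.approx(-4.184)

    def test_generator_matrix_roundtrips_bit_exactly(self, tmp_path):
        matrix, _ = sd.make_ddg_matrix(3, {10: "A", 40: "G"},
                                       planted_stabilizing=["A10W"])
        path = tmp_path / "gen.tsv"
        ms.write_ddg_tsv(matrix, path)
        back = ms.load_ddg_tsv(path)
        assert back.entries == matrix.entries
        assert set(back.interface_ids) == set(matrix.interface_ids)


class TestEnsembleAverage:
    def test_identical_snapshots(self):
        m = tiny_matrix({("N70G", "i1", "affinity"): -2.0,
                         ("N70G", "i1", "stability"): -1.0})
        mean, sdev = ms.ensemble_average([m, m, m])
        assert mean.entries == m.entries
        assert all(v == 0.0 for v in sdev.entries.values())

    def test_two_snapshot_mean(self):
        a = tiny_matrix({("N65R", "i1", "affinity"): -5.0})
        b = tiny_matrix({("N65R", "i1", "affinity"): 17.0})
        mean, _ = ms.ensemble_average([a, b])
        assert mean.entries[(ms.Mutation.parse("N65R"), "i1", "affinity")] == pytest.approx(6.0)

    def test_key_mismatch_raises(self):
        a = tiny_matrix({("N65R", "i1", "affinity"): 1.0})
        b = tiny_matrix({("N70G", "i1", "affinity"): 1.0})
        with pytest.raises(ValueError):
            ms.ensemble_average([a, b])

    def test_matches_two_pass_oracle(self):
        rng = np.random.default_rng(0)
        key = ("K115Y", "i1", "affinity")
        vals = rng.normal(0, 3, 100)
        mats = [tiny_matrix({key: float(v)}) for v in vals]
        mean, sdev = ms.ensemble_average(mats)
        k = (ms.Mutation.parse("K115Y"), "i1", "affinity")
        assert mean.entries[k] == pytest.approx(vals.mean(), rel=1e-12)
        assert sdev.entries[k] == pytest.approx(vals.std(), rel=1e-12)

    def test_linearity(self):
        rng = np.random.default_rng(1)
        key = ("S95R", "i1", "stability")
        vals = rng.normal(0, 2, 10)
        mats = [tiny_matrix({key: float(v)}) for v in vals]
        scaled = [tiny_matrix({key: float(3 * v)}) for v in vals]
        k = (ms.Mutation.parse("S95R"), "i1", "stability")
        m1, _ = ms.ensemble_average(mats)
        m3, _ = ms.ensemble_average(scaled)
        assert m3.entries[k] == pytest.approx(3 * m1.entries[k], rel=1e-12)


class TestBestWorst:
    def _matrix(self, vals, mut="N96W"):
        return tiny_matrix({(mut, f"i{j+1}", "affinity"): v for j, v in enumerate(vals)})

    def test_best_is_most_negative(self):
        m = self._matrix([-9.9, -8.0, -7.2, -6.5])
        best, worst = ms.summarize_best_worst(m, ms.Mutation.parse("N96W"), "affinity")
        assert best == pytest.approx(-9.9)
        assert worst == pytest.approx(-6.5)

    def test_all_equal(self):
        m = self._matrix([2.0, 2.0, 2.0, 2.0])
        best, worst = ms.summarize_best_worst(m, ms.Mutation.parse("N96W"), "affinity")
        assert best == worst == pytest.approx(2.0)

    def test_destabilize_least_positive(self):
        m = self._matrix([6.7, 8.0, 9.2, 7.1], mut="H222D")
        best, worst = ms.summarize_best_worst(
            m, ms.Mutation.parse("H222D"), "affinity", mode="destabilize")
        assert best == pytest.approx(6.7)
        assert worst == pytest.approx(9.2)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_sort_oracle(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.normal(0, 5, 4).tolist()
        m = self._matrix(vals)
        best, worst = ms.summarize_best_worst(m, ms.Mutation.parse("N96W"), "affinity")
        assert best == pytest.approx(sorted(vals)[0])
        assert worst == pytest.approx(sorted(vals)[-1])

    def test_missing_interface_raises(self):
        m = tiny_matrix({("N96W", "i1", "affinity"): -1.0,
                         ("N96F", "i1", "affinity"): -1.0,
                         ("N96F", "i2", "affinity"): -1.0})
        with pytest.raises(KeyError):
            m.values(ms.Mutation.parse("N96W"), "affinity")


def selection_oracle(matrix, profile, criteria):
    """Brute-force triple-loop filter over mutations/interfaces/types."""
    selected = set()
    for mut in matrix.mutations:
        ok = True
        for iface in matrix.interface_ids:
            aff = matrix.entries[(mut, iface, "affinity")]
            stab = matrix.entries[(mut, iface, "stability")]
            if criteria.mode == "stabilize":
                if not (aff < criteria.affinity_threshold and stab < criteria.stability_threshold):
                    ok = False
            else:
                if not (aff > 0 and stab < 0):
                    ok = False
        if criteria.mode == "stabilize" and profile is not None:
            if profile.fraction(mut.position) > criteria.conservation_threshold:
                ok = False
        if ok:
            selected.add(mut)
    return selected


class TestSelectCandidates:
    def _planted(self, conservation=0.3):
        matrix = tiny_matrix({
            ("N96W", f"i{j}", e): -5.0
            for j in range(1, 5) for e in ("affinity", "stability")
        } | {
            ("N65R", f"i{j}", e): (-5.0 if j < 4 else 2.0)
            for j in range(1, 5) for e in ("affinity", "stability")
        })
        profile = cons.ConservationProfile(
            reference_id="REF",
            positions={96: ("N", conservation, "N"), 65: ("N", 0.3, "N")},
        )
        return matrix, profile

    def test_all_interface_favorable_selected(self):
        matrix, profile = self._planted()
        report = ms.select_candidates(matrix, profile, ms.SelectionCriteria())
        assert report.selected == [ms.Mutation.parse("N96W")]

    def test_conserved_position_rejected_with_provenance(self):
        matrix, profile = self._planted(conservation=0.70)
        report = ms.select_candidates(matrix, profile, ms.SelectionCriteria())
        row = report.row(ms.Mutation.parse("N96W"))
        assert not row.passed
        assert row.checks["not_conserved"] is False

    def test_three_of_four_interfaces_rejected(self):
        matrix, profile = self._planted()
        report = ms.select_candidates(matrix, profile, ms.SelectionCriteria())
        row = report.row(ms.Mutation.parse("N65R"))
        assert not row.passed
        assert row.checks["affinity_all_interfaces"] is False

    def test_unmapped_position_raises(self):
        matrix, _ = self._planted()
        profile = cons.ConservationProfile("REF", {96: ("N", 0.3, "N")})
        with pytest.raises(ValueError, match="not covered"):
            ms.select_candidates(matrix, profile, ms.SelectionCriteria())

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        positions = {int(p): "A" for p in rng.choice(range(10, 90), 6, replace=False)}
        matrix, _ = sd.make_ddg_matrix(
            seed, positions,
            planted_stabilizing=[f"A{p}W" for p in list(positions)[:2]],
            background_per_position=3,
        )
        profile = flat_profile({m.position for m in matrix.mutations},
                               fraction=float(rng.uniform(0.1, 0.9)))
        criteria = ms.SelectionCriteria(
            conservation_threshold=0.65,
            affinity_threshold=float(rng.normal(0, 1)),
            stability_threshold=float(rng.normal(0, 1)),
        )
        report = ms.select_candidates(matrix, profile, criteria)
        assert set(report.selected) == selection_oracle(matrix, profile, criteria)

    def test_destabilize_mode(self):
        matrix = tiny_matrix(
            {("H222D", f"i{j}", "affinity"): 5.0 for j in range(1, 5)}
            | {("H222D", f"i{j}", "stability"): -2.0 for j in range(1, 5)}
            | {("N96W", f"i{j}", e): -5.0 for j in range(1, 5)
               for e in ("affinity", "stability")}
        )
        report = ms.select_candidates(
            matrix, None, ms.SelectionCriteria(mode="destabilize"))
        assert report.selected == [ms.Mutation.parse("H222D")]

    def test_invariant_to_interface_and_row_order(self, tmp_path):
        matrix, _ = sd.make_ddg_matrix(5, {10: "A", 30: "C"},
                                       planted_stabilizing=["A10W"])
        profile = flat_profile({m.position for m in matrix.mutations})
        base = ms.select_candidates(matrix, profile, ms.SelectionCriteria())
        # permute interface declaration order and entry insertion order
        perm = ms.DdgMatrix(
            entries=dict(sorted(matrix.entries.items(), key=lambda kv: str(kv[0])[::-1])),
            interface_ids=matrix.interface_ids[::-1],
        )
        again = ms.select_candidates(perm, profile, ms.SelectionCriteria())
        assert again.selected == base.selected

    def test_loosening_thresholds_never_shrinks_selection(self):
        matrix, _ = sd.make_ddg_matrix(8, {10: "A", 30: "C", 55: "G"},
                                       planted_stabilizing=["A10W", "C30W"])
        profile = flat_profile({m.position for m in matrix.mutations})
        tight = ms.select_candidates(
            matrix, profile, ms.SelectionCriteria(affinity_threshold=-2.0))
        loose = ms.select_candidates(
            matrix, profile, ms.SelectionCriteria(affinity_threshold=2.0))
        assert set(tight.selected) <= set(loose.selected)

    def test_ranking_by_best_affinity_then_position(self):
        matrix = tiny_matrix(
            {("A10W", f"i{j}", e): -3.0 for j in range(1, 5)
             for e in ("affinity", "stability")}
            | {("C30W", f"i{j}", e): -8.0 for j in range(1, 5)
               for e in ("affinity", "stability")}
        )
        profile = flat_profile({10, 30})
        report = ms.select_candidates(matrix, profile, ms.SelectionCriteria())
        assert [str(m) for m in report.selected] == ["C30W", "A10W"]


class TestDesignCombinations:
    def test_three_compatible_singles_give_four_multis(self):
        s, _ = sd.make_toy_complex(1, n_receptor_res=120, n_interface=0)
        singles = [ms.Mutation.parse("A10W"), ms.Mutation.parse("A50W"),
                   ms.Mutation.parse("A100W")]
        combos = ms.design_combinations(singles, s, chain_id="R",
                                        min_seq_sep=25, min_spatial_sep=20.0)
        assert len(combos) == 4
        orders = sorted(len(c.mutations) for c in combos)
        assert orders == [2, 2, 2, 3]

    def test_spatially_close_pair_not_emitted(self):
        s, _ = sd.make_toy_complex(1, n_receptor_res=120, n_interface=0)
        # 3.8 A spacing: positions 2 apart are ~7.6 A apart in space
        singles = [ms.Mutation.parse("A10W"), ms.Mutation.parse("A12W")]
        combos = ms.design_combinations(singles, s, chain_id="R",
                                        min_seq_sep=1, min_spatial_sep=20.0)
        assert combos == []

    def test_sequence_separation_enforced(self):
        s, _ = sd.make_toy_complex(1, n_receptor_res=120, n_interface=0)
        singles = [ms.Mutation.parse("A10W"), ms.Mutation.parse("A20W")]
        combos = ms.design_combinations(singles, s, chain_id="R",
                                        min_seq_sep=25, min_spatial_sep=2.0)
        assert combos == []

    def test_position_absent_raises(self):
        s, _ = sd.make_toy_complex(1, n_receptor_res=20, n_interface=0)
        with pytest.raises(ValueError, match="absent"):
            ms.design_combinations([ms.Mutation.parse("A99W")], s, chain_id="R")

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_power_set_oracle(self, seed):
        rng = np.random.default_rng(seed)
        s, _ = sd.make_toy_complex(seed, n_receptor_res=150, n_interface=0)
        positions = sorted(rng.choice(range(1, 151), 5, replace=False).tolist())
        singles = [ms.Mutation(position=p, wt="A", mut="W") for p in positions]
        seq_sep, sp_sep = 20, 25.0
        combos = ms.design_combinations(singles, s, chain_id="R",
                                        min_seq_sep=seq_sep, min_spatial_sep=sp_sep)

        ca = {m: s.residue("R", m.position).atom("CA").coords for m in singles}
        ok = lambda a, b: (abs(a.position - b.position) >= seq_sep
                           and float(np.linalg.norm(ca[a] - ca[b])) > sp_sep)
        oracle = set()
        for order in (2, 3):
            for combo in itertools.combinations(singles, order):
                if all(ok(a, b) for a, b in itertools.combinations(combo, 2)):
                    oracle.add(ms.MultiMutation(frozenset(combo)))
        assert set(combos) == oracle


def test_report_serialization(tmp_path):
    matrix, _ = sd.make_ddg_matrix(9, {10: "A", 40: "G"}, planted_stabilizing=["A10W"])
    profile = flat_profile({m.position for m in matrix.mutations})
    report = ms.select_candidates(matrix, profile, ms.SelectionCriteria())
    report.to_tsv(tmp_path / "r.tsv")
    report.to_json(tmp_path / "r.json")
    import json

    payload = json.loads((tmp_path / "r.json").read_text())
    assert payload["selected"] == ["A10W"]
    assert (tmp_path / "r.tsv").read_text().startswith("mutation\t")
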